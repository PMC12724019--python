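"""Per-event morphology and per-electrode feature aggregation.

Each detected event is characterized by four morphological features:
duration (ms), maximum spectral power (uV^2), frequency at maximum power
(Hz), and normalized spectral entropy. Power is estimated with a multitaper
time-frequency transform on 200-ms windows and a 5-Hz frequency grid over
the 80-500 Hz analysis band, sliding sample by sample (1 ms at 1 kHz).

Spectral entropy is the Shannon entropy of the event's normalized power
distribution over the N frequency bins,

    H = -sum_i P(f_i) * log2(P(f_i) + eps),     H_norm = H / log2(N),

so H_norm in [0, 1]: 0 for power concentrated in a single band (a pure
oscillation), 1 for a flat spectrum (broadband, spike-like). The spectrum
fed to the entropy is the time-averaged power over the event's extent.

Electrode-level rows aggregate events to the seven model features: rate
(events/min), median duration, median power, median frequency, median
entropy, anatomical region, and patient age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import dpss

from .montage import map_pair_values_to_contacts

__all__ = [
    "TfMap",
    "multitaper_tf",
    "max_power_and_peak_freq",
    "normalized_entropy",
    "event_feature_table",
    "aggregate_electrode",
    "electrode_feature_table",
    "cohort_feature_table",
    "training_table",
]

ENTROPY_EPS = 1e-12
FEATURE_COLUMNS = ["rate", "duration", "power", "freq", "entropy", "region", "age"]


@dataclass
class TfMap:
    """Multitaper power map over (frequency bin x sample time), in uV^2."""

    power: np.ndarray  # (n_freq, n_time), >= 0
    freqs: np.ndarray  # bin centers, Hz
    times: np.ndarray  # sample indices into the source signal
    window_ms: float


def _freq_grid(fs: float, band=(80.0, 500.0), step: float = 5.0) -> np.ndarray:
    high = min(float(band[1]), fs / 2.0)
    return np.arange(float(band[0]), high + 1e-9, step)


def multitaper_tf(
    signal,
    onset: int,
    offset: int,
    fs: float,
    band=(80.0, 500.0),
    window_ms: float = 200.0,
    freq_step: float = 5.0,
    time_bandwidth: float = 2.0,
    n_tapers: int = 3,
) -> TfMap:
    """Multitaper time-frequency power around one event.

    A ``window_ms`` DPSS-tapered window is centered on every sample in
    ``[onset, offset)``; power is evaluated by direct DFT on the 5-Hz
    frequency grid and averaged over tapers. The signal is reflection-padded
    so events near the epoch edges keep full window support; events whose
    own extent leaves the epoch are rejected.
    """
    x = np.asarray(signal, dtype=float)
    if not 0 <= onset < offset <= x.size:
        raise ValueError("event bounds must lie within the epoch")
    n_win = int(round(window_ms * fs / 1000.0)) | 1  # odd, centered
    half = n_win // 2
    xp = np.pad(x, half, mode="reflect")
    segments = sliding_window_view(xp, n_win)[onset:offset]  # (T, n_win)

    freqs = _freq_grid(fs, band, freq_step)
    t = np.arange(n_win) / fs
    basis = np.exp(-2j * np.pi * np.outer(freqs, t))  # (n_freq, n_win)
    tapers = dpss(n_win, time_bandwidth, Kmax=n_tapers)  # (K, n_win), unit energy

    power = np.zeros((freqs.size, offset - onset))
    for h in tapers:
        spec = basis @ (segments * h).T  # (n_freq, T)
        power += (spec.real**2 + spec.imag**2)
    # one-sided PSD scaling, averaged over tapers, times the 5-Hz bin width
    power *= 2.0 / (fs * n_tapers) * freq_step
    return TfMap(power=power, freqs=freqs, times=np.arange(onset, offset), window_ms=window_ms)


def max_power_and_peak_freq(tf: TfMap, bounds: tuple[int, int] | None = None):
    """Maximum power over the event's cells and its frequency bin center.

    ``bounds`` restricts the time axis (sample indices, half-open) to the
    event; ties in power are broken toward the lower frequency bin.
    """
    power = tf.power
    if bounds is not None:
        a, b = bounds
        sel = (tf.times >= a) & (tf.times < b)
        if not sel.any():
            raise ValueError("empty event bounds")
        power = power[:, sel]
    if power.size == 0:
        raise ValueError("empty event bounds")
    i_f, _ = np.unravel_index(int(np.argmax(power)), power.shape)
    return float(power.max()), float(tf.freqs[i_f])


def normalized_entropy(spectrum, eps: float = ENTROPY_EPS) -> float:
    """Normalized spectral entropy H_norm = H / log2(N) in [0, 1].

    ``spectrum`` is the per-bin power of one event (time-averaged over its
    extent); it is normalized to sum to one before the Shannon sum. An
    all-zero spectrum is undefined and returns NaN with a warning.
    """
    p = np.asarray(spectrum, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("spectrum must be a vector over N >= 2 bins")
    if (p < 0).any():
        raise ValueError("spectral power must be nonnegative")
    total = p.sum()
    if total == 0:
        warnings.warn("all-zero spectrum: entropy undefined", RuntimeWarning)
        return float("nan")
    p = p / total
    h = -np.sum(p * np.log2(p + eps))
    return float(np.clip(h / np.log2(p.size), 0.0, 1.0))


def event_feature_table(
    signal,
    events,
    fs: float,
    band=(80.0, 500.0),
    window_ms: float = 200.0,
    freq_step: float = 5.0,
) -> pd.DataFrame:
    """Morphological features for a list of ``(onset, offset)`` events on one
    channel. Events that leave the epoch are flagged with missing features."""
    rows = []
    n = np.asarray(signal).size
    for onset, offset in events:
        row = {
            "onset": int(onset),
            "offset": int(offset),
            "duration_ms": (offset - onset) / fs * 1000.0,
            "max_power_uv2": np.nan,
            "peak_freq_hz": np.nan,
            "entropy": np.nan,
        }
        if 0 <= onset < offset <= n:
            tf = multitaper_tf(signal, onset, offset, fs, band, window_ms, freq_step)
            row["max_power_uv2"], row["peak_freq_hz"] = max_power_and_peak_freq(tf)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                row["entropy"] = normalized_entropy(tf.power.mean(axis=1))
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["onset", "offset", "duration_ms", "max_power_uv2", "peak_freq_hz", "entropy"]
    )


def aggregate_electrode(event_features: pd.DataFrame, epoch_minutes: float) -> dict:
    """Aggregate one electrode's events to the model features.

    rate = count / epoch_minutes; morphology medians over the electrode's
    events. Zero-event electrodes keep rate 0 with NaN morphology (the
    missingness is passed through to the tree model, which handles it
    natively; dropping such electrodes would bias toward high-rate sites).
    """
    if epoch_minutes <= 0:
        raise ValueError("epoch_minutes must be positive")
    n = len(event_features)
    if n == 0:
        return {"rate": 0.0, "duration": np.nan, "power": np.nan, "freq": np.nan, "entropy": np.nan}
    return {
        "rate": n / epoch_minutes,
        "duration": float(event_features["duration_ms"].median()),
        "power": float(event_features["max_power_uv2"].median()),
        "freq": float(event_features["peak_freq_hz"].median()),
        "entropy": float(event_features["entropy"].median()),
    }


def _site_group(row) -> str:
    if row["soz"]:
        return "soz"
    if row["spiking"]:
        return "spiking"
    if row["resected"]:
        return "resected_other"
    return "non_epileptic"


def electrode_feature_table(
    events: pd.DataFrame,
    montaged_channels: pd.DataFrame,
    electrodes: pd.DataFrame,
    epoch_minutes: float,
    age: float,
    patient: str,
    detector: str,
) -> pd.DataFrame:
    """Per-electrode feature rows for one patient and one detector.

    ``events`` carries per-event morphology on montaged channel names
    (subdural contacts and depth bipolar pairs). Pair-level statistics are
    mapped back to depth contacts by averaging adjacent pairs. One row per
    non-excluded electrode; electrodes absent from the montage metadata
    raise an error naming the channel.
    """
    known = set(montaged_channels["name"])
    unknown = set(events["channel"]) - known
    if unknown:
        raise ValueError(f"events on channels without metadata: {sorted(unknown)}")

    per_channel: dict[str, dict] = {}
    grouped = dict(tuple(events.groupby("channel"))) if len(events) else {}
    empty = events.iloc[0:0]
    for name in montaged_channels["name"]:
        per_channel[name] = aggregate_electrode(grouped.get(name, empty), epoch_minutes)

    stat_names = ["rate", "duration", "power", "freq", "entropy"]
    rows = []
    elec = electrodes[~electrodes["excluded"].astype(bool)]
    sub = elec[elec["kind"] == "subdural"]
    for _, e in sub.iterrows():
        if e["name"] not in per_channel:
            continue
        rows.append({"channel": e["name"], **per_channel[e["name"]], **_meta_fields(e)})

    for shaft_id, grp in elec[elec["kind"] == "depth"].groupby("shaft_id"):
        grp = grp.sort_values("contact_index")
        names = grp["name"].tolist()
        mapped = {}
        for stat in stat_names:
            pair_vals = {ch: v[stat] for ch, v in per_channel.items()}
            mapped[stat] = map_pair_values_to_contacts(pair_vals, names)
        for _, e in grp.iterrows():
            rows.append(
                {
                    "channel": e["name"],
                    **{stat: mapped[stat][e["name"]] for stat in stat_names},
                    **_meta_fields(e),
                }
            )

    out = pd.DataFrame(rows)
    out.insert(0, "patient", patient)
    out.insert(2, "detector", detector)
    out["age"] = float(age)
    return out


def _meta_fields(e) -> dict:
    group = _site_group(e)
    return {
        "region": e["region"],
        "site_group": group,
        "label": {"soz": 1.0, "non_epileptic": 0.0}.get(group, np.nan),
    }


def cohort_feature_table(
    events: pd.DataFrame, cohort_meta: dict, epoch_minutes: float
) -> dict[str, pd.DataFrame]:
    """Cohort-level feature tables, one per detector (never pooled).

    ``cohort_meta`` maps patient id to a dict with keys ``montaged``
    (montaged channel table), ``electrodes`` (original electrode table) and
    ``age``.
    """
    tables: dict[str, pd.DataFrame] = {}
    for detector, det_events in events.groupby("detector"):
        parts = []
        for patient, meta in cohort_meta.items():
            ev = det_events[det_events["patient"] == patient]
            parts.append(
                electrode_feature_table(
                    ev,
                    meta["montaged"],
                    meta["electrodes"],
                    epoch_minutes,
                    meta["age"],
                    patient,
                    detector,
                )
            )
        tables[detector] = pd.concat(parts, ignore_index=True)
    return tables


def training_table(table: pd.DataFrame) -> pd.DataFrame:
    """Restrict a feature table to labeled training rows.

    Training uses SOZ versus non-epileptic sites only; spiking-only and
    resected-but-not-SOZ electrodes are excluded from the label set.
    """
    return table[table["label"].notna()].reset_index(drop=True)
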