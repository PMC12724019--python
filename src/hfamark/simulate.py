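"""Synthetic iEEG cohort generator.

Emulates the data a desk-scale HFA biomarker study needs: multichannel
non-REM iEEG epochs (5 or 20 minutes at 1,000 Hz) with subdural and depth
channels, ground-truth high-frequency events of three morphological classes
(narrow-band oscillation, broadband spike, spike-oscillation complex), SOZ /
spiking / resected / excluded site labels at ~16.8% SOZ prevalence, the ten
standard-care clinical covariates, and an ILAE class-1 outcome generated
through a logistic link on the true per-patient biomarker difference so that
outcome-model recovery is testable.

Background activity is pink noise (spectral exponent ~1) plus one slow-wave
component, standing in for non-REM sleep. Site-class effect directions
(SOZ sites: higher rate, higher power, higher amplitude, more
spike-oscillation complexes, higher entropy) and the class-conditional
medians follow the published SOZ vs non-epileptic contrasts for the Hilbert
detector family; spreads are widened to electrode-level variability so that
occurrence rate remains the dominant discriminating feature.

Two granularities are provided:

* :func:`generate_cohort` synthesizes full waveforms with injected events —
  used to exercise montage, detection and morphology end to end.
* :func:`sample_feature_cohort` draws per-electrode feature rows directly
  from the same generative distributions without waveform synthesis — used
  for classifier- and outcome-scale experiments (hundreds of patients)
  where waveform synthesis would be prohibitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sg

from .montage import REGIONS, Recording

__all__ = [
    "SimulationConfig",
    "Cohort",
    "generate_background",
    "inject_event",
    "generate_cohort",
    "sample_feature_cohort",
    "inband_rms",
    "write_cohort",
]

EVENT_CLASSES = ("oscillation", "spike", "spike_oscillation")
SITE_CLASSES = ("soz", "spiking", "resected_other", "non_epileptic")
ETIOLOGIES = ("non_lesional", "tumor", "dysplasia", "encephalomalacia")

STANDARD_CARE_COVARIATES = [
    "age",
    "sex",
    "daily_seizures",
    "n_asms",
    "hemisphere",
    "mri_lesion",
    "habitual_seizures_captured",
    "soz_incompletely_removed",
    "extratemporal_resection",
    "resection_extent",
]


@dataclass
class SimulationConfig:
    """The stated world of the synthetic cohort. See docs/methods.md for the
    provenance of every default."""

    n_patients: int = 10
    channels_per_patient: int = 60  # subdural; depth shafts add contacts
    n_depth_shafts: int = 1
    depth_contacts: int = 6
    soz_prevalence: float = 0.168
    spiking_fraction: float = 0.10
    resected_other_fraction: float = 0.05
    excluded_fraction: float = 0.03
    epoch_minutes: float = 5.0
    sampling_rate: float = 1000.0

    # events/min by site class (lognormal medians) and their log-SD
    rate_params: dict = field(
        default_factory=lambda: {
            "soz": 2.65,
            "spiking": 1.5,
            "resected_other": 0.8,
            "non_epileptic": 0.63,
        }
    )
    rate_sigma: float = 1.1
    # injected waveform amplitude, uV, by site class (lognormal medians)
    amplitude_params: dict = field(
        default_factory=lambda: {
            "soz": 35.0,
            "spiking": 28.0,
            "resected_other": 25.0,
            "non_epileptic": 20.0,
        }
    )
    amplitude_sigma: float = 0.4
    # probabilities over (oscillation, spike, spike_oscillation) per site class
    event_class_mix: dict = field(
        default_factory=lambda: {
            "soz": (0.35, 0.25, 0.40),
            "spiking": (0.30, 0.60, 0.10),
            "resected_other": (0.50, 0.35, 0.15),
            "non_epileptic": (0.60, 0.30, 0.10),
        }
    )
    # Hz range by oscillatory event class
    freq_params: dict = field(
        default_factory=lambda: {
            "oscillation": (90.0, 300.0),
            "spike_oscillation": (90.0, 300.0),
        }
    )
    osc_duration_ms: tuple = (20.0, 80.0)
    spike_duration_ms: tuple = (40.0, 80.0)

    background_rms_uv: float = 10.0
    slow_wave_uv: float = 40.0
    slow_wave_hz: float = 1.1

    # feature-level class-conditional morphology (sample_feature_cohort)
    entropy_params: dict = field(
        default_factory=lambda: {
            "soz": 0.70,
            "spiking": 0.68,
            "resected_other": 0.67,
            "non_epileptic": 0.65,
        }
    )
    entropy_sigma: float = 0.09
    power_params: dict = field(
        default_factory=lambda: {
            "soz": 9.11,
            "spiking": 6.5,
            "resected_other": 5.5,
            "non_epileptic": 4.71,
        }
    )
    power_sigma: float = 1.2
    freq_feature_params: dict = field(
        default_factory=lambda: {
            "soz": 101.5,
            "spiking": 101.0,
            "resected_other": 100.5,
            "non_epileptic": 100.0,
        }
    )
    freq_feature_sigma: float = 10.0
    duration_feature_params: dict = field(
        default_factory=lambda: {
            "soz": 20.7,
            "spiking": 20.0,
            "resected_other": 19.5,
            "non_epileptic": 19.3,
        }
    )
    duration_feature_sigma: float = 6.0

    # logistic link from the standardized true biomarker difference to ILAE 1
    outcome_link: float = 2.0
    outcome_link_by_etiology: dict | None = None
    etiology_probs: dict = field(
        default_factory=lambda: {
            "non_lesional": 0.30,
            "tumor": 0.15,
            "dysplasia": 0.35,
            "encephalomalacia": 0.20,
        }
    )

    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.soz_prevalence < 1.0:
            raise ValueError("soz_prevalence must lie in (0, 1)")
        for cls, mix in self.event_class_mix.items():
            if abs(sum(mix) - 1.0) > 1e-9 or min(mix) < 0:
                raise ValueError(f"event_class_mix[{cls!r}] must be a probability vector")
        if abs(sum(self.etiology_probs.values()) - 1.0) > 1e-9:
            raise ValueError("etiology_probs must sum to 1")
        max_freq = max(hi for _, hi in self.freq_params.values())
        if self.sampling_rate < 2.0 * max_freq:
            raise ValueError("sampling_rate must be at least twice the maximum event frequency")
        if self.n_patients < 1 or self.channels_per_patient < 2:
            raise ValueError("need >= 1 patient and >= 2 channels")
        if self.epoch_minutes <= 0 or self.sampling_rate <= 0:
            raise ValueError("epoch_minutes and sampling_rate must be positive")


@dataclass
class Cohort:
    """A synthetic cohort with its complete ground truth."""

    recordings: list  # list[Recording]; empty for feature-level cohorts
    electrodes: pd.DataFrame  # per-channel metadata incl. site_class
    patients: pd.DataFrame  # clinical table incl. ILAE outcome and etiology
    true_events: pd.DataFrame  # ground-truth event list
    config: SimulationConfig


def generate_background(
    duration_s: float,
    fs: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    rms_uv: float = 10.0,
    slow_uv: float = 40.0,
    slow_hz: float = 1.1,
    scale: float = 1.0,
) -> np.ndarray:
    """Zero-mean non-REM-like background: pink noise plus one slow wave.

    The pink component has amplitude spectrum 1/sqrt(f) (flat below 1 Hz),
    so spectral power decreases with frequency above the slow-wave band.
    ``scale`` multiplies the whole signal; 0 gives an all-zero trace.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration and sampling rate must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec /= np.sqrt(np.maximum(f, 1.0))
    pink = np.fft.irfft(spec, n)
    sd = pink.std()
    if sd > 0:
        pink *= rms_uv / sd
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / fs
    x = scale * (pink + slow_uv * np.sin(2 * np.pi * slow_hz * t + phase))
    return x - x.mean()


def _spike_waveform(n: int, fs: float, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Sharp biphasic transient plus a broadband high-frequency burst.

    The biphasic component carries the low-frequency spike morphology; the
    Hann-enveloped 80-400 Hz noise burst carries the broadband augmentation
    that makes spike events high-entropy in the analysis band.
    """
    t = np.arange(n) / fs
    tc = t[n // 2]
    sharp = np.exp(-((t - tc) ** 2) / (2 * 0.003**2))
    sharp -= 0.6 * np.exp(-((t - tc - 0.008) ** 2) / (2 * 0.005**2))
    taps = sg.firwin(min(65, (n // 2) * 2 - 1) | 1, [80.0, 400.0], fs=fs, pass_zero=False)
    burst = np.convolve(rng.standard_normal(n), taps, mode="same")
    sd = burst.std()
    if sd > 0:
        burst *= 0.5 / sd
    burst *= sg.windows.hann(n)
    return amplitude * (sharp + burst)


def inject_event(
    signal,
    fs: float,
    onset: int,
    kind: str,
    amplitude: float,
    duration_ms: float,
    center_freq: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Add one tapered event to a copy of ``signal``.

    oscillation: Hann-windowed sinusoid at ``center_freq`` (80-500 Hz).
    spike: sharp biphasic transient with broadband spectral content.
    spike_oscillation: both, superimposed.
    Events extending past the epoch end are rejected.
    """
    x = np.asarray(signal, dtype=float).copy()
    n = int(round(duration_ms * fs / 1000.0))
    if onset < 0 or onset + n > x.size:
        raise ValueError("event extends past the epoch bounds")
    if kind not in EVENT_CLASSES:
        raise ValueError(f"unknown event class {kind!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    t = np.arange(n) / fs
    wave = np.zeros(n)
    if kind in ("oscillation", "spike_oscillation"):
        if center_freq is None or not 80.0 <= center_freq <= 500.0:
            raise ValueError("oscillatory events need a center frequency in [80, 500] Hz")
        wave += amplitude * sg.windows.hann(n) * np.sin(2 * np.pi * center_freq * t)
    if kind in ("spike", "spike_oscillation"):
        wave += _spike_waveform(n, fs, amplitude, rng)
    x[onset : onset + n] += wave
    return x


def inband_rms(signal, fs: float, band=(80.0, 500.0)) -> float:
    """RMS of the band-passed signal; the SNR reference for injected events."""
    from .detect import bandpass

    return float(np.sqrt(np.mean(bandpass(signal, fs, band) ** 2)))


def _draw_site_classes(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    p_soz = cfg.soz_prevalence
    p_spk = cfg.spiking_fraction
    p_res = cfg.resected_other_fraction
    probs = [p_soz, p_spk, p_res, 1.0 - p_soz - p_spk - p_res]
    return rng.choice(SITE_CLASSES, size=n, p=probs)


def _resection_mask(rng, site_class: np.ndarray, completeness: float) -> np.ndarray:
    resected = np.zeros(site_class.size, dtype=bool)
    resected[site_class == "soz"] = rng.random((site_class == "soz").sum()) < completeness
    resected[site_class == "spiking"] = rng.random((site_class == "spiking").sum()) < 0.3
    resected[site_class == "resected_other"] = True
    ne = site_class == "non_epileptic"
    resected[ne] = rng.random(ne.sum()) < 0.02
    return resected


def _patient_covariates(rng, patient_id: str, electrodes: pd.DataFrame) -> dict:
    resected = electrodes["resected"].to_numpy(bool)
    soz = electrodes["soz"].to_numpy(bool)
    return {
        "id": patient_id,
        "age": float(np.round(rng.uniform(3.0, 21.0), 1)),
        "sex": int(rng.integers(0, 2)),
        "daily_seizures": int(rng.random() < 0.4),
        "n_asms": int(1 + rng.poisson(1.5)),
        "hemisphere": int(rng.integers(0, 2)),
        "habitual_seizures_captured": int(rng.random() < 0.9),
        "soz_incompletely_removed": int(bool((soz & ~resected).any())),
        "extratemporal_resection": int(rng.random() < 0.5),
        "resection_extent": float(np.round(0.25 * resected.mean(), 4)),
    }


def _finalize_patients(cfg: SimulationConfig, rng, rows: list[dict], diffs: np.ndarray):
    """Draw etiology and the ILAE class-1 outcome from the logistic link on
    the standardized true biomarker difference."""
    etis = rng.choice(ETIOLOGIES, size=len(rows), p=[cfg.etiology_probs[e] for e in ETIOLOGIES])
    sd = np.nanstd(diffs)
    z = (diffs - np.nanmean(diffs)) / (sd if sd > 0 else 1.0)
    z = np.nan_to_num(z)
    for i, row in enumerate(rows):
        beta = cfg.outcome_link
        if cfg.outcome_link_by_etiology and etis[i] in cfg.outcome_link_by_etiology:
            beta = cfg.outcome_link_by_etiology[etis[i]]
        p1 = 1.0 / (1.0 + np.exp(-beta * z[i]))
        row["etiology"] = etis[i]
        row["mri_lesion"] = int(etis[i] != "non_lesional")
        row["true_biomarker_difference"] = float(diffs[i])
        row["true_p_ilae1"] = float(p1)
        row["ilae_class1"] = int(rng.random() < p1)
    return pd.DataFrame(rows)


def _electrode_frame(cfg, rng, patient_id: str) -> pd.DataFrame:
    """Channel metadata for one patient: a subdural array plus depth shafts."""
    hemi = "L" if rng.random() < 0.5 else "R"
    lobes = ["frontal", "central", "parietal", "occipital", "temporal", "insular"]
    rows = []
    for i in range(cfg.channels_per_patient):
        rows.append(
            {
                "name": f"G{i + 1:02d}",
                "kind": "subdural",
                "shaft_id": "",
                "contact_index": -1,
                "hemisphere": hemi,
                "region": f"{hemi}_{rng.choice(lobes[:5])}",
            }
        )
    for s in range(cfg.n_depth_shafts):
        region = f"{hemi}_{rng.choice(['temporal', 'insular'])}"
        for k in range(cfg.depth_contacts):
            rows.append(
                {
                    "name": f"D{s + 1}{k + 1}",
                    "kind": "depth",
                    "shaft_id": f"D{s + 1}",
                    "contact_index": k,
                    "hemisphere": hemi,
                    "region": region,
                }
            )
    df = pd.DataFrame(rows)
    n = len(df)
    df["site_class"] = _draw_site_classes(rng, n, cfg)
    df["soz"] = df["site_class"] == "soz"
    df["spiking"] = df["site_class"] == "spiking"
    df["resected"] = _resection_mask(rng, df["site_class"].to_numpy(), rng.uniform(0.2, 1.0))
    df["excluded"] = rng.random(n) < cfg.excluded_fraction
    df["patient"] = patient_id
    return df


def _draw_events_for_channel(cfg, rng, site_class: str, n_samples: int, fs: float):
    """Ground-truth events for one channel: Poisson count at the channel's
    latent rate, non-overlapping onsets, class-conditional morphology."""
    lam = float(
        np.exp(np.log(cfg.rate_params[site_class]) + cfg.rate_sigma * rng.standard_normal())
    )
    count = int(rng.poisson(lam * n_samples / fs / 60.0))
    margin = int(0.3 * fs)
    onsets: list[int] = []
    for _ in range(count):
        for _try in range(50):
            cand = int(rng.integers(margin, n_samples - margin))
            if all(abs(cand - o) > margin for o in onsets):
                onsets.append(cand)
                break
    events = []
    for onset in sorted(onsets):
        kind = rng.choice(EVENT_CLASSES, p=cfg.event_class_mix[site_class])
        if kind == "spike":
            dur = rng.uniform(*cfg.spike_duration_ms)
            freq = np.nan
        else:
            dur = rng.uniform(*cfg.osc_duration_ms)
            freq = rng.uniform(*cfg.freq_params[kind])
        amp = float(
            np.exp(
                np.log(cfg.amplitude_params[site_class])
                + cfg.amplitude_sigma * rng.standard_normal()
            )
        )
        events.append(
            {
                "onset": onset,
                "offset": onset + int(round(dur * fs / 1000.0)),
                "kind": kind,
                "center_freq": freq,
                "amplitude": amp,
                "true_rate": lam,
            }
        )
    return lam, events


def generate_cohort(cfg: SimulationConfig) -> Cohort:
    """Full waveform-level synthetic cohort.

    SOZ channels receive higher event rates, amplitudes, and a larger
    spike-oscillation share than non-epileptic channels (margins set by the
    config); a resection mask and an outcome drawn through the logistic link
    complete the ground truth. Fixed seed implies byte-identical output.
    """
    cfg.validate()
    root = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    n_samples = int(round(cfg.epoch_minutes * 60.0 * fs))

    recordings, elec_frames, event_rows, patient_rows, diffs = [], [], [], [], []
    for p in range(cfg.n_patients):
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        pid = f"sub-{p + 1:03d}"
        elec = _electrode_frame(cfg, rng, pid)
        data = np.empty((len(elec), n_samples))
        true_rates = np.empty(len(elec))
        for i, row in elec.iterrows():
            x = generate_background(
                cfg.epoch_minutes * 60.0,
                fs,
                rng=rng,
                rms_uv=cfg.background_rms_uv,
                slow_uv=cfg.slow_wave_uv,
                slow_hz=cfg.slow_wave_hz,
            )
            lam, events = _draw_events_for_channel(cfg, rng, row["site_class"], n_samples, fs)
            true_rates[i] = lam
            for ev in events:
                x = inject_event(
                    x,
                    fs,
                    ev["onset"],
                    ev["kind"],
                    ev["amplitude"],
                    (ev["offset"] - ev["onset"]) / fs * 1000.0,
                    center_freq=None if np.isnan(ev["center_freq"]) else ev["center_freq"],
                    rng=rng,
                )
                event_rows.append({"patient": pid, "channel": row["name"], **ev})
            data[i] = x
        elec["true_rate"] = true_rates
        recordings.append(
            Recording(
                data=data,
                fs=fs,
                channels=elec.drop(columns=["patient", "site_class", "true_rate"]),
                patient=pid,
            )
        )
        elec_frames.append(elec)
        patient_rows.append(_patient_covariates(rng, pid, elec))
        ok = ~elec["excluded"].to_numpy(bool)
        res = elec["resected"].to_numpy(bool)
        if (ok & res).any() and (ok & ~res).any():
            diffs.append(true_rates[ok & res].mean() - true_rates[ok & ~res].mean())
        else:
            diffs.append(np.nan)

    outcome_rng = np.random.default_rng(root.integers(0, 2**31 - 1))
    patients = _finalize_patients(cfg, outcome_rng, patient_rows, np.asarray(diffs))
    return Cohort(
        recordings=recordings,
        electrodes=pd.concat(elec_frames, ignore_index=True),
        patients=patients,
        true_events=pd.DataFrame(
            event_rows,
            columns=[
                "patient",
                "channel",
                "onset",
                "offset",
                "kind",
                "center_freq",
                "amplitude",
                "true_rate",
            ],
        ),
        config=cfg,
    )


def sample_feature_cohort(cfg: SimulationConfig, detector: str = "SIM"):
    """Electrode-level feature cohort drawn straight from the generative
    distributions (no waveforms).

    Each channel gets a latent event rate (lognormal around its site-class
    median), a realized Poisson event count over the epoch, and morphology
    medians computed from that many class-conditional event draws — so
    zero-event electrodes carry NaN morphology exactly as in the signal
    path. Returns ``(features, patients)``; features carry the seven model
    columns plus site/resection metadata.
    """
    cfg.validate()
    root = np.random.default_rng(cfg.seed)
    rows, patient_rows, diffs = [], [], []
    for p in range(cfg.n_patients):
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        pid = f"sub-{p + 1:03d}"
        elec = _electrode_frame(cfg, rng, pid)
        cov = _patient_covariates(rng, pid, elec)
        true_rates = np.empty(len(elec))
        for i, e in elec.iterrows():
            cls = e["site_class"]
            lam = float(np.exp(np.log(cfg.rate_params[cls]) + cfg.rate_sigma * rng.standard_normal()))
            true_rates[i] = lam
            count = int(rng.poisson(lam * cfg.epoch_minutes))
            k = min(count, 500)
            if k:
                # electrode-level random effect plus median-of-events noise:
                # between-electrode spread dominates and does not shrink with
                # event count, as for real electrode medians
                def _med(center, sigma):
                    c = center + sigma * rng.standard_normal()
                    return c + sigma / np.sqrt(k) * rng.standard_normal()

                dur = max(5.0, _med(cfg.duration_feature_params[cls], cfg.duration_feature_sigma))
                pwr = float(np.exp(_med(np.log(cfg.power_params[cls]), cfg.power_sigma)))
                frq = float(
                    np.clip(_med(cfg.freq_feature_params[cls], cfg.freq_feature_sigma), 80.0, 500.0)
                )
                ent = float(np.clip(_med(cfg.entropy_params[cls], cfg.entropy_sigma), 0.0, 1.0))
            else:
                dur = pwr = frq = ent = np.nan
            rows.append(
                {
                    "patient": pid,
                    "channel": e["name"],
                    "detector": detector,
                    "rate": count / cfg.epoch_minutes,
                    "true_rate": lam,
                    "duration": dur,
                    "power": pwr,
                    "freq": frq,
                    "entropy": ent,
                    "region": e["region"],
                    "age": cov["age"],
                    "site_group": cls,
                    "label": {"soz": 1.0, "non_epileptic": 0.0}.get(cls, np.nan),
                    "resected": bool(e["resected"]),
                    "excluded": bool(e["excluded"]),
                }
            )
        patient_rows.append(cov)
        ok = ~elec["excluded"].to_numpy(bool)
        res = elec["resected"].to_numpy(bool)
        if (ok & res).any() and (ok & ~res).any():
            diffs.append(true_rates[ok & res].mean() - true_rates[ok & ~res].mean())
        else:
            diffs.append(np.nan)
    outcome_rng = np.random.default_rng(root.integers(0, 2**31 - 1))
    patients = _finalize_patients(cfg, outcome_rng, patient_rows, np.asarray(diffs))
    features = pd.DataFrame(rows)
    features = features[~features["excluded"]].reset_index(drop=True)
    return features, patients


def write_cohort(cohort: Cohort, outdir) -> None:
    """Persist a cohort: per-patient signals (.npy) and electrode TSVs, a
    cohort patient CSV, and the ground-truth event list as JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        np.save(outdir / f"{rec.patient}_signals.npy", rec.data.astype(np.float32))
        elec = cohort.electrodes[cohort.electrodes["patient"] == rec.patient]
        elec.drop(columns=["patient"]).to_csv(
            outdir / f"{rec.patient}_electrodes.tsv", sep="\t", index=False
        )
    cohort.patients.to_csv(outdir / "patients.csv", index=False)
    cohort.true_events.to_json(outdir / "ground_truth_events.json", orient="records")
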