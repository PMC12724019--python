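"""Montage and channel-exclusion preprocessing.

Subdural grid/strip channels are re-referenced to the common average of the
included subdural channels; depth-electrode shafts are converted to bipolar
pairs (contact k minus contact k+1 along the shaft). Statistics computed on
bipolar pair signals are mapped back to contacts by averaging the values of
the adjacent pairs; shaft-end contacts inherit their single adjacent pair.
Channels flagged ``excluded`` (artifact / white matter / out of brain) are
removed before any reference is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "REGIONS",
    "common_average_reference",
    "bipolar_pairs",
    "contact_value_from_pairs",
    "apply_montage",
    "map_pair_values_to_contacts",
]

#: Fixed 12-label anatomical vocabulary (6 lobar labels x 2 hemispheres).
REGIONS = tuple(
    f"{hemi}_{lobe}"
    for hemi in ("L", "R")
    for lobe in ("frontal", "central", "parietal", "occipital", "temporal", "insular")
)

CHANNEL_COLUMNS = [
    "name",
    "kind",  # subdural | depth
    "shaft_id",  # depth only
    "contact_index",  # depth only, 0-based order along the shaft
    "hemisphere",
    "region",
    "soz",
    "spiking",
    "resected",
    "excluded",
]


@dataclass
class Recording:
    """A multichannel iEEG epoch: (n_channels, n_samples) in microvolts."""

    data: np.ndarray
    fs: float
    channels: pd.DataFrame  # one row per data row, CHANNEL_COLUMNS schema
    patient: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel table must align with data rows")
        bad = set(self.channels["region"].dropna()) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown anatomical regions: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_minutes(self) -> float:
        return self.n_samples / self.fs / 60.0


def common_average_reference(signals: np.ndarray) -> np.ndarray:
    """Subtract the per-sample mean across channels.

    The output's cross-channel mean is exactly zero at every sample.
    Requires at least two channels (the common average of one channel
    would zero it out entirely).
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[0] < 2:
        raise ValueError("common average reference requires >= 2 channels")
    return signals - signals.mean(axis=0, keepdims=True)


def bipolar_pairs(shaft_signals: np.ndarray) -> np.ndarray:
    """Ordered bipolar derivation along one depth shaft.

    Pair k = contact k - contact k+1; n contacts yield n-1 pairs.
    """
    shaft_signals = np.asarray(shaft_signals, dtype=float)
    if shaft_signals.ndim != 2 or shaft_signals.shape[0] < 2:
        raise ValueError("bipolar montage requires a shaft with >= 2 contacts")
    return shaft_signals[:-1] - shaft_signals[1:]


def contact_value_from_pairs(pair_values, contact_index: int) -> float:
    """Assign a per-contact value from adjacent bipolar-pair values.

    Interior contact k is flanked by pairs k-1 and k and receives their
    mean; shaft-end contacts have a single adjacent pair and inherit its
    value unchanged.
    """
    pair_values = np.asarray(pair_values, dtype=float)
    n_pairs = pair_values.size
    if n_pairs == 0:
        raise ValueError("contact has no adjacent bipolar pairs")
    n_contacts = n_pairs + 1
    if not 0 <= contact_index < n_contacts:
        raise ValueError("contact_index outside the shaft")
    if contact_index == 0:
        return float(pair_values[0])
    if contact_index == n_contacts - 1:
        return float(pair_values[-1])
    return float(0.5 * (pair_values[contact_index - 1] + pair_values[contact_index]))


def apply_montage(recording: Recording) -> Recording:
    """Re-reference a recording for detection.

    Excluded channels are dropped first. Subdural channels get the common
    average of the included subdural set; each depth shaft is replaced by
    its bipolar pairs (named ``A-B``). Pair rows keep the shaft id and the
    upper contact's index so pair-level statistics can be mapped back to
    contacts with :func:`map_pair_values_to_contacts`.
    """
    ch = recording.channels.reset_index(drop=True)
    keep = ~ch["excluded"].astype(bool)
    ch = ch[keep].reset_index(drop=True)
    data = recording.data[keep.to_numpy()]

    out_rows: list[dict] = []
    out_sig: list[np.ndarray] = []

    sub_mask = (ch["kind"] == "subdural").to_numpy()
    if sub_mask.sum() >= 2:
        car = common_average_reference(data[sub_mask])
        for sig, (_, row) in zip(car, ch[sub_mask].iterrows()):
            out_rows.append(dict(row))
            out_sig.append(sig)
    elif sub_mask.sum() == 1:
        raise ValueError("common average undefined for a single subdural channel")

    depth = ch[ch["kind"] == "depth"]
    for shaft_id, grp in depth.groupby("shaft_id", sort=True):
        grp = grp.sort_values("contact_index")
        if len(grp) < 2:
            raise ValueError(f"depth shaft {shaft_id!r} has a singleton contact")
        sig = bipolar_pairs(data[grp.index.to_numpy()])
        names = grp["name"].tolist()
        for k in range(len(names) - 1):
            row = dict(grp.iloc[k])
            row["name"] = f"{names[k]}-{names[k + 1]}"
            row["kind"] = "depth_pair"
            row["contact_index"] = k
            # pair-level flags: union of the two contacts' flags
            for flag in ("soz", "spiking", "resected"):
                row[flag] = bool(grp.iloc[k][flag]) or bool(grp.iloc[k + 1][flag])
            out_rows.append(row)
            out_sig.append(sig[k])

    if not out_sig:
        raise ValueError("no channels left after exclusion")
    return Recording(
        data=np.vstack(out_sig),
        fs=recording.fs,
        channels=pd.DataFrame(out_rows).reset_index(drop=True),
        patient=recording.patient,
    )


def map_pair_values_to_contacts(
    pair_values: "pd.Series | dict", shaft_contact_names: list[str]
) -> dict[str, float]:
    """Map per-pair statistics back to per-contact values for one shaft.

    ``pair_values`` is keyed by pair name ``A-B`` in shaft order. Missing
    pairs are treated as NaN; a contact whose adjacent pairs are all NaN
    gets NaN.
    """
    if isinstance(pair_values, dict):
        pair_values = pd.Series(pair_values)
    n = len(shaft_contact_names)
    if n < 2:
        raise ValueError("shaft needs >= 2 contacts")
    pv = np.array(
        [
            pair_values.get(f"{shaft_contact_names[k]}-{shaft_contact_names[k + 1]}", np.nan)
            for k in range(n - 1)
        ],
        dtype=float,
    )
    out: dict[str, float] = {}
    for k, name in enumerate(shaft_contact_names):
        adj = pv[max(0, k - 1) : k + 1]
        adj = adj[~np.isnan(adj)]
        out[name] = float(np.mean(adj)) if adj.size else float("nan")
    return out
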