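"""Per-ROI neural features as subjects x ROIs tables.

Five features enter the prediction stage:

* ``coupling`` — structure-function coupling: within each subject, the
  Spearman correlation between a ROI's nonzero structural edge weights and
  the functional connectivity on those same edges.
* ``alff`` — amplitude of low-frequency fluctuation: mean amplitude of the
  demeaned BOLD spectrum in 0.01-0.1 Hz, z-scored across ROIs per subject.
* ``sdc`` / ``fdc`` — structural / functional degree centrality: summed
  edge weights of a ROI over its structurally present connections.
* ``gmv`` — gray matter volume per ROI, passed through from tabular input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import CohortConnectome
from .errors import DataError

__all__ = [
    "FeatureTable",
    "structure_function_coupling",
    "alff",
    "alff_table",
    "degree_centrality",
    "gmv_table",
    "drop_undefined_rois",
]

FEATURE_NAMES = ("coupling", "alff", "sdc", "fdc", "gmv")


@dataclass
class FeatureTable:
    """A subjects x ROIs matrix for one named feature."""

    name: str
    values: np.ndarray
    subject_ids: list[str]
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.roi_labels)):
            raise DataError(
                f"feature {self.name!r}: values shape {self.values.shape} does not "
                f"match {len(self.subject_ids)} subjects x {len(self.roi_labels)} ROIs"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.roi_labels)

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame) -> "FeatureTable":
        return cls(name, frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))


def structure_function_coupling(
    cc: CohortConnectome, min_edges: int = 3
) -> FeatureTable:
    """Region-wise Spearman correlation between SC and FC edge weights.

    For subject s and ROI i the coupling is the Spearman rho between
    ``{W_ij : W_ij > 0, j != i}`` (that subject's thresholded structural
    row) and the corresponding Fisher-z functional values ``{Z_ij}``.
    Ties receive average ranks.  ROIs with fewer than ``min_edges`` nonzero
    structural edges get NaN — a documented return contract, not an error.
    """
    n_sub, n = cc.n_subjects, cc.n_rois
    out = np.full((n_sub, n), np.nan)
    for s in range(n_sub):
        w = cc.sc[s]
        z = cc.fc[s]
        for i in range(n):
            nz = np.flatnonzero(w[i] > 0)
            nz = nz[nz != i]
            if nz.size < min_edges:
                continue
            rho = stats.spearmanr(w[i, nz], z[i, nz]).statistic
            out[s, i] = rho
    return FeatureTable("coupling", out, list(cc.subject_ids), list(cc.roi_labels))


def alff(
    timeseries: np.ndarray,
    sampling_interval: float,
    band: tuple[float, float] = (0.01, 0.1),
    zscore: bool = True,
    subject_id: str = "?",
) -> np.ndarray:
    """Amplitude of low-frequency fluctuation per ROI.

    Raw ALFF of ROI i is the mean one-sided amplitude spectrum
    ``2|FFT(x_i - mean)|/T`` over frequencies inside ``band`` (inclusive).
    With ``zscore=True`` the vector is standardized across ROIs within the
    subject, which makes the arbitrary amplitude scale irrelevant.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise DataError("timeseries must be 2-D (n_timepoints, n_rois)")
    n_t = ts.shape[0]
    nyquist = 0.5 / sampling_interval
    low, high = band
    if not (0.0 < low < high <= nyquist):
        raise DataError(
            f"band {band} must lie within (0, Nyquist={nyquist:.4g}] Hz"
        )
    if n_t < 64:
        warnings.warn(
            f"only {n_t} timepoints; ALFF band estimates will be coarse",
            stacklevel=2,
        )
    flat = np.ptp(ts, axis=0) == 0
    if np.any(flat):
        bad = int(np.flatnonzero(flat)[0])
        raise DataError(f"zero-variance time series for ROI index {bad}")
    freqs = np.fft.rfftfreq(n_t, d=sampling_interval)
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():
        raise DataError(f"no FFT frequency falls inside band {band}")
    amp = 2.0 * np.abs(np.fft.rfft(ts - ts.mean(axis=0, keepdims=True), axis=0)) / n_t
    raw = amp[mask].mean(axis=0)
    if not zscore:
        return raw
    mu, s = raw.mean(), raw.std(ddof=0)
    if s == 0:
        raise DataError(
            f"subject {subject_id}: identical ALFF across all ROIs, cannot z-score"
        )
    return (raw - mu) / s


def alff_table(
    records: Sequence,
    sampling_interval: float | None = None,
    band: tuple[float, float] = (0.01, 0.1),
    roi_labels: Sequence[str] | None = None,
) -> FeatureTable:
    """Z-scored ALFF for every subject.

    Records generated in fast FC mode carry a precomputed per-ROI spectral
    amplitude (``alff_raw``) instead of time series; it is z-scored the same
    way.
    """
    rows, ids = [], []
    for rec in records:
        ids.append(rec.subject_id)
        if rec.timeseries is not None:
            dt = sampling_interval if sampling_interval is not None else 2.0
            rows.append(alff(rec.timeseries, dt, band=band, subject_id=rec.subject_id))
        elif getattr(rec, "alff_raw", None) is not None:
            raw = np.asarray(rec.alff_raw, dtype=float)
            s = raw.std(ddof=0)
            if s == 0:
                raise DataError(
                    f"subject {rec.subject_id}: identical ALFF across all ROIs"
                )
            rows.append((raw - raw.mean()) / s)
        else:
            raise DataError(f"subject {rec.subject_id}: no timeseries or ALFF data")
    values = np.vstack(rows)
    n = values.shape[1]
    labels = list(roi_labels) if roi_labels is not None else [f"ROI{i:03d}" for i in range(n)]
    return FeatureTable("alff", values, ids, labels)


def degree_centrality(
    cc: CohortConnectome,
    modality: Literal["structural", "functional"],
    fdc_edges: Literal["structural", "all"] = "structural",
) -> FeatureTable:
    """Weighted degree centrality per ROI.

    ``structural``: sum of a ROI's nonzero structural weights (sDC).
    ``functional``: sum of the Fisher-z functional values on that same
    structurally present edge set (fDC) — or over every other ROI when
    ``fdc_edges="all"``.
    """
    present = cc.sc > 0
    if modality == "structural":
        vals = cc.sc.sum(axis=2)
        name = "sdc"
    elif modality == "functional":
        if fdc_edges == "structural":
            vals = (cc.fc * present).sum(axis=2)
        elif fdc_edges == "all":
            off = ~np.eye(cc.n_rois, dtype=bool)
            vals = (cc.fc * off[None]).sum(axis=2)
        else:
            raise DataError(f"unknown fdc_edges {fdc_edges!r}")
        name = "fdc"
    else:
        raise DataError(f"unknown modality {modality!r}")
    return FeatureTable(name, vals, list(cc.subject_ids), list(cc.roi_labels))


def gmv_table(
    source,
    subject_ids: Sequence[str] | None = None,
    roi_labels: Sequence[str] | None = None,
) -> FeatureTable:
    """Gray matter volume table, validated against the expected cohort.

    ``source`` is a subjects x ROIs ``DataFrame`` (or a path to a TSV with a
    subject_id index) of strictly positive, finite volumes.
    """
    if isinstance(source, pd.DataFrame):
        frame = source
    else:
        frame = pd.read_csv(source, sep="\t", index_col=0)
    if subject_ids is not None:
        missing = [s for s in subject_ids if s not in frame.index]
        if missing:
            raise DataError(f"gmv table missing subjects: {missing}")
        frame = frame.loc[list(subject_ids)]
    if roi_labels is not None:
        missing_r = [r for r in roi_labels if r not in frame.columns]
        if missing_r:
            raise DataError(f"gmv table missing ROIs: {missing_r}")
        frame = frame[list(roi_labels)]
    vals = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise DataError("gmv table contains non-finite values")
    if np.any(vals <= 0):
        raise DataError("gmv table contains non-positive volumes")
    return FeatureTable.from_frame("gmv", frame)


def drop_undefined_rois(tables: Sequence[FeatureTable]) -> tuple[list[FeatureTable], list[str]]:
    """Listwise-drop ROIs that are NaN for any subject in any table.

    Coupling is NaN for ROIs with too few structural edges; such ROIs are
    removed from every feature table so all models see the same columns.
    Returns the filtered tables and the dropped ROI labels.
    """
    if not tables:
        return [], []
    labels = tables[0].roi_labels
    keep = np.ones(len(labels), dtype=bool)
    for t in tables:
        if t.roi_labels != labels:
            raise DataError("feature tables have mismatched ROI labels")
        keep &= ~np.isnan(t.values).any(axis=0)
    dropped = [lab for lab, k in zip(labels, keep) if not k]
    kept_labels = [lab for lab, k in zip(labels, keep) if k]
    out = [
        FeatureTable(t.name, t.values[:, keep], list(t.subject_ids), kept_labels)
        for t in tables
    ]
    return out, dropped
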