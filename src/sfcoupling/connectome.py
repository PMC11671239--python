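"""Analysis-ready structural and functional connectomes.

Three operations turn raw per-subject data into a multi-subject connectome:

* :func:`functional_connectivity` — pairwise Pearson correlation of ROI
  time series, Fisher z-transformed.
* :func:`symmetrize_structural` — symmetrize a directed streamline-count
  matrix from probabilistic tractography and normalize it by the number of
  initiated samples and the sizes of the two ROIs,
  ``W_ij = (S_ij + S_ji) / (samples_per_voxel * (N_i + N_j))``.
* :func:`consistency_threshold` — remove edges whose weight is least
  consistent across subjects (highest coefficient of variation), treating
  them as tractography false positives.

:func:`build_connectome` chains these for a cohort of subject records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "CohortConnectome",
    "functional_connectivity",
    "symmetrize_structural",
    "consistency_threshold",
    "build_connectome",
]


@dataclass
class CohortConnectome:
    """Aligned multi-subject symmetric SC and FC stacks plus a shared edge mask.

    Attributes
    ----------
    sc : (n_subjects, n_rois, n_rois) float array
        Normalized symmetric structural weights, zeroed outside ``edge_mask``
        once thresholding has been applied.
    fc : (n_subjects, n_rois, n_rois) float array
        Fisher-z functional correlations; the diagonal is 0 and unused.
    edge_mask : (n_rois, n_rois) bool array
        Symmetric mask of structural edges retained by consistency
        thresholding (zero diagonal).
    """

    sc: np.ndarray
    fc: np.ndarray
    edge_mask: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    roi_labels: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.sc.shape[0]

    @property
    def n_rois(self) -> int:
        return self.sc.shape[1]

    def validate(self) -> None:
        if self.sc.shape != self.fc.shape or self.sc.ndim != 3:
            raise DataError("sc and fc stacks must share shape (n_subjects, n, n)")
        n = self.sc.shape[1]
        if self.sc.shape[2] != n or self.edge_mask.shape != (n, n):
            raise DataError("connectome matrices must be square and aligned")
        if not np.array_equal(self.edge_mask, self.edge_mask.T):
            raise DataError("edge_mask must be symmetric")
        if np.any(np.diagonal(self.edge_mask)):
            raise DataError("edge_mask diagonal must be zero")
        if not np.allclose(self.sc, np.transpose(self.sc, (0, 2, 1))):
            raise DataError("structural stack must be symmetric per subject")
        off = ~np.eye(n, dtype=bool)
        if not np.all(np.isfinite(self.fc[:, off])):
            raise DataError("functional stack has non-finite off-diagonal entries")


def functional_connectivity(timeseries: np.ndarray) -> np.ndarray:
    """Fisher-z functional connectivity from an ROI time-series matrix.

    Parameters
    ----------
    timeseries : (n_timepoints, n_rois) array
        One column per ROI. At least 10 timepoints; no constant column.

    Returns
    -------
    (n_rois, n_rois) array with ``atanh(pearson_r)`` off-diagonal and 0 on
    the diagonal.

    Raises
    ------
    DataError
        If a column is constant (naming the ROI) or a pair of distinct ROIs
        is perfectly correlated (``|r| = 1``), which has no finite Fisher z.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise DataError("timeseries must be 2-D (n_timepoints, n_rois)")
    n_t, n_rois = ts.shape
    if n_t < 10:
        raise DataError(f"need >= 10 timepoints to estimate FC, got {n_t}")
    const = np.flatnonzero(np.ptp(ts, axis=0) == 0)
    if const.size:
        raise DataError(f"constant time series for ROI index {const[0]}")
    r = np.corrcoef(ts, rowvar=False)
    off = ~np.eye(n_rois, dtype=bool)
    # Guard against exact +-1 before atanh; corrcoef round-off above 1 is clipped.
    r = np.clip(r, -1.0, 1.0)
    bad = np.abs(r[off]) >= 1.0 - 1e-12
    if np.any(bad):
        i, j = np.argwhere(off & (np.abs(r) >= 1.0 - 1e-12))[0]
        raise DataError(
            f"degenerate input: ROIs {i} and {j} are perfectly correlated (|r|=1)"
        )
    np.fill_diagonal(r, 0.0)  # diagonal unused; avoids atanh(1)
    z = np.arctanh(r)
    return (z + z.T) / 2.0


def symmetrize_structural(
    sc_counts: np.ndarray,
    roi_volumes: np.ndarray,
    samples_per_voxel: int = 5000,
    normalization: Literal["divide_by_volumes", "multiply_by_volumes"] = "divide_by_volumes",
) -> np.ndarray:
    """Symmetric normalized structural weights from directed streamline counts.

    ``W_ij = (S_ij + S_ji) / (samples_per_voxel * (N_i + N_j))`` where
    ``S_ij`` counts streamlines seeded in ROI i reaching ROI j and ``N_i``
    is the voxel count of ROI i.  Dividing by initiated samples times ROI
    size converts counts to a connection probability comparable across ROIs
    of different sizes.  ``normalization="multiply_by_volumes"`` instead
    computes ``(S_ij + S_ji) / samples_per_voxel * (N_i + N_j)``.
    """
    counts = np.asarray(sc_counts, dtype=float)
    vols = np.asarray(roi_volumes, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise DataError("sc_counts must be square")
    if vols.shape != (counts.shape[0],):
        raise DataError("roi_volumes length must match sc_counts")
    if np.any(counts < 0):
        raise DataError("streamline counts must be nonnegative")
    if np.any(np.diagonal(counts) != 0):
        raise DataError("sc_counts diagonal must be zero")
    if np.any(vols <= 0):
        raise DataError("all ROI volumes must be strictly positive")
    if samples_per_voxel <= 0:
        raise ConfigError("samples_per_voxel must be positive")
    pair_sum = counts + counts.T
    vol_sum = vols[:, None] + vols[None, :]
    if normalization == "divide_by_volumes":
        w = pair_sum / (samples_per_voxel * vol_sum)
    elif normalization == "multiply_by_volumes":
        w = pair_sum / samples_per_voxel * vol_sum
    else:
        raise ConfigError(f"unknown sc normalization {normalization!r}")
    np.fill_diagonal(w, 0.0)
    return w


def consistency_threshold(
    sc_stack: np.ndarray,
    removal_fraction: float = 0.30,
    mode: Literal["remove_top", "keep_bottom"] = "remove_top",
) -> tuple[np.ndarray, np.ndarray]:
    """Zero out the least consistent structural edges across subjects.

    For every candidate edge (upper triangle, nonzero in at least one
    subject) the coefficient of variation CV = sd/mean of its weight across
    all subjects is computed, with zeros included, so edges present in only
    a few subjects score high.  With ``mode="remove_top"`` the
    ``ceil(removal_fraction * E)`` highest-CV edges are zeroed in every
    subject; ``mode="keep_bottom"`` instead keeps only the
    ``floor(removal_fraction * E)`` lowest-CV edges (the alternative reading
    of a "30th percentile" cut).  Ties are broken by ascending edge index
    for determinism.

    Returns
    -------
    edge_mask : (n, n) bool array of retained edges.
    thresholded : stack with removed edges zeroed in every subject.
    """
    stack = np.asarray(sc_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise DataError("sc_stack must have shape (n_subjects, n, n)")
    if not (0.0 <= removal_fraction < 1.0):
        raise ConfigError("removal_fraction must be in [0, 1)")
    n_sub, n = stack.shape[0], stack.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    vals = stack[:, iu, ju]  # (n_sub, E_all)
    candidate = np.any(vals != 0, axis=0)
    cand_idx = np.flatnonzero(candidate)
    e = cand_idx.size
    mean = vals[:, cand_idx].mean(axis=0)
    assert np.all(mean > 0) or np.any(vals[:, cand_idx] < 0) or e == 0, (
        "candidate edge with zero cross-subject mean"
    )
    sd = vals[:, cand_idx].std(axis=0, ddof=1) if n_sub > 1 else np.zeros(e)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.inf)

    # stable order: CV descending, edge index ascending
    order = np.lexsort((cand_idx, -cv))
    if mode == "remove_top":
        n_remove = math.ceil(removal_fraction * e)
        removed = cand_idx[order[:n_remove]]
    elif mode == "keep_bottom":
        n_keep = math.floor(removal_fraction * e)
        removed = cand_idx[order[: e - n_keep]]
    else:
        raise ConfigError(f"unknown thresholding mode {mode!r}")

    keep = np.ones(iu.size, dtype=bool)
    keep[~candidate] = False
    keep[removed] = False
    edge_mask = np.zeros((n, n), dtype=bool)
    edge_mask[iu[keep], ju[keep]] = True
    edge_mask |= edge_mask.T
    thresholded = stack * edge_mask[None, :, :]
    return edge_mask, thresholded


def build_connectome(
    records: Sequence,
    samples_per_voxel: int | None = None,
    removal_fraction: float = 0.30,
    sc_normalization: Literal["divide_by_volumes", "multiply_by_volumes"] = "divide_by_volumes",
    threshold_mode: Literal["remove_top", "keep_bottom"] = "remove_top",
    roi_labels: Sequence[str] | None = None,
) -> CohortConnectome:
    """Assemble a :class:`CohortConnectome` from subject records.

    Each record needs ``sc_counts``, ``roi_volumes``, ``subject_id`` and
    either ``timeseries`` or a precomputed Fisher-z ``fc``.  When a record
    has ``samples_per_voxel`` unset, the argument (default 5000) is used.
    """
    if not records:
        raise DataError("empty cohort")
    spv = samples_per_voxel
    sc_list, fc_list, ids = [], [], []
    for rec in records:
        rec_spv = spv if spv is not None else getattr(rec, "samples_per_voxel", 5000)
        sc_list.append(
            symmetrize_structural(
                rec.sc_counts, rec.roi_volumes, rec_spv, normalization=sc_normalization
            )
        )
        fc = getattr(rec, "fc", None)
        if fc is None:
            if rec.timeseries is None:
                raise DataError(f"subject {rec.subject_id}: no timeseries and no FC")
            fc = functional_connectivity(rec.timeseries)
        fc_list.append(np.asarray(fc, dtype=float))
        ids.append(rec.subject_id)
    sc = np.stack(sc_list)
    fc = np.stack(fc_list)
    edge_mask, sc = consistency_threshold(sc, removal_fraction, mode=threshold_mode)
    n = sc.shape[1]
    labels = list(roi_labels) if roi_labels is not None else [f"ROI{i:03d}" for i in range(n)]
    cc = CohortConnectome(sc=sc, fc=fc, edge_mask=edge_mask, subject_ids=ids, roi_labels=labels)
    cc.validate()
    return cc
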