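"""Synthetic multi-subject connectome cohorts.

The generator emulates a resting-state MRI cohort at the statistical level
the downstream analysis actually touches: per-subject directed streamline
counts on a shared structural backbone, ROI time series whose pairwise
correlations are a noisy monotone function of the structural weights, and a
behavioral score driven by the latent structure-function coupling of a
designated set of "signal" ROIs.

Construction, in full (all draws from one ``numpy`` Generator seeded by
``config.seed``):

1. *Backbone*: a symmetric binary graph on ``n_rois`` nodes containing a
   random spanning chain (so the graph is connected) plus uniformly random
   extra edges up to ``backbone_density``.
2. *Structural counts*: each backbone edge gets a group-level mean count
   ``mu_e ~ LogNormal(log 150, 0.8)``; subject s draws directed counts
   ``S_ij = round(g_s * mu_e * exp(0.4 z))`` with a subject-level scaling
   factor ``g_s ~ LogNormal(0, 0.25)`` and independent noise per direction.
   A small set of off-backbone "spurious" edges (8% of the backbone count)
   is present in each subject with probability 0.2 with weaker counts;
   because they are absent in most subjects their cross-subject coefficient
   of variation is far above the backbone median, so consistency
   thresholding removes them.
3. *Latent coupling and functional data*: subject s, ROI i draws a latent
   coupling level ``lambda_si`` around a per-ROI baseline; ROIs listed in
   ``signal_rois`` form one functional circuit and share a subject-level
   factor (pairwise correlation 0.6).  A target correlation matrix assigns
   each structural edge ``r_ij = r_lo + (r_hi - r_lo) * rank(W_ij) + noise``
   with noise SD ``s_min + s_max * ((1 - lambda_i)(1 - lambda_j))^2``: an
   edge stays clean whenever either endpoint is strongly coupled, and noise
   grows steeply only when both are decoupled, which keeps each ROI's rank
   correlation a sharp readout of its own coupling level.  The matrix is
   projected to the nearest valid correlation matrix and ROI time series
   are drawn as band-limited Gaussian noise (0.01-0.2 Hz, emulating
   band-passed resting-state data) mixed through its Cholesky factor; the
   shared spectral mask leaves cross-ROI correlations untouched.
4. *Score*: ``score = score_mean + effect_size * score_sd * z + noise_sd * eps``
   where ``z`` is the cohort-standardized mean latent coupling over
   ``signal_rois`` and ``eps`` is standard normal.  ``effect_size = 0``
   yields a null cohort.
5. *Covariates*: age, sex and head motion drawn independently of the score
   unless ``motion_confound`` is nonzero, in which case motion is scaled by
   ``exp(motion_confound * z_score)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .connectome import symmetrize_structural
from .errors import ConfigError

__all__ = ["SyntheticConfig", "SubjectRecord", "generate_cohort"]

# Internal construction constants (documented above; not study conditions).
_COUNT_LOG_MEAN = math.log(150.0)
_COUNT_GROUP_SD = 0.8
_COUNT_SUBJECT_SD = 0.4
_SUBJECT_SCALE_SD = 0.25
_VOLUME_LOG_MEAN = math.log(300.0)
_VOLUME_GROUP_SD = 0.3
_VOLUME_SUBJECT_SD = 0.05
_SPURIOUS_EDGE_FRACTION = 0.08
_SPURIOUS_PREVALENCE = 0.2
_SPURIOUS_LOG_MEAN = math.log(30.0)
_LAMBDA_BASE_RANGE = (0.3, 0.7)
_LAMBDA_SD = 0.25
_CIRCUIT_SHARE = 0.6  # variance share of the common factor within signal_rois
_R_LO, _R_HI = 0.05, 0.80
_EDGE_NOISE_MAX = 2.0
_EDGE_NOISE_MIN = 0.02
_OFF_EDGE_R_SD = 0.03
_GMV_SUBJECT_SD = 0.1


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``effect_size`` is the standardized slope of the behavioral score on the
    cohort-standardized mean latent coupling of ``signal_rois``; with the
    defaults (score_sd 3, noise_sd 1.8) an effect size of 0.8 gives a total
    score SD of 3 and a score-coupling correlation of 0.8.  Score scale
    defaults mimic an averaged music-perception battery score in the 14.5 to
    29.5 range.
    """

    n_subjects: int = 106
    n_rois: int = 246
    n_timepoints: int = 300
    backbone_density: float = 0.6
    signal_rois: tuple[int, ...] = ()
    effect_size: float = 0.0
    noise_sd: float = 1.8
    score_mean: float = 22.0
    score_sd: float = 3.0
    samples_per_voxel: int = 5000
    sampling_interval: float = 2.0
    motion_confound: float = 0.0
    mode: str = "timeseries"  # "timeseries" | "fc"
    seed: int = 0

    def __post_init__(self) -> None:
        self.signal_rois = tuple(int(i) for i in self.signal_rois)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_rois < 2:
            raise ConfigError("need n_subjects >= 1 and n_rois >= 2")
        if self.n_timepoints < 10:
            raise ConfigError("n_timepoints < 10 is too short to estimate FC")
        if not (0.0 < self.backbone_density <= 1.0):
            raise ConfigError("backbone_density must be in (0, 1]")
        if any(i < 0 or i >= self.n_rois for i in self.signal_rois):
            raise ConfigError("signal_rois must lie in [0, n_rois)")
        if self.effect_size != 0.0 and not self.signal_rois:
            raise ConfigError("nonzero effect_size requires signal_rois")
        if self.noise_sd <= 0 or self.score_sd <= 0:
            raise ConfigError("noise_sd and score_sd must be positive")
        if self.samples_per_voxel < 1:
            raise ConfigError("samples_per_voxel must be positive")
        if self.sampling_interval <= 0:
            raise ConfigError("sampling_interval must be positive")
        if self.mode not in ("timeseries", "fc"):
            raise ConfigError("mode must be 'timeseries' or 'fc'")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["signal_rois"] = list(self.signal_rois)
        return d


@dataclass
class SubjectRecord:
    """One subject's raw data plus phenotype row.

    ``latent_coupling`` is the generator's ground-truth coupling level per
    ROI; it is carried for diagnostics and never used by the analysis.
    """

    subject_id: str
    sc_counts: np.ndarray  # (n, n) nonnegative ints, zero diagonal
    roi_volumes: np.ndarray  # (n,) positive voxel counts
    gmv: np.ndarray  # (n,) positive gray-matter volumes
    score: float
    age: float
    sex: int
    motion: float
    timeseries: np.ndarray | None = None  # (T, n), zero column mean
    fc: np.ndarray | None = None  # (n, n) Fisher-z, fast mode only
    alff_raw: np.ndarray | None = None  # (n,) spectral-model ALFF, fast mode only
    latent_coupling: np.ndarray | None = None
    samples_per_voxel: int = 5000


def _backbone(rng: np.random.Generator, n: int, density: float) -> np.ndarray:
    """Connected symmetric binary graph at approximately the given density."""
    iu, ju = np.triu_indices(n, k=1)
    n_possible = iu.size
    target = max(n - 1, int(round(density * n_possible)))
    adj = np.zeros((n, n), dtype=bool)
    chain = rng.permutation(n)
    adj[chain[:-1], chain[1:]] = True
    adj |= adj.T
    present = adj[iu, ju]
    extra_needed = target - int(present.sum())
    if extra_needed > 0:
        pool = np.flatnonzero(~present)
        chosen = rng.choice(pool, size=min(extra_needed, pool.size), replace=False)
        adj[iu[chosen], ju[chosen]] = True
        adj |= adj.T
    return adj


def _band_limited_noise(
    rng: np.random.Generator, n_t: int, n_cols: int, dt: float,
    band: tuple[float, float] = (0.01, 0.2),
) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to a frequency band.

    The same spectral mask is applied to every column, so mixing the columns
    afterwards preserves the intended cross-column correlations.
    """
    z = rng.standard_normal((n_t, n_cols))
    freqs = np.fft.rfftfreq(n_t, d=dt)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():  # band empty at this resolution: keep white noise
        return z
    spec = np.fft.rfft(z, axis=0)
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n_t, axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def _nearest_correlation(c: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Clip eigenvalues and renormalize to unit diagonal."""
    c = (c + c.T) / 2.0
    w, v = np.linalg.eigh(c)
    w = np.clip(w, eps, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diagonal(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def generate_cohort(config: SyntheticConfig) -> list[SubjectRecord]:
    """Draw a full cohort; deterministic given ``config`` (seed included)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, n_sub, n_t = config.n_rois, config.n_subjects, config.n_timepoints

    adj = _backbone(rng, n, config.backbone_density)
    iu, ju = np.triu_indices(n, k=1)
    bb_edges = np.flatnonzero(adj[iu, ju])
    n_bb = bb_edges.size

    mu_e = rng.lognormal(_COUNT_LOG_MEAN, _COUNT_GROUP_SD, size=n_bb)
    group_vol = rng.lognormal(_VOLUME_LOG_MEAN, _VOLUME_GROUP_SD, size=n)

    n_spur = max(1, int(round(_SPURIOUS_EDGE_FRACTION * n_bb)))
    off_pool = np.flatnonzero(~adj[iu, ju])
    n_spur = min(n_spur, off_pool.size)
    spur_edges = rng.choice(off_pool, size=n_spur, replace=False) if n_spur else np.array([], int)
    mu_spur = rng.lognormal(_SPURIOUS_LOG_MEAN, 0.5, size=n_spur)

    lam_base = rng.uniform(*_LAMBDA_BASE_RANGE, size=n)
    z_lam = rng.standard_normal((n_sub, n))
    if config.signal_rois:
        # ROIs of the designated circuit share a subject-level coupling
        # factor (pairwise correlation _CIRCUIT_SHARE), as expected for
        # regions belonging to one functional circuit.
        shared = rng.standard_normal(n_sub)
        sig = list(config.signal_rois)
        z_lam[:, sig] = (
            np.sqrt(_CIRCUIT_SHARE) * shared[:, None]
            + np.sqrt(1.0 - _CIRCUIT_SHARE) * z_lam[:, sig]
        )
    lam = np.clip(lam_base[None, :] + _LAMBDA_SD * z_lam, 0.02, 0.98)

    records: list[SubjectRecord] = []
    for s in range(n_sub):
        g_s = rng.lognormal(0.0, _SUBJECT_SCALE_SD)
        counts = np.zeros((n, n))
        bi, bj = iu[bb_edges], ju[bb_edges]
        counts[bi, bj] = np.round(
            g_s * mu_e * np.exp(_COUNT_SUBJECT_SD * rng.standard_normal(n_bb))
        )
        counts[bj, bi] = np.round(
            g_s * mu_e * np.exp(_COUNT_SUBJECT_SD * rng.standard_normal(n_bb))
        )
        if n_spur:
            present = rng.random(n_spur) < _SPURIOUS_PREVALENCE
            si, sj = iu[spur_edges], ju[spur_edges]
            fwd = np.round(
                g_s * mu_spur * np.exp(_COUNT_SUBJECT_SD * rng.standard_normal(n_spur))
            ) * present
            rev = np.round(
                g_s * mu_spur * np.exp(_COUNT_SUBJECT_SD * rng.standard_normal(n_spur))
            ) * present
            counts[si, sj] = fwd
            counts[sj, si] = rev
        counts = counts.astype(np.int64)
        vols = group_vol * np.exp(_VOLUME_SUBJECT_SD * rng.standard_normal(n))

        w = symmetrize_structural(counts, vols, config.samples_per_voxel)
        wi, wj = np.nonzero(np.triu(w, k=1))
        wvals = w[wi, wj]
        order = np.argsort(wvals, kind="stable")
        u = np.empty(wvals.size)
        u[order] = np.arange(wvals.size) / max(wvals.size - 1, 1)
        r_base = _R_LO + (_R_HI - _R_LO) * u
        # Decoupling is multiplicative across the two endpoints and squared,
        # so an edge stays clean whenever either ROI is strongly coupled and
        # noise grows steeply only when both are decoupled; this keeps the
        # per-ROI rank correlation a sharp readout of that ROI's own level.
        decouple = (1.0 - lam[s, wi]) * (1.0 - lam[s, wj])
        noise_sd = _EDGE_NOISE_MIN + _EDGE_NOISE_MAX * decouple**2
        r_edge = np.clip(r_base + noise_sd * rng.standard_normal(wvals.size), -0.9, 0.95)

        c = np.zeros((n, n))
        c[wi, wj] = r_edge
        off_i, off_j = np.nonzero(np.triu(w == 0, k=1))
        c[off_i, off_j] = np.clip(
            _OFF_EDGE_R_SD * rng.standard_normal(off_i.size), -0.3, 0.3
        )
        c = c + c.T
        np.fill_diagonal(c, 1.0)
        c = _nearest_correlation(c)
        chol = np.linalg.cholesky(c)

        z = _band_limited_noise(rng, n_t, n, config.sampling_interval)
        x = z @ chol.T
        x = x - x.mean(axis=0, keepdims=True)

        gmv = vols * 0.027 * np.exp(_GMV_SUBJECT_SD * rng.standard_normal(n))

        age = float(rng.integers(18, 25))
        sex = int(rng.integers(0, 2))
        motion = float(rng.lognormal(math.log(0.08), 0.3))

        rec = SubjectRecord(
            subject_id=f"sub-{s + 1:04d}",
            sc_counts=counts,
            roi_volumes=vols,
            gmv=gmv,
            score=np.nan,
            age=age,
            sex=sex,
            motion=motion,
            latent_coupling=lam[s].copy(),
            samples_per_voxel=config.samples_per_voxel,
        )
        if config.mode == "timeseries":
            rec.timeseries = x
        else:
            # Fast mode: store FC directly plus a per-ROI spectral-model ALFF
            # (log-normal regional amplitude) instead of raw time series.
            from .connectome import functional_connectivity

            rec.fc = functional_connectivity(x)
            rec.alff_raw = rng.lognormal(0.0, 0.25, size=n)
        records.append(rec)

    # Scores need the cohort-standardized latent coupling of the signal ROIs.
    eps = rng.standard_normal(n_sub)
    if config.signal_rois:
        mean_lam = lam[:, list(config.signal_rois)].mean(axis=1)
        sd = mean_lam.std()
        z_lam = (mean_lam - mean_lam.mean()) / sd if sd > 0 else np.zeros(n_sub)
    else:
        z_lam = np.zeros(n_sub)
    scores = (
        config.score_mean
        + config.effect_size * config.score_sd * z_lam
        + config.noise_sd * eps
    )
    if config.motion_confound != 0.0:
        z_score = (scores - scores.mean()) / (scores.std() or 1.0)
        for s, rec in enumerate(records):
            rec.motion = float(rec.motion * np.exp(config.motion_confound * z_score[s]))
    for s, rec in enumerate(records):
        rec.score = float(scores[s])
        if not np.isfinite(rec.score):
            raise ConfigError("generated a non-finite behavioral score")
    return records
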