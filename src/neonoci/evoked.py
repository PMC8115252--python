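"""Noxious-evoked response estimation and map-level statistics.

Pipeline: per-subject voxelwise GLM of the event-related run against the
HRF-convolved stimulus regressor (plus intercept and polynomial drift),
a one-sample group t-map across subjects, and a scalar *overall response
amplitude* per subject defined as the spatial-regression slope of the
subject beta map on the group map.  Expression of external template maps
(adult pain signatures, meta-analytic association maps) is quantified by
spatial Pearson correlation or cosine similarity, with group-level and
between-subject inference by sign-flip / permutation tests.  Cluster-level
inference uses one-sample sign-flip permutation of subject maps with a
variance-smoothed pseudo-t statistic and max-cluster-size family-wise error
control.

No temporal prewhitening is applied in the GLM; drift regressors stand in
for high-pass filtering, and the synthetic noise model keeps temporal
autocorrelation mild.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .hrf import Hrf, double_gamma_hrf
from .images import Bold4D, VoxelMap
from .permutation import PermResult, exhaustive_p, mc_p

__all__ = [
    "GlmResult",
    "ClusterResult",
    "build_design",
    "stimulus_regressor",
    "glm_fit",
    "group_tmap",
    "cluster_inference",
    "overall_amplitude",
    "template_expression",
    "group_expression_test",
    "perm_correlation",
    "effective_tests",
]


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def stimulus_regressor(events: pd.DataFrame, n_vols: int, tr: float,
                       hrf: Hrf = Hrf()) -> np.ndarray:
    """Boxcar-of-events convolved with the HRF, sampled at volume times.

    The convolution is performed on the HRF's fine grid (step ``hrf.dt``)
    and linearly interpolated at acquisition times t = 0, tr, 2 tr, ...
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if n_vols < 1:
        raise ValueError("empty run")
    run_dur = n_vols * tr
    onsets = np.asarray(events["onset"], dtype=float)
    durations = np.asarray(events["duration"], dtype=float)
    if np.any(durations < 0):
        raise ValueError("negative event duration")
    if np.any(onsets + durations > run_dur + 1e-9):
        raise ValueError("events extend beyond run end")
    dt = hrf.dt
    fine_t = np.arange(0.0, run_dur + hrf.duration, dt)
    boxcar = np.zeros_like(fine_t)
    for on, du in zip(onsets, durations):
        boxcar[(fine_t >= on) & (fine_t < on + du)] = 1.0
    _, kernel = double_gamma_hrf(hrf)
    conv = np.convolve(boxcar, kernel)[: fine_t.size] * dt
    vol_t = np.arange(n_vols) * tr
    return np.interp(vol_t, fine_t, conv)


def build_design(events: pd.DataFrame, n_vols: int, tr: float,
                 hrf: Hrf = Hrf(), drift_order: int = 1) -> np.ndarray:
    """Design matrix: [stimulus, intercept, demeaned polynomial drifts].

    Column 0 is the HRF-convolved stimulus regressor; column 1 the
    intercept; columns 2..1+drift_order are Legendre-style polynomial drift
    terms in normalised time, each demeaned so they are orthogonal to the
    intercept.
    """
    if drift_order < 0:
        raise ValueError("drift_order must be >= 0")
    stim = stimulus_regressor(events, n_vols, tr, hrf)
    cols = [stim, np.ones(n_vols)]
    if n_vols > 1:
        tau = np.linspace(-1.0, 1.0, n_vols)
        for k in range(1, drift_order + 1):
            col = tau ** k
            cols.append(col - col.mean())
    elif drift_order > 0:
        raise ValueError("cannot build drift terms for a single volume")
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Subject GLM
# ---------------------------------------------------------------------------

@dataclass
class GlmResult:
    """Per-voxel OLS fit of a 4D run against a design matrix."""

    betas: list           # one VoxelMap per design column
    residual_variance: VoxelMap
    goodness_of_fit: VoxelMap   # per-voxel R^2 in [0, 1]
    df: int
    design: np.ndarray = field(repr=False, default=None)

    @property
    def stimulus_beta(self) -> VoxelMap:
        return self.betas[0]


def glm_fit(bold: Bold4D, design: np.ndarray, mask: Optional[np.ndarray] = None) -> GlmResult:
    """Voxelwise ordinary least squares of a 4D run on a design matrix."""
    design = np.asarray(design, dtype=float)
    n_vols, p = design.shape
    if n_vols != bold.n_vols:
        raise ValueError(f"design rows {n_vols} != run volumes {bold.n_vols}")
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    df = n_vols - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    mask = bold.mask if mask is None else np.asarray(mask, dtype=bool)
    Y = bold.data[mask].T                       # (T, V)
    beta, _, _, _ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    ss_res = np.sum(resid ** 2, axis=0)
    ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    proto = VoxelMap(np.zeros(bold.data.shape[:3]), mask,
                     bold.voxel_size_mm, bold.affine)
    betas = [proto.embed(beta[j]) for j in range(p)]
    return GlmResult(
        betas=betas,
        residual_variance=proto.embed(ss_res / df),
        goodness_of_fit=proto.embed(r2),
        df=df,
        design=design,
    )


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def _common_stack(maps: Sequence[VoxelMap]) -> tuple[np.ndarray, VoxelMap]:
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    mask = maps[0].mask
    for m in maps[1:]:
        if m.data.shape != maps[0].data.shape or not np.array_equal(m.mask, mask):
            raise ValueError("maps must share grid and mask")
    data = np.stack([m.values() for m in maps])   # (n, V)
    return data, maps[0]


def group_tmap(beta_maps: Sequence[VoxelMap]) -> VoxelMap:
    """One-sample t-statistic map across subject beta maps.

    t = mean / (sd / sqrt(n)) with the n-1 sample standard deviation.
    Voxels with zero across-subject variance get t = 0 and raise a warning
    (phantom edges commonly produce them).
    """
    data, proto = _common_stack(beta_maps)
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance voxel(s): t set to 0",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, mean / np.where(zero, 1.0, sd / math.sqrt(n)))
    return proto.embed(t)


def overall_amplitude(subject_map: VoxelMap, group_map: VoxelMap,
                      mask: Optional[np.ndarray] = None) -> float:
    """Spatial-regression amplitude of a subject map on the group map.

    OLS slope of ``subject = beta * group + intercept`` over in-mask voxels:
    a per-subject scale factor relative to the group-average response.
    """
    mask = group_map.mask if mask is None else np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    g = group_map.data[mask]
    s = subject_map.data[mask]
    gc = g - g.mean()
    var_g = np.dot(gc, gc)
    if var_g == 0:
        raise ValueError("group map constant within mask")
    return float(np.dot(gc, s - s.mean()) / var_g)


def template_expression(subject_map: VoxelMap, template: VoxelMap,
                        mask: Optional[np.ndarray] = None,
                        method: str = "pearson") -> float:
    """Spatial similarity of a subject map to a template.

    ``pearson`` demeans both maps; ``cosine`` does not (it therefore retains
    magnitude/offset information, appropriate for signature-response scores).
    """
    mask = template.mask if mask is None else np.asarray(mask, dtype=bool)
    s = subject_map.data[mask]
    t = template.data[mask]
    if method == "pearson":
        if s.std() == 0 or t.std() == 0:
            raise ValueError("constant map: Pearson expression undefined")
        return float(np.corrcoef(s, t)[0, 1])
    if method == "cosine":
        ns, nt = np.linalg.norm(s), np.linalg.norm(t)
        if ns == 0 or nt == 0:
            raise ValueError("zero map: cosine expression undefined")
        return float(np.dot(s, t) / (ns * nt))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def _one_sample_t(x: np.ndarray) -> float:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance input")
    return float(x.mean() / (sd / math.sqrt(x.size)))


def group_expression_test(values: Sequence[float], n_perm: int = 10000,
                          seed: int = 0) -> PermResult:
    """One-sample t-test with a sign-flip permutation null (two-tailed).

    Exhaustive over all 2^n sign patterns when that is no larger than
    ``n_perm``; Monte-Carlo otherwise.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    t_obs = _one_sample_t(x)
    if 2 ** n <= n_perm:
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
        flipped = signs * x
        # sign patterns can zero the sample sd; such patterns get t = +-inf
        with np.errstate(divide="ignore", invalid="ignore"):
            null = flipped.mean(axis=1) / (flipped.std(axis=1, ddof=1) / math.sqrt(n))
        p = exhaustive_p(int(np.sum(np.abs(null) >= abs(t_obs) - 1e-12)), signs.shape[0])
        return PermResult(t_obs, null, p, "two", "exhaustive", signs.shape[0], seed)
    rng = np.random.default_rng(seed)
    signs = rng.choice([1.0, -1.0], size=(n_perm, n))
    flipped = signs * x
    with np.errstate(divide="ignore", invalid="ignore"):
        null = flipped.mean(axis=1) / (flipped.std(axis=1, ddof=1) / math.sqrt(n))
    p = mc_p(int(np.sum(np.abs(null) >= abs(t_obs) - 1e-12)), n_perm)
    return PermResult(t_obs, null, p, "two", "monte_carlo", n_perm, seed)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("constant input: correlation undefined")
    return float(np.dot(xc, yc) / (nx * ny))


def perm_correlation(x: Sequence[float], y: Sequence[float], tails: str = "two",
                     direction: str = "positive", n_perm: int = 10000,
                     seed: int = 0) -> PermResult:
    """Pearson correlation with a permutation null (y permuted).

    Exhaustive over all n! orderings when that is no larger than ``n_perm``.
    One-tailed tests use the signed correlation in the hypothesised
    ``direction`` ("positive" or "negative").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    r_obs = _pearson(x, y)

    def extreme(r_null: np.ndarray) -> np.ndarray:
        if tails == "two":
            return np.abs(r_null) >= abs(r_obs) - 1e-12
        if direction == "positive":
            return r_null >= r_obs - 1e-12
        return r_null <= r_obs + 1e-12

    if math.factorial(x.size) <= n_perm:
        perms = np.array(list(itertools.permutations(range(x.size))))
        null = np.array([_pearson(x, y[p]) for p in perms])
        p = exhaustive_p(int(extreme(null).sum()), perms.shape[0])
        return PermResult(r_obs, null, p, tails, "exhaustive", perms.shape[0], seed)
    rng = np.random.default_rng(seed)
    null = np.array([_pearson(x, rng.permutation(y)) for _ in range(n_perm)])
    p = mc_p(int(extreme(null).sum()), n_perm)
    return PermResult(r_obs, null, p, tails, "monte_carlo", n_perm, seed)


# ---------------------------------------------------------------------------
# Effective number of tests
# ---------------------------------------------------------------------------

def effective_tests(corr_matrix: np.ndarray, method: str = "liji",
                    family_alpha: float = 0.05) -> dict:
    """Effective number of independent tests from a correlation matrix.

    ``liji``: m_eff = sum_i [ 1(lambda_i >= 1) + frac(lambda_i) ] over the
    eigenvalues of the elementwise-absolute correlation matrix.
    ``nyholt``: m_eff = 1 + (m - 1) (1 - var(lambda)/m), sample variance with
    the m-1 denominator.  The family alpha is Bonferroni-divided by m_eff.
    """
    C = np.asarray(corr_matrix, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    m = C.shape[0]
    if method == "liji":
        lam = np.linalg.eigvalsh(np.abs(C))
        lam = np.clip(lam, 0.0, None)
        # snap near-integer eigenvalues so the floor is numerically stable
        near = np.abs(lam - np.round(lam)) < 1e-9
        lam = np.where(near, np.round(lam), lam)
        m_eff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    elif method == "nyholt":
        lam = np.linalg.eigvalsh(C)
        var = lam.var(ddof=1) if m > 1 else 0.0
        m_eff = float(1.0 + (m - 1) * (1.0 - var / m))
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"m_eff": m_eff, "corrected_alpha": family_alpha / m_eff}


# ---------------------------------------------------------------------------
# Cluster inference
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    z_map: VoxelMap               # permutation-rank z of the observed pseudo-t
    thresholded: VoxelMap         # z map retained only in FWER-significant clusters
    clusters: pd.DataFrame        # size (voxels), fwer_p, significant
    null_max_size: np.ndarray
    convention: str
    n_perm: int
    seed: int


def _smooth_in_mask(values: np.ndarray, mask: np.ndarray, sigma_vox: np.ndarray) -> np.ndarray:
    """Gaussian smoothing restricted to the mask (mask-normalised)."""
    vol = np.zeros(mask.shape)
    vol[mask] = values
    num = ndimage.gaussian_filter(vol, sigma=sigma_vox)
    den = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_vox)
    with np.errstate(divide="ignore", invalid="ignore"):
        sm = np.where(den > 1e-12, num / np.where(den > 1e-12, den, 1.0), 0.0)
    return sm[mask]


def cluster_inference(beta_maps: Sequence[VoxelMap], cluster_forming_p: float = 0.001,
                      n_perm: int = 10000, variance_fwhm_mm: float = 6.0,
                      alpha: float = 0.05, seed: int = 0,
                      connectivity: int = 26) -> ClusterResult:
    """One-sample cluster inference by sign-flip permutation.

    The test statistic is a pseudo-t whose denominator variance map is
    Gaussian-smoothed at ``variance_fwhm_mm`` (stabilising low-df variance
    estimates).  Each voxel's pseudo-t is converted to a z-score through its
    own permutation-null rank, clusters are formed at
    z >= Phi^-1(1 - cluster_forming_p) with the requested connectivity
    (default 26, i.e. faces+edges+corners), the cluster statistic is voxel
    count, and the family-wise error p of each observed cluster is the
    proportion of permutations whose maximum cluster size is at least as
    large.  With n subjects the null is enumerated exhaustively (all 2^n
    sign patterns) whenever that is no larger than ``n_perm``.
    """
    data, proto = _common_stack(beta_maps)
    n, V = data.shape
    if n < 4:
        raise ValueError("need at least 4 subjects for cluster inference")
    if not (0.0 < cluster_forming_p < 1.0):
        raise ValueError("cluster_forming_p must lie in (0, 1)")
    vox = np.asarray(proto.voxel_size_mm, dtype=float)
    sigma_vox = (variance_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))) / vox
    if min(proto.mask.shape) < 2:
        raise ValueError("mask too small for smoothing kernel")

    if 2 ** n <= n_perm:
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
        # identity flip first so row 0 is the observed statistic
        order = np.argsort(-signs.sum(axis=1), kind="stable")
        signs = signs[order]
        convention = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_perm + 1, n))
        signs[0] = 1.0
        convention = "monte_carlo"
    n_rows = signs.shape[0]

    pseudo_t = np.empty((n_rows, V))
    sqrt_n = math.sqrt(n)
    for i, s in enumerate(signs):
        flipped = data * s[:, None]
        mean = flipped.mean(axis=0)
        var = flipped.var(axis=0, ddof=1)
        var_sm = _smooth_in_mask(var, proto.mask, sigma_vox)
        denom = np.sqrt(np.clip(var_sm, 1e-30, None)) / sqrt_n
        pseudo_t[i] = mean / denom

    # voxelwise permutation-rank z: p = #{other rows >= value} / n_rows,
    # clipped away from 0 so the top rank maps to a finite z
    ranks = stats.rankdata(pseudo_t, axis=0, method="min")
    p_exceed = (n_rows - ranks) / n_rows
    z = stats.norm.isf(np.clip(p_exceed, 1.0 / (2.0 * n_rows), 1.0))
    z_thresh = stats.norm.isf(cluster_forming_p)

    structure = (np.ones((3, 3, 3), dtype=bool) if connectivity == 26
                 else ndimage.generate_binary_structure(3, 1))

    def max_cluster_size(zrow: np.ndarray) -> int:
        supra = proto.embed((zrow >= z_thresh).astype(float)).data > 0.5
        labels, nlab = ndimage.label(supra, structure=structure)
        if nlab == 0:
            return 0
        return int(np.bincount(labels.ravel())[1:].max())

    null_max = np.array([max_cluster_size(z[i]) for i in range(1, n_rows)])

    supra_obs = proto.embed((z[0] >= z_thresh).astype(float)).data > 0.5
    labels, nlab = ndimage.label(supra_obs, structure=structure)
    rows = []
    keep = np.zeros(proto.mask.shape, dtype=bool)
    for lab in range(1, nlab + 1):
        size = int(np.sum(labels == lab))
        if convention == "exhaustive":
            count = int(np.sum(null_max >= size)) + 1   # identity row counts
            p = exhaustive_p(count, n_rows)
        else:
            p = mc_p(int(np.sum(null_max >= size)), n_rows - 1)
        sig = p <= alpha
        if sig:
            keep |= labels == lab
        rows.append({"cluster": lab, "size": size, "fwer_p": p, "significant": sig})
    z_map = proto.embed(z[0])
    thresholded = z_map.with_data(np.where(keep, z_map.data, 0.0))
    table = pd.DataFrame(rows, columns=["cluster", "size", "fwer_p", "significant"])
    return ClusterResult(z_map, thresholded, table, null_max, convention,
                         n_rows if convention == "exhaustive" else n_rows - 1, seed)
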