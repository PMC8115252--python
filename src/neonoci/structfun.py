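"""Exploratory-confirmatory structure-function analysis.

White-matter microstructure is summarised per tract as the mean of a
diffusion parameter map (MD, FA or MK) over the thresholded tract
probability mask, after removing voxels outside each parameter's
theoretical range.  The exploratory arm screens all 16 tracts x 3
parameters = 48 confound-adjusted Pearson correlations against (predicted)
response amplitudes, with family-wise error control by a single-step
max-|r| permutation (Westfall-Young style).  Tracts surviving the screen
are pooled by the first principal component of their MD (MD PC1), and the
confirmatory arm tests the hypothesised-direction correlation one-tailed
in the independent cohort, compares the chosen subset against every
possible tract combination, and correlates tract-to-tract association
profiles across datasets.

Conventions: PCA operates on column-standardized, confound-residualised
values by default (raw modes are available); the PC1 sign is fixed so the
mean loading is positive, making "higher PC1 = higher MD" and the
hypothesised correlation direction well-defined.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .images import VoxelMap
from .permutation import PermResult, mc_p

__all__ = [
    "TRACTS",
    "CONFIRMED_TRACTS",
    "DTI_PARAMS",
    "PARAM_RANGES",
    "qc_threshold_map",
    "tract_mean",
    "adjusted_correlation",
    "exploratory_screen",
    "md_pc1",
    "confirmatory_test",
    "subset_combination_analysis",
    "compare_tract_profiles",
]

#: the 16 bilateral white-matter tract labels
TRACTS = ("ar", "atr", "cgc", "cgh", "cst", "fma", "fmi", "for",
          "ifo", "ilf", "mcp", "ml", "ptr", "slf", "str", "unc")

#: tracts whose MD association is carried to the confirmatory arm
CONFIRMED_TRACTS = ("atr", "cst", "fmi", "str", "unc")

DTI_PARAMS = ("MD", "FA", "MK")

#: theoretical ranges; voxels outside are treated as noise and removed
PARAM_RANGES = {"MD": (0.0, np.inf), "FA": (0.0, 1.0), "MK": (0.0, 3.0)}


# ---------------------------------------------------------------------------
# Tract features
# ---------------------------------------------------------------------------

def qc_threshold_map(param_map: VoxelMap, kind: str) -> tuple[VoxelMap, int]:
    """Remove voxels outside the parameter's theoretical range.

    Returns the map with a tightened mask and the number of removed voxels
    (counted among previously in-mask voxels).
    """
    if kind not in PARAM_RANGES:
        raise ValueError(f"unknown parameter kind {kind!r}")
    lo, hi = PARAM_RANGES[kind]
    ok = (param_map.data >= lo) & (param_map.data <= hi)
    removed = int(np.sum(param_map.mask & ~ok))
    cleaned = VoxelMap(param_map.data, param_map.mask & ok,
                       param_map.voxel_size_mm, param_map.affine)
    return cleaned, removed


def tract_mean(param_map: VoxelMap, tract_prob_map: VoxelMap,
               prob_threshold: float = 0.01) -> float:
    """Mean parameter value over the thresholded tract probability mask."""
    sel = (tract_prob_map.data >= prob_threshold) & param_map.mask
    if not sel.any():
        raise ValueError("empty tract mask after thresholding and QC")
    return float(param_map.data[sel].mean())


# ---------------------------------------------------------------------------
# Adjusted correlation and the exploratory screen
# ---------------------------------------------------------------------------

def _residuals(A: np.ndarray, Z: Optional[np.ndarray]) -> np.ndarray:
    """Residuals of columns of A on [Z, 1] (full-sample OLS)."""
    A = np.asarray(A, dtype=float)
    squeeze = A.ndim == 1
    if squeeze:
        A = A[:, None]
    n = A.shape[0]
    if Z is None or np.asarray(Z).size == 0:
        Z1 = np.ones((n, 1))
    else:
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        Z1 = np.column_stack([Z, np.ones(n)])
    if np.linalg.matrix_rank(Z1) < Z1.shape[1]:
        raise ValueError("confound matrix rank deficient")
    beta, _, _, _ = np.linalg.lstsq(Z1, A, rcond=None)
    resid = A - Z1 @ beta
    return resid[:, 0] if squeeze else resid


def adjusted_correlation(x, y, Z=None) -> float:
    """Pearson correlation of the confound residuals of x and y.

    Both variables are residualised on the confound matrix Z (plus
    intercept); with Z empty this is the plain Pearson correlation.
    """
    rx = _residuals(np.asarray(x, dtype=float), Z)
    ry = _residuals(np.asarray(y, dtype=float), Z)
    nx, ny = np.linalg.norm(rx - rx.mean()), np.linalg.norm(ry - ry.mean())
    if nx < 1e-12 or ny < 1e-12:
        raise ValueError("zero-variance residual: correlation undefined")
    return float(np.dot(rx - rx.mean(), ry - ry.mean()) / (nx * ny))


@dataclass
class ScreenResult:
    """Per-(tract, parameter) adjusted correlations with FWER control."""

    table: pd.DataFrame           # tract, parameter, r, p, fwer_p, significant
    alpha: float
    n_perm: int
    seed: int
    null_max_abs_r: np.ndarray

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def _std_columns(A: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=0)
    norms = np.linalg.norm(Ac, axis=0)
    if np.any(norms < 1e-12):
        raise ValueError("zero-variance column")
    return Ac / norms


def exploratory_screen(amplitudes, feature_table: pd.DataFrame,
                       confounds=None, alpha: float = 0.05,
                       n_perm: int = 10000, seed: int = 0) -> ScreenResult:
    """Max-statistic permutation screen over all tract/parameter features.

    Each column of ``feature_table`` (named ``{tract}_{PARAM}``) is tested
    for confound-adjusted Pearson correlation with the amplitude vector.
    Every permutation shuffles the amplitude vector, re-residualises it on
    the confounds, recomputes all adjusted correlations and records the
    maximum |r|; the FWER p of feature i is (1 + #{max_b >= |r_i|})/(1 + B).
    Per-feature unadjusted p-values use the same permutations featurewise.
    """
    y = np.asarray(amplitudes, dtype=float)
    F = feature_table.to_numpy(dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 subjects for the screen")
    if F.shape[0] != n:
        raise ValueError("feature table row count mismatch")
    if np.isnan(F).any():
        raise ValueError("feature table contains missing values; drop incomplete rows first")
    Z = None if confounds is None else np.asarray(confounds, dtype=float)

    U = _std_columns(_residuals(F, Z))            # (n, m), unit-norm columns
    yr = _residuals(y, Z)
    yv = (yr - yr.mean())
    r_obs = U.T @ (yv / np.linalg.norm(yv))

    rng = np.random.default_rng(seed)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    Yp = _residuals(y[perm_idx.T], Z)             # (n, B) residualised perms
    Yp = Yp - Yp.mean(axis=0)
    Yp /= np.linalg.norm(Yp, axis=0)
    R = U.T @ Yp                                   # (m, B)
    null_max = np.abs(R).max(axis=0)
    fwer_p = np.array([mc_p(int(np.sum(null_max >= abs(r) - 1e-12)), n_perm)
                       for r in r_obs])
    p_unadj = np.array([mc_p(int(np.sum(np.abs(R[i]) >= abs(r_obs[i]) - 1e-12)), n_perm)
                        for i in range(r_obs.size)])

    tracts, params = [], []
    for col in feature_table.columns:
        tract, _, param = col.rpartition("_")
        tracts.append(tract)
        params.append(param)
    table = pd.DataFrame({
        "tract": tracts, "parameter": params,
        "r": r_obs, "p": p_unadj, "fwer_p": fwer_p,
        "significant": fwer_p <= alpha,
    })
    return ScreenResult(table, alpha, n_perm, seed, null_max)


# ---------------------------------------------------------------------------
# MD PC1 pooling and confirmation
# ---------------------------------------------------------------------------

def md_pc1(values: np.ndarray, standardize: bool = True) -> dict:
    """First principal component of a subjects x tracts matrix.

    Returns PC1 ``scores`` (projections), the ``variance_fraction`` carried
    by PC1, and the ``loadings``; the sign is fixed so the mean loading is
    positive.
    """
    A = np.asarray(values, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    n, k = A.shape
    if n < 2 or k < 1:
        raise ValueError("need >= 2 subjects and >= 1 tract")
    Ac = A - A.mean(axis=0)
    if standardize:
        sd = Ac.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance column cannot be standardized")
        Ac = Ac / sd
    U, S, Vt = np.linalg.svd(Ac, full_matrices=False)
    loadings = Vt[0]
    if loadings.mean() < 0:
        loadings = -loadings
    scores = Ac @ loadings
    total = float(np.sum(S ** 2))
    frac = float(S[0] ** 2 / total) if total > 0 else 1.0
    return {"scores": scores, "variance_fraction": frac, "loadings": loadings}


def confirmatory_test(amplitudes, md_subset: pd.DataFrame, confounds=None,
                      direction: str = "negative", n_perm: int = 10000,
                      seed: int = 0, residualize_first: bool = True,
                      standardize: bool = True) -> dict:
    """One-tailed confirmation of the pooled-MD association.

    Per-tract adjusted correlation signs are reported as the polarity table;
    MD PC1 is built (by default from confound-residualised, standardized
    values), correlated with the amplitudes after adjustment, and tested
    one-tailed in the hypothesised ``direction`` by permuting amplitudes.
    Rows with missing tract values are dropped (subjects with incomplete
    diffusion data).
    """
    if direction not in ("negative", "positive"):
        raise ValueError("direction must be 'negative' or 'positive'")
    y = np.asarray(amplitudes, dtype=float)
    M = md_subset.to_numpy(dtype=float)
    Z = None if confounds is None else np.asarray(confounds, dtype=float)
    complete = ~(np.isnan(M).any(axis=1) | np.isnan(y))
    if Z is not None:
        complete &= ~np.isnan(Z).any(axis=1)
        Z = Z[complete]
    y, M = y[complete], M[complete]
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 complete subjects")

    polarity = pd.DataFrame({
        "tract": list(md_subset.columns),
        "r": [adjusted_correlation(M[:, j], y, Z) for j in range(M.shape[1])],
    })
    polarity["sign"] = np.sign(polarity["r"]).astype(int)

    basis = _residuals(M, Z) if residualize_first else M
    pca = md_pc1(basis, standardize=standardize)
    pc1 = pca["scores"]
    r_obs = adjusted_correlation(pc1, y, Z)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    pc_res = _residuals(pc1, Z)
    pc_res = (pc_res - pc_res.mean()) / np.linalg.norm(pc_res - pc_res.mean())
    for b in range(n_perm):
        yb = _residuals(y[rng.permutation(n)], Z)
        yb = yb - yb.mean()
        null[b] = float(pc_res @ (yb / np.linalg.norm(yb)))
    if direction == "negative":
        c = int(np.sum(null <= r_obs + 1e-12))
    else:
        c = int(np.sum(null >= r_obs - 1e-12))
    perm = PermResult(r_obs, null, mc_p(c, n_perm), "one", "monte_carlo",
                      n_perm, seed)
    return {
        "polarity": polarity,
        "pc1_r": r_obs,
        "p": perm,
        "variance_fraction": pca["variance_fraction"],
        "n": n,
        "pc1_scores": pc1,
    }


# ---------------------------------------------------------------------------
# All-subsets analysis and cross-dataset profiles
# ---------------------------------------------------------------------------

def subset_combination_analysis(amplitudes, md_table: pd.DataFrame,
                                confounds=None,
                                target_subset: Sequence[str] = CONFIRMED_TRACTS,
                                residualize_first: bool = True) -> dict:
    """Squared PC1 correlation for every nonempty tract subset.

    For each of the 2^k - 1 nonempty subsets of the tract universe, the
    subset's MD PC1 (standardized; residualised first by default) is
    correlated with the adjusted amplitudes; the target subset's percentile
    within the distribution of squared correlations is reported with the
    inclusive (<=) convention.

    The per-subset computation uses the eigenstructure of the residualised
    correlation matrix: for subset S with top eigenpair (lambda_1, v_1) and
    feature-amplitude correlation vector c_S, the PC1 correlation is
    v_1' c_S / sqrt(lambda_1).
    """
    tract_names = list(md_table.columns)
    target = list(target_subset)
    if len(target) == 0:
        raise ValueError("target subset must be nonempty")
    missing = [t for t in target if t not in tract_names]
    if missing:
        raise ValueError(f"target tracts {missing} not in table")
    y = np.asarray(amplitudes, dtype=float)
    M = md_table.to_numpy(dtype=float)
    Z = None if confounds is None else np.asarray(confounds, dtype=float)
    complete = ~(np.isnan(M).any(axis=1) | np.isnan(y))
    if Z is not None:
        complete &= ~np.isnan(Z).any(axis=1)
        Z = Z[complete]
    y, M = y[complete], M[complete]

    basis = _residuals(M, Z) if residualize_first else M
    U = _std_columns(basis)                  # unit-norm residualised columns
    yr = _residuals(y, Z)
    yv = yr - yr.mean()
    yv /= np.linalg.norm(yv)
    C = U.T @ U                              # correlation matrix of features
    c = U.T @ yv                             # feature-amplitude correlations

    k = len(tract_names)
    n_subsets = 2 ** k - 1
    r2 = np.empty(n_subsets)
    subsets = []
    for s in range(1, n_subsets + 1):
        idx = [j for j in range(k) if s >> j & 1]
        subsets.append(s)
        if len(idx) == 1:
            r2[s - 1] = c[idx[0]] ** 2
            continue
        Cs = C[np.ix_(idx, idx)]
        lam, vec = np.linalg.eigh(Cs)
        v1 = vec[:, -1]
        r2[s - 1] = float((v1 @ c[idx]) ** 2 / lam[-1])
    target_mask = sum(1 << tract_names.index(t) for t in target)
    target_r2 = r2[target_mask - 1]
    percentile = 100.0 * float(np.sum(r2 <= target_r2 + 1e-12)) / n_subsets
    return {
        "r2": pd.DataFrame({"subset_bitmask": subsets, "r2": r2}),
        "target_bitmask": target_mask,
        "target_r2": float(target_r2),
        "percentile": percentile,
        "n_subsets": n_subsets,
        "tracts": tract_names,
    }


def compare_tract_profiles(r_a: Sequence[float], r_b: Sequence[float]) -> float:
    """Pearson correlation between two per-tract association profiles."""
    a = np.asarray(r_a, dtype=float)
    b = np.asarray(r_b, dtype=float)
    if a.size != b.size:
        raise ValueError("profile length mismatch")
    if a.size < 3:
        raise ValueError("need at least 3 tracts")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant profile")
    return float(np.corrcoef(a, b)[0, 1])
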