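"""Synthetic neonatal cohorts with the latent structure the analysis assumes.

A single latent "maturity" factor m per subject drives every modality in a
linear-Gaussian generative model:

* the overall noxious-evoked response amplitude
  a = intercept + loading * m + noise, which scales a shared group response
  map embedded in the subject's 4D task run;
* positive loadings on the resting-state network amplitudes, largest for
  the somatomotor-like networks;
* negative loadings on tract-mean MD and positive loadings on FA/MK across
  16 white-matter tracts, with larger magnitudes for the five
  somatomotor/limbic tracts carried to the confirmatory arm.

The linear-Gaussian form is a deliberate convention (the real-world law is
unknown): it gives closed-form population moments, so parameter-recovery
tests have analytic targets.  Defaults are documented in docs/methods.md;
sample-size defaults mirror the two cohorts of interest (n = 18 event-
related; n = 215 resting + diffusion).

Resting-state runs are sums of network maps times Gaussian network
timeseries whose scale is amplitude / 0.6745, so the *population MAD* of
each network timeseries equals the requested amplitude (the Gaussian
MAD/sd ratio is 0.6745) — amplitudes are therefore in the same MAD units
the analysis measures.  Task runs embed the amplitude-scaled group map
times the HRF-convolved stimulus regressor, plus per-voxel intercept,
linear drift, and AR(1) thermal noise; a zero-noise configuration yields
exactly the signal component, so the GLM recovers the amplitude to
machine precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .evoked import stimulus_regressor
from .hrf import Hrf
from .images import Bold4D, VoxelMap, write_volume
from .structfun import CONFIRMED_TRACTS, TRACTS
from .tables import MOTION_COLUMNS, write_table

__all__ = [
    "PhantomGeometry",
    "CohortSpec",
    "CohortTruth",
    "default_event_schedule",
    "gen_cohort",
    "gen_templates",
    "gen_task_run",
    "gen_rest_run",
    "gen_motion_table",
    "write_dataset",
    "RSN_LABELS",
]

#: nine replicable network labels: two visual, two auditory, two
#: somatomotor, default mode, dorsal attention, executive control
RSN_LABELS = ("vnm", "vnop", "anr", "anl", "smn1", "smn2", "dmn", "dan", "ecn")

GAUSSIAN_MAD = 0.6745  # population MAD/sd ratio of a Gaussian


def _default_mask(grid_shape: tuple) -> np.ndarray:
    nx, ny, nz = grid_shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    return ((x - cx) ** 2 / (0.45 * nx) ** 2
            + (y - cy) ** 2 / (0.45 * ny) ** 2
            + (z - cz) ** 2 / (0.45 * nz) ** 2) <= 1.0


@dataclass
class PhantomGeometry:
    """Desk-scale acquisition grid (default 24 x 24 x 16 voxels at 2 mm)."""

    grid_shape: tuple = (24, 24, 16)
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if any(d < 4 for d in self.grid_shape):
            raise ValueError("all grid dimensions must be >= 4")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.mask is None:
            self.mask = _default_mask(self.grid_shape)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.grid_shape):
            raise ValueError("mask shape does not match grid")
        if not self.mask.any():
            raise ValueError("mask is empty")

    def blank(self) -> VoxelMap:
        return VoxelMap(np.zeros(self.grid_shape), self.mask.copy(),
                        tuple(self.voxel_size_mm))


def _designated_loadings(designated_value: float, other_value: float,
                         designated: Sequence[str] = CONFIRMED_TRACTS) -> tuple:
    return tuple(designated_value if t in designated else other_value
                 for t in TRACTS)


@dataclass
class CohortSpec:
    """Parameters of the linear-Gaussian cohort generator.

    Loadings are regression coefficients on the latent factor m; noise sds
    are residual standard deviations.  The default amplitude parameters put
    60% of amplitude variance on m (signal fraction 0.6); the default MD
    loadings give the five designated tracts a per-tract correlation with m
    of about 0.31, placing the population correlation between the 5-tract
    MD PC1 and the amplitude near -0.45.
    """

    n_subjects: int = 18
    latent_sd: float = 1.0
    # amplitude: a = intercept + loading * m + N(0, noise_sd)
    amplitude_intercept: float = 1.0
    amplitude_loading: float = 1.0
    amplitude_noise_sd: float = float(np.sqrt(2.0 / 3.0))
    # resting-state network amplitudes (MAD units)
    rsn_labels: tuple = RSN_LABELS
    rsn_baselines: tuple = (1.0,) * 9
    rsn_loadings: tuple = (0.30, 0.30, 0.30, 0.30, 0.60, 0.50, 0.30, 0.30, -0.02)
    rsn_noise_sd: float = 0.15
    # tract-mean diffusion parameters; MD in 1e-3 mm^2/s units
    tract_labels: tuple = TRACTS
    designated_tracts: tuple = CONFIRMED_TRACTS
    tract_md_baselines: tuple = (1.25, 1.30, 1.35, 1.30, 1.15, 1.40, 1.35, 1.45,
                                 1.30, 1.35, 1.10, 1.05, 1.35, 1.30, 1.25, 1.30)
    tract_md_loadings: tuple = field(
        default_factory=lambda: _designated_loadings(-0.05, -0.005))
    tract_md_noise_sd: float = 0.1545
    tract_fa_baselines: tuple = (0.22, 0.25, 0.24, 0.20, 0.32, 0.30, 0.28, 0.24,
                                 0.26, 0.25, 0.30, 0.34, 0.27, 0.24, 0.26, 0.23)
    tract_fa_loadings: tuple = field(
        default_factory=lambda: _designated_loadings(0.006, 0.003))
    tract_fa_noise_sd: float = 0.03
    tract_mk_baselines: tuple = (0.72, 0.75, 0.74, 0.70, 0.82, 0.78, 0.76, 0.70,
                                 0.74, 0.73, 0.80, 0.84, 0.75, 0.72, 0.74, 0.71)
    tract_mk_loadings: tuple = field(
        default_factory=lambda: _designated_loadings(0.002, 0.001))
    tract_mk_noise_sd: float = 0.08
    # confound variables (coupling to m defaults to 0: confounds are
    # nuisance, not signal)
    confound_couplings: dict = field(default_factory=dict)
    clinical_couplings: dict = field(default_factory=dict)
    # 4D run noise model
    thermal_sd: float = 1.0
    ar1: float = 0.3
    drift_sd: float = 0.5
    # subjects with incomplete diffusion data (NaN tract rows); the default
    # mirrors one event-related-cohort subject lacking usable dMRI
    n_dmri_incomplete: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("latent_sd", "amplitude_noise_sd", "rsn_noise_sd",
                     "tract_md_noise_sd", "tract_fa_noise_sd", "tract_mk_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        k = len(self.rsn_labels)
        if k < 1:
            raise ValueError("need at least one network")
        if not (len(self.rsn_baselines) == len(self.rsn_loadings) == k):
            raise ValueError("network parameter vectors must share length")
        if any(b <= 0 for b in self.rsn_baselines):
            raise ValueError("network baselines must be positive")
        t = len(self.tract_labels)
        for name in ("tract_md_baselines", "tract_md_loadings",
                     "tract_fa_baselines", "tract_fa_loadings",
                     "tract_mk_baselines", "tract_mk_loadings"):
            if len(getattr(self, name)) != t:
                raise ValueError(f"{name} must have {t} entries")
        if not set(self.designated_tracts) <= set(self.tract_labels):
            raise ValueError("designated tracts must be a subset of tract labels")
        if not (0 <= self.n_dmri_incomplete < self.n_subjects):
            raise ValueError("n_dmri_incomplete out of range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confound_couplings"] = dict(self.confound_couplings)
        d["clinical_couplings"] = dict(self.clinical_couplings)
        return d


#: confound columns generated per subject: event-related run, resting run,
#: diffusion session
CONFOUND_SPECS = {
    "mean_fd": (0.15, 0.05),
    "stim_corr_motion": (0.20, 0.07),
    "csf_amp": (1.0, 0.2),
    "mean_fd_rest": (0.18, 0.06),
    "csf_amp_rest": (1.0, 0.2),
    "wm_amp_rest": (0.8, 0.15),
    "dmri_motion": (0.5, 0.1),
    "noisy_voxels": (200.0, 40.0),
    "tbv": (289823.0, 49021.0),
}

#: clinical variables: means/sds mirror a healthy term cohort
CLINICAL_SPECS = {
    "ga_weeks": (38.3, 1.8),
    "pma_weeks": (38.7, 1.7),
    "pna_days": (2.8, 2.3),
    "birth_weight_kg": (3.34, 0.69),
    "tbv_mm3": (289823.0, 49021.0),
}


@dataclass
class CohortTruth:
    """Ground-truth tables for a generated cohort (one row per subject)."""

    spec: CohortSpec
    subject_ids: list
    latent: np.ndarray
    amplitudes: pd.DataFrame     # subject_id, amplitude
    rsn: pd.DataFrame            # subject_id + one column per network
    tracts: pd.DataFrame         # subject_id + 48 {tract}_{PARAM} columns
    confounds: pd.DataFrame
    clinical: pd.DataFrame


def gen_cohort(spec: CohortSpec) -> CohortTruth:
    """Draw a cohort from the linear-Gaussian latent model.

    Deterministic: identical (spec, seed) yields bit-identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    ids = [f"sub-{i:03d}" for i in range(n)]
    m = rng.normal(0.0, spec.latent_sd, n)

    a = (spec.amplitude_intercept + spec.amplitude_loading * m
         + rng.normal(0.0, spec.amplitude_noise_sd, n))
    amplitudes = pd.DataFrame({"subject_id": ids, "amplitude": a})

    rsn = {"subject_id": ids}
    for k, label in enumerate(spec.rsn_labels):
        rsn[label] = (spec.rsn_baselines[k] + spec.rsn_loadings[k] * m
                      + rng.normal(0.0, spec.rsn_noise_sd, n))
    rsn = pd.DataFrame(rsn)

    tracts = {"subject_id": ids}
    for param, baselines, loadings, sd in (
            ("MD", spec.tract_md_baselines, spec.tract_md_loadings, spec.tract_md_noise_sd),
            ("FA", spec.tract_fa_baselines, spec.tract_fa_loadings, spec.tract_fa_noise_sd),
            ("MK", spec.tract_mk_baselines, spec.tract_mk_loadings, spec.tract_mk_noise_sd)):
        for j, tract in enumerate(spec.tract_labels):
            tracts[f"{tract}_{param}"] = (baselines[j] + loadings[j] * m
                                          + rng.normal(0.0, sd, n))
    tracts = pd.DataFrame(tracts)
    if spec.n_dmri_incomplete > 0:
        drop = rng.choice(n, size=spec.n_dmri_incomplete, replace=False)
        cols = [c for c in tracts.columns if c != "subject_id"]
        tracts.loc[drop, cols] = np.nan

    conf = {"subject_id": ids}
    for name, (mu, sd) in CONFOUND_SPECS.items():
        coupling = float(spec.confound_couplings.get(name, 0.0))
        conf[name] = np.abs(mu + coupling * m + rng.normal(0.0, sd, n))
    confounds = pd.DataFrame(conf)

    clin = {"subject_id": ids}
    for name, (mu, sd) in CLINICAL_SPECS.items():
        coupling = float(spec.clinical_couplings.get(name, 0.0))
        clin[name] = mu + coupling * m * sd + rng.normal(0.0, sd, n)
    clin["sex"] = rng.integers(0, 2, n)
    clinical = pd.DataFrame(clin)

    return CohortTruth(spec, ids, m, amplitudes, rsn, tracts, confounds, clinical)


# ---------------------------------------------------------------------------
# Template maps
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, geometry: PhantomGeometry,
                  fwhm_vox: float = 4.0) -> np.ndarray:
    """Smooth standardized Gaussian random field restricted to the mask."""
    sigma = fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    field3d = ndimage.gaussian_filter(rng.normal(size=geometry.grid_shape), sigma)
    v = field3d[geometry.mask]
    field3d = field3d - v.mean()
    field3d /= v.std()
    field3d[~geometry.mask] = 0.0
    return field3d


def _inmask_standardize(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    v = data[mask]
    out = np.zeros_like(data)
    out[mask] = (v - v.mean()) / v.std()
    return out


def gen_templates(geometry: PhantomGeometry, k_rsn: int = 9,
                  adult_target_corrs: Sequence[float] = (),
                  seed: int = 0, rsn_replica_noise: float = 0.0) -> dict:
    """Generate a group evoked map, K network maps, and adult template maps.

    All maps are smooth random fields within the mask.  Network maps are
    Gram-Schmidt orthogonalised in-mask, so pairwise spatial correlations
    are zero by construction.  Each adult template is built as
    rho * group + sqrt(1 - rho^2) * (residual field orthogonal to the
    group map), realising its target spatial correlation exactly.

    With ``rsn_replica_noise`` > 0 a second, perturbed network set is also
    returned (``rsn_replica``), emulating the same networks estimated in an
    independent dataset.
    """
    targets = np.asarray(adult_target_corrs, dtype=float)
    if np.any(np.abs(targets) > 1.0):
        raise ValueError("adult target correlations must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    mask = geometry.mask

    group = _inmask_standardize(_smooth_field(rng, geometry), mask)

    rsn_fields = []
    basis = [group[mask] / np.linalg.norm(group[mask])]
    for _ in range(k_rsn):
        f = _smooth_field(rng, geometry)
        v = f[mask] - f[mask].mean()
        for b in basis:
            v = v - np.dot(v, b) * b
        nv = np.linalg.norm(v)
        if nv < 1e-10:
            raise ValueError("degenerate network field; enlarge the phantom")
        basis.append(v / nv)
        full = np.zeros(geometry.grid_shape)
        full[mask] = v / v.std()
        rsn_fields.append(full)

    adult = []
    gv = group[mask]
    gv = gv / np.linalg.norm(gv)   # in-mask values are already mean-zero
    for rho in targets:
        f = _smooth_field(rng, geometry)
        v = f[mask] - f[mask].mean()
        v = v - np.dot(v, gv) * gv
        nv = np.linalg.norm(v)
        if nv < 1e-10:
            raise ValueError("infeasible adult template construction")
        t = rho * gv + np.sqrt(max(0.0, 1.0 - rho ** 2)) * (v / nv)
        full = np.zeros(geometry.grid_shape)
        full[mask] = t / t.std() if t.std() > 0 else t
        adult.append(full)

    def as_map(arr):
        return VoxelMap(arr, mask.copy(), tuple(geometry.voxel_size_mm))

    out = {
        "group_map": as_map(group),
        "rsn_maps": [as_map(f) for f in rsn_fields],
        "adult_maps": [as_map(a) for a in adult],
        "adult_target_corrs": targets,
    }
    if rsn_replica_noise > 0:
        replica = []
        for f in rsn_fields:
            noise = _smooth_field(rng, geometry)
            pert = _inmask_standardize(f + rsn_replica_noise * noise, mask)
            replica.append(as_map(pert))
        out["rsn_replica"] = replica
    return out


# ---------------------------------------------------------------------------
# 4D runs and motion
# ---------------------------------------------------------------------------

def default_event_schedule(n_events: int = 10, duration_s: float = 1.0,
                           first_onset_s: float = 10.0,
                           isi_s: float = 26.0) -> pd.DataFrame:
    """Event-related schedule: 10 one-second trials, >= 25 s apart."""
    onsets = first_onset_s + isi_s * np.arange(n_events)
    return pd.DataFrame({"onset": onsets, "duration": np.full(n_events, duration_s)})


def _ar1_noise(rng: np.random.Generator, shape_vt: tuple, sd: float,
               ar1: float) -> np.ndarray:
    """AR(1) noise with stationary marginal sd along the last axis."""
    V, T = shape_vt
    eps = rng.normal(0.0, sd, (V, T))
    if ar1 == 0.0:
        return eps
    out = np.empty((V, T))
    out[:, 0] = eps[:, 0]
    innov_scale = np.sqrt(1.0 - ar1 ** 2)
    for t in range(1, T):
        out[:, t] = ar1 * out[:, t - 1] + innov_scale * eps[:, t]
    return out


def gen_task_run(a_true: float, group_map: VoxelMap, events: pd.DataFrame,
                 tr: float = 1.3, n_vols: int = 277,
                 thermal_sd: float = 1.0, ar1: float = 0.3,
                 drift_sd: float = 0.5, baseline: float = 100.0,
                 hrf: Hrf = Hrf(), seed: int = 0) -> Bold4D:
    """Event-related run embedding the amplitude-scaled group response.

    data(v, t) = baseline + a_true * group_map(v) * x(t) + d_v * tau(t)
                 + AR(1) noise, where x is the HRF-convolved stimulus
    regressor, tau a linear drift, and d_v per-voxel drift coefficients.
    With all noise parameters zero the data equal the signal component
    exactly.
    """
    rng = np.random.default_rng(seed)
    x = stimulus_regressor(events, n_vols, tr, hrf)
    mask = group_map.mask
    V = int(mask.sum())
    sig = baseline + np.outer(group_map.data[mask], x) * a_true
    if drift_sd > 0:
        tau = np.linspace(-1.0, 1.0, n_vols)
        sig = sig + np.outer(rng.normal(0.0, drift_sd, V), tau)
    if thermal_sd > 0:
        sig = sig + _ar1_noise(rng, (V, n_vols), thermal_sd, ar1)
    data = np.zeros(mask.shape + (n_vols,))
    data[mask] = sig
    return Bold4D(data, tr=tr, mask=mask.copy(),
                  voxel_size_mm=group_map.voxel_size_mm, events=events.copy())


def gen_rest_run(rsn_amplitudes_true: Sequence[float], rsn_maps: Sequence[VoxelMap],
                 tr: float = 1.3, n_vols: int = 500,
                 thermal_sd: float = 1.0, ar1: float = 0.3,
                 baseline: float = 100.0, seed: int = 0) -> Bold4D:
    """Resting run: sum of network maps times Gaussian network timeseries.

    Each network timeseries is N(0, (amplitude / 0.6745)^2), so its
    population MAD equals the requested amplitude.
    """
    amps = np.asarray(rsn_amplitudes_true, dtype=float)
    if amps.size != len(rsn_maps):
        raise ValueError("one amplitude per network map required")
    rng = np.random.default_rng(seed)
    mask = rsn_maps[0].mask
    V = int(mask.sum())
    Z = rng.normal(size=(amps.size, n_vols)) * (amps[:, None] / GAUSSIAN_MAD)
    M = np.stack([m.data[mask] for m in rsn_maps])          # (K, V)
    sig = baseline + M.T @ Z                                # (V, T)
    if thermal_sd > 0:
        sig = sig + _ar1_noise(rng, (V, n_vols), thermal_sd, ar1)
    data = np.zeros(mask.shape + (n_vols,))
    data[mask] = sig
    return Bold4D(data, tr=tr, mask=mask.copy(),
                  voxel_size_mm=rsn_maps[0].voxel_size_mm)


def gen_motion_table(n_vols: int, step_sd_mm: float = 0.02,
                     step_sd_rad: float = 0.0004, ar1: float = 0.95,
                     spike_rate: float = 0.0, spike_scale: float = 20.0,
                     seed: int = 0) -> pd.DataFrame:
    """Rigid-motion parameters as AR(1) random walks, with optional spikes."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_vols, 6)) * np.r_[[step_sd_mm] * 3, [step_sd_rad] * 3]
    if spike_rate > 0:
        spikes = rng.random((n_vols, 6)) < spike_rate
        steps = np.where(spikes, steps * spike_scale, steps)
    out = np.empty((n_vols, 6))
    out[0] = steps[0]
    for t in range(1, n_vols):
        out[t] = ar1 * out[t - 1] + steps[t]
    return pd.DataFrame(out, columns=list(MOTION_COLUMNS))


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_dataset(cohort: CohortTruth, templates: dict, runs: dict,
                  out_dir) -> pd.DataFrame:
    """Write a cohort to disk (NIfTI + TSV) and return a checksum manifest.

    ``runs`` maps subject_id -> {"task": Bold4D, "rest": Bold4D, ...}; any
    subset of run types may be present.  Event and motion tables attached
    to runs are written alongside.  Volumes are written uncompressed so
    repeated writes are byte-identical.
    """
    out = Path(out_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    (out / "func").mkdir(exist_ok=True)
    (out / "tables").mkdir(exist_ok=True)
    files = []

    def record(path):
        files.append({"file": str(path.relative_to(out)), "sha256": _sha256(path)})

    write_volume(templates["group_map"], out / "maps" / "group_map.nii")
    record(out / "maps" / "group_map.nii")
    for k, m in enumerate(templates.get("rsn_maps", [])):
        p = out / "maps" / f"rsn_{k:02d}.nii"
        write_volume(m, p)
        record(p)
    for k, m in enumerate(templates.get("adult_maps", [])):
        p = out / "maps" / f"adult_{k:02d}.nii"
        write_volume(m, p)
        record(p)

    for sid, subject_runs in runs.items():
        for run_type, bold in subject_runs.items():
            p = out / "func" / f"{sid}_{run_type}_bold.nii"
            write_volume(bold, p)
            record(p)
            if bold.events is not None:
                p = write_table(bold.events, out / "func" / f"{sid}_{run_type}_events.tsv")
                record(p)
            if bold.motion is not None:
                p = write_table(bold.motion, out / "func" / f"{sid}_{run_type}_motion.tsv")
                record(p)

    for name in ("amplitudes", "rsn", "tracts", "confounds", "clinical"):
        p = write_table(getattr(cohort, name), out / "tables" / f"{name}.tsv")
        record(p)

    manifest = pd.DataFrame(files)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps({
        "seed": cohort.spec.seed,
        "n_subjects": cohort.spec.n_subjects,
        "files": files,
    }, indent=1))
    return manifest
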