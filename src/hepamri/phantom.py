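"""Synthetic two-group liver cohort and MR phantom rendering.

The generator stands in for an in-vivo experiment comparing a hepatic
warm ischemia-reperfusion injury (model) group against sham-operated
controls, ten animals per group.  It has two layers:

* :func:`sample_cohort` draws per-animal ground-truth records — six MR
  parameters (Dslow, Dfast, PF, MD, FA, R2*), six serum/tissue
  biochemical variables (ALT, AST, LDH, MDA, MPO, SOD) and two ordinal
  histology scores (inflammation I, fibrosis F) — from group-specific
  Gaussian marginals coupled through a Gaussian copula calibrated to
  Spearman rank-correlation targets (latent Pearson r = 2*sin(pi*rho/6)).

* :func:`render_animal` evaluates the three forward models (IVIM
  bi-exponential, single-shell tensor, monoexponential gradient-echo
  decay) voxel by voxel on a digital liver layout, with a narrow
  within-animal parameter spread around the animal truth, vessel voxels
  with high perfusion fraction and pseudodiffusion (to exercise ROI
  vessel exclusion), and Rician magnitude noise.

Default group means and SDs are the observed group summaries of the
in-vivo comparison the pipeline targets; the default dependence matrix
carries the reference MR-vs-reference rank correlations where available
and is completed by nearest positive-semidefinite projection.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi import ROISet, jitter_rois, place_rois
from .schemes import (
    BValueScheme,
    EchoScheme,
    GradientScheme,
    default_dti_scheme,
    default_echo_scheme,
    default_ivim_scheme,
)

__all__ = [
    "GroupSpec",
    "NoiseModel",
    "PhantomLayout",
    "AnimalRecord",
    "ImageSeries",
    "VARIABLES",
    "CONTINUOUS_VARIABLES",
    "default_group_specs",
    "default_dependence",
    "default_layout",
    "nearest_psd_correlation",
    "spearman_to_latent",
    "sample_cohort",
    "cohort_to_frame",
    "render_animal",
    "simulate_observers",
    "WITHIN_ANIMAL_CV",
]

#: Continuous cohort variables, in canonical order.  Diffusivities are in
#: mm^2/s, PF in percent, R2* in s^-1, biochemistry in its assay units
#: (ALT/AST/LDH U/L, MDA nmol/ml, MPO U/G, SOD U/ml).
CONTINUOUS_VARIABLES: tuple[str, ...] = (
    "Dslow", "Dfast", "PF", "MD", "FA", "R2star",
    "ALT", "AST", "LDH", "MDA", "MPO", "SOD",
)

#: All copula variables: continuous block plus ordinal histology scores.
VARIABLES: tuple[str, ...] = CONTINUOUS_VARIABLES + ("I_score", "F_score")

#: Within-animal voxelwise coefficient of variation around the animal's
#: ROI-level truth.
WITHIN_ANIMAL_CV: float = 0.05

# positivity floors / caps applied after Gaussian sampling
_CLIPS: dict[str, tuple[float, float]] = {
    "Dslow": (1e-5, 5e-3),
    "Dfast": (5e-3, 0.5),
    "PF": (1e-3, 99.9),       # percent
    "MD": (1e-5, 5e-3),
    "FA": (0.0, 0.999),
    "R2star": (1.0, 1e4),
    "ALT": (1.0, np.inf),
    "AST": (1.0, np.inf),
    "LDH": (1.0, np.inf),
    "MDA": (0.01, np.inf),
    "MPO": (0.1, np.inf),
    "SOD": (1.0, np.inf),
}


@dataclass(frozen=True)
class GroupSpec:
    """Marginal and dependence specification of one cohort group.

    ``param_means``/``param_sds`` hold Gaussian location/scale for every
    continuous variable; ``score_dist`` maps "I_score"/"F_score" to a
    probability vector over the ordinal levels 0, 1, 2, ...;
    ``dependence`` is the Spearman rank-correlation target matrix over
    :data:`VARIABLES` (unit diagonal, symmetric).
    """

    name: str
    n: int
    param_means: dict[str, float]
    param_sds: dict[str, float]
    score_dist: dict[str, tuple[float, ...]]
    dependence: np.ndarray = field(default_factory=lambda: np.eye(len(VARIABLES)))

    def __post_init__(self) -> None:
        if self.name not in ("control", "model"):
            raise ValueError("group name must be 'control' or 'model'")
        if self.n < 2:
            raise ValueError("need at least two animals per group")
        missing = set(CONTINUOUS_VARIABLES) - set(self.param_means)
        if missing:
            raise ValueError(f"missing marginal means for {sorted(missing)}")
        for v in CONTINUOUS_VARIABLES:
            if self.param_sds[v] < 0:
                raise ValueError(f"negative SD for {v}")
        for s, pmf in self.score_dist.items():
            p = np.asarray(pmf, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"score distribution for {s} is not a pmf")
        dep = np.asarray(self.dependence, dtype=float)
        k = len(VARIABLES)
        if dep.shape != (k, k):
            raise ValueError(f"dependence matrix must be {k}x{k}")
        if not np.allclose(dep, dep.T, atol=1e-12):
            raise ValueError("dependence matrix must be symmetric")
        if not np.allclose(np.diag(dep), 1.0):
            raise ValueError("dependence matrix needs a unit diagonal")
        if np.any(np.abs(dep) > 1.0 + 1e-12):
            raise ValueError("dependence entries must lie in [-1, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Magnitude-image noise: Rician (default), Gaussian, or none.

    ``snr`` is the signal-to-noise ratio at b=0 / the first echo.
    """

    kind: str = "rician"
    snr: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("rician", "gaussian", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind != "none" and self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass(frozen=True)
class PhantomLayout:
    """Digital liver geometry: boolean liver and vessel masks on a grid."""

    liver_mask: np.ndarray
    vessel_mask: np.ndarray

    def __post_init__(self) -> None:
        liver = np.asarray(self.liver_mask, dtype=bool)
        vessel = np.asarray(self.vessel_mask, dtype=bool)
        object.__setattr__(self, "liver_mask", liver)
        object.__setattr__(self, "vessel_mask", vessel)
        if liver.ndim != 3 or liver.shape != vessel.shape:
            raise ValueError("masks must be matching 3-D volumes")
        if np.any(vessel & ~liver):
            raise ValueError("vessel mask must be a subset of the liver mask")
        n_slices = int(np.sum(liver.any(axis=(0, 1))))
        if n_slices < 3:
            raise ValueError("liver mask must be nonempty on at least 3 slices")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.liver_mask.shape

    @property
    def parenchyma_mask(self) -> np.ndarray:
        return self.liver_mask & ~self.vessel_mask


@dataclass(frozen=True)
class AnimalRecord:
    """Ground-truth record of one animal."""

    id: str
    group: str
    mr: dict[str, float]
    biochem: dict[str, float]
    histology: dict[str, int]
    s0: float = 100.0


@dataclass
class ImageSeries:
    """One rendered 4-D series with its scheme and the phantom masks."""

    kind: str  # "ivim" | "dti" | "megre"
    data: np.ndarray
    scheme: BValueScheme | GradientScheme | EchoScheme
    liver_mask: np.ndarray
    vessel_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("series data must be 4-D")
        if self.data.shape[3] != len(self.scheme):
            raise ValueError("series length does not match its scheme")


def default_layout(
    grid_shape: tuple[int, int, int] = (40, 40, 5)
) -> PhantomLayout:
    """Elliptical liver cross-section with three small intrahepatic vessels."""
    nx, ny, nz = grid_shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    liver = np.zeros(grid_shape, dtype=bool)
    for z in range(nz):
        # taper the ellipse toward the first/last slice
        shrink = 1.0 - 0.12 * abs(z - (nz - 1) / 2.0)
        rx, ry = 0.42 * nx * shrink, 0.34 * ny * shrink
        liver[:, :, z] = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0
    vessel = np.zeros(grid_shape, dtype=bool)
    centers = [(cx - 0.18 * nx, cy), (cx + 0.15 * nx, cy - 0.12 * ny),
               (cx + 0.1 * nx, cy + 0.15 * ny)]
    for vx, vy in centers:
        disc = (x - vx) ** 2 + (y - vy) ** 2 <= 1.6**2
        vessel |= disc[:, :, None] & liver
    return PhantomLayout(liver, vessel)


# ---------------------------------------------------------------------------
# default group specifications

_CONTROL_MEANS = {
    "Dslow": 1.29e-3, "Dfast": 32.33e-3, "PF": 30.44,
    "MD": 1.76e-3, "FA": 0.36, "R2star": 88.89,
    "ALT": 34.50, "AST": 44.70, "LDH": 314.20,
    "MDA": 2.06, "MPO": 14.22, "SOD": 183.20,
}
_CONTROL_SDS = {
    "Dslow": 0.14e-3, "Dfast": 8.87e-3, "PF": 2.80,
    "MD": 0.20e-3, "FA": 0.03, "R2star": 12.77,
    # ALT reported as median(IQR) 34.50(24.75, 37.00): scale = IQR/1.349
    "ALT": 9.08, "AST": 31.23, "LDH": 285.60,
    "MDA": 0.34, "MPO": 3.87, "SOD": 20.89,
}
_MODEL_MEANS = {
    "Dslow": 1.04e-3, "Dfast": 22.99e-3, "PF": 19.97,
    "MD": 1.46e-3, "FA": 0.38, "R2star": 119.34,
    # enzymes reported as median(IQR); location = median
    "ALT": 165.00, "AST": 348.00, "LDH": 1117.00,
    "MDA": 3.44, "MPO": 19.29, "SOD": 121.78,
}
_MODEL_SDS = {
    "Dslow": 0.21e-3, "Dfast": 1.59e-3, "PF": 3.39,
    "MD": 0.14e-3, "FA": 0.04, "R2star": 7.53,
    # scale = IQR width / 1.349 for median(IQR) variables
    "ALT": 135.47, "AST": 304.30, "LDH": 915.94,
    "MDA": 0.43, "MPO": 2.84, "SOD": 11.92,
}

# reference MR-vs-reference Spearman correlations (rows: MR variables,
# columns: ALT, AST, LDH, MDA, MPO, SOD, I, F), pooled over both groups
_MR_REF_SPEARMAN = np.array([
    [-0.568, -0.513, -0.707, -0.611, -0.514, 0.549, -0.609, -0.441],
    [-0.711, -0.600, -0.586, -0.749, -0.676, 0.630, -0.552, -0.451],
    [-0.670, -0.662, -0.726, -0.835, -0.760, 0.772, -0.715, -0.471],
    [-0.454, -0.542, -0.693, -0.616, -0.460, 0.568, -0.831, -0.631],
    [0.024, 0.313, 0.175, 0.316, -0.073, -0.414, 0.139, 0.336],
    [0.756, 0.802, 0.680, 0.760, 0.485, -0.792, 0.445, 0.390],
])


def nearest_psd_correlation(
    m: np.ndarray, eps: float = 1e-8, max_iter: int = 200
) -> np.ndarray:
    """Nearest positive-semidefinite correlation matrix (alternating
    projections between the PSD cone and the unit-diagonal set)."""
    a = np.asarray(m, dtype=float).copy()
    for _ in range(max_iter):
        w, v = np.linalg.eigh(a)
        if w.min() >= eps and np.allclose(np.diag(a), 1.0, atol=1e-12):
            break
        a = (v * np.maximum(w, eps)) @ v.T
        np.fill_diagonal(a, 1.0)
        a = np.clip((a + a.T) / 2.0, -1.0, 1.0)
    return a


def default_dependence() -> np.ndarray:
    """Default Spearman target matrix over :data:`VARIABLES`.

    The MR-vs-reference block carries the reference rank correlations;
    unreported blocks start at zero.  The matrix is completed by
    projecting its latent Gaussian image (r = 2*sin(pi*rho/6)) to the
    nearest positive-semidefinite correlation matrix and mapping back,
    so the copula factorization is guaranteed to exist.
    """
    k = len(VARIABLES)
    dep = np.eye(k)
    dep[0:6, 6:14] = _MR_REF_SPEARMAN
    dep[6:14, 0:6] = _MR_REF_SPEARMAN.T
    latent = nearest_psd_correlation(spearman_to_latent(dep))
    np.fill_diagonal(latent, 1.0)
    dep = (6.0 / np.pi) * np.arcsin(np.clip(latent, -1.0, 1.0) / 2.0)
    np.fill_diagonal(dep, 1.0)
    return dep


def default_group_specs(
    n_control: int = 10, n_model: int = 10
) -> tuple[GroupSpec, GroupSpec]:
    """Cohort defaults: two groups of ten animals with the observed group
    summaries and the default dependence structure."""
    dep = default_dependence()
    control = GroupSpec(
        name="control", n=n_control,
        param_means=dict(_CONTROL_MEANS), param_sds=dict(_CONTROL_SDS),
        score_dist={"I_score": (1.0,), "F_score": (1.0,)},
        dependence=dep,
    )
    model = GroupSpec(
        name="model", n=n_model,
        param_means=dict(_MODEL_MEANS), param_sds=dict(_MODEL_SDS),
        # ordinal {0,1,2} with population medians 1 (I) and 0.5 (F)
        score_dist={"I_score": (0.4, 0.4, 0.2), "F_score": (0.5, 0.4, 0.1)},
        dependence=dep,
    )
    return control, model


# ---------------------------------------------------------------------------
# cohort sampling

def spearman_to_latent(rho: np.ndarray) -> np.ndarray:
    """Latent Gaussian (Pearson) correlation achieving a Spearman target:
    r = 2 * sin(pi * rho / 6)."""
    return 2.0 * np.sin(np.pi * np.asarray(rho, dtype=float) / 6.0)


def _latent_cholesky(dep: np.ndarray) -> np.ndarray:
    latent = spearman_to_latent(dep)
    np.fill_diagonal(latent, 1.0)
    w = np.linalg.eigvalsh(latent)
    if w.min() < -1e-8:
        raise ValueError(
            "dependence matrix is not positive semidefinite after copula "
            f"mapping: smallest eigenvalue {w.min():.3e}"
        )
    # tiny negative eigenvalues from roundoff: nudge before factorizing
    latent = latent + (abs(min(w.min(), 0.0)) + 1e-10) * np.eye(len(dep))
    d = np.sqrt(np.diag(latent))
    latent = latent / np.outer(d, d)
    return np.linalg.cholesky(latent)


def _sample_group(
    spec: GroupSpec, rng: np.random.Generator, id_offset: int
) -> list[AnimalRecord]:
    chol = _latent_cholesky(spec.dependence)
    z = rng.standard_normal((spec.n, len(VARIABLES))) @ chol.T
    records = []
    from scipy.stats import norm

    u = norm.cdf(z)
    for i in range(spec.n):
        values: dict[str, float] = {}
        for j, var in enumerate(CONTINUOUS_VARIABLES):
            x = spec.param_means[var] + spec.param_sds[var] * z[i, j]
            lo, hi = _CLIPS[var]
            values[var] = float(np.clip(x, lo, hi))
        # identifiability floor: keep the bi-exponential compartments
        # separated by the same ratio the fitter guards
        values["Dfast"] = max(values["Dfast"], 5.0 * values["Dslow"])
        scores: dict[str, int] = {}
        for var in ("I_score", "F_score"):
            pmf = np.asarray(spec.score_dist[var], dtype=float)
            edges = np.cumsum(pmf)
            j = VARIABLES.index(var)
            scores[var] = int(np.searchsorted(edges, u[i, j], side="right"))
            scores[var] = min(scores[var], len(pmf) - 1)
        records.append(
            AnimalRecord(
                id=f"{spec.name}-{id_offset + i + 1:02d}",
                group=spec.name,
                mr={k: values[k] for k in
                    ("Dslow", "Dfast", "PF", "MD", "FA", "R2star")},
                biochem={k: values[k] for k in
                         ("ALT", "AST", "LDH", "MDA", "MPO", "SOD")},
                histology=scores,
            )
        )
    return records


def sample_cohort(
    control: GroupSpec, model: GroupSpec, seed: int
) -> list[AnimalRecord]:
    """Draw the two-group cohort; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    recs = _sample_group(control, rng, 0)
    recs += _sample_group(model, rng, 0)
    return recs


def cohort_to_frame(records: list[AnimalRecord]) -> pd.DataFrame:
    """Flatten AnimalRecords into one row per animal."""
    rows = []
    for r in records:
        row = {"id": r.id, "group": r.group}
        row.update(r.mr)
        row.update(r.biochem)
        row.update(r.histology)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering

def _voxel_field(
    rng: np.random.Generator, truth: float, n: int,
    lo: float, hi: float, cv: float = WITHIN_ANIMAL_CV,
) -> np.ndarray:
    return np.clip(truth * (1.0 + cv * rng.standard_normal(n)), lo, hi)


def _apply_noise(
    data: np.ndarray, noise: NoiseModel, sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if noise.kind == "none":
        return data
    if noise.kind == "gaussian":
        return data + sigma * rng.standard_normal(data.shape)
    g1 = rng.standard_normal(data.shape)
    g2 = rng.standard_normal(data.shape)
    return np.sqrt((data + sigma * g1) ** 2 + (sigma * g2) ** 2)


def render_animal(
    record: AnimalRecord,
    layout: PhantomLayout,
    noise: NoiseModel,
    ivim_scheme: BValueScheme | None = None,
    dti_scheme: GradientScheme | None = None,
    echo_scheme: EchoScheme | None = None,
    restrict_mask: np.ndarray | None = None,
) -> dict[str, ImageSeries]:
    """Render the animal's three MR series on the phantom layout.

    Liver voxels draw parameters with a narrow spread around the animal's
    truth; vessel voxels get a high perfusion fraction (>= 0.6) and a
    pseudodiffusion at least three times the liver mean, so that ROI
    placement must avoid them.  ``restrict_mask`` optionally limits the
    rendered voxels (the rest stay at background zero before noise),
    which leaves ROI statistics unchanged when the mask covers the ROIs.

    Deterministic for a fixed ``noise.seed`` (the seed also drives the
    within-animal spread so a noise-free rendering is reproducible).
    """
    ivim_scheme = ivim_scheme or default_ivim_scheme()
    dti_scheme = dti_scheme or default_dti_scheme()
    echo_scheme = echo_scheme or default_echo_scheme()

    id_key = zlib.crc32(record.id.encode()) % (2**31)
    ss = np.random.SeedSequence([noise.seed % (2**31), id_key])
    rng_param, rng_noise, rng_rot = [
        np.random.default_rng(s) for s in ss.spawn(3)
    ]

    liver = layout.liver_mask
    if restrict_mask is not None:
        liver = liver & np.asarray(restrict_mask, dtype=bool)
    vessel = layout.vessel_mask & liver
    parench = liver & ~vessel
    idx_p = np.argwhere(parench)
    idx_v = np.argwhere(vessel)
    n_p, n_v = len(idx_p), len(idx_v)
    s0 = record.s0
    mr = record.mr

    # voxelwise parameter fields (parenchyma then vessels)
    dslow = np.concatenate([
        _voxel_field(rng_param, mr["Dslow"], n_p, *_CLIPS["Dslow"]),
        _voxel_field(rng_param, mr["Dslow"], n_v, *_CLIPS["Dslow"]),
    ])
    dfast = np.concatenate([
        _voxel_field(rng_param, mr["Dfast"], n_p, *_CLIPS["Dfast"]),
        np.clip(3.0 * mr["Dfast"] * (1.0 + 0.2 * rng_param.random(n_v)),
                *_CLIPS["Dfast"]),
    ])
    pf_frac = np.concatenate([
        _voxel_field(rng_param, mr["PF"] / 100.0, n_p, 1e-5, 0.999),
        0.6 + 0.25 * rng_param.random(n_v),
    ])
    md = np.concatenate([
        _voxel_field(rng_param, mr["MD"], n_p, *_CLIPS["MD"]),
        _voxel_field(rng_param, mr["MD"], n_v, *_CLIPS["MD"]),
    ])
    fa = np.concatenate([
        _voxel_field(rng_param, mr["FA"], n_p, 0.0, 0.95),
        _voxel_field(rng_param, mr["FA"], n_v, 0.0, 0.95),
    ])
    r2s = np.concatenate([
        _voxel_field(rng_param, mr["R2star"], n_p, *_CLIPS["R2star"]),
        _voxel_field(rng_param, mr["R2star"], n_v, *_CLIPS["R2star"]),
    ])
    idx = np.vstack([idx_p, idx_v]) if n_v else idx_p
    dfast = np.maximum(dfast, 5.0 * dslow)

    shape = layout.grid_shape
    sigma = s0 / noise.snr if noise.kind != "none" else 0.0
    # Full renderings carry noise over the whole volume (Rayleigh
    # background included); restricted renderings add noise only to the
    # rendered voxels, leaving the untouched background at zero.
    noise_everywhere = restrict_mask is None

    def _finish(sig: np.ndarray, n_vol: int) -> np.ndarray:
        vol = np.zeros(shape + (n_vol,))
        if noise_everywhere:
            vol[idx[:, 0], idx[:, 1], idx[:, 2], :] = sig
            return _apply_noise(vol, noise, sigma, rng_noise)
        vol[idx[:, 0], idx[:, 1], idx[:, 2], :] = _apply_noise(
            sig, noise, sigma, rng_noise
        )
        return vol

    # IVIM series
    b = ivim_scheme.b
    sig = s0 * (pf_frac[:, None] * np.exp(-np.outer(dfast, b))
                + (1.0 - pf_frac[:, None]) * np.exp(-np.outer(dslow, b)))
    ivim_data = _finish(sig, len(ivim_scheme))

    # DTI series: axisymmetric tensors with a fixed per-animal orientation
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=int(rng_rot.integers(2**31))).as_matrix()
    delta = fa * np.sqrt(3.0 / (9.0 - 6.0 * fa**2))
    lam = md[:, None] * np.stack(
        [1.0 + 2.0 * delta, 1.0 - delta, 1.0 - delta], axis=1
    )
    # D = R diag(lam) R^T per voxel
    tensors = np.einsum("ab,nb,cb->nac", rot, lam, rot)
    d6 = np.stack(
        [tensors[:, 0, 0], tensors[:, 1, 1], tensors[:, 2, 2],
         tensors[:, 0, 1], tensors[:, 0, 2], tensors[:, 1, 2]], axis=1
    )
    design = dti_scheme.design_matrix()
    adc = d6 @ design.T
    dti_weighted = s0 * np.exp(-(dti_scheme.b_high - dti_scheme.b_low) * adc)
    dti_sig = np.concatenate(
        [np.full((len(d6), 1), s0), dti_weighted], axis=1
    )
    dti_data = _finish(dti_sig, len(dti_scheme))

    # multi-echo gradient-echo series
    te_s = echo_scheme.te_ms / 1000.0
    megre_sig = s0 * np.exp(-np.outer(r2s, te_s))
    megre_data = _finish(megre_sig, len(echo_scheme))

    return {
        "ivim": ImageSeries("ivim", ivim_data, ivim_scheme,
                            layout.liver_mask, layout.vessel_mask),
        "dti": ImageSeries("dti", dti_data, dti_scheme,
                           layout.liver_mask, layout.vessel_mask),
        "megre": ImageSeries("megre", megre_data, echo_scheme,
                             layout.liver_mask, layout.vessel_mask),
    }


def simulate_observers(
    layout: PhantomLayout, jitter_px: float, seed: int
) -> tuple[ROISet, ROISet]:
    """Two readers' ROI sets: a seeded placement and a jittered copy.

    The second set emulates a second radiologist re-drawing the same
    protocol: each center is displaced by at most ``jitter_px`` pixels
    while staying inside the liver and outside vessels.  ``jitter_px = 0``
    returns two identical sets.
    """
    obs1 = place_rois(layout.liver_mask, layout.vessel_mask, seed)
    obs2 = jitter_rois(
        obs1, layout.liver_mask, layout.vessel_mask, jitter_px,
        seed=seed + 104729,
    )
    return obs1, obs2
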