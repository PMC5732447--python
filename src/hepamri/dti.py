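"""Diffusion-tensor estimation and scalar metrics (MD, FA).

The single-shell tensor model is

    S(g, b) = S0 * exp(-b * g^T D g)

with D the symmetric 3x3 diffusion tensor.  Estimation is log-linear
least squares of ln(S/S0) against the six-column second-order design
matrix, followed by eigendecomposition; negative eigenvalues are clamped
to zero and the voxel flagged.  Mean diffusivity is the eigenvalue mean
(trace/3) and fractional anisotropy the normalized eigenvalue dispersion

    FA = sqrt(3/2) * sqrt(sum_i (l_i - MD)^2) / sqrt(sum_i l_i^2),

which ranges from 0 (isotropic) to 1 (a single nonzero eigenvalue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schemes import GradientScheme

__all__ = [
    "DiffusionTensor",
    "dti_signal",
    "fit_tensor_voxel",
    "tensor_metrics",
    "fit_dti_map",
    "tensor_from_eigensystem",
    "axisymmetric_tensor",
]

_PACK = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class DiffusionTensor:
    """Symmetric diffusion tensor packed as its six unique elements.

    ``d6`` is ordered (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in mm^2/s.
    ``clamped`` marks tensors whose negative eigenvalues were clipped.
    """

    d6: np.ndarray
    clamped: bool = False
    valid: bool = True

    def __post_init__(self) -> None:
        self.d6 = np.asarray(self.d6, dtype=float)
        if self.d6.shape != (6,):
            raise ValueError("d6 must have exactly six elements")

    @property
    def matrix(self) -> np.ndarray:
        xx, yy, zz, xy, xz, yz = self.d6
        return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])

    def eigenvalues(self, clamp: bool = True) -> np.ndarray:
        """Eigenvalues sorted descending; negatives clamped to 0 if asked."""
        lam = np.linalg.eigvalsh(self.matrix)[::-1]
        if clamp and lam[-1] < 0:
            lam = np.maximum(lam, 0.0)
            self.clamped = True
        return lam


def tensor_from_eigensystem(
    eigenvalues: np.ndarray, rotation: np.ndarray | None = None
) -> DiffusionTensor:
    """Assemble a tensor from eigenvalues and an optional rotation matrix."""
    lam = np.asarray(eigenvalues, dtype=float)
    r = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    m = r @ np.diag(lam) @ r.T
    return DiffusionTensor(
        np.array([m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2]])
    )


def axisymmetric_tensor(
    md: float, fa: float, rotation: np.ndarray | None = None
) -> DiffusionTensor:
    """Prolate axisymmetric tensor with prescribed MD and FA.

    Eigenvalues are MD*(1+2*delta), MD*(1-delta), MD*(1-delta) with delta
    chosen so the closed-form FA of this family matches the target:
    delta = FA * sqrt(3 / (9 - 6 FA^2)).
    """
    if not (0.0 <= fa < 1.0):
        raise ValueError("FA must lie in [0, 1) for a positive-definite tensor")
    delta = fa * np.sqrt(3.0 / (9.0 - 6.0 * fa**2))
    lam = md * np.array([1.0 + 2.0 * delta, 1.0 - delta, 1.0 - delta])
    return tensor_from_eigensystem(lam, rotation)


def dti_signal(
    t: DiffusionTensor, s0: float, scheme: GradientScheme
) -> np.ndarray:
    """Forward tensor signal: one b_low volume then one per direction."""
    adc = scheme.design_matrix() @ t.d6
    weighted = s0 * np.exp(-(scheme.b_high - scheme.b_low) * adc)
    return np.concatenate([[s0], weighted])


def fit_tensor_voxel(
    signal: np.ndarray, scheme: GradientScheme
) -> DiffusionTensor:
    """Log-linear least-squares tensor fit of a 1 + n_directions signal.

    S0 is taken from the measured b=0 volume (single-b0 acquisition), not
    refit.  Any non-positive signal invalidates the voxel.
    """
    s = np.asarray(signal, dtype=float)
    if s.size != len(scheme):
        raise ValueError("signal length does not match gradient scheme")
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        return DiffusionTensor(np.zeros(6), valid=False)
    s0 = s[0]
    y = np.log(s[1:] / s0)
    design = -(scheme.b_high - scheme.b_low) * scheme.design_matrix()
    d6, *_ = np.linalg.lstsq(design, y, rcond=None)
    return DiffusionTensor(d6)


def tensor_metrics(t: DiffusionTensor) -> tuple[float, float]:
    """(MD, FA) from the tensor's eigenvalues.

    An all-zero tensor returns (0, 0).  FA is clipped to [0, 1].
    """
    lam = t.eigenvalues(clamp=True)
    md = float(lam.mean())
    denom = float(np.sum(lam**2))
    if denom == 0.0:
        return 0.0, 0.0
    fa = np.sqrt(1.5 * np.sum((lam - md) ** 2) / denom)
    return md, float(np.clip(fa, 0.0, 1.0))


@dataclass
class TensorMapSummary:
    n_fit: int
    n_invalid: int
    n_clamped: int
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)


def fit_dti_map(
    series_data: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray,
) -> tuple[dict[str, np.ndarray], TensorMapSummary]:
    """Voxelwise tensor fit producing MD and FA maps over a mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    if series_data.shape[:3] != mask.shape or series_data.shape[3] != len(scheme):
        raise ValueError("series shape inconsistent with mask/scheme")
    maps = {k: np.full(mask.shape, np.nan) for k in ("MD", "FA")}
    n_invalid = n_clamped = 0
    idx = np.argwhere(mask)
    for i, j, k in idx:
        t = fit_tensor_voxel(series_data[i, j, k, :], scheme)
        if not t.valid:
            n_invalid += 1
            continue
        md, fa = tensor_metrics(t)
        if t.clamped:
            n_clamped += 1
        maps["MD"][i, j, k] = md
        maps["FA"][i, j, k] = fa
    summary = TensorMapSummary(
        n_fit=len(idx) - n_invalid, n_invalid=n_invalid, n_clamped=n_clamped
    )
    for k, m in maps.items():
        vals = m[mask]
        vals = vals[np.isfinite(vals)]
        summary.means[k] = float(vals.mean()) if vals.size else np.nan
        summary.sds[k] = float(vals.std()) if vals.size else np.nan
    return maps, summary
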