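"""Monoexponential T2*/R2* relaxometry from a multi-echo gradient-echo series.

The signal decays as S(TE) = S0 * exp(-TE * R2*) with TE in seconds and
R2* in s^-1 (echo times are carried in ms and converted internally).
T2* (ms) is 1000 / R2*.

The default estimator is log-linear least squares on ln S vs TE, which is
exact on noise-free data; a Levenberg-Marquardt nonlinear refinement is
available for low-SNR robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .schemes import EchoScheme

__all__ = [
    "RelaxParams",
    "decay_signal",
    "fit_r2star_voxel",
    "fit_r2star_map",
]

_R2_MIN = 1e-6  # s^-1, lower bound flagging non-decaying voxels


@dataclass(frozen=True)
class RelaxParams:
    """S0 (arbitrary units) and R2* in s^-1; T2* in ms is derived."""

    S0: float
    R2star: float

    def __post_init__(self) -> None:
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")
        if self.R2star <= 0:
            raise ValueError("R2* must be positive")

    @property
    def T2star_ms(self) -> float:
        return 1000.0 / self.R2star


@dataclass
class RelaxFitResult:
    params: RelaxParams | None
    valid: bool
    degenerate: bool = False
    n_echoes_used: int = 0


def decay_signal(p: RelaxParams, scheme: EchoScheme) -> np.ndarray:
    """Monoexponential decay evaluated at the scheme's echo times."""
    return p.S0 * np.exp(-scheme.te_ms / 1000.0 * p.R2star)


def fit_r2star_voxel(
    signal: np.ndarray,
    scheme: EchoScheme,
    method: str = "loglinear",
) -> RelaxFitResult:
    """Fit R2* for one voxel.

    ``method`` is "loglinear" (default) or "nonlinear" (log-linear start,
    Levenberg-Marquardt refinement).  Echoes with non-positive signal are
    dropped; the voxel is invalid if fewer than 3 remain.
    """
    s = np.asarray(signal, dtype=float)
    if s.size != len(scheme):
        raise ValueError("signal length does not match echo scheme")
    te_s = scheme.te_ms / 1000.0
    keep = np.isfinite(s) & (s > 0)
    if keep.sum() < 3:
        return RelaxFitResult(None, valid=False, n_echoes_used=int(keep.sum()))
    te_k, s_k = te_s[keep], s[keep]
    slope, intercept = np.polyfit(te_k, np.log(s_k), 1)
    r2 = -slope
    s0 = float(np.exp(intercept))
    degenerate = r2 <= _R2_MIN
    if degenerate:
        r2 = _R2_MIN
    if method == "nonlinear" and not degenerate:
        try:
            popt, _ = curve_fit(
                lambda te, a, r: a * np.exp(-te * r),
                te_k, s_k, p0=[s0, r2], maxfev=2000,
            )
            if popt[0] > 0 and popt[1] > _R2_MIN:
                s0, r2 = float(popt[0]), float(popt[1])
        except RuntimeError:
            pass  # keep the log-linear estimate
    elif method not in ("loglinear", "nonlinear"):
        raise ValueError(f"unknown method {method!r}")
    return RelaxFitResult(
        RelaxParams(S0=s0, R2star=float(r2)),
        valid=True,
        degenerate=degenerate,
        n_echoes_used=int(keep.sum()),
    )


@dataclass
class RelaxMapSummary:
    n_fit: int
    n_invalid: int
    n_degenerate: int
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)


def fit_r2star_map(
    series_data: np.ndarray,
    scheme: EchoScheme,
    mask: np.ndarray,
    method: str = "loglinear",
) -> tuple[dict[str, np.ndarray], RelaxMapSummary]:
    """Voxelwise R2* (s^-1) and T2* (ms) maps over a mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    if series_data.shape[:3] != mask.shape or series_data.shape[3] != len(scheme):
        raise ValueError("series shape inconsistent with mask/scheme")
    maps = {k: np.full(mask.shape, np.nan) for k in ("R2star", "T2star")}
    n_invalid = n_degen = 0
    idx = np.argwhere(mask)
    for i, j, k in idx:
        res = fit_r2star_voxel(series_data[i, j, k, :], scheme, method)
        if not res.valid:
            n_invalid += 1
            continue
        if res.degenerate:
            n_degen += 1
        maps["R2star"][i, j, k] = res.params.R2star
        maps["T2star"][i, j, k] = res.params.T2star_ms
    summary = RelaxMapSummary(
        n_fit=len(idx) - n_invalid, n_invalid=n_invalid, n_degenerate=n_degen
    )
    for k, m in maps.items():
        vals = m[mask]
        vals = vals[np.isfinite(vals)]
        summary.means[k] = float(vals.mean()) if vals.size else np.nan
        summary.sds[k] = float(vals.std()) if vals.size else np.nan
    return maps, summary
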