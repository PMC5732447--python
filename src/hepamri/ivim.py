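"""Intravoxel incoherent motion (IVIM) bi-exponential model and fitting.

The IVIM model decomposes the diffusion-weighted signal decay into a slow
compartment of true molecular diffusion and a fast, perfusion-driven
pseudodiffusion compartment:

    S(b) = S0 * [ PF * exp(-b * Dfast) + (1 - PF) * exp(-b * Dslow) ]

where ``Dslow`` is the true diffusion coefficient (mm^2/s), ``Dfast`` the
pseudodiffusion coefficient (mm^2/s) and ``PF`` the perfusion fraction.

Fitting is a bound-constrained simultaneous ("full bi-exponential")
nonlinear least squares over (S0, PF, Dslow, Dfast), initialized by a
segmented prefit: a log-linear fit over the perfusion-free high-b portion
of the curve yields Dslow and, through its intercept, PF; Dfast is then
estimated from the low-b residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .schemes import BValueScheme

__all__ = [
    "IVIMParams",
    "FitOptions",
    "IVIMFitResult",
    "ivim_signal",
    "segmented_prefit",
    "fit_ivim_voxel",
    "fit_ivim_map",
]


@dataclass(frozen=True)
class IVIMParams:
    """Per-voxel IVIM parameters.

    Dslow, Dfast in mm^2/s; PF dimensionless in [0, 1]; S0 arbitrary units.
    """

    Dslow: float
    Dfast: float
    PF: float
    S0: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.Dslow < self.Dfast):
            raise ValueError("require 0 < Dslow < Dfast")
        if not (0.0 <= self.PF <= 1.0):
            raise ValueError("PF must lie in [0, 1]")
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")


@dataclass(frozen=True)
class FitOptions:
    """Bounds and controls for the bi-exponential fit.

    Default bounds cover the standard liver range; ``b_split`` is the
    threshold above which perfusion is assumed fully attenuated in the
    segmented prefit.  ``min_ratio`` guards identifiability: solutions
    with Dfast < min_ratio * Dslow are rejected in favour of the
    segmented estimate.
    """

    dslow_bounds: tuple[float, float] = (1e-5, 5e-3)
    dfast_bounds: tuple[float, float] = (5e-3, 0.5)
    pf_bounds: tuple[float, float] = (0.0, 0.7)
    b_split: float = 200.0
    min_ratio: float = 5.0
    max_nfev: int = 200


@dataclass
class IVIMFitResult:
    params: IVIMParams | None
    residual_norm: float
    converged: bool
    valid: bool
    degenerate: bool = False
    used_fallback: bool = False


def ivim_signal(p: IVIMParams, scheme: BValueScheme) -> np.ndarray:
    """Evaluate the bi-exponential forward model on a b-value scheme."""
    b = scheme.b
    return p.S0 * (
        p.PF * np.exp(-b * p.Dfast) + (1.0 - p.PF) * np.exp(-b * p.Dslow)
    )


def _biexp(x: np.ndarray, b: np.ndarray) -> np.ndarray:
    s0, pf, dslow, dfast = x
    return s0 * (pf * np.exp(-b * dfast) + (1.0 - pf) * np.exp(-b * dslow))


def _biexp_jac(x: np.ndarray, b: np.ndarray) -> np.ndarray:
    s0, pf, dslow, dfast = x
    ef = np.exp(-b * dfast)
    es = np.exp(-b * dslow)
    return np.stack(
        [
            pf * ef + (1.0 - pf) * es,
            s0 * (ef - es),
            -s0 * (1.0 - pf) * b * es,
            -s0 * pf * b * ef,
        ],
        axis=1,
    )


def segmented_prefit(
    signal: np.ndarray, scheme: BValueScheme, opts: FitOptions = FitOptions()
) -> tuple[float, float, float, float]:
    """Segmented IVIM estimate used as initializer and fallback.

    Log-linear fit over b >= ``opts.b_split`` gives Dslow and the
    zero-b intercept of the slow compartment, hence PF; Dfast comes from a
    log-linear fit of the low-b perfusion residual.  Returns
    (S0, PF, Dslow, Dfast) clipped to the fit bounds.
    """
    b = scheme.b
    s = np.asarray(signal, dtype=float)
    s0_meas = s[0]
    hi = b >= opts.b_split
    if hi.sum() < 2:  # degenerate scheme; fall back to crude defaults
        return s0_meas, 0.2, 1e-3, 2e-2
    slope, intercept = np.polyfit(b[hi], np.log(s[hi]), 1)
    dslow = float(np.clip(-slope, *opts.dslow_bounds))
    slow_s0 = np.exp(intercept)
    pf = float(np.clip(1.0 - slow_s0 / s0_meas, *opts.pf_bounds))

    dfast = 2e-2
    lo = ~hi & (b > 0)
    if pf > 1e-6 and lo.sum() >= 2:
        resid = s[lo] - slow_s0 * np.exp(-b[lo] * dslow)
        pos = resid > 0
        if pos.sum() >= 2:
            fslope, _ = np.polyfit(b[lo][pos], np.log(resid[pos]), 1)
            dfast = float(-fslope)
    dfast = float(np.clip(dfast, *opts.dfast_bounds))
    if dfast < opts.min_ratio * dslow:
        dfast = float(np.clip(opts.min_ratio * dslow, *opts.dfast_bounds))
    return s0_meas, pf, dslow, dfast


def fit_ivim_voxel(
    signal: np.ndarray,
    scheme: BValueScheme,
    opts: FitOptions = FitOptions(),
) -> IVIMFitResult:
    """Full bi-exponential fit of a single voxel's decay curve.

    The signal is normalized by its b=0 entry before fitting (S0 is still
    refit jointly to absorb noise in the b=0 volume).  Non-positive or
    non-finite signals invalidate the voxel.
    """
    s = np.asarray(signal, dtype=float)
    if s.size != len(scheme):
        raise ValueError("signal length does not match b-value scheme")
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        return IVIMFitResult(None, np.inf, False, valid=False)

    scale = s[0]
    y = s / scale
    s0_0, pf_0, dslow_0, dfast_0 = segmented_prefit(y, scheme, opts)

    # flat curves carry no decay information: flag degenerate
    if np.ptp(y) < 1e-12:
        p = IVIMParams(
            Dslow=opts.dslow_bounds[0],
            Dfast=opts.dfast_bounds[0],
            PF=0.0,
            S0=float(scale * y[0]),
        )
        return IVIMFitResult(p, 0.0, True, valid=True, degenerate=True)

    lb = [0.1, opts.pf_bounds[0], opts.dslow_bounds[0], opts.dfast_bounds[0]]
    ub = [10.0, opts.pf_bounds[1], opts.dslow_bounds[1], opts.dfast_bounds[1]]
    x0 = np.clip([s0_0, pf_0, dslow_0, dfast_0], lb, ub)
    sol = least_squares(
        lambda x: _biexp(x, scheme.b) - y,
        x0,
        jac=lambda x: _biexp_jac(x, scheme.b),
        bounds=(lb, ub),
        x_scale=[1.0, 0.3, 1e-3, 2e-2],
        max_nfev=opts.max_nfev,
    )
    s0, pf, dslow, dfast = sol.x
    fallback = False
    if (not sol.success) or dfast < opts.min_ratio * dslow:
        # identifiability guard / non-convergence: segmented fallback
        s0, pf, dslow, dfast = x0
        fallback = True
    dslow = min(dslow, dfast / 1.0000001)  # keep strict ordering
    p = IVIMParams(
        Dslow=float(dslow), Dfast=float(dfast), PF=float(pf),
        S0=float(s0 * scale),
    )
    rnorm = float(np.linalg.norm(_biexp([s0, pf, dslow, dfast], scheme.b) - y))
    return IVIMFitResult(
        p, rnorm, bool(sol.success) and not fallback, valid=True,
        used_fallback=fallback,
    )


def _segmented_prefit_batch(
    y: np.ndarray, b: np.ndarray, opts: FitOptions
) -> np.ndarray:
    """Vectorized segmented initializer for normalized signals (n, nb)."""
    hi = b >= opts.b_split
    design = np.stack([b[hi], np.ones(hi.sum())], axis=1)
    coef = np.log(y[:, hi]) @ np.linalg.pinv(design).T  # (n, 2)
    dslow = np.clip(-coef[:, 0], *opts.dslow_bounds)
    slow_s0 = np.exp(coef[:, 1])
    pf = np.clip(1.0 - slow_s0 / y[:, 0], *opts.pf_bounds)
    dfast = np.clip(
        np.maximum(2e-2, opts.min_ratio * dslow), *opts.dfast_bounds
    )
    return np.stack([np.ones(len(y)), pf, dslow, dfast], axis=1)


def _batch_model(x: np.ndarray, b: np.ndarray) -> np.ndarray:
    s0, pf, ds, df = (x[:, i : i + 1] for i in range(4))
    return s0 * (pf * np.exp(-b[None, :] * df)
                 + (1.0 - pf) * np.exp(-b[None, :] * ds))


def _fit_ivim_batch(
    y: np.ndarray, b: np.ndarray, opts: FitOptions, n_iter: int = 60
) -> np.ndarray:
    """Bound-projected Levenberg-Marquardt over many voxels at once.

    Minimizes the same bi-exponential least-squares objective as
    :func:`fit_ivim_voxel` but vectorized across voxels; used by the map
    fitter where per-voxel optimizer overhead dominates.  Steps that do
    not reduce a voxel's cost are rejected and its damping increased.
    """
    n = y.shape[0]
    lb = np.array([0.1, opts.pf_bounds[0], opts.dslow_bounds[0],
                   opts.dfast_bounds[0]])
    ub = np.array([10.0, opts.pf_bounds[1], opts.dslow_bounds[1],
                   opts.dfast_bounds[1]])
    x = np.clip(_segmented_prefit_batch(y, b, opts), lb, ub)
    lam = np.full(n, 1e-3)
    cost = np.sum((_batch_model(x, b) - y) ** 2, axis=1)
    eye = np.eye(4)
    for _ in range(n_iter):
        s0, pf, ds, df = (x[:, i : i + 1] for i in range(4))
        ef = np.exp(-b[None, :] * df)
        es = np.exp(-b[None, :] * ds)
        r = s0 * (pf * ef + (1.0 - pf) * es) - y
        jac = np.empty((n, b.size, 4))
        jac[:, :, 0] = pf * ef + (1.0 - pf) * es
        jac[:, :, 1] = s0 * (ef - es)
        jac[:, :, 2] = -s0 * (1.0 - pf) * b[None, :] * es
        jac[:, :, 3] = -s0 * pf * b[None, :] * ef
        g = np.einsum("nbk,nb->nk", jac, r)
        h = np.einsum("nbk,nbl->nkl", jac, jac)
        diag = np.maximum(np.einsum("nkk->nk", h), 1e-12)
        a = h + lam[:, None, None] * diag[:, None, :] * eye[None, :, :]
        try:
            delta = -np.linalg.solve(a, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            lam *= 10.0
            continue
        x_new = np.clip(x + delta, lb, ub)
        cost_new = np.sum((_batch_model(x_new, b) - y) ** 2, axis=1)
        better = cost_new < cost
        x[better] = x_new[better]
        cost[better] = cost_new[better]
        lam = np.where(better, lam / 3.0, lam * 4.0)
        lam = np.clip(lam, 1e-12, 1e12)
        if np.all(np.abs(delta[better]).max(initial=0.0) < 1e-14):
            break
    return x


@dataclass
class MapFitSummary:
    n_fit: int
    n_invalid: int
    n_fallback: int
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)


def fit_ivim_map(
    series_data: np.ndarray,
    scheme: BValueScheme,
    mask: np.ndarray,
    opts: FitOptions = FitOptions(),
    engine: str = "batch",
) -> tuple[dict[str, np.ndarray], MapFitSummary]:
    """Voxelwise IVIM fit over a mask.

    Parameters
    ----------
    series_data : 4-D array (x, y, z, b).
    mask : boolean 3-D array selecting the voxels to fit.
    engine : "batch" (vectorized Levenberg-Marquardt, default) or
        "voxelwise" (per-voxel trust-region fit); both minimize the same
        objective.

    Returns the parametric maps {"Dslow", "Dfast", "PF"} (NaN outside the
    mask and at invalid voxels) and a summary with within-mask statistics.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    if series_data.shape[:3] != mask.shape or series_data.shape[3] != len(scheme):
        raise ValueError("series shape inconsistent with mask/scheme")
    if engine not in ("batch", "voxelwise"):
        raise ValueError(f"unknown engine {engine!r}")

    maps = {k: np.full(mask.shape, np.nan) for k in ("Dslow", "Dfast", "PF")}
    n_invalid = n_fallback = 0
    idx = np.argwhere(mask)
    signals = series_data[mask]  # (n, nb), order matches idx
    finite = np.all(np.isfinite(signals), axis=1) & np.all(signals > 0, axis=1)
    n_invalid = int((~finite).sum())

    if engine == "batch" and finite.any():
        y = signals[finite] / signals[finite][:, :1]
        x = _fit_ivim_batch(y, scheme.b, opts)
        # identifiability guard: fall back to the segmented estimate
        bad = x[:, 3] < opts.min_ratio * x[:, 2]
        if bad.any():
            lb = np.array([0.1, opts.pf_bounds[0], opts.dslow_bounds[0],
                           opts.dfast_bounds[0]])
            ub = np.array([10.0, opts.pf_bounds[1], opts.dslow_bounds[1],
                           opts.dfast_bounds[1]])
            x[bad] = np.clip(
                _segmented_prefit_batch(y[bad], scheme.b, opts), lb, ub
            )
            n_fallback = int(bad.sum())
        sub = idx[finite]
        maps["Dslow"][sub[:, 0], sub[:, 1], sub[:, 2]] = x[:, 2]
        maps["Dfast"][sub[:, 0], sub[:, 1], sub[:, 2]] = x[:, 3]
        maps["PF"][sub[:, 0], sub[:, 1], sub[:, 2]] = x[:, 1]
    elif engine == "voxelwise":
        n_invalid = 0
        for i, j, k in idx:
            res = fit_ivim_voxel(series_data[i, j, k, :], scheme, opts)
            if not res.valid:
                n_invalid += 1
                continue
            if res.used_fallback:
                n_fallback += 1
            maps["Dslow"][i, j, k] = res.params.Dslow
            maps["Dfast"][i, j, k] = res.params.Dfast
            maps["PF"][i, j, k] = res.params.PF
    summary = MapFitSummary(
        n_fit=len(idx) - n_invalid, n_invalid=n_invalid, n_fallback=n_fallback
    )
    for k, m in maps.items():
        vals = m[mask]
        vals = vals[np.isfinite(vals)]
        summary.means[k] = float(vals.mean()) if vals.size else np.nan
        summary.sds[k] = float(vals.std()) if vals.size else np.nan
    return maps, summary


def grid_search_residual(
    signal: np.ndarray,
    scheme: BValueScheme,
    n_grid: int = 50,
    opts: FitOptions = FitOptions(),
) -> float:
    """Best residual norm over an exhaustive (PF, Dslow, Dfast) lattice.

    Brute-force reference for the nonlinear fit: S0 is fixed at the
    measured b=0 signal and the three remaining parameters are swept over
    a regular n_grid^3 lattice spanning the fit bounds.
    """
    s = np.asarray(signal, dtype=float)
    y = s / s[0]
    b = scheme.b
    pfs = np.linspace(*opts.pf_bounds, n_grid)
    dslows = np.linspace(*opts.dslow_bounds, n_grid)
    dfasts = np.linspace(*opts.dfast_bounds, n_grid)
    es = np.exp(-np.outer(dslows, b))  # (n, nb)
    ef = np.exp(-np.outer(dfasts, b))
    best = np.inf
    for pf in pfs:
        # model[i, j, :] for dslow_i, dfast_j
        model = pf * ef[None, :, :] + (1.0 - pf) * es[:, None, :]
        r2 = np.sum((model - y) ** 2, axis=2)
        best = min(best, float(r2.min()))
    return float(np.sqrt(best))
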