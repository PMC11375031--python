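"""Global least-squares sizing of diffusion profiles against a simulated basis.

The measured profile (all crossings jointly) is fitted as

    value(y) ~ a * P_rh(y) + b

where ``P_rh`` is the simulated basis profile at candidate radius ``rh``,
``a >= 0`` a global amplitude and ``b`` a global baseline, minimizing the
weighted sum of squared residuals. The radius is scanned over the basis grid
and refined by parabolic interpolation of the SSE over the three best nodes
(in log radius); ties on the grid are broken toward the smallest radius.

Weights default to Poisson (1/max(count, 1)) for digital step-scan profiles
and uniform for continuous intensity profiles.

The global uncertainty is a curvature (Taylor-expansion) estimate:
``var(rh) = 2 * sigma^2 / (d2 SSE / d rh^2)`` with ``sigma^2`` estimated from
the weighted residuals at the minimum. Local radius errors refit each
crossing alone and report the deviation from the global radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import physics
from .chip import BasisLibrary
from .exceptions import DegenerateFitError, InvalidInputError, NoSignalError
from .profiles import DiffusionProfile


@dataclass
class FitResult:
    """Outcome of a global diffusion-profile fit."""

    r_h_nm: float
    d_m2_s: float
    amplitude: float
    baseline: float
    sse: float
    r_h_error_nm: float | None = None
    local_errors_nm: list[float | None] = field(default_factory=list)
    at_boundary: bool = False
    n_points: int = 0
    metadata: dict = field(default_factory=dict)


def _design_matrix(profile: DiffusionProfile, basis: BasisLibrary,
                   crossings: list[int] | None = None):
    """Sample basis profiles at the measured coordinates.

    Returns (values, weights_mask_info): measured values v, per-point crossing
    index, and transverse positions on the basis grid axis. Points on walls
    (crossing -1) are dropped.
    """
    idx = profile.crossing_index()
    pos = profile.transverse_position_um(basis.width_um)
    keep = idx >= 0
    if crossings is not None:
        keep &= np.isin(idx, crossings)
    if not np.any(keep):
        raise InvalidInputError("no profile points inside the requested crossings")
    return profile.values[keep], idx[keep], pos[keep]


def _model_at(basis_profiles: np.ndarray, basis: BasisLibrary,
              pos: np.ndarray, idx: np.ndarray) -> np.ndarray:
    out = np.empty(pos.size)
    for k in np.unique(idx):
        m = idx == k
        out[m] = np.interp(pos[m], basis.transverse_um, basis_profiles[k])
    return out


def _solve_amp_baseline(v, m, w):
    """Weighted LS for value ~ a*model + b with a >= 0; returns (a, b, sse)."""
    sw = w.sum()
    mw = (w * m).sum() / sw
    vw = (w * v).sum() / sw
    var_m = (w * (m - mw) ** 2).sum()
    if var_m <= 0:
        a = 0.0
    else:
        a = (w * (m - mw) * (v - vw)).sum() / var_m
        a = max(a, 0.0)
    b = vw - a * mw
    r = v - a * m - b
    return a, b, float((w * r * r).sum())


def default_weights(profile: DiffusionProfile, values: np.ndarray) -> np.ndarray:
    """Uniform first-pass weights.

    Step-mode counts are Poisson, but weighting by the *observed* counts
    (1/max(v, 1)) correlates the weights with the noise and biases the
    radius; the fit therefore iterates once with Pearson weights
    1/max(expected, 1) computed from the first-pass model (see
    :func:`global_fit`). Continuous intensity profiles keep uniform weights.
    """
    return np.ones_like(values)


def _pearson_weights(v: np.ndarray, expected: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(expected, 1.0)


def _sse_on_grid(v, idx, pos, w, basis, crossings=None):
    sses = np.empty(len(basis.rh_nm))
    params = []
    for i in range(len(basis.rh_nm)):
        m = _model_at(basis.profiles[i], basis, pos, idx)
        a, b, sse = _solve_amp_baseline(v, m, w)
        sses[i] = sse
        params.append((a, b))
    return sses, params


def _parabolic_refine(basis: BasisLibrary, sses: np.ndarray, i_best: int):
    """Parabola through the best node and neighbors in log-radius.

    Returns (r_refined_nm, curvature d2SSE/dr2 in (per nm^2), at_boundary).
    """
    lr = np.log(basis.rh_nm)
    if i_best == 0 or i_best == len(lr) - 1:
        return float(basis.rh_nm[i_best]), None, True
    x0, x1, x2 = lr[i_best - 1], lr[i_best], lr[i_best + 1]
    y0, y1, y2 = sses[i_best - 1], sses[i_best], sses[i_best + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a2 = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    a1 = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a2 <= 0:
        return float(basis.rh_nm[i_best]), None, False
    x_min = float(np.clip(-a1 / (2 * a2), x0, x2))
    r_ref = float(np.exp(x_min))
    # chain rule: d2/dr2 = (1/r^2) * d2/d(ln r)^2 at the minimum (first deriv ~ 0)
    curv = 2.0 * a2 / r_ref**2
    return r_ref, curv, False


def _fit_once(v, idx, pos, w, basis):
    sses, _ = _sse_on_grid(v, idx, pos, w, basis)
    i_best = int(np.argmin(sses))  # first minimum = smallest radius on ties
    r_ref, curv, at_boundary = _parabolic_refine(basis, sses, i_best)
    m = _model_at(basis.interpolate(r_ref), basis, pos, idx)
    a, b, sse = _solve_amp_baseline(v, m, w)
    if sse > sses[i_best]:  # refinement must not degrade the grid optimum
        r_ref = float(basis.rh_nm[i_best])
        m = _model_at(basis.profiles[i_best], basis, pos, idx)
        a, b, sse = _solve_amp_baseline(v, m, w)
    return r_ref, a, b, sse, curv, at_boundary, sses, m


def _fit_subset(profile, basis, weights, crossings=None):
    v, idx, pos = _design_matrix(profile, basis, crossings)
    if not np.any(v > 0):
        raise NoSignalError("profile is all zero; nothing to fit")
    auto = weights is None
    w = default_weights(profile, v) if auto else weights
    if np.isscalar(w):
        w = np.full_like(v, float(w))
    w = np.asarray(w, dtype=float)
    if w.size != v.size:
        # caller passed weights over the full profile; subset them identically
        full_idx = profile.crossing_index()
        keep = full_idx >= 0
        if crossings is not None:
            keep &= np.isin(full_idx, crossings)
        w = w[keep]
    r_ref, a, b, sse, curv, at_boundary, sses, m = _fit_once(v, idx, pos, w, basis)
    if auto and profile.mode == "step":
        # one Pearson iteration: weights from the fitted expectation
        w = _pearson_weights(v, a * m + b)
        r_ref, a, b, sse, curv, at_boundary, sses, m = _fit_once(v, idx, pos, w, basis)
    return r_ref, a, b, sse, curv, at_boundary, v.size, sses


def global_fit(profile: DiffusionProfile, basis: BasisLibrary,
               weights: np.ndarray | float | None = None,
               cond: physics.SolventConditions | None = None,
               compute_errors: bool = True) -> FitResult:
    """Fit a diffusion profile against the basis to extract the radius.

    Parameters
    ----------
    profile : DiffusionProfile
        Measured profile; its coordinates are registered onto the basis
        transverse grid through the crossing boundaries.
    weights : array or scalar, optional
        Per-point weights (over the full profile or the in-crossing subset);
        defaults to Poisson weights for step mode, uniform for continuous.
    compute_errors : bool
        Also compute the global +/- range and per-crossing local errors.
    """
    cond = _basis_conditions(basis, cond)
    r, a, b, sse, curv, at_boundary, n, sses = _fit_subset(profile, basis, weights)
    result = FitResult(
        r_h_nm=r,
        d_m2_s=physics.diffusion_coefficient(r * 1e-9, cond),
        amplitude=a, baseline=b, sse=sse, at_boundary=at_boundary, n_points=n,
        metadata={"sse_grid": sses.tolist(), "curvature": curv,
                  "basis_flux_drift": basis.metadata.get("max_flux_drift_rel")},
    )
    if compute_errors:
        if not at_boundary and curv is not None:
            result.r_h_error_nm = fit_uncertainty(profile, basis, result)
        result.local_errors_nm = local_radius_error(profile, basis, result, weights)
    return result


def _basis_conditions(basis: BasisLibrary, cond):
    if cond is not None:
        return cond
    c = basis.metadata.get("conditions")
    if c:
        return physics.SolventConditions(c["temperature_K"], c["viscosity_Pa_s"])
    return physics.SolventConditions()


def local_radius_error(profile: DiffusionProfile, basis: BasisLibrary,
                       fit: FitResult, weights=None) -> list[float | None]:
    """Per-crossing radius deviation: r_global - r_local.

    Each crossing is refitted on its own; crossings with no signal yield
    ``None`` (undefined), never zero.
    """
    errors: list[float | None] = []
    for k in range(basis.n_crossings):
        try:
            r_loc, _a, _b, _sse, _c, _bd, _n, sses = _fit_subset(
                profile, basis, weights, crossings=[k])
        except (NoSignalError, InvalidInputError):
            errors.append(None)
            continue
        # a crossing whose SSE is flat across the radius grid carries no size
        # information (e.g. the inlet crossing at zero residence time)
        if sses.max() - sses.min() <= 1e-9 * max(sses.max(), 1e-300):
            errors.append(None)
            continue
        errors.append(fit.r_h_nm - r_loc)
    return errors


def fit_uncertainty(profile: DiffusionProfile, basis: BasisLibrary,
                    fit: FitResult) -> float:
    """Symmetric +/- range (nm) from the curvature of the SSE at the minimum.

    var(rh) = 2 * sigma^2 / (d2 SSE/d rh^2), sigma^2 = SSE_min / (n - 3)
    (three fitted parameters: radius, amplitude, baseline). Raises
    :class:`DegenerateFitError` for flat or boundary minima.
    """
    if fit.at_boundary:
        raise DegenerateFitError("fit at basis grid boundary; uncertainty undefined")
    curv = fit.metadata.get("curvature")
    if curv is None or curv <= 0:
        raise DegenerateFitError("non-positive SSE curvature; flat minimum")
    dof = max(fit.n_points - 3, 1)
    sigma2 = fit.sse / dof
    return float(np.sqrt(2.0 * sigma2 / curv))
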