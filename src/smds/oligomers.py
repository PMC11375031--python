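"""Brightness-histogram deconvolution of oligomeric states.

Because the degree of labeling is kept at or below one dye per monomer, the
normalized burst intensity (photons/ms) of an n-mer scales with n. The burst
intensity distribution of an oligomerizing protein is therefore modeled as a
constrained mixture:

* monomer: skew-normal (location, scale, shape) — the right skew reflects
  undersampling of short transits;
* n-mer (n = 2..k): Gaussian centered at exactly n x the monomer *mean*
  intensity, with standard deviation tied to the monomer sd.

Only the three skew-normal parameters and the k mixture weights are free;
centers and widths of all oligomer components are derived. Fitting is by
maximum likelihood on the unbinned intensities (histograms are for display
only). Species regions of +/- one monomer sd around each center gate bursts
into subpopulations whose diffusion profiles are sized independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr

from . import _fastmix
from .bursts import Burst, BurstSearchParams, PhotonTrace, find_bursts
from .exceptions import FitFailureError, InvalidInputError, InvalidParameterError
from .profiles import DiffusionProfile

_SQRT_2PI = math.sqrt(2.0 * math.pi)


# ----------------------------------------------------------------- skew-normal

def skewnorm_moments(xi: float, omega: float, alpha: float) -> tuple[float, float]:
    """(mean, sd) of a skew-normal(xi, omega, alpha)."""
    delta = alpha / math.sqrt(1.0 + alpha * alpha)
    mean = xi + omega * delta * math.sqrt(2.0 / math.pi)
    sd = omega * math.sqrt(1.0 - 2.0 * delta * delta / math.pi)
    return mean, sd


def skewnorm_params_from_moments(mean: float, sd: float, alpha: float) -> tuple[float, float, float]:
    """Invert :func:`skewnorm_moments` at fixed shape alpha."""
    delta = alpha / math.sqrt(1.0 + alpha * alpha)
    omega = sd / math.sqrt(1.0 - 2.0 * delta * delta / math.pi)
    xi = mean - omega * delta * math.sqrt(2.0 / math.pi)
    return xi, omega, alpha


def _skewnorm_logpdf(x: np.ndarray, xi: float, omega: float, alpha: float) -> np.ndarray:
    t = (x - xi) / omega
    return (math.log(2.0 / omega) - 0.5 * t * t - math.log(_SQRT_2PI)
            + log_ndtr(alpha * t))


def _normal_logpdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    t = (x - mu) / sd
    return -0.5 * t * t - math.log(sd * _SQRT_2PI)


# ------------------------------------------------------------------- mixtures

def oligomer_centers(i_monomer: float, n_max: int) -> np.ndarray:
    """Center intensities of the n-mer regions, n = 2..n_max.

    The n-mer carries n labeled monomer units, so its normalized intensity
    is exactly n x the monomer mean: centers are (2, 3, ..., n_max) x
    ``i_monomer``.
    """
    if not i_monomer > 0:
        raise InvalidParameterError("i_monomer must be > 0")
    if n_max < 2:
        raise InvalidParameterError("n_max must be >= 2")
    return i_monomer * np.arange(2, n_max + 1, dtype=float)


@dataclass
class BrightnessMixture:
    """Fitted burst-brightness mixture (monomer skew-normal + tied Gaussians)."""

    xi: float
    omega: float
    alpha: float
    n_species: int
    abundances: np.ndarray
    nll: float
    n_bursts: int
    abundance_ci99: np.ndarray | None = None  # (k, 2) after abundance_ci
    metadata: dict = field(default_factory=dict)

    @property
    def i_monomer(self) -> float:
        return skewnorm_moments(self.xi, self.omega, self.alpha)[0]

    @property
    def sigma_monomer(self) -> float:
        return skewnorm_moments(self.xi, self.omega, self.alpha)[1]

    @property
    def oligomer_centers(self) -> np.ndarray:
        if self.n_species < 2:
            return np.empty(0)
        return oligomer_centers(self.i_monomer, self.n_species)

    @property
    def bic(self) -> float:
        n_params = 3 + (self.n_species - 1)
        return 2.0 * self.nll + n_params * math.log(self.n_bursts)

    def component_logpdfs(self, x: np.ndarray) -> np.ndarray:
        """(k, n) log densities of every component at x."""
        mu, sd = skewnorm_moments(self.xi, self.omega, self.alpha)
        out = np.empty((self.n_species, x.size))
        out[0] = _skewnorm_logpdf(x, self.xi, self.omega, self.alpha)
        for s in range(1, self.n_species):
            out[s] = _normal_logpdf(x, (s + 1) * mu, sd)
        return out


@dataclass(frozen=True)
class SpeciesRegion:
    """Intensity gate for one species: |I - center| <= half_width."""

    label: str
    center: float
    half_width: float

    def __post_init__(self) -> None:
        if not self.half_width > 0:
            raise InvalidParameterError("half_width must be > 0")


def _intensities(bursts) -> np.ndarray:
    if isinstance(bursts, np.ndarray):
        return np.asarray(bursts, dtype=float)
    return np.array([b.normalized_intensity for b in bursts], dtype=float)


def _component_logpdfs(x: np.ndarray, xi: float, omega: float, alpha: float,
                       k: int) -> np.ndarray | None:
    mu, sd = skewnorm_moments(xi, omega, alpha)
    if mu <= 0 or sd <= 0:
        return None
    comp = np.empty((k, x.size))
    comp[0] = _skewnorm_logpdf(x, xi, omega, alpha)
    for s in range(1, k):
        comp[s] = _normal_logpdf(x, (s + 1) * mu, sd)
    return comp


def _shape_nll(theta: np.ndarray, x: np.ndarray, k: int, logw: np.ndarray) -> float:
    xi, log_omega, alpha = theta
    if not np.all(np.isfinite(theta)) or abs(log_omega) > 20:
        return 1e300
    return _fastmix.mixture_nll(x, xi, math.exp(log_omega), alpha, logw)


def _shape_nll_grad(theta: np.ndarray, x: np.ndarray, logw: np.ndarray):
    xi, log_omega, alpha = theta
    if not np.all(np.isfinite(theta)) or abs(log_omega) > 20:
        return 1e300, np.zeros(3)
    return _fastmix.mixture_nll_grad(x, xi, math.exp(log_omega), alpha, logw)


def _shape_step(theta0: np.ndarray, x: np.ndarray, logw: np.ndarray,
                maxiter: int = 40):
    res = minimize(_shape_nll_grad, theta0, args=(x, logw), jac=True,
                   method="L-BFGS-B", options={"maxiter": maxiter, "ftol": 1e-10})
    return res.x, float(res.fun)


def _monomer_init(x: np.ndarray) -> tuple[float, float]:
    """Monomer mean/sd guess from the histogram mode and the lower flank."""
    hist, edges = np.histogram(x, bins=60)
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    mode = max(mode, float(np.percentile(x, 10)), 1e-6)
    lower = x[x < 1.6 * mode]
    sd0 = float(np.std(lower)) if lower.size > 10 else float(0.5 * np.std(x))
    return float(mode), max(sd0, 1e-6)


def _coordinate_ascent(x: np.ndarray, k: int, i0: float, sd0: float, alpha0: float,
                       n_outer: int = 40):
    xi, omega, alpha = skewnorm_params_from_moments(i0, sd0, alpha0)
    w = np.array([0.70, 0.18, 0.08, 0.04] + [0.02] * max(k - 4, 0))[:k]
    w = w / w.sum()
    prev = np.inf
    for _ in range(n_outer):
        mu, sd = skewnorm_moments(xi, omega, alpha)
        if mu <= 0 or sd <= 0:
            return None
        w = _fastmix.em_weights(x, xi, omega, alpha, w, 100, 1e-8)
        logw = np.log(np.maximum(w, 1e-300))
        theta, nll = _shape_step(np.array([xi, math.log(omega), alpha]), x, logw)
        xi, omega, alpha = theta[0], math.exp(theta[1]), theta[2]
        if prev - nll < 1e-7 * max(abs(nll), 1.0):
            prev = nll
            break
        prev = nll
    return xi, omega, alpha, w, float(prev)


def fit_brightness_mixture(bursts, n_species: int, min_bursts: int = 200) -> BrightnessMixture:
    """Maximum-likelihood fit of the constrained brightness mixture.

    Alternates EM updates of the mixture weights with simplex refinement of
    the three skew-normal shape parameters (all oligomer centers/widths are
    derived from the shape, so the shape step re-ties the whole comb).
    Two starts with different initial skewness guard against the wide-monomer
    local optimum that swallows the dimer shoulder; the best likelihood wins.

    Parameters
    ----------
    bursts : list of Burst or array of normalized intensities (photons/ms)
    n_species : int
        Number of species (monomer + n_species-1 oligomer states), >= 1.
    min_bursts : int
        Floor on the sample size (default 200).
    """
    if n_species < 1:
        raise InvalidParameterError("n_species must be >= 1")
    x = _intensities(bursts)
    if x.size < min_bursts:
        raise InvalidInputError(f"need >= {min_bursts} bursts, got {x.size}")

    i0, sd0 = _monomer_init(x)
    best = None
    for alpha0 in (1.5, 4.0):
        fit = _coordinate_ascent(x, n_species, i0, sd0, alpha0)
        if fit is not None and (best is None or fit[4] < best[4]):
            best = fit
    if best is None or not np.isfinite(best[4]):
        raise FitFailureError("mixture fit failed to converge from all starts")
    xi, omega, alpha, w, nll = best
    return BrightnessMixture(
        xi=float(xi), omega=float(omega), alpha=float(alpha),
        n_species=n_species, abundances=np.asarray(w), nll=nll, n_bursts=int(x.size),
        metadata={"starts": 2, "optimizer": "em-weights + simplex-shape"},
    )


def select_species_count(bursts, k_range, min_bursts: int = 200) -> tuple[int, pd.DataFrame]:
    """Choose the number of species by BIC over candidate counts.

    Returns (best_k, table) where the table lists k, negative log-likelihood
    and BIC for every candidate. The criterion (BIC on the unbinned mixture
    likelihood) penalizes each added species by one weight parameter.
    """
    k_range = list(k_range)
    if not k_range:
        raise InvalidParameterError("k_range must be nonempty")
    rows = []
    for k in k_range:
        mix = fit_brightness_mixture(bursts, k, min_bursts=min_bursts)
        rows.append({"k": k, "nll": mix.nll, "bic": mix.bic})
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["bic"].idxmin(), "k"])
    return best_k, table


def species_regions(mixture: BrightnessMixture) -> list[SpeciesRegion]:
    """Gating regions of +/- one monomer sd around every species center."""
    mu, sd = mixture.i_monomer, mixture.sigma_monomer
    regions = [SpeciesRegion("monomer", mu, sd)]
    names = {2: "dimer", 3: "trimer", 4: "tetramer"}
    for s in range(2, mixture.n_species + 1):
        regions.append(SpeciesRegion(names.get(s, f"{s}-mer"), s * mu, sd))
    return regions


def gate_bursts(bursts: list[Burst], region: SpeciesRegion) -> list[Burst]:
    """Bursts whose normalized intensity falls inside the region."""
    return [b for b in bursts
            if abs(b.normalized_intensity - region.center) <= region.half_width]


def abundance_ci(mixture: BrightnessMixture, bursts, n_boot: int = 1000,
                 level: float = 0.99, seed: int = 0) -> np.ndarray:
    """Percentile-bootstrap confidence intervals for the abundances.

    Bursts are resampled with replacement and the full mixture (weights and
    skew-normal shape, hence all tied centers/widths) is refitted on every
    resample, warm-started from the full-sample fit: weight-EM, a simplex
    pass over the shape, then a final weight-EM. Reproducible under a fixed
    seed.

    Returns a (n_species, 2) array of [lo, hi] at the requested level.
    """
    if n_boot < 100:
        raise InvalidParameterError("n_boot must be >= 100")
    x = _intensities(bursts)
    if x.size < 10:
        raise InvalidInputError("too few bursts to resample")
    rng = np.random.default_rng(seed)
    k = mixture.n_species
    out = np.empty((n_boot, k))
    theta0 = np.array([mixture.xi, math.log(mixture.omega), mixture.alpha])
    for b in range(n_boot):
        xb = x[rng.integers(0, x.size, x.size)]
        w = _fastmix.em_weights(xb, mixture.xi, mixture.omega, mixture.alpha,
                                mixture.abundances.copy(), 100, 1e-7)
        theta = theta0
        for it_max in (12, 8):  # two coordinate cycles reach the resample's own MLE
            logw = np.log(np.maximum(w, 1e-300))
            theta, _ = _shape_step(theta, xb, logw, maxiter=it_max)
            w = _fastmix.em_weights(xb, theta[0], math.exp(theta[1]), theta[2],
                                    w, 100, 1e-7)
        out[b] = w
    lo = (1.0 - level) / 2.0
    # conservative endpoints: no interpolation between order statistics, so
    # finite n_boot does not narrow the extreme tails
    ci = np.stack([np.quantile(out, lo, axis=0, method="lower"),
                   np.quantile(out, 1.0 - lo, axis=0, method="higher")], axis=1)
    mixture.abundance_ci99 = ci
    return ci


def threshold_sweep(
    traces: list[PhotonTrace],
    n_min_values,
    ipt_max_ms: float,
    basis,
    lee_window: int = 3,
    crossing_boundaries=None,
    cond=None,
    min_bursts: int = 50,
) -> tuple[pd.DataFrame, "FitResult"]:
    """Size-vs-photon-threshold analysis of a heterogeneous sample.

    The burst search runs once at the smallest ``n_min``; each threshold then
    keeps only bursts with at least that many photons, rebuilds the digital
    step profile, and refits the radius. Thresholds retaining fewer than
    ``min_bursts`` bursts are marked undersampled (NaN radius). Also returns
    the ensemble fit from all bursts.
    """
    from .fitting import global_fit  # local import to avoid cycle

    n_min_values = sorted(int(v) for v in n_min_values)
    if not n_min_values:
        raise InvalidParameterError("n_min_values must be nonempty")
    params = BurstSearchParams(ipt_max_ms=ipt_max_ms, n_min=n_min_values[0],
                               lee_window=lee_window)
    per_trace = [find_bursts(tr, params) for tr in traces]
    coords = np.array([tr.transverse_um for tr in traces])
    order = np.argsort(coords)

    def build_profile(nmin: int) -> tuple[DiffusionProfile, int]:
        counts = np.array(
            [sum(1 for b in bl if b.n_photons >= nmin) for bl in per_trace], dtype=float)
        prof = DiffusionProfile(coords[order], counts[order], "step",
                                crossing_boundaries or
                                [(float(coords.min()), float(coords.max()))])
        return prof, int(counts.sum())

    rows = []
    for nmin in n_min_values:
        prof, total = build_profile(nmin)
        if total < min_bursts:
            rows.append({"n_min": nmin, "r_h_nm": np.nan, "r_h_error_nm": np.nan,
                         "n_bursts": total, "undersampled": True})
            continue
        fit = global_fit(prof, basis, cond=cond, compute_errors=False)
        try:
            from .fitting import fit_uncertainty
            err = fit_uncertainty(prof, basis, fit) if not fit.at_boundary else np.nan
        except Exception:
            err = np.nan
        rows.append({"n_min": nmin, "r_h_nm": fit.r_h_nm, "r_h_error_nm": err,
                     "n_bursts": total, "undersampled": False})
    ens_prof, _ = build_profile(n_min_values[0])
    ensemble = global_fit(ens_prof, basis, cond=cond, compute_errors=False)
    return pd.DataFrame(rows), ensemble
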