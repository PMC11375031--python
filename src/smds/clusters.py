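"""Rare-species separation and nanoscale-cluster sizing.

Two related analyses for mixtures where a rare, very bright species rides on
an abundant bulk signal:

* fibril/monomer separation — a Savitzky-Golay-smoothed 1-ms binned trace is
  split at a fixed count-rate threshold (e.g. >250 kHz): supra-threshold
  runs are attributed to large assemblies (counted per position), the
  remainder forms the bulk signal, and each stream is sized independently;

* nanocluster detection and Fick sizing — clusters are detected as runs of
  bins exceeding mean + k*sd of the bulk (robust median/MAD estimates so the
  rare events do not inflate the threshold), histogrammed per position,
  Gaussian-fitted per crossing, and the half-FWHM diffusion distances x(t)
  are fitted with the one-dimensional Fick broadening law x = sqrt(2 D t)
  after quadrature normalization by the t = 0 width. Event counts convert to
  flux, particle concentration and condensed-phase volume fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from . import physics
from .exceptions import (
    ConfigurationRequiredError,
    DegenerateStatisticsError,
    InvalidParameterError,
    NoBroadeningError,
)

#: FWHM of a Gaussian in units of its standard deviation.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class SplitTrace:
    """A 1-ms binned trace split into spike segments and bulk signal."""

    spike_segments: list[tuple[int, int]]  # [start_bin, end_bin) intervals
    bulk_series: np.ndarray  # supra-threshold intervals removed
    bulk_mask: np.ndarray  # True where the original trace is bulk
    threshold_khz: float
    smoothing: dict = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_segments)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


def split_trace_by_threshold(trace_counts: np.ndarray, rate_threshold_khz: float,
                             smooth_window: int = 11, smooth_order: int = 3,
                             bin_ms: float = 1.0) -> SplitTrace:
    """Split a binned trace at a smoothed count-rate threshold.

    Spikes are maximal runs where the Savitzky-Golay smoothed rate exceeds
    the threshold, padded by one smoothing window on each side; the bulk is
    everything else.
    """
    x = np.asarray(trace_counts, dtype=float)
    if not rate_threshold_khz > 0:
        raise InvalidParameterError("rate_threshold_khz must be > 0")
    if smooth_window % 2 == 0 or smooth_window <= smooth_order:
        raise InvalidParameterError("smoothing window must be odd and > order")
    if smooth_window >= x.size:
        raise InvalidParameterError(
            f"smoothing window {smooth_window} >= trace length {x.size}")
    rate_khz = savgol_filter(x / bin_ms, smooth_window, smooth_order)
    above = rate_khz > rate_threshold_khz
    segments = []
    spike_mask = np.zeros(x.size, dtype=bool)
    for s, e in _runs(above):
        s_pad = max(s - smooth_window, 0)
        e_pad = min(e + smooth_window, x.size)
        segments.append((s_pad, e_pad))
        spike_mask[s_pad:e_pad] = True
    # merge padded overlaps
    merged = []
    for seg in segments:
        if merged and seg[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(seg[1], merged[-1][1]))
        else:
            merged.append(seg)
    bulk_mask = ~spike_mask
    return SplitTrace(spike_segments=merged, bulk_series=x[bulk_mask],
                      bulk_mask=bulk_mask, threshold_khz=rate_threshold_khz,
                      smoothing={"window": smooth_window, "order": smooth_order,
                                 "bin_ms": bin_ms})


def detect_cluster_events(trace_counts: np.ndarray, k_sd: float = 5.0,
                          bin_ms: float = 1.0) -> list[tuple[int, int]]:
    """Detect rare bright events as runs of bins above mean + k_sd * sd.

    Bulk mean and sd are estimated robustly (median and 1.4826 x MAD) so the
    events themselves do not inflate the threshold. Returns [start, end)
    bin intervals; len() of the result is the event count at this position.
    """
    x = np.asarray(trace_counts, dtype=float)
    if x.size < 10:
        raise InvalidParameterError("trace too short to estimate bulk statistics")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    sd = 1.4826 * mad
    if sd <= 0:
        sd = float(np.std(x))
        if sd <= 0:
            raise DegenerateStatisticsError("zero-variance trace; no threshold definable")
    return _runs(x > med + k_sd * sd)


@dataclass
class PeakFit:
    """Gaussian fit of one per-crossing event histogram."""

    crossing: int
    mean_um: float
    sigma_um: float
    amplitude: float

    @property
    def fwhm_um(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_um

    @property
    def diffusion_distance_um(self) -> float:
        """Half of the FWHM — the distance convention of the Fick analysis."""
        return 0.5 * self.fwhm_um


def fit_position_peaks(coordinates_um: np.ndarray, counts: np.ndarray,
                       crossing_boundaries: list[tuple[float, float]],
                       min_positions: int = 3) -> tuple[list[PeakFit], list[int]]:
    """Independent Gaussian fit of the event histogram in every crossing.

    Crossings with fewer than ``min_positions`` informative (nonzero)
    positions are excluded and their indices returned in the second element.
    """
    coords = np.asarray(coordinates_um, dtype=float)
    vals = np.asarray(counts, dtype=float)
    fits: list[PeakFit] = []
    excluded: list[int] = []

    def gauss(x, a, mu, sig):
        return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    for k, (lo, hi) in enumerate(crossing_boundaries):
        m = (coords >= lo) & (coords <= hi)
        xs, ys = coords[m], vals[m]
        if np.count_nonzero(ys) < min_positions:
            excluded.append(k)
            continue
        w = ys.sum()
        mu0 = float((xs * ys).sum() / w)
        sig0 = float(np.sqrt(np.maximum(((xs - mu0) ** 2 * ys).sum() / w, 1e-6)))
        try:
            popt, _ = curve_fit(gauss, xs, ys, p0=[ys.max(), mu0, sig0], maxfev=10_000)
        except RuntimeError:
            excluded.append(k)
            continue
        fits.append(PeakFit(crossing=k, mean_um=float(popt[1]),
                            sigma_um=float(abs(popt[2])), amplitude=float(popt[0])))
    return fits, excluded


def fick_fit(distances_um: np.ndarray, times_s: np.ndarray,
             cond: physics.SolventConditions | None = None) -> tuple[float, float]:
    """Diffusion coefficient and radius from diffusion distances vs time.

    The width at t = 0 is removed in quadrature, x_net = sqrt(x^2 - x0^2),
    and the net distances are least-squares fitted with the one-dimensional
    broadening law x_net = sqrt(2 D t); the Stokes-Einstein relation then
    gives the hydrodynamic radius.

    Returns (D in m^2/s, r_h in nm).
    """
    x = np.asarray(distances_um, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if x.size != t.size or x.size < 3:
        raise InvalidParameterError("need x(0) plus >= 2 later time points")
    if t[0] != 0:
        raise InvalidParameterError("first time point must be the t = 0 reference")
    x0 = x[0]
    xs, ts = x[1:], t[1:]
    if np.any(ts <= 0):
        raise InvalidParameterError("later time points must be strictly positive")
    net_sq = xs**2 - x0**2
    if np.all(net_sq <= 0):
        raise NoBroadeningError("no broadening beyond the t = 0 width")
    x_net = np.sqrt(np.maximum(net_sq, 0.0)) * 1e-6  # m
    # least squares of x_net = s * sqrt(t): s = sum(x sqrt(t)) / sum(t)
    st = np.sqrt(ts)
    s = float((x_net * st).sum() / ts.sum())
    d = 0.5 * s * s
    r_h = physics.hydrodynamic_radius(d, cond)
    return d, r_h * 1e9


def cluster_flux(n_events: int, total_observation_s: float,
                 detection_efficiency: float | None = None) -> float:
    """Particle flux (clusters/s) from a digital event count.

    The geometric/optical conversion from counted events to the flux through
    the full channel cross-section is instrument calibration; the detection
    efficiency is therefore mandatory explicit configuration and never
    defaulted.
    """
    if detection_efficiency is None:
        raise ConfigurationRequiredError(
            "detection_efficiency must be supplied explicitly (no silent default)")
    if not 0 < detection_efficiency <= 1:
        raise InvalidParameterError("detection_efficiency must be in (0, 1]")
    if not total_observation_s > 0:
        raise InvalidParameterError("observation time must be > 0")
    return (n_events / total_observation_s) / detection_efficiency


def cluster_concentration(flux_per_s: float, flow: "FlowSettings") -> float:
    """Particle concentration (pM) from flux and volumetric flow rate.

    c = F / (Q * N_A) with Q the volumetric flow: every particle in the
    fluid volume passing per second is counted once.
    """
    if flux_per_s < 0:
        raise InvalidParameterError("flux must be >= 0")
    q_l_s = flow.flow_rate_m3_s * 1e3  # L/s
    c_molar = flux_per_s / (q_l_s * physics.AVOGADRO)
    return c_molar * 1e12  # pM


def volume_fraction(concentration_pm: float, radius_nm: float) -> float:
    """Total volume fraction of spherical particles at a number concentration.

    phi = c * N_A * (4/3) pi r^3 in consistent units.
    """
    if concentration_pm < 0:
        raise InvalidParameterError("concentration must be >= 0")
    if not radius_nm > 0:
        raise InvalidParameterError("radius must be > 0")
    n_per_m3 = concentration_pm * 1e-12 * 1000.0 * physics.AVOGADRO
    return n_per_m3 * (4.0 / 3.0) * math.pi * (radius_nm * 1e-9) ** 3


def concentration_from_volume_fraction(phi: float, radius_nm: float) -> float:
    """Inverse of :func:`volume_fraction`; returns pM."""
    v = (4.0 / 3.0) * math.pi * (radius_nm * 1e-9) ** 3
    return phi / (v * physics.AVOGADRO * 1000.0) * 1e12


def monomers_per_cluster(r_cluster_nm: float, r_monomer_nm: float,
                         packing_fractions=(0.10, 0.35)) -> tuple[float, float, float]:
    """Bounds on the number of monomers per cluster from volume ratios.

    Returns (lower, upper, ceiling): packing x (r_cluster/r_monomer)^3 for
    the supplied packing-fraction range, plus the pure-protein ceiling
    (packing = 1), all unrounded.
    """
    if r_cluster_nm <= 0 or r_monomer_nm <= 0:
        raise InvalidParameterError("radii must be > 0")
    fr = sorted(packing_fractions)
    if any(not 0 < f <= 1 for f in fr):
        raise InvalidParameterError("packing fractions must be in (0, 1]")
    ratio = (r_cluster_nm / r_monomer_nm) ** 3
    return fr[0] * ratio, fr[-1] * ratio, ratio


@dataclass
class ClusterResult:
    """Full nanocluster analysis report."""

    events_per_position: np.ndarray
    peak_fits: list[PeakFit]
    distances_um: np.ndarray
    times_s: np.ndarray
    d_m2_s: float
    r_h_nm: float
    n_events: int
    flux_per_s: float | None = None
    concentration_pm: float | None = None
    volume_fraction: float | None = None


def analyze_cluster_scan(
    coordinates_um: np.ndarray,
    events_per_position: np.ndarray,
    crossing_boundaries: list[tuple[float, float]],
    crossing_times_s: np.ndarray,
    cond: physics.SolventConditions | None = None,
    flow: "FlowSettings | None" = None,
    total_observation_s: float | None = None,
    detection_efficiency: float | None = None,
) -> ClusterResult:
    """Per-position event histogram -> peak fits -> Fick fit -> flux/c/phi."""
    fits, excluded = fit_position_peaks(coordinates_um, events_per_position,
                                        crossing_boundaries)
    times = np.asarray(crossing_times_s, dtype=float)
    used = [f for f in fits if f.crossing not in excluded]
    x = np.array([f.diffusion_distance_um for f in used])
    t = times[[f.crossing for f in used]]
    d, r_h = fick_fit(x, t, cond)
    n_events = int(np.asarray(events_per_position).sum())
    result = ClusterResult(events_per_position=np.asarray(events_per_position),
                           peak_fits=fits, distances_um=x, times_s=t,
                           d_m2_s=d, r_h_nm=r_h, n_events=n_events)
    if total_observation_s is not None and detection_efficiency is not None:
        result.flux_per_s = cluster_flux(n_events, total_observation_s,
                                         detection_efficiency)
        if flow is not None:
            result.concentration_pm = cluster_concentration(result.flux_per_s, flow)
            result.volume_fraction = volume_fraction(result.concentration_pm, r_h)
    return result
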