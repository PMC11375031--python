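"""Ground-truth generator: photon traces and scans for species mixtures.

Every analysis stage in the package has a synthetic oracle generated here.
The generator emulates the measurement physics at the level the analysis
sees it:

* flow-focused sample stream (~1:8 sample:buffer) whose transverse
  concentration field at each crossing comes from the same advection-
  diffusion basis the fitter uses (so generator and fitter share one
  physical model of spreading, while noise, detection and burst structure
  are produced independently);
* molecule transits as a Poisson process with rate proportional to local
  concentration x mean flow velocity x effective detection area;
* Poissonian photon emission at (brightness x labeled units) during each
  transit, on top of Poissonian background;
* every artifact ships a manifest recording true parameters, per-position
  expected rates and the seed, sufficient to recompute expected statistics
  analytically.

Transit durations are detection_length / mean velocity; diffusion during a
transit is neglected (flow-dominated regime, Peclet >> 1 at the default
100 uL/h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import physics
from .bursts import TICK_S, PhotonTrace
from .chip import BasisLibrary, ChipGeometry, FlowSettings, mean_velocity
from .exceptions import InvalidParameterError, OutOfRangeError

#: Default gap (um) between scanned crossings on the scan axis (PDMS wall).
DEFAULT_GAP_UM = 50.0


@dataclass(frozen=True)
class SpeciesSpec:
    """One diffusing, fluorescent species."""

    r_h_nm: float
    concentration_M: float
    # peak detected count rate per labeled unit during a transit. Default 1000
    # photons/ms (~1 MHz) keeps the intra-burst inter-photon time an order of
    # magnitude below the default 0.01-ms burst threshold, so one transit maps
    # to one cohesive burst -- the operating regime of single-molecule counting.
    brightness_photons_ms: float = 1000.0
    labeled_units_dist: dict = field(default_factory=lambda: {1: 1.0})
    label: str = "species"

    def __post_init__(self) -> None:
        if self.r_h_nm <= 0 or self.concentration_M < 0 or self.brightness_photons_ms <= 0:
            raise InvalidParameterError("species parameters must be positive")
        total = sum(self.labeled_units_dist.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise InvalidParameterError("labeled_units_dist must be normalized")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scan acquisition settings; the seed is mandatory."""

    mode: str = "step"  # "step" | "continuous"
    seed: int = 0
    dwell_s: float = 2.0
    bin_ms: float = 1.0
    background_rate_khz: float = 2.0
    n_steps_per_crossing: int = 50
    scan_speed_um_s: float = 50.0
    detection_length_um: float = 1.0
    detection_area_um2: float = 0.3

    def __post_init__(self) -> None:
        if self.dwell_s <= 0 or self.bin_ms <= 0:
            raise InvalidParameterError("dwell and bin must be > 0")
        if self.mode not in ("step", "continuous"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")


def scan_layout(geom: ChipGeometry, n_crossings: int = 4,
                gap_um: float = DEFAULT_GAP_UM) -> list[tuple[float, float]]:
    """Crossing boundary ranges along the scan axis."""
    W = geom.observation_width_um
    return [(k * (W + gap_um), k * (W + gap_um) + W) for k in range(n_crossings)]


def step_positions(geom: ChipGeometry, n_per_crossing: int, n_crossings: int = 4,
                   gap_um: float = DEFAULT_GAP_UM) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Evenly spaced step-scan coordinates (cell-centered within each crossing)."""
    bounds = scan_layout(geom, n_crossings, gap_um)
    W = geom.observation_width_um
    coords = []
    for lo, _hi in bounds:
        coords.append(lo + (np.arange(n_per_crossing) + 0.5) * W / n_per_crossing)
    return np.concatenate(coords), bounds


def _local_number_density(species: SpeciesSpec, geom: ChipGeometry,
                          basis: BasisLibrary, transverse_um: np.ndarray,
                          crossing: int) -> np.ndarray:
    """Local number density (1/m^3) at mid-height given the basis shape.

    The inlet stream carries concentration c over fraction f of the width, so
    the conserved transverse line density is c*N_A*1000 * f*W; the basis
    profile (unit area in um^-1) distributes it across the width.
    """
    if not basis.rh_nm[0] <= species.r_h_nm <= basis.rh_nm[-1]:
        raise OutOfRangeError(
            f"species r_h={species.r_h_nm} nm outside basis grid "
            f"[{basis.rh_nm[0]}, {basis.rh_nm[-1]}] nm"
        )
    prof = basis.interpolate(species.r_h_nm)[crossing]
    p_per_m = np.interp(transverse_um, basis.transverse_um, prof) * 1e6  # 1/m
    n_bulk = species.concentration_M * 1000.0 * physics.AVOGADRO  # 1/m^3
    line_density = n_bulk * geom.sample_flow_fraction * geom.observation_width_um * 1e-6
    return line_density * p_per_m


def transit_rates(species: list[SpeciesSpec], geom: ChipGeometry, flow: FlowSettings,
                  acq: AcquisitionSpec, basis: BasisLibrary,
                  positions_um: np.ndarray,
                  boundaries: list[tuple[float, float]]) -> np.ndarray:
    """Expected transit rate (1/s) per species per position, shape (n_species, n_pos)."""
    v = mean_velocity(geom, flow)
    a_det = acq.detection_area_um2 * 1e-12
    W = geom.observation_width_um
    rates = np.zeros((len(species), positions_um.size))
    for k, (lo, hi) in enumerate(boundaries):
        m = (positions_um >= lo) & (positions_um <= hi)
        if not np.any(m):
            continue
        y_t = (positions_um[m] - lo) / (hi - lo) * W
        for s, sp in enumerate(species):
            dens = _local_number_density(sp, geom, basis, y_t, k)
            rates[s, m] = dens * v * a_det
    return rates


def expected_total_counts(species, geom, flow, acq, basis, positions_um, boundaries) -> float:
    return float(transit_rates(species, geom, flow, acq, basis,
                               positions_um, boundaries).sum() * acq.dwell_s)


def concentration_for_total_counts(target_counts: float, species: SpeciesSpec,
                                   geom, flow, acq, basis,
                                   positions_um, boundaries) -> float:
    """Concentration (M) at which the expected total transit count hits target."""
    probe = SpeciesSpec(species.r_h_nm, 1e-12, species.brightness_photons_ms,
                        dict(species.labeled_units_dist), species.label)
    base = expected_total_counts([probe], geom, flow, acq, basis, positions_um, boundaries)
    if base <= 0:
        raise InvalidParameterError("zero expected counts at probe concentration")
    return 1e-12 * target_counts / base


def _sample_units(rng: np.random.Generator, dist: dict, n: int) -> np.ndarray:
    units = np.array(sorted(dist))
    probs = np.array([dist[u] for u in units], dtype=float)
    return rng.choice(units, size=n, p=probs / probs.sum())


def _to_trace(times_s: np.ndarray, dwell_s: float, position_id: int,
              transverse_um: float) -> PhotonTrace:
    ticks = np.unique(np.floor(np.clip(times_s, 0, dwell_s - TICK_S) / TICK_S).astype(np.int64))
    return PhotonTrace(ticks, dwell_s, position_id, transverse_um)


def generate_step_scan(
    species: list[SpeciesSpec],
    geom: ChipGeometry,
    flow: FlowSettings,
    cond: physics.SolventConditions,
    acq: AcquisitionSpec,
    basis: BasisLibrary,
    n_crossings: int = 4,
    gap_um: float = DEFAULT_GAP_UM,
) -> tuple[list[PhotonTrace], dict]:
    """Simulate a full step scan; returns per-position traces + manifest."""
    rng = np.random.default_rng(acq.seed)
    positions, bounds = step_positions(geom, acq.n_steps_per_crossing, n_crossings, gap_um)
    rates = transit_rates(species, geom, flow, acq, basis, positions, bounds)
    v = mean_velocity(geom, flow)
    transit_s = acq.detection_length_um * 1e-6 / v
    traces: list[PhotonTrace] = []
    true_counts = np.zeros((len(species), positions.size), dtype=int)
    for j, x in enumerate(positions):
        times = [rng.uniform(0, acq.dwell_s,
                             rng.poisson(acq.background_rate_khz * 1e3 * acq.dwell_s))]
        for s, sp in enumerate(species):
            n_tr = rng.poisson(rates[s, j] * acq.dwell_s)
            true_counts[s, j] = n_tr
            if n_tr == 0:
                continue
            starts = rng.uniform(0, acq.dwell_s - transit_s, n_tr)
            units = _sample_units(rng, sp.labeled_units_dist, n_tr)
            n_ph = rng.poisson(sp.brightness_photons_ms * units * transit_s * 1e3)
            for t0, k in zip(starts, n_ph):
                if k:
                    times.append(t0 + rng.uniform(0, transit_s, k))
        traces.append(_to_trace(np.concatenate(times), acq.dwell_s, j, float(x)))
    manifest = {
        "mode": "step", "seed": acq.seed,
        "species": [{"label": sp.label, "r_h_nm": sp.r_h_nm,
                     "concentration_M": sp.concentration_M,
                     "brightness_photons_ms": sp.brightness_photons_ms}
                    for sp in species],
        "positions_um": positions.tolist(),
        "crossing_boundaries": [list(b) for b in bounds],
        "expected_rates_per_s": rates.tolist(),
        "true_transit_counts": true_counts.tolist(),
        "transit_duration_s": transit_s,
        "dwell_s": acq.dwell_s,
        "background_rate_khz": acq.background_rate_khz,
    }
    return traces, manifest


def generate_continuous_scan(
    species: list[SpeciesSpec],
    geom: ChipGeometry,
    flow: FlowSettings,
    cond: physics.SolventConditions,
    acq: AcquisitionSpec,
    basis: BasisLibrary,
    n_crossings: int = 4,
    gap_um: float = DEFAULT_GAP_UM,
) -> tuple[PhotonTrace, dict]:
    """Simulate a constant-speed scan as one photon trace.

    The expected intensity at scan coordinate y is
    (local number density x detection volume) x brightness + background;
    photons are drawn per 1-ms micro-bin as a Poisson count.
    """
    rng = np.random.default_rng(acq.seed)
    bounds = scan_layout(geom, n_crossings, gap_um)
    length = bounds[-1][1]
    duration = length / acq.scan_speed_um_s
    n_bins = int(np.ceil(duration / (acq.bin_ms * 1e-3)))
    mid_t = (np.arange(n_bins) + 0.5) * acq.bin_ms * 1e-3
    coords = acq.scan_speed_um_s * mid_t
    v_det = acq.detection_area_um2 * acq.detection_length_um * 1e-18  # m^3
    W = geom.observation_width_um
    intensity_ms = np.full(n_bins, acq.background_rate_khz)  # photons/ms
    for k, (lo, hi) in enumerate(bounds):
        m = (coords >= lo) & (coords <= hi)
        if not np.any(m):
            continue
        y_t = (coords[m] - lo) / (hi - lo) * W
        for sp in species:
            dens = _local_number_density(sp, geom, basis, y_t, k)
            mean_units = sum(u * p for u, p in sp.labeled_units_dist.items())
            intensity_ms[m] += dens * v_det * sp.brightness_photons_ms * mean_units
    counts = rng.poisson(intensity_ms * acq.bin_ms)
    times = []
    t_edges = np.arange(n_bins) * acq.bin_ms * 1e-3
    for i in np.flatnonzero(counts):
        times.append(t_edges[i] + rng.uniform(0, acq.bin_ms * 1e-3, counts[i]))
    all_times = np.concatenate(times) if times else np.empty(0)
    trace = _to_trace(all_times, duration, 0, 0.0)
    manifest = {
        "mode": "continuous", "seed": acq.seed,
        "scan_speed_um_s": acq.scan_speed_um_s,
        "crossing_boundaries": [list(b) for b in bounds],
        "expected_intensity_photons_ms": intensity_ms.tolist(),
        "coordinates_um": coords.tolist(),
        "duration_s": duration,
    }
    return trace, manifest


def generate_oligomer_bursts(i_monomer: float, sigma_monomer: float,
                             abundances: np.ndarray, n_bursts: int, seed: int,
                             skew_shape: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Sample burst normalized intensities from the oligomer brightness model.

    Monomers draw from a skew-normal with mean ``i_monomer`` and sd
    ``sigma_monomer`` (shape ``skew_shape`` reflecting the undersampling skew
    at short burst durations); n-mers draw from Normal(n * i_monomer,
    sigma_monomer). Species counts are multinomial in ``abundances``.

    Returns (intensities, species_index) with species_index 0 = monomer.
    """
    from .oligomers import skewnorm_params_from_moments

    abundances = np.asarray(abundances, dtype=float)
    if abs(abundances.sum() - 1.0) > 1e-9 or np.any(abundances < 0):
        raise InvalidParameterError("abundances must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_bursts, abundances)
    xi, omega, alpha = skewnorm_params_from_moments(i_monomer, sigma_monomer, skew_shape)
    chunks, labels = [], []
    for s, n in enumerate(counts):
        if n == 0:
            continue
        if s == 0:
            # skew-normal draw: xi + omega * (delta*|z0| + sqrt(1-delta^2)*z1)
            delta = alpha / math.sqrt(1 + alpha**2)
            z0 = np.abs(rng.standard_normal(n))
            z1 = rng.standard_normal(n)
            x = xi + omega * (delta * z0 + math.sqrt(1 - delta**2) * z1)
        else:
            x = rng.normal((s + 1) * i_monomer, sigma_monomer, n)
        chunks.append(x)
        labels.append(np.full(n, s))
    intensities = np.concatenate(chunks)
    labels = np.concatenate(labels)
    order = rng.permutation(intensities.size)
    return intensities[order], labels[order]


def generate_cluster_positions(
    d_m2_s: float,
    times_s: np.ndarray,
    n_events_per_crossing: int,
    seed: int,
    initial_sigma_um: float = 9.0,
    geom: ChipGeometry | None = None,
    gap_um: float = DEFAULT_GAP_UM,
) -> tuple[np.ndarray, list[tuple[float, float]], dict]:
    """Sample cluster detection coordinates for each crossing.

    The event cloud at residence time t is Gaussian about the crossing
    center. Its spreading is defined in the half-FWHM distance convention
    used by the Fick analysis (x = FWHM/2, x_net = sqrt(2 D t)), i.e. the
    sampling sigma grows as sigma^2 = sigma0^2 + 2 D t / (2 ln 2).
    """
    geom = geom or ChipGeometry()
    rng = np.random.default_rng(seed)
    bounds = scan_layout(geom, len(times_s), gap_um)
    positions = []
    sigmas = []
    for k, t in enumerate(times_s):
        sigma_um = math.sqrt(initial_sigma_um**2 + 2.0 * d_m2_s * t / (2.0 * math.log(2)) * 1e12)
        sigmas.append(sigma_um)
        center = 0.5 * (bounds[k][0] + bounds[k][1])
        positions.append(rng.normal(center, sigma_um, n_events_per_crossing))
    manifest = {"d_m2_s": d_m2_s, "times_s": list(map(float, times_s)),
                "initial_sigma_um": initial_sigma_um, "sigmas_um": sigmas,
                "n_events_per_crossing": n_events_per_crossing, "seed": seed}
    return np.concatenate(positions), bounds, manifest


def generate_spike_traces(
    bulk_rate_khz: np.ndarray,
    spike_expect: np.ndarray,
    dwell_s: float,
    seed: int,
    spike_amp_khz: float = 600.0,
    spike_duration_ms: int = 5,
    bin_ms: float = 1.0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-position binned intensity traces: Poissonian bulk + rare bright spikes.

    Emulates a step scan over a mixture of an abundant small species (bulk
    signal, mean rate ``bulk_rate_khz[j]``) and rare large assemblies
    (``spike_expect[j]`` expected spike events of amplitude ``spike_amp_khz``
    lasting ``spike_duration_ms``). Returns (traces, true_spike_counts);
    traces are photon counts per bin.
    """
    rng = np.random.default_rng(seed)
    n_bins = int(round(dwell_s / (bin_ms * 1e-3)))
    traces = []
    true_counts = np.zeros(len(bulk_rate_khz), dtype=int)
    for j, rate in enumerate(bulk_rate_khz):
        counts = rng.poisson(rate * bin_ms, n_bins).astype(float)
        n_spikes = rng.poisson(spike_expect[j])
        true_counts[j] = n_spikes
        for _ in range(n_spikes):
            i0 = rng.integers(0, max(n_bins - spike_duration_ms, 1))
            counts[i0:i0 + spike_duration_ms] += rng.poisson(
                spike_amp_khz * bin_ms, spike_duration_ms)
        traces.append(counts)
    return traces, true_counts
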