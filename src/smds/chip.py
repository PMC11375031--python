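"""Chip geometry, flow model, and the advection-diffusion basis solver.

The sizing chip flow-focuses a sample stream between two buffer streams in a
rectangular observation channel (default 25 um high x 225 um wide, sample
drawn at a ~1:8 sample:buffer volume ratio so the inlet stream occupies 1/9
of the width). As the stream travels downstream under laminar flow, species
spread transversely by Brownian diffusion; the spreading observed at several
channel crossings encodes the diffusion coefficient.

The solver integrates the steady-state advection-diffusion equation

    u(y, z) dc/dx = D (d2c/dy2 + d2c/dz2)

as a marching problem in the downstream coordinate, with the rectangular-duct
Poiseuille velocity field u(y, z). Substituting x = v_mean * t (t the mean
residence time) turns this into a pseudo-time diffusion problem with a
spatially varying mobility D * v_mean / u(y, z), discretized on a cell-centered
(y, z) cross-section grid with zero-flux walls and marched with
Crank-Nicolson steps (Rannacher start-up to damp the inlet top-hat).
A cheaper depth-averaged mode (uniform plug velocity, 1-D in y) is available
and flagged in metadata.

The output of :func:`simulate_basis` is a :class:`BasisLibrary`: for every
hydrodynamic radius on a grid, the unit-area normalized mid-height transverse
concentration profile at each scanned crossing. These simulated profiles are
the calibration-free reference against which measured diffusion profiles are
least-squares fitted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter1d
from scipy.sparse.linalg import splu

from . import physics
from .exceptions import InvalidParameterError, OutOfRangeError, SolverConfigError

#: Residence times (s) of the four scanned channel crossings at the
#: configured flow. Absolute downstream distances are chip-folding dependent
#: and remain user configuration; times parameterize the solver directly.
DEFAULT_CROSSING_TIMES_S = (0.0, 10.0, 26.0, 55.0)


@dataclass(frozen=True)
class ChipGeometry:
    """Observation-channel geometry of the sizing chip (lengths in um)."""

    channel_height_um: float = 25.0
    observation_width_um: float = 225.0
    channel_length_um: float = 90_000.0
    sample_flow_fraction: float = 1.0 / 9.0

    def __post_init__(self) -> None:
        for name in ("channel_height_um", "observation_width_um", "channel_length_um"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not 0 < self.sample_flow_fraction < 1:
            raise InvalidParameterError("sample_flow_fraction must be in (0, 1)")

    @property
    def cross_section_m2(self) -> float:
        return self.channel_height_um * self.observation_width_um * 1e-12


@dataclass(frozen=True)
class FlowSettings:
    """Volumetric flow through the observation channel."""

    total_flow_rate_ul_h: float = 100.0

    def __post_init__(self) -> None:
        if not self.total_flow_rate_ul_h > 0:
            raise InvalidParameterError("total_flow_rate_ul_h must be > 0")

    @property
    def flow_rate_m3_s(self) -> float:
        return self.total_flow_rate_ul_h * 1e-9 / 3600.0


def mean_velocity(geom: ChipGeometry, flow: FlowSettings) -> float:
    """Plug-flow mean velocity Q / (height * width), in m/s."""
    return flow.flow_rate_m3_s / geom.cross_section_m2


def residence_time(geom: ChipGeometry, flow: FlowSettings, distance_um: float) -> float:
    """Mean residence time (s) to reach ``distance_um`` downstream of the nozzle."""
    if not 0 <= distance_um <= geom.channel_length_um:
        raise InvalidParameterError(
            f"distance {distance_um} um outside [0, {geom.channel_length_um}] um"
        )
    return distance_um * 1e-6 / mean_velocity(geom, flow)


@dataclass(frozen=True)
class SolverOptions:
    """Discretization settings for the basis solver.

    n_transverse/n_depth are cell counts across the width/height;
    cell-centered so no node sits on a wall (the duct velocity vanishes
    there). The marching step count per inter-crossing segment is chosen so
    the diffusion length added per step stays below two transverse cells,
    clamped to [min_steps, max_steps]; Crank-Nicolson with two implicit-Euler
    start-up steps keeps the top-hat inlet stable.
    """

    n_transverse: int = 151
    n_depth: int = 31
    n_velocity_terms: int = 11  # odd terms of the duct Poiseuille series
    spot_waist_um: float = 0.3  # lateral 1/e^2-like Gaussian waist of the confocal spot
    depth_averaged: bool = False
    min_steps: int = 12
    max_steps: int = 200

    def __post_init__(self) -> None:
        if self.n_transverse < 11 or self.n_depth < 1:
            raise SolverConfigError(
                f"grid too coarse: n_transverse={self.n_transverse}, n_depth={self.n_depth}"
            )
        if self.n_velocity_terms < 11 and not self.depth_averaged:
            raise SolverConfigError(
                "duct velocity series needs >= 11 odd terms for the 9:1 aspect ratio"
            )
        if self.min_steps < 2 or self.max_steps < self.min_steps:
            raise SolverConfigError("need max_steps >= min_steps >= 2")


def duct_velocity(y_m: np.ndarray, z_m: np.ndarray, height_m: float, width_m: float,
                  n_terms: int = 11) -> np.ndarray:
    """Rectangular-duct Poiseuille profile (unnormalized) on a (z, y) grid.

    Series solution for pressure-driven flow in a duct, truncated at
    ``n_terms`` odd harmonics; y runs across the width (centered on 0),
    z across the height (0..H). Evaluated with overflow-safe cosh ratios.
    """
    u = np.zeros((z_m.size, y_m.size))
    for k in range(n_terms):
        n = 2 * k + 1
        a = n * math.pi * np.abs(y_m) / height_m
        b = n * math.pi * width_m / (2.0 * height_m)
        # cosh(a)/cosh(b) for a <= b without overflow
        ratio = np.exp(a - b) * (1.0 + np.exp(-2.0 * a)) / (1.0 + math.exp(-2.0 * b))
        u += (1.0 / n**3) * np.outer(np.sin(n * math.pi * z_m / height_m), 1.0 - ratio)
    return u


@dataclass
class BasisLibrary:
    """Simulated diffusion profiles on a hydrodynamic-radius grid.

    Attributes
    ----------
    rh_nm : array, shape (n_rh,)
        Sorted hydrodynamic radii (nm) of the simulated species.
    transverse_um : array, shape (n_y,)
        Cell-center transverse coordinates across the channel width (um).
    crossing_times_s : array, shape (n_cross,)
        Residence times of the scanned crossings.
    profiles : array, shape (n_rh, n_cross, n_y)
        Unit-area normalized mid-height concentration profiles
        (integral over transverse_um equals 1 for every row).
    metadata : dict
        Geometry, flow, conditions and solver settings sufficient to
        regenerate the library bit-for-bit.
    """

    rh_nm: np.ndarray
    transverse_um: np.ndarray
    crossing_times_s: np.ndarray
    profiles: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_crossings(self) -> int:
        return len(self.crossing_times_s)

    @property
    def width_um(self) -> float:
        return float(self.metadata.get("geometry", {}).get(
            "observation_width_um",
            self.transverse_um[-1] + self.transverse_um[0]))

    def profile_variances_um2(self) -> np.ndarray:
        """Second central moment (um^2) of every (r_h, crossing) profile."""
        y = self.transverse_um
        dy = y[1] - y[0]
        p = self.profiles * dy  # per-cell probability mass
        mean = (p * y).sum(axis=-1)
        return (p * (y[None, None, :] - mean[..., None]) ** 2).sum(axis=-1)

    def interpolate(self, r_h_nm: float) -> np.ndarray:
        """Profiles at an off-grid radius by log-radius linear interpolation.

        Exact at grid nodes; interpolants are renormalized to unit area.
        """
        grid = self.rh_nm
        if not grid[0] <= r_h_nm <= grid[-1]:
            raise OutOfRangeError(
                f"r_h={r_h_nm} nm outside basis grid [{grid[0]}, {grid[-1]}] nm"
            )
        i = int(np.searchsorted(grid, r_h_nm, side="right") - 1)
        if i == len(grid) - 1 or grid[i] == r_h_nm:
            return self.profiles[i].copy()
        w = (math.log(r_h_nm) - math.log(grid[i])) / (math.log(grid[i + 1]) - math.log(grid[i]))
        prof = (1.0 - w) * self.profiles[i] + w * self.profiles[i + 1]
        dy = self.transverse_um[1] - self.transverse_um[0]
        area = prof.sum(axis=-1, keepdims=True) * dy
        return prof / area

    def save(self, path: str | Path) -> None:
        """Write the library as CSV matrices + a JSON metadata sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "rh_nm.csv", self.rh_nm, delimiter=",")
        np.savetxt(path / "transverse_um.csv", self.transverse_um, delimiter=",")
        np.savetxt(path / "crossing_times_s.csv", self.crossing_times_s, delimiter=",")
        flat = self.profiles.reshape(len(self.rh_nm) * self.n_crossings, -1)
        np.savetxt(path / "profiles.csv", flat, delimiter=",")
        (path / "metadata.json").write_text(json.dumps(self.metadata, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "BasisLibrary":
        path = Path(path)
        rh = np.atleast_1d(np.loadtxt(path / "rh_nm.csv", delimiter=","))
        y = np.loadtxt(path / "transverse_um.csv", delimiter=",")
        t = np.atleast_1d(np.loadtxt(path / "crossing_times_s.csv", delimiter=","))
        flat = np.atleast_2d(np.loadtxt(path / "profiles.csv", delimiter=","))
        profiles = flat.reshape(len(rh), len(t), len(y))
        metadata = json.loads((path / "metadata.json").read_text())
        return cls(rh_nm=rh, transverse_um=y, crossing_times_s=t,
                   profiles=profiles, metadata=metadata)


def default_rh_grid(n: int = 60, lo_nm: float = 0.3, hi_nm: float = 300.0) -> np.ndarray:
    """Log-spaced radius grid spanning sub-nm dyes to >100 nm assemblies."""
    return np.geomspace(lo_nm, hi_nm, n)


def _neumann_laplacian_1d(n: int, h: float) -> sparse.csr_matrix:
    # conservative zero-flux Laplacian on a cell-centered grid
    main = -2.0 * np.ones(n)
    main[0] = main[-1] = -1.0
    off = np.ones(n - 1)
    return sparse.diags([off, main, off], [-1, 0, 1], format="csr") / h**2


def _inlet_tophat(y_um: np.ndarray, width_um: float, fraction: float) -> np.ndarray:
    """Centered top-hat occupying ``fraction`` of the width; fractional cell fill."""
    dy = y_um[1] - y_um[0]
    half = 0.5 * fraction * width_um
    center = 0.5 * width_um
    lo, hi = center - half, center + half
    left = np.clip((y_um + dy / 2 - lo) / dy, 0.0, 1.0)
    right = np.clip((hi - (y_um - dy / 2)) / dy, 0.0, 1.0)
    return np.minimum(left, right)


def simulate_basis(
    geom: ChipGeometry,
    flow: FlowSettings,
    cond: physics.SolventConditions,
    rh_grid_nm: np.ndarray,
    opts: SolverOptions | None = None,
    crossing_times_s: tuple[float, ...] | np.ndarray = DEFAULT_CROSSING_TIMES_S,
) -> BasisLibrary:
    """Simulate mid-height diffusion profiles for every radius on a grid.

    Parameters
    ----------
    rh_grid_nm : array
        Positive, strictly increasing hydrodynamic radii (nm).
    crossing_times_s : sequence
        Residence times of the scanned crossings, nondecreasing, first 0.

    Returns
    -------
    BasisLibrary
        Unit-area normalized profiles, one per (radius, crossing), plus
        metadata recording geometry/flow/conditions/solver settings and the
        worst relative drift of the conserved u-weighted mass flux.
    """
    opts = opts or SolverOptions()
    rh_grid_nm = np.asarray(rh_grid_nm, dtype=float)
    if rh_grid_nm.ndim != 1 or len(rh_grid_nm) < 1:
        raise InvalidParameterError("rh_grid_nm must be a 1-D array")
    if np.any(rh_grid_nm <= 0) or np.any(np.diff(rh_grid_nm) <= 0):
        raise InvalidParameterError("rh_grid_nm must be positive and strictly increasing")
    times = np.asarray(crossing_times_s, dtype=float)
    if times[0] != 0 or np.any(np.diff(times) < 0):
        raise InvalidParameterError("crossing times must be nondecreasing with first = 0")

    W = geom.observation_width_um * 1e-6
    H = geom.channel_height_um * 1e-6
    ny = opts.n_transverse
    nz = 1 if opts.depth_averaged else opts.n_depth
    dy = W / ny
    dz = H / nz
    y = (np.arange(ny) + 0.5) * dy  # cell centers, 0..W
    z = (np.arange(nz) + 0.5) * dz

    v_mean = mean_velocity(geom, flow)
    if opts.depth_averaged:
        u = np.full((nz, ny), v_mean)
    else:
        u = duct_velocity(y - W / 2, z, H, W, opts.n_velocity_terms)
        u *= flow.flow_rate_m3_s / (u.sum() * dy * dz)  # normalize to the set flow rate

    # pseudo-time mobility: dc/dt = kappa * laplacian(c), kappa = D * v_mean / u
    mobility_shape = (v_mean / u).ravel()

    Ly = _neumann_laplacian_1d(ny, dy)
    if nz > 1:
        Lz = _neumann_laplacian_1d(nz, dz)
        L = sparse.kron(sparse.identity(nz), Ly) + sparse.kron(Lz, sparse.identity(ny))
    else:
        L = Ly
    L = L.tocsr()

    c0 = np.tile(_inlet_tophat(y * 1e6, geom.observation_width_um, geom.sample_flow_fraction),
                 nz)
    u_flat = u.ravel()
    mid_iz = nz // 2
    mid_slice = slice(mid_iz * ny, (mid_iz + 1) * ny)
    waist_cells = opts.spot_waist_um / (dy * 1e6)

    def readout(c: np.ndarray) -> np.ndarray:
        prof = c[mid_slice].copy()
        if waist_cells > 1e-3:
            prof = gaussian_filter1d(prof, sigma=waist_cells, mode="nearest")
        area = prof.sum() * (dy * 1e6)
        if area <= 0:
            raise SolverConfigError("solver produced a non-positive profile area")
        return prof / area

    profiles = np.empty((len(rh_grid_nm), len(times), ny))
    flux_drift = 0.0
    for ir, r_nm in enumerate(rh_grid_nm):
        D = physics.diffusion_coefficient(r_nm * 1e-9, cond)
        kappa = D * mobility_shape  # m^2/s per cell
        KL = sparse.diags(kappa) @ L
        c = c0.copy()
        flux0 = float(u_flat @ c)
        profiles[ir, 0] = readout(c)
        first_segment = True
        for k in range(1, len(times)):
            dt_seg = times[k] - times[k - 1]
            if dt_seg == 0:
                profiles[ir, k] = profiles[ir, k - 1]
                continue
            n_steps = int(np.clip(math.ceil(D * dt_seg / (2.0 * dy * dy)),
                                  opts.min_steps, opts.max_steps))
            h = dt_seg / n_steps
            ident = sparse.identity(KL.shape[0], format="csr")
            lu_cn = splu((ident - 0.5 * h * KL).tocsc())
            B_cn = (ident + 0.5 * h * KL).tocsr()
            lu_be = splu((ident - h * KL).tocsc()) if first_segment else None
            for step in range(n_steps):
                if first_segment and step < 2:
                    c = lu_be.solve(c)  # Rannacher damping of the top-hat edges
                else:
                    c = lu_cn.solve(B_cn @ c)
            first_segment = False
            if not np.all(np.isfinite(c)):
                raise SolverConfigError(
                    f"marching diverged at r_h={r_nm} nm, segment {k} (step {h:.3g} s)"
                )
            profiles[ir, k] = readout(c)
        flux_drift = max(flux_drift, abs(float(u_flat @ c) - flux0) / flux0)

    metadata = {
        "geometry": {
            "channel_height_um": geom.channel_height_um,
            "observation_width_um": geom.observation_width_um,
            "channel_length_um": geom.channel_length_um,
            "sample_flow_fraction": geom.sample_flow_fraction,
        },
        "flow": {"total_flow_rate_ul_h": flow.total_flow_rate_ul_h},
        "conditions": {"temperature_K": cond.temperature, "viscosity_Pa_s": cond.viscosity},
        "solver": {
            "n_transverse": opts.n_transverse,
            "n_depth": opts.n_depth,
            "n_velocity_terms": opts.n_velocity_terms,
            "spot_waist_um": opts.spot_waist_um,
            "depth_averaged": opts.depth_averaged,
            "min_steps": opts.min_steps,
            "max_steps": opts.max_steps,
            "scheme": "crank-nicolson residence-time marching, rannacher start",
        },
        "crossing_times_s": [float(t) for t in times],
        "max_flux_drift_rel": flux_drift,
    }
    return BasisLibrary(rh_nm=rh_grid_nm.copy(), transverse_um=y * 1e6,
                        crossing_times_s=times, profiles=profiles, metadata=metadata)


def interpolate_profile(basis: BasisLibrary, r_h_nm: float) -> np.ndarray:
    """Continuous-in-radius profile set; see :meth:`BasisLibrary.interpolate`."""
    return basis.interpolate(r_h_nm)
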