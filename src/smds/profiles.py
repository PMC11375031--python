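"""Build diffusion profiles from scans.

Continuous mode: the confocal spot moves at constant speed; photon counts in
fixed time bins map to intensity (photons/ms) versus scan coordinate.

Step mode: the spot parks at discrete positions; single-molecule bursts are
counted per position, so the profile is a digital molecule count versus
coordinate.

Coordinates are continuous micrometres along the scan axis; the four scanned
channel crossings are demarcated by configured boundary ranges (the PDMS
walls between crossings carry no signal and are excluded from fitting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bursts import BurstSearchParams, PhotonTrace, find_bursts
from .exceptions import InvalidInputError, InvalidParameterError


@dataclass
class DiffusionProfile:
    """Signal versus transverse scan coordinate across the scanned crossings."""

    coordinates_um: np.ndarray
    values: np.ndarray
    mode: str  # "continuous" | "step"
    crossing_boundaries: list[tuple[float, float]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates_um, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if c.size != v.size or c.size == 0:
            raise InvalidInputError("coordinates and values must be same nonzero length")
        if np.any(np.diff(c) <= 0):
            raise InvalidInputError("coordinates must be strictly increasing")
        if np.any(v < 0):
            raise InvalidInputError("profile values must be >= 0")
        if self.mode not in ("continuous", "step"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        self.coordinates_um = c
        self.values = v

    def crossing_index(self) -> np.ndarray:
        """Crossing index per point; -1 for points on inter-channel walls."""
        idx = np.full(self.coordinates_um.size, -1, dtype=int)
        for k, (lo, hi) in enumerate(self.crossing_boundaries):
            idx[(self.coordinates_um >= lo) & (self.coordinates_um <= hi)] = k
        return idx

    def transverse_position_um(self, channel_width_um: float) -> np.ndarray:
        """Map each in-crossing coordinate onto the channel-transverse axis [0, W]."""
        pos = np.full(self.coordinates_um.size, np.nan)
        for lo, hi in self.crossing_boundaries:
            m = (self.coordinates_um >= lo) & (self.coordinates_um <= hi)
            pos[m] = (self.coordinates_um[m] - lo) / (hi - lo) * channel_width_um
        return pos

    @property
    def total(self) -> float:
        return float(self.values.sum())


def profile_from_continuous(
    trace: PhotonTrace,
    scan_speed_um_s: float,
    bin_ms: float,
    crossing_boundaries: list[tuple[float, float]],
    scan_start_um: float = 0.0,
    scan_length_um: float | None = None,
) -> DiffusionProfile:
    """Intensity profile from a constant-speed scan.

    Photons are binned in ``bin_ms`` intervals; each bin maps to the
    coordinate swept at its midpoint time, and values are photons per ms.
    """
    if not scan_speed_um_s > 0 or not bin_ms > 0:
        raise InvalidParameterError("scan speed and bin must be > 0")
    if scan_length_um is not None:
        if scan_speed_um_s * trace.duration_s > scan_length_um * (1 + 1e-9):
            raise InvalidInputError(
                "scan trajectory shorter than trace: "
                f"{scan_speed_um_s * trace.duration_s:.1f} um needed, "
                f"{scan_length_um:.1f} um available"
            )
    from .bursts import TICK_S

    t_s = trace.timestamps_ticks * TICK_S
    n_bins = int(np.ceil(trace.duration_s / (bin_ms * 1e-3)))
    counts, _ = np.histogram(t_s, bins=n_bins, range=(0.0, n_bins * bin_ms * 1e-3))
    mid_t = (np.arange(n_bins) + 0.5) * bin_ms * 1e-3
    coords = scan_start_um + scan_speed_um_s * mid_t
    return DiffusionProfile(coords, counts / bin_ms, "continuous", list(crossing_boundaries),
                            metadata={"scan_speed_um_s": scan_speed_um_s, "bin_ms": bin_ms,
                                      "scan_start_um": scan_start_um})


def profile_from_step(
    traces: list[PhotonTrace],
    params: BurstSearchParams | None = None,
    crossing_boundaries: list[tuple[float, float]] | None = None,
) -> DiffusionProfile:
    """Molecule-count profile from parked-spot traces.

    Values are burst counts per position; if dwell times differ between
    positions, counts are normalized to counts per second (otherwise raw
    integer counts are kept so Poisson-weighted fitting stays exact).
    """
    if len(traces) < 2:
        raise InvalidInputError("step profile needs >= 2 positions")
    order = np.argsort([tr.transverse_um for tr in traces])
    traces = [traces[i] for i in order]
    coords = np.array([tr.transverse_um for tr in traces])
    if np.any(np.diff(coords) <= 0):
        raise InvalidInputError("step positions must have distinct transverse coordinates")
    counts = np.array([len(find_bursts(tr, params)) for tr in traces], dtype=float)
    dwells = np.array([tr.duration_s for tr in traces])
    normalized = not np.allclose(dwells, dwells[0])
    values = counts / dwells if normalized else counts
    if crossing_boundaries is None:
        crossing_boundaries = [(float(coords[0]), float(coords[-1]))]
    return DiffusionProfile(coords, values, "step", list(crossing_boundaries),
                            metadata={"dwell_normalized": normalized,
                                      "dwell_s": dwells.tolist(),
                                      "burst_params": None if params is None else vars(params)})


def rebin_profile(profile: DiffusionProfile, factor: int) -> DiffusionProfile:
    """Coarsen a profile by an integer factor.

    Step mode sums counts (total conserved exactly, trailing partial group
    kept); continuous mode averages intensities.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise InvalidParameterError("factor must be an integer >= 1")
    n = profile.values.size
    if factor > n:
        raise InvalidParameterError(f"factor {factor} exceeds profile length {n}")
    if factor == 1:
        return DiffusionProfile(profile.coordinates_um.copy(), profile.values.copy(),
                                profile.mode, list(profile.crossing_boundaries),
                                dict(profile.metadata))
    edges = np.arange(0, n, factor)
    coords = np.array([profile.coordinates_um[s:s + factor].mean() for s in edges])
    if profile.mode == "step":
        values = np.array([profile.values[s:s + factor].sum() for s in edges])
    else:
        values = np.array([profile.values[s:s + factor].mean() for s in edges])
    meta = dict(profile.metadata)
    meta["rebin_factor"] = meta.get("rebin_factor", 1) * factor
    return DiffusionProfile(coords, values, profile.mode,
                            list(profile.crossing_boundaries), meta)
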