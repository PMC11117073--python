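"""Core data records exchanged between the simulator and the analysis stages.

All times are seconds, all lengths and coordinates are micrometres (µm),
and fluorescence intensities are in arbitrary units. A ``FilamentTrack`` is
the unit of kinetic analysis: the length of one actin filament sampled on a
uniform frame grid. ``DwellRecord``, ``IntensityTrace`` and ``SpotSet``
carry the single-molecule readouts (plus-end dwell times, photobleaching
traces and per-channel spot coordinates, respectively).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Actin's linear subunit density: subunits per micrometre of filament.
SUBUNITS_PER_MICRON = 370.0

#: Plus-end states recognised by the simulator and the analysis stages.
END_STATES = (
    "free",
    "formin",
    "formin_pfn1",
    "cp_capped",
    "decision_complex",
    "iqgap1_paused",
)

#: States in which the plus end adds no subunits.
NON_GROWING_STATES = frozenset({"cp_capped", "decision_complex", "iqgap1_paused"})

#: States whose residence time is drawn from a (truncated) Gaussian rather
#: than the exponential clock of the jump process.
PAUSE_STATES = frozenset({"iqgap1_paused"})


@dataclass
class FilamentTrack:
    """Length of one filament over time, sampled at a fixed frame interval."""

    filament_id: int
    fov_id: int
    times: np.ndarray
    lengths: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.times.size < 2:
            raise ConfigurationError("FilamentTrack needs at least 2 samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ConfigurationError("FilamentTrack times must strictly increase")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
            raise ConfigurationError("FilamentTrack times must be uniformly spaced")
        if np.any(self.lengths < 0):
            raise ConfigurationError("FilamentTrack lengths must be non-negative")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class EndStateEvent:
    """Ground-truth interval during which a filament's plus end occupies one state."""

    filament_id: int
    state: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class IntensityTrace:
    """Integrated fluorescence of one surface-adsorbed molecule over time."""

    molecule_id: int
    times: np.ndarray
    intensities: np.ndarray
    true_step_count: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not np.all(np.isfinite(self.intensities)):
            raise ConfigurationError("IntensityTrace intensities must be finite")


@dataclass(frozen=True)
class DwellRecord:
    """One end-bound molecule: species, bind/release times, censoring flag.

    For censored records (still bound when the movie ends) ``release_time``
    holds the censoring time, i.e. the last moment the molecule was seen
    bound.
    """

    molecule_id: int
    species: str
    bind_time: float
    release_time: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.censored and self.release_time <= self.bind_time:
            raise ConfigurationError(
                "uncensored DwellRecord must have release_time > bind_time"
            )

    @property
    def duration(self) -> float:
        return self.release_time - self.bind_time


@dataclass
class SpotSet:
    """2-D point coordinates of detected molecules in one channel of one FOV."""

    fov_id: int
    channel: str
    points: np.ndarray  # shape (n, 2), µm
    fov_extent: tuple[float, float]  # (width, height), µm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        w, h = self.fov_extent
        if self.points.size and (
            np.any(self.points < 0)
            or np.any(self.points[:, 0] > w)
            or np.any(self.points[:, 1] > h)
        ):
            raise ConfigurationError("SpotSet points must lie inside fov_extent")

    @property
    def n_spots(self) -> int:
        return int(self.points.shape[0])

    @property
    def area(self) -> float:
        return float(self.fov_extent[0] * self.fov_extent[1])


@dataclass(frozen=True)
class CompartmentSpec:
    """Geometry and composition of a cell compartment for molecule budgeting.

    ``dimensions`` are (x, y, z) in µm; species concentrations are mol/L;
    ``filament_density`` is filaments per µm² of the x·y footprint.
    """

    dimensions: tuple[float, float, float]
    species: tuple[tuple[str, float, int], ...] = field(default_factory=tuple)
    filament_density: float = 0.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dimensions):
            raise ConfigurationError("CompartmentSpec dimensions must be positive")
        for name, conc, size in self.species:
            if conc < 0:
                raise ConfigurationError(f"negative concentration for {name!r}")
            if size < 1:
                raise ConfigurationError(f"oligomer size for {name!r} must be >= 1")
        if self.filament_density < 0:
            raise ConfigurationError("filament_density must be non-negative")
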