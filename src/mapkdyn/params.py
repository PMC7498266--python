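"""Simulation parameter types and ground-truth records.

All spatial units are µm, time is minutes, angles are degrees, and the z
axis increases apically (0 = coverslip). KTR "ratio" values are the
dimensionless cytoplasm/nucleus intensity quotient of the ERK activity
reporter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

from mapkdyn.errors import ParameterError

#: FWHM of a Gaussian in units of its sigma.
FWHM_PER_SIGMA = 2.3548200450309493


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class PulseTrainParams:
    """Pulsatile ERK activity: Gaussian bumps at Poisson-thinned times.

    The experiment emulated is a monolayer imaged every ``frame_interval_min``
    minutes for ``duration_min`` minutes after induction at t = 0. Pulse
    timing is a homogeneous Poisson process of intensity ``mean_rate``
    (events per hour) thinned so consecutive kept events are at least
    ``refractory_min`` apart; each kept event contributes a symmetric
    Gaussian bump of height ``pulse_amplitude`` and full width at half
    maximum ``pulse_width_min``. Events are placed wholly inside the
    recording (one pulse width away from either end) so that every
    ground-truth peak is a well-defined in-window extremum.
    """

    duration_min: float = 360.0
    frame_interval_min: float = 5.0
    mean_rate: float = 2.0  # pulses per hour
    pulse_amplitude: float = 0.5
    pulse_width_min: float = 20.0  # FWHM
    baseline: float = 0.5
    noise_sd: float = 0.05
    refractory_min: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.duration_min > 0, "duration_min must be > 0")
        _require(self.frame_interval_min > 0, "frame_interval_min must be > 0")
        _require(
            self.pulse_width_min >= self.frame_interval_min,
            "pulse_width_min must be at least one frame interval",
        )
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.mean_rate >= 0, "mean_rate must be >= 0")
        _require(self.refractory_min >= 0, "refractory_min must be >= 0")
        _require(self.pulse_amplitude >= 0, "pulse_amplitude must be >= 0")

    @property
    def pulse_sigma_min(self) -> float:
        return self.pulse_width_min / FWHM_PER_SIGMA

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_min / self.frame_interval_min))


@dataclass(frozen=True)
class SustainedParams:
    """Sustained ERK activity: logistic step from baseline to plateau.

    The logistic is centred at ``onset_min + rise_time_min / 2`` with its
    10%-90% rise spanning ``rise_time_min``. ``loc_fold`` programs the
    nuclear accumulation of the tagged kinase (final/basal N/C ratio of
    the localization channel) that accompanies sustained activity.
    """

    onset_min: float = 60.0
    plateau: float = 1.5
    rise_time_min: float = 30.0
    baseline: float = 0.5
    noise_sd: float = 0.05
    duration_min: float = 360.0
    frame_interval_min: float = 5.0
    loc_fold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.duration_min > 0, "duration_min must be > 0")
        _require(self.frame_interval_min > 0, "frame_interval_min must be > 0")
        _require(self.plateau > self.baseline, "plateau must exceed baseline")
        _require(
            0 <= self.onset_min < self.duration_min,
            "onset_min must lie in [0, duration_min)",
        )
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.rise_time_min > 0, "rise_time_min must be > 0")
        _require(self.loc_fold > 0, "loc_fold must be > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_min / self.frame_interval_min))


@dataclass(frozen=True)
class MigrationSimParams:
    """Coculture migration geometry and kinematics.

    A fraction ``inducible_fraction`` of cells is placed as a compact group
    around ``center_xy`` (emulating an isolated group of oncogene-inducible
    cells); the remainder ("neighbors") are scattered uniformly over the
    field. Neighbor step headings follow a von Mises distribution about the
    direction to the group center with concentration ``bias_kappa``
    (0 = unbiased random walk), active from ``bias_start_min`` onward.
    ``speed_factor_after``/``speed_change_min`` optionally rescale step
    length from a given time, emulating oncogene-induced migration
    speed-ups.
    """

    n_cells: int = 100
    field_size_um: float = 400.0
    center_xy: tuple[float, float] = (200.0, 200.0)
    speed_um_per_frame: float = 1.0
    bias_kappa: float = 0.0
    frame_interval_min: float = 5.0
    n_frames: int = 72
    inducible_fraction: float = 0.1
    bias_start_min: float = 0.0
    speed_factor_after: float = 1.0
    speed_change_min: float | None = None
    cluster_sd_um: float = 15.0
    position_noise_sd_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cells >= 1, "n_cells must be >= 1")
        _require(self.bias_kappa >= 0, "bias_kappa must be >= 0")
        _require(
            0 <= self.inducible_fraction <= 1,
            "inducible_fraction must be in [0, 1]",
        )
        _require(self.speed_um_per_frame >= 0, "speed must be >= 0")
        _require(self.n_frames >= 1, "n_frames must be >= 1")
        _require(self.field_size_um > 0, "field_size_um must be > 0")
        _require(self.frame_interval_min > 0, "frame_interval_min must be > 0")


@dataclass(frozen=True)
class WaveParams:
    """Phenomenological paracrine activity wave.

    Neighboring cells receive a single activity pulse whose onset is delayed
    proportionally to their distance d from the inducible-group center:
    onset = ``trigger_min`` + d / ``speed_um_per_min``. Purely kinematic; no
    diffusion or receptor model is implied.
    """

    trigger_min: float = 60.0
    speed_um_per_min: float = 2.0
    pulse_amplitude: float = 0.5
    pulse_width_min: float = 20.0

    def __post_init__(self) -> None:
        _require(self.speed_um_per_min > 0, "wave speed must be > 0")
        _require(self.pulse_amplitude >= 0, "pulse_amplitude must be >= 0")


@dataclass(frozen=True)
class ZStackSimParams:
    """Two-channel confocal z-stack of nuclei in a monolayer.

    Channel 0 ("inducible") contains only the inducible nuclei, channel 1
    ("all") contains every nucleus — mirroring an H2B label expressed in the
    inducible subpopulation versus one expressed in all cells. Nuclei are
    rendered as 3-D Gaussian blobs; inducible nuclear z-centers are drawn
    from N(monolayer_z_mean + extrusion_offset, sd), all others from
    N(monolayer_z_mean, sd).
    """

    nx: int = 128
    ny: int = 128
    pixel_size_um: float = 0.65
    z_min_um: float = 0.0
    z_max_um: float = 25.0
    z_step_um: float = 1.0
    n_nuclei: int = 100
    inducible_fraction: float = 0.1
    monolayer_z_mean_um: float = 8.0
    monolayer_z_sd_um: float = 1.5
    extrusion_offset_um: float = 0.0
    nucleus_sigma_um: float = 2.5
    nucleus_sigma_xy_um: float = 3.5
    nucleus_amplitude: float = 1000.0
    intensity_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.z_step_um > 0, "z_step_um must be > 0")
        _require(self.extrusion_offset_um >= 0, "extrusion_offset_um must be >= 0")
        _require(self.z_max_um > self.z_min_um, "z_max_um must exceed z_min_um")
        _require(0 <= self.inducible_fraction <= 1, "inducible_fraction in [0,1]")
        _require(self.n_nuclei >= 1, "n_nuclei must be >= 1")
        _require(self.nx > 0 and self.ny > 0, "nx, ny must be > 0")
        _require(self.pixel_size_um > 0, "pixel_size_um must be > 0")
        _require(
            self.z_min_um
            <= self.monolayer_z_mean_um
            <= self.monolayer_z_mean_um + self.extrusion_offset_um
            <= self.z_max_um,
            "population z distributions must lie within [z_min, z_max]",
        )

    @property
    def z_grid_um(self):
        import numpy as np

        n = int(round((self.z_max_um - self.z_min_um) / self.z_step_um)) + 1
        return self.z_min_um + self.z_step_um * np.arange(n)


@dataclass
class GroundTruth:
    """Hidden parameters of a simulated dataset, for recovery tests.

    Every simulated entity (cell, position, protein) has exactly one
    ground-truth record; only the fields relevant to the generating module
    are populated.
    """

    peak_times_min: dict[str, list[float]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)
    onset_times_min: dict[str, float] = field(default_factory=dict)
    loc_folds: dict[str, float] = field(default_factory=dict)
    bias_kappa: float | None = None
    extrusion_offset_um: float | None = None
    nucleus_z_um: dict[str, float] = field(default_factory=dict)
    nucleus_xy_um: dict[str, list] = field(default_factory=dict)
    sphase_fractions: dict[str, float] = field(default_factory=dict)
    protein_lnfc: dict[str, float] = field(default_factory=dict)
    hit_proteins: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload: dict[str, Any] = json.load(fh)
        return cls(**payload)
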