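"""Colonic motility patterns, actuator calibration and motility indices.

The segmented-lumen colon model replicates peristalsis with ten hydraulically
actuated segments.  Wall motion is commanded through syringe drivers, so in
vivo wall parameters (occlusion degree OD, occlusion velocity OV, membrane
displacement MD) are related to actuator commands (syringe displacement SD,
syringe speed SS) through linear calibrations:

    MD = 0.3425 * SD + 0.7246        [mm]
    OD = 5.797  * SD - 44.03         [%]
    OV = 0.3172 * SS + 0.9221        [mm/s]

A motility pattern is a schedule of segment contraction events over one cycle
(120 s in the study protocol).  Two summary indices quantify contractile
intensity:

* ``MI``      -- the cine-MRI motility index: the cycle is split into K
  sub-intervals of duration t_iv and MI = sum_k t_iv * N_seg,k where N_seg,k
  counts segments whose contraction phase overlaps sub-interval k.
* ``MI_DCM``  -- a dimensionless variant weighting each counted segment by its
  occlusion velocity: MI_DCM = (1 / (omega * L)) * sum_k (v * N_seg)_k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .errors import (
    ConfigError,
    DegenerateCalibrationError,
    InvalidGeometryError,
    MalformedWaveError,
)

__all__ = [
    "CalibrationMap",
    "ContractionEvent",
    "MotilityPattern",
    "MotilityIndexConfig",
    "WaveSummary",
    "occlusion_degree_from_areas",
    "membrane_displacement",
    "occlusion_degree_from_syringe",
    "occlusion_velocity",
    "invert_calibration",
    "motility_index",
    "motility_index_dcm",
    "summarize_wave",
]

#: Relaxation-to-contraction speed ratio for propagating / stimulated events.
RELAXATION_RATIO_STIMULATED = 0.26
#: Relaxation-to-contraction speed ratio for baseline isolated contractions.
RELAXATION_RATIO_BASELINE = 0.91


@dataclass(frozen=True)
class CalibrationMap:
    """Linear actuator <-> wall transforms for the hydraulic segments.

    Slopes/intercepts default to the calibrations measured on the physical
    model (correlation coefficients 0.996-0.997).
    """

    md_slope: float = 0.3425      # dimensionless (mm membrane per mm syringe)
    md_intercept: float = 0.7246  # mm
    od_slope: float = 5.797       # % per mm
    od_intercept: float = -44.03  # %
    ov_slope: float = 0.3172      # dimensionless (mm/s per mm/s)
    ov_intercept: float = 0.9221  # mm/s

    def __post_init__(self):
        if not (self.md_slope > 0 and self.od_slope > 0 and self.ov_slope > 0):
            raise DegenerateCalibrationError("calibration slopes must be positive")


#: Calibrated syringe-displacement range in mm.
_SD_RANGE = (0.0, 28.0)
#: Syringe-displacement span over which the OD calibration matches the
#: occlusion degrees reported in vivo (warn outside).
_SD_OD_RANGE = (8.0, 25.0)
#: Calibrated syringe-speed range in mm/s.
_SS_RANGE = (0.0, 50.0)


def occlusion_degree_from_areas(a_x: float, a_n: float) -> float:
    """Occlusion degree (%) from luminal cross-sectional areas.

    ``a_x`` is the area at the central apex of the haustra in the current wall
    position, ``a_n`` the area at the neutral position.  Negative values
    indicate relaxation beyond neutral (area larger than neutral).
    """
    if a_n <= 0:
        raise InvalidGeometryError(f"neutral area must be positive, got {a_n!r}")
    if a_x < 0:
        raise InvalidGeometryError(f"luminal area cannot be negative, got {a_x!r}")
    return 100.0 * (1.0 - a_x / a_n)


def membrane_displacement(sd: float, cal: CalibrationMap | None = None) -> float:
    """Membrane displacement MD (mm) for a syringe displacement SD (mm)."""
    cal = cal or CalibrationMap()
    if not _SD_RANGE[0] <= sd <= _SD_RANGE[1]:
        warnings.warn(
            f"syringe displacement {sd} mm outside calibrated range {_SD_RANGE}",
            stacklevel=2,
        )
    return cal.md_slope * sd + cal.md_intercept


def occlusion_degree_from_syringe(sd: float, cal: CalibrationMap | None = None) -> float:
    """Occlusion degree OD (%) for a syringe displacement SD (mm)."""
    cal = cal or CalibrationMap()
    if not _SD_OD_RANGE[0] <= sd <= _SD_OD_RANGE[1]:
        warnings.warn(
            f"syringe displacement {sd} mm outside the span {_SD_OD_RANGE} where the"
            " OD calibration tracks occlusion degrees reported in vivo",
            stacklevel=2,
        )
    return cal.od_slope * sd + cal.od_intercept


def occlusion_velocity(ss: float, cal: CalibrationMap | None = None) -> float:
    """Occlusion velocity OV (mm/s) for a syringe speed SS (mm/s)."""
    cal = cal or CalibrationMap()
    if not _SS_RANGE[0] <= ss <= _SS_RANGE[1]:
        warnings.warn(
            f"syringe speed {ss} mm/s outside calibrated range {_SS_RANGE}",
            stacklevel=2,
        )
    return cal.ov_slope * ss + cal.ov_intercept

# The maximum operable syringe speed on the physical rig is 38 mm/s; commands
# above it are meaningful for the model, so out-of-range values warn rather
# than raise.


def invert_calibration(value: float, which: str, cal: CalibrationMap | None = None) -> float:
    """Actuator command for a wall parameter (exact inverse of the linear maps).

    ``which`` selects the transform: ``"md"`` (membrane displacement -> syringe
    displacement), ``"od"`` (occlusion degree -> syringe displacement) or
    ``"ov"`` (occlusion velocity -> syringe speed).

    Note: with the default coefficients an occlusion velocity of 36 mm/s maps
    to a syringe speed of 110.60 mm/s by exact inversion; the study protocol
    quotes 109.63 mm/s for the same conversion (consistent with a rounded
    slope).  This function always performs the exact inversion.
    """
    cal = cal or CalibrationMap()
    try:
        slope, intercept = {
            "md": (cal.md_slope, cal.md_intercept),
            "od": (cal.od_slope, cal.od_intercept),
            "ov": (cal.ov_slope, cal.ov_intercept),
        }[which]
    except KeyError:
        raise ValueError(f"unknown calibration {which!r}; expected 'md', 'od' or 'ov'")
    if slope == 0:
        raise DegenerateCalibrationError(f"{which} calibration has zero slope")
    return (value - intercept) / slope


@dataclass(frozen=True)
class ContractionEvent:
    """One segment contraction within a motility cycle.

    The contraction phase runs from ``start_time`` until the membrane reaches
    full displacement; its duration is membrane travel distance over occlusion
    velocity.  The wall then relaxes ``relaxation_speed_ratio`` times slower
    than it contracted.
    """

    segment_index: int                    # 1..n_segments, 1 = caecal end
    start_time: float                     # s within the cycle
    occlusion_degree: float               # %
    occlusion_velocity: float             # mm/s
    membrane_displacement: float          # mm
    relaxation_speed_ratio: float = RELAXATION_RATIO_STIMULATED
    kind: str = "isolated"                # "isolated" | "wave_member"
    wave_id: str | None = None
    direction: str = "none"               # "antegrade" | "retrograde" | "none"

    def __post_init__(self):
        if not 0 <= self.occlusion_degree <= 100:
            raise ValueError(f"occlusion degree {self.occlusion_degree} outside [0, 100]%")
        if self.occlusion_velocity <= 0:
            raise ValueError("occlusion velocity must be positive for a contraction event")
        if self.membrane_displacement <= 0:
            raise ValueError("membrane displacement must be positive for a contraction event")
        if not 0 < self.relaxation_speed_ratio <= 1:
            raise ValueError("relaxation speed ratio must lie in (0, 1]")
        if self.kind not in ("isolated", "wave_member"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.direction not in ("antegrade", "retrograde", "none"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def contraction_duration(self) -> float:
        """Duration of the contraction phase (s): membrane travel / velocity."""
        return self.membrane_displacement / self.occlusion_velocity

    @property
    def end_time(self) -> float:
        """Time at which the segment reaches full contraction (s)."""
        return self.start_time + self.contraction_duration

    @property
    def relaxation_duration(self) -> float:
        """Duration of the relaxation phase (s)."""
        return self.contraction_duration / self.relaxation_speed_ratio


@dataclass(frozen=True)
class MotilityPattern:
    """A named schedule of contraction events over one repeating cycle."""

    name: str
    events: tuple[ContractionEvent, ...] = ()
    cycle_period: float = 120.0           # s
    segment_length: float = 2.8           # cm
    n_segments: int = 10
    relaxation_occlusion_degree: float = -10.0  # % (outward displacement in waves)

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        if self.cycle_period <= 0:
            raise ValueError("cycle period must be positive")
        if self.n_segments < 1:
            raise ValueError("pattern needs at least one segment")
        for ev in self.events:
            if not 1 <= ev.segment_index <= self.n_segments:
                raise ValueError(
                    f"event segment {ev.segment_index} outside 1..{self.n_segments}"
                )
            if not 0 <= ev.start_time < self.cycle_period:
                raise ValueError(
                    f"event start {ev.start_time} s outside cycle [0, {self.cycle_period})"
                )

    @property
    def is_static(self) -> bool:
        return not self.events

    @property
    def tube_length_cm(self) -> float:
        return self.n_segments * self.segment_length

    def cycles_over(self, duration_h: float) -> int:
        """Number of whole cycles executed over ``duration_h`` hours."""
        return int(duration_h * 3600.0 / self.cycle_period)

    def wave_events(self, wave_id: str) -> tuple[ContractionEvent, ...]:
        return tuple(ev for ev in self.events if ev.wave_id == wave_id)

    @property
    def wave_ids(self) -> tuple[str, ...]:
        seen = []
        for ev in self.events:
            if ev.wave_id is not None and ev.wave_id not in seen:
                seen.append(ev.wave_id)
        return tuple(seen)

    def with_events(self, events) -> "MotilityPattern":
        return replace(self, events=tuple(events))


@dataclass(frozen=True)
class MotilityIndexConfig:
    """Sub-interval partition and normalisation constants for the indices.

    ``omega`` (1/s) and ``length`` (mm) only enter through their product,
    which makes MI_DCM dimensionless for velocities in mm/s.  The defaults
    (omega = 12 /s, length = 280 mm, i.e. the full tube length) are the pair
    under which the published stimulated-pattern index values are recovered;
    both are overridable.
    """

    t_iv: float = 20.0       # s, sub-interval duration
    k: int = 6               # number of sub-intervals
    omega: float = 12.0      # 1/s, normalisation frequency
    length: float = 280.0    # mm, normalisation length

    def __post_init__(self):
        if self.t_iv <= 0 or self.k < 1:
            raise ConfigError("need positive t_iv and at least one sub-interval")
        if not self.omega * self.length > 0:
            raise ConfigError("normalisation constants must satisfy omega * length > 0")

    def validate_for(self, pattern: MotilityPattern) -> None:
        if abs(self.k * self.t_iv - pattern.cycle_period) > 1e-9:
            raise ConfigError(
                f"K * t_iv = {self.k * self.t_iv} s does not partition the"
                f" {pattern.cycle_period} s cycle"
            )


def _interval_events(pattern: MotilityPattern, cfg: MotilityIndexConfig):
    """Events whose contraction phase overlaps each sub-interval.

    A segment counts in sub-interval k when its contraction phase
    [start, full occlusion) overlaps the interval with positive measure; a
    contraction spanning an interval boundary counts in both intervals.
    """
    cfg.validate_for(pattern)
    buckets: list[list[ContractionEvent]] = [[] for _ in range(cfg.k)]
    for ev in pattern.events:
        for i in range(cfg.k):
            lo, hi = i * cfg.t_iv, (i + 1) * cfg.t_iv
            if ev.start_time < hi and ev.end_time > lo:
                buckets[i].append(ev)
    return buckets


def motility_index(pattern: MotilityPattern, cfg: MotilityIndexConfig | None = None) -> float:
    """Classical motility index MI = sum_k t_iv * N_seg,k  (segment * s)."""
    cfg = cfg or MotilityIndexConfig()
    buckets = _interval_events(pattern, cfg)
    return cfg.t_iv * sum(len(b) for b in buckets)


def motility_index_dcm(pattern: MotilityPattern, cfg: MotilityIndexConfig | None = None) -> float:
    """Dimensionless motility index MI_DCM = (1/(omega*L)) * sum_k (v * N_seg)_k.

    Each counted segment contributes its own occlusion velocity (mm/s), which
    reduces to the (v * N_seg)_k form when all events in a sub-interval share
    one velocity, and generalises it when they do not.
    """
    cfg = cfg or MotilityIndexConfig()
    buckets = _interval_events(pattern, cfg)
    total = sum(ev.occlusion_velocity for b in buckets for ev in b)
    return total / (cfg.omega * cfg.length)


@dataclass(frozen=True)
class WaveSummary:
    """Propagation summary of one wave: distance, duration and velocity."""

    propagation_distance: float   # cm
    wave_velocity: float          # cm/s
    time_taken: float             # s
    n_segments_involved: int


def summarize_wave(pattern: MotilityPattern, wave_id: str) -> WaveSummary:
    """Summarise a propagating wave's travel distance, duration and velocity.

    Travel distance is from the start of the first contracting segment to the
    end of the last (n * segment length); time runs from the first contraction
    start to the moment the final segment reaches full contraction.
    """
    events = pattern.wave_events(wave_id)
    if len(events) < 2:
        raise MalformedWaveError(
            f"wave {wave_id!r} has {len(events)} member(s); a wave needs at least 2"
        )
    indices = sorted(ev.segment_index for ev in events)
    if indices != list(range(indices[0], indices[0] + len(indices))):
        raise MalformedWaveError(
            f"wave {wave_id!r} segments {indices} are not consecutive"
        )
    ordered = sorted(events, key=lambda ev: ev.start_time)
    time_taken = ordered[-1].end_time - ordered[0].start_time
    distance = len(events) * pattern.segment_length
    return WaveSummary(
        propagation_distance=distance,
        wave_velocity=distance / time_taken,
        time_taken=time_taken,
        n_segments_involved=len(events),
    )
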