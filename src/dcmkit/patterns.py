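"""The library of study motility patterns, plus YAML pattern IO.

Six patterns are packaged, named after the conditions they mimic:

* ``static``          -- zero-motility control.
* ``baseline``        -- resting healthy adult colon: one short propagating
  pressure wave (S2->S4) and four isolated contractions (S3, S6, S5, S8 in
  chronological order), all slow and shallow.
* ``cppw_antegrade`` / ``cppw_retrograde`` -- a cyclic propagating pressure
  wave travelling the full ten segments toward / away from the flexure.
* ``peg`` / ``maltose`` -- stimulated-colon patterns with multiple short
  antegrade and retrograde waves and isolated contractions at high occlusion
  degree and velocity.

Wave parameters (occlusion degree/velocity, membrane displacement, wave
velocity, propagation distance) are the published operating points of each
pattern.  Event start times within the 120 s cycle are not published as
numbers; the times used here are reconstructed so that the schedule is
consistent with the published per-pattern narratives, wave sizes and wave
velocities, and with the published motility-index values.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigError, MalformedWaveError
from .motility import (
    RELAXATION_RATIO_BASELINE,
    RELAXATION_RATIO_STIMULATED,
    ContractionEvent,
    MotilityPattern,
)

__all__ = ["STUDY_PATTERN_NAMES", "make_wave", "build_pattern", "load_pattern",
           "save_pattern", "pattern_to_dict", "pattern_from_dict"]

STUDY_PATTERN_NAMES = (
    "static",
    "baseline",
    "cppw_antegrade",
    "cppw_retrograde",
    "peg",
    "maltose",
)


def make_wave(
    wave_id: str,
    segments: list[int],
    start_time: float,
    occlusion_degree: float,
    occlusion_velocity: float,
    membrane_displacement: float,
    wave_velocity_cm_s: float,
    segment_length_cm: float = 2.8,
    relaxation_speed_ratio: float = RELAXATION_RATIO_STIMULATED,
    overrides: dict[int, dict] | None = None,
) -> list[ContractionEvent]:
    """Build the member events of one propagating wave.

    ``segments`` lists segment indices in propagation order (increasing for
    antegrade, decreasing for retrograde).  The wave's total travel time is
    fixed by its published velocity (distance / velocity, measured from the
    first contraction start to the last segment's full contraction), and the
    inter-segment stagger is derived from it.  ``overrides`` patches
    per-segment parameters (e.g. the shallower caecal segment of the full-tube
    wave).
    """
    n = len(segments)
    if n < 2:
        raise MalformedWaveError("a propagating wave needs at least two segments")
    steps = [segments[i + 1] - segments[i] for i in range(n - 1)]
    if all(s == 1 for s in steps):
        direction = "antegrade"
    elif all(s == -1 for s in steps):
        direction = "retrograde"
    else:
        raise MalformedWaveError(f"wave segments {segments} are not consecutive")

    overrides = overrides or {}

    def params(seg):
        p = {
            "occlusion_degree": occlusion_degree,
            "occlusion_velocity": occlusion_velocity,
            "membrane_displacement": membrane_displacement,
        }
        p.update(overrides.get(seg, {}))
        return p

    last = params(segments[-1])
    duration_last = last["membrane_displacement"] / last["occlusion_velocity"]
    total_time = n * segment_length_cm / wave_velocity_cm_s
    stagger = (total_time - duration_last) / (n - 1)
    if stagger <= 0:
        raise MalformedWaveError(
            f"wave velocity {wave_velocity_cm_s} cm/s is too fast for the"
            " contraction duration; segments would contract out of order"
        )
    return [
        ContractionEvent(
            segment_index=seg,
            start_time=start_time + i * stagger,
            relaxation_speed_ratio=relaxation_speed_ratio,
            kind="wave_member",
            wave_id=wave_id,
            direction=direction,
            **params(seg),
        )
        for i, seg in enumerate(segments)
    ]


def _isolated(seg, t, od, ov, md, ratio):
    return ContractionEvent(
        segment_index=seg,
        start_time=t,
        occlusion_degree=od,
        occlusion_velocity=ov,
        membrane_displacement=md,
        relaxation_speed_ratio=ratio,
        kind="isolated",
        direction="none",
    )


def _build_baseline() -> MotilityPattern:
    # Slow, shallow motility: PPW S2->S4 (OD 20%, wave velocity 0.37 cm/s)
    # plus isolated contractions at S3, S6, S5, S8 (OD 25%), all at 1.55 mm/s.
    events = make_wave(
        "ppw", [2, 3, 4], start_time=0.0,
        occlusion_degree=20.0, occlusion_velocity=1.55,
        membrane_displacement=4.51, wave_velocity_cm_s=0.37,
    )
    iso = [(3, 30.0), (6, 38.5), (5, 65.0), (8, 95.0)]
    events += [
        _isolated(s, t, 25.0, 1.55, 4.80, RELAXATION_RATIO_BASELINE) for s, t in iso
    ]
    return MotilityPattern(name="baseline", events=events)


# The first (caecal) segment of the full-tube wave occludes less than the rest.
_CPPW_S1 = {"occlusion_degree": 23.15, "membrane_displacement": 3.99}


def _build_cppw(direction: str) -> MotilityPattern:
    if direction == "antegrade":
        segments, velocity = list(range(1, 11)), 3.72
    else:
        segments, velocity = list(range(10, 0, -1)), 3.62
    events = make_wave(
        "cppw", segments, start_time=0.0,
        occlusion_degree=40.0, occlusion_velocity=10.80,
        membrane_displacement=7.12, wave_velocity_cm_s=velocity,
        overrides={1: _CPPW_S1},
    )
    return MotilityPattern(name=f"cppw_{direction}", events=events)


# Stimulated-pattern wave tables: (wave id, segments in order, OD %, MD mm,
# wave velocity cm/s, start time s).  Occlusion velocity is 12.98 mm/s for all
# stimulated events.
_PEG_WAVES = [
    ("a1", [3, 4, 5, 6],   75.0, 7.76, 4.25, 5.0),
    ("a2", [5, 6, 7],      55.0, 6.58, 5.05, 25.0),
    ("a3", [6, 7, 8],      50.0, 6.28, 5.26, 45.0),
    ("r1", [10, 9, 8, 7],  75.0, 7.76, 4.25, 65.0),
    ("r2", [9, 8, 7, 6],   50.0, 6.28, 5.14, 85.0),
]
_PEG_ISOLATED = [(2, 12.0), (2, 52.0), (2, 92.0), (2, 105.0)]

_MALTOSE_WAVES = [
    ("a1", [2, 3],         75.0, 7.76, 4.76, 5.0),
    ("a2", [3, 4, 5],      55.0, 6.58, 5.31, 25.0),
    ("a3", [4, 5, 6],      50.0, 6.28, 5.54, 45.0),
    ("r1", [10, 9, 8, 7],  75.0, 7.76, 6.09, 65.0),
    ("r2", [8, 7, 6],      50.0, 6.28, 5.54, 85.0),
]
_MALTOSE_ISOLATED = [(5, 12.0), (7, 52.0), (9, 92.0), (6, 105.0)]


def _build_stimulated(name, waves, isolated) -> MotilityPattern:
    events = []
    for wave_id, segments, od, md, velocity, t0 in waves:
        events += make_wave(
            wave_id, segments, start_time=t0,
            occlusion_degree=od, occlusion_velocity=12.98,
            membrane_displacement=md, wave_velocity_cm_s=velocity,
        )
    events += [
        _isolated(s, t, 60.0, 12.98, 6.87, RELAXATION_RATIO_STIMULATED)
        for s, t in isolated
    ]
    return MotilityPattern(name=name, events=events)


_BUILDERS = {
    "static": lambda: MotilityPattern(name="static"),
    "baseline": _build_baseline,
    "cppw_antegrade": lambda: _build_cppw("antegrade"),
    "cppw_retrograde": lambda: _build_cppw("retrograde"),
    "peg": lambda: _build_stimulated("peg", _PEG_WAVES, _PEG_ISOLATED),
    "maltose": lambda: _build_stimulated("maltose", _MALTOSE_WAVES, _MALTOSE_ISOLATED),
}


def build_pattern(name: str) -> MotilityPattern:
    """Construct one of the packaged study patterns by name."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise ConfigError(
            f"unknown pattern {name!r}; packaged patterns: {', '.join(STUDY_PATTERN_NAMES)}"
        )


# ---------------------------------------------------------------------------
# YAML serialisation

_EVENT_FIELDS = (
    "segment_index", "start_time", "occlusion_degree", "occlusion_velocity",
    "membrane_displacement", "relaxation_speed_ratio", "kind", "wave_id",
    "direction",
)


def pattern_to_dict(pattern: MotilityPattern) -> dict:
    return {
        "name": pattern.name,
        "cycle_period": pattern.cycle_period,
        "segment_length": pattern.segment_length,
        "n_segments": pattern.n_segments,
        "relaxation_occlusion_degree": pattern.relaxation_occlusion_degree,
        "events": [
            {f: getattr(ev, f) for f in _EVENT_FIELDS} for ev in pattern.events
        ],
    }


def pattern_from_dict(data: dict) -> MotilityPattern:
    try:
        events = [ContractionEvent(**ev) for ev in data.get("events", [])]
        return MotilityPattern(
            name=data["name"],
            events=events,
            cycle_period=data.get("cycle_period", 120.0),
            segment_length=data.get("segment_length", 2.8),
            n_segments=data.get("n_segments", 10),
            relaxation_occlusion_degree=data.get("relaxation_occlusion_degree", -10.0),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed pattern definition: {exc}") from exc


def save_pattern(pattern: MotilityPattern, path) -> None:
    Path(path).write_text(yaml.safe_dump(pattern_to_dict(pattern), sort_keys=False))


def load_pattern(name_or_path) -> MotilityPattern:
    """Load a pattern: a packaged name (e.g. ``"peg"``) or a YAML file path."""
    if isinstance(name_or_path, str) and name_or_path in _BUILDERS:
        return _BUILDERS[name_or_path]()
    path = Path(name_or_path)
    if not path.exists():
        raise ConfigError(
            f"{name_or_path!r} is neither a packaged pattern name nor an existing file"
        )
    return pattern_from_dict(yaml.safe_load(path.read_text()))
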