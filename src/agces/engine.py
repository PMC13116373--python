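"""AGCES staging engine.

Implements every published staging criterion for the three components and
combines them into the tripartite code. Each component function returns the
*maximum* stage among its fired criteria, so mixed presentations (e.g. one
small and one large focal lesion) are staged by the most severe criterion
that is satisfied, and Stage-IV supersession rules dominate the spot-count
bands by construction.

Interval convention
-------------------
The printed criteria use ranges like "> 20–30 mm" without endpoint
semantics. This engine fixes one reading, applied everywhere:

* ``"> a–b"`` is the half-open-above interval ``(a, b]``;
* ``"≤ a"`` closes at ``a``; ``"> a"`` opens at ``a``.

Hence a 20 mm wall is in the minimal band, a 30 mm unilateral endometrioma
is Stage III, 5 mm depth is superficial, and an 8 mm junctional zone is
Stage I. Adjacent printed ranges then partition without gap or overlap,
with two deliberate tie-breaks where the source bands leave a gap: a
diffuse-JZ extent of exactly 50% is assigned to Stage III and exactly 80%
to Stage IV (ties break toward higher severity, matching the system's
supersession philosophy). The full convention is exported as
:data:`INTERVAL_CONVENTION` so tests can assert it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import CaseValidationError, CodeParseError
from .model import (
    AdenomyosisFindings,
    AdhesionGrade,
    AgcesCode,
    CaseRecord,
    CuldesacObliteration,
    ExtragenitalFindings,
    FrozenPelvis,
    GenitalFindings,
    InvasionLayer,
    RuleTrace,
    Side,
    Stage,
    validate_case,
)

ENGINE_VERSION = "agces-engine/1.0"

# Published thresholds (all lengths mm, extents percent of uterus).
WALL_MINIMAL_MAX_MM = 20.0      # wall ≤ 20 mm: minimal band
WALL_MODERATE_MAX_MM = 30.0     # wall in (20, 30]: intermediate band; > 30: severe
JZ_ENTRY_MM = 6.0               # JZ max ≤ 6 mm: junctional zone not staged
JZ_MILD_MM = 8.0                # JZ max in (6, 8]: Stage I; > 8: Stage II
JZ_EXTENT_DIFFUSE_PCT = 50.0    # extent ≥ 50%: Stage III regardless of JZ band
JZ_EXTENT_SEVERE_PCT = 80.0     # extent ≥ 80%: Stage IV
FOCAL_SMALL_MAX_MM = 10.0       # lesion ≤ 10 mm: small
FOCAL_MID_MAX_MM = 20.0         # lesion in (10, 20]: mid; > 20: large
SPOTS_MINIMAL_MAX = 6           # total spots ≤ 6: Stage I band (G and E)
SPOTS_MILD_MAX = 10             # total spots in (6, 10]: Stage II; > 10: Stage III
ENDOMETRIOMA_MAX_MM = 30.0      # unilateral endometrioma ≤ 30 mm: Stage III; > 30: IV
DIE_DEPTH_MM = 5.0              # depth ≤ 5 mm: superficial; > 5 mm: deep (Stage IV)


@dataclass(frozen=True)
class Boundary:
    """One documented threshold and which band owns the boundary value.

    ``closed_below`` is True when the threshold value itself belongs to the
    lower-severity band (the ``(a, b]`` reading); False when it belongs to
    the higher band (the two extent tie-breaks).
    """

    quantity: str
    value: float
    closed_below: bool


INTERVAL_CONVENTION: tuple[Boundary, ...] = (
    Boundary("wall_thickness_mm", WALL_MINIMAL_MAX_MM, True),
    Boundary("wall_thickness_mm", WALL_MODERATE_MAX_MM, True),
    Boundary("jz_max_mm", JZ_ENTRY_MM, True),
    Boundary("jz_max_mm", JZ_MILD_MM, True),
    Boundary("jz_diffuse_extent_pct", JZ_EXTENT_DIFFUSE_PCT, False),
    Boundary("jz_diffuse_extent_pct", JZ_EXTENT_SEVERE_PCT, False),
    Boundary("focal_lesion_mm", FOCAL_SMALL_MAX_MM, True),
    Boundary("focal_lesion_mm", FOCAL_MID_MAX_MM, True),
    Boundary("genital_spot_total", SPOTS_MINIMAL_MAX, True),
    Boundary("genital_spot_total", SPOTS_MILD_MAX, True),
    Boundary("extragenital_spot_total", SPOTS_MINIMAL_MAX, True),
    Boundary("extragenital_spot_total", SPOTS_MILD_MAX, True),
    Boundary("endometrioma_mm", ENDOMETRIOMA_MAX_MM, True),
    Boundary("depth_mm", DIE_DEPTH_MM, True),
)

_ROMAN = {"I": Stage.I, "II": Stage.II, "III": Stage.III, "IV": Stage.IV}


def criterion_stage(criterion_id: str) -> Stage:
    """The stage a criterion identifier awards (the roman-numeral token)."""
    for tok in criterion_id.split("."):
        if tok in _ROMAN:
            return _ROMAN[tok]
    raise ValueError(f"no stage token in criterion id {criterion_id!r}")


Fired = list[tuple[Stage, str]]


def _max_stage(fired: Fired) -> Stage:
    return max((s for s, _ in fired), default=Stage.ABSENT)


def _wall_fired(f: AdenomyosisFindings) -> Fired:
    t = [w.thickness_mm for w in f.walls
         if w.affected and w.thickness_mm is not None]
    n_minimal = sum(1 for x in t if x <= WALL_MINIMAL_MAX_MM)
    n_mid = sum(1 for x in t if WALL_MINIMAL_MAX_MM < x <= WALL_MODERATE_MAX_MM)
    n_severe = sum(1 for x in t if x > WALL_MODERATE_MAX_MM)
    fired: Fired = []
    if n_minimal >= 1:
        fired.append((Stage.I, "A.wall.I.one_wall_le_20mm"))
    if n_minimal >= 2:
        fired.append((Stage.II, "A.wall.II.two_walls_le_20mm"))
    if n_mid >= 1:
        fired.append((Stage.II, "A.wall.II.one_wall_20_30mm"))
    if n_severe >= 1:
        fired.append((Stage.III, "A.wall.III.one_wall_gt_30mm"))
    if n_mid >= 2:
        fired.append((Stage.III, "A.wall.III.two_walls_20_30mm"))
    if n_severe >= 2:
        fired.append((Stage.IV, "A.wall.IV.two_walls_gt_30mm"))
    if f.globally_enlarged:
        fired.append((Stage.IV, "A.wall.IV.global_enlargement"))
    return fired


def _jz_fired(f: AdenomyosisFindings) -> Fired:
    jz = f.jz_max_mm
    if jz is None or jz <= JZ_ENTRY_MM:
        return []
    ext = f.jz_diffuse_extent_pct if f.jz_diffuse_extent_pct is not None else 0.0
    fired: Fired = []
    if jz <= JZ_MILD_MM and ext < JZ_EXTENT_DIFFUSE_PCT:
        fired.append((Stage.I, "A.JZ.I.max_6_8mm_extent_lt_50pct"))
    if jz > JZ_MILD_MM and ext < JZ_EXTENT_DIFFUSE_PCT:
        fired.append((Stage.II, "A.JZ.II.max_gt_8mm_extent_lt_50pct"))
    if JZ_EXTENT_DIFFUSE_PCT <= ext < JZ_EXTENT_SEVERE_PCT:
        fired.append((Stage.III, "A.JZ.III.extent_50_80pct"))
    if ext >= JZ_EXTENT_SEVERE_PCT:
        fired.append((Stage.IV, "A.JZ.IV.extent_ge_80pct"))
    return fired


def _focal_fired(f: AdenomyosisFindings) -> Fired:
    n_small = sum(1 for d in f.focal_lesions_mm if d <= FOCAL_SMALL_MAX_MM)
    n_mid = sum(1 for d in f.focal_lesions_mm
                if FOCAL_SMALL_MAX_MM < d <= FOCAL_MID_MAX_MM)
    n_large = sum(1 for d in f.focal_lesions_mm if d > FOCAL_MID_MAX_MM)
    fired: Fired = []
    if n_small >= 1:
        fired.append((Stage.I, "A.focal.I.one_lesion_le_10mm"))
    if n_small >= 2:
        fired.append((Stage.II, "A.focal.II.two_lesions_le_10mm"))
    if n_mid >= 1:
        fired.append((Stage.II, "A.focal.II.one_lesion_10_20mm"))
    if n_mid >= 2:
        fired.append((Stage.III, "A.focal.III.two_lesions_10_20mm"))
    if n_large >= 1:
        fired.append((Stage.III, "A.focal.III.one_lesion_gt_20mm"))
    if n_large >= 2:
        fired.append((Stage.IV, "A.focal.IV.two_lesions_gt_20mm"))
    return fired


def stage_wall_thickening(f: AdenomyosisFindings) -> Stage:
    """Stage the diffuse uterine-wall-thickening sub-scale (0 if no
    affected wall and not globally enlarged)."""
    return _max_stage(_wall_fired(f))


def stage_jz(f: AdenomyosisFindings) -> Stage:
    """Stage the diffuse junctional-zone-thickening sub-scale.

    A JZ max of 6 mm or less (or no measurement) does not enter staging;
    above that, the JZ band and the diffuse-extent band compete and the
    higher stage wins.
    """
    return _max_stage(_jz_fired(f))


def stage_focal(f: AdenomyosisFindings) -> Stage:
    """Stage the focal adenomyosis/adenomyoma sub-scale from the size-bin
    counts of all lesions (≤10 mm, (10, 20] mm, >20 mm)."""
    return _max_stage(_focal_fired(f))


def stage_adenomyosis(f: AdenomyosisFindings) -> tuple[Stage, RuleTrace]:
    """Combine the three adenomyosis sub-scales: the highest stage across
    wall thickening, JZ thickening and focal lesions wins."""
    fired = _wall_fired(f) + _jz_fired(f) + _focal_fired(f)
    stage = _max_stage(fired)
    return stage, RuleTrace("A", stage, [c for _, c in fired], superseded=False)


def stage_genital(f: GenitalFindings) -> tuple[Stage, RuleTrace]:
    """Stage the genital component.

    Total spot count across sites sets the I–III bands; an endometrioma
    burden confined to a single ovary with no cyst over 30 mm is Stage III;
    dense adhesions, bilateral endometriomas, or any endometrioma over
    30 mm force Stage IV regardless of spot count.
    """
    total = sum(f.spots_by_site.values())
    sides = {m.side for m in f.endometriomas}
    fired: Fired = []
    if f.adhesions is AdhesionGrade.DENSE:
        fired.append((Stage.IV, "G.IV.dense_adhesions"))
    if Side.LEFT in sides and Side.RIGHT in sides:
        fired.append((Stage.IV, "G.IV.bilateral_endometriomas"))
    if any(m.diameter_mm > ENDOMETRIOMA_MAX_MM for m in f.endometriomas):
        fired.append((Stage.IV, "G.IV.endometrioma_gt_30mm"))
    if total > SPOTS_MILD_MAX:
        fired.append((Stage.III, "G.III.spots_gt_10"))
    if (f.endometriomas and len(sides) == 1
            and all(m.diameter_mm <= ENDOMETRIOMA_MAX_MM for m in f.endometriomas)):
        fired.append((Stage.III, "G.III.unilateral_endometrioma_le_30mm"))
    if SPOTS_MINIMAL_MAX < total <= SPOTS_MILD_MAX:
        fired.append((Stage.II, "G.II.spots_7_10"))
    if 1 <= total <= SPOTS_MINIMAL_MAX:
        fired.append((Stage.I, "G.I.spots_le_6"))
    stage = _max_stage(fired)
    return stage, RuleTrace("G", stage, [c for _, c in fired],
                            superseded=stage is Stage.IV)


def stage_extragenital(f: ExtragenitalFindings) -> tuple[Stage, RuleTrace]:
    """Stage the extragenital component.

    Total spot count sets the I–III bands while disease stays superficial
    (≤ 5 mm depth). Deep infiltration (> 5 mm), muscularis or mucosal
    invasion, any cul-de-sac obliteration, frozen pelvis, or organ
    dysfunction force Stage IV regardless of spot count.
    """
    total = sum(f.spots_by_site.values())
    fired: Fired = []
    if f.max_depth_mm is not None and f.max_depth_mm > DIE_DEPTH_MM:
        fired.append((Stage.IV, "E.IV.depth_gt_5mm"))
    if f.invasion in (InvasionLayer.MUSCULARIS, InvasionLayer.MUCOSAL):
        fired.append((Stage.IV, "E.IV.muscularis_or_mucosal_invasion"))
    if f.culdesac is not CuldesacObliteration.NONE:
        fired.append((Stage.IV, "E.IV.culdesac_obliteration"))
    if f.frozen_pelvis is not FrozenPelvis.NONE:
        fired.append((Stage.IV, "E.IV.frozen_pelvis"))
    if f.organ_dysfunction:
        fired.append((Stage.IV, "E.IV.organ_dysfunction"))
    if total > SPOTS_MILD_MAX:
        fired.append((Stage.III, "E.III.spots_gt_10"))
    if SPOTS_MINIMAL_MAX < total <= SPOTS_MILD_MAX:
        fired.append((Stage.II, "E.II.spots_7_10"))
    if 1 <= total <= SPOTS_MINIMAL_MAX:
        fired.append((Stage.I, "E.I.spots_le_6"))
    stage = _max_stage(fired)
    return stage, RuleTrace("E", stage, [c for _, c in fired],
                            superseded=stage is Stage.IV)


def classify_case(case: CaseRecord) -> tuple[AgcesCode, list[RuleTrace]]:
    """Stage all three components of a validated case.

    Raises :class:`CaseValidationError` (carrying the full violation list)
    if the record breaks any model invariant.
    """
    violations = validate_case(case)
    if violations:
        raise CaseValidationError(violations)
    a, trace_a = stage_adenomyosis(case.adenomyosis)
    g, trace_g = stage_genital(case.genital)
    e, trace_e = stage_extragenital(case.extragenital)
    return AgcesCode(a, g, e), [trace_a, trace_g, trace_e]


def format_code(code: AgcesCode) -> str:
    """Canonical string form, e.g. ``AgcesCode(3, 2, 4)`` → ``"A3 G2 E4"``."""
    return str(code)


_CODE_RE = re.compile(r"a\s*(\d+)\s*g\s*(\d+)\s*e\s*(\d+)")


def parse_code(s: str) -> AgcesCode:
    """Parse an AGCES code string.

    Accepts the canonical form plus tolerant variants (case-insensitive,
    optional whitespace: ``"a3g2e4"``). Raises :class:`CodeParseError`
    naming the offending token on malformed input or out-of-range stages.
    """
    m = _CODE_RE.fullmatch(s.strip().lower())
    if m is None:
        raise CodeParseError(f"not an AGCES code: {s!r} (expected 'A# G# E#')")
    stages = []
    for letter, digits in zip("AGE", m.groups()):
        value = int(digits)
        if value > 4:
            raise CodeParseError(
                f"stage out of range in {s!r}: {letter}{digits} (stages are 0-4)")
        stages.append(Stage(value))
    return AgcesCode(*stages)
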