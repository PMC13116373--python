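"""Synthetic case generation and the independent rule-table oracle.

Three test-bed facilities live here:

* :func:`generate_case` / :func:`generate_cases` — seeded random valid
  cases with controllable per-component severity, by *inversion*: given a
  target (A, G, E) triple, findings are sampled inside the target stage's
  criterion region, so the engine must classify the case back to its
  target. Every generated case records the generator name and seed in its
  metadata so any failing case is replayable.
* :func:`enumerate_boundary_cases` — a deterministic case pair (one on
  each side) for every documented staging threshold.
* :func:`oracle_stage` — an independent re-implementation of the staging
  table as a flat list of (predicate, stage) pairs, sharing no code with
  the engine; it is the cross-check the engine is tested against.

Measurements are sampled uniformly inside the target band and rounded to
0.1 mm (0.1 %), matching the precision of clinical imaging reports. The
default severity weights are uniform over stages 0–4; the generator makes
no attempt to match real-world stage prevalence.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import (
    AdenomyosisFindings,
    AdhesionGrade,
    AgcesCode,
    CaseRecord,
    CuldesacObliteration,
    DysfunctionKind,
    Endometrioma,
    ExtragenitalFindings,
    ExtragenitalSite,
    FrozenPelvis,
    GenitalFindings,
    GenitalSite,
    InvasionLayer,
    OrganDysfunction,
    Side,
    Stage,
    WallFinding,
    WallLocation,
)

GENERATOR_VERSION = "agces-synth/1"

_UNIFORM = (0.2, 0.2, 0.2, 0.2, 0.2)


@dataclass
class GeneratorConfig:
    """Configuration for the seeded case generator.

    ``severity_weights`` maps each component ("A", "G", "E") to a
    probability vector over target stages 0–4 (rows must sum to 1 within
    1e-9). ``boundary_fraction`` of the cases are drawn from the
    deterministic boundary enumerator instead of being sampled.
    """

    seed: int = 0
    n_cases: int = 1
    severity_weights: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"A": _UNIFORM, "G": _UNIFORM, "E": _UNIFORM})
    boundary_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if not 0 <= self.boundary_fraction <= 1:
            raise ValueError("boundary_fraction must lie in [0, 1]")
        for comp, row in self.severity_weights.items():
            if len(row) != 5 or any(p < 0 for p in row):
                raise ValueError(
                    f"severity_weights[{comp!r}] must be 5 non-negative probabilities")
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(
                    f"severity_weights[{comp!r}] must sum to 1 (got {sum(row)})")


def _round1(x: float) -> float:
    return round(x, 1)


def _distribute_spots(rng: random.Random, total: int, sites: list) -> dict:
    """Split a spot total across 1–3 randomly chosen sites."""
    if total == 0:
        return {}
    chosen = rng.sample(sites, k=min(len(sites), rng.randint(1, 3)))
    counts = {s: 0 for s in chosen}
    for _ in range(total):
        counts[rng.choice(chosen)] += 1
    return {s: n for s, n in counts.items() if n > 0}


def _gen_adenomyosis(rng: random.Random, target: int) -> AdenomyosisFindings:
    if target == 0:
        return AdenomyosisFindings()
    route = rng.choice(("wall", "jz", "focal"))
    if route == "wall":
        locations = rng.sample(list(WallLocation), k=2)

        def wall(loc, lo, hi):
            return WallFinding(location=loc, thickness_mm=_round1(rng.uniform(lo, hi)),
                               affected=True)

        if target == 1:
            return AdenomyosisFindings(walls=[wall(locations[0], 8, 20)])
        if target == 2:
            if rng.random() < 0.5:
                return AdenomyosisFindings(walls=[wall(locations[0], 20.5, 30)])
            return AdenomyosisFindings(
                walls=[wall(locations[0], 8, 20), wall(locations[1], 8, 20)])
        if target == 3:
            if rng.random() < 0.5:
                return AdenomyosisFindings(walls=[wall(locations[0], 30.5, 45)])
            return AdenomyosisFindings(
                walls=[wall(locations[0], 20.5, 30), wall(locations[1], 20.5, 30)])
        if rng.random() < 0.5:
            return AdenomyosisFindings(globally_enlarged=True)
        return AdenomyosisFindings(
            walls=[wall(locations[0], 30.5, 45), wall(locations[1], 30.5, 45)])
    if route == "jz":
        if target == 1:
            jz, ext = rng.uniform(6.2, 8.0), rng.uniform(0, 49)
        elif target == 2:
            jz, ext = rng.uniform(8.2, 14), rng.uniform(0, 49)
        elif target == 3:
            jz, ext = rng.uniform(6.5, 14), rng.uniform(50, 79.5)
        else:
            jz, ext = rng.uniform(6.5, 14), rng.uniform(80, 100)
        return AdenomyosisFindings(jz_max_mm=_round1(jz),
                                  jz_diffuse_extent_pct=_round1(ext))

    def lesion(lo, hi):
        return _round1(rng.uniform(lo, hi))

    if target == 1:
        lesions = [lesion(3, 10)]
    elif target == 2:
        lesions = ([lesion(3, 10), lesion(3, 10)] if rng.random() < 0.5
                   else [lesion(10.5, 20)])
    elif target == 3:
        lesions = ([lesion(10.5, 20), lesion(10.5, 20)] if rng.random() < 0.5
                   else [lesion(20.5, 40)])
    else:
        lesions = [lesion(20.5, 40), lesion(20.5, 40)]
    return AdenomyosisFindings(focal_lesions_mm=lesions)


def _gen_genital(rng: random.Random, target: int) -> GenitalFindings:
    sites = list(GenitalSite)
    mild_adhesions = rng.choice((AdhesionGrade.NONE, AdhesionGrade.FILMY))
    if target == 0:
        return GenitalFindings()
    if target == 1:
        return GenitalFindings(
            spots_by_site=_distribute_spots(rng, rng.randint(1, 6), sites),
            adhesions=mild_adhesions)
    if target == 2:
        return GenitalFindings(
            spots_by_site=_distribute_spots(rng, rng.randint(7, 10), sites),
            adhesions=mild_adhesions)
    if target == 3:
        if rng.random() < 0.5:
            return GenitalFindings(
                spots_by_site=_distribute_spots(rng, rng.randint(11, 25), sites),
                adhesions=mild_adhesions)
        side = rng.choice((Side.LEFT, Side.RIGHT))
        return GenitalFindings(
            spots_by_site=_distribute_spots(rng, rng.randint(0, 10), sites),
            adhesions=mild_adhesions,
            endometriomas=[Endometrioma(side=side,
                                        diameter_mm=_round1(rng.uniform(10, 30)))])
    trigger = rng.choice(("dense", "bilateral", "large"))
    spots = _distribute_spots(rng, rng.randint(0, 15), sites)
    if trigger == "dense":
        return GenitalFindings(spots_by_site=spots,
                               adhesions=AdhesionGrade.DENSE)
    if trigger == "bilateral":
        return GenitalFindings(
            spots_by_site=spots, adhesions=mild_adhesions,
            endometriomas=[
                Endometrioma(Side.LEFT, _round1(rng.uniform(10, 60))),
                Endometrioma(Side.RIGHT, _round1(rng.uniform(10, 60)))])
    side = rng.choice((Side.LEFT, Side.RIGHT))
    return GenitalFindings(
        spots_by_site=spots, adhesions=mild_adhesions,
        endometriomas=[Endometrioma(side, _round1(rng.uniform(30.5, 70)))])


def _gen_extragenital(rng: random.Random, target: int) -> ExtragenitalFindings:
    sites = list(ExtragenitalSite)
    if target == 0:
        return ExtragenitalFindings()
    if target in (1, 2, 3):
        totals = {1: (1, 6), 2: (7, 10), 3: (11, 25)}[target]
        return ExtragenitalFindings(
            spots_by_site=_distribute_spots(rng, rng.randint(*totals), sites),
            max_depth_mm=_round1(rng.uniform(0.5, 5)),
            invasion=rng.choice((InvasionLayer.NONE, InvasionLayer.PERITONEAL)))
    trigger = rng.choice(("depth", "invasion", "culdesac", "frozen",
                          "dysfunction"))
    if trigger == "depth":
        return ExtragenitalFindings(
            spots_by_site=_distribute_spots(rng, rng.randint(1, 15), sites),
            max_depth_mm=_round1(rng.uniform(5.5, 15)))
    if trigger == "invasion":
        return ExtragenitalFindings(
            spots_by_site=_distribute_spots(rng, rng.randint(1, 15), sites),
            max_depth_mm=_round1(rng.uniform(0.5, 5)),
            invasion=rng.choice((InvasionLayer.MUSCULARIS,
                                 InvasionLayer.MUCOSAL)))
    total = rng.randint(0, 15)
    spots = _distribute_spots(rng, total, sites)
    depth = _round1(rng.uniform(0.5, 5)) if total else None
    if trigger == "culdesac":
        return ExtragenitalFindings(
            spots_by_site=spots, max_depth_mm=depth,
            culdesac=rng.choice((CuldesacObliteration.PARTIAL,
                                 CuldesacObliteration.COMPLETE)))
    if trigger == "frozen":
        return ExtragenitalFindings(
            spots_by_site=spots, max_depth_mm=depth,
            frozen_pelvis=rng.choice((FrozenPelvis.ANTERIOR,
                                      FrozenPelvis.POSTERIOR)))
    kind = rng.choice(list(DysfunctionKind))
    organ = {DysfunctionKind.URETERAL_OBSTRUCTION: "ureter",
             DysfunctionKind.BOWEL_OBSTRUCTION: "bowel",
             DysfunctionKind.OTHER_COMPROMISE: "bladder"}[kind]
    return ExtragenitalFindings(
        spots_by_site=spots, max_depth_mm=depth,
        organ_dysfunction=[OrganDysfunction(organ=organ, kind=kind)])


def _sample_target(rng: random.Random,
                   weights: dict[str, tuple[float, ...]]) -> tuple[int, int, int]:
    return tuple(rng.choices(range(5), weights=weights[c])[0]
                 for c in ("A", "G", "E"))  # type: ignore[return-value]


def _build_case(rng: random.Random, target: tuple[int, int, int],
                case_id: str, seed: int) -> CaseRecord:
    return CaseRecord(
        case_id=case_id,
        adenomyosis=_gen_adenomyosis(rng, target[0]),
        genital=_gen_genital(rng, target[1]),
        extragenital=_gen_extragenital(rng, target[2]),
        metadata={"generator": GENERATOR_VERSION, "seed": seed,
                  "target": f"A{target[0]} G{target[1]} E{target[2]}"},
    )


def generate_case(config: GeneratorConfig,
                  target: tuple[int, int, int] | None = None) -> CaseRecord:
    """Generate one valid case; with a target triple, the case classifies
    exactly to that triple (deterministic for a fixed config)."""
    rng = random.Random(config.seed)
    if target is None:
        target = _sample_target(rng, config.severity_weights)
    return _build_case(rng, target, f"SYN-{config.seed}-00000", config.seed)


def generate_cases(config: GeneratorConfig) -> list[CaseRecord]:
    """Generate ``config.n_cases`` valid cases (deterministic sequence for
    a fixed config); a ``boundary_fraction`` of them are taken, in order,
    from the deterministic boundary enumerator."""
    rng = random.Random(config.seed)
    boundary_pool = enumerate_boundary_cases() if config.boundary_fraction else []
    out = []
    b = 0
    for i in range(config.n_cases):
        if boundary_pool and rng.random() < config.boundary_fraction:
            case = boundary_pool[b % len(boundary_pool)]
            b += 1
        else:
            target = _sample_target(rng, config.severity_weights)
            case = _build_case(rng, target, f"SYN-{config.seed}-{i:05d}",
                               config.seed)
        out.append(case)
    return out


# --------------------------------------------------------------------------
# Boundary enumeration
# --------------------------------------------------------------------------

def _a_case(cid: str, **kw) -> CaseRecord:
    return CaseRecord(case_id=cid, adenomyosis=AdenomyosisFindings(**kw))


def _g_case(cid: str, **kw) -> CaseRecord:
    return CaseRecord(case_id=cid, genital=GenitalFindings(**kw))


def _e_case(cid: str, **kw) -> CaseRecord:
    return CaseRecord(case_id=cid, extragenital=ExtragenitalFindings(**kw))


def _spots(site, n):
    return {site: n}


def boundary_cases_with_expected() -> list[tuple[CaseRecord, AgcesCode]]:
    """One (case, expected code) pair for each side of every documented
    threshold, isolating that threshold's rule."""
    S = Stage
    g_site, e_site = GenitalSite.OVARY_LEFT, ExtragenitalSite.PELVIC_SIDEWALL
    wall = WallLocation.ANTERIOR

    def code(a=0, g=0, e=0):
        return AgcesCode(S(a), S(g), S(e))

    pairs: list[tuple[CaseRecord, AgcesCode]] = []

    def add(case: CaseRecord, expected: AgcesCode) -> None:
        pairs.append((case, expected))

    # genital spot totals at 6 and 10
    add(_g_case("BND-genital-spots-6-low", spots_by_site=_spots(g_site, 6)), code(g=1))
    add(_g_case("BND-genital-spots-6-high", spots_by_site=_spots(g_site, 7)), code(g=2))
    add(_g_case("BND-genital-spots-10-low", spots_by_site=_spots(g_site, 10)), code(g=2))
    add(_g_case("BND-genital-spots-10-high", spots_by_site=_spots(g_site, 11)), code(g=3))
    # extragenital spot totals at 6 and 10 (superficial depth)
    add(_e_case("BND-extragenital-spots-6-low",
                spots_by_site=_spots(e_site, 6), max_depth_mm=3.0), code(e=1))
    add(_e_case("BND-extragenital-spots-6-high",
                spots_by_site=_spots(e_site, 7), max_depth_mm=3.0), code(e=2))
    add(_e_case("BND-extragenital-spots-10-low",
                spots_by_site=_spots(e_site, 10), max_depth_mm=3.0), code(e=2))
    add(_e_case("BND-extragenital-spots-10-high",
                spots_by_site=_spots(e_site, 11), max_depth_mm=3.0), code(e=3))
    # depth of penetration at 5 mm
    add(_e_case("BND-depth-5-low",
                spots_by_site=_spots(e_site, 1), max_depth_mm=5.0), code(e=1))
    add(_e_case("BND-depth-5-high",
                spots_by_site=_spots(e_site, 1), max_depth_mm=5.1), code(e=4))
    # endometrioma diameter at 30 mm (single ovary)
    add(_g_case("BND-endometrioma-30-low",
                endometriomas=[Endometrioma(Side.LEFT, 30.0)]), code(g=3))
    add(_g_case("BND-endometrioma-30-high",
                endometriomas=[Endometrioma(Side.LEFT, 30.1)]), code(g=4))
    # wall thickness at 20 and 30 mm (single wall)
    add(_a_case("BND-wall-20-low",
                walls=[WallFinding(wall, 20.0)]), code(a=1))
    add(_a_case("BND-wall-20-high",
                walls=[WallFinding(wall, 20.1)]), code(a=2))
    add(_a_case("BND-wall-30-low",
                walls=[WallFinding(wall, 30.0)]), code(a=2))
    add(_a_case("BND-wall-30-high",
                walls=[WallFinding(wall, 30.1)]), code(a=3))
    # JZ max at 6 and 8 mm (extent below 50%)
    add(_a_case("BND-jz-6-low", jz_max_mm=6.0, jz_diffuse_extent_pct=30.0), code(a=0))
    add(_a_case("BND-jz-6-high", jz_max_mm=6.1, jz_diffuse_extent_pct=30.0), code(a=1))
    add(_a_case("BND-jz-8-low", jz_max_mm=8.0, jz_diffuse_extent_pct=30.0), code(a=1))
    add(_a_case("BND-jz-8-high", jz_max_mm=8.1, jz_diffuse_extent_pct=30.0), code(a=2))
    # diffuse JZ extent at 50 and 80 percent
    add(_a_case("BND-extent-50-low", jz_max_mm=9.0, jz_diffuse_extent_pct=49.9), code(a=2))
    add(_a_case("BND-extent-50-high", jz_max_mm=9.0, jz_diffuse_extent_pct=50.0), code(a=3))
    add(_a_case("BND-extent-80-low", jz_max_mm=9.0, jz_diffuse_extent_pct=79.9), code(a=3))
    add(_a_case("BND-extent-80-high", jz_max_mm=9.0, jz_diffuse_extent_pct=80.0), code(a=4))
    # focal lesion diameter at 10 and 20 mm (single lesion)
    add(_a_case("BND-lesion-10-low", focal_lesions_mm=[10.0]), code(a=1))
    add(_a_case("BND-lesion-10-high", focal_lesions_mm=[10.1]), code(a=2))
    add(_a_case("BND-lesion-20-low", focal_lesions_mm=[20.0]), code(a=2))
    add(_a_case("BND-lesion-20-high", focal_lesions_mm=[20.1]), code(a=3))
    return pairs


def enumerate_boundary_cases() -> list[CaseRecord]:
    """Deterministic cases sitting exactly on both sides of every
    documented staging threshold (two per threshold, 14 thresholds)."""
    return [case for case, _ in boundary_cases_with_expected()]


# --------------------------------------------------------------------------
# Independent rule-table oracle
# --------------------------------------------------------------------------

def oracle_stage(case: CaseRecord) -> AgcesCode:
    """Stage a case by literal, flat enumeration of every staging-table
    cell, independent of the engine.

    Each printed criterion is one predicate paired with its stage; the
    component stage is the maximum over fired predicates (0 if none fire).
    This function intentionally shares no code or constants with
    :mod:`agces.engine`.
    """
    a, g, e = case.adenomyosis, case.genital, case.extragenital

    walls = [w.thickness_mm for w in a.walls
             if w.affected and w.thickness_mm is not None]
    jz = a.jz_max_mm
    ext = a.jz_diffuse_extent_pct or 0.0
    jz_entered = jz is not None and jz > 6
    lesions = a.focal_lesions_mm
    rules_a = [
        # diffuse uterine wall thickening
        (1, sum(1 for t in walls if t <= 20) >= 1),
        (2, sum(1 for t in walls if t <= 20) >= 2),
        (2, sum(1 for t in walls if 20 < t <= 30) >= 1),
        (3, sum(1 for t in walls if t > 30) >= 1),
        (3, sum(1 for t in walls if 20 < t <= 30) >= 2),
        (4, sum(1 for t in walls if t > 30) >= 2),
        (4, a.globally_enlarged),
        # diffuse junctional-zone thickening
        (1, jz_entered and jz <= 8 and ext < 50),
        (2, jz_entered and jz > 8 and ext < 50),
        (3, jz_entered and 50 <= ext < 80),
        (4, jz_entered and ext >= 80),
        # focal adenomyosis / adenomyoma
        (1, sum(1 for d in lesions if d <= 10) >= 1),
        (2, sum(1 for d in lesions if d <= 10) >= 2),
        (2, sum(1 for d in lesions if 10 < d <= 20) >= 1),
        (3, sum(1 for d in lesions if 10 < d <= 20) >= 2),
        (3, sum(1 for d in lesions if d > 20) >= 1),
        (4, sum(1 for d in lesions if d > 20) >= 2),
    ]

    g_total = sum(g.spots_by_site.values())
    g_sides = {m.side for m in g.endometriomas}
    rules_g = [
        (1, 1 <= g_total <= 6),
        (2, 6 < g_total <= 10),
        (3, g_total > 10),
        (3, bool(g.endometriomas) and len(g_sides) == 1
            and max(m.diameter_mm for m in g.endometriomas) <= 30),
        (4, len(g_sides) == 2),
        (4, any(m.diameter_mm > 30 for m in g.endometriomas)),
        (4, g.adhesions == AdhesionGrade.DENSE),
    ]

    e_total = sum(e.spots_by_site.values())
    rules_e = [
        (1, 1 <= e_total <= 6),
        (2, 6 < e_total <= 10),
        (3, e_total > 10),
        (4, e.max_depth_mm is not None and e.max_depth_mm > 5),
        (4, e.invasion in (InvasionLayer.MUSCULARIS, InvasionLayer.MUCOSAL)),
        (4, e.culdesac in (CuldesacObliteration.PARTIAL,
                           CuldesacObliteration.COMPLETE)),
        (4, e.frozen_pelvis in (FrozenPelvis.ANTERIOR, FrozenPelvis.POSTERIOR)),
        (4, len(e.organ_dysfunction) > 0),
    ]

    def best(rules):
        return Stage(max((s for s, fired in rules if fired), default=0))

    return AgcesCode(best(rules_a), best(rules_g), best(rules_e))
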