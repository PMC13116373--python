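"""Self-verification harness: worked examples, exhaustive grids, and
property suites.

The staging rules form a small closed decision table, so the package can
check itself end-to-end at run time:

* worked examples — one constructed case per published criterion row,
  with the stage the row prints;
* oracle equivalence — the engine against the independent flat rule-table
  oracle (:func:`agces.synth.oracle_stage`) on an exhaustive discretized
  grid around every threshold and on seeded random cases;
* monotonicity — no severity-increasing perturbation may lower the
  affected component's stage;
* supersession — every Stage-IV trigger forces its component to 4 in any
  context;
* inversion — targeted generation re-classifies to its target for all
  125 stage triples;
* round-trips — JSON save/load identity, code parse/format identity,
  byte-stable report rendering.

Each function returns ``(failures, n_checked)`` so callers can report or
assert on the counts. These checks run in seconds on one CPU.
"""

from __future__ import annotations

import copy
import itertools
import random
import tempfile
from pathlib import Path
from typing import Callable

from .case_io import load_case, save_case, stage_case
from .engine import classify_case, format_code, parse_code
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
from .report import render_report
from .synth import GeneratorConfig, generate_cases, oracle_stage

# --------------------------------------------------------------------------
# Worked examples: one case per published criterion row
# --------------------------------------------------------------------------

_GS = GenitalSite.OVARY_LEFT
_ES = ExtragenitalSite.PELVIC_SIDEWALL


def _case(cid: str, a: AdenomyosisFindings | None = None,
          g: GenitalFindings | None = None,
          e: ExtragenitalFindings | None = None) -> CaseRecord:
    return CaseRecord(case_id=cid,
                      adenomyosis=a or AdenomyosisFindings(),
                      genital=g or GenitalFindings(),
                      extragenital=e or ExtragenitalFindings())


def _walls(*thicknesses: float) -> list[WallFinding]:
    locs = list(WallLocation)
    return [WallFinding(loc, t) for loc, t in zip(locs, thicknesses)]


def worked_examples() -> list[tuple[CaseRecord, AgcesCode]]:
    """Constructed cases reproducing each printed staging-criterion row,
    paired with the expected code."""
    S = Stage

    def code(a=0, g=0, e=0):
        return AgcesCode(S(a), S(g), S(e))

    return [
        # adenomyosis: diffuse uterine wall thickening
        (_case("wall-one-18mm", a=AdenomyosisFindings(walls=_walls(18))), code(a=1)),
        (_case("wall-two-25-28mm", a=AdenomyosisFindings(walls=_walls(25, 28))), code(a=3)),
        (_case("wall-15-32mm", a=AdenomyosisFindings(walls=_walls(15, 32))), code(a=3)),
        (_case("wall-two-gt30", a=AdenomyosisFindings(walls=_walls(33, 36))), code(a=4)),
        (_case("globally-enlarged",
               a=AdenomyosisFindings(globally_enlarged=True)), code(a=4)),
        # adenomyosis: diffuse junctional-zone thickening
        (_case("jz-7mm-30pct",
               a=AdenomyosisFindings(jz_max_mm=7, jz_diffuse_extent_pct=30)), code(a=1)),
        (_case("jz-5mm-10pct",
               a=AdenomyosisFindings(jz_max_mm=5, jz_diffuse_extent_pct=10)), code()),
        (_case("jz-9mm-30pct",
               a=AdenomyosisFindings(jz_max_mm=9, jz_diffuse_extent_pct=30)), code(a=2)),
        (_case("jz-9mm-60pct",
               a=AdenomyosisFindings(jz_max_mm=9, jz_diffuse_extent_pct=60)), code(a=3)),
        (_case("jz-9mm-85pct",
               a=AdenomyosisFindings(jz_max_mm=9, jz_diffuse_extent_pct=85)), code(a=4)),
        # adenomyosis: focal lesions
        (_case("focal-8mm", a=AdenomyosisFindings(focal_lesions_mm=[8])), code(a=1)),
        (_case("focal-7-9mm", a=AdenomyosisFindings(focal_lesions_mm=[7, 9])), code(a=2)),
        (_case("focal-15mm", a=AdenomyosisFindings(focal_lesions_mm=[15])), code(a=2)),
        (_case("focal-12-18mm",
               a=AdenomyosisFindings(focal_lesions_mm=[12, 18])), code(a=3)),
        (_case("focal-8-25mm",
               a=AdenomyosisFindings(focal_lesions_mm=[8, 25])), code(a=3)),
        (_case("focal-22-25mm",
               a=AdenomyosisFindings(focal_lesions_mm=[22, 25])), code(a=4)),
        # adenomyosis: highest sub-scale wins
        (_case("jz60-plus-small-focal",
               a=AdenomyosisFindings(jz_max_mm=9, jz_diffuse_extent_pct=60,
                                     focal_lesions_mm=[5])), code(a=3)),
        # genital
        (_case("g-6-spots", g=GenitalFindings(spots_by_site={_GS: 6})), code(g=1)),
        (_case("g-8-spots-filmy",
               g=GenitalFindings(spots_by_site={_GS: 8},
                                 adhesions=AdhesionGrade.FILMY)), code(g=2)),
        (_case("g-12-spots", g=GenitalFindings(spots_by_site={_GS: 12})), code(g=3)),
        (_case("g-unilateral-30mm",
               g=GenitalFindings(spots_by_site={_GS: 2},
                                 adhesions=AdhesionGrade.FILMY,
                                 endometriomas=[Endometrioma(Side.LEFT, 30)])),
         code(g=3)),
        (_case("g-bilateral-20mm",
               g=GenitalFindings(spots_by_site={_GS: 2},
                                 adhesions=AdhesionGrade.FILMY,
                                 endometriomas=[Endometrioma(Side.LEFT, 20),
                                                Endometrioma(Side.RIGHT, 20)])),
         code(g=4)),
        (_case("g-35mm-endometrioma",
               g=GenitalFindings(endometriomas=[Endometrioma(Side.RIGHT, 35)])),
         code(g=4)),
        (_case("g-3-spots-dense",
               g=GenitalFindings(spots_by_site={_GS: 3},
                                 adhesions=AdhesionGrade.DENSE)), code(g=4)),
        # extragenital
        (_case("e-4-spots-5mm",
               e=ExtragenitalFindings(spots_by_site={_ES: 4}, max_depth_mm=5)),
         code(e=1)),
        (_case("e-8-spots-3mm",
               e=ExtragenitalFindings(spots_by_site={_ES: 8}, max_depth_mm=3)),
         code(e=2)),
        (_case("e-12-spots-4mm",
               e=ExtragenitalFindings(spots_by_site={_ES: 12}, max_depth_mm=4)),
         code(e=3)),
        (_case("e-3-spots-7mm-deep",
               e=ExtragenitalFindings(spots_by_site={_ES: 3}, max_depth_mm=7)),
         code(e=4)),
        (_case("e-partial-culdesac",
               e=ExtragenitalFindings(spots_by_site={_ES: 2}, max_depth_mm=3,
                                      culdesac=CuldesacObliteration.PARTIAL)),
         code(e=4)),
        (_case("e-frozen-pelvis",
               e=ExtragenitalFindings(frozen_pelvis=FrozenPelvis.POSTERIOR)),
         code(e=4)),
        (_case("e-ureteral-obstruction",
               e=ExtragenitalFindings(organ_dysfunction=[
                   OrganDysfunction("ureter",
                                    DysfunctionKind.URETERAL_OBSTRUCTION)])),
         code(e=4)),
        # empty case
        (_case("all-absent"), code()),
    ]


def worked_example_failures() -> tuple[int, int]:
    """Classify every worked example; count mismatches."""
    examples = worked_examples()
    failures = sum(1 for case, expected in examples
                   if classify_case(case)[0] != expected)
    return failures, len(examples)


# --------------------------------------------------------------------------
# Oracle equivalence
# --------------------------------------------------------------------------

_WALL_VALUES = (0.0, 15.0, 20.0, 20.1, 25.0, 30.0, 30.1, 35.0)
_JZ_VALUES = (5.0, 6.0, 6.1, 7.0, 8.0, 8.1, 10.0)
_EXTENT_VALUES = (0.0, 30.0, 49.9, 50.0, 79.9, 80.0, 100.0)
_LESION_VALUES = (5.0, 10.0, 10.1, 15.0, 20.0, 20.1, 25.0)
_DEPTH_VALUES = (0.0, 3.0, 5.0, 5.1, 7.0)
_SPOT_TOTALS = tuple(range(16))


def _iter_adenomyosis_grid():
    locs = (WallLocation.ANTERIOR, WallLocation.POSTERIOR)
    wall_sets = [[]]
    wall_sets += [[WallFinding(locs[0], t)] for t in _WALL_VALUES]
    wall_sets += [[WallFinding(locs[0], t1), WallFinding(locs[1], t2)]
                  for t1, t2 in
                  itertools.combinations_with_replacement(_WALL_VALUES, 2)]
    jz_configs = [(None, None)] + [(j, x) for j in _JZ_VALUES
                                   for x in _EXTENT_VALUES]
    lesion_sets = [list(c) for size in range(4)
                   for c in itertools.combinations_with_replacement(
                       _LESION_VALUES, size)]
    for walls in wall_sets:
        for enlarged in (False, True):
            for jz, ext in jz_configs:
                for lesions in lesion_sets:
                    yield AdenomyosisFindings(
                        walls=walls, globally_enlarged=enlarged,
                        jz_max_mm=jz, jz_diffuse_extent_pct=ext,
                        focal_lesions_mm=lesions)


def _iter_genital_grid():
    site1, site2 = GenitalSite.OVARY_LEFT, GenitalSite.UTERINE_SEROSA
    endo_configs = [
        [],
        [Endometrioma(Side.LEFT, 20.0)],
        [Endometrioma(Side.LEFT, 30.0)],
        [Endometrioma(Side.LEFT, 30.1)],
        [Endometrioma(Side.RIGHT, 45.0)],
        [Endometrioma(Side.LEFT, 20.0), Endometrioma(Side.LEFT, 25.0)],
        [Endometrioma(Side.LEFT, 20.0), Endometrioma(Side.LEFT, 40.0)],
        [Endometrioma(Side.LEFT, 20.0), Endometrioma(Side.RIGHT, 20.0)],
        [Endometrioma(Side.LEFT, 35.0), Endometrioma(Side.RIGHT, 40.0)],
    ]
    for total in _SPOT_TOTALS:
        spot_splits = [{site1: total}] if total else [{}]
        if total >= 2:
            spot_splits.append({site1: total - 1, site2: 1})
        for spots in spot_splits:
            for adhesions in AdhesionGrade:
                for endos in endo_configs:
                    yield GenitalFindings(spots_by_site=spots,
                                          adhesions=adhesions,
                                          endometriomas=endos)


def _iter_extragenital_grid():
    site = ExtragenitalSite.BOWEL
    dysfunction_configs = [
        [],
        [OrganDysfunction("bowel", DysfunctionKind.BOWEL_OBSTRUCTION)],
    ]
    for total in _SPOT_TOTALS:
        spots = {site: total} if total else {}
        depths = _DEPTH_VALUES if total else (None,) + _DEPTH_VALUES
        for depth in depths:
            for invasion in InvasionLayer:
                if total == 0 and invasion in (InvasionLayer.MUSCULARIS,
                                               InvasionLayer.MUCOSAL):
                    continue
                for culdesac in CuldesacObliteration:
                    for frozen in FrozenPelvis:
                        for dysfunction in dysfunction_configs:
                            yield ExtragenitalFindings(
                                spots_by_site=spots, max_depth_mm=depth,
                                invasion=invasion, culdesac=culdesac,
                                frozen_pelvis=frozen,
                                organ_dysfunction=dysfunction)


def grid_disagreements() -> tuple[int, int]:
    """Engine vs oracle on the exhaustive per-component threshold grid."""
    from .engine import stage_adenomyosis, stage_extragenital, stage_genital

    failures = 0
    n = 0
    shell = _case("grid")
    for findings in _iter_adenomyosis_grid():
        shell.adenomyosis = findings
        n += 1
        if stage_adenomyosis(findings)[0] != oracle_stage(shell).a:
            failures += 1
    shell.adenomyosis = AdenomyosisFindings()
    for findings in _iter_genital_grid():
        shell.genital = findings
        n += 1
        if stage_genital(findings)[0] != oracle_stage(shell).g:
            failures += 1
    shell.genital = GenitalFindings()
    for findings in _iter_extragenital_grid():
        shell.extragenital = findings
        n += 1
        if stage_extragenital(findings)[0] != oracle_stage(shell).e:
            failures += 1
    return failures, n


def _random_cases(seed: int, n: int) -> list[CaseRecord]:
    return generate_cases(GeneratorConfig(seed=seed, n_cases=n))


def random_disagreements(seed: int, n: int) -> tuple[int, int]:
    """Engine vs oracle on seeded random full cases."""
    failures = 0
    for case in _random_cases(seed, n):
        if classify_case(case)[0] != oracle_stage(case):
            failures += 1
    return failures, n


# --------------------------------------------------------------------------
# Monotonicity
# --------------------------------------------------------------------------

def _bump_spots(findings, sites, rng) -> None:
    site = rng.choice(sites)
    findings.spots_by_site[site] = findings.spots_by_site.get(site, 0) \
        + rng.randint(1, 5)


def _perturbations() -> list[tuple[str, Callable]]:
    """Severity-increasing mutations: (affected component, apply).

    ``apply(case, rng)`` mutates in place and returns False when the
    perturbation does not apply to this case (caller retries another).
    """

    def more_genital_spots(case, rng):
        _bump_spots(case.genital, list(GenitalSite), rng)
        return True

    def more_extragenital_spots(case, rng):
        e = case.extragenital
        _bump_spots(e, list(ExtragenitalSite), rng)
        if e.max_depth_mm is None:
            e.max_depth_mm = round(rng.uniform(0.5, 5), 1)
        return True

    def thicker_wall(case, rng):
        walls = [w for w in case.adenomyosis.walls
                 if w.affected and w.thickness_mm is not None]
        if not walls:
            return False
        rng.choice(walls).thickness_mm += round(rng.uniform(0.5, 20), 1)
        return True

    def thicker_jz(case, rng):
        a = case.adenomyosis
        if a.jz_max_mm is None:
            return False
        a.jz_max_mm += round(rng.uniform(0.5, 6), 1)
        return True

    def wider_jz_extent(case, rng):
        a = case.adenomyosis
        if a.jz_max_mm is None or a.jz_diffuse_extent_pct is None:
            return False
        a.jz_diffuse_extent_pct = min(
            100.0, a.jz_diffuse_extent_pct + round(rng.uniform(1, 40), 1))
        return True

    def bigger_lesion(case, rng):
        lesions = case.adenomyosis.focal_lesions_mm
        if not lesions:
            return False
        i = rng.randrange(len(lesions))
        lesions[i] += round(rng.uniform(0.5, 15), 1)
        return True

    def deeper_penetration(case, rng):
        e = case.extragenital
        if e.max_depth_mm is None:
            e.max_depth_mm = 0.0
        e.max_depth_mm += round(rng.uniform(0.5, 8), 1)
        return True

    def worse_adhesions(case, rng):
        order = [AdhesionGrade.NONE, AdhesionGrade.FILMY, AdhesionGrade.DENSE]
        i = order.index(case.genital.adhesions)
        if i == len(order) - 1:
            return False
        case.genital.adhesions = order[i + 1]
        return True

    def worse_culdesac(case, rng):
        order = [CuldesacObliteration.NONE, CuldesacObliteration.PARTIAL,
                 CuldesacObliteration.COMPLETE]
        i = order.index(case.extragenital.culdesac)
        if i == len(order) - 1:
            return False
        case.extragenital.culdesac = order[i + 1]
        return True

    def bigger_endometrioma(case, rng):
        endos = case.genital.endometriomas
        if not endos:
            return False
        rng.choice(endos).diameter_mm += round(rng.uniform(0.5, 25), 1)
        return True

    return [
        ("G", more_genital_spots),
        ("E", more_extragenital_spots),
        ("A", thicker_wall),
        ("A", thicker_jz),
        ("A", wider_jz_extent),
        ("A", bigger_lesion),
        ("E", deeper_penetration),
        ("G", worse_adhesions),
        ("E", worse_culdesac),
        ("G", bigger_endometrioma),
    ]


def monotonicity_violations(seed: int, n_pairs: int) -> tuple[int, int]:
    """Apply random severity-increasing perturbations; count stage drops."""
    rng = random.Random(seed)
    perturbations = _perturbations()
    base_cases = _random_cases(seed + 1, n_pairs)
    failures = 0
    checked = 0
    for case in base_cases:
        before = classify_case(case)[0]
        mutated = copy.deepcopy(case)
        component = None
        order = rng.sample(perturbations, len(perturbations))
        for comp, apply in order:  # some (e.g. more spots) always apply
            if apply(mutated, rng):
                component = comp
                break
        assert component is not None
        after = classify_case(mutated)[0]
        checked += 1
        key = component.lower()
        if getattr(after, key) < getattr(before, key):
            failures += 1
    return failures, checked


# --------------------------------------------------------------------------
# Supersession
# --------------------------------------------------------------------------

def _supersession_triggers() -> list[tuple[str, Callable]]:
    def dense(case, rng):
        case.genital.adhesions = AdhesionGrade.DENSE

    def bilateral(case, rng):
        case.genital.endometriomas += [
            Endometrioma(Side.LEFT, round(rng.uniform(5, 30), 1)),
            Endometrioma(Side.RIGHT, round(rng.uniform(5, 30), 1))]

    def large_endometrioma(case, rng):
        side = rng.choice((Side.LEFT, Side.RIGHT))
        case.genital.endometriomas.append(
            Endometrioma(side, round(rng.uniform(30.5, 70), 1)))

    def deep(case, rng):
        case.extragenital.max_depth_mm = round(rng.uniform(5.5, 15), 1)

    def invasion(case, rng):
        e = case.extragenital
        if sum(e.spots_by_site.values()) == 0:
            e.spots_by_site[ExtragenitalSite.BOWEL] = 1
        if e.max_depth_mm is None:
            e.max_depth_mm = round(rng.uniform(0.5, 5), 1)
        e.invasion = rng.choice((InvasionLayer.MUSCULARIS,
                                 InvasionLayer.MUCOSAL))

    def culdesac(case, rng):
        case.extragenital.culdesac = rng.choice(
            (CuldesacObliteration.PARTIAL, CuldesacObliteration.COMPLETE))

    def frozen(case, rng):
        case.extragenital.frozen_pelvis = rng.choice(
            (FrozenPelvis.ANTERIOR, FrozenPelvis.POSTERIOR))

    def dysfunction(case, rng):
        case.extragenital.organ_dysfunction.append(
            OrganDysfunction("bowel", rng.choice(list(DysfunctionKind))))

    return [("G", dense), ("G", bilateral), ("G", large_endometrioma),
            ("E", deep), ("E", invasion), ("E", culdesac), ("E", frozen),
            ("E", dysfunction)]


def supersession_violations(seed: int,
                            contexts_per_trigger: int) -> tuple[int, int]:
    """Each Stage-IV trigger, applied to random contexts, must force its
    component to stage 4."""
    rng = random.Random(seed)
    failures = 0
    n = 0
    for i, (component, apply) in enumerate(_supersession_triggers()):
        contexts = _random_cases(seed + 100 + i, contexts_per_trigger)
        for case in contexts:
            mutated = copy.deepcopy(case)
            apply(mutated, rng)
            code = classify_case(mutated)[0]
            n += 1
            if getattr(code, component.lower()) != Stage.IV:
                failures += 1
    return failures, n


# --------------------------------------------------------------------------
# Inversion, round-trips
# --------------------------------------------------------------------------

def inversion_mismatches(seed: int, per_triple: int) -> tuple[int, int]:
    """Targeted generation over all 125 (A, G, E) triples must classify
    back to the target."""
    from .synth import _build_case  # internal builder, one rng for the run

    rng = random.Random(seed)
    failures = 0
    n = 0
    for target in itertools.product(range(5), repeat=3):
        for k in range(per_triple):
            case = _build_case(rng, target, f"INV-{target}-{k}", seed)
            code = classify_case(case)[0]
            n += 1
            if (int(code.a), int(code.g), int(code.e)) != target:
                failures += 1
    return failures, n


def code_roundtrip_failures() -> tuple[int, int]:
    """parse(format(code)) identity over the full 5x5x5 code grid, plus
    tolerant lower-case compact parsing."""
    failures = 0
    n = 0
    for a, g, e in itertools.product(Stage, repeat=3):
        code = AgcesCode(a, g, e)
        n += 1
        if parse_code(format_code(code)) != code:
            failures += 1
        compact = f"a{int(a)}g{int(g)}e{int(e)}"
        if parse_code(compact) != code:
            failures += 1
    return failures, n


def json_roundtrip_failures(seed: int, n: int) -> tuple[int, int]:
    """save_case -> load_case identity on random cases."""
    failures = 0
    cases = _random_cases(seed, n)
    with tempfile.TemporaryDirectory() as tmp:
        path = Path(tmp) / "case.json"
        for case in cases:
            save_case(case, path)
            if load_case(path) != case:
                failures += 1
    return failures, n


def report_determinism_failures(seed: int, n: int) -> tuple[int, int]:
    """Rendering the same staged case twice must be byte-identical."""
    failures = 0
    for case in _random_cases(seed, n):
        staged = stage_case(case)
        if render_report(staged) != render_report(copy.deepcopy(staged)):
            failures += 1
    return failures, n


def boundary_mismatches() -> tuple[int, int]:
    """Every enumerated boundary case must classify to its documented code."""
    from .synth import boundary_cases_with_expected

    pairs = boundary_cases_with_expected()
    failures = sum(1 for case, expected in pairs
                   if classify_case(case)[0] != expected)
    return failures, len(pairs)
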