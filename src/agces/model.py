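"""Typed data model for AGCES case records.

The AGCES system describes endometriosis burden with three parallel,
independently staged components:

* **A** — adenomyosis, staged from preoperative imaging measurements
  (uterine wall thickening, junctional-zone thickening, focal lesions);
* **G** — genital endometriosis (uterine serosa, ovaries, tubes, cervix,
  vulva, vagina), staged from intraoperative findings;
* **E** — extragenital endometriosis (bladder, inguinal canal, pelvic
  sidewall, ureter, nerve, rectovaginal space, bowel, appendix, diaphragm,
  lung, other), staged from intraoperative findings.

Each component carries an ordinal stage. Stages 1–4 are the published
minimal/mild/moderate/severe bands; stage 0 is emitted when no staging
criterion of any band fires for that component, so that absence of disease
is never conflated with minimal disease.

All lengths are millimetres; extents are percent of the uterus in [0, 100].
Validation is non-throwing: :func:`validate_case` returns a list of
:class:`Violation` descriptors, empty iff the record satisfies every
invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Any, Optional


class Stage(IntEnum):
    """Ordinal component stage: 0 = component absent, 1–4 = minimal…severe."""

    ABSENT = 0
    I = 1
    II = 2
    III = 3
    IV = 4

    def __str__(self) -> str:  # "A3" style formatting wants the digit
        return str(int(self))


class WallLocation(str, Enum):
    """Uterine wall measured on imaging."""

    ANTERIOR = "anterior"
    POSTERIOR = "posterior"
    FUNDAL = "fundal"
    LATERAL_LEFT = "lateral_left"
    LATERAL_RIGHT = "lateral_right"


class GenitalSite(str, Enum):
    """Genital sites, in the anatomical reporting order."""

    UTERINE_SEROSA = "uterine_serosa"
    OVARY_LEFT = "ovary_left"
    OVARY_RIGHT = "ovary_right"
    TUBE_LEFT = "tube_left"
    TUBE_RIGHT = "tube_right"
    CERVIX = "cervix"
    VULVA = "vulva"
    VAGINA = "vagina"


class ExtragenitalSite(str, Enum):
    """Extragenital sites, in the anatomical reporting order."""

    BLADDER = "bladder"
    INGUINAL_CANAL = "inguinal_canal"
    PELVIC_SIDEWALL = "pelvic_sidewall"
    URETER = "ureter"
    NERVE = "nerve"
    RECTOVAGINAL_SPACE = "rectovaginal_space"
    BOWEL = "bowel"
    APPENDIX = "appendix"
    DIAPHRAGM = "diaphragm"
    LUNG = "lung"
    OTHER = "other"


class AdhesionGrade(str, Enum):
    """Filmy (thin, avascular, bluntly separable) vs dense (thick, vascular,
    requiring sharp dissection) pelvic adhesions; dense forces genital
    Stage IV."""

    NONE = "none"
    FILMY = "filmy"
    DENSE = "dense"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class InvasionLayer(str, Enum):
    """Deepest anatomical layer reached by an extragenital lesion."""

    NONE = "none"
    PERITONEAL = "peritoneal"
    MUSCULARIS = "muscularis"
    MUCOSAL = "mucosal"


class CuldesacObliteration(str, Enum):
    """Pouch-of-Douglas obliteration; any obliteration forces extragenital
    Stage IV."""

    NONE = "none"
    PARTIAL = "partial"
    COMPLETE = "complete"


class FrozenPelvis(str, Enum):
    """Dense fibrotic tethering of pelvic organs; either compartment forces
    extragenital Stage IV."""

    NONE = "none"
    ANTERIOR = "anterior"
    POSTERIOR = "posterior"


class DysfunctionKind(str, Enum):
    URETERAL_OBSTRUCTION = "ureteral_obstruction"
    BOWEL_OBSTRUCTION = "bowel_obstruction"
    OTHER_COMPROMISE = "other_compromise"


@dataclass
class WallFinding:
    """One measured uterine wall.

    ``affected`` is the observer's explicit judgement; the engine never
    infers involvement from a thickness cutoff. An affected wall must carry
    a thickness measurement.
    """

    location: WallLocation
    thickness_mm: Optional[float] = None
    affected: bool = True


@dataclass
class AdenomyosisFindings:
    """Imaging findings for the adenomyosis (A) component.

    ``jz_max_mm`` is the maximum measured junctional-zone thickness;
    ``jz_diffuse_extent_pct`` the diffusely thickened fraction of the
    uterus. The two are reported as a pair: extent must accompany a JZ
    measurement, and a positive extent requires a JZ measurement.
    """

    walls: list[WallFinding] = field(default_factory=list)
    globally_enlarged: bool = False
    jz_max_mm: Optional[float] = None
    jz_diffuse_extent_pct: Optional[float] = None
    focal_lesions_mm: list[float] = field(default_factory=list)


@dataclass
class Endometrioma:
    side: Side
    diameter_mm: float


@dataclass
class GenitalFindings:
    """Intraoperative findings for the genital (G) component.

    Spot counts are per site; staging uses the total across sites.
    Clustered implants are counted as supplied by the observer.
    """

    spots_by_site: dict[GenitalSite, int] = field(default_factory=dict)
    adhesions: AdhesionGrade = AdhesionGrade.NONE
    endometriomas: list[Endometrioma] = field(default_factory=list)


@dataclass
class OrganDysfunction:
    organ: str
    kind: DysfunctionKind


@dataclass
class ExtragenitalFindings:
    """Intraoperative findings for the extragenital (E) component.

    ``max_depth_mm`` is the maximum depth of penetration beneath the
    peritoneal surface and is required whenever any spot is recorded;
    muscularis/mucosal invasion likewise presupposes a recorded lesion.
    """

    spots_by_site: dict[ExtragenitalSite, int] = field(default_factory=dict)
    max_depth_mm: Optional[float] = None
    invasion: InvasionLayer = InvasionLayer.NONE
    culdesac: CuldesacObliteration = CuldesacObliteration.NONE
    frozen_pelvis: FrozenPelvis = FrozenPelvis.NONE
    organ_dysfunction: list[OrganDysfunction] = field(default_factory=list)


@dataclass
class CaseRecord:
    """The complete structured findings for one patient encounter.

    All three component groups are always present; an empty group means
    "no findings", which stages to 0.
    """

    case_id: str
    adenomyosis: AdenomyosisFindings = field(default_factory=AdenomyosisFindings)
    genital: GenitalFindings = field(default_factory=GenitalFindings)
    extragenital: ExtragenitalFindings = field(default_factory=ExtragenitalFindings)
    metadata: Optional[dict[str, Any]] = None


@dataclass(frozen=True)
class AgcesCode:
    """The (A, G, E) stage triple; canonical string form ``"A{a} G{g} E{e}"``."""

    a: Stage
    g: Stage
    e: Stage

    def __str__(self) -> str:
        return f"A{int(self.a)} G{int(self.g)} E{int(self.e)}"


@dataclass
class RuleTrace:
    """Audit record of which staging criteria fired for one component.

    ``fired_criteria`` holds stable criterion identifiers (documented in
    docs/case_schema.md); the component stage equals the maximum stage among
    them (0 with an empty list). ``superseded`` is true when a Stage-IV
    supersession rule overrode the spot-count bands (G and E only).
    """

    component: str  # "A" | "G" | "E"
    stage: Stage
    fired_criteria: list[str] = field(default_factory=list)
    superseded: bool = False


@dataclass(frozen=True)
class Violation:
    """One broken invariant: the offending field, the rule, and the value."""

    field: str
    rule: str
    value: Any

    def __str__(self) -> str:
        return f"{self.field}: {self.rule} (got {self.value!r})"


def _is_count(x: Any) -> bool:
    return isinstance(x, int) and not isinstance(x, bool)


def _validate_adenomyosis(a: AdenomyosisFindings, out: list[Violation]) -> None:
    seen: set[WallLocation] = set()
    for i, w in enumerate(a.walls):
        path = f"adenomyosis.walls[{i}]"
        if w.location in seen:
            out.append(Violation(f"{path}.location",
                                 "at most one wall finding per location",
                                 w.location.value))
        seen.add(w.location)
        if w.thickness_mm is not None and w.thickness_mm < 0:
            out.append(Violation(f"{path}.thickness_mm",
                                 "thickness must be non-negative", w.thickness_mm))
        if w.affected and w.thickness_mm is None:
            out.append(Violation(f"{path}.thickness_mm",
                                 "affected wall must carry a thickness measurement",
                                 None))
    if a.jz_max_mm is not None:
        if a.jz_max_mm < 0:
            out.append(Violation("adenomyosis.jz_max_mm",
                                 "JZ max must be non-negative", a.jz_max_mm))
        if a.jz_diffuse_extent_pct is None:
            out.append(Violation("adenomyosis.jz_diffuse_extent_pct",
                                 "diffuse JZ extent must accompany a JZ max measurement",
                                 None))
    if a.jz_diffuse_extent_pct is not None:
        if not 0 <= a.jz_diffuse_extent_pct <= 100:
            out.append(Violation("adenomyosis.jz_diffuse_extent_pct",
                                 "extent must lie in [0, 100] percent",
                                 a.jz_diffuse_extent_pct))
        if a.jz_diffuse_extent_pct > 0 and a.jz_max_mm is None:
            out.append(Violation("adenomyosis.jz_max_mm",
                                 "positive diffuse JZ extent requires a JZ max measurement",
                                 None))
    for i, d in enumerate(a.focal_lesions_mm):
        if not d > 0:
            out.append(Violation(f"adenomyosis.focal_lesions_mm[{i}]",
                                 "lesion diameter must be positive", d))


def _validate_genital(g: GenitalFindings, out: list[Violation]) -> None:
    for site, n in g.spots_by_site.items():
        if not _is_count(n) or n < 0:
            out.append(Violation(f"genital.spots_by_site.{site.value}",
                                 "spot count must be a non-negative integer", n))
    for i, m in enumerate(g.endometriomas):
        if not m.diameter_mm > 0:
            out.append(Violation(f"genital.endometriomas[{i}].diameter_mm",
                                 "endometrioma diameter must be positive",
                                 m.diameter_mm))


def _validate_extragenital(e: ExtragenitalFindings, out: list[Violation]) -> None:
    total = 0
    for site, n in e.spots_by_site.items():
        if not _is_count(n) or n < 0:
            out.append(Violation(f"extragenital.spots_by_site.{site.value}",
                                 "spot count must be a non-negative integer", n))
        elif n > 0:
            total += n
    if e.max_depth_mm is not None and e.max_depth_mm < 0:
        out.append(Violation("extragenital.max_depth_mm",
                             "depth must be non-negative", e.max_depth_mm))
    if total > 0 and e.max_depth_mm is None:
        out.append(Violation("extragenital.max_depth_mm",
                             "depth of penetration required when spots are recorded",
                             None))
    if e.invasion in (InvasionLayer.MUSCULARIS, InvasionLayer.MUCOSAL) and total == 0:
        out.append(Violation("extragenital.invasion",
                             "muscularis/mucosal invasion requires at least one recorded lesion",
                             e.invasion.value))


def validate_case(case: CaseRecord) -> list[Violation]:
    """Check every model invariant; return violations instead of raising.

    An empty list means the record is valid. Each violation names the
    offending field (dotted path), the rule broken, and the value found.
    """
    out: list[Violation] = []
    _validate_adenomyosis(case.adenomyosis, out)
    _validate_genital(case.genital, out)
    _validate_extragenital(case.extragenital, out)
    return out
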