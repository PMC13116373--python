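"""Case file I/O: strict JSON case documents and flat CSV batches.

The JSON schema is closed — unknown keys are rejected with an error naming
the key — so that clinical documents stay auditable, and it is versioned
through a top-level ``schema_version`` key so future criterion revisions
can be gated. The CSV dialect is one row per case with flat columns
(``wall_anterior_mm``, per-site spot counts, semicolon-separated list
cells); an empty cell means the finding is absent. Both are documented in
docs/case_schema.md.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

from .engine import ENGINE_VERSION, classify_case, format_code
from .errors import BatchParseError, SchemaError
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
    RuleTrace,
    Side,
    Stage,
    WallFinding,
    WallLocation,
)

SCHEMA_VERSION = "1"

PathLike = Union[str, Path]


@dataclass
class StagedCase:
    """A case together with its classification and audit trail.

    The stored code must be reproducible from the case by re-running the
    engine; :func:`verify_staged` checks exactly that.
    """

    case: CaseRecord
    code: AgcesCode
    traces: list[RuleTrace] = field(default_factory=list)
    engine_version: str = ENGINE_VERSION


def stage_case(case: CaseRecord) -> StagedCase:
    """Classify a case and package the result for reporting/serialization."""
    code, traces = classify_case(case)
    return StagedCase(case=case, code=code, traces=traces)


def verify_staged(staged: StagedCase) -> bool:
    """True iff re-running the engine reproduces the stored code."""
    code, _ = classify_case(staged.case)
    return code == staged.code


# --------------------------------------------------------------------------
# JSON case documents
# --------------------------------------------------------------------------

def case_to_dict(case: CaseRecord) -> dict[str, Any]:
    a, g, e = case.adenomyosis, case.genital, case.extragenital
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "case_id": case.case_id,
        "adenomyosis": {
            "walls": [
                {"location": w.location.value,
                 "thickness_mm": w.thickness_mm,
                 "affected": w.affected}
                for w in a.walls
            ],
            "globally_enlarged": a.globally_enlarged,
            "jz_max_mm": a.jz_max_mm,
            "jz_diffuse_extent_pct": a.jz_diffuse_extent_pct,
            "focal_lesions_mm": list(a.focal_lesions_mm),
        },
        "genital": {
            "spots_by_site": {s.value: n for s, n in g.spots_by_site.items()},
            "adhesions": g.adhesions.value,
            "endometriomas": [
                {"side": m.side.value, "diameter_mm": m.diameter_mm}
                for m in g.endometriomas
            ],
        },
        "extragenital": {
            "spots_by_site": {s.value: n for s, n in e.spots_by_site.items()},
            "max_depth_mm": e.max_depth_mm,
            "invasion": e.invasion.value,
            "culdesac": e.culdesac.value,
            "frozen_pelvis": e.frozen_pelvis.value,
            "organ_dysfunction": [
                {"organ": d.organ, "kind": d.kind.value}
                for d in e.organ_dysfunction
            ],
        },
    }
    if case.metadata is not None:
        doc["metadata"] = case.metadata
    return doc


def _reject_unknown(d: dict, allowed: set[str], where: str) -> None:
    for key in d:
        if key not in allowed:
            raise SchemaError(f"unknown key {key!r} in {where}")


def _opt_number(d: dict, key: str, where: str) -> Optional[float]:
    v = d.get(key)
    if v is None:
        return None
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise SchemaError(f"{where}.{key} must be a number, got {v!r}")
    return float(v)


def _bool(d: dict, key: str, where: str, default: bool = False) -> bool:
    v = d.get(key, default)
    if not isinstance(v, bool):
        raise SchemaError(f"{where}.{key} must be a boolean, got {v!r}")
    return v


def _enum(enum_cls, value, where: str):
    try:
        return enum_cls(value)
    except ValueError:
        allowed = ", ".join(m.value for m in enum_cls)
        raise SchemaError(
            f"{where}: {value!r} is not one of ({allowed})") from None


def _spots(d: dict, site_enum, where: str) -> dict:
    raw = d.get("spots_by_site", {})
    if not isinstance(raw, dict):
        raise SchemaError(f"{where}.spots_by_site must be an object")
    out = {}
    for name, n in raw.items():
        site = _enum(site_enum, name, f"{where}.spots_by_site")
        if isinstance(n, bool) or not isinstance(n, int):
            raise SchemaError(
                f"{where}.spots_by_site.{name} must be an integer, got {n!r}")
        out[site] = n
    return out


def _adenomyosis_from_dict(d: dict) -> AdenomyosisFindings:
    _reject_unknown(d, {"walls", "globally_enlarged", "jz_max_mm",
                        "jz_diffuse_extent_pct", "focal_lesions_mm"},
                    "adenomyosis")
    walls = []
    for i, w in enumerate(d.get("walls", [])):
        where = f"adenomyosis.walls[{i}]"
        _reject_unknown(w, {"location", "thickness_mm", "affected"}, where)
        if "location" not in w:
            raise SchemaError(f"{where} missing required key 'location'")
        walls.append(WallFinding(
            location=_enum(WallLocation, w["location"], f"{where}.location"),
            thickness_mm=_opt_number(w, "thickness_mm", where),
            affected=_bool(w, "affected", where, default=True),
        ))
    lesions = d.get("focal_lesions_mm", [])
    if not isinstance(lesions, list):
        raise SchemaError("adenomyosis.focal_lesions_mm must be an array")
    for x in lesions:
        if isinstance(x, bool) or not isinstance(x, (int, float)):
            raise SchemaError(
                f"adenomyosis.focal_lesions_mm entries must be numbers, got {x!r}")
    return AdenomyosisFindings(
        walls=walls,
        globally_enlarged=_bool(d, "globally_enlarged", "adenomyosis"),
        jz_max_mm=_opt_number(d, "jz_max_mm", "adenomyosis"),
        jz_diffuse_extent_pct=_opt_number(d, "jz_diffuse_extent_pct",
                                          "adenomyosis"),
        focal_lesions_mm=[float(x) for x in lesions],
    )


def _genital_from_dict(d: dict) -> GenitalFindings:
    _reject_unknown(d, {"spots_by_site", "adhesions", "endometriomas"},
                    "genital")
    endometriomas = []
    for i, m in enumerate(d.get("endometriomas", [])):
        where = f"genital.endometriomas[{i}]"
        _reject_unknown(m, {"side", "diameter_mm"}, where)
        if "side" not in m or "diameter_mm" not in m:
            raise SchemaError(f"{where} requires 'side' and 'diameter_mm'")
        diameter = _opt_number(m, "diameter_mm", where)
        if diameter is None:
            raise SchemaError(f"{where}.diameter_mm must be a number")
        endometriomas.append(Endometrioma(
            side=_enum(Side, m["side"], f"{where}.side"),
            diameter_mm=diameter,
        ))
    return GenitalFindings(
        spots_by_site=_spots(d, GenitalSite, "genital"),
        adhesions=_enum(AdhesionGrade, d.get("adhesions", "none"),
                        "genital.adhesions"),
        endometriomas=endometriomas,
    )


def _extragenital_from_dict(d: dict) -> ExtragenitalFindings:
    _reject_unknown(d, {"spots_by_site", "max_depth_mm", "invasion",
                        "culdesac", "frozen_pelvis", "organ_dysfunction"},
                    "extragenital")
    dysfunction = []
    for i, od in enumerate(d.get("organ_dysfunction", [])):
        where = f"extragenital.organ_dysfunction[{i}]"
        _reject_unknown(od, {"organ", "kind"}, where)
        if "kind" not in od:
            raise SchemaError(f"{where} missing required key 'kind'")
        organ = od.get("organ", "")
        if not isinstance(organ, str):
            raise SchemaError(f"{where}.organ must be a string")
        dysfunction.append(OrganDysfunction(
            organ=organ,
            kind=_enum(DysfunctionKind, od["kind"], f"{where}.kind"),
        ))
    return ExtragenitalFindings(
        spots_by_site=_spots(d, ExtragenitalSite, "extragenital"),
        max_depth_mm=_opt_number(d, "max_depth_mm", "extragenital"),
        invasion=_enum(InvasionLayer, d.get("invasion", "none"),
                       "extragenital.invasion"),
        culdesac=_enum(CuldesacObliteration, d.get("culdesac", "none"),
                       "extragenital.culdesac"),
        frozen_pelvis=_enum(FrozenPelvis, d.get("frozen_pelvis", "none"),
                            "extragenital.frozen_pelvis"),
        organ_dysfunction=dysfunction,
    )


def case_from_dict(doc: dict[str, Any]) -> CaseRecord:
    """Build a CaseRecord from a JSON document; strict (unknown keys fail)."""
    if not isinstance(doc, dict):
        raise SchemaError("case document must be a JSON object")
    _reject_unknown(doc, {"schema_version", "case_id", "adenomyosis",
                          "genital", "extragenital", "metadata"}, "case")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"unknown schema_version {version!r} (this reader handles "
            f"{SCHEMA_VERSION!r})")
    for group in ("case_id", "adenomyosis", "genital", "extragenital"):
        if group not in doc:
            raise SchemaError(f"case document missing required key {group!r}")
    metadata = doc.get("metadata")
    if metadata is not None and not isinstance(metadata, dict):
        raise SchemaError("metadata must be an object")
    return CaseRecord(
        case_id=str(doc["case_id"]),
        adenomyosis=_adenomyosis_from_dict(doc["adenomyosis"]),
        genital=_genital_from_dict(doc["genital"]),
        extragenital=_extragenital_from_dict(doc["extragenital"]),
        metadata=metadata,
    )


def load_case(path: PathLike) -> CaseRecord:
    """Read one JSON case document (strict schema)."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON in {path}: {exc}") from None
    return case_from_dict(doc)


def save_case(case: CaseRecord, path: PathLike) -> None:
    """Write one JSON case document (lossless round-trip with load_case)."""
    Path(path).write_text(
        json.dumps(case_to_dict(case), indent=2) + "\n", encoding="utf-8")


def save_cases(cases: list[CaseRecord], path: PathLike) -> None:
    """Write several cases as a JSON array of case documents."""
    Path(path).write_text(
        json.dumps([case_to_dict(c) for c in cases], indent=2) + "\n",
        encoding="utf-8")


def load_cases(path: PathLike) -> list[CaseRecord]:
    """Read a JSON array of case documents."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        docs = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON in {path}: {exc}") from None
    if not isinstance(docs, list):
        raise SchemaError("multi-case document must be a JSON array")
    return [case_from_dict(d) for d in docs]


def staged_to_dict(staged: StagedCase) -> dict[str, Any]:
    return {
        "schema_version": SCHEMA_VERSION,
        "case": case_to_dict(staged.case),
        "code": format_code(staged.code),
        "stages": {"a": int(staged.code.a), "g": int(staged.code.g),
                   "e": int(staged.code.e)},
        "traces": [
            {"component": t.component, "stage": int(t.stage),
             "fired_criteria": list(t.fired_criteria),
             "superseded": t.superseded}
            for t in staged.traces
        ],
        "engine_version": staged.engine_version,
    }


def save_staged(staged: StagedCase, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps(staged_to_dict(staged), indent=2) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# CSV batches
# --------------------------------------------------------------------------

_WALL_COLUMNS = {f"wall_{loc.value}_mm": loc for loc in WallLocation}
_GENITAL_SPOT_COLUMNS = {f"genital_spots_{s.value}": s for s in GenitalSite}
_EXTRAGENITAL_SPOT_COLUMNS = {
    f"extragenital_spots_{s.value}": s for s in ExtragenitalSite}

CSV_COLUMNS: list[str] = (
    ["case_id"]
    + list(_WALL_COLUMNS)
    + ["globally_enlarged", "jz_max_mm", "jz_diffuse_extent_pct",
       "focal_lesions_mm"]
    + list(_GENITAL_SPOT_COLUMNS)
    + ["adhesions", "endometriomas"]
    + list(_EXTRAGENITAL_SPOT_COLUMNS)
    + ["max_depth_mm", "invasion", "culdesac", "frozen_pelvis",
       "organ_dysfunction"]
)

STAGED_COLUMNS = ["stage_a", "stage_g", "stage_e", "agces_code",
                  "fired_criteria"]


def _fmt_num(x: Optional[float]) -> str:
    if x is None:
        return ""
    if isinstance(x, float) and x.is_integer():
        return str(int(x))
    return f"{x:g}"


def case_to_row(case: CaseRecord) -> dict[str, str]:
    a, g, e = case.adenomyosis, case.genital, case.extragenital
    row = {col: "" for col in CSV_COLUMNS}
    row["case_id"] = case.case_id
    for w in a.walls:
        if w.affected:
            row[f"wall_{w.location.value}_mm"] = _fmt_num(w.thickness_mm)
    row["globally_enlarged"] = "true" if a.globally_enlarged else ""
    row["jz_max_mm"] = _fmt_num(a.jz_max_mm)
    row["jz_diffuse_extent_pct"] = _fmt_num(a.jz_diffuse_extent_pct)
    row["focal_lesions_mm"] = ";".join(_fmt_num(d) for d in a.focal_lesions_mm)
    for site, n in g.spots_by_site.items():
        if n:
            row[f"genital_spots_{site.value}"] = str(n)
    row["adhesions"] = "" if g.adhesions is AdhesionGrade.NONE else g.adhesions.value
    row["endometriomas"] = ";".join(
        f"{m.side.value}:{_fmt_num(m.diameter_mm)}" for m in g.endometriomas)
    for site, n in e.spots_by_site.items():
        if n:
            row[f"extragenital_spots_{site.value}"] = str(n)
    row["max_depth_mm"] = _fmt_num(e.max_depth_mm)
    row["invasion"] = "" if e.invasion is InvasionLayer.NONE else e.invasion.value
    row["culdesac"] = "" if e.culdesac is CuldesacObliteration.NONE else e.culdesac.value
    row["frozen_pelvis"] = ("" if e.frozen_pelvis is FrozenPelvis.NONE
                            else e.frozen_pelvis.value)
    row["organ_dysfunction"] = ";".join(
        f"{d.organ}:{d.kind.value}" for d in e.organ_dysfunction)
    return row


class _RowReader:
    """Parses one CSV row with row/column-addressed errors."""

    def __init__(self, row: dict[str, str], line: int):
        self.row = row
        self.line = line

    def _cell(self, column: str) -> str:
        return (self.row.get(column) or "").strip()

    def number(self, column: str) -> Optional[float]:
        cell = self._cell(column)
        if not cell:
            return None
        try:
            return float(cell)
        except ValueError:
            raise BatchParseError(self.line, column,
                                  f"not a number: {cell!r}") from None

    def count(self, column: str) -> int:
        cell = self._cell(column)
        if not cell:
            return 0
        try:
            return int(cell)
        except ValueError:
            raise BatchParseError(self.line, column,
                                  f"not an integer: {cell!r}") from None

    def flag(self, column: str) -> bool:
        cell = self._cell(column).lower()
        if cell in ("", "false", "0", "no"):
            return False
        if cell in ("true", "1", "yes"):
            return True
        raise BatchParseError(self.line, column, f"not a boolean: {cell!r}")

    def choice(self, column: str, enum_cls, default):
        cell = self._cell(column)
        if not cell:
            return default
        try:
            return enum_cls(cell.lower())
        except ValueError:
            allowed = ", ".join(m.value for m in enum_cls)
            raise BatchParseError(
                self.line, column,
                f"{cell!r} is not one of ({allowed})") from None

    def number_list(self, column: str) -> list[float]:
        cell = self._cell(column)
        if not cell:
            return []
        out = []
        for part in cell.split(";"):
            try:
                out.append(float(part.strip()))
            except ValueError:
                raise BatchParseError(self.line, column,
                                      f"not a number: {part.strip()!r}") from None
        return out

    def pair_list(self, column: str) -> list[tuple[str, str]]:
        cell = self._cell(column)
        if not cell:
            return []
        out = []
        for part in cell.split(";"):
            if ":" not in part:
                raise BatchParseError(self.line, column,
                                      f"expected 'key:value', got {part.strip()!r}")
            k, v = part.split(":", 1)
            out.append((k.strip(), v.strip()))
        return out


def row_to_case(row: dict[str, str], line: int) -> CaseRecord:
    r = _RowReader(row, line)
    walls = []
    for column, loc in _WALL_COLUMNS.items():
        thickness = r.number(column)
        if thickness is not None:
            walls.append(WallFinding(location=loc, thickness_mm=thickness,
                                     affected=True))
    genital_spots = {}
    for column, site in _GENITAL_SPOT_COLUMNS.items():
        n = r.count(column)
        if n:
            genital_spots[site] = n
    endometriomas = []
    for side_name, diameter in r.pair_list("endometriomas"):
        try:
            side = Side(side_name.lower())
        except ValueError:
            raise BatchParseError(line, "endometriomas",
                                  f"side must be left/right, got {side_name!r}") from None
        try:
            d = float(diameter)
        except ValueError:
            raise BatchParseError(line, "endometriomas",
                                  f"not a number: {diameter!r}") from None
        endometriomas.append(Endometrioma(side=side, diameter_mm=d))
    extragenital_spots = {}
    for column, site in _EXTRAGENITAL_SPOT_COLUMNS.items():
        n = r.count(column)
        if n:
            extragenital_spots[site] = n
    dysfunction = []
    for organ, kind_name in r.pair_list("organ_dysfunction"):
        try:
            kind = DysfunctionKind(kind_name.lower())
        except ValueError:
            allowed = ", ".join(m.value for m in DysfunctionKind)
            raise BatchParseError(line, "organ_dysfunction",
                                  f"{kind_name!r} is not one of ({allowed})") from None
        dysfunction.append(OrganDysfunction(organ=organ, kind=kind))
    return CaseRecord(
        case_id=(row.get("case_id") or "").strip() or f"row-{line}",
        adenomyosis=AdenomyosisFindings(
            walls=walls,
            globally_enlarged=r.flag("globally_enlarged"),
            jz_max_mm=r.number("jz_max_mm"),
            jz_diffuse_extent_pct=r.number("jz_diffuse_extent_pct"),
            focal_lesions_mm=r.number_list("focal_lesions_mm"),
        ),
        genital=GenitalFindings(
            spots_by_site=genital_spots,
            adhesions=r.choice("adhesions", AdhesionGrade, AdhesionGrade.NONE),
            endometriomas=endometriomas,
        ),
        extragenital=ExtragenitalFindings(
            spots_by_site=extragenital_spots,
            max_depth_mm=r.number("max_depth_mm"),
            invasion=r.choice("invasion", InvasionLayer, InvasionLayer.NONE),
            culdesac=r.choice("culdesac", CuldesacObliteration,
                              CuldesacObliteration.NONE),
            frozen_pelvis=r.choice("frozen_pelvis", FrozenPelvis,
                                   FrozenPelvis.NONE),
            organ_dysfunction=dysfunction,
        ),
    )


def load_batch(path: PathLike) -> list[CaseRecord]:
    """Read a CSV batch; row order preserved.

    The header is mandatory. The five staging columns written by
    :func:`save_staged_batch` are recognized and ignored, so a staged
    output file can be re-loaded and re-staged directly.
    """
    known = set(CSV_COLUMNS) | set(STAGED_COLUMNS)
    cases = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise BatchParseError(1, "", "missing header row")
        for name in reader.fieldnames:
            if name not in known:
                raise BatchParseError(1, name, "unknown column")
        for row in reader:
            cases.append(row_to_case(row, reader.line_num))
    return cases


def save_batch(cases: list[CaseRecord], path: PathLike) -> None:
    """Write unstaged cases as a CSV batch."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for case in cases:
            writer.writerow(case_to_row(case))


def save_staged_batch(staged: list[StagedCase], path: PathLike) -> None:
    """Write staged cases: the case columns plus stage_a/g/e, the code, and
    the fired criteria (semicolon-joined across components)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS + STAGED_COLUMNS)
        writer.writeheader()
        for s in staged:
            row = case_to_row(s.case)
            row["stage_a"] = str(int(s.code.a))
            row["stage_g"] = str(int(s.code.g))
            row["stage_e"] = str(int(s.code.e))
            row["agces_code"] = format_code(s.code)
            row["fired_criteria"] = ";".join(
                c for t in s.traces for c in t.fired_criteria)
            writer.writerow(row)
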