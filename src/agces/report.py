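"""Standardized operative report rendering.

Produces a deterministic Markdown document with three sections mirroring
the operative worksheet — genital mapping per site, extragenital assessment
per site, adenomyosis evaluation — followed by the classification and the
fired criteria. Sites appear in the fixed anatomical order of the model
enums, only where findings are non-zero; numbers use fixed decimal
formatting, so identical input yields byte-identical output.
"""

from __future__ import annotations

from .case_io import StagedCase
from .model import (
    AdhesionGrade,
    CuldesacObliteration,
    ExtragenitalSite,
    FrozenPelvis,
    GenitalSite,
    InvasionLayer,
)

_COMPONENT_NAMES = {"A": "Adenomyosis", "G": "Genital endometriosis",
                    "E": "Extragenital endometriosis"}


def _num(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return f"{x:g}"


def _label(value: str) -> str:
    return value.replace("_", " ")


def render_report(staged: StagedCase) -> str:
    """Render the operative report for a staged case as Markdown text."""
    case = staged.case
    a, g, e = case.adenomyosis, case.genital, case.extragenital
    lines: list[str] = []
    w = lines.append

    w("# AGCES operative report")
    w("")
    w(f"Case: {case.case_id}")
    w("")

    w("## Genital endometriosis mapping")
    w("")
    sites = [(s, g.spots_by_site.get(s, 0)) for s in GenitalSite]
    any_genital = False
    for site, n in sites:
        if n > 0:
            w(f"- {_label(site.value)}: {n} spot{'s' if n != 1 else ''}")
            any_genital = True
    if not any_genital:
        w("- No endometriotic spots recorded.")
    w(f"- Adhesions: {g.adhesions.value}")
    if g.endometriomas:
        for m in g.endometriomas:
            w(f"- Endometrioma: {m.side.value} ovary, {_num(m.diameter_mm)} mm")
    else:
        w("- Endometriomas: none")
    w("")

    w("## Extragenital assessment")
    w("")
    any_extr = False
    for site in ExtragenitalSite:
        n = e.spots_by_site.get(site, 0)
        if n > 0:
            w(f"- {_label(site.value)}: {n} spot{'s' if n != 1 else ''}")
            any_extr = True
    if not any_extr:
        w("- No endometriotic spots recorded.")
    if e.max_depth_mm is not None:
        w(f"- Maximum depth of penetration: {_num(e.max_depth_mm)} mm")
    if e.invasion is not InvasionLayer.NONE:
        w(f"- Invasion: {e.invasion.value}")
    w(f"- Cul-de-sac obliteration: {e.culdesac.value}")
    w(f"- Frozen pelvis: {e.frozen_pelvis.value}")
    if e.organ_dysfunction:
        for d in e.organ_dysfunction:
            organ = f"{d.organ}: " if d.organ else ""
            w(f"- Organ dysfunction: {organ}{_label(d.kind.value)}")
    else:
        w("- Organ dysfunction: none")
    w("")

    w("## Adenomyosis evaluation")
    w("")
    affected = [x for x in a.walls if x.affected]
    if affected:
        for wall in affected:
            thickness = (f"{_num(wall.thickness_mm)} mm"
                         if wall.thickness_mm is not None else "not measured")
            w(f"- Wall ({_label(wall.location.value)}): {thickness}")
    else:
        w("- Walls: no affected wall recorded.")
    if a.globally_enlarged:
        w("- Uterus globally enlarged.")
    if a.jz_max_mm is not None:
        extent = (f", diffuse extent {_num(a.jz_diffuse_extent_pct)}% of uterus"
                  if a.jz_diffuse_extent_pct is not None else "")
        w(f"- Junctional zone: max {_num(a.jz_max_mm)} mm{extent}")
    else:
        w("- Junctional zone: not assessed.")
    if a.focal_lesions_mm:
        sizes = ", ".join(f"{_num(d)} mm" for d in a.focal_lesions_mm)
        w(f"- Focal lesions: {sizes}")
    else:
        w("- Focal lesions: none")
    w("")

    w("## Classification")
    w("")
    for t in staged.traces:
        name = _COMPONENT_NAMES.get(t.component, t.component)
        if t.fired_criteria:
            fired = ", ".join(t.fired_criteria)
            extra = " (supersedes spot count)" if t.superseded else ""
            w(f"- {name}: stage {int(t.stage)} — fired: {fired}{extra}")
        else:
            w(f"- {name}: stage 0 — no criterion fired")
    w("")
    w(f"AGCES code: {staged.code}")
    return "\n".join(lines) + "\n"
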