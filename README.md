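# agces

A deterministic staging engine for the **AGCES endometriosis
classification**: structured clinical findings in, a three-component stage
code (`A_ G_ E_`) and a standardized operative report out.

Endometriosis burden is notoriously hard to summarize: existing staging
schemes exclude adenomyosis and conflate genital with extragenital
disease, although the three call for very different surgical planning.
The AGCES framework addresses this by staging three components
independently, each from 1 (minimal) to 4 (severe):

* **A — adenomyosis**, from imaging: diffuse uterine wall thickening,
  junctional-zone (JZ) thickening, and focal lesions; the highest
  sub-scale wins.
* **G — genital endometriosis** (uterine serosa, ovaries, tubes, cervix,
  vulva, vagina), from intraoperative findings: spot count, adhesion
  grade, endometrioma size/laterality.
* **E — extragenital endometriosis** (bladder, inguinal canal, pelvic
  sidewall, ureter, nerve, rectovaginal space, bowel, appendix,
  diaphragm, lung, other): spot count, depth of penetration, cul-de-sac
  obliteration, frozen pelvis, organ dysfunction.

The result is reported as e.g. `A3 G2 E4`. Stage-IV triggers (dense
adhesions; bilateral or > 30 mm endometrioma; depth > 5 mm;
muscularis/mucosal invasion; cul-de-sac obliteration; frozen pelvis;
organ dysfunction) supersede spot counts. This package adds stage 0 for
"component absent", so absence of disease is never reported as minimal
disease.

The package is aimed at surgeons and clinical researchers who need
reproducible, auditable staging: every classification carries a rule
trace naming exactly which published criterion fired, validation is
non-throwing and field-addressed, and all rendering and serialization is
byte-deterministic. An independent flat rule-table oracle, an exhaustive
threshold grid, and a seeded synthetic-case generator make the decision
table fully testable. See `docs/methods.md` for the model and
`docs/case_schema.md` for the JSON/CSV formats and criterion identifiers.

## Worked example

```python
from agces import (CaseRecord, AdenomyosisFindings, GenitalFindings,
                   ExtragenitalFindings, WallFinding, WallLocation,
                   GenitalSite, ExtragenitalSite, classify_case, format_code)

case = CaseRecord(
    case_id="example-001",
    adenomyosis=AdenomyosisFindings(
        walls=[WallFinding(WallLocation.POSTERIOR, thickness_mm=32.0)]),
    genital=GenitalFindings(
        spots_by_site={GenitalSite.OVARY_LEFT: 5,
                       GenitalSite.UTERINE_SEROSA: 3}),
    extragenital=ExtragenitalFindings(
        spots_by_site={ExtragenitalSite.BOWEL: 2}, max_depth_mm=7.0),
)
code, traces = classify_case(case)
print(format_code(code))
for t in traces:
    print(t.component, int(t.stage), t.fired_criteria, t.superseded)
```

prints

```
A3 G2 E4
A 3 ['A.wall.III.one_wall_gt_30mm'] False
G 2 ['G.II.spots_7_10'] False
E 4 ['E.IV.depth_gt_5mm', 'E.I.spots_le_6'] True
```

A 32 mm posterior wall puts adenomyosis in Stage III (one wall > 30 mm);
eight genital spots land in the 7–10 band (Stage II); and although only
two bowel spots are present, 7 mm depth of penetration is deep
infiltrating disease, which supersedes the spot count and forces the
extragenital component to Stage IV (`superseded=True`).

The same classification from the shell, plus the operative report and
batch staging:

```sh
agces stage case.json            # prints: A3 G2 E4
agces report case.json           # Markdown operative report
agces synth -n 100 --seed 12 -o batch.csv
agces batch batch.csv staged.csv # adds stage_a/g/e, agces_code, fired_criteria
agces validate case.json         # field-addressed invariant check
```

Exit codes: 0 success, 2 usage error, 3 validation/schema error, 4 I/O
error.

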