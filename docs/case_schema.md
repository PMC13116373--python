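# Case file formats and criterion identifiers

## JSON case document (schema version `"1"`)

One JSON object per case. The schema is **closed**: any key not listed
below is rejected with an error naming the key, so documents stay
auditable. `schema_version`, `case_id`, and all three finding groups are
required (a group may be `{}`, meaning no findings); `metadata` is an
optional free-form object. All lengths are millimetres (`_mm` suffix),
extents are percent of uterus in [0, 100] (`_pct` suffix).

```json
{
  "schema_version": "1",
  "case_id": "example-001",
  "adenomyosis": {
    "walls": [
      {"location": "anterior", "thickness_mm": 18.0, "affected": true}
    ],
    "globally_enlarged": false,
    "jz_max_mm": 7.0,
    "jz_diffuse_extent_pct": 30.0,
    "focal_lesions_mm": [8.0]
  },
  "genital": {
    "spots_by_site": {"ovary_left": 3, "uterine_serosa": 2},
    "adhesions": "filmy",
    "endometriomas": [{"side": "left", "diameter_mm": 25.0}]
  },
  "extragenital": {
    "spots_by_site": {"bladder": 2},
    "max_depth_mm": 3.0,
    "invasion": "peritoneal",
    "culdesac": "none",
    "frozen_pelvis": "none",
    "organ_dysfunction": []
  },
  "metadata": {"assessment": "TVUS + laparoscopy"}
}
```

Enumerated values:

| field | values |
|---|---|
| `walls[].location` | `anterior`, `posterior`, `fundal`, `lateral_left`, `lateral_right` |
| genital `spots_by_site` keys | `uterine_serosa`, `ovary_left`, `ovary_right`, `tube_left`, `tube_right`, `cervix`, `vulva`, `vagina` |
| `adhesions` | `none`, `filmy`, `dense` |
| `endometriomas[].side` | `left`, `right` |
| extragenital `spots_by_site` keys | `bladder`, `inguinal_canal`, `pelvic_sidewall`, `ureter`, `nerve`, `rectovaginal_space`, `bowel`, `appendix`, `diaphragm`, `lung`, `other` |
| `invasion` | `none`, `peritoneal`, `muscularis`, `mucosal` |
| `culdesac` | `none`, `partial`, `complete` |
| `frozen_pelvis` | `none`, `anterior`, `posterior` |
| `organ_dysfunction[].kind` | `ureteral_obstruction`, `bowel_obstruction`, `other_compromise` |

Model invariants (checked by `validate_case`, returned as a violation
list, never raised during loading): an affected wall carries a thickness;
at most one wall finding per location; `jz_diffuse_extent_pct` accompanies
`jz_max_mm` and a positive extent requires a JZ measurement; lesion and
endometrioma diameters are positive; spot counts are non-negative
integers; `max_depth_mm` is required when any extragenital spot is
recorded; muscularis/mucosal invasion requires a recorded lesion.

A staged case (written by `agces stage -o` / `save_staged`) wraps the case
with `code`, `stages`, per-component `traces`, and `engine_version`.

## CSV batch dialect

UTF-8, comma-delimited, header row mandatory, one row per case, row order
preserved. An empty cell means the finding is absent. List cells are
semicolon-separated. Unknown columns are rejected with the column name;
missing optional columns are treated as all-empty.

Columns, in order: `case_id`; `wall_<location>_mm` (5 columns; a value
means that wall is affected at that thickness); `globally_enlarged`
(true/false); `jz_max_mm`; `jz_diffuse_extent_pct`; `focal_lesions_mm`
(e.g. `8;12.5`); `genital_spots_<site>` (8 columns); `adhesions`;
`endometriomas` (e.g. `left:25;right:40`); `extragenital_spots_<site>`
(11 columns); `max_depth_mm`; `invasion`; `culdesac`; `frozen_pelvis`;
`organ_dysfunction` (e.g. `ureter:ureteral_obstruction`).

Staged output (`agces batch`) appends `stage_a`, `stage_g`, `stage_e`,
`agces_code`, `fired_criteria`. These five columns are recognized and
ignored on load, so a staged file can be re-staged directly.

## Criterion identifiers

`RuleTrace.fired_criteria` uses stable dotted identifiers; the roman
numeral token is the stage the criterion awards.

Adenomyosis (A): `A.wall.I.one_wall_le_20mm`, `A.wall.II.two_walls_le_20mm`,
`A.wall.II.one_wall_20_30mm`, `A.wall.III.one_wall_gt_30mm`,
`A.wall.III.two_walls_20_30mm`, `A.wall.IV.two_walls_gt_30mm`,
`A.wall.IV.global_enlargement`, `A.JZ.I.max_6_8mm_extent_lt_50pct`,
`A.JZ.II.max_gt_8mm_extent_lt_50pct`, `A.JZ.III.extent_50_80pct`,
`A.JZ.IV.extent_ge_80pct`, `A.focal.I.one_lesion_le_10mm`,
`A.focal.II.two_lesions_le_10mm`, `A.focal.II.one_lesion_10_20mm`,
`A.focal.III.two_lesions_10_20mm`, `A.focal.III.one_lesion_gt_20mm`,
`A.focal.IV.two_lesions_gt_20mm`.

Genital (G): `G.I.spots_le_6`, `G.II.spots_7_10`, `G.III.spots_gt_10`,
`G.III.unilateral_endometrioma_le_30mm`, `G.IV.dense_adhesions`,
`G.IV.bilateral_endometriomas`, `G.IV.endometrioma_gt_30mm`.

Extragenital (E): `E.I.spots_le_6`, `E.II.spots_7_10`, `E.III.spots_gt_10`,
`E.IV.depth_gt_5mm`, `E.IV.muscularis_or_mucosal_invasion`,
`E.IV.culdesac_obliteration`, `E.IV.frozen_pelvis`,
`E.IV.organ_dysfunction`.
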