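"""Model invariants: non-throwing validation and violation addressing."""

import pytest

from agces import (
    AdenomyosisFindings,
    Endometrioma,
    ExtragenitalFindings,
    ExtragenitalSite,
    GenitalFindings,
    GenitalSite,
    InvasionLayer,
    Side,
    Stage,
    WallFinding,
    WallLocation,
    validate_case,
)
from conftest import make_case


def test_empty_case_is_valid(empty_case):
    assert validate_case(empty_case) == []


@pytest.mark.parametrize(
    "case, expected_field",
    [
        # JZ measurement without its paired diffuse extent
        (make_case(a=AdenomyosisFindings(jz_max_mm=9)),
         "adenomyosis.jz_diffuse_extent_pct"),
        # positive extent without a JZ measurement
        (make_case(a=AdenomyosisFindings(jz_diffuse_extent_pct=40)),
         "adenomyosis.jz_max_mm"),
        # extent outside [0, 100]
        (make_case(a=AdenomyosisFindings(jz_max_mm=9,
                                         jz_diffuse_extent_pct=140)),
         "adenomyosis.jz_diffuse_extent_pct"),
        # negative wall thickness
        (make_case(a=AdenomyosisFindings(
            walls=[WallFinding(WallLocation.ANTERIOR, -3.0)])),
         "adenomyosis.walls[0].thickness_mm"),
        # affected wall with no measurement
        (make_case(a=AdenomyosisFindings(
            walls=[WallFinding(WallLocation.ANTERIOR, None, affected=True)])),
         "adenomyosis.walls[0].thickness_mm"),
        # duplicate wall location
        (make_case(a=AdenomyosisFindings(
            walls=[WallFinding(WallLocation.FUNDAL, 12.0),
                   WallFinding(WallLocation.FUNDAL, 14.0)])),
         "adenomyosis.walls[1].location"),
        # non-positive lesion diameter
        (make_case(a=AdenomyosisFindings(focal_lesions_mm=[0.0])),
         "adenomyosis.focal_lesions_mm[0]"),
        # negative endometrioma diameter
        (make_case(g=GenitalFindings(
            endometriomas=[Endometrioma(Side.LEFT, -5.0)])),
         "genital.endometriomas[0].diameter_mm"),
        # negative spot count
        (make_case(g=GenitalFindings(
            spots_by_site={GenitalSite.CERVIX: -1})),
         "genital.spots_by_site.cervix"),
        # recorded spots but no depth of penetration
        (make_case(e=ExtragenitalFindings(
            spots_by_site={ExtragenitalSite.BLADDER: 2})),
         "extragenital.max_depth_mm"),
        # deep invasion without any recorded lesion
        (make_case(e=ExtragenitalFindings(invasion=InvasionLayer.MUSCULARIS)),
         "extragenital.invasion"),
        # negative depth
        (make_case(e=ExtragenitalFindings(max_depth_mm=-1.0)),
         "extragenital.max_depth_mm"),
    ],
)
def test_violation_names_offending_field(case, expected_field):
    violations = validate_case(case)
    assert len(violations) == 1
    assert violations[0].field == expected_field


def test_multiple_violations_all_reported():
    case = make_case(
        a=AdenomyosisFindings(jz_max_mm=9, focal_lesions_mm=[-2.0]),
        g=GenitalFindings(endometriomas=[Endometrioma(Side.LEFT, 0.0)]),
    )
    fields = {v.field for v in validate_case(case)}
    assert fields == {"adenomyosis.jz_diffuse_extent_pct",
                      "adenomyosis.focal_lesions_mm[0]",
                      "genital.endometriomas[0].diameter_mm"}


def test_stage_is_totally_ordered():
    assert Stage.ABSENT < Stage.I < Stage.II < Stage.III < Stage.IV
    assert list(Stage) == [Stage(v) for v in range(5)]
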