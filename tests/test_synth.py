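"""Synthetic generator: seeded determinism, inversion, boundaries, oracle."""

import itertools

import pytest

from agces import (
    AdhesionGrade,
    GeneratorConfig,
    Stage,
    classify_case,
    enumerate_boundary_cases,
    format_code,
    generate_case,
    generate_cases,
    oracle_stage,
    validate_case,
)
from agces.synth import boundary_cases_with_expected
from conftest import make_case


def test_fixed_seed_reproduces_sequence():
    config = GeneratorConfig(seed=17, n_cases=50)
    assert generate_cases(config) == generate_cases(config)
    other = GeneratorConfig(seed=18, n_cases=50)
    assert generate_cases(config) != generate_cases(other)


def test_generated_cases_are_valid():
    for case in generate_cases(GeneratorConfig(seed=5, n_cases=200)):
        assert validate_case(case) == []


def test_metadata_records_generator_and_seed():
    case = generate_case(GeneratorConfig(seed=9))
    assert case.metadata["seed"] == 9
    assert "agces-synth" in case.metadata["generator"]


@pytest.mark.parametrize("target", [(0, 0, 0), (4, 4, 4), (1, 2, 3),
                                    (3, 0, 4), (2, 4, 1)])
def test_targeted_generation_inverts(target):
    for seed in range(5):
        case = generate_case(GeneratorConfig(seed=seed), target=target)
        code = classify_case(case)[0]
        assert (int(code.a), int(code.g), int(code.e)) == target


def test_target_triple_coverage_all_125():
    for target in itertools.product(range(5), repeat=3):
        case = generate_case(GeneratorConfig(seed=123), target=target)
        code = classify_case(case)[0]
        assert (int(code.a), int(code.g), int(code.e)) == target


def test_extreme_weights_force_stage():
    forced = (0.0, 0.0, 0.0, 0.0, 1.0)
    config = GeneratorConfig(
        seed=2, n_cases=20,
        severity_weights={"A": forced, "G": forced, "E": forced})
    for case in generate_cases(config):
        assert format_code(classify_case(case)[0]) == "A4 G4 E4"


@pytest.mark.parametrize("kwargs", [
    {"n_cases": 0},
    {"boundary_fraction": 1.5},
    {"severity_weights": {"A": (0.5, 0.5, 0.5, 0.0, 0.0),
                          "G": (1, 0, 0, 0, 0), "E": (1, 0, 0, 0, 0)}},
    {"severity_weights": {"A": (1, 0, 0, 0), "G": (1, 0, 0, 0, 0),
                          "E": (1, 0, 0, 0, 0)}},
])
def test_config_rejects_bad_parameters(kwargs):
    with pytest.raises(ValueError):
        GeneratorConfig(**kwargs)


# --- boundary enumeration -------------------------------------------------

def test_boundary_suite_size_and_determinism():
    cases = enumerate_boundary_cases()
    assert len(cases) == 28  # two sides of each of the 14 thresholds
    assert cases == enumerate_boundary_cases()


def test_boundary_cases_classify_as_documented():
    for case, expected in boundary_cases_with_expected():
        assert classify_case(case)[0] == expected, case.case_id


def test_boundary_contains_the_spot_and_depth_pairs():
    by_id = {c.case_id: c for c in enumerate_boundary_cases()}
    assert classify_case(by_id["BND-genital-spots-6-low"])[0].g == Stage.I
    assert classify_case(by_id["BND-genital-spots-6-high"])[0].g == Stage.II
    assert classify_case(by_id["BND-depth-5-low"])[0].e == Stage.I
    assert classify_case(by_id["BND-depth-5-high"])[0].e == Stage.IV


# --- oracle ---------------------------------------------------------------

def test_oracle_on_reference_cases(empty_case):
    assert format_code(oracle_stage(empty_case)) == "A0 G0 E0"
    from agces import GenitalFindings
    dense = make_case(g=GenitalFindings(adhesions=AdhesionGrade.DENSE))
    assert oracle_stage(dense).g == Stage.IV


def test_oracle_agrees_with_engine_on_random_sample():
    for case in generate_cases(GeneratorConfig(seed=31, n_cases=2000)):
        assert oracle_stage(case) == classify_case(case)[0]
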