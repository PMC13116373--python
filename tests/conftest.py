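import pytest

from agces import (
    AdenomyosisFindings,
    CaseRecord,
    ExtragenitalFindings,
    GenitalFindings,
    GeneratorConfig,
    generate_case,
)


def make_case(case_id="case", a=None, g=None, e=None):
    return CaseRecord(
        case_id=case_id,
        adenomyosis=a or AdenomyosisFindings(),
        genital=g or GenitalFindings(),
        extragenital=e or ExtragenitalFindings(),
    )


def random_case(seed, target=None):
    return generate_case(GeneratorConfig(seed=seed), target)


@pytest.fixture
def empty_case():
    return make_case("empty")
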