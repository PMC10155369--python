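import pytest

from subdos import (
    ExpressionScenario,
    GeneArchitecture,
    ModelSpec,
    SelectionParams,
    Variant,
)

# reference parameterization: four 775-nt regulatory domains, 50-kb coding
# region, per-nucleotide loss rates 2.5e-8/gen, tight binder, N_e = 1.4e5
REF_KEQ = 1.0e10
REF_NE = 1.4e5


@pytest.fixture(scope="session")
def architecture() -> GeneArchitecture:
    return GeneArchitecture(z=4, l_c=5.0e4, l_r=775.0, u_b=2.5e-8, u_h=2.5e-8)


@pytest.fixture(scope="session")
def selection() -> SelectionParams:
    return SelectionParams(w=1.0, n_e=REF_NE)


@pytest.fixture(scope="session")
def wgd() -> ExpressionScenario:
    return ExpressionScenario.wgd()


@pytest.fixture(scope="session")
def ssd() -> ExpressionScenario:
    return ExpressionScenario.ssd()


@pytest.fixture(scope="session")
def sub_only_spec(architecture, selection, wgd) -> ModelSpec:
    return ModelSpec(Variant.SUB_ONLY, architecture, selection, wgd, REF_KEQ)


@pytest.fixture(scope="session")
def sub_dos_spec(architecture, selection, wgd) -> ModelSpec:
    return ModelSpec(Variant.SUB_DOS, architecture, selection, wgd, REF_KEQ)


@pytest.fixture(scope="session")
def sub_dos_ssd_spec(architecture, selection, ssd) -> ModelSpec:
    return ModelSpec(Variant.SUB_DOS, architecture, selection, ssd, REF_KEQ)
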