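import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rtkdel.genemodel import Exon, GeneModel, toy_egfr, toy_pdgfra
from rtkdel.probes import ProbeCountMatrix, ProbeDef
from rtkdel.synthetic import CohortSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def egfr_model() -> GeneModel:
    return toy_egfr()


@pytest.fixture(scope="session")
def pdgfra_model() -> GeneModel:
    return toy_pdgfra()


@pytest.fixture
def default_spec() -> CohortSpec:
    return CohortSpec(n_samples=200, seed=7)


@pytest.fixture(scope="session")
def tiny_gene() -> GeneModel:
    """3-exon toy gene for hand-enumerable junction fixtures."""
    return GeneModel(
        gene="TOY",
        exons=[
            Exon(1, "chrT", 100, 200),
            Exon(2, "chrT", 300, 400),
            Exon(3, "chrT", 500, 600),
        ],
    )


def make_matrix(counts: dict[str, list], samples: list[str], probes: list[ProbeDef]):
    df = pd.DataFrame(counts, index=samples)[[p.probe_id for p in probes]]
    return ProbeCountMatrix(counts=df, probes=probes)


@pytest.fixture
def mini_probes() -> list[ProbeDef]:
    return [
        ProbeDef("HK1", "housekeeping", "HK1", "control"),
        ProbeDef("HK2", "housekeeping", "HK2", "control"),
        ProbeDef("MUT", "target", "EGFR", "mutant_junction"),
        ProbeDef("REF", "target", "EGFR", "kinase_domain"),
        ProbeDef("NEG_A", "negative_control"),
        ProbeDef("NEG_B", "negative_control"),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
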