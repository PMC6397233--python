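import numpy as np
import pytest

import vusnet as vn


@pytest.fixture
def tiny_matrix() -> vn.GenotypeMatrix:
    """3 variants x 4 samples, no missing entries."""
    variants = [
        vn.VariantRecord("rs1", "BRCA1"),
        vn.VariantRecord("rs2", "TP53"),
        vn.VariantRecord("rs3", "BRCA1"),
    ]
    dosages = np.array(
        [
            [0, 1, 2, 1],
            [1, 0, 0, 2],
            [2, 2, 1, 0],
        ],
        dtype=float,
    )
    return vn.GenotypeMatrix(variants, ["S1", "S2", "S3", "S4"], dosages)


@pytest.fixture
def tiny_phenotypes() -> vn.PhenotypeVector:
    return vn.PhenotypeVector(
        {"S1": "case", "S2": "case", "S3": "control", "S4": "control"}
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """Moderate planted cohort shared across model-level tests."""
    groups = (
        vn.VariantGroup(genes=("GA1", "GA2", "GA3"), variants_per_gene=2, beta=0.8, maf=0.3),
        vn.VariantGroup(genes=("GB1", "GB2", "GB3"), variants_per_gene=2, beta=-0.8, maf=0.3),
    )
    spec = vn.SimulationSpec(
        n_cases=150, n_controls=150, groups=groups, n_noise_variants=20, seed=7
    )
    g, y, truth = vn.simulate_cohort(spec)
    return g, y, truth


def make_risk_vector(risks, prefix="S", provenance="in_sample"):
    risks = np.asarray(risks, dtype=float)
    ids = [f"{prefix}{i + 1}" for i in range(risks.shape[0])]
    return vn.RiskVector(ids, risks, provenance)


def make_phenotypes(labels, prefix="S"):
    return vn.PhenotypeVector(
        {
            f"{prefix}{i + 1}": ("case" if int(v) == 1 else "control")
            for i, v in enumerate(labels)
        }
    )
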