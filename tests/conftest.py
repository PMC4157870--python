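import numpy as np
import pandas as pd
import pytest

from dualsite.association import GenotypeCounts
from dualsite.core_io import PWM
from dualsite.synthetic_data import RegulatoryFixtureSpec, make_regulatory_fixture


# genotype-by-status counts as printed in the study's association table
# (hom-ref, het, hom-alt); cases then controls
TABLE2 = {
    "overall": GenotypeCounts((280, 551, 241), (538, 998, 461), "overall"),
    "male": GenotypeCounts((229, 448, 180), (405, 815, 381), "male"),
    "female": GenotypeCounts((51, 103, 61), (133, 183, 80), "female"),
}

CONTROL_HWE_COUNTS = (538, 998, 461)


@pytest.fixture(scope="session")
def table2():
    return TABLE2


@pytest.fixture
def rng():
    return np.random.default_rng(20140908)


@pytest.fixture(scope="session")
def toy_pwm():
    """Skewed 4-position matrix (distinct max/min base per position)."""
    freqs = np.array(
        [
            [0.70, 0.10, 0.15, 0.05],
            [0.05, 0.80, 0.10, 0.05],
            [0.10, 0.10, 0.60, 0.20],
            [0.25, 0.25, 0.25, 0.25],
        ]
    )
    return PWM("toy4", freqs)


@pytest.fixture(scope="session")
def regulatory_fixture(tmp_path_factory):
    """A seeded planted-truth regulatory fixture shared across tests."""
    out = tmp_path_factory.mktemp("regfix")
    spec = RegulatoryFixtureSpec(
        seed=101,
        n_genes=16,
        n_planted_dual_promoter=4,
        n_planted_tfbe_variants=4,
        n_planted_common=2,
    )
    truth = make_regulatory_fixture(spec, out)
    return truth


def subjects_from_counts(counts: GenotypeCounts, sex: str) -> pd.DataFrame:
    """Expand a genotype table into a subject frame (for tabulation tests)."""
    rows = []
    for status, triple in (("case", counts.case_counts), ("control", counts.control_counts)):
        for geno, n in zip(("CC", "CG", "GG"), triple):
            rows += [
                {"id": f"{status}{geno}{i}", "status": status, "sex": sex,
                 "age": 55.0, "smoking": "never", "drinking": "never",
                 "genotype": geno}
                for i in range(n)
            ]
    return pd.DataFrame(rows)
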