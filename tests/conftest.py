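import numpy as np
import pandas as pd
import pytest

from glocerna.synthetic import SyntheticConfig, generate_cohort
from glocerna.types import MatchedExpressionMatrix


@pytest.fixture
def tiny_matrix() -> MatchedExpressionMatrix:
    """Two genes (one lncRNA, one PCG) over three patients."""
    patients = ["P1", "P2", "P3"]
    genes = ["L1", "G1"]
    normal = pd.DataFrame(
        [[2.0, 4.0, 1.0], [1.0, 2.0, 8.0]], index=genes, columns=patients
    )
    tumor = pd.DataFrame(
        [[8.0, 4.0, 0.5], [4.0, 2.0, 2.0]], index=genes, columns=patients
    )
    gene_class = pd.Series(["lncRNA", "PCG"], index=genes)
    return MatchedExpressionMatrix(normal=normal, tumor=tumor, gene_class=gene_class)


@pytest.fixture
def expression_files(tmp_path):
    """A 2-gene x 3-patient expression TSV with its pairing sidecar."""
    expr = tmp_path / "expr.tsv"
    pairing = tmp_path / "pairing.tsv"
    expr.write_text(
        "gene_id\tgene_class\tS1\tS2\tS3\tS4\tS5\tS6\n"
        "L1\tlncRNA\t2\t8\t4\t4\t1\t0.5\n"
        "G1\tPCG\t1\t4\t2\t2\t8\t2\n"
    )
    pairing.write_text(
        "sample\tpatient_id\ttissue\n"
        "S1\tP1\tN\nS2\tP1\tT\nS3\tP2\tN\nS4\tP2\tT\nS5\tP3\tN\nS6\tP3\tT\n"
    )
    return expr, pairing


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared across tests (read-only)."""
    config = SyntheticConfig(
        n_patients=20,
        n_lncrnas=30,
        n_pcgs=90,
        n_true_pairs=10,
        n_decoy_pairs=30,
        seed=42,
    )
    matrix, interactions, truth = generate_cohort(config)
    return config, matrix, interactions, truth


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
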