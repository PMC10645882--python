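import numpy as np
import pandas as pd
import pytest

from hemonet import synthetic as sy
from hemonet.io_formats import ExpressionMatrix, validate_annotation


@pytest.fixture(scope="session")
def small_annotation() -> pd.DataFrame:
    """200 genes on 4 chromosomes, 15% pseudogenes."""
    return sy.generate_annotation(
        200,
        chromosome_lengths={"1": 50, "2": 50, "3": 50, "4": 50},
        pseudogene_fraction=0.15,
        seed=11,
    )


@pytest.fixture(scope="session")
def planted_cohort(small_annotation):
    """Cancer-mode cohort with 4 chromosome-restricted modules, n=120."""
    mods = sy.plant_modules(
        small_annotation, "cancer", n_modules=4, module_size=12,
        latent_correlation=0.8, pseudogene_module_size=8, seed=12,
    )
    matrix, truth = sy.generate_cohort(
        small_annotation, mods, "cancer", 120, seed=13, param_seed=10
    )
    return matrix, truth


@pytest.fixture()
def toy_annotation() -> pd.DataFrame:
    rows = [
        ("g1", "1", "protein_coding", 40.0, 100, 400, None),
        ("g2", "1", "protein_coding", 45.0, 500, 900, None),
        ("g3", "2", "processed_pseudogene", 50.0, 100, 300, "g1"),
        ("g4", "2", "protein_coding", 55.0, 50, 950, None),
        ("g5", "X", "lncRNA", 60.0, 10, 110, None),
    ]
    return validate_annotation(
        pd.DataFrame(
            rows,
            columns=[
                "gene_id", "chromosome", "biotype", "gc_percent",
                "start_position", "end_position", "parent_gene_id",
            ],
        )
    )


def make_matrix(values, genes=None, samples=None, phenotype=None) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(arr.shape[1])]
    pheno = pd.Series(phenotype, index=samples) if phenotype is not None else None
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), pheno)
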