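import numpy as np
import pandas as pd
import pytest

from sigrisk.matrix import ExpressionMatrix


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with simple hand-checkable values."""
    values = pd.DataFrame(
        [[1.0, 1.0, 2.0, 2.0], [5.0, 5.0, 5.0, 5.0], [3.0, 4.0, 1.0, 2.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def two_group_labels() -> pd.Series:
    return pd.Series(["g1", "g1", "g2", "g2"], index=["s1", "s2", "s3", "s4"])


@pytest.fixture
def annotated_matrix() -> ExpressionMatrix:
    """10 genes with symbols/chromosomes exercising every preprocessing rule."""
    rng = np.random.default_rng(42)
    genes = [f"probe{i}" for i in range(10)]
    values = pd.DataFrame(
        rng.normal(7, 1, size=(10, 6)), index=genes, columns=[f"s{j}" for j in range(6)]
    )
    ann = pd.DataFrame(
        {
            "symbol": ["A", "B", "MT1G", "MT1G", "C", "D", "E", "F", "G", "H"],
            "chromosome": ["1", "2", "3", "3", "chrX", "X", "23", "Y", "5", "chr7"],
        },
        index=genes,
    )
    return ExpressionMatrix(values, ann)


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced study bundle shared by slower integration tests."""
    from sigrisk.simulate import generate_study_bundle

    return generate_study_bundle(
        seed=11,
        n_genes=400,
        n_signature=12,
        paired_patients=(15, 15, 15, 15),
        n_train=80,
        n_validation=(80,),
    )
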