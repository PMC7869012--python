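import numpy as np
import pandas as pd
import pytest

from lncnet.io import AnnotationTable, ExpressionMatrix


def make_matrix(values: np.ndarray, n_control: int = 4, n_treated: int = 4,
                feature_ids=None) -> ExpressionMatrix:
    """Wrap a raw array (features x samples) into an ExpressionMatrix."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    assert n == n_control + n_treated
    samples = [f"c{i}" for i in range(n_control)] + [f"t{i}" for i in range(n_treated)]
    if feature_ids is None:
        feature_ids = [f"F{i:04d}" for i in range(values.shape[0])]
    groups = pd.Series(["control"] * n_control + ["treated"] * n_treated, index=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=feature_ids, columns=samples), groups)


def make_annotation(rows, exons=None) -> AnnotationTable:
    """Build an AnnotationTable from (id, biotype, chrom, strand, start, end) tuples."""
    df = pd.DataFrame(
        rows, columns=["feature_id", "biotype", "chrom", "strand", "start", "end"]
    )
    df["symbol"] = df["feature_id"]
    return AnnotationTable(df, exons or {})


def de_frame(entries) -> pd.DataFrame:
    """DE table from (feature_id, fold_change, p_value) tuples."""
    df = pd.DataFrame(entries, columns=["feature_id", "fold_change", "p_value"])
    df["direction"] = np.where(df["fold_change"] > 0, "up", "down")
    df["fdr"] = df["p_value"]
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(42)
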