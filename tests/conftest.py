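import numpy as np
import pandas as pd
import pytest

from sphingostate.io import ExpressionMatrix, LipidStudy, SignatureSet


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """2 genes x 2 samples, [[1, 2], [3, 4]]."""
    return ExpressionMatrix(
        values=pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]], index=["g1", "g2"], columns=["s1", "s2"]
        )
    )


@pytest.fixture
def tiny_study() -> LipidStudy:
    """2 patients x 2 lipids with simple power-of-two fold changes."""
    idx = ["p1", "p2"]
    return LipidStudy(
        baseline=pd.DataFrame({"lipA": [1.0, 4.0], "lipB": [2.0, 2.0]}, index=idx),
        week6=pd.DataFrame({"lipA": [2.0, 2.0], "lipB": [2.0, 8.0]}, index=idx),
        response=pd.Series(["R", "NR"], index=idx),
        cohort=pd.Series(["bi", "tri"], index=idx),
    )


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "SIG_A\tliterature\tMITF\tTYR\n"
        "SIG_B\tliterature\tMLANA\tMLANA\tDCT\n"
    )
    return path


def make_expr(arr, genes=None, samples=None) -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(values=pd.DataFrame(arr, index=genes, columns=samples))


def make_signatures(**kwargs) -> SignatureSet:
    return SignatureSet(signatures={k: list(v) for k, v in kwargs.items()})
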