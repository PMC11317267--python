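"""Per-sample gene-set enrichment via a normal-scores rank statistic.

For each sample, all genes are ranked by expression (average ranks for
ties), rank r mapped to u = r/(n+1) and then to a normal score
s = Phi^-1(u).  A set's enrichment score is the mean normal score of its
member genes times sqrt(m), which is asymptotically standard normal when
the set is a random draw from the gene universe.  The statistic is
rank-based, hence invariant under any strictly monotone transform of a
sample's expression values.

This is a deliberately simple, fully specified single-sample enrichment
statistic; it is NOT the GSVA kernel-density KS-walk algorithm, whose
per-sample scores it stands in for here only as input to rank (Spearman)
correlations, which are robust to the choice of monotone-consistent
enrichment statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, spearmanr

from ._errors import NumericalError, ValidationError
from .io import ExpressionMatrix, SignatureSet
from .scoring import STATE_NAMES, StateFeatures


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Map values to Phi^-1(rank/(n+1)) normal scores (average ranks on ties)."""
    r = rankdata(values)
    return norm.ppf(r / (len(values) + 1.0))


def sample_es(expr: ExpressionMatrix, gene_set: list[str], name: str = "<set>") -> pd.Series:
    """Per-sample enrichment score of one gene set.

    ES(sample) = sqrt(m) * mean over present set genes of the sample's
    gene normal scores, m = number of set genes present in the matrix.
    """
    n_genes = expr.shape[0]
    if n_genes < 2:
        raise ValidationError("need >=2 genes in the expression matrix")
    present = [g for g in gene_set if g in expr.values.index]
    if not present:
        raise ValidationError(f"gene set {name!r}: no genes present in expression matrix")
    arr = expr.values.to_numpy(dtype=float)
    idx = expr.values.index.get_indexer(present)
    m = len(present)
    es = np.empty(expr.shape[1])
    for j in range(expr.shape[1]):
        s = _normal_scores(arr[:, j])
        es[j] = np.sqrt(m) * s[idx].mean()
    return pd.Series(es, index=expr.values.columns, name=name)


def enrich_all(expr: ExpressionMatrix, gene_sets: SignatureSet) -> pd.DataFrame:
    """Enrichment scores for every set; returns a set × sample matrix."""
    return pd.DataFrame({name: sample_es(expr, genes, name=name)
                         for name, genes in gene_sets.items()}).T


def feature_es_correlation(
    features: StateFeatures,
    es: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of each state feature against each set's
    enrichment scores, over the shared samples.

    Returns a tidy table (state, set, rho, p, significant); two-sided p
    values come from the t approximation.  Non-significant pairs
    (p >= alpha) are flagged but still reported.
    """
    shared = [s for s in features.features.index if s in es.columns]
    if len(shared) < 4:
        raise ValidationError("need >=4 shared samples between features and enrichment")
    rows = []
    for state in STATE_NAMES:
        f = features.features.loc[shared, state].to_numpy(dtype=float)
        if np.std(f) == 0:
            raise NumericalError(f"state feature {state!r} is constant")
        for set_name in es.index:
            e = es.loc[set_name, shared].to_numpy(dtype=float)
            if np.std(e) == 0:
                raise NumericalError(f"enrichment row {set_name!r} is constant")
            rho, p = spearmanr(f, e)
            rows.append(
                {
                    "state": state,
                    "set": set_name,
                    "rho": float(rho),
                    "p": float(p),
                    "significant": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)
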