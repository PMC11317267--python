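"""Melanoma differentiation-state scoring.

The framework turns a collection of literature gene signatures into three
per-sample state features and a categorical state call:

1. each signature is summarized per sample by the geometric mean of its
   genes' expression (with an additive pseudocount so zeros are defined);
2. signatures are correlated (Spearman, across samples) and the
   correlation matrix is clustered (complete linkage, distance 1 - rho)
   into k = 3 groups;
3. the per-cluster average of (z-scored) signature scores yields the
   Differentiated / Transitory / Dedifferentiated features;
4. each sample is called by its highest feature.

Also provides the differential-expression threshold filter
(|logFC| > 1 and adjusted p < 0.05, both strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._errors import NumericalError, ValidationError
from .io import ExpressionMatrix, SignatureSet

logger = logging.getLogger(__name__)

STATE_NAMES = ("Differentiated", "Transitory", "Dedifferentiated")
#: argmax tie priority: earlier wins
_STATE_PRIORITY = {s: i for i, s in enumerate(STATE_NAMES)}


# ---------------------------------------------------------------------------
# geometric-mean signature scores
# ---------------------------------------------------------------------------


def score_signature(
    expr: ExpressionMatrix,
    genes: list[str],
    pseudocount: float = 1.0,
    name: str = "<signature>",
) -> pd.Series:
    """Per-sample geometric-mean score of a gene signature.

    score(sample) = exp( mean_g ln(expr[g, sample] + pseudocount) ) - pseudocount

    Genes absent from the matrix are dropped with a warning; a signature
    with no genes present is an error.  The additive pseudocount keeps the
    geometric mean defined at zero expression and preserves the identity
    property for single-gene signatures.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    present = [g for g in genes if g in expr.values.index]
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        logger.warning(
            "signature %s: %d/%d genes absent from expression matrix: %s",
            name, len(missing), len(genes), ", ".join(missing[:5]),
        )
    if not present:
        raise ValidationError(f"signature {name!r}: no genes present in expression matrix")
    sub = expr.values.loc[present].to_numpy(dtype=float)
    score = np.exp(np.log(sub + pseudocount).mean(axis=0)) - pseudocount
    return pd.Series(score, index=expr.values.columns, name=name)


def score_all(
    expr: ExpressionMatrix, signatures: SignatureSet, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Score every signature; returns a signature × sample ScoreMatrix.

    Per-signature errors are aggregated and re-raised naming each failing
    signature.
    """
    rows = {}
    failures = []
    for sig_name, genes in signatures.items():
        try:
            rows[sig_name] = score_signature(expr, genes, pseudocount, name=sig_name)
        except ValidationError as exc:
            failures.append(str(exc))
    if failures:
        raise ValidationError("; ".join(failures))
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Spearman correlation of signature scores
# ---------------------------------------------------------------------------


def spearman_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Signature × signature Spearman correlation across samples.

    Ties receive average (fractional) ranks.  A constant score row has no
    defined correlation and raises, naming the signature.
    """
    if scores.shape[1] < 3:
        raise ValidationError("need >=3 samples for a Spearman correlation")
    arr = scores.to_numpy(dtype=float)
    const = arr.std(axis=1) == 0
    if const.any():
        raise NumericalError(
            f"constant score row(s): {', '.join(scores.index[const])}"
        )
    ranks = np.apply_along_axis(rankdata, 1, arr)
    corr = np.corrcoef(ranks)
    out = pd.DataFrame(corr, index=scores.index, columns=scores.index)
    np.fill_diagonal(out.values, 1.0)
    return out


# ---------------------------------------------------------------------------
# complete-link clustering of the correlation matrix
# ---------------------------------------------------------------------------


@dataclass
class SignatureClustering:
    """Result of complete-link agglomeration on 1 - rho distances.

    ``merges`` records the agglomeration history as (members_a, members_b,
    distance) tuples; ``assignment`` maps each signature to a cluster id in
    0..k-1 (ids ordered by first signature appearance); ``cluster_labels``
    maps cluster ids onto the three state names once labeled.
    """

    k: int
    assignment: dict[str, int]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    method: str = "complete"
    cluster_labels: dict[int, str] = field(default_factory=dict)

    def members(self, cluster_id: int) -> list[str]:
        return [s for s, c in self.assignment.items() if c == cluster_id]

    def labeled(self) -> bool:
        return set(self.cluster_labels.values()) == set(STATE_NAMES)

    def with_labels(self, labels: dict[int, str]) -> "SignatureClustering":
        if sorted(labels) != sorted(set(self.assignment.values())) or sorted(
            labels.values()
        ) != sorted(STATE_NAMES):
            raise ValidationError(
                "cluster labels must be a bijection from cluster ids onto "
                f"{STATE_NAMES}"
            )
        return SignatureClustering(
            k=self.k,
            assignment=dict(self.assignment),
            merges=list(self.merges),
            method=self.method,
            cluster_labels=dict(labels),
        )


def cluster_signatures(corr: pd.DataFrame, k: int = 3) -> SignatureClustering:
    """Agglomerative complete-link clustering of signatures.

    Distance d(i, j) = 1 - corr(i, j); the dendrogram is cut at ``k``
    clusters.  Among equal-distance merge candidates the lexicographically
    smallest cluster pair (by sorted member indices) is merged, so the
    result is deterministic for any input.
    """
    n = corr.shape[0]
    if corr.shape[0] != corr.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not (1 <= k <= n):
        raise ValidationError(f"k={k} out of range for {n} signatures")
    names = list(corr.index)
    dist = 1.0 - corr.to_numpy(dtype=float)
    # clusters as sorted tuples of original indices
    clusters: list[tuple[int, ...]] = [(i,) for i in range(n)]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []

    def complete_dist(a: tuple[int, ...], b: tuple[int, ...]) -> float:
        return max(dist[i, j] for i in a for j in b)

    while len(clusters) > k:
        best = None
        best_d = np.inf
        for ai in range(len(clusters)):
            for bi in range(ai + 1, len(clusters)):
                d = complete_dist(clusters[ai], clusters[bi])
                pair = (clusters[ai], clusters[bi])
                if d < best_d - 1e-15 or (
                    abs(d - best_d) <= 1e-15 and (best is None or pair < best)
                ):
                    best_d = d
                    best = pair
                    best_idx = (ai, bi)
        ai, bi = best_idx
        a, b = clusters[ai], clusters[bi]
        merges.append(
            (tuple(names[i] for i in a), tuple(names[j] for j in b), float(best_d))
        )
        clusters = [c for idx, c in enumerate(clusters) if idx not in (ai, bi)]
        clusters.append(tuple(sorted(a + b)))
        clusters.sort()
    # cluster ids by first signature appearance in input order
    clusters.sort(key=lambda c: c[0])
    assignment = {names[i]: cid for cid, c in enumerate(clusters) for i in c}
    assignment = {name: assignment[name] for name in names}
    return SignatureClustering(k=k, assignment=assignment, merges=merges)


def label_clusters_by_anchor(
    clustering: SignatureClustering, corr: pd.DataFrame, anchor: str
) -> SignatureClustering:
    """Auto-label the three clusters from a caller-designated anchor signature.

    The anchor marks the differentiated pole (e.g. a melanocytic/MITF-high
    signature): clusters are ranked by their mean correlation with the
    anchor and labeled Differentiated / Transitory / Dedifferentiated in
    decreasing order.
    """
    if anchor not in corr.index:
        raise ValidationError(f"anchor signature {anchor!r} not in correlation matrix")
    cluster_ids = sorted(set(clustering.assignment.values()))
    if len(cluster_ids) != 3:
        raise ValidationError("anchor labeling requires exactly 3 clusters")
    mean_corr = {
        cid: float(corr.loc[clustering.members(cid), anchor].mean())
        for cid in cluster_ids
    }
    ranked = sorted(cluster_ids, key=lambda c: -mean_corr[c])
    labels = {cid: STATE_NAMES[i] for i, cid in enumerate(ranked)}
    return clustering.with_labels(labels)


# ---------------------------------------------------------------------------
# state features and classification
# ---------------------------------------------------------------------------


@dataclass
class StateFeatures:
    """Per-sample differentiation-state features and categorical call."""

    features: pd.DataFrame  # samples × (Differentiated, Transitory, Dedifferentiated)
    state_call: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.features.index)


def _argmax_state(row: pd.Series) -> str:
    best = row.max()
    tied = [s for s in STATE_NAMES if row[s] == best]
    if len(tied) > 1:
        logger.warning("state-call tie for a sample; priority order %s applied", STATE_NAMES)
    return min(tied, key=_STATE_PRIORITY.__getitem__)


def build_state_features(
    scores: pd.DataFrame,
    clustering: SignatureClustering,
    standardize: bool = True,
) -> StateFeatures:
    """Average per-cluster signature scores into the three state features.

    With ``standardize`` (default), each signature's score row is z-scored
    across samples before averaging; geometric means of different
    signatures live on different scales, so the cross-state argmax is only
    meaningful on standardized rows.  The state call is the argmax of the
    three features (ties resolved Differentiated > Transitory >
    Dedifferentiated, logged).
    """
    if not clustering.labeled():
        raise ValidationError(
            "clustering must carry the three state labels (use with_labels or "
            "label_clusters_by_anchor)"
        )
    mat = scores.copy().astype(float)
    if standardize:
        sd = mat.std(axis=1, ddof=0)
        zero = sd == 0
        if zero.any():
            raise NumericalError(
                f"zero-variance score row(s) under standardization: "
                f"{', '.join(mat.index[zero])}"
            )
        mat = mat.sub(mat.mean(axis=1), axis=0).div(sd, axis=0)
    feats = {}
    for cid, state in clustering.cluster_labels.items():
        members = clustering.members(cid)
        missing = [m for m in members if m not in mat.index]
        if missing:
            raise ValidationError(f"signatures missing from score matrix: {missing}")
        feats[state] = mat.loc[members].mean(axis=0)
    features = pd.DataFrame(feats)[list(STATE_NAMES)]
    call = features.apply(_argmax_state, axis=1)
    call.name = "state_call"
    return StateFeatures(features=features, state_call=call)


# ---------------------------------------------------------------------------
# DE threshold filter
# ---------------------------------------------------------------------------


def filter_de(
    de_table: pd.DataFrame,
    gene_col: str = "gene",
    logfc_col: str = "logFC",
    padj_col: str = "padj",
    logfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> list[str]:
    """Significantly differentially expressed genes: |logFC| > 1 (strict)
    AND adjusted p < 0.05 (strict); input order preserved."""
    if len(de_table) == 0:
        return []
    padj = de_table[padj_col].to_numpy(dtype=float)
    if ((padj < 0) | (padj > 1)).any():
        raise ValidationError("adjusted p values must lie in [0, 1]")
    logfc = de_table[logfc_col].to_numpy(dtype=float)
    if not np.isfinite(logfc).all():
        raise ValidationError("logFC values must be finite")
    keep = (np.abs(logfc) > logfc_threshold) & (padj < alpha)
    return list(de_table.loc[keep, gene_col])
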