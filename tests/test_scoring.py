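"""Differentiation scoring: geometric means, correlation, clustering,
state features and the DE filter."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sphingostate._errors import NumericalError, ValidationError
from sphingostate.scoring import (
    build_state_features,
    cluster_signatures,
    filter_de,
    label_clusters_by_anchor,
    score_all,
    score_signature,
    spearman_matrix,
)

from conftest import make_expr, make_signatures


# ---------------------------------------------------------------------------
# geometric-mean score
# ---------------------------------------------------------------------------


def test_score_is_geometric_mean_in_small_pseudocount_limit():
    expr = make_expr([[2.0], [8.0]])
    s = score_signature(expr, ["g0", "g1"], pseudocount=1e-12)
    assert s.iloc[0] == pytest.approx(4.0, abs=1e-9)  # sqrt(2*8)


def test_single_gene_signature_is_identity_for_any_pseudocount():
    expr = make_expr([[3.7, 0.0, 12.5]])
    for pc in (1e-6, 1.0, 10.0):
        s = score_signature(expr, ["g0"], pseudocount=pc)
        np.testing.assert_allclose(s.to_numpy(), [3.7, 0.0, 12.5], atol=1e-12)


def test_all_ones_signature_scores_one():
    expr = make_expr(np.ones((3, 2)))
    s = score_signature(expr, ["g0", "g1", "g2"], pseudocount=1.0)
    np.testing.assert_allclose(s.to_numpy(), 1.0)


def test_missing_genes_warned_absent_all_errors(caplog):
    expr = make_expr([[1.0, 2.0]])
    with caplog.at_level("WARNING"):
        score_signature(expr, ["g0", "NOT_THERE"], name="SIG")
    assert "absent" in caplog.text
    with pytest.raises(ValidationError, match="SIG"):
        score_signature(expr, ["NOPE"], name="SIG")


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    vals=st.lists(
        st.floats(min_value=0.0, max_value=1e4), min_size=2, max_size=6
    ),
    bump=st.floats(min_value=0.1, max_value=10.0),
)
def test_score_gene_order_invariant_and_monotone(vals, bump):
    """Permuting signature genes never changes the score; raising any one
    gene's expression strictly raises it."""
    expr = make_expr(np.array(vals)[:, None])
    genes = [f"g{i}" for i in range(len(vals))]
    base = score_signature(expr, genes).iloc[0]
    perm = score_signature(expr, genes[::-1]).iloc[0]
    assert perm == pytest.approx(base, rel=1e-12)
    bumped_vals = list(vals)
    bumped_vals[0] += bump
    bumped = score_signature(make_expr(np.array(bumped_vals)[:, None]), genes).iloc[0]
    assert bumped > base


def test_score_all_shape_and_scaling():
    rng = np.random.default_rng(1)
    expr = make_expr(rng.lognormal(size=(6, 3)))
    sigs = make_signatures(A=["g0", "g1", "g2"], B=["g3", "g4"])
    scores = score_all(expr, sigs, pseudocount=1e-12)
    assert scores.shape == (2, 3)
    # scaling expression by c scales scores by c (pseudocount -> 0 limit)
    c = 3.5
    scaled = score_all(make_expr(c * expr.values.to_numpy()), sigs, pseudocount=1e-12)
    np.testing.assert_allclose(scaled.to_numpy(), c * scores.to_numpy(), rtol=1e-6)


def test_score_all_names_every_failing_signature():
    expr = make_expr([[1.0, 2.0]])
    sigs = make_signatures(OK=["g0"], BAD1=["x"], BAD2=["y"])
    with pytest.raises(ValidationError) as err:
        score_all(expr, sigs)
    assert "BAD1" in str(err.value) and "BAD2" in str(err.value)


# ---------------------------------------------------------------------------
# Spearman matrix
# ---------------------------------------------------------------------------


def _brute_spearman(a, b):
    """1 - 6*sum(d^2)/(n(n^2-1)) on tie-free vectors."""
    ra = np.argsort(np.argsort(a)) + 1
    rb = np.argsort(np.argsort(b)) + 1
    n = len(a)
    return 1 - 6 * np.sum((ra - rb) ** 2) / (n * (n**2 - 1))


def test_spearman_known_values():
    scores = pd.DataFrame(
        [[1, 2, 3, 4], [1, 3, 2, 4], [4, 3, 2, 1]],
        index=["a", "b", "c"],
        columns=list("wxyz"),
    )
    corr = spearman_matrix(scores)
    assert corr.loc["a", "b"] == pytest.approx(0.8)
    assert corr.loc["a", "c"] == pytest.approx(-1.0)
    assert corr.loc["a", "a"] == 1.0
    assert np.allclose(corr, corr.T)


def test_spearman_matches_bruteforce_rank_formula():
    rng = np.random.default_rng(7)
    for _ in range(20):
        scores = pd.DataFrame(rng.normal(size=(4, 6)))  # ties a.s. absent
        corr = spearman_matrix(scores)
        for i, j in itertools.combinations(range(4), 2):
            expected = _brute_spearman(
                scores.iloc[i].to_numpy(), scores.iloc[j].to_numpy()
            )
            assert corr.iloc[i, j] == pytest.approx(expected, abs=1e-12)


def test_spearman_rejects_constant_row_and_few_samples():
    with pytest.raises(NumericalError, match="flat"):
        spearman_matrix(
            pd.DataFrame([[1, 1, 1], [1, 2, 3]], index=["flat", "ok"])
        )
    with pytest.raises(ValidationError):
        spearman_matrix(pd.DataFrame([[1, 2], [2, 1]]))


# ---------------------------------------------------------------------------
# complete-link clustering
# ---------------------------------------------------------------------------


def _block_corr(sizes, within=0.9, between=-0.8, names=None):
    n = sum(sizes)
    corr = np.full((n, n), between)
    start = 0
    blocks = []
    for s in sizes:
        corr[start : start + s, start : start + s] = within
        blocks.append(list(range(start, start + s)))
        start += s
    np.fill_diagonal(corr, 1.0)
    names = names or [f"sig{i}" for i in range(n)]
    return pd.DataFrame(corr, index=names, columns=names), blocks


def test_blocks_recovered_exactly():
    corr, blocks = _block_corr([2, 2])
    clustering = cluster_signatures(corr, k=2)
    groups = {}
    for sig, cid in clustering.assignment.items():
        groups.setdefault(cid, []).append(corr.index.get_loc(sig))
    assert sorted(map(sorted, groups.values())) == blocks


def test_k_equals_n_gives_singletons_and_k_too_large_errors():
    corr, _ = _block_corr([2, 2])
    singletons = cluster_signatures(corr, k=4)
    assert len(set(singletons.assignment.values())) == 4
    with pytest.raises(ValidationError):
        cluster_signatures(corr, k=5)


def test_degenerate_equal_distances_still_deterministic():
    n = 4
    corr = pd.DataFrame(
        np.full((n, n), 0.5) + np.eye(n) * 0.5,
        index=[f"s{i}" for i in range(n)],
        columns=[f"s{i}" for i in range(n)],
    )
    a = cluster_signatures(corr, k=2)
    b = cluster_signatures(corr, k=2)
    assert a.assignment == b.assignment
    assert len(set(a.assignment.values())) == 2


def test_matches_scipy_complete_linkage_on_tiefree_input():
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(3)
    scores = pd.DataFrame(rng.normal(size=(7, 30)))
    corr = spearman_matrix(scores)
    ours = cluster_signatures(corr, k=3)
    d = squareform(1 - corr.to_numpy(), checks=False)
    flat = fcluster(linkage(d, method="complete"), t=3, criterion="maxclust")
    # same partition up to relabeling
    ours_part = {}
    scipy_part = {}
    for i, sig in enumerate(corr.index):
        ours_part.setdefault(ours.assignment[sig], set()).add(i)
        scipy_part.setdefault(flat[i], set()).add(i)
    assert sorted(map(sorted, ours_part.values())) == sorted(
        map(sorted, scipy_part.values())
    )


# ---------------------------------------------------------------------------
# state features and call
# ---------------------------------------------------------------------------


def _one_per_cluster_setup():
    scores = pd.DataFrame(
        [[5.0, 1.0, 2.0], [1.0, 6.0, 2.0], [2.0, 1.0, 7.0]],
        index=["dif", "tra", "ded"],
        columns=["s1", "s2", "s3"],
    )
    corr, _ = _block_corr([1, 1, 1], names=["dif", "tra", "ded"])
    clustering = cluster_signatures(corr, k=3).with_labels(
        {0: "Differentiated", 1: "Transitory", 2: "Dedifferentiated"}
    )
    return scores, clustering


def test_features_equal_raw_scores_without_standardize():
    scores, clustering = _one_per_cluster_setup()
    sf = build_state_features(scores, clustering, standardize=False)
    np.testing.assert_allclose(
        sf.features.to_numpy(), scores.to_numpy().T
    )
    assert list(sf.state_call) == [
        "Differentiated", "Transitory", "Dedifferentiated",
    ]


def test_state_call_matches_argmax_and_tie_priority():
    scores, clustering = _one_per_cluster_setup()
    sf = build_state_features(scores, clustering, standardize=False)
    argmax = sf.features.idxmax(axis=1)
    assert (sf.state_call == argmax).all()
    tied = pd.DataFrame(
        [[1.0, 2.0, 0.0], [1.0, 0.0, 2.0], [1.0, 1.0, 1.0]],
        index=["dif", "tra", "ded"],
        columns=["s1", "s2", "s3"],
    )
    sf2 = build_state_features(tied, clustering, standardize=False)
    assert sf2.state_call["s1"] == "Differentiated"  # priority on exact tie


def test_features_invariant_to_within_cluster_order():
    rng = np.random.default_rng(5)
    scores = pd.DataFrame(
        rng.normal(size=(6, 10)), index=[f"sig{i}" for i in range(6)]
    )
    corr, _ = _block_corr([2, 2, 2], names=list(scores.index))
    labels = {0: "Differentiated", 1: "Transitory", 2: "Dedifferentiated"}
    c1 = cluster_signatures(corr, k=3).with_labels(labels)
    shuffled = scores.iloc[::-1]
    a = build_state_features(scores, c1)
    b = build_state_features(shuffled, c1)
    pd.testing.assert_frame_equal(a.features, b.features)


def test_unlabeled_or_zero_variance_errors():
    scores, clustering = _one_per_cluster_setup()
    bare = cluster_signatures(1 - (1 - spearman_matrix(scores)), k=3)
    with pytest.raises(ValidationError, match="label"):
        build_state_features(scores, bare)
    flat = scores.copy()
    flat.loc["dif"] = 1.0
    with pytest.raises(NumericalError, match="dif"):
        build_state_features(flat, clustering, standardize=True)


def test_anchor_labeling_orders_clusters_by_anchor_correlation():
    corr, _ = _block_corr([2, 2, 2], within=0.9, between=0.0)
    # make block 1 mildly positive and block 2 negative wrt the anchor block
    corr.iloc[0:2, 2:4] = corr.iloc[2:4, 0:2] = 0.3
    corr.iloc[0:2, 4:6] = corr.iloc[4:6, 0:2] = -0.7
    clustering = cluster_signatures(corr, k=3)
    labeled = label_clusters_by_anchor(clustering, corr, anchor="sig0")
    lab = {s: labeled.cluster_labels[c] for s, c in labeled.assignment.items()}
    assert lab["sig0"] == "Differentiated"
    assert lab["sig2"] == "Transitory"
    assert lab["sig4"] == "Dedifferentiated"


# ---------------------------------------------------------------------------
# DE filter
# ---------------------------------------------------------------------------


def test_filter_de_rule_and_boundaries():
    table = pd.DataFrame(
        {
            "gene": ["gA", "gB", "gC", "gD", "gE"],
            "logFC": [1.5, 0.5, -2.0, 1.0, -1.2],
            "padj": [0.01, 0.01, 0.2, 0.01, 0.05],
        }
    )
    # strict on both |logFC| > 1 and padj < 0.05
    assert filter_de(table) == ["gA"]
    assert filter_de(table.iloc[0:0]) == []


def test_filter_de_rejects_bad_p():
    table = pd.DataFrame({"gene": ["g"], "logFC": [2.0], "padj": [1.5]})
    with pytest.raises(ValidationError):
        filter_de(table)
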