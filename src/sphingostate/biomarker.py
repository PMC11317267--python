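"""Plasma sphingolipid biomarker pipeline.

Given a paired (baseline / week-6) lipid panel with a binary response
label per patient, the pipeline

1. computes each patient's per-lipid log2 fold change under treatment;
2. repeatedly runs Boruta all-relevant feature selection on the fold
   changes and ranks lipids by how often they are confirmed predictive;
3. builds the sphingolipid score from the top-k lipids:
   score = mean(FC of lipids higher in non-responders)
         - mean(FC of lipids lower in non-responders);
4. dichotomizes the score at 0 (high/low) and tests its association with
   response by a 2x2 Pearson chi-square;
5. estimates predictive performance by repeated stratified k-fold
   cross-validated logistic regression, pooling out-of-fold predicted
   probabilities per repeat into a rank-formula ROC AUC;
6. compares fold-change evolution between treatment cohorts per lipid
   (Welch t, unadjusted — a screening comparison, not an inference).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, chi2 as chi2_dist, rankdata, ttest_ind
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._errors import ContractError, NumericalError, ValidationError
from .io import LipidStudy

logger = logging.getLogger(__name__)

Direction = Literal["higher_in_NR", "lower_in_NR"]


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------


@dataclass
class FoldChangeMatrix:
    """Patient × lipid matrix of log2(week6 / baseline) with labels."""

    fc: pd.DataFrame
    response: pd.Series
    cohort: pd.Series

    @property
    def patient_ids(self) -> list[str]:
        return list(self.fc.index)

    @property
    def lipid_ids(self) -> list[str]:
        return list(self.fc.columns)

    @property
    def y(self) -> np.ndarray:
        """Binary outcome: 1 = non-responder (the event being predicted)."""
        return (self.response == "NR").to_numpy(dtype=int)


def compute_log2fc(study: LipidStudy) -> FoldChangeMatrix:
    """Per-patient lipid evolution: fc[p, l] = log2(week6[p, l] / baseline[p, l])."""
    fc = np.log2(study.week6.to_numpy(dtype=float) / study.baseline.to_numpy(dtype=float))
    if not np.isfinite(fc).all():
        raise NumericalError("non-finite log2 fold change (check concentrations)")
    return FoldChangeMatrix(
        fc=pd.DataFrame(fc, index=study.baseline.index, columns=study.baseline.columns),
        response=study.response.copy(),
        cohort=study.cohort.copy(),
    )


# ---------------------------------------------------------------------------
# Boruta all-relevant feature selection
# ---------------------------------------------------------------------------

ImportanceFn = Callable[[np.ndarray, np.ndarray, np.random.Generator], np.ndarray]


def tree_importance(n_estimators: int = 25) -> ImportanceFn:
    """Impurity importance from an extremely-randomized trees ensemble.

    The default Boruta backend: n_estimators randomized trees, seeded from
    the Boruta iteration RNG so runs are reproducible.
    """

    def fn(X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        est = ExtraTreesClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        est.fit(X, y)
        return est.feature_importances_

    return fn


@lru_cache(maxsize=100_000)
def _binom_two_sided(k: int, n: int) -> float:
    """Two-sided exact binomial p of k hits in n fair trials (cached)."""
    return binomtest(k, n, 0.5, alternative="two-sided").pvalue


@dataclass
class BorutaResult:
    """Per-feature decision of one Boruta run."""

    status: pd.Series  # feature -> {confirmed, rejected, tentative}
    hits: pd.Series  # hit counts while the feature was undecided
    iterations: pd.Series  # iterations the feature stayed in play
    n_iter: int

    @property
    def confirmed(self) -> list[str]:
        return list(self.status.index[self.status == "confirmed"])


def boruta_select(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int] | np.ndarray,
    max_iter: int = 30,
    alpha: float = 0.01,
    importance_fn: ImportanceFn | None = None,
    seed: int | None = None,
) -> BorutaResult:
    """Classic Boruta with shadow features and a binomial hit test.

    Each iteration appends a shadow copy of every still-undecided feature
    (values independently permuted), scores real + shadow features with
    ``importance_fn``, and counts a hit for a real feature whose
    importance strictly exceeds the maximum shadow importance.  After each
    iteration a two-sided binomial test of the hit count against
    Binomial(iterations, 1/2), Bonferroni-corrected over the FULL feature
    set, confirms (upper tail) or rejects (lower tail) at level ``alpha``;
    features undecided at ``max_iter`` are tentative.  The Bonferroni
    divisor stays at the original feature count throughout: the family of
    hypotheses is every feature that entered the run, and shrinking the
    divisor as features get decided loosens late decisions exactly when
    the shadow pool is weakest, inflating false confirmations.
    Deterministic given seed.
    """
    if isinstance(X, pd.DataFrame):
        feat_names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        feat_names = [f"f{i}" for i in range(Xa.shape[1])]
    ya = np.asarray(y)
    classes, counts = np.unique(ya, return_counts=True)
    if len(classes) != 2 or counts.min() < 6:
        raise ValidationError("need two classes with >=6 samples each")
    if max_iter < 20:
        raise ValidationError("max_iter must be >= 20")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    imp_fn = importance_fn or tree_importance()
    rng = np.random.default_rng(seed)
    n, p = Xa.shape

    active = np.ones(p, dtype=bool)  # undecided
    status = np.array(["tentative"] * p, dtype=object)
    hits = np.zeros(p, dtype=int)
    iters = np.zeros(p, dtype=int)
    n_iter = 0
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        n_iter = it
        Xr = Xa[:, idx]
        shadow = Xr.copy()
        for j in range(shadow.shape[1]):
            shadow[:, j] = shadow[rng.permutation(n), j]
        imp = imp_fn(np.hstack([Xr, shadow]), ya, rng)
        imp = np.asarray(imp, dtype=float)
        if imp.shape != (2 * idx.size,) or (imp < 0).any() or not np.isfinite(imp).all():
            raise ContractError(
                "importance_fn must return one finite non-negative importance "
                "per real and shadow feature"
            )
        real_imp, shadow_imp = imp[: idx.size], imp[idx.size :]
        threshold = shadow_imp.max()
        hit = real_imp > threshold
        hits[idx] += hit
        iters[idx] = it
        # binomial decisions, Bonferroni over the full original feature set
        for j in idx:
            if _binom_two_sided(int(hits[j]), it) * p < alpha:
                status[j] = "confirmed" if hits[j] > it / 2 else "rejected"
                active[j] = False
    return BorutaResult(
        status=pd.Series(status, index=feat_names),
        hits=pd.Series(hits, index=feat_names),
        iterations=pd.Series(iters, index=feat_names),
        n_iter=n_iter,
    )


@dataclass
class SelectionResult:
    """Aggregate of repeated Boruta runs on the fold-change matrix."""

    counts: pd.Series  # lipid -> times confirmed, in panel order
    runs: int
    per_run_status: pd.DataFrame  # runs × lipids
    seed: int | None

    def ranking(self) -> pd.Series:
        """Counts sorted descending; ties keep panel order (stable sort)."""
        return self.counts.sort_values(ascending=False, kind="stable")

    def top(self, k: int, min_support: float = 0.6) -> list[str]:
        """Top-k lipids of the ranking, restricted to stably selected
        species: only lipids confirmed in at least ``min_support`` of the
        runs are signature candidates (stability-selection style majority
        rule).  The result may therefore hold fewer than k names —
        possibly none, when the panel carries no reproducible signal.
        Truly predictive lipids are confirmed in nearly every run, while a
        lipid whose apparent relevance is a finite-sample accident rarely
        sustains majority support."""
        threshold = max(1, int(np.ceil(min_support * self.runs)))
        eligible = self.ranking()
        eligible = eligible[eligible >= threshold]
        return list(eligible.index[:k])


def selection_frequency(
    fc: FoldChangeMatrix,
    runs: int = 1000,
    max_iter: int = 30,
    alpha: float = 0.01,
    importance_fn: ImportanceFn | None = None,
    seed: int | None = None,
) -> SelectionResult:
    """Run Boruta ``runs`` times with independently derived child seeds and
    count, per lipid, how often it is confirmed predictive."""
    if runs < 1:
        raise ValidationError("runs must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(runs) % (2**31 - 1)
    statuses = []
    for r in range(runs):
        res = boruta_select(
            fc.fc, fc.y, max_iter=max_iter, alpha=alpha,
            importance_fn=importance_fn, seed=int(child_seeds[r]),
        )
        statuses.append(res.status)
    per_run = pd.DataFrame(statuses, index=range(runs))
    counts = (per_run == "confirmed").sum(axis=0)
    counts.name = "confirmed_count"
    return SelectionResult(counts=counts, runs=runs, per_run_status=per_run, seed=seed)


# ---------------------------------------------------------------------------
# sphingolipid score
# ---------------------------------------------------------------------------


def assign_direction(fc: FoldChangeMatrix, lipids: Sequence[str]) -> dict[str, Direction]:
    """Mark each selected lipid by which response class its fold change is
    higher in: higher_in_NR iff mean FC over non-responders exceeds the
    mean over responders.  An exact tie is degenerate and raises."""
    is_nr = fc.response == "NR"
    if is_nr.all() or (~is_nr).all():
        raise ValidationError("both response classes must be present")
    out: dict[str, Direction] = {}
    for l in lipids:
        m_nr = fc.fc.loc[is_nr, l].mean()
        m_r = fc.fc.loc[~is_nr, l].mean()
        if m_nr == m_r:
            raise NumericalError(f"lipid {l!r}: identical class means, direction undefined")
        out[l] = "higher_in_NR" if m_nr > m_r else "lower_in_NR"
    return out


def sphingolipid_score(
    fc: FoldChangeMatrix, directions: dict[str, Direction]
) -> pd.Series:
    """Per-patient score: mean FC over the higher-in-NR lipids minus mean
    FC over the lower-in-NR lipids.  An empty direction group contributes
    0 (logged), so one-sided top-k sets still score."""
    if not directions:
        raise ValidationError("selected lipid set must be non-empty")
    higher = [l for l, d in directions.items() if d == "higher_in_NR"]
    lower = [l for l, d in directions.items() if d == "lower_in_NR"]
    for group, name in ((higher, "higher_in_NR"), (lower, "lower_in_NR")):
        if not group:
            logger.warning("direction group %s is empty; its mean is taken as 0", name)
    hi = fc.fc[higher].mean(axis=1) if higher else pd.Series(0.0, index=fc.fc.index)
    lo = fc.fc[lower].mean(axis=1) if lower else pd.Series(0.0, index=fc.fc.index)
    score = hi - lo
    score.name = "sphingolipid_score"
    return score


def classify_score(score: pd.Series) -> pd.Series:
    """Dichotomize: score > 0 -> high, < 0 -> low; exactly 0 -> low with a
    warning (conservative toward the responder-like class)."""
    zero = score == 0
    if zero.any():
        logger.warning(
            "score exactly 0 for %d patient(s); classified as low", int(zero.sum())
        )
    out = pd.Series(np.where(score > 0, "high", "low"), index=score.index, name="score_class")
    return out


def score_response_association(
    classes: pd.Series, response: pd.Series, continuity: bool = False
) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-square (1 df, default no continuity correction) of the
    2x2 high/low × R/NR table.  Returns (statistic, p, table)."""
    table = pd.crosstab(classes, response).reindex(
        index=["high", "low"], columns=["R", "NR"], fill_value=0
    )
    t = table.to_numpy(dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise NumericalError("chi-square undefined: a table margin is zero")
    n = t.sum()
    a, b, c, d = t.ravel()
    det = a * d - b * c
    if continuity:
        det = max(abs(det) - n / 2.0, 0.0) * np.sign(det)
    stat = n * det**2 / (t.sum(axis=1).prod() * t.sum(axis=0).prod())
    p = float(chi2_dist.sf(stat, df=1))
    return float(stat), p, table


# ---------------------------------------------------------------------------
# cross-validated AUC
# ---------------------------------------------------------------------------


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC by the rank (Mann-Whitney) formula with tie correction:
    average ranks of the positives, AUC = (R+ - n+(n+ + 1)/2) / (n+ n-)."""
    y = np.asarray(y_true, dtype=int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise NumericalError("AUC undefined with a single class")
    r = rankdata(scores)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class AucSummary:
    """Repeated cross-validation AUC: mean, sd and per-repeat values."""

    mean: float
    sd: float
    per_repeat: np.ndarray
    folds: int
    repeats: int


def _fit_predict_logistic(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray
) -> np.ndarray:
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X_train, y_train)
    return model.predict_proba(X_test)[:, 1]


def crossval_auc(
    fc: FoldChangeMatrix,
    lipids: Sequence[str],
    folds: int = 5,
    repeats: int = 100,
    seed: int | None = None,
    nested_selector: Callable[[pd.DataFrame, np.ndarray, int], Sequence[str]] | None = None,
) -> AucSummary:
    """Repeated stratified k-fold cross-validated AUC of a binomial
    (logistic) model on the selected lipids' fold changes.

    Per repeat: a stratified shuffle into ``folds`` folds; per fold a
    logistic fit on the training folds predicts held-out non-response
    probabilities; the repeat's pooled out-of-fold predictions give one
    rank-formula AUC.  Summary is the mean and sd across repeats.
    With ``nested_selector``, feature selection is re-run inside each
    training fold (selector(fc_train, y_train, fold_seed) -> lipids),
    avoiding the selection leakage of the default design.
    """
    y = fc.y
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if min(n_pos, n_neg) < folds:
        raise ValidationError(
            f"each class must have >= folds samples (have {n_pos} NR / {n_neg} R, folds={folds})"
        )
    if not nested_selector:
        missing = [l for l in lipids if l not in fc.fc.columns]
        if missing:
            raise ValidationError(f"unknown lipids: {missing}")
    rng = np.random.default_rng(seed)
    per_repeat = np.empty(repeats)
    for rep in range(repeats):
        for attempt in range(10):
            cv = StratifiedKFold(
                n_splits=folds, shuffle=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            preds = np.empty(len(y))
            ok = True
            for fold_i, (tr, te) in enumerate(cv.split(fc.fc, y)):
                if len(np.unique(y[tr])) < 2:
                    ok = False
                    break
                cols = (
                    list(nested_selector(fc.fc.iloc[tr], y[tr], int(rng.integers(2**31 - 1))))
                    if nested_selector
                    else list(lipids)
                )
                preds[te] = _fit_predict_logistic(
                    fc.fc.iloc[tr][cols].to_numpy(), y[tr], fc.fc.iloc[te][cols].to_numpy()
                )
            if ok:
                break
            logger.warning("degenerate single-class training fold; repartitioning")
        else:
            raise NumericalError("could not build non-degenerate stratified folds")
        per_repeat[rep] = rank_auc(y, preds)
    return AucSummary(
        mean=float(per_repeat.mean()),
        sd=float(per_repeat.std(ddof=1)) if repeats > 1 else 0.0,
        per_repeat=per_repeat,
        folds=folds,
        repeats=repeats,
    )


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------


def cohort_compare(fc: FoldChangeMatrix) -> pd.DataFrame:
    """Per-lipid Welch two-sample t of fold changes between the two
    treatment cohorts; two-sided p, no multiplicity adjustment."""
    cohorts = list(dict.fromkeys(fc.cohort))
    if len(cohorts) != 2:
        raise ValidationError(f"need exactly two cohort labels, got {cohorts}")
    a_idx = fc.cohort == cohorts[0]
    b_idx = fc.cohort == cohorts[1]
    if a_idx.sum() < 2 or b_idx.sum() < 2:
        raise ValidationError("need >=2 patients per cohort")
    a = fc.fc.loc[a_idx].to_numpy(dtype=float)
    b = fc.fc.loc[b_idx].to_numpy(dtype=float)
    res = ttest_ind(a, b, axis=0, equal_var=False)
    out = pd.DataFrame(
        {
            "lipid": fc.lipid_ids,
            "mean_diff": a.mean(axis=0) - b.mean(axis=0),
            "t": np.nan_to_num(res.statistic, nan=0.0),
            "p": np.nan_to_num(res.pvalue, nan=1.0),
        }
    )
    return out
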