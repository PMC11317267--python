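"""Model/Results front end for the two pipelines.

:class:`DifferentiationModel` fits the differentiation-state scoring
framework to an expression cohort; :class:`SphingolipidBiomarkerModel`
fits the plasma sphingolipid resistance score to a paired lipid study.
Both follow the fit() -> Results convention: the model object holds data
and settings, the results object carries the estimates, diagnostics, a
``summary()`` table, and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .biomarker import (
    AucSummary,
    FoldChangeMatrix,
    SelectionResult,
    assign_direction,
    classify_score,
    cohort_compare,
    compute_log2fc,
    crossval_auc,
    score_response_association,
    selection_frequency,
    sphingolipid_score,
    tree_importance,
)
from .io import ExpressionMatrix, LipidStudy, SignatureSet
from .scoring import (
    STATE_NAMES,
    SignatureClustering,
    StateFeatures,
    build_state_features,
    cluster_signatures,
    label_clusters_by_anchor,
    score_all,
    spearman_matrix,
)


def _rule(width: int = 64) -> str:
    return "=" * width


# ---------------------------------------------------------------------------
# differentiation model
# ---------------------------------------------------------------------------


class DifferentiationModel:
    """Differentiation-state scoring framework for an expression cohort.

    Parameters
    ----------
    expr : ExpressionMatrix
        Gene × sample abundances (non-negative).
    signatures : SignatureSet
        Literature differentiation signatures (>= k needed).
    pseudocount : float
        Additive pseudocount inside the geometric mean (default 1.0,
        suited to count-like data).
    k : int
        Number of signature clusters / states (default 3).
    standardize : bool
        Z-score signature scores across samples before cluster averaging
        (default True; required for a meaningful cross-state argmax).
    anchor : str, optional
        Signature marking the differentiated pole, used to auto-label the
        three clusters.  Alternatively pass explicit ``labels`` to fit().
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        signatures: SignatureSet,
        pseudocount: float = 1.0,
        k: int = 3,
        standardize: bool = True,
        anchor: str | None = None,
    ) -> None:
        self.expr = expr
        self.signatures = signatures
        self.pseudocount = pseudocount
        self.k = k
        self.standardize = standardize
        self.anchor = anchor

    @classmethod
    def from_files(cls, expr_path, gmt_path, **kwargs) -> "DifferentiationModel":
        from .io import read_expression, read_gmt

        return cls(read_expression(expr_path), read_gmt(gmt_path), **kwargs)

    def fit(self, labels: dict[int, str] | None = None) -> "DifferentiationResults":
        """Score, correlate, cluster, label, and call states.

        ``labels`` maps cluster ids onto the three state names; when
        omitted, the model's ``anchor`` signature labels the clusters by
        decreasing mean correlation.  With k != 3 the fit stops after
        clustering (features need exactly three labeled clusters).
        """
        scores = score_all(self.expr, self.signatures, self.pseudocount)
        corr = spearman_matrix(scores)
        clustering = cluster_signatures(corr, k=self.k)
        features = None
        if labels is not None:
            clustering = clustering.with_labels(labels)
        elif self.anchor is not None and self.k == 3:
            clustering = label_clusters_by_anchor(clustering, corr, self.anchor)
        if clustering.labeled():
            features = build_state_features(scores, clustering, self.standardize)
        return DifferentiationResults(
            model=self, scores=scores, corr=corr, clustering=clustering,
            features=features,
        )


@dataclass
class DifferentiationResults:
    """Fitted differentiation-state framework."""

    model: DifferentiationModel
    scores: pd.DataFrame  # signature × sample geometric-mean scores
    corr: pd.DataFrame  # signature × signature Spearman correlation
    clustering: SignatureClustering
    features: StateFeatures | None

    @property
    def state_call(self) -> pd.Series:
        if self.features is None:
            raise ValidationError("clusters are unlabeled; no state call available")
        return self.features.state_call

    def accuracy(self, truth: pd.Series, mapping: dict[str, str]) -> float:
        """Fraction of samples whose call matches a ground-truth labeling
        (mapping: truth label -> state name)."""
        mapped = truth.map(mapping)
        return float((self.state_call.loc[mapped.index] == mapped).mean())

    def summary(self) -> str:
        lines = [
            _rule(),
            "Differentiation-state scoring results",
            _rule(),
            f"signatures: {len(self.scores)}    samples: {self.scores.shape[1]}"
            f"    clusters: {self.clustering.k}",
        ]
        for cid in sorted(set(self.clustering.assignment.values())):
            label = self.clustering.cluster_labels.get(cid, f"cluster {cid}")
            lines.append(f"  {label}: {', '.join(self.clustering.members(cid))}")
        if self.features is not None:
            counts = self.state_call.value_counts()
            lines.append("state calls: " + ", ".join(
                f"{s}={int(counts.get(s, 0))}" for s in STATE_NAMES
            ))
        lines.append(_rule())
        return "\n".join(lines)

    def plot_correlation(self, ax=None):
        """Heatmap of the signature score correlation matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(self.corr)), self.corr.columns, rotation=90)
        ax.set_yticks(range(len(self.corr)), self.corr.index)
        ax.figure.colorbar(im, ax=ax, label="Spearman rho")
        return ax


# ---------------------------------------------------------------------------
# sphingolipid biomarker model
# ---------------------------------------------------------------------------


class SphingolipidBiomarkerModel:
    """Resistance-predictive sphingolipid score fitted to a paired lipid study.

    Parameters
    ----------
    study : LipidStudy
        Paired baseline/week-6 concentrations with R/NR response labels.
    top_k : int
        Number of top-ranked lipids entering the score (default 8).
    boruta_runs : int
        Repetitions of Boruta selection (default 1000, as many as the
        ranking was designed with; lower for quick runs).
    boruta_max_iter, boruta_alpha, n_estimators
        Boruta loop controls and tree count of the default importance
        backend.
    folds, repeats
        Stratified cross-validation design for the AUC (default 5 × 100).
    nested : bool
        Re-run feature selection inside every training fold and report a
        leakage-free AUC alongside the default whole-cohort-selection AUC.
    seed : int
        Master seed; all randomness derives from it.
    """

    def __init__(
        self,
        study: LipidStudy,
        top_k: int = 8,
        boruta_runs: int = 1000,
        boruta_max_iter: int = 30,
        boruta_alpha: float = 0.01,
        n_estimators: int = 25,
        folds: int = 5,
        repeats: int = 100,
        nested: bool = False,
        seed: int | None = None,
    ) -> None:
        self.study = study
        self.top_k = top_k
        self.boruta_runs = boruta_runs
        self.boruta_max_iter = boruta_max_iter
        self.boruta_alpha = boruta_alpha
        self.n_estimators = n_estimators
        self.folds = folds
        self.repeats = repeats
        self.nested = nested
        self.seed = seed

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SphingolipidBiomarkerModel":
        from .io import read_lipid_study

        return cls(read_lipid_study(path), **kwargs)

    def fit(self) -> "BiomarkerResults":
        seeds = np.random.SeedSequence(self.seed).generate_state(4) % (2**31 - 1)
        fc = compute_log2fc(self.study)
        imp = tree_importance(self.n_estimators)
        selection = selection_frequency(
            fc, runs=self.boruta_runs, max_iter=self.boruta_max_iter,
            alpha=self.boruta_alpha, importance_fn=imp, seed=int(seeds[0]),
        )
        selected = selection.top(self.top_k)
        if not selected:
            # no lipid was ever confirmed predictive: the panel carries no
            # detectable signal and no score/association/AUC is reported
            return BiomarkerResults(
                model=self, fc=fc, selection=selection, selected=[],
                directions={}, score=None, score_class=None, chi2=None,
                chi2_p=None, contingency=None, auc=None,
                cohort_table=cohort_compare(fc) if len(set(fc.cohort)) == 2 else None,
            )
        directions = assign_direction(fc, selected)
        score = sphingolipid_score(fc, directions)
        classes = classify_score(score)
        chi2, chi2_p, table = score_response_association(classes, fc.response)
        auc = crossval_auc(
            fc, selected, folds=self.folds, repeats=self.repeats, seed=int(seeds[1])
        )
        nested_auc = None
        if self.nested:
            def selector(fc_train: pd.DataFrame, y_train: np.ndarray, s: int):
                sub = FoldChangeMatrix(
                    fc=fc_train,
                    response=pd.Series(
                        np.where(y_train == 1, "NR", "R"), index=fc_train.index
                    ),
                    cohort=fc.cohort.loc[fc_train.index],
                )
                sel = selection_frequency(
                    sub, runs=max(1, self.boruta_runs // 20),
                    max_iter=self.boruta_max_iter, alpha=self.boruta_alpha,
                    importance_fn=imp, seed=s,
                )
                return sel.top(self.top_k)

            nested_auc = crossval_auc(
                fc, selected, folds=self.folds, repeats=self.repeats,
                seed=int(seeds[2]), nested_selector=selector,
            )
        cohorts = (
            cohort_compare(fc) if len(set(fc.cohort)) == 2 else None
        )
        return BiomarkerResults(
            model=self, fc=fc, selection=selection, selected=selected,
            directions=directions, score=score, score_class=classes,
            chi2=chi2, chi2_p=chi2_p, contingency=table, auc=auc,
            nested_auc=nested_auc, cohort_table=cohorts,
        )


@dataclass
class BiomarkerResults:
    """Fitted sphingolipid biomarker pipeline."""

    model: SphingolipidBiomarkerModel
    fc: FoldChangeMatrix
    selection: SelectionResult
    selected: list[str]
    directions: dict[str, str]
    score: pd.Series | None
    score_class: pd.Series | None
    chi2: float | None
    chi2_p: float | None
    contingency: pd.DataFrame | None
    auc: AucSummary | None
    nested_auc: AucSummary | None = None
    cohort_table: pd.DataFrame | None = None

    @property
    def has_signature(self) -> bool:
        """True when at least one lipid was confirmed predictive."""
        return bool(self.selected)

    def patient_table(self) -> pd.DataFrame:
        """Per-patient score, high/low class, and response label."""
        if not self.has_signature:
            raise ValidationError("no predictive lipids were selected; no score exists")
        return pd.DataFrame(
            {
                "score": self.score,
                "score_class": self.score_class,
                "response": self.fc.response,
            }
        )

    def summary(self) -> str:
        lines = [
            _rule(),
            "Sphingolipid biomarker results",
            _rule(),
            f"patients: {len(self.fc.patient_ids)}"
            f" ({int((self.fc.response == 'R').sum())} R /"
            f" {int((self.fc.response == 'NR').sum())} NR)"
            f"    lipids: {len(self.fc.lipid_ids)}",
            f"Boruta: {self.selection.runs} runs"
            f" (alpha={self.model.boruta_alpha}, max_iter={self.model.boruta_max_iter})",
        ]
        if not self.has_signature:
            lines.append("no lipid was ever confirmed predictive; no score reported")
            lines.append(_rule())
            return "\n".join(lines)
        lines.append(f"top {self.model.top_k} lipids (confirmation count, direction):")
        for l in self.selected:
            lines.append(
                f"  {l}: {int(self.selection.counts[l])}  {self.directions[l]}"
            )
        lines += [
            f"chi2 (high/low vs R/NR, 1 df): {self.chi2:.4f}   p = {self.chi2_p:.3g}",
            f"cross-validated AUC ({self.auc.folds}-fold x {self.auc.repeats}):"
            f" {self.auc.mean:.3f} (sd {self.auc.sd:.3f})",
        ]
        if self.nested_auc is not None:
            lines.append(
                f"nested-selection AUC: {self.nested_auc.mean:.3f}"
                f" (sd {self.nested_auc.sd:.3f})"
            )
        lines.append(_rule())
        return "\n".join(lines)

    def plot_roc_auc(self, ax=None):
        """Histogram of per-repeat cross-validated AUCs."""
        import matplotlib.pyplot as plt

        if self.auc is None:
            raise ValidationError("no predictive lipids were selected; no AUC exists")
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.auc.per_repeat, bins=20)
        ax.axvline(self.auc.mean, color="red", label=f"mean={self.auc.mean:.3f}")
        ax.set_xlabel("per-repeat pooled AUC")
        ax.set_ylabel("repeats")
        ax.legend()
        return ax
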