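"""Synthetic data generators with the statistical structure the two
pipelines assume, so every stage is testable without cohort downloads.

``gen_expression`` emulates a bulk expression cohort in which signature
genes covary within latent differentiation states: each state owns a set
of signatures whose genes load on a shared per-sample latent factor, the
factors of different states are negatively correlated (-0.5 by
construction), and a sample's own state shifts its state's signature
genes upward on the log scale.  Geometric-mean signature scores computed
on such a matrix therefore correlate positively within a state and
negatively between states, reproducing the blocked correlation structure
the scoring framework clusters.

``gen_lipidomics`` emulates a paired plasma lipid panel: log-normal
baselines, Gaussian log2 fold changes under treatment, and a planted
subset of effect lipids whose fold change is shifted (up or down) in
non-responders only — the effect lives on the *evolution* of the lipid,
not its baseline level, matching the predictive design.

Both generators are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .io import ExpressionMatrix, LipidStudy, SignatureSet


@dataclass
class ExprGenConfig:
    """Configuration for the expression-cohort generator.

    All shifts and noise are on the log-expression scale.
    """

    n_states: int = 3
    signatures_per_state: int = 3
    genes_per_signature: int = 20
    n_background_genes: int = 500
    samples_per_state: int = 20
    delta: float = 1.0  # own-state mean shift of signature genes
    factor_loading: float = 0.3  # latent state factor -> gene log-expression
    noise_sd: float = 0.5
    between_state_corr: float = -0.5
    base_log_expr: float = 2.0
    seed: int | None = None

    def validate(self) -> None:
        for name in ("n_states", "signatures_per_state", "genes_per_signature",
                     "n_background_genes", "samples_per_state"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.delta <= 0:
            raise ValidationError("delta must be > 0")
        if self.noise_sd < 0 or self.factor_loading < 0:
            raise ValidationError("noise_sd and factor_loading must be >= 0")
        # the equicorrelation matrix is PSD iff rho >= -1/(k-1)
        if self.n_states > 1 and self.between_state_corr < -1.0 / (self.n_states - 1):
            raise ValidationError(
                f"between_state_corr={self.between_state_corr} invalid for "
                f"{self.n_states} states"
            )


@dataclass
class LipidGenConfig:
    """Configuration for the paired lipid-panel generator.

    Defaults match the study design the pipeline targets: 25 responders,
    23 non-responders, a 78-species panel, and a planted 4-up + 4-down
    effect subset whose log2 fold change is shifted in non-responders.
    """

    n_R: int = 25
    n_NR: int = 23
    n_lipids: int = 78
    n_effect_up: int = 4
    n_effect_down: int = 4
    delta_fc: float = 1.0  # mean log2FC shift in NR for effect lipids
    fc_sd: float = 0.7
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 0.8
    cohort_names: tuple[str, str] = ("bi-therapy", "tri-therapy")
    cohort_fraction: float = 27.0 / 48.0  # fraction assigned to first cohort
    seed: int | None = None

    def validate(self) -> None:
        for name in ("n_R", "n_NR", "n_lipids"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_effect_up < 0 or self.n_effect_down < 0:
            raise ValidationError("effect counts must be >= 0")
        if self.n_effect_up + self.n_effect_down > self.n_lipids:
            raise ValidationError("more effect lipids than panel size")
        if self.fc_sd <= 0 or self.baseline_log_sd <= 0:
            raise ValidationError("sds must be positive")
        if not (0 <= self.cohort_fraction <= 1):
            raise ValidationError("cohort_fraction must lie in [0, 1]")


def gen_expression(
    cfg: ExprGenConfig,
) -> tuple[ExpressionMatrix, SignatureSet, pd.Series]:
    """Generate (expression matrix, signatures, true state per sample).

    log-expression of a signature gene = base + loading * state factor
    + delta * [sample's state == signature's state] + noise; background
    genes carry base + noise only.  Expression = exp(log-expression).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_states
    n_samples = k * cfg.samples_per_state
    states = np.repeat(np.arange(k), cfg.samples_per_state)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]

    # latent per-sample state factors with equicorrelation rho between states
    cov = np.full((k, k), cfg.between_state_corr)
    np.fill_diagonal(cov, 1.0)
    # sample via symmetric square root (cov may be singular at the PSD boundary)
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    factors = rng.standard_normal((n_samples, k)) @ root.T  # samples × states

    gene_rows = []
    gene_ids = []
    signatures: dict[str, list[str]] = {}
    state_names = [f"state{s}" for s in range(k)]
    for s in range(k):
        for j in range(cfg.signatures_per_state):
            sig_name = f"SIG_{state_names[s]}_{j}"
            sig_genes = []
            for g in range(cfg.genes_per_signature):
                gid = f"G_{s}_{j}_{g}"
                sig_genes.append(gid)
                gene_ids.append(gid)
                shift = cfg.delta * (states == s)
                log_expr = (
                    cfg.base_log_expr
                    + cfg.factor_loading * factors[:, s]
                    + shift
                    + rng.normal(0.0, cfg.noise_sd, n_samples)
                )
                gene_rows.append(log_expr)
            signatures[sig_name] = sig_genes
    for g in range(cfg.n_background_genes):
        gene_ids.append(f"BG_{g}")
        gene_rows.append(
            cfg.base_log_expr + rng.normal(0.0, cfg.noise_sd, n_samples)
        )
    values = pd.DataFrame(
        np.exp(np.asarray(gene_rows)), index=gene_ids, columns=sample_ids
    )
    truth = pd.Series(
        [state_names[s] for s in states], index=sample_ids, name="true_state"
    )
    return (
        ExpressionMatrix(values=values, unit="synthetic (exp of Gaussian log-expression)"),
        SignatureSet(signatures=signatures),
        truth,
    )


def gen_lipidomics(cfg: LipidGenConfig) -> tuple[LipidStudy, dict[str, list[str]]]:
    """Generate a paired lipid study plus the planted ground truth
    ({'up': [...], 'down': [...]}: effect lipids shifted in non-responders).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_R + cfg.n_NR
    patient_ids = [f"P{i:03d}" for i in range(n)]
    response = np.array(["R"] * cfg.n_R + ["NR"] * cfg.n_NR)
    lipid_ids = [f"lipid_{i:02d}" for i in range(cfg.n_lipids)]
    effect_idx = rng.choice(
        cfg.n_lipids, size=cfg.n_effect_up + cfg.n_effect_down, replace=False
    )
    up_idx = effect_idx[: cfg.n_effect_up]
    down_idx = effect_idx[cfg.n_effect_up :]

    baseline = np.exp(
        rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, (n, cfg.n_lipids))
    )
    fc = rng.normal(0.0, cfg.fc_sd, (n, cfg.n_lipids))
    is_nr = response == "NR"
    fc[np.ix_(is_nr, up_idx)] += cfg.delta_fc
    fc[np.ix_(is_nr, down_idx)] -= cfg.delta_fc
    week6 = baseline * np.exp2(fc)

    n_first = int(round(cfg.cohort_fraction * n))
    cohort_labels = np.array(
        [cfg.cohort_names[0]] * n_first + [cfg.cohort_names[1]] * (n - n_first)
    )
    # interleave cohorts across the R/NR blocks so both cohorts see both classes
    order = rng.permutation(n)
    cohort_labels = cohort_labels[np.argsort(order)]

    study = LipidStudy(
        baseline=pd.DataFrame(baseline, index=patient_ids, columns=lipid_ids),
        week6=pd.DataFrame(week6, index=patient_ids, columns=lipid_ids),
        response=pd.Series(response, index=patient_ids, name="response"),
        cohort=pd.Series(cohort_labels, index=patient_ids, name="cohort"),
    )
    truth = {
        "up": [lipid_ids[i] for i in sorted(up_idx)],
        "down": [lipid_ids[i] for i in sorted(down_idx)],
    }
    return study, truth
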