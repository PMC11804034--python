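"""Proportion-statistic biomarker framework.

The diagnostic score for a marker gene is the percentage of a sample's
eccDNA records that overlap the gene. Evaluation follows the liquid-biopsy
recipe: ROC/AUC by the rank (Mann-Whitney) formulation with midrank ties,
a stratified percentile bootstrap CI over 2000 replicates, the Youden
cutoff applied inclusively (score >= c* calls cancer), validation-cohort
accuracy at that training cutoff, and marker combination via a bivariate
logistic model (rank-average fallback for degenerate fits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .records import SampleProfile

log = logging.getLogger("bilecirc")

POSITIVE = "cancer"


def marker_proportion(profile: SampleProfile, marker_gene: str,
                      gene_hits: dict[str, list[str]]) -> float:
    """Percent of the sample's records overlapping ``marker_gene``.

    ``gene_hits`` maps ecc id -> overlapping gene ids (the eccGene
    annotation of this sample).
    """
    if not profile.eccdna:
        raise ValueError(f"sample {profile.sample_id} has no eccDNA")
    n_hit = sum(marker_gene in gene_hits.get(rec.id, ())
                for rec in profile.eccdna)
    return 100.0 * n_hit / len(profile.eccdna)


def _to_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == POSITIVE else 0 for l in labels])
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return scores, y


def roc_auc(scores, labels) -> float:
    """AUC via the rank formulation with midrank tie handling."""
    scores, y = _to_arrays(scores, labels)
    ranks = rankdata(scores)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve(scores, labels) -> np.ndarray:
    """ROC points (FPR, TPR) at every distinct threshold, positive = score
    >= threshold; includes the (0,0) and (1,1) endpoints."""
    scores, y = _to_arrays(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], y[order]
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.concatenate((distinct, [len(s) - 1]))
    tp = np.cumsum(y)[cut]
    fp = np.cumsum(1 - y)[cut]
    tpr = np.concatenate(([0], tp / y.sum()))
    fpr = np.concatenate(([0], fp / (len(y) - y.sum())))
    return np.column_stack((fpr, tpr))


@dataclass
class BootstrapCI:
    lower: float
    upper: float
    level: float
    n_replicates: int
    degenerate: bool = False
    replicates: np.ndarray | None = None


def bootstrap_auc_ci(scores, labels, B: int = 2000, level: float = 0.95,
                     seed: int = 0, keep_replicates: bool = False) -> BootstrapCI:
    """Stratified percentile bootstrap CI for the AUC.

    Resampling is within class; replicates that lose a class are redrawn
    implicitly by stratification. A class with a single sample yields a
    degenerate (flagged) interval.
    """
    scores, y = _to_arrays(scores, labels)
    rng = np.random.default_rng(seed)
    pos, neg = scores[y == 1], scores[y == 0]
    degenerate = len(pos) < 2 or len(neg) < 2
    aucs = np.empty(B)
    labs = np.array([POSITIVE] * len(pos) + ["noncancer"] * len(neg))
    for b in range(B):
        sp = pos[rng.integers(0, len(pos), size=len(pos))]
        sn = neg[rng.integers(0, len(neg), size=len(neg))]
        aucs[b] = roc_auc(np.concatenate((sp, sn)), labs)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(aucs, [alpha, 1 - alpha])
    return BootstrapCI(float(lo), float(hi), level, B, degenerate,
                       aucs if keep_replicates else None)


def youden_cutoff(scores, labels) -> tuple[float, float, float, float]:
    """(c*, J, sensitivity, specificity) maximizing TPR - FPR.

    Candidate cutoffs are midpoints of adjacent distinct scores plus
    sentinels below/above all scores; a positive call is score >= c*.
    Ties in J break toward higher specificity (larger cutoff).
    """
    scores, y = _to_arrays(scores, labels)
    uniq = np.unique(scores)
    candidates = np.concatenate((
        [uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]))
    best = (-np.inf, -np.inf, 0.0, 0.0, 0.0)
    n1, n0 = y.sum(), len(y) - y.sum()
    for c in candidates:
        call = scores >= c
        tpr = (call & (y == 1)).sum() / n1
        fpr = (call & (y == 0)).sum() / n0
        j = tpr - fpr
        if (j, c) > (best[0], best[1]):
            best = (j, c, tpr, 1 - fpr, fpr)
    j, c, sens, spec, _ = best
    return float(c), float(j), float(sens), float(spec)


def validate_cutoff(scores, labels, cutoff: float) -> dict[str, float]:
    """Accuracy/sensitivity/specificity of a fixed training cutoff."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == POSITIVE else 0 for l in labels])
    call = scores >= cutoff
    correct = (call == (y == 1)).sum()
    out = {"accuracy": correct / len(y)}
    out["sensitivity"] = float((call & (y == 1)).sum() / y.sum()) \
        if y.any() else np.nan
    out["specificity"] = float((~call & (y == 0)).sum() / (len(y) - y.sum())) \
        if (y == 0).any() else np.nan
    return out


@dataclass
class CombinedModel:
    method: str  # "logistic" | "rank_average"
    coef: np.ndarray | None = None
    intercept: float = 0.0
    means: np.ndarray | None = None
    stds: np.ndarray | None = None
    log_transform: tuple[bool, ...] = ()
    pseudo: float = 1e-4

    def score(self, columns: list[np.ndarray]) -> np.ndarray:
        X = self._design(columns)
        if self.method == "logistic":
            return X @ self.coef + self.intercept
        return np.mean([rankdata(c) for c in columns], axis=0)

    def _design(self, columns) -> np.ndarray:
        cols = []
        for x, lg in zip(columns, self.log_transform):
            x = np.asarray(x, dtype=float)
            cols.append(np.log10(x + self.pseudo) if lg else x)
        X = np.column_stack(cols)
        return (X - self.means) / self.stds


def combine_markers(score_vectors: list[np.ndarray], labels,
                    log_transform: tuple[bool, ...] | None = None,
                    pseudo: float = 1e-4) -> tuple[CombinedModel, np.ndarray]:
    """Linear predictor of a logistic model over the marker scores.

    Proportion scores are log10-transformed with a pseudo-count (set
    ``log_transform`` False per column for already-scaled serum values);
    all columns are standardized on the training data. Degenerate or
    non-convergent fits fall back to a rank-average combination (logged).
    Returns the fitted model and the combined training scores.
    """
    if len(score_vectors) < 2:
        raise ValueError("need >= 2 score vectors")
    y = np.asarray([1 if l == POSITIVE else 0 for l in labels])
    if log_transform is None:
        log_transform = (True,) * len(score_vectors)
    cols = []
    for x, lg in zip(score_vectors, log_transform):
        x = np.asarray(x, dtype=float)
        cols.append(np.log10(x + pseudo) if lg else x)
    X = np.column_stack(cols)
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    stds[stds == 0] = 1.0
    Xs = (X - means) / stds
    model = CombinedModel("logistic", means=means, stds=stds,
                          log_transform=tuple(log_transform), pseudo=pseudo)
    try:
        from sklearn.exceptions import ConvergenceWarning
        from sklearn.linear_model import LogisticRegression
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            clf = LogisticRegression(C=1e12, max_iter=5000)
            clf.fit(Xs, y)
        model.coef = clf.coef_.ravel()
        model.intercept = float(clf.intercept_[0])
    except Exception as exc:  # separation / collinearity / non-convergence
        log.warning("logistic combination failed (%s); rank-average fallback",
                    exc)
        model = CombinedModel("rank_average")
        return model, model.score(score_vectors)
    combined = Xs @ model.coef + model.intercept
    return model, combined


@dataclass
class DiagnosticResult:
    """One marker's full diagnostic evaluation."""

    marker: str
    auc: float
    ci: BootstrapCI
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    roc: np.ndarray
    validation: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"marker": self.marker, "auc": self.auc,
                "ci": [self.ci.lower, self.ci.upper],
                "ci_level": self.ci.level, "cutoff": self.cutoff,
                "youden_j": self.youden_j, "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "validation": self.validation}


def evaluate_marker(marker: str, train_scores, train_labels,
                    val_scores=None, val_labels=None, B: int = 2000,
                    level: float = 0.95, seed: int = 0) -> DiagnosticResult:
    """Train-set ROC/AUC/CI/cutoff plus optional validation at the cutoff.

    When the marker separates in the inverse direction (AUC < 0.5 on
    training data) the score sign is flipped for the whole evaluation and
    the flip is logged.
    """
    train_scores = np.asarray(train_scores, dtype=float)
    if roc_auc(train_scores, train_labels) < 0.5:
        log.warning("marker %s separates inversely; flipping score sign",
                    marker)
        train_scores = -train_scores
        if val_scores is not None:
            val_scores = -np.asarray(val_scores, dtype=float)
    auc = roc_auc(train_scores, train_labels)
    ci = bootstrap_auc_ci(train_scores, train_labels, B=B, level=level,
                          seed=seed)
    c, j, sens, spec = youden_cutoff(train_scores, train_labels)
    res = DiagnosticResult(marker, auc, ci, c, j, sens, spec,
                           roc_curve(train_scores, train_labels))
    if val_scores is not None:
        res.validation = validate_cutoff(val_scores, val_labels, c)
    return res
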