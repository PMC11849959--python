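"""Supervised evaluation harness.

Features are CLR-transformed (after augmentation, on model inputs), models
are trained under repeated stratified k-fold cross-validation with
augmentation applied to training folds only, and per-repeat AUROC/AUPRC are
computed on the concatenated test-fold predictions. Because synthetic labels
are continuous, augmented runs train each model's regression counterpart and
use its raw predictions as ranking scores.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC, LinearSVR

from .augment import AugmentConfig, phylomix_augment, vanilla_mixup
from .datasets import LabeledDataset
from .tree import PhyloTree

__all__ = [
    "EvalConfig",
    "MetricsReport",
    "clr_transform",
    "cross_validated_eval",
    "compare_methods",
    "two_sample_t",
]

AUGMENTERS = ("none", "phylomix", "vanilla_mixup")


@dataclass(frozen=True)
class EvalConfig:
    model: str = "logistic"
    n_folds: int = 5
    n_repeats: int = 20
    seed: int = 0
    pseudocount: float = 1.0
    clr: bool = True

    def __post_init__(self) -> None:
        if self.model not in ("logistic", "svm", "rf"):
            raise ValueError(f"unknown model: {self.model!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class MetricsReport:
    method: str
    model: str
    auroc: np.ndarray  # one entry per repeat
    auprc: np.ndarray

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.auroc))

    @property
    def mean_auprc(self) -> float:
        return float(np.mean(self.auprc))

    def ci95(self, metric: str = "auprc") -> tuple[float, float]:
        """Normal-approximation 95% CI of the mean over repeats."""
        vals = getattr(self, metric)
        m = float(np.mean(vals))
        half = 1.96 * float(np.std(vals, ddof=1)) / np.sqrt(len(vals))
        return m - half, m + half

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "model": self.model,
                "repeat": np.arange(len(self.auroc)),
                "auroc": self.auroc,
                "auprc": self.auprc,
            }
        )


def clr_transform(x: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform with a pseudocount for zeros.

    Works on a vector or a samples x taxa matrix (centered per row). Output
    rows sum to zero.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("clr_transform requires nonnegative input")
    if pseudocount <= 0 and np.any(x == 0):
        raise ValueError("pseudocount must be > 0 when zeros are present")
    logs = np.log(x + pseudocount)
    return logs - logs.mean(axis=-1, keepdims=True)


def _classifier(model: str, seed: int):
    if model == "logistic":
        return LogisticRegression(max_iter=2000)
    if model == "svm":
        return LinearSVC()
    return RandomForestClassifier(random_state=seed)


def _regressor(model: str, seed: int):
    if model == "logistic":
        return LinearRegression()
    if model == "svm":
        return LinearSVR(max_iter=5000)
    return RandomForestRegressor(random_state=seed)


def _scores(fitted, X: np.ndarray) -> np.ndarray:
    if hasattr(fitted, "predict_proba"):
        return fitted.predict_proba(X)[:, 1]
    if hasattr(fitted, "decision_function"):
        return fitted.decision_function(X)
    return fitted.predict(X)


def cross_validated_eval(
    dataset: LabeledDataset,
    augmenter: str,
    tree: PhyloTree | None,
    aug_config: AugmentConfig,
    eval_config: EvalConfig,
) -> MetricsReport:
    """Repeated stratified k-fold evaluation of one augmentation method.

    Augmentation sees only the training fold; its provenance indices are
    checked against the fold to guarantee no test-set leakage.
    """
    if augmenter not in AUGMENTERS:
        raise ValueError(f"augmenter must be one of {AUGMENTERS}")
    if augmenter == "phylomix" and tree is None:
        raise ValueError("phylomix augmentation requires a tree")
    y = dataset.y
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("cross_validated_eval requires binary 0/1 labels")

    aurocs = np.empty(eval_config.n_repeats)
    auprcs = np.empty(eval_config.n_repeats)
    for rep in range(eval_config.n_repeats):
        skf = StratifiedKFold(
            n_splits=eval_config.n_folds,
            shuffle=True,
            random_state=eval_config.seed + rep,
        )
        scores = np.empty(dataset.n)
        for fold, (tr, te) in enumerate(skf.split(dataset.X, y)):
            if len(np.unique(y[tr])) < 2:
                raise ValueError("single-class training fold; reduce n_folds")
            Xtr, ytr = dataset.X[tr], y[tr]
            fold_seed = int(
                np.random.default_rng(
                    [eval_config.seed, rep, fold]
                ).integers(2**31)
            )
            if augmenter == "none":
                model = _classifier(eval_config.model, fold_seed)
            else:
                sub = LabeledDataset(
                    X=Xtr, y=ytr, taxa=dataset.taxa, mode=dataset.mode
                )
                cfg = replace(aug_config, seed=fold_seed)
                if augmenter == "phylomix":
                    synth = phylomix_augment(sub, tree, cfg)
                else:
                    synth = vanilla_mixup(sub, cfg)
                for rec in synth.provenance:
                    if rec.i >= len(tr) or rec.j >= len(tr):
                        raise AssertionError("augmentation leaked test samples")
                Xtr = np.vstack([Xtr, synth.X])
                ytr = np.concatenate([ytr, synth.y])
                model = _regressor(eval_config.model, fold_seed)
            Xte = dataset.X[te]
            if eval_config.clr:
                Xtr = clr_transform(Xtr, eval_config.pseudocount)
                Xte = clr_transform(Xte, eval_config.pseudocount)
            model.fit(Xtr, ytr)
            scores[te] = _scores(model, Xte)
        aurocs[rep] = roc_auc_score(y, scores)
        auprcs[rep] = average_precision_score(y, scores)
    return MetricsReport(augmenter, eval_config.model, aurocs, auprcs)


def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """One-tailed pooled two-sample t-test of mean(a) > mean(b).

    Returns (t, p). With zero pooled variance the test degenerates: p is 0.5
    for equal means, 0 or 1 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    diff = a.mean() - b.mean()
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if denom == 0.0:
        if diff == 0.0:
            return 0.0, 0.5
        return (np.inf, 0.0) if diff > 0 else (-np.inf, 1.0)
    t = diff / denom
    p = float(stats.t.sf(t, df))
    return float(t), p


def _stars(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_methods(
    reports: list[MetricsReport], metric: str = "auprc"
) -> pd.DataFrame:
    """Pairwise one-tailed comparisons (earlier report > later report)."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    n_rep = {len(getattr(r, metric)) for r in reports}
    if len(n_rep) != 1:
        raise ValueError("reports have mismatched repeat counts")
    rows = []
    for ra, rb in combinations(reports, 2):
        va = getattr(ra, metric)
        vb = getattr(rb, metric)
        t, p = two_sample_t(va, vb)
        rows.append(
            {
                "method_a": ra.method,
                "method_b": rb.method,
                "metric": metric,
                "mean_a": float(np.mean(va)),
                "mean_b": float(np.mean(vb)),
                "diff": float(np.mean(va) - np.mean(vb)),
                "t": t,
                "p": p,
                "stars": _stars(p),
            }
        )
    return pd.DataFrame(rows)
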