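"""miRNA risk score and ROC evaluation.

The diagnostic model is a fixed linear combination of miRNA expression
values, S = intercept + Σ β_i·x_i. Coefficients can be fitted from a labeled
panel (minimum-norm least squares on standardized features — the panel
regime here is p features >> n samples, where ordinary least squares is
underdetermined) or loaded from a coefficient file. A 19-miRNA reference
coefficient set ships with the package.

Model transfer mirrors real validation sets: features absent from a
validation panel simply contribute nothing to the score (coefficients are
not renormalized), and the evaluation reports which model features were
available.

AUC is the midrank Mann-Whitney statistic — the probability that a random
case outscores a random control, ties counted half.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, RiskModel

log = logging.getLogger(__name__)

_REFERENCE_COEFFS = "reference_19mirna_coefficients.tsv"


@dataclass(frozen=True)
class ROCResult:
    """AUC plus the threshold-sweep curve as (fpr, tpr) points."""

    auc: float
    curve: tuple[tuple[float, float], ...]
    n_pos: int
    n_neg: int


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(uniq)}")
    pos = labels == 1
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present")
    return pos, ~pos


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Midrank Mann-Whitney AUC and ROC curve (higher score = positive).

    AUC = U / (n_pos * n_neg) with U computed from midranks, so tied scores
    contribute half a concordance. The curve sweeps thresholds over the
    unique scores from high to low, starting at (0, 0) and ending at (1, 1);
    tied scores move diagonally in one step, keeping both rates monotone.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_labels(np.asarray(labels))
    if scores.shape[0] != pos.shape[0]:
        raise ValueError("scores and labels must have equal length")
    n_pos, n_neg = int(pos.sum()), int(neg.sum())

    ranks = stats.rankdata(scores)  # midranks
    u = float(ranks[pos].sum()) - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = pos[order]
    curve: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and sorted_scores[j] == sorted_scores[i]:
            j += 1
        tp += int(sorted_pos[i:j].sum())
        fp += (j - i) - int(sorted_pos[i:j].sum())
        curve.append((fp / n_neg, tp / n_pos))
        i = j
    return ROCResult(auc=float(auc), curve=tuple(curve), n_pos=n_pos, n_neg=n_neg)


def fit_risk_model(panel: ExpressionMatrix, labels: Sequence[int]) -> RiskModel:
    """Minimum-norm least squares of labels on standardized miRNA features.

    With more features than samples the normal equations are rank-deficient;
    ``numpy.linalg.lstsq`` returns the unique minimum-norm solution, which is
    deterministic. Coefficients are mapped back to the raw expression scale
    so the model scores unstandardized values. Constant features get a zero
    coefficient with a warning.
    """
    labels = np.asarray(labels)
    pos, neg = _check_labels(labels)
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("need >= 2 samples per class to fit")
    x = panel.values.to_numpy(dtype=float).T  # samples x features
    features = list(panel.values.index)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) received zero coefficients",
            stacklevel=2,
        )
    sd_safe = np.where(constant, 1.0, sd)
    xs = (x - mu) / sd_safe
    xs[:, constant] = 0.0
    y = labels.astype(float)
    beta_std, *_ = np.linalg.lstsq(xs, y - y.mean(), rcond=None)
    beta_raw = np.where(constant, 0.0, beta_std / sd_safe)
    intercept = float(y.mean() - float(beta_raw @ mu))
    return RiskModel(
        coefficients={f: float(b) for f, b in zip(features, beta_raw)},
        intercept=intercept,
        provenance="fitted",
    )


def risk_score(model: RiskModel, sample_expr: Mapping[str, float]) -> tuple[float, list[str]]:
    """Score one sample; returns (score, miRNAs actually used).

    Only miRNAs present in both the model and the sample contribute; absent
    model features add 0 (no renormalization). Zero overlap is an error —
    the score would be vacuous.
    """
    used = [m for m in model.coefficients if m in sample_expr]
    if not used:
        raise ValueError("no overlap between model miRNAs and sample features")
    s = model.intercept + sum(model.coefficients[m] * float(sample_expr[m]) for m in used)
    return float(s), used


def score_panel(model: RiskModel, panel: ExpressionMatrix) -> tuple[pd.Series, list[str]]:
    """Risk score per sample of a panel; returns (scores, used features)."""
    overlap = [m for m in model.coefficients if m in panel.values.index]
    if not overlap:
        raise ValueError("no overlap between model miRNAs and panel features")
    sub = panel.values.loc[overlap]
    beta = np.array([model.coefficients[m] for m in overlap])
    scores = pd.Series(beta @ sub.to_numpy(dtype=float) + model.intercept, index=sub.columns)
    return scores, overlap


def evaluate_on_validation(
    model: RiskModel, panel: ExpressionMatrix, labels: Sequence[int]
) -> tuple[ROCResult, list[str]]:
    """Apply a trained/loaded model to a validation panel and compute ROC.

    Validation panels routinely carry only a subset of the model's miRNAs;
    the returned feature list records which were available.
    """
    scores, used = score_panel(model, panel)
    roc = roc_auc(scores.to_numpy(), np.asarray(labels))
    return roc, used


@dataclass(frozen=True)
class FeatureROC:
    """Single-feature ROC in both orientations (direction unknown a priori)."""

    feature: str
    forward: ROCResult
    auc_reversed: float

    @property
    def auc_best(self) -> float:
        return max(self.forward.auc, self.auc_reversed)


def single_feature_auc(
    panel: ExpressionMatrix, labels: Sequence[int], feature: str
) -> FeatureROC:
    """ROC of one miRNA/gene's raw expression as the score.

    Reports both orientations: AUC(x) and AUC(-x) = 1 - AUC(x), since the
    direction of a marker is not known in advance.
    """
    if feature not in panel.values.index:
        raise KeyError(f"unknown feature {feature!r}")
    fwd = roc_auc(panel.values.loc[feature].to_numpy(dtype=float), np.asarray(labels))
    return FeatureROC(feature=feature, forward=fwd, auc_reversed=1.0 - fwd.auc)


def load_coefficients(path, provenance: str = "loaded") -> RiskModel:
    """Read a 2-column TSV (mirna_id, coefficient) into a RiskModel."""
    coeffs: dict[str, float] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for ln, row in enumerate(reader, 1):
            if not row or not row[0].strip():
                continue
            if ln == 1 and not _is_number(row[1]):
                continue  # header
            if len(row) < 2 or not _is_number(row[1]):
                raise ValueError(f"{path}:{ln}: expected 'mirna_id<TAB>coefficient'")
            if row[0] in coeffs:
                raise ValueError(f"{path}:{ln}: duplicate miRNA id {row[0]!r}")
            coeffs[row[0]] = float(row[1])
    if not coeffs:
        raise ValueError(f"{path}: no coefficients found")
    return RiskModel(coefficients=coeffs, intercept=0.0, provenance=provenance)


def write_coefficients(model: RiskModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tcoefficient\n")
        for m, b in model.coefficients.items():
            fh.write(f"{m}\t{b}\n")


def reference_coefficients() -> RiskModel:
    """The packaged fixed coefficients of the 19-miRNA diagnostic risk score."""
    ref = resources.files("cernet").joinpath("data", _REFERENCE_COEFFS)
    with resources.as_file(ref) as path:
        return load_coefficients(path)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
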