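"""ROC analysis, DeLong AUC comparison and Fisher's linear discriminant.

The classifiers under study are per-animal change scores: ΔADC (therapy
animals tend to score higher), ΔVOL in percent (therapy animals tend to
score lower) and their FLDA combination.  The empirical ROC curve uses
midpoints between consecutive distinct scores as threshold candidates
(plus ∓∞ sentinels) — the convention under which printed thresholds such
as the midpoint 61.35 % are reproducible — and the "optimal" operating
point maximizes the Youden index J = sensitivity + specificity - 1.

Correlated AUCs measured on the same animals are compared with DeLong's
test via placement values (structural components).  The Fisher linear
discriminant direction is the inverse pooled within-class covariance times
the group-mean difference; it is defined only up to positive scale, so the
canonical model is unit-norm with the orientation fixed such that the
control group scores higher (therapy falls below the threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.stats

from .errors import DegenerateInputError, ValidationError
from .stats import TestResult

GREATER = "greater_is_positive"
LESS = "less_is_positive"


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    """Empirical ROC curve.  ``thresholds`` ascend and include ∓∞ sentinels;
    ``sens``/``spec`` are aligned with them.  ``auc`` is the trapezoidal area
    under (1 - spec, sens), identical to the tie-corrected rank statistic."""

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    direction: str
    positive_label: str
    n_pos: int
    n_neg: int


@dataclass
class ThresholdMetrics:
    """Operating point selected on an ROC curve."""

    threshold: float
    sens: float
    spec: float
    accuracy: float
    youden_j: float


def _positive_mask(labels, positive_label: str) -> np.ndarray:
    labels = np.asarray(labels)
    pos = labels == positive_label
    if not pos.any() or pos.all():
        raise ValidationError("both classes must be present")
    return pos


def roc_curve(scores, labels, direction: str = GREATER,
              positive_label: str = "therapy") -> ROCResult:
    """Empirical ROC curve of a score against binary group labels.

    ``direction`` states which tail is called positive: under
    ``greater_is_positive`` a case is called positive when its score exceeds
    the threshold, under ``less_is_positive`` when it falls below.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    if direction not in (GREATER, LESS):
        raise ValidationError(f"unknown direction {direction!r}")
    pos = _positive_mask(labels, positive_label)
    distinct = np.unique(scores)
    thresholds = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    if direction == GREATER:
        called_pos = scores[None, :] > thresholds[:, None]
    else:
        called_pos = scores[None, :] < thresholds[:, None]
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    sens = called_pos[:, pos].sum(axis=1) / n_pos
    spec = (~called_pos[:, ~pos]).sum(axis=1) / n_neg
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return ROCResult(
        thresholds=thresholds, sens=sens, spec=spec, auc=auc,
        direction=direction, positive_label=positive_label,
        n_pos=n_pos, n_neg=n_neg,
    )


def optimal_threshold(roc: ROCResult) -> ThresholdMetrics:
    """Youden-optimal operating point.

    Maximizes J = sens + spec - 1; ties are broken by higher specificity and
    then by lower threshold.  Accuracy comes from the raw confusion counts at
    the selected threshold.
    """
    j = roc.sens + roc.spec - 1.0
    best = 0
    for i in range(1, len(j)):
        if (j[i], roc.spec[i], -roc.thresholds[i]) > (j[best], roc.spec[best],
                                                      -roc.thresholds[best]):
            best = i
    n = roc.n_pos + roc.n_neg
    accuracy = (roc.sens[best] * roc.n_pos + roc.spec[best] * roc.n_neg) / n
    return ThresholdMetrics(
        threshold=float(roc.thresholds[best]),
        sens=float(roc.sens[best]),
        spec=float(roc.spec[best]),
        accuracy=float(accuracy),
        youden_j=float(j[best]),
    )


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

def _placement_values(scores, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Structural components of the AUC: per-positive and per-negative
    placement values (ties count 1/2), plus the AUC itself."""
    x = scores[pos][:, None]
    y = scores[~pos][None, :]
    psi = np.where(x > y, 1.0, np.where(x == y, 0.5, 0.0))
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def delong_auc_variance(scores, labels, direction: str = GREATER,
                        positive_label: str = "therapy") -> tuple[float, float]:
    """(AUC, variance of the AUC) for a single classifier via DeLong's
    structural-component estimator."""
    scores = np.asarray(scores, dtype=float)
    pos = _positive_mask(labels, positive_label)
    oriented = scores if direction == GREATER else -scores
    v10, v01, auc = _placement_values(oriented, pos)
    var = np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size
    return auc, float(var)


def delong_test(scores_a, scores_b, labels,
                directions: tuple[str, str] = (GREATER, GREATER),
                positive_label: str = "therapy") -> TestResult:
    """Two-sided DeLong test for the difference of two correlated AUCs.

    Both classifiers must be scored on the same cases (paired design).  The
    covariance matrix of the two AUCs is estimated from the placement
    values; the statistic is the z-score of the AUC difference.  Zero
    estimated variance with equal AUCs yields p = 1; with unequal AUCs it is
    a degenerate-input error.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValidationError("paired designs need equal-length score vectors")
    pos = _positive_mask(labels, positive_label)
    a = scores_a if directions[0] == GREATER else -scores_a
    b = scores_b if directions[1] == GREATER else -scores_b
    v10_a, v01_a, auc_a = _placement_values(a, pos)
    v10_b, v01_b, auc_b = _placement_values(b, pos)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / v10_a.size \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / v01_a.size
    diff = auc_a - auc_b
    if var <= 0:
        if diff == 0:
            return TestResult(0.0, 1.0, "delong", False)
        raise DegenerateInputError("zero variance with unequal AUCs")
    z = diff / np.sqrt(var)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return TestResult(float(z), float(min(p, 1.0)), "delong", False)


# ---------------------------------------------------------------------------
# Fisher's linear discriminant
# ---------------------------------------------------------------------------

@dataclass
class FLDAModel:
    """Two-class linear discriminant over (ΔVOL %, ΔADC).

    ``score = w_dvol * d_vol_pct + w_dadc * d_adc``; the orientation is fixed
    such that the therapy group scores lower ("below = therapy"), so the
    projected scores feed an ROC with ``less_is_positive``.  ``scaling`` tags
    the normalization ("unit-norm" canonical, or "pinned" after rescaling).
    """

    w_dvol: float
    w_dadc: float
    scaling: str
    threshold: float
    orientation: str = "therapy_low"

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.w_dvol, self.w_dadc])

    def with_pinned_dadc(self, w_dadc: float) -> "FLDAModel":
        """Rescale by the positive factor that pins the ΔADC weight to the
        given value (reporting convenience; classification is unchanged)."""
        factor = w_dadc / self.w_dadc
        if factor <= 0:
            raise ValidationError("pinned weight must match the sign of w_dadc")
        return replace(
            self,
            w_dvol=self.w_dvol * factor,
            w_dadc=w_dadc,
            scaling="pinned",
            threshold=self.threshold * factor,
        )


def fit_flda(features, labels, positive_label: str = "therapy") -> FLDAModel:
    """Fit the Fisher discriminant combining ΔVOL (percent) and ΔADC.

    ``features`` is (n, 2) with columns (d_vol_pct, d_adc).  The weight
    direction is the inverse pooled within-class covariance (denominator
    n1 + n2 - 2) applied to the difference of group means; the canonical
    model is unit-norm and oriented so the control group scores higher.
    The stored threshold is the Youden-optimal cut of the projected scores.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != 2:
        raise ValidationError("features must be (n, 2): (d_vol_pct, d_adc)")
    pos = _positive_mask(labels, positive_label)
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValidationError("at least 2 animals per group required")
    x_pos = features[pos]
    x_neg = features[~pos]
    mean_diff = x_neg.mean(axis=0) - x_pos.mean(axis=0)
    if np.allclose(mean_diff, 0.0):
        raise DegenerateInputError("identical group means: zero discriminant direction")
    scatter = (
        (x_pos - x_pos.mean(axis=0)).T @ (x_pos - x_pos.mean(axis=0))
        + (x_neg - x_neg.mean(axis=0)).T @ (x_neg - x_neg.mean(axis=0))
    )
    pooled_cov = scatter / (len(features) - 2)
    try:
        direction = np.linalg.solve(pooled_cov, mean_diff)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(f"singular pooled scatter: {exc}") from exc
    if not np.all(np.isfinite(direction)):
        raise DegenerateInputError("singular pooled scatter")
    w = direction / np.linalg.norm(direction)
    # control must score higher; for a positive-definite pooled covariance the
    # solved direction already satisfies this, the check guards rounding
    if w @ mean_diff < 0:
        w = -w
    model = FLDAModel(w_dvol=float(w[0]), w_dadc=float(w[1]),
                      scaling="unit-norm", threshold=0.0)
    scores = project_flda(model, features)
    roc = roc_curve(scores, labels, direction=LESS, positive_label=positive_label)
    return replace(model, threshold=optimal_threshold(roc).threshold)


def project_flda(model: FLDAModel, features) -> np.ndarray:
    """Discriminant scores w_dvol * d_vol_pct + w_dadc * d_adc."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != 2:
        raise ValidationError("features must be (n, 2): (d_vol_pct, d_adc)")
    return features @ model.weights
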