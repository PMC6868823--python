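"""Diagnostic validation statistics for the four-category classifier.

Agreement between physician diagnosis (gold standard, rows) and the
algorithm (columns) is tallied in a 4x4 confusion matrix in the fixed
category order (RD, BD, HD, OED).  Each category is evaluated
one-vs-rest: the true negatives for a category are the patients the
physicians placed in the three other categories, so

    sensitivity = TP / row_total
    specificity = TN / (n - row_total),   TN = n - row_total - col_total + TP
    Youden J    = sensitivity + specificity - 1

Proportion confidence intervals default to the continuity-corrected
Wald interval p +/- (z*sqrt(p(1-p)/n) + 1/(2n)) truncated to [0, 1];
plain Wald, Wilson and Clopper-Pearson are available as options (via
statsmodels).  Global chance-corrected agreement is Cohen's kappa
(po - pe)/(1 - pe) with the common asymptotic standard error
sqrt(po(1-po)) / ((1-pe) sqrt(n)).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .core import BroadCategory, PatientRecord, ValidationError, map_dsm5_to_broad
from .rules import ClassificationStatus, RuleTable, classify

__all__ = [
    "CATEGORY_ORDER",
    "CI_METHODS",
    "ConfusionMatrix4",
    "ProportionCI",
    "DiagnosticMetrics",
    "KappaResult",
    "EvaluationReport",
    "build_confusion",
    "wald_cc_ci",
    "proportion_ci",
    "sensitivity",
    "specificity",
    "youden",
    "cohen_kappa",
    "evaluate_all",
]

#: Fixed category order used for every matrix, table and report.
CATEGORY_ORDER: tuple[BroadCategory, ...] = tuple(BroadCategory)

CI_METHODS = ("wald-cc", "wald", "wilson", "clopper-pearson")


@dataclass(frozen=True)
class ConfusionMatrix4:
    """4x4 agreement counts: rows physician (truth), columns algorithm."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (4, 4):
            raise ValidationError(f"confusion matrix must be 4x4, got {arr.shape}")
        if (arr < 0).any():
            raise ValidationError("confusion-matrix counts must be nonnegative")
        if arr.sum() == 0:
            raise ValidationError("confusion matrix is empty")
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)

    @classmethod
    def from_labels(
        cls,
        truth: Iterable[BroadCategory],
        predicted: Iterable[BroadCategory],
    ) -> "ConfusionMatrix4":
        arr = np.zeros((4, 4), dtype=np.int64)
        for t, p in zip(truth, predicted, strict=True):
            arr[t.index, p.index] += 1
        return cls(arr)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_total(self, cat: BroadCategory) -> int:
        return int(self.counts[cat.index].sum())

    def col_total(self, cat: BroadCategory) -> int:
        return int(self.counts[:, cat.index].sum())

    def diagonal(self, cat: BroadCategory) -> int:
        return int(self.counts[cat.index, cat.index])

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        labels = [c.value for c in CATEGORY_ORDER]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def build_confusion(
    records: Sequence[PatientRecord], table: RuleTable
) -> ConfusionMatrix4:
    """Tally physician category vs algorithm category over a cohort.

    Every record must carry a DSM-5 diagnosis and be screen-positive;
    offending ids are listed in the error.
    """
    if not records:
        raise ValidationError("cannot build a confusion matrix from an empty cohort")
    undiagnosed = [r.id for r in records if r.dsm5 is None]
    if undiagnosed:
        raise ValidationError(
            f"records without a DSM-5 diagnosis: {undiagnosed}"
        )
    truth, predicted, negative = [], [], []
    for rec in records:
        result = classify(rec.scoff, rec.bmi, table)
        if result.status is ClassificationStatus.SCREEN_NEGATIVE:
            negative.append(rec.id)
            continue
        truth.append(map_dsm5_to_broad(rec.dsm5))
        predicted.append(result.category)
    if negative:
        raise ValidationError(f"screen-negative records not allowed: {negative}")
    return ConfusionMatrix4.from_labels(truth, predicted)


# ---------------------------------------------------------------------------
# Proportion confidence intervals

@dataclass(frozen=True)
class ProportionCI:
    estimate: float
    lower: float
    upper: float
    level: float
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.estimate <= self.upper <= 1):
            raise ValidationError(
                f"invalid proportion CI: {self.lower}, {self.estimate}, {self.upper}"
            )


def wald_cc_ci(successes: int, n: int, level: float = 0.95) -> ProportionCI:
    """Continuity-corrected Wald interval for a binomial proportion.

    p +/- (z * sqrt(p(1-p)/n) + 1/(2n)), truncated to [0, 1].
    """
    if n < 1 or not 0 <= successes <= n:
        raise ValidationError(f"invalid counts: {successes}/{n}")
    if not 0 < level < 1:
        raise ValidationError(f"confidence level must be in (0,1), got {level}")
    p = successes / n
    z = norm.ppf((1 + level) / 2)
    half = z * np.sqrt(p * (1 - p) / n) + 1 / (2 * n)
    return ProportionCI(
        estimate=p,
        lower=max(0.0, p - half),
        upper=min(1.0, p + half),
        level=level,
        numerator=successes,
        denominator=n,
    )


def proportion_ci(
    successes: int, n: int, level: float = 0.95, method: str = "wald-cc"
) -> ProportionCI:
    """Binomial proportion CI by the requested method.

    ``wald-cc`` is computed here; ``wald``, ``wilson`` and
    ``clopper-pearson`` delegate to statsmodels.
    """
    if method == "wald-cc":
        return wald_cc_ci(successes, n, level)
    sm_method = {"wald": "normal", "wilson": "wilson", "clopper-pearson": "beta"}.get(
        method
    )
    if sm_method is None:
        raise ValidationError(f"unknown CI method {method!r}; choose from {CI_METHODS}")
    if n < 1 or not 0 <= successes <= n:
        raise ValidationError(f"invalid counts: {successes}/{n}")
    lower, upper = proportion_confint(successes, n, alpha=1 - level, method=sm_method)
    return ProportionCI(
        estimate=successes / n,
        lower=max(0.0, float(lower)),
        upper=min(1.0, float(upper)),
        level=level,
        numerator=successes,
        denominator=n,
    )


# ---------------------------------------------------------------------------
# Per-category operating characteristics

@dataclass(frozen=True)
class DiagnosticMetrics:
    category: BroadCategory
    sensitivity: ProportionCI
    specificity: ProportionCI
    youden: float


def sensitivity(
    cm: ConfusionMatrix4,
    cat: BroadCategory,
    level: float = 0.95,
    method: str = "wald-cc",
) -> ProportionCI:
    """TP / (patients the physicians placed in ``cat``)."""
    row = cm.row_total(cat)
    if row == 0:
        raise ValidationError(
            f"undefined sensitivity for {cat.value}: no true cases"
        )
    return proportion_ci(cm.diagonal(cat), row, level, method)


def specificity(
    cm: ConfusionMatrix4,
    cat: BroadCategory,
    level: float = 0.95,
    method: str = "wald-cc",
) -> ProportionCI:
    """TN / (patients in the three other categories)."""
    negatives = cm.n - cm.row_total(cat)
    if negatives == 0:
        raise ValidationError(
            f"undefined specificity for {cat.value}: no true negatives"
        )
    tn = negatives - cm.col_total(cat) + cm.diagonal(cat)
    return proportion_ci(tn, negatives, level, method)


def youden(cm: ConfusionMatrix4, cat: BroadCategory) -> float:
    """Youden index J = sensitivity + specificity - 1, unrounded."""
    return sensitivity(cm, cat).estimate + specificity(cm, cat).estimate - 1


# ---------------------------------------------------------------------------
# Cohen's kappa

@dataclass(frozen=True)
class KappaResult:
    kappa: float
    po: float
    pe: float
    se: float
    lower: float
    upper: float
    level: float
    n: int


def cohen_kappa(cm: ConfusionMatrix4, level: float = 0.95) -> KappaResult:
    """Chance-corrected agreement between the two label sources.

    po = trace/n; pe = sum_i row_i * col_i / n^2; kappa = (po-pe)/(1-pe).
    The CI uses the asymptotic se = sqrt(po(1-po)/n) / (1-pe), truncated
    to [-1, 1].
    """
    n = cm.n
    po = cm.trace / n
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    pe = float(rows @ cols) / n**2
    if pe >= 1:
        raise ValidationError("degenerate margins: chance agreement pe = 1")
    kappa = (po - pe) / (1 - pe)
    se = np.sqrt(po * (1 - po) / n) / (1 - pe)
    z = norm.ppf((1 + level) / 2)
    return KappaResult(
        kappa=kappa,
        po=po,
        pe=pe,
        se=float(se),
        lower=max(-1.0, kappa - z * se),
        upper=min(1.0, kappa + z * se),
        level=level,
        n=n,
    )


# ---------------------------------------------------------------------------
# Full evaluation and rendering

def _pct1(x: float) -> str:
    """Percentage to one decimal, half-up (display only)."""
    return str(
        Decimal(repr(float(x) * 100)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def _dec2(x: float) -> str:
    return str(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class EvaluationReport:
    """Per-category operating characteristics plus global kappa."""

    metrics: list[DiagnosticMetrics]
    kappa: KappaResult
    confusion: ConfusionMatrix4

    def to_frame(self) -> pd.DataFrame:
        rows = []
        cm = self.confusion
        for m in self.metrics:
            cat = m.category
            tp = cm.diagonal(cat)
            fn = cm.row_total(cat) - tp
            fp = cm.col_total(cat) - tp
            tn = cm.n - tp - fn - fp
            rows.append(
                {
                    "category": cat.value,
                    "tp": tp,
                    "fn": fn,
                    "fp": fp,
                    "tn": tn,
                    "sensitivity": m.sensitivity.estimate,
                    "sens_lo": m.sensitivity.lower,
                    "sens_hi": m.sensitivity.upper,
                    "specificity": m.specificity.estimate,
                    "spec_lo": m.specificity.lower,
                    "spec_hi": m.specificity.upper,
                    "youden": m.youden,
                }
            )
        return pd.DataFrame(rows)

    def render(self) -> str:
        """Aligned text: one column per category, percentages to one decimal."""
        width = 16
        header = "".ljust(18) + "".join(
            m.category.value.ljust(width) for m in self.metrics
        )
        def row(label: str, cells: list[str]) -> str:
            return label.ljust(18) + "".join(c.ljust(width) for c in cells)

        sens = [
            f"{m.sensitivity.numerator}/{m.sensitivity.denominator}"
            f"-{_pct1(m.sensitivity.estimate)}%"
            for m in self.metrics
        ]
        sens_ci = [
            f"({_pct1(m.sensitivity.lower)}-{_pct1(m.sensitivity.upper)})"
            for m in self.metrics
        ]
        spec = [
            f"{m.specificity.numerator}/{m.specificity.denominator}"
            f"-{_pct1(m.specificity.estimate)}%"
            for m in self.metrics
        ]
        spec_ci = [
            f"({_pct1(m.specificity.lower)}-{_pct1(m.specificity.upper)})"
            for m in self.metrics
        ]
        youdens = [_dec2(m.youden) for m in self.metrics]
        k = self.kappa
        lines = [
            header,
            row("Sensitivity n-%", sens),
            row("(95% CI)", sens_ci),
            row("Specificity n-%", spec),
            row("(95% CI)", spec_ci),
            row("Youden index", youdens),
            "",
            f"Cohen kappa {_dec2(k.kappa)} "
            f"({int(k.level * 100)}% CI {_dec2(k.lower)}-{_dec2(k.upper)}); "
            f"po={k.po:.4f}, pe={k.pe:.4f}, n={k.n}",
        ]
        return "\n".join(lines)


def evaluate_all(
    cm: ConfusionMatrix4, level: float = 0.95, method: str = "wald-cc"
) -> EvaluationReport:
    """Operating characteristics for all four categories plus kappa."""
    metrics = []
    for cat in CATEGORY_ORDER:
        sens = sensitivity(cm, cat, level, method)
        spec = specificity(cm, cat, level, method)
        metrics.append(
            DiagnosticMetrics(
                category=cat,
                sensitivity=sens,
                specificity=spec,
                youden=sens.estimate + spec.estimate - 1,
            )
        )
    return EvaluationReport(
        metrics=metrics, kappa=cohen_kappa(cm, level), confusion=cm
    )
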