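"""The original validation study's published results, and their reproduction.

The algorithm was validated on a cohort of 206 screen-positive adult
eating-disorder patients; the study published the 4x4 physician-vs-
algorithm confusion matrix together with per-category sensitivity,
specificity, 95% CIs, Youden indices, and the overall Cohen kappa.
This module embeds those published numbers as reference data and
recomputes every derived value from the confusion matrix alone, so the
statistics pipeline can be checked end-to-end without the study dataset.

The published percentages were not all rounded by one consistent rule
(e.g. 67/84 = 79.76% is printed as 79.7 while 3/18 = 16.67% is printed
as 16.7), so :func:`reproduce_reference` compares each computed value to
its published counterpart within one unit in the last printed digit:
0.1 for percentages, 0.01 for Youden and kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BroadCategory
from .diagnostics import ConfusionMatrix4, cohen_kappa, evaluate_all

__all__ = [
    "REFERENCE_CONFUSION",
    "REFERENCE_N",
    "PUBLISHED",
    "reference_confusion",
    "reproduce_reference",
    "ReproductionCheck",
]

#: Published confusion matrix: rows = physician diagnosis, columns =
#: algorithm category, both in (RD, BD, HD, OED) order; n = 206.
REFERENCE_CONFUSION: tuple[tuple[int, int, int, int], ...] = (
    (50, 6, 3, 6),
    (4, 27, 7, 1),
    (0, 6, 67, 11),
    (1, 9, 5, 3),
)

REFERENCE_N = 206

#: Published per-category results: sensitivity %, its 95% CI, specificity %,
#: its 95% CI, Youden index — in (RD, BD, HD, OED) order — plus kappa.
PUBLISHED = {
    "sensitivity_pct": (76.9, 69.2, 79.7, 16.7),
    "sensitivity_ci_pct": ((65.9, 87.9), (53.5, 85.0), (70.6, 88.9), (0.0, 36.7)),
    "specificity_pct": (96.4, 87.4, 87.7, 90.4),
    "specificity_ci_pct": ((93.0, 99.9), (82.1, 92.8), (81.5, 93.9), (86.0, 94.9)),
    "youden": (0.73, 0.57, 0.67, 0.07),
    "kappa": 0.59,
}

#: One unit in the last printed digit, per quantity.
_TOL_PCT = 0.1 + 1e-9
_TOL_2DP = 0.01 + 1e-9


def reference_confusion() -> ConfusionMatrix4:
    """The published validation confusion matrix as a domain object."""
    return ConfusionMatrix4(np.array(REFERENCE_CONFUSION, dtype=np.int64))


@dataclass
class ReproductionCheck:
    """Outcome of recomputing the published results from the matrix."""

    ok: bool
    mismatches: list[str]
    report_text: str


def reproduce_reference(
    ci_method: str = "wald-cc", matrix: ConfusionMatrix4 | None = None
) -> ReproductionCheck:
    """Recompute every published Table-style value from the embedded matrix.

    Each computed value must agree with its published counterpart within
    one unit in the last printed digit.  With the default CI method
    (continuity-corrected Wald) every value matches; other CI methods
    are offered to show they do not reproduce the published intervals.
    ``matrix`` overrides the embedded counts (testing hook).
    """
    cm = matrix if matrix is not None else reference_confusion()
    report = evaluate_all(cm, method=ci_method)
    mismatches: list[str] = []

    def check(name: str, computed: float, published: float, tol: float) -> None:
        if abs(computed - published) > tol:
            mismatches.append(
                f"{name}: computed {computed:.3f}, published {published}"
            )

    for i, (m, cat) in enumerate(zip(report.metrics, BroadCategory)):
        check(
            f"sensitivity[{cat.value}]",
            m.sensitivity.estimate * 100,
            PUBLISHED["sensitivity_pct"][i],
            _TOL_PCT,
        )
        lo, hi = PUBLISHED["sensitivity_ci_pct"][i]
        check(f"sensitivity_ci_lo[{cat.value}]", m.sensitivity.lower * 100, lo, _TOL_PCT)
        check(f"sensitivity_ci_hi[{cat.value}]", m.sensitivity.upper * 100, hi, _TOL_PCT)
        check(
            f"specificity[{cat.value}]",
            m.specificity.estimate * 100,
            PUBLISHED["specificity_pct"][i],
            _TOL_PCT,
        )
        lo, hi = PUBLISHED["specificity_ci_pct"][i]
        check(f"specificity_ci_lo[{cat.value}]", m.specificity.lower * 100, lo, _TOL_PCT)
        check(f"specificity_ci_hi[{cat.value}]", m.specificity.upper * 100, hi, _TOL_PCT)
        check(f"youden[{cat.value}]", m.youden, PUBLISHED["youden"][i], _TOL_2DP)

    kappa = cohen_kappa(cm)
    check("kappa", kappa.kappa, PUBLISHED["kappa"], _TOL_2DP)

    return ReproductionCheck(
        ok=not mismatches, mismatches=mismatches, report_text=report.render()
    )
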