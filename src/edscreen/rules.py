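"""The screening algorithm proper: a 104-cell rule table.

Every eligible SCOFF answer pattern (at least 2 of the 5 items positive;
26 of the 32 patterns) crossed with the four BMI classes gives 104
combinations, each mapped to one broad eating-disorder category.  The
table IS the algorithm: classification is a lookup, and the engine's job
is loading, constraint validation, and classification.

The original Expali(tm) cell-by-cell assignments are proprietary and
unpublished; only the per-class marginal counts and three worked
assignments are public.  The default table shipped here is therefore a
RECONSTRUCTION: it reproduces every published marginal count and worked
example exactly, and fills the remaining cells by documented clinical
heuristics (see :func:`default_rule_table`).  Any user table in the same
CSV format can be swapped in; :func:`validate_rule_table` reports its
fidelity to the published marginals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from pathlib import Path

import pandas as pd

from .core import (
    BmiClass,
    BroadCategory,
    ScoffResponse,
    ValidationError,
    classify_bmi,
    is_screen_positive,
)

__all__ = [
    "ScoffPattern",
    "RuleTable",
    "MarginalSpec",
    "ClassificationResult",
    "ClassificationStatus",
    "ValidationReport",
    "REFERENCE_MARGINALS",
    "WORKED_EXAMPLES",
    "enumerate_eligible_patterns",
    "default_rule_table",
    "load_rule_table",
    "write_rule_table",
    "validate_rule_table",
    "classify",
]

#: An answer pattern is an ordered 5-bit tuple (sick, control, one_stone, fat, food).
ScoffPattern = tuple[int, int, int, int, int]

RULE_COLUMNS = ("sick", "control", "one_stone", "fat", "food", "bmi_class", "category")


def is_eligible(pattern: ScoffPattern) -> bool:
    """Eligible for the algorithm: at least 2 positive answers."""
    return sum(pattern) >= 2


def enumerate_eligible_patterns() -> list[ScoffPattern]:
    """All 26 eligible patterns, in lexicographic (canonical) order."""
    return [p for p in product((0, 1), repeat=5) if sum(p) >= 2]


@dataclass
class RuleTable:
    """The 104-cell mapping (eligible pattern, BMI class) -> category.

    ``provenance`` is a free-text label: ``"default-reconstruction"`` for
    the shipped table, or the source path for a loaded one.
    """

    cells: dict[tuple[ScoffPattern, BmiClass], BroadCategory]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for (pattern, bmi_class), category in self.cells.items():
            if not is_eligible(pattern):
                raise ValidationError(
                    f"pattern {pattern} not eligible (fewer than 2 positive answers)"
                )
            if not isinstance(bmi_class, BmiClass) or not isinstance(
                category, BroadCategory
            ):
                raise ValidationError("rule-table cells must use domain enums")

    def require_complete(self) -> None:
        expected = {
            (p, c) for p in enumerate_eligible_patterns() for c in BmiClass
        }
        missing = expected - set(self.cells)
        if missing:
            pattern, bmi_class = sorted(missing)[0]
            raise ValidationError(
                f"rule table incomplete: {len(missing)} missing cells, "
                f"first missing ({pattern}, {bmi_class.label})"
            )

    def category_of(self, pattern: ScoffPattern, bmi_class: BmiClass) -> BroadCategory:
        try:
            return self.cells[(pattern, bmi_class)]
        except KeyError:
            raise ValidationError(
                f"rule table has no cell for pattern {pattern}, "
                f"class {bmi_class.label}"
            ) from None

    def marginals(self) -> pd.DataFrame:
        """Observed category counts per BMI class (rows) and category (cols)."""
        counts = pd.DataFrame(
            0,
            index=[c.label for c in BmiClass],
            columns=[cat.value for cat in BroadCategory],
        )
        for (pattern, bmi_class), category in self.cells.items():
            counts.loc[bmi_class.label, category.value] += 1
        return counts

    def __len__(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class MarginalSpec:
    """Expected cell counts per (BMI class, category) — the published marginals."""

    counts: dict[BmiClass, dict[BroadCategory, int]]

    def row(self, bmi_class: BmiClass) -> tuple[int, ...]:
        return tuple(self.counts[bmi_class][cat] for cat in BroadCategory)

    def category_totals(self) -> tuple[int, ...]:
        return tuple(
            sum(self.counts[c][cat] for c in BmiClass) for cat in BroadCategory
        )


def _marginal_spec(rows: dict[BmiClass, tuple[int, int, int, int]]) -> MarginalSpec:
    return MarginalSpec(
        counts={
            bmi_class: dict(zip(BroadCategory, row)) for bmi_class, row in rows.items()
        }
    )


#: Published per-class marginal counts of the original algorithm:
#: every underweight combination is restrictive; category totals are
#: (29, 34, 15, 26) for (RD, BD, HD, OED), grand total 104.
REFERENCE_MARGINALS = _marginal_spec(
    {
        BmiClass.UNDERWEIGHT: (26, 0, 0, 0),
        BmiClass.NORMAL: (3, 18, 1, 4),
        BmiClass.OVERWEIGHT: (0, 8, 7, 11),
        BmiClass.OBESE: (0, 8, 7, 11),
    }
)

#: The three published worked assignments:
#: items 3+4 (recent weight loss, feeling fat) at BMI 16.5 -> RD;
#: items 1+2 (vomiting, loss of control) at BMI 21 -> BD;
#: items 2+5 (loss of control, food dominates) at BMI 34 -> HD.
WORKED_EXAMPLES: tuple[tuple[ScoffPattern, BmiClass, BroadCategory], ...] = (
    ((0, 0, 1, 1, 0), BmiClass.UNDERWEIGHT, BroadCategory.RD),
    ((1, 1, 0, 0, 0), BmiClass.NORMAL, BroadCategory.BD),
    ((0, 1, 0, 0, 1), BmiClass.OBESE, BroadCategory.HD),
)


# ---------------------------------------------------------------------------
# Default reconstruction

def _affinity(category: BroadCategory, p: ScoffPattern) -> int:
    """Clinical-plausibility score of a pattern for a category.

    Heuristics: One-stone (recent weight loss) and Fat (feeling fat)
    mark restriction; Sick (self-induced vomiting) and Control (loss of
    control over eating) mark bulimic behaviour; Control plus Food
    dominating, without vomiting, marks hyperphagia.  OED takes the
    leftovers — it is the residual category.
    """
    s, c, o, f, fd = p
    if category is BroadCategory.RD:
        return 2 * o + 2 * f - s - c - fd
    if category is BroadCategory.BD:
        return 2 * s + 2 * c - o
    if category is BroadCategory.HD:
        return 2 * c + 2 * fd - 2 * s - o
    return 0


def default_rule_table() -> RuleTable:
    """The shipped default table: a constrained reconstruction.

    Construction, fully deterministic:

    1. every underweight cell is RD (forced by the published marginals);
    2. the three published worked-example cells are pinned;
    3. within each remaining BMI class, categories are filled to their
       published quota greedily in the order RD, HD, BD, with unassigned
       patterns ranked by clinical affinity (descending) then
       lexicographic pattern order; OED receives the remainder.

    The result matches every published marginal count and worked example;
    the other 75 cells are this package's reconstruction, not the
    proprietary original.
    """
    patterns = enumerate_eligible_patterns()
    cells: dict[tuple[ScoffPattern, BmiClass], BroadCategory] = {}
    pins = {(p, c): cat for p, c, cat in WORKED_EXAMPLES}

    for bmi_class in BmiClass:
        quotas = dict(zip(BroadCategory, REFERENCE_MARGINALS.row(bmi_class)))
        assigned: dict[ScoffPattern, BroadCategory] = {}
        for (p, c), cat in pins.items():
            if c is bmi_class:
                assigned[p] = cat
                quotas[cat] -= 1
        for category in (BroadCategory.RD, BroadCategory.HD, BroadCategory.BD):
            ranked = sorted(
                (p for p in patterns if p not in assigned),
                key=lambda p: (-_affinity(category, p), p),
            )
            for p in ranked[: quotas[category]]:
                assigned[p] = category
        for p in patterns:
            assigned.setdefault(p, BroadCategory.OED)
        for p, cat in assigned.items():
            cells[(p, bmi_class)] = cat

    return RuleTable(cells=cells, provenance="default-reconstruction")


def shipped_rule_table() -> RuleTable:
    """The default reconstruction as shipped on disk (``data/default_rules.csv``).

    Cell-identical to :func:`default_rule_table`; exists so the packaged
    CSV is exercised through the ordinary loader.
    """
    from importlib.resources import files

    csv_text = (files("edscreen") / "data" / "default_rules.csv").read_text("utf-8")
    table = load_rule_table(csv_text)
    table.provenance = "default-reconstruction"
    return table


# ---------------------------------------------------------------------------
# CSV I/O

def write_rule_table(table: RuleTable, path: str | Path | None = None) -> str:
    """Serialize a table as CSV in canonical (pattern, class) order.

    Returns the CSV text; writes it to ``path`` when given.
    """
    table.require_complete()
    rows = []
    for pattern in enumerate_eligible_patterns():
        for bmi_class in BmiClass:
            rows.append(
                pattern + (bmi_class.label, table.category_of(pattern, bmi_class).value)
            )
    df = pd.DataFrame(rows, columns=RULE_COLUMNS)
    text = df.to_csv(index=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def load_rule_table(source: str | Path) -> RuleTable:
    """Load a rule table from a CSV path or CSV text.

    The file must contain exactly the 104 eligible cells, each once.
    Errors carry the offending data row number (header = row 1).
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and "," not in source
    ):
        provenance = str(source)
        df = pd.read_csv(source)
    else:
        provenance = "inline-text"
        df = pd.read_csv(io.StringIO(source))
    missing_cols = [c for c in RULE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"rule-table CSV missing columns: {missing_cols}")

    cells: dict[tuple[ScoffPattern, BmiClass], BroadCategory] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        data = dict(zip(df.columns, row))
        try:
            pattern = tuple(int(data[c]) for c in RULE_COLUMNS[:5])
            if any(b not in (0, 1) for b in pattern):
                raise ValidationError(f"bits must be 0/1, got {pattern}")
            if not is_eligible(pattern):
                raise ValidationError(f"pattern {pattern} not eligible (< 2 positive)")
            bmi_class = BmiClass.from_label(data["bmi_class"])
            category = BroadCategory.from_label(data["category"])
        except (ValidationError, TypeError, ValueError) as exc:
            raise ValidationError(f"row {row_no}: {exc}") from exc
        key = (pattern, bmi_class)
        if key in cells:
            raise ValidationError(
                f"row {row_no}: duplicate cell ({pattern}, {bmi_class.label})"
            )
        cells[key] = category

    table = RuleTable(cells=cells, provenance=provenance)
    table.require_complete()
    return table


# ---------------------------------------------------------------------------
# Validation against the published constraints

@dataclass
class MarginalRow:
    bmi_class: BmiClass
    observed: tuple[int, ...]
    expected: tuple[int, ...]

    @property
    def ok(self) -> bool:
        return self.observed == self.expected


@dataclass
class ValidationReport:
    """Fidelity of a rule table to the published marginals and examples."""

    rows: list[MarginalRow]
    category_totals_observed: tuple[int, ...]
    category_totals_expected: tuple[int, ...]
    worked_examples: list[tuple[ScoffPattern, BmiClass, BroadCategory, BroadCategory]]
    # each entry: (pattern, class, expected category, observed category)

    @property
    def marginals_ok(self) -> bool:
        return all(r.ok for r in self.rows) and (
            self.category_totals_observed == self.category_totals_expected
        )

    @property
    def examples_ok(self) -> bool:
        return all(exp is obs for (_, _, exp, obs) in self.worked_examples)

    @property
    def ok(self) -> bool:
        return self.marginals_ok and self.examples_ok

    def render(self) -> str:
        lines = ["BMI class     observed (RD,BD,HD,OED)  expected            status"]
        for r in self.rows:
            lines.append(
                f"{r.bmi_class.label:<13} {str(r.observed):<25}"
                f"{str(r.expected):<20}{'pass' if r.ok else 'FAIL'}"
            )
        tot_ok = self.category_totals_observed == self.category_totals_expected
        lines.append(
            f"{'totals':<13} {str(self.category_totals_observed):<25}"
            f"{str(self.category_totals_expected):<20}{'pass' if tot_ok else 'FAIL'}"
        )
        for pattern, bmi_class, expected, observed in self.worked_examples:
            ok = expected is observed
            lines.append(
                f"worked example {pattern} {bmi_class.label}: expected "
                f"{expected.value}, observed {observed.value} "
                f"[{'pass' if ok else 'FAIL'}]"
            )
        lines.append(f"overall: {'pass' if self.ok else 'FAIL'}")
        return "\n".join(lines)


def validate_rule_table(
    table: RuleTable, spec: MarginalSpec = REFERENCE_MARGINALS
) -> ValidationReport:
    """Compare a complete table's marginals and worked examples to ``spec``.

    Failures are reported, never raised.
    """
    table.require_complete()
    observed = table.marginals()
    rows = [
        MarginalRow(
            bmi_class=c,
            observed=tuple(int(x) for x in observed.loc[c.label]),
            expected=spec.row(c),
        )
        for c in BmiClass
    ]
    cat_obs = tuple(int(observed[cat.value].sum()) for cat in BroadCategory)
    examples = [
        (p, c, cat, table.category_of(p, c)) for p, c, cat in WORKED_EXAMPLES
    ]
    return ValidationReport(
        rows=rows,
        category_totals_observed=cat_obs,
        category_totals_expected=spec.category_totals(),
        worked_examples=examples,
    )


# ---------------------------------------------------------------------------
# Classification

class ClassificationStatus(str, Enum):
    SCREEN_NEGATIVE = "screen_negative"
    CLASSIFIED = "classified"


@dataclass(frozen=True)
class ClassificationResult:
    status: ClassificationStatus
    pattern: ScoffPattern
    bmi_class: BmiClass
    category: BroadCategory | None = None

    def __post_init__(self) -> None:
        has_cat = self.category is not None
        if has_cat != (self.status is ClassificationStatus.CLASSIFIED):
            raise ValidationError("category present iff status is classified")


def classify(
    resp: ScoffResponse, bmi: float, table: RuleTable
) -> ClassificationResult:
    """Apply the algorithm to one questionnaire + BMI.

    Fewer than 2 positive answers is a negative screen and yields no
    category; otherwise the result is the table cell for the answer
    pattern and BMI class.  A pure function of (pattern, BMI class).
    """
    bmi_class = classify_bmi(bmi)
    pattern = resp.pattern
    if not is_screen_positive(resp):
        return ClassificationResult(
            status=ClassificationStatus.SCREEN_NEGATIVE,
            pattern=pattern,
            bmi_class=bmi_class,
        )
    return ClassificationResult(
        status=ClassificationStatus.CLASSIFIED,
        pattern=pattern,
        bmi_class=bmi_class,
        category=table.category_of(pattern, bmi_class),
    )
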