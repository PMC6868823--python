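"""Synthetic screen-positive cohorts with the validation study's structure.

The generator emulates the published cohort of 206 screen-positive
adult eating-disorder patients: category prevalences (65, 39, 84, 18)
out of 206 for (RD, BD, HD, OED); per-category BMI-class mixes, female
fractions and age distributions as published; and DSM-5 labels drawn
from each category's member diagnoses.

The questionnaire response model is this package's own construction
(the study was observational and published no generative model): given
the true category and the sampled BMI class, the answer pattern is
drawn uniformly from the patterns the rule table maps, in that class,
to the true category ("compatible" patterns); with probability
``epsilon`` the draw is instead uniform over the other eligible
patterns (response noise).  When no compatible pattern exists — e.g. a
bulimic patient sampled underweight, where every cell is restrictive —
the pattern is uniform over all eligible patterns, modelling structural
misclassification.  With epsilon = 0 and BMI classes restricted to
compatible ones the algorithm agrees perfectly with the truth, giving
kappa = 1 as a testable anchor; realistic discordance emerges from the
class/category incompatibilities the published BMI mixes contain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.stats import truncnorm

from .core import (
    DSM5_TO_BROAD,
    BmiClass,
    BroadCategory,
    Dsm5Diagnosis,
    PatientRecord,
    ScoffResponse,
    Sex,
    classify_bmi,
)
from .diagnostics import CATEGORY_ORDER, build_confusion, evaluate_all
from .rules import RuleTable, ScoffPattern, enumerate_eligible_patterns

__all__ = [
    "CohortConfig",
    "RecoverySummary",
    "generate_cohort",
    "recover_operating_characteristics",
]

_CATS = [c.value for c in CATEGORY_ORDER]

#: Uniform BMI sampling intervals per class (kg/m²).
BMI_RANGES = {
    BmiClass.UNDERWEIGHT: (12.0, 18.5),
    BmiClass.NORMAL: (18.5, 25.0),
    BmiClass.OVERWEIGHT: (25.0, 30.0),
    BmiClass.OBESE: (30.0, 60.0),
}

#: DSM-5 member diagnoses per broad category.
CATEGORY_MEMBERS: dict[str, list[Dsm5Diagnosis]] = {
    cat.value: [dx for dx, c in DSM5_TO_BROAD.items() if c is cat]
    for cat in CATEGORY_ORDER
}


def _normalized(probs: list[float]) -> list[float]:
    total = float(sum(probs))
    return [p / total for p in probs]


class CohortConfig(BaseModel):
    """Generator parameters; defaults are the published cohort's.

    ``prevalence`` is over (RD, BD, HD, OED); ``bmi_class_probs``,
    ``female_prob`` and ``age_mean_sd`` are per category, the BMI-class
    probabilities over (underweight, normal, overweight, obese).
    ``bmi_within_class`` is ``uniform`` (flat within each class
    interval) or ``truncnorm`` (the category's published BMI mean/SD
    truncated to the class interval).  ``epsilon`` is the response-noise
    probability.
    """

    n: int = Field(default=206, ge=1)
    seed: int = Field(default=0, ge=0)
    prevalence: dict[str, float] = Field(
        default_factory=lambda: {
            "RD": 65 / 206, "BD": 39 / 206, "HD": 84 / 206, "OED": 18 / 206,
        }
    )
    bmi_class_probs: dict[str, list[float]] = Field(
        default_factory=lambda: {
            "RD": [0.785, 0.185, 0.015, 0.015],
            "BD": [0.102, 0.487, 0.102, 0.307],
            "HD": [0.0, 0.024, 0.024, 0.952],
            "OED": [0.056, 0.222, 0.111, 0.611],
        }
    )
    bmi_within_class: str = Field(default="uniform", pattern="^(uniform|truncnorm)$")
    bmi_mean_sd: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "RD": (17.6, 3.8), "BD": (25.9, 8.1), "HD": (39.1, 7.0), "OED": (30.8, 8.3),
        }
    )
    female_prob: dict[str, float] = Field(
        default_factory=lambda: {"RD": 0.984, "BD": 1.0, "HD": 0.917, "OED": 0.944}
    )
    age_mean_sd: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "RD": (30.4, 12.1), "BD": (28.5, 9.8), "HD": (43.9, 13.9), "OED": (37.1, 15.6),
        }
    )
    epsilon: float = Field(default=0.1, ge=0.0, le=1.0)

    @field_validator("prevalence", "female_prob", "bmi_class_probs",
                     "bmi_mean_sd", "age_mean_sd")
    @classmethod
    def _check_categories(cls, v: dict) -> dict:
        if set(v) != set(_CATS):
            raise ValueError(f"keys must be exactly {_CATS}, got {sorted(v)}")
        return v

    @model_validator(mode="after")
    def _check_probs(self) -> "CohortConfig":
        if any(p < 0 for p in self.prevalence.values()):
            raise ValueError("prevalences must be nonnegative")
        if abs(sum(self.prevalence.values()) - 1) > 1e-6:
            raise ValueError("prevalences must sum to 1")
        for cat, probs in self.bmi_class_probs.items():
            if len(probs) != 4 or any(p < 0 for p in probs):
                raise ValueError(f"bmi_class_probs[{cat}] must be 4 nonnegative values")
            if not 0.98 < sum(probs) < 1.02:
                raise ValueError(f"bmi_class_probs[{cat}] must sum to ~1")
        for cat, p in self.female_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"female_prob[{cat}] must be in [0,1]")
        return self

    def compatible_with(self, table: RuleTable) -> "CohortConfig":
        """A copy whose BMI-class mix avoids structurally impossible cells.

        For each category, classes in which the table maps no pattern to
        that category get probability 0; the rest are renormalized.
        Useful as the epsilon = 0 perfect-agreement anchor.
        """
        table.require_complete()
        new_probs = {}
        for cat in CATEGORY_ORDER:
            probs = list(self.bmi_class_probs[cat.value])
            for bmi_class in BmiClass:
                if not _compatible_patterns(table, cat, bmi_class):
                    probs[bmi_class.value] = 0.0
            if sum(probs) == 0:
                raise ValueError(f"no compatible BMI class for {cat.value}")
            new_probs[cat.value] = _normalized(probs)
        return self.model_copy(update={"bmi_class_probs": new_probs})

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)

    @classmethod
    def from_file(cls, path: str) -> "CohortConfig":
        text = open(path, encoding="utf-8").read()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValueError(f"config file {path!r} must hold a mapping")
        return cls.model_validate(data)


def _compatible_patterns(
    table: RuleTable, cat: BroadCategory, bmi_class: BmiClass
) -> list[ScoffPattern]:
    return [
        p
        for p in enumerate_eligible_patterns()
        if table.category_of(p, bmi_class) is cat
    ]


def generate_cohort(config: CohortConfig, table: RuleTable) -> list[PatientRecord]:
    """Draw a synthetic screen-positive cohort; deterministic in (config, table)."""
    table.require_complete()
    rng = np.random.default_rng(config.seed)
    eligible = enumerate_eligible_patterns()
    compat = {
        (cat, bmi_class): _compatible_patterns(table, cat, bmi_class)
        for cat in CATEGORY_ORDER
        for bmi_class in BmiClass
    }

    prev = _normalized([config.prevalence[c] for c in _CATS])
    cat_idx = rng.choice(4, size=config.n, p=prev)
    records: list[PatientRecord] = []
    digits = len(str(config.n))
    for i in range(config.n):
        cat = CATEGORY_ORDER[cat_idx[i]]
        class_probs = _normalized(config.bmi_class_probs[cat.value])
        bmi_class = BmiClass(int(rng.choice(4, p=class_probs)))
        lo, hi = BMI_RANGES[bmi_class]
        if config.bmi_within_class == "truncnorm":
            mu, sd = config.bmi_mean_sd[cat.value]
            a, b = (lo - mu) / sd, (hi - mu) / sd
            bmi = float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
        else:
            bmi = float(rng.uniform(lo, hi))
        # sampled BMI must land in the intended class
        assert classify_bmi(bmi) is bmi_class

        sex = Sex.FEMALE if rng.random() < config.female_prob[cat.value] else Sex.MALE
        mu, sd = config.age_mean_sd[cat.value]
        age = float(truncnorm.rvs((18 - mu) / sd, np.inf, loc=mu, scale=sd,
                                  random_state=rng))
        dx = CATEGORY_MEMBERS[cat.value][rng.integers(len(CATEGORY_MEMBERS[cat.value]))]

        compatible = compat[(cat, bmi_class)]
        if not compatible:
            # structurally impossible cell: any eligible pattern
            pattern = eligible[rng.integers(len(eligible))]
        else:
            others = [p for p in eligible if p not in compatible]
            if others and rng.random() < config.epsilon:
                pattern = others[rng.integers(len(others))]
            else:
                pattern = compatible[rng.integers(len(compatible))]

        records.append(
            PatientRecord(
                id=f"S{i + 1:0{digits}d}",
                sex=sex,
                age=age,
                bmi=bmi,
                scoff=ScoffResponse.from_pattern(pattern),
                dsm5=dx,
            )
        )
    return records


@dataclass
class RecoverySummary:
    """Mean/SD of operating characteristics over repeated simulated cohorts."""

    per_category: pd.DataFrame  # index category; columns sens/spec mean & sd
    kappa_mean: float
    kappa_sd: float
    reps: int

    def render(self) -> str:
        lines = [self.per_category.round(4).to_string()]
        lines.append(
            f"kappa mean {self.kappa_mean:.4f} (sd {self.kappa_sd:.4f}) "
            f"over {self.reps} replicates"
        )
        return "\n".join(lines)


def recover_operating_characteristics(
    config: CohortConfig, table: RuleTable, reps: int
) -> RecoverySummary:
    """Parameter-recovery harness: simulate, evaluate, summarize.

    Runs ``reps`` independent cohorts (seeds ``config.seed + rep``),
    evaluates the full diagnostics on each, and returns mean/SD of each
    category's sensitivity and specificity plus kappa.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    sens = np.empty((reps, 4))
    spec = np.empty((reps, 4))
    kappas = np.empty(reps)
    for rep in range(reps):
        cfg = config.model_copy(update={"seed": int(config.seed + rep) % 2**31})
        records = generate_cohort(cfg, table)
        report = evaluate_all(build_confusion(records, table))
        for j, m in enumerate(report.metrics):
            sens[rep, j] = m.sensitivity.estimate
            spec[rep, j] = m.specificity.estimate
        kappas[rep] = report.kappa.kappa
    frame = pd.DataFrame(
        {
            "sensitivity_mean": sens.mean(axis=0),
            "sensitivity_sd": sens.std(axis=0, ddof=1) if reps > 1 else np.zeros(4),
            "specificity_mean": spec.mean(axis=0),
            "specificity_sd": spec.std(axis=0, ddof=1) if reps > 1 else np.zeros(4),
        },
        index=_CATS,
    )
    return RecoverySummary(
        per_category=frame,
        kappa_mean=float(kappas.mean()),
        kappa_sd=float(kappas.std(ddof=1)) if reps > 1 else 0.0,
        reps=reps,
    )
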