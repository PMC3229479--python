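"""Synthetic case-control cohorts emulating the empirical study.

The real patient-level data (591 MS cases, 600 controls typed for six
SNPs) is not public; this generator produces cohorts with the same
statistical structure so that the downstream analysis pipeline is
testable.  Per stratum the genotypes follow HWE — controls at the
observed control risk-allele frequency, cases at the allele frequency
implied by the per-allele OR — ages are truncated normal at the
reported moments (cases 45 ± 12, controls 49 ± 17, truncated to
[18, 90] years), sex is Bernoulli at the reported fractions (71% /
55% female), and genotypes go missing independently at a small
per-genotype rate calibrated so that roughly 564/591 cases and 581/600
controls have complete data.

Age and sex are generated independently of genotype, so crude and
age/sex-adjusted ORs coincide in expectation; the study gives no
genotype-demographic dependence to emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .panels import Panel, builtin_panel
from .riskmodel import case_allele_freq

__all__ = [
    "CohortSpec",
    "CohortParseError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "complete_subjects",
    "DEFAULT_MISSING_RATE",
    "AGE_RANGE",
]

AGE_RANGE = (18.0, 90.0)

# (564+581)/(591+600) complete over 6 independently missing genotypes
DEFAULT_MISSING_RATE = 1.0 - ((564 + 581) / (591 + 600)) ** (1 / 6)


class CohortParseError(ValueError):
    """A cohort file row is malformed."""


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic case-control cohort.

    Defaults reproduce the empirical study's design: 591 cases / 600
    controls, demographics as reported, and the cohort-observed panel
    (control RAFs and crude ORs) as the generative genotype model.
    """

    panel: Panel | None = None
    n_cases: int = 591
    n_controls: int = 600
    age_case_mean: float = 45.0
    age_case_sd: float = 12.0
    age_control_mean: float = 49.0
    age_control_sd: float = 17.0
    frac_female_cases: float = 0.71
    frac_female_controls: float = 0.55
    missing_rate: float = DEFAULT_MISSING_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.frac_female_cases, self.frac_female_controls, self.missing_rate):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.age_case_sd <= 0 or self.age_control_sd <= 0:
            raise ValueError("age SDs must be positive")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be nonnegative")

    def resolved_panel(self) -> Panel:
        return self.panel if self.panel is not None else builtin_panel("panel_empirical_6")


def _truncnorm_ages(mean, sd, n, rng):
    lo, hi = AGE_RANGE
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one synthetic cohort as a tidy DataFrame.

    Columns: ``subject_id``, ``status`` (1 case / 0 control), ``age``,
    ``sex`` ('F'/'M'), then one nullable-integer column per rsid with
    risk-allele counts in {0, 1, 2} (pd.NA where the genotype failed).
    Reproducible from ``spec.seed``.
    """
    panel = spec.resolved_panel()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    status = np.r_[np.ones(spec.n_cases, dtype=int), np.zeros(spec.n_controls, dtype=int)]

    age = np.empty(n)
    age[: spec.n_cases] = _truncnorm_ages(spec.age_case_mean, spec.age_case_sd, spec.n_cases, rng)
    age[spec.n_cases:] = _truncnorm_ages(
        spec.age_control_mean, spec.age_control_sd, spec.n_controls, rng
    )
    female = np.empty(n, dtype=bool)
    female[: spec.n_cases] = rng.random(spec.n_cases) < spec.frac_female_cases
    female[spec.n_cases:] = rng.random(spec.n_controls) < spec.frac_female_controls

    data = {
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "status": status,
        "age": np.round(age, 1),
        "sex": np.where(female, "F", "M"),
    }
    frame = pd.DataFrame(data)
    for v in panel.variants:
        raf_case = case_allele_freq(v.raf_controls, v.per_allele_or)
        g = np.empty(n, dtype=float)
        g[: spec.n_cases] = rng.binomial(2, raf_case, size=spec.n_cases)
        g[spec.n_cases:] = rng.binomial(2, v.raf_controls, size=spec.n_controls)
        if spec.missing_rate > 0:
            g[rng.random(n) < spec.missing_rate] = np.nan
        frame[v.rsid] = pd.array(g, dtype="Int64")
    return frame


def genotype_columns(cohort: pd.DataFrame) -> list[str]:
    fixed = {"subject_id", "status", "age", "sex"}
    return [c for c in cohort.columns if c not in fixed]


def complete_subjects(cohort: pd.DataFrame) -> pd.DataFrame:
    """Subjects with complete genotype information on all variants."""
    geno = genotype_columns(cohort)
    return cohort.loc[~cohort[geno].isna().any(axis=1)].copy()


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """TSV with missing genotypes encoded as ``NA``; lossless round trip."""
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort TSV written by :func:`write_cohort`.

    Genotype values outside {0, 1, 2} raise a :class:`CohortParseError`
    naming the offending line.
    """
    frame = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False, dtype={"subject_id": str}
    )
    for col in genotype_columns(frame):
        try:
            frame[col] = pd.array(frame[col], dtype="Int64")
        except (ValueError, TypeError) as exc:
            raise CohortParseError(f"column {col}: non-integer genotype: {exc}") from exc
        bad = frame[col].dropna()
        bad = bad[(bad < 0) | (bad > 2)]
        if len(bad):
            lineno = int(bad.index[0]) + 2  # header + 1-based
            raise CohortParseError(
                f"line {lineno}: genotype {bad.iloc[0]} in column {col} "
                "outside {0, 1, 2}"
            )
    return frame
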