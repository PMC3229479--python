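"""Bayes likelihood-ratio risk models for multi-SNP panels.

The model treats each locus as independent evidence about disease
status.  For an individual carrying genotype :math:`g_j` (0, 1 or 2
risk-allele copies) at locus :math:`j`,

.. math::

    \\mathrm{odds}_{\\mathrm{post}}
        = \\frac{p}{1-p} \\prod_j \\mathrm{LR}_j(g_j),
    \\qquad
    \\mathrm{risk} = \\frac{\\mathrm{odds}}{1 + \\mathrm{odds}},

where :math:`p` is the baseline lifetime disease risk and
:math:`\\mathrm{LR}_j(g) = P(g \\mid \\mathrm{case}) /
P(g \\mid \\mathrm{control})`.

Per-locus genotype distributions follow Hardy-Weinberg equilibrium
within controls and within cases separately.  The case allele frequency
is obtained from the control frequency by odds scaling with the
per-allele odds ratio; at small :math:`p` the control population is
indistinguishable from the general population, so published control
frequencies are used directly.  An alternative constructor that solves
genotype penetrances against a marginal-risk constraint is provided as
a numerical cross-check.

All likelihood-ratio products are accumulated in log space.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .panels import Panel, PanelValidationError, VariantSpec

__all__ = [
    "GenotypeDistribution",
    "VariantLR",
    "RiskModel",
    "EnumerationCapacityError",
    "hwe_genotype_freqs",
    "case_allele_freq",
    "build_variant_lr",
    "build_variant_lr_penetrance",
    "build_risk_model",
    "posterior_risk",
    "analytic_auc",
]

#: tie tolerance on log-odds scores in the exact AUC enumeration
_LOG_ODDS_TIE_TOL = 1e-12

#: largest panel enumerated exactly (3**k genotype combinations)
DEFAULT_ENUMERATION_CAP = 12


class EnumerationCapacityError(ValueError):
    """Panel too large for exact genotype enumeration; use Monte Carlo."""


@dataclass(frozen=True)
class GenotypeDistribution:
    """Probabilities of carrying 0, 1, 2 copies of the risk allele."""

    freq_by_count: tuple[float, float, float]

    def __post_init__(self) -> None:
        f = self.freq_by_count
        if min(f) < 0.0 or abs(sum(f) - 1.0) > 1e-12:
            raise PanelValidationError(
                f"genotype frequencies {f} must be nonnegative and sum to 1"
            )

    def __getitem__(self, g: int) -> float:
        return self.freq_by_count[g]


@dataclass(frozen=True)
class VariantLR:
    """Calibrated per-genotype likelihood ratios for one locus.

    ``lr_by_count[g]`` is P(g | case) / P(g | control); by construction
    the expectation of the LR under the control genotype distribution is
    exactly 1 (it telescopes to the sum of case genotype frequencies).
    """

    rsid: str
    lr_by_count: tuple[float, float, float]
    freq_controls: GenotypeDistribution
    freq_cases: GenotypeDistribution


@dataclass(frozen=True)
class RiskModel:
    """A panel of calibrated loci plus the baseline disease risk."""

    panel: Panel
    population_risk: float
    variant_lrs: tuple[VariantLR, ...]

    def __post_init__(self) -> None:
        if len(self.variant_lrs) != len(self.panel):
            raise PanelValidationError("one VariantLR required per panel variant")

    @property
    def prior_odds(self) -> float:
        p = self.population_risk
        return p / (1.0 - p)

    @property
    def log_lr_table(self) -> np.ndarray:
        """(K, 3) array of log likelihood ratios, panel order."""
        return np.log([v.lr_by_count for v in self.variant_lrs]).reshape(-1, 3)

    @property
    def control_freq_table(self) -> np.ndarray:
        """(K, 3) array of control genotype frequencies."""
        return np.array([v.freq_controls.freq_by_count for v in self.variant_lrs]).reshape(-1, 3)

    @property
    def case_freq_table(self) -> np.ndarray:
        """(K, 3) array of case genotype frequencies."""
        return np.array([v.freq_cases.freq_by_count for v in self.variant_lrs]).reshape(-1, 3)


def hwe_genotype_freqs(raf: float) -> GenotypeDistribution:
    """Hardy-Weinberg genotype distribution at allele frequency ``raf``."""
    if not (0.0 <= raf <= 1.0):
        raise PanelValidationError(f"allele frequency {raf} outside [0, 1]")
    q = raf
    return GenotypeDistribution(((1.0 - q) ** 2, 2.0 * q * (1.0 - q), q * q))


def case_allele_freq(raf_controls: float, per_allele_or: float) -> float:
    """Risk-allele frequency among cases implied by a per-allele OR.

    Solves q/(1-q) = OR * raf/(1-raf): the per-allele odds ratio scales
    the allele odds from controls to cases.
    """
    if not (0.0 < raf_controls < 1.0):
        raise PanelValidationError(
            f"control allele frequency {raf_controls} must lie strictly in (0, 1)"
        )
    if per_allele_or <= 0.0:
        raise PanelValidationError(f"per-allele OR {per_allele_or} must be > 0")
    odds = per_allele_or * raf_controls / (1.0 - raf_controls)
    return odds / (1.0 + odds)


def build_variant_lr(spec: VariantSpec) -> VariantLR:
    """Genotype LRs from control RAF and per-allele OR under HWE.

    HWE is imposed within controls (at the published control frequency)
    and within cases (at the odds-scaled case frequency); the LR of each
    genotype is the ratio of the two genotype frequencies.
    """
    spec.validate()
    fc = hwe_genotype_freqs(spec.raf_controls)
    fd = hwe_genotype_freqs(case_allele_freq(spec.raf_controls, spec.per_allele_or))
    if min(fc.freq_by_count) <= 0.0:
        raise PanelValidationError(
            f"{spec.rsid}: degenerate control genotype distribution {fc.freq_by_count}"
        )
    lrs = tuple(fd[g] / fc[g] for g in range(3))
    return VariantLR(rsid=spec.rsid, lr_by_count=lrs, freq_controls=fc, freq_cases=fd)


def build_variant_lr_penetrance(
    spec: VariantSpec, population_risk: float
) -> VariantLR:
    """Cross-check constructor via genotype penetrances.

    Solves the baseline penetrance f0 such that, with heterozygote odds
    OR * odds(f0) and homozygote odds OR^2 * odds(f0), the marginal risk
    over the HWE population genotype distribution equals
    ``population_risk`` (to |delta| < 1e-12).  Case/control genotype
    distributions then follow from Bayes' rule.  Agrees with
    :func:`build_variant_lr` to high accuracy at small population risk.
    """
    spec.validate()
    pop = hwe_genotype_freqs(spec.raf_controls)
    or_by_g = np.array([1.0, spec.per_allele_or, spec.per_allele_or**2])
    w = np.asarray(pop.freq_by_count)

    def marginal(f0: float) -> float:
        odds0 = f0 / (1.0 - f0)
        f = (or_by_g * odds0) / (1.0 + or_by_g * odds0)
        return float(w @ f) - population_risk

    f0 = brentq(marginal, 1e-15, 1.0 - 1e-15, xtol=1e-16, rtol=8.9e-16)
    odds0 = f0 / (1.0 - f0)
    pen = (or_by_g * odds0) / (1.0 + or_by_g * odds0)
    p = population_risk
    cases = w * pen / p
    controls = w * (1.0 - pen) / (1.0 - p)
    cases = cases / cases.sum()
    controls = controls / controls.sum()
    lrs = tuple(float(c / n) for c, n in zip(cases, controls))
    return VariantLR(
        rsid=spec.rsid,
        lr_by_count=lrs,
        freq_controls=GenotypeDistribution(tuple(controls)),
        freq_cases=GenotypeDistribution(tuple(cases)),
    )


def build_risk_model(panel: Panel, population_risk: float = 0.001) -> RiskModel:
    """Calibrate one :class:`VariantLR` per panel variant."""
    if not (0.0 < population_risk < 1.0):
        raise PanelValidationError(
            f"population_risk {population_risk} must lie in (0, 1)"
        )
    return RiskModel(
        panel=panel,
        population_risk=population_risk,
        variant_lrs=tuple(build_variant_lr(v) for v in panel.variants),
    )


def posterior_log_odds(model: RiskModel, genotype_counts: np.ndarray) -> np.ndarray:
    """Log posterior odds for an (n, K) or (K,) genotype-count array."""
    g = np.asarray(genotype_counts)
    squeeze = g.ndim == 1
    g = np.atleast_2d(g)
    k = len(model.panel)
    if g.shape[1] != k:
        raise PanelValidationError(
            f"genotype matrix has {g.shape[1]} columns; panel has {k} variants"
        )
    if g.size and (g.min() < 0 or g.max() > 2):
        raise PanelValidationError("genotype counts must be in {0, 1, 2}")
    loglr = model.log_lr_table  # (K, 3)
    log_odds = math.log(model.prior_odds) + loglr[np.arange(k), g].sum(axis=1)
    return log_odds[0] if squeeze else log_odds


def posterior_risk(model: RiskModel, genotype_counts: np.ndarray) -> np.ndarray | float:
    """Posterior disease risk(s) odds/(1+odds); log-space accumulation."""
    log_odds = posterior_log_odds(model, genotype_counts)
    # expit of log-odds
    risk = 1.0 / (1.0 + np.exp(-log_odds))
    return float(risk) if np.ndim(risk) == 0 else risk


def analytic_auc(model: RiskModel, enumeration_cap: int = DEFAULT_ENUMERATION_CAP) -> float:
    """Exact AUC by enumeration over all genotype combinations.

    Enumerates the 3**K joint genotypes; the probability of a combination
    is the product of per-locus genotype frequencies (independent loci),
    separately under cases and controls.  The AUC is the probability that
    a random case outscores a random control, ties counted half, scores
    being the posterior risks (any strictly increasing transform gives
    the same value; log-odds are used internally).
    """
    k = len(model.panel)
    if k > enumeration_cap:
        raise EnumerationCapacityError(
            f"panel of {k} variants exceeds enumeration cap {enumeration_cap} "
            "(3**k combinations); use Monte Carlo estimation instead"
        )
    if k == 0:
        return 0.5
    loglr = model.log_lr_table
    logf_ctrl = np.log(model.control_freq_table)
    logf_case = np.log(model.case_freq_table)
    combos = np.array(list(itertools.product(range(3), repeat=k)), dtype=np.int8)
    idx = np.arange(k)
    score = loglr[idx, combos].sum(axis=1)
    p_case = np.exp(logf_case[idx, combos].sum(axis=1))
    p_ctrl = np.exp(logf_ctrl[idx, combos].sum(axis=1))

    order = np.argsort(score, kind="stable")
    score, p_case, p_ctrl = score[order], p_case[order], p_ctrl[order]
    # group scores equal within tolerance
    boundaries = np.nonzero(np.diff(score) > _LOG_ODDS_TIE_TOL)[0] + 1
    groups = np.split(np.arange(score.size), boundaries)
    auc = 0.0
    ctrl_below = 0.0
    for g in groups:
        pc = p_case[g].sum()
        pn = p_ctrl[g].sum()
        auc += pc * (ctrl_below + 0.5 * pn)
        ctrl_below += pn
    return float(auc)
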