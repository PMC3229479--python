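"""Population simulation of genotypes, disease status and AUC.

Each scenario replicate draws genotypes for N individuals from the
control (≈ population, at 0.1% lifetime risk) Hardy-Weinberg genotype
frequencies, scores every individual with the Bayes posterior risk, and
assigns disease status by an independent Bernoulli draw at that risk.
Discriminative accuracy of the risk score is then the Mann-Whitney AUC
of score against status.  A scenario repeats this ``n_reps`` times
(default 100) and reports the per-replicate AUCs and their mean.

Seed policy: replicate r (attempt a, for the rare re-draws) uses
``numpy.random.SeedSequence(master_seed, spawn_key=(r, a))`` so a whole
run is reproducible from one integer and replicate streams are
independent.  The same scheme makes common-random-number comparisons
across models possible: two models evaluated at the same
(master_seed, r) see identical genotype and disease uniforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .panels import Panel, StudyConfig
from .riskmodel import RiskModel, build_risk_model, posterior_risk

__all__ = [
    "SimulatedPopulation",
    "AUCDistribution",
    "UndefinedAUCError",
    "simulate_genotypes",
    "assign_disease",
    "empirical_auc",
    "simulate_population",
    "run_scenario",
]

logger = logging.getLogger(__name__)

_MAX_ZERO_CASE_RETRIES = 5


class UndefinedAUCError(ValueError):
    """AUC is undefined when only one class is present."""


@dataclass(frozen=True)
class SimulatedPopulation:
    """Genotypes, posterior risks and disease status for one replicate."""

    genotype_counts: np.ndarray  # (n, K) int8 in {0,1,2}
    posterior: np.ndarray  # (n,) in (0,1)
    status: np.ndarray  # (n,) in {0,1}


@dataclass(frozen=True)
class AUCDistribution:
    """Per-replicate AUCs of a scenario with their arithmetic mean."""

    per_rep_auc: tuple[float, ...]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_rep_auc))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.per_rep_auc, ddof=1)) if len(self.per_rep_auc) > 1 else 0.0

    @property
    def n_reps(self) -> int:
        return len(self.per_rep_auc)


def _replicate_rng(master_seed: int, rep: int, attempt: int = 0) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(master_seed, spawn_key=(rep, attempt)))
    )


def simulate_genotypes(model: RiskModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an (n, K) genotype-count matrix from control HWE frequencies.

    Each column j is an independent Binomial(2, raf_j) draw — equivalent
    to sampling the HWE genotype distribution of variant j.  At 0.1%
    population risk the control and population frequencies coincide for
    all practical purposes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rafs = np.array([v.raf_controls for v in model.panel.variants])
    if rafs.size == 0:
        return np.zeros((n, 0), dtype=np.int8)
    return rng.binomial(2, rafs, size=(n, rafs.size)).astype(np.int8)


def assign_disease(posterior: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli disease indicator at each individual's risk."""
    posterior = np.asarray(posterior)
    return (rng.random(posterior.shape) < posterior).astype(np.int8)


def empirical_auc(scores: np.ndarray, status: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling.

    Equals brute-force counting over all case-control pairs (ties worth
    one half): AUC = (R1 - n1(n1+1)/2) / (n1 n0), with R1 the midrank sum
    of the cases.
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status)
    n1 = int(status.sum())
    n0 = status.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError(
            f"AUC undefined with {n1} cases and {n0} controls"
        )
    ranks = rankdata(scores)  # midranks
    r1 = ranks[status == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def simulate_population(
    model: RiskModel, n: int, rng: np.random.Generator
) -> SimulatedPopulation:
    """One replicate: genotypes -> posterior risks -> disease status."""
    g = simulate_genotypes(model, n, rng)
    post = posterior_risk(model, g)
    post = np.atleast_1d(post)
    status = assign_disease(post, rng)
    return SimulatedPopulation(genotype_counts=g, posterior=post, status=status)


def run_scenario(
    panel: Panel, config: StudyConfig, model: RiskModel | None = None
) -> AUCDistribution:
    """Repeated-simulation AUC for a panel under a study configuration.

    A replicate that happens to draw zero cases (possible at very small
    populations) is re-drawn with a fresh derived seed, at most
    5 retries, and the event is logged.
    """
    if model is None:
        model = build_risk_model(panel, config.population_risk)
    aucs = []
    for rep in range(config.n_reps):
        for attempt in range(_MAX_ZERO_CASE_RETRIES + 1):
            rng = _replicate_rng(config.master_seed, rep, attempt)
            pop = simulate_population(model, config.n_individuals, rng)
            n_cases = int(pop.status.sum())
            if 0 < n_cases < pop.status.size:
                break
            logger.info(
                "replicate %d attempt %d drew a single-class population "
                "(%d cases); re-drawing", rep, attempt, n_cases
            )
        else:
            raise UndefinedAUCError(
                f"replicate {rep}: no two-class population after "
                f"{_MAX_ZERO_CASE_RETRIES} retries"
            )
        auc = empirical_auc(pop.posterior, pop.status)
        logger.debug("rep=%d n_cases=%d auc=%.4f", rep, n_cases, auc)
        aucs.append(auc)
    return AUCDistribution(per_rep_auc=tuple(aucs))
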