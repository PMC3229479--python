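"""Inverse design of hypothetical risk panels.

Given a base panel, how strong must k additional (exchangeable,
identical) variants of a chosen allele frequency be for the augmented
model to reach a target mean AUC?  The answer is found by bisection on
the per-allele OR, with the Monte-Carlo objective evaluated under
common random numbers (the same replicate seeds for every candidate
OR), which makes mean AUC effectively monotone in OR.  Required ORs are
reported to one decimal; each objective evaluation averages 20
replicates by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panels import Panel, StudyConfig, VariantSpec
from .simulate import run_scenario

__all__ = [
    "SearchSpec",
    "SearchResult",
    "UnreachableTargetError",
    "augment_panel",
    "mean_auc_at",
    "required_or",
    "table4_grid",
    "DEFAULT_GRID_RAFS",
    "DEFAULT_GRID_COUNTS",
    "DEFAULT_GRID_TARGETS",
]

DEFAULT_GRID_RAFS = (0.05, 0.30, 0.50)
DEFAULT_GRID_COUNTS = (1, 5, 20, 50, 100)
DEFAULT_GRID_TARGETS = (0.70, 0.75, 0.80, 0.85)

#: stop when the OR bracket is narrower than half a reporting step
BRACKET_WIDTH = 0.05


class UnreachableTargetError(ValueError):
    """Target AUC not reachable within the OR bracket."""


@dataclass(frozen=True)
class SearchSpec:
    """One inverse-search problem: base panel + k hypothetical variants."""

    base_panel: Panel
    n_extra: int
    raf_extra: float
    target_auc: float
    reps_per_eval: int = 20
    or_max: float = 20.0

    def __post_init__(self) -> None:
        if self.n_extra < 0:
            raise ValueError("n_extra must be >= 0")
        if not (0.0 < self.raf_extra < 1.0):
            raise ValueError("raf_extra must lie in (0, 1)")


@dataclass(frozen=True)
class SearchResult:
    """Outcome of one bisection run."""

    required_or: float  # reported to one decimal
    evaluations: tuple[tuple[float, float], ...]  # (or, mean_auc) pairs
    converged: bool
    achieved_auc: float


def augment_panel(
    base: Panel, k: int, raf: float, or_value: float, name: str | None = None
) -> Panel:
    """Base panel plus ``k`` identical hypothetical variants.

    The synthetic loci are named ``synth_1 .. synth_k`` and appended
    after the base variants.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    extras = tuple(
        VariantSpec(
            gene_symbol="synthetic",
            rsid=f"synth_{i + 1}",
            chromosome="NA",
            risk_allele="A",
            raf_controls=raf,
            per_allele_or=or_value,
        )
        for i in range(k)
    )
    return base.extend(extras, name=name or f"{base.name}+{k}x(raf={raf})")


def mean_auc_at(spec: SearchSpec, or_value: float, config: StudyConfig) -> float:
    """Mean AUC of the augmented panel at a candidate OR.

    Uses ``spec.reps_per_eval`` replicates with the configuration's
    master seed, so repeated calls at different ORs share random numbers.
    """
    if or_value < 1.0:
        raise ValueError("candidate OR must be >= 1")
    panel = augment_panel(spec.base_panel, spec.n_extra, spec.raf_extra, or_value)
    dist = run_scenario(panel, config.with_(n_reps=spec.reps_per_eval))
    return dist.mean_auc


def required_or(spec: SearchSpec, config: StudyConfig) -> SearchResult:
    """Bisection for the per-allele OR reaching the target mean AUC.

    The upper bracket grows geometrically from OR 2 until the target is
    exceeded (never past ``or_max``); evaluation at the same replicate
    seeds for every candidate (common random numbers) keeps the
    objective monotone up to residual Monte-Carlo noise.  Stops when the
    bracket is narrower than 0.05 and reports the midpoint rounded to
    one decimal.  If the base panel already meets the target, the
    answer is 1.0 (no extra effect needed); if even ``or_max`` falls
    short, an :class:`UnreachableTargetError` reports the AUC achieved.
    """
    evals: list[tuple[float, float]] = []

    def f(or_value: float) -> float:
        auc = mean_auc_at(spec, or_value, config)
        evals.append((or_value, auc))
        return auc

    lo = 1.0
    auc_lo = f(lo)
    if auc_lo >= spec.target_auc:
        return SearchResult(
            required_or=1.0,
            evaluations=tuple(evals),
            converged=True,
            achieved_auc=auc_lo,
        )
    # expand the upper bracket geometrically; evaluating very large ORs
    # on many-variant panels is wasteful and numerically extreme
    hi = min(2.0, spec.or_max)
    while (auc_hi := f(hi)) < spec.target_auc:
        if hi >= spec.or_max:
            raise UnreachableTargetError(
                f"target AUC {spec.target_auc} unreachable: mean AUC at "
                f"OR {hi} is {auc_hi:.4f}"
            )
        lo = hi
        hi = min(hi * 2.0, spec.or_max)
    while hi - lo > BRACKET_WIDTH:
        mid = 0.5 * (lo + hi)
        if f(mid) >= spec.target_auc:
            hi = mid
        else:
            lo = mid
    reported = round(0.5 * (lo + hi), 1)
    achieved = evals[-1][1]
    return SearchResult(
        required_or=reported,
        evaluations=tuple(evals),
        converged=True,
        achieved_auc=achieved,
    )


def table4_grid(
    base_panel: Panel,
    config: StudyConfig,
    rafs: tuple[float, ...] = DEFAULT_GRID_RAFS,
    counts: tuple[int, ...] = DEFAULT_GRID_COUNTS,
    targets: tuple[float, ...] = DEFAULT_GRID_TARGETS,
    reps_per_eval: int = 20,
):
    """Required-OR grid over RAF x count x target-AUC cells.

    Returns a list of dict rows (raf, n_extra, target_auc, required_or,
    mean_auc_achieved, n_evals, error); per-cell failures are recorded
    and the grid continues.
    """
    rows = []
    for raf in rafs:
        for k in counts:
            for target in targets:
                spec = SearchSpec(
                    base_panel=base_panel,
                    n_extra=k,
                    raf_extra=raf,
                    target_auc=target,
                    reps_per_eval=reps_per_eval,
                )
                row = {
                    "raf": raf,
                    "n_extra": k,
                    "target_auc": target,
                    "required_or": float("nan"),
                    "mean_auc_achieved": float("nan"),
                    "n_evals": 0,
                    "error": "",
                }
                try:
                    res = required_or(spec, config)
                    row.update(
                        required_or=res.required_or,
                        mean_auc_achieved=res.achieved_auc,
                        n_evals=len(res.evaluations),
                    )
                except UnreachableTargetError as exc:
                    row["error"] = str(exc)
                rows.append(row)
    return rows
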