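"""Case-control analysis of weighted risk-allele scores.

Mirrors the empirical study's procedure on (synthetic) cohort tables:

* per-SNP logistic regression of status on risk-allele count, crude or
  age/sex-adjusted, with Wald 95% CIs and a Bonferroni significance
  flag at 0.05 / n_variants;
* the *a-priori* risk — the fraction of complete-genotype subjects who
  are cases — used as the reference for bin-level odds ratios;
* weighted risk-allele scores: sum over variants of risk-allele count
  times ln(per-allele OR) (literature effect sizes; raw-OR weighting is
  available for sensitivity);
* odds ratios of risk-allele-count bins against the a-priori odds,
  with CIs from a weighted effect-coded (sum-to-zero) logistic
  regression, optionally age/sex-adjusted;
* the AUC of the weighted score.

Only subjects with complete genotype information enter the score-based
analyses, as in the original study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import complete_subjects, genotype_columns
from .panels import Panel
from .simulate import empirical_auc

__all__ = [
    "BinOR",
    "SnpAssociation",
    "DEFAULT_BINS_6",
    "DEFAULT_BINS_5",
    "per_snp_association",
    "a_priori_risk",
    "weighted_scores",
    "binned_or_vs_prior",
    "cohort_auc",
    "plot_binned_or",
]

# allele-count bins named in the study: extremes as reported, interior
# single-count bins by design
DEFAULT_BINS_6 = ((0, 5), (6, 6), (7, 7), (8, 8), (9, 9), (10, 12))
DEFAULT_BINS_5 = ((0, 5), (6, 6), (7, 7), (8, 10))

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class SnpAssociation:
    rsid: str
    per_allele_or: float
    ci_low: float
    ci_high: float
    p_value: float
    significant_bonferroni: bool
    n_used: int
    flagged: str = ""  # nonempty when separation/degeneracy detected


@dataclass(frozen=True)
class BinOR:
    bin_label: str
    bin_range: tuple[int, int]
    n_cases: int
    n_controls: int
    or_vs_prior: float
    ci_low: float
    ci_high: float


def _design(frame: pd.DataFrame, cols: list[np.ndarray], adjust: str) -> np.ndarray:
    parts = list(cols)
    if adjust == "age_sex":
        parts.append(np.asarray(frame["age"], dtype=float))
        parts.append((frame["sex"].to_numpy() == "F").astype(float))
    elif adjust != "none":
        raise ValueError(f"adjust must be 'none' or 'age_sex', got {adjust!r}")
    return np.column_stack(parts)


def per_snp_association(
    cohort: pd.DataFrame, adjust: str = "age_sex", alpha_bonferroni: float | None = None
) -> list[SnpAssociation]:
    """Per-variant logistic regression of status on risk-allele count.

    Subjects missing the variant's genotype are dropped variant-wise.
    The Bonferroni threshold defaults to 0.05 divided by the number of
    variants (0.008 for six).  Degenerate variants (monomorphic in the
    analysed subjects) or separated fits are flagged with CIs reported
    as NaN.
    """
    geno = genotype_columns(cohort)
    if alpha_bonferroni is None:
        alpha_bonferroni = 0.05 / max(len(geno), 1)
    out = []
    for rsid in geno:
        sub = cohort.loc[~cohort[rsid].isna()]
        counts = sub[rsid].to_numpy(dtype=float)
        y = sub["status"].to_numpy(dtype=float)
        if counts.size == 0 or np.all(counts == counts[0]):
            out.append(
                SnpAssociation(rsid, np.nan, np.nan, np.nan, np.nan, False,
                               int(counts.size), flagged="monomorphic")
            )
            continue
        x = sm.add_constant(_design(sub, [counts], adjust))
        try:
            fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
            beta, se = fit.params[1], fit.bse[1]
            if not np.isfinite(se) or se > 50:
                raise ValueError("separation: unstable standard error")
            out.append(
                SnpAssociation(
                    rsid=rsid,
                    per_allele_or=float(np.exp(beta)),
                    ci_low=float(np.exp(beta - _Z95 * se)),
                    ci_high=float(np.exp(beta + _Z95 * se)),
                    p_value=float(fit.pvalues[1]),
                    significant_bonferroni=bool(fit.pvalues[1] < alpha_bonferroni),
                    n_used=int(counts.size),
                )
            )
        except Exception as exc:  # separation / convergence failure
            out.append(
                SnpAssociation(rsid, np.nan, np.nan, np.nan, np.nan, False,
                               int(counts.size), flagged=str(exc))
            )
    return out


def a_priori_risk(cohort: pd.DataFrame) -> float:
    """Fraction of complete-genotype subjects who are cases.

    This is the baseline probability that a random member of the
    analysed sample is a case, the reference for the bin-level ORs.
    """
    comp = complete_subjects(cohort)
    if len(comp) == 0:
        raise ValueError("no subjects with complete genotype information")
    return float(comp["status"].mean())


def weighted_scores(
    cohort: pd.DataFrame, panel: Panel, weight: str = "log_or"
) -> pd.DataFrame:
    """Weighted risk-allele score per complete-genotype subject.

    score = sum_j count_j * w_j with w_j = ln(OR_j) by default
    (``weight='raw_or'`` uses the OR itself, for sensitivity only).
    Returns subject_id, status, risk_allele_count (plain sum) and
    weighted_score.
    """
    if weight == "log_or":
        w = np.log([v.per_allele_or for v in panel.variants])
    elif weight == "raw_or":
        w = np.array([v.per_allele_or for v in panel.variants])
    else:
        raise ValueError(f"unknown weight scheme {weight!r}")
    comp = complete_subjects(cohort)
    missing = [v.rsid for v in panel.variants if v.rsid not in comp.columns]
    if missing:
        raise KeyError(f"cohort lacks genotype columns {missing}")
    counts = comp[[v.rsid for v in panel.variants]].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "subject_id": comp["subject_id"].to_numpy(),
            "status": comp["status"].to_numpy(),
            "age": comp["age"].to_numpy(),
            "sex": comp["sex"].to_numpy(),
            "risk_allele_count": counts.sum(axis=1).astype(int),
            "weighted_score": counts @ w,
        }
    )


def _weighted_effect_design(bin_idx: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Weighted effect (sum-to-zero by bin size) coding.

    Returns the (n, B-1) coded matrix and the bin sizes.  With this
    coding the intercept equals the bin-size-weighted mean of the bin
    log-odds, so each coefficient is a deviation from that reference.
    """
    sizes = np.bincount(bin_idx, minlength=n_bins).astype(float)
    x = np.zeros((bin_idx.size, n_bins - 1))
    last = n_bins - 1
    for b in range(n_bins - 1):
        x[bin_idx == b, b] = 1.0
        x[bin_idx == last, b] = -sizes[b] / sizes[last]
    return x, sizes


def binned_or_vs_prior(
    scores: pd.DataFrame,
    bins: tuple[tuple[int, int], ...] = DEFAULT_BINS_6,
    adjust: str = "age_sex",
) -> list[BinOR]:
    """Odds ratios of allele-count bins against the a-priori odds.

    The point estimate for a bin is its case odds over the odds in the
    whole complete-genotype sample (the a-priori reference).  CIs come
    from a logistic regression with weighted effect (sum-to-zero)
    coding of the bins — so the reference is internal to the model —
    plus age and sex when ``adjust='age_sex'``.  Empty bins are dropped.
    """
    counts = scores["risk_allele_count"].to_numpy()
    y = scores["status"].to_numpy(dtype=float)
    lo_all, hi_all = counts.min(), counts.max()
    if lo_all < bins[0][0] or hi_all > bins[-1][1]:
        raise ValueError(
            f"bins {bins} do not cover observed counts [{lo_all}, {hi_all}]"
        )
    kept = []
    bin_idx = np.full(counts.size, -1)
    for (lo, hi) in bins:
        mask = (counts >= lo) & (counts <= hi)
        if not mask.any():
            continue
        bin_idx[mask] = len(kept)
        kept.append((lo, hi))
    n_bins = len(kept)
    if n_bins < 2:
        raise ValueError("need at least two non-empty bins")

    coded, sizes = _weighted_effect_design(bin_idx, n_bins)
    x = sm.add_constant(_design(scores, [coded], adjust))
    fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
    beta = fit.params[1:n_bins]
    cov = fit.cov_params()[1:n_bins, 1:n_bins]
    # effect of the last bin is determined by the sum-to-zero constraint
    wts = sizes[:-1] / sizes[-1]
    beta_last = -wts @ beta
    se_last = float(np.sqrt(wts @ cov @ wts))
    betas = np.r_[beta, beta_last]
    ses = np.r_[np.sqrt(np.diag(cov)), se_last]

    odds_overall = y.mean() / (1.0 - y.mean())
    out = []
    for b, (lo, hi) in enumerate(kept):
        mask = bin_idx == b
        n_case = int(y[mask].sum())
        n_ctrl = int(mask.sum() - n_case)
        if n_case == 0 or n_ctrl == 0:
            point = float(np.exp(betas[b]))  # crude odds degenerate
        else:
            point = (n_case / n_ctrl) / odds_overall
        half = _Z95 * ses[b]
        out.append(
            BinOR(
                bin_label=f"{lo}" if lo == hi else f"{lo}-{hi}",
                bin_range=(lo, hi),
                n_cases=n_case,
                n_controls=n_ctrl,
                or_vs_prior=point,
                ci_low=point * float(np.exp(-half)),
                ci_high=point * float(np.exp(half)),
            )
        )
    return out


def cohort_auc(scores: pd.DataFrame) -> float:
    """AUC of the weighted risk-allele score against case status."""
    return empirical_auc(
        scores["weighted_score"].to_numpy(dtype=float),
        scores["status"].to_numpy(dtype=int),
    )


def plot_binned_or(bin_ors: list[BinOR], path, title: str = "Weighted risk-allele score") -> None:
    """Bin-vs-OR figure with 95% CI whiskers on a log odds axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = np.arange(len(bin_ors))
    ors = [b.or_vs_prior for b in bin_ors]
    lows = [b.or_vs_prior - b.ci_low for b in bin_ors]
    highs = [b.ci_high - b.or_vs_prior for b in bin_ors]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(xs, ors, yerr=[lows, highs], fmt="o", capsize=4, color="k")
    ax.axhline(1.0, ls="--", lw=1, color="grey")
    ax.set_yscale("log")
    ax.set_xticks(xs, [b.bin_label for b in bin_ors])
    ax.set_xlabel("Number of risk alleles")
    ax.set_ylabel("OR vs a-priori risk (95% CI)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
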