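"""Heterogeneity, outlier, directionality and concordance diagnostics.

For one exposure–outcome analysis this module provides Cochran's Q
around the IVW fit and Rucker's Q′ around the Egger fit (with their
difference as the model-choice statistic), radial-MR per-SNP
heterogeneity contributions with Bonferroni-corrected outlier flags,
leave-one-out re-estimation, the Steiger directionality test, and the
three-way agree/disagree/uncertain concordance classification of a
sensitivity estimator against the IVW result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import TraitMeta
from .instruments import HarmonizedSet, variance_explained
from .estimators import MRResult, ivw, egger, ivw_q, ratios_and_weights, _normal_p


class QTest(NamedTuple):
    q: float
    df: int
    pval: float


class RuckerQ(NamedTuple):
    q_prime: float
    df: int
    pval: float
    q_diff: float       # Q − Q′, 1 df: evidence for directional pleiotropy
    q_diff_pval: float


def cochran_q(hs: HarmonizedSet) -> QTest:
    """Cochran's Q heterogeneity of the Wald ratios around the
    fixed-effects IVW estimate; J−1 df, chi-square upper-tail p."""
    if hs.n_snps < 2:
        raise ValueError("cochran_q needs at least 2 SNPs")
    q = ivw_q(hs)
    df = hs.n_snps - 1
    return QTest(q, df, float(stats.chi2.sf(q, df)))


def rucker_q(hs: HarmonizedSet) -> RuckerQ:
    """Rucker's Q′: weighted residual sum of squares of the Egger fit
    (J−2 df), plus the 1-df model-choice statistic Q − Q′."""
    if hs.n_snps < 3:
        raise ValueError("rucker_q needs at least 3 SNPs")
    q = ivw_q(hs)
    q_prime = float(egger(hs).extra["q_prime"])
    df = hs.n_snps - 2
    q_diff = max(q - q_prime, 0.0)
    return RuckerQ(
        q_prime, df, float(stats.chi2.sf(q_prime, df)), q_diff, float(stats.chi2.sf(q_diff, 1))
    )


def radial_ivw(
    hs: HarmonizedSet, alpha_outlier: float = 0.05, bonferroni: bool = True
) -> tuple[MRResult, list[str], pd.DataFrame]:
    """Radial (modified second-order-free) IVW with per-SNP outlier flags.

    Regressing β_j·√w_j on √w_j through the origin (w_j = γ_j²/se_Γj²)
    reproduces the fixed-effects IVW slope exactly; the per-SNP squared
    weighted residual q_j = w_j(β_j − β̂)² sums to Cochran's Q.  SNP j is
    flagged when q_j exceeds the chi-square(1) upper-α point, with α
    Bonferroni-divided by J by default.  Returns the slope result, the
    flagged SNP ids, and the radial plot coordinates (x = √w, y = β·√w,
    one row per SNP).
    """
    if hs.n_snps < 2:
        raise ValueError("radial_ivw needs at least 2 SNPs")
    b, w = ratios_and_weights(hs)
    slope = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    res = MRResult(
        method="radial_ivw", beta=slope, se=se, pval=_normal_p(slope, se), n_snp=hs.n_snps
    )
    q_j = w * (b - slope) ** 2
    alpha = alpha_outlier / hs.n_snps if bonferroni else alpha_outlier
    crit = float(stats.chi2.isf(alpha, 1))
    snp = hs.pairs["SNP"].to_numpy()
    outliers = [str(s) for s, q in zip(snp, q_j) if q > crit]
    coords = pd.DataFrame(
        {"SNP": snp, "x": np.sqrt(w), "y": b * np.sqrt(w), "q_j": q_j, "outlier": q_j > crit}
    )
    return res, outliers, coords


def leave_one_out(hs: HarmonizedSet) -> list[tuple[str, MRResult]]:
    """Re-estimate the multiplicative random-effects IVW J times, each
    time omitting one SNP; order follows the harmonized set."""
    if hs.n_snps < 2:
        raise ValueError("leave_one_out needs at least 2 SNPs")
    out = []
    for snp in hs.pairs["SNP"]:
        out.append((str(snp), ivw(hs.drop(str(snp)), model="multiplicative_random")))
    return out


@dataclass
class SteigerResult:
    """Directionality verdict from comparing instrument variance explained."""

    r2_exposure: float
    r2_outcome: float
    direction: str  # exposure_to_outcome | outcome_to_exposure
    z_diff: float
    pval: float
    note: str = ""


def steiger(
    hs: HarmonizedSet,
    exposure_meta: TraitMeta | None = None,
    outcome_meta: TraitMeta | None = None,
) -> SteigerResult:
    """Steiger directionality test.

    The instrument's variance explained in each trait is the sum of
    per-SNP z²/(z²+n); the causal direction is oriented toward the trait
    in which the SNPs explain less variance.  The two correlations
    (√r²) are compared via Fisher's r-to-z with the usual 1/(n−3)
    variances.  For a binary outcome the same z-based quantity is used
    as a pseudo-r² on the log-odds scale (flagged in ``note``).
    """
    exposure_meta = exposure_meta or hs.exposure_meta
    outcome_meta = outcome_meta or hs.outcome_meta
    gamma, se_g, big_gamma, se_big = hs.arrays()
    n_exp, n_out = exposure_meta.n_total, outcome_meta.n_total
    r2_exp = min(variance_explained(gamma / se_g, n=n_exp), 1.0 - 1e-12)
    r2_out = min(variance_explained(big_gamma / se_big, n=n_out), 1.0 - 1e-12)
    z1 = np.arctanh(np.sqrt(r2_exp))
    z2 = np.arctanh(np.sqrt(r2_out))
    denom = np.sqrt(1.0 / max(n_exp - 3, 1) + 1.0 / max(n_out - 3, 1))
    z_diff = float((z1 - z2) / denom)
    direction = "exposure_to_outcome" if r2_exp > r2_out else "outcome_to_exposure"
    note = "pseudo-r2 on log-odds scale (binary outcome)" if outcome_meta.trait_type == "binary" else ""
    return SteigerResult(
        r2_exposure=float(r2_exp),
        r2_outcome=float(r2_out),
        direction=direction,
        z_diff=z_diff,
        pval=float(2.0 * stats.norm.sf(abs(z_diff))),
        note=note,
    )


def classify_concordance(
    ivw_res: MRResult, other: MRResult, alpha: float = 0.05, mode: str = "ci_overlap"
) -> str:
    """Three-way concordance of a sensitivity estimator with the IVW result.

    ``uncertain`` when the sensitivity estimator's p-value does not reach
    ``alpha``; otherwise ``agree`` when the direction of effect matches
    the IVW estimate and (by default) the two 95% CIs overlap —
    the magnitude criterion; ``mode="sign_only"`` drops the CI-overlap
    requirement.  ``disagree`` otherwise.
    """
    if mode not in ("ci_overlap", "sign_only"):
        raise ValueError("mode must be 'ci_overlap' or 'sign_only'")
    if other.pval >= alpha:
        return "uncertain"
    same_sign = np.sign(other.beta) == np.sign(ivw_res.beta)
    if mode == "sign_only":
        return "agree" if same_sign else "disagree"
    overlap = (other.ci_low <= ivw_res.ci_high) and (ivw_res.ci_low <= other.ci_high)
    return "agree" if (same_sign and overlap) else "disagree"


@dataclass
class SensitivityReport:
    """Full diagnostic battery for one exposure–outcome analysis."""

    q: float
    q_df: int
    q_pval: float
    rucker_q: float
    rucker_df: int
    rucker_pval: float
    egger_intercept: tuple[float, float, float]  # (estimate, se, p)
    radial_outliers: list[str]
    loo: list[tuple[str, MRResult]]
    steiger: SteigerResult
    concordance: dict = field(default_factory=dict)


def sensitivity_report(
    hs: HarmonizedSet,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    concordance_mode: str = "ci_overlap",
) -> SensitivityReport:
    """Run the whole battery (Q, Q′, Egger intercept, radial outliers,
    leave-one-out, Steiger, concordance labels vs the IVW result)."""
    from .estimators import weighted_median, mode_based

    ivw_res = ivw(hs, model="multiplicative_random")
    q = cochran_q(hs)
    rq = rucker_q(hs)
    egg = egger(hs)
    wme = weighted_median(hs, n_boot=n_boot, seed=seed)
    mbe = mode_based(hs, n_boot=n_boot, seed=seed + 1)
    _, outliers, _ = radial_ivw(hs)
    return SensitivityReport(
        q=q.q,
        q_df=q.df,
        q_pval=q.pval,
        rucker_q=rq.q_prime,
        rucker_df=rq.df,
        rucker_pval=rq.pval,
        egger_intercept=(
            egg.extra["intercept"], egg.extra["intercept_se"], egg.extra["intercept_pval"]
        ),
        radial_outliers=outliers,
        loo=leave_one_out(hs),
        steiger=steiger(hs),
        concordance={
            "egger": classify_concordance(ivw_res, egg, alpha, concordance_mode),
            "wme": classify_concordance(ivw_res, wme, alpha, concordance_mode),
            "mbe": classify_concordance(ivw_res, mbe, alpha, concordance_mode),
        },
    )
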