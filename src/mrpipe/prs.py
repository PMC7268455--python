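"""PRS-style association from summary statistics, power, multiple testing.

A summary-statistic polygenic-score association relaxes the instrument
p-value threshold (default 1e-5 instead of 5e-8) to capture more trait
variance, then applies exactly the fixed-effects IVW model; it therefore
gains power at the cost of robustness to horizontal pleiotropy.
Post-hoc power for a binary-outcome MR uses the usual normal
approximation on the instrument's variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gwas_io import SummaryDataset
from .instruments import select_instruments, clump, harmonize
from .estimators import ivw


@dataclass
class PrsResult:
    """Fixed-effects IVW association of a relaxed-threshold score."""

    n_snp: int
    beta: float
    se: float
    pval: float
    p_threshold_used: float
    r2_threshold_used: float


@dataclass
class PowerResult:
    """Analytic power of a two-sided MR test on a binary outcome."""

    n_outcome: int
    case_fraction: float | None
    r2_instrument: float
    beta_target: float
    alpha: float
    power: float


def prs_association(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld=None,
    p_threshold: float = 1e-5,
    r2_threshold: float = 0.001,
) -> PrsResult:
    """Summary-statistic PRS association: select at ``P < p_threshold``,
    clump at ``r² < r2_threshold``, harmonize, then fixed-effects IVW.

    At the strict instrument threshold (5e-8) this reproduces the
    strict-instrument fixed-effects IVW exactly.
    """
    scored = select_instruments(exposure, p_threshold)
    if scored.n_snps == 0:
        raise ValueError(f"no score SNPs at P < {p_threshold:g}")
    pruned = clump(scored, ld, r2_threshold)
    hs = harmonize(pruned, outcome)
    if hs.n_snps == 0:
        raise ValueError("no score SNPs survived harmonization")
    res = ivw(hs, model="fixed")
    return PrsResult(
        n_snp=res.n_snp,
        beta=res.beta,
        se=res.se,
        pval=res.pval,
        p_threshold_used=p_threshold,
        r2_threshold_used=r2_threshold,
    )


def mr_power(
    n_outcome: int,
    case_fraction: float | None,
    r2_instrument: float,
    beta_target: float,
    alpha: float = 0.05,
) -> PowerResult:
    """Analytic power of the IVW test for a target causal effect.

    The IVW z statistic is approximately normal with mean
    ``b = √(n·R²·cf·(1−cf))·|β|`` for a binary outcome with case
    fraction ``cf`` (``case_fraction=None`` gives the continuous-outcome
    version, ``b = √(n·R²)·|β|``).  Two-sided power at level α is
    ``Φ(b − z₁₋α/₂) + Φ(−b − z₁₋α/₂)``, which equals α when β = 0 and is
    monotone in n, R² and |β|.
    """
    if not 0.0 <= r2_instrument <= 1.0:
        raise ValueError("r2_instrument must lie in [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    scale = n_outcome * r2_instrument
    if case_fraction is not None:
        if not 0.0 < case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        scale *= case_fraction * (1.0 - case_fraction)
    b = np.sqrt(scale) * abs(beta_target)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    power = float(stats.norm.cdf(b - z) + stats.norm.cdf(-b - z))
    return PowerResult(
        n_outcome=int(n_outcome),
        case_fraction=case_fraction,
        r2_instrument=float(r2_instrument),
        beta_target=float(beta_target),
        alpha=float(alpha),
        power=power,
    )


def bonferroni(alpha_family: float = 0.05, m_tests: int = 1) -> tuple[float, tuple[float, float]]:
    """Family-wise corrected strict threshold and the suggestive band.

    ``strict = alpha_family / m_tests``; the suggestive band is
    ``[strict, alpha_family)`` (empty when m_tests = 1).
    """
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    strict = alpha_family / m_tests
    return strict, (strict, alpha_family)
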