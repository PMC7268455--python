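"""Causal-effect estimators for two-sample MR.

Given J harmonized SNP pairs (γ̂_j, Γ̂_j) the per-SNP Wald ratio is
β_j = Γ̂_j/γ̂_j, and the estimators combine these with different
robustness trade-offs:

- IVW: precision-weighted combination of the ratios (equivalently
  weighted regression of Γ on γ through the origin); the multiplicative
  random-effects variant inflates the SE by residual overdispersion
  √max(1, Q/(J−1)) and is the primary analysis model.
- MR-Egger: the same regression with an unconstrained intercept; the
  intercept estimates directional pleiotropy and the slope remains
  consistent under the InSIDE assumption.
- Weighted median: consistent when ≥50% of the weight comes from valid
  instruments.
- Mode-based estimator: the mode of the weighted Wald-ratio density;
  consistent when the largest cluster of SNPs is valid.

Binary exposures are re-expressed per doubling of exposure odds by
raising the OR and CI to the power ln 2 ≈ 0.693.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gwas_io import TraitMeta, P_FLOOR
from .instruments import HarmonizedSet

#: two-sided 95% normal quantile used for all Wald-type intervals
Z95 = float(stats.norm.ppf(0.975))

#: exponent converting a per-unit OR for a binary exposure to an OR per
#: doubling of the exposure odds (ln 2)
DOUBLING_EXPONENT = math.log(2.0)


@dataclass
class MRResult:
    """One estimator's causal-effect estimate on the log-odds scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    ci_low: float = field(default=None)  # type: ignore[assignment]
    ci_high: float = field(default=None)  # type: ignore[assignment]
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ci_low is None:
            self.ci_low = self.beta - Z95 * self.se
        if self.ci_high is None:
            self.ci_high = self.beta + Z95 * self.se


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return float(1.0 if beta == 0 else P_FLOOR)
    return float(max(2.0 * stats.norm.sf(abs(beta) / se), P_FLOOR))


def _require_pairs(hs: HarmonizedSet, k: int, method: str) -> None:
    if hs.n_snps < k:
        raise ValueError(f"{method}: insufficient SNPs ({hs.n_snps} < {k})")


def ratios_and_weights(hs: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Wald ratios β_j = Γ_j/γ_j and inverse first-order-variance weights
    w_j = γ_j²/se_Γj² (unnormalised)."""
    gamma, _, big_gamma, se_big = hs.arrays()
    if np.any(gamma == 0):
        raise ValueError("zero exposure effect: Wald ratio undefined")
    return big_gamma / gamma, gamma**2 / se_big**2


def ivw_q(hs: HarmonizedSet) -> float:
    """Cochran's Q around the fixed-effects IVW estimate (ratio form)."""
    b, w = ratios_and_weights(hs)
    beta = float(np.sum(w * b) / np.sum(w))
    return float(np.sum(w * (b - beta) ** 2))


def wald_ratio(pair) -> MRResult:
    """Single-SNP causal estimate Γ/γ with first-order delta-method SE."""
    gamma = float(pair["gamma"])
    if gamma == 0:
        raise ValueError("zero exposure effect: Wald ratio undefined")
    beta = float(pair["Gamma"]) / gamma
    se = float(pair["se_Gamma"]) / abs(gamma)
    return MRResult(method="wald", beta=beta, se=se, pval=_normal_p(beta, se), n_snp=1)


def ivw(hs: HarmonizedSet, model: str = "multiplicative_random") -> MRResult:
    """Inverse-variance weighted estimate.

    Weighted regression of Γ on γ through the origin with weights
    1/se_Γ²; ``model="multiplicative_random"`` (default, the primary
    analysis model) inflates the fixed-effects SE by √max(1, Q/(J−1)),
    never deflating it; ``model="fixed"`` reports the fixed-effects SE.
    """
    if model not in ("multiplicative_random", "fixed"):
        raise ValueError(f"unknown IVW model {model!r}")
    _require_pairs(hs, 1, "ivw")
    gamma, _, big_gamma, se_big = hs.arrays()
    w = 1.0 / se_big**2
    denom = float(np.sum(w * gamma**2))
    beta = float(np.sum(w * gamma * big_gamma) / denom)
    se = 1.0 / math.sqrt(denom)
    j = hs.n_snps
    phi = 1.0
    if model == "multiplicative_random" and j >= 2:
        phi = max(1.0, ivw_q(hs) / (j - 1))
    se *= math.sqrt(phi)
    label = "ivw_mre" if model == "multiplicative_random" else "ivw_fe"
    return MRResult(
        method=label, beta=beta, se=se, pval=_normal_p(beta, se), n_snp=j,
        extra={"dispersion": phi},
    )


def egger(hs: HarmonizedSet) -> MRResult:
    """MR-Egger regression: weighted fit of Γ_j = a + b·γ_j.

    Pairs are oriented so γ_j ≥ 0 before fitting (required for the
    intercept's directional-pleiotropy interpretation).  SEs carry the
    multiplicative overdispersion √max(1, Q′/(J−2)).  The intercept, its
    SE and p-value are reported in ``extra``.
    """
    _require_pairs(hs, 3, "egger (requires a large number of instrumental SNPs)")
    gamma, _, big_gamma, se_big = hs.arrays()
    flip = np.sign(gamma)
    flip[flip == 0] = 1.0
    g = gamma * flip
    gg = big_gamma * flip
    w = 1.0 / se_big**2

    x = np.column_stack([np.ones_like(g), g])
    xtwx = x.T @ (w[:, None] * x)
    if np.linalg.cond(xtwx) > 1e12:
        raise ValueError("egger: design is collinear (no spread in instrument strengths)")
    coef = np.linalg.solve(xtwx, x.T @ (w * gg))
    a, b = float(coef[0]), float(coef[1])
    resid = gg - (a + b * g)
    j = hs.n_snps
    q_prime = float(np.sum(w * resid**2))
    phi = max(1.0, q_prime / (j - 2))
    cov = np.linalg.inv(xtwx) * phi
    se_a, se_b = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    return MRResult(
        method="egger", beta=b, se=se_b, pval=_normal_p(b, se_b), n_snp=j,
        extra={
            "intercept": a,
            "intercept_se": se_a,
            "intercept_pval": _normal_p(a, se_a),
            "q_prime": q_prime,
            "dispersion": phi,
        },
    )


def _weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of ratios b with weights w (sum 1)."""
    order = np.argsort(b, kind="mergesort")
    b, w = b[order], w[order]
    cums = np.cumsum(w) - 0.5 * w  # midpoint cumulative weight of each ratio
    if cums[0] >= 0.5:
        return float(b[0])
    if cums[-1] <= 0.5:
        return float(b[-1])
    k = int(np.searchsorted(cums, 0.5, side="right")) - 1
    frac = (0.5 - cums[k]) / (cums[k + 1] - cums[k])
    return float(b[k] + frac * (b[k + 1] - b[k]))


def _parametric_bootstrap(hs: HarmonizedSet, estimate_fn, n_boot: int, seed: int) -> float:
    """Bootstrap SD of an estimator that maps (γ*, Γ*) draws to a scalar."""
    gamma, se_g, big_gamma, se_big = hs.arrays()
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        g = rng.normal(gamma, se_g)
        gg = rng.normal(big_gamma, se_big)
        g = np.where(g == 0, 1e-300, g)
        reps[i] = estimate_fn(gg / g, g**2 / se_big**2)
    return float(reps.std(ddof=1))


def weighted_median(hs: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of the Wald ratios.

    Weights γ_j²/se_Γj² (inverse first-order ratio variance) normalised
    to sum 1; the estimate interpolates between the two ratios whose
    cumulative weights straddle 0.5.  SE from a seeded parametric
    bootstrap (normal-theory SE from the bootstrap SD).
    """
    _require_pairs(hs, 3, "weighted_median")
    b, w = ratios_and_weights(hs)
    beta = _weighted_median(b, w / w.sum())
    se = _parametric_bootstrap(hs, lambda bb, ww: _weighted_median(bb, ww / ww.sum()), n_boot, seed)
    return MRResult(
        method="wme", beta=beta, se=se, pval=_normal_p(beta, se), n_snp=hs.n_snps,
        extra={"n_boot": n_boot},
    )


def _mbe_point(b: np.ndarray, w: np.ndarray, phi: float) -> tuple[float, float]:
    """Mode of the weighted Gaussian KDE over ratios; returns (mode, bandwidth)."""
    j = len(b)
    mad = stats.median_abs_deviation(b, scale="normal")
    s = 0.9 * min(float(np.std(b, ddof=1)) if j > 1 else 0.0, float(mad)) * j ** (-1 / 5)
    h = phi * s
    if h <= 0 or not np.isfinite(h):
        # degenerate spread: fall back to the weighted median of ratios
        return _weighted_median(b, w / w.sum()), 0.0
    grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, 1024)
    dens = np.exp(-0.5 * ((grid[:, None] - b[None, :]) / h) ** 2) @ w
    return float(grid[int(np.argmax(dens))]), h


def mode_based(hs: HarmonizedSet, phi: float = 1.0, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Simple weighted mode-based estimate of the causal effect.

    The estimate is the argmax of a weighted Gaussian kernel density over
    the Wald ratios, evaluated on a fixed fine grid spanning the ratio
    range ±3 bandwidths.  Bandwidth is ``phi`` times a modified
    Silverman scale, 0.9·min(sd, MAD·1.4826)·J^(−1/5), robust to outlying
    ratios.  SE from a seeded parametric bootstrap.
    """
    _require_pairs(hs, 3, "mode_based")
    b, w = ratios_and_weights(hs)
    beta, h = _mbe_point(b, w / w.sum(), phi)
    se = _parametric_bootstrap(
        hs, lambda bb, ww: _mbe_point(bb, ww / ww.sum(), phi)[0], n_boot, seed
    )
    return MRResult(
        method="mbe", beta=beta, se=se, pval=_normal_p(beta, se), n_snp=hs.n_snps,
        extra={"bandwidth": h, "phi": phi, "n_boot": n_boot},
    )


def to_odds_ratio(res: MRResult, exposure_meta: TraitMeta) -> tuple[float, float, float]:
    """Convert a log-odds estimate to the outcome OR scale.

    Continuous exposures report the OR per 1 SD increase, ``exp(beta)``.
    Binary exposures are re-expressed per doubling of the exposure odds
    by raising OR and CI to the power ln 2 (≈0.693).
    """
    power = DOUBLING_EXPONENT if exposure_meta.trait_type == "binary" else 1.0
    return (
        math.exp(res.beta) ** power,
        math.exp(res.ci_low) ** power,
        math.exp(res.ci_high) ** power,
    )
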