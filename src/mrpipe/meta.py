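"""GWAS meta-analysis and inflation/heritability diagnostics.

Per-consortium summary statistics are combined with the fixed-effects
inverse-variance method: weights are the reciprocal squared standard
errors, the pooled effect is the weighted mean, and across-study
heterogeneity is summarised by Cochran's Q.  Test-statistic inflation is
quantified by the genomic inflation factor λGC and by univariate LD
score regression (intercept ≈ confounding/inflation, slope ≈ polygenic
heritability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import SummaryDataset, TraitMeta, P_FLOOR

logger = logging.getLogger("mrpipe")

#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


def meta_fixed(betas, ses) -> tuple[float, float, float, float]:
    """Fixed-effects inverse-variance combination of one SNP across studies.

    Returns ``(beta_meta, se_meta, pval_meta, q_het)`` where
    ``q_het = Σ w_i (β_i − β_meta)²`` is the across-study Cochran Q.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size < 1:
        raise ValueError("meta_fixed needs at least one study")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(max(2.0 * stats.norm.sf(abs(beta) / se), P_FLOOR))
    q = float(np.sum(w * (betas - beta) ** 2))
    return beta, se, p, q


def _align_to_first(rows: pd.DataFrame) -> pd.DataFrame | None:
    """Align each study's effect allele to the first study's frame.

    Swapped alleles flip the sign of beta and complement the frequency;
    any other configuration is unresolvable and drops the SNP.
    """
    ref = rows.iloc[0]
    out = rows.copy()
    same = (rows["EA"] == ref["EA"]) & (rows["OA"] == ref["OA"])
    swapped = (rows["EA"] == ref["OA"]) & (rows["OA"] == ref["EA"])
    if not bool((same | swapped).all()):
        return None
    out.loc[swapped, "BETA"] = -rows.loc[swapped, "BETA"]
    out.loc[swapped, "EAF"] = 1.0 - rows.loc[swapped, "EAF"]
    out.loc[swapped, ["EA", "OA"]] = [ref["EA"], ref["OA"]]
    return out


def meta_analyze(
    studies: list[SummaryDataset], trait_name: str | None = None
) -> tuple[SummaryDataset, pd.DataFrame]:
    """Fixed-effects meta-analysis of ≥1 per-consortium GWAS.

    SNPs present in all studies are aligned to the first study's effect
    allele and combined with :func:`meta_fixed`.  Returns the pooled
    dataset (canonical columns; N summed, EAF precision-weighted) and a
    per-SNP table with ``n_studies`` and the across-study Q.  SNPs with
    irreconcilable alleles are excluded and logged.
    """
    if not studies:
        raise ValueError("need at least one study")
    common = set(studies[0].df["SNP"])
    for s in studies[1:]:
        common &= set(s.df["SNP"])
    if not common:
        raise ValueError("no SNPs shared across studies")
    frames = [s.df.set_index("SNP") for s in studies]
    order = [snp for snp in studies[0].df["SNP"] if snp in common]

    records, dropped = [], 0
    for snp in order:
        rows = pd.DataFrame([f.loc[snp] for f in frames])
        aligned = _align_to_first(rows)
        if aligned is None:
            dropped += 1
            continue
        beta, se, p, q = meta_fixed(aligned["BETA"], aligned["SE"])
        w = 1.0 / aligned["SE"].to_numpy() ** 2
        ref = aligned.iloc[0]
        records.append(
            {
                "SNP": snp, "CHR": ref["CHR"], "POS": int(ref["POS"]),
                "EA": ref["EA"], "OA": ref["OA"],
                "EAF": float(np.sum(w * aligned["EAF"]) / np.sum(w)),
                "BETA": beta, "SE": se, "P": p,
                "N": int(aligned["N"].sum()),
                "n_studies": len(aligned), "q_het": q,
            }
        )
    if dropped:
        logger.warning("meta_analyze: excluded %d SNP(s) with irreconcilable alleles", dropped)
    if not records:
        raise ValueError("no SNPs could be meta-analysed")
    table = pd.DataFrame(records)

    m0 = studies[0].meta
    n_total = sum(s.meta.n_total for s in studies)
    n_cases = (
        sum(s.meta.n_cases for s in studies)
        if all(s.meta.n_cases is not None for s in studies) and m0.trait_type == "binary"
        else None
    )
    meta = TraitMeta(
        trait_name=trait_name or f"{m0.trait_name}_meta",
        trait_type=m0.trait_type,
        n_total=n_total,
        n_cases=n_cases,
        unit_note=m0.unit_note,
    )
    pooled = SummaryDataset(meta=meta, df=table[[c for c in table.columns if c not in ("n_studies", "q_het")]])
    return pooled, table[["SNP", "BETA", "SE", "P", "n_studies", "q_het"]].rename(
        columns={"BETA": "beta_meta", "SE": "se_meta", "P": "pval_meta"}
    )


def lambda_gc(pvals=None, zscores=None) -> float:
    """Genomic inflation factor: median test chi-square over the null median."""
    if (pvals is None) == (zscores is None):
        raise ValueError("provide exactly one of pvals, zscores")
    if zscores is not None:
        chi2 = np.asarray(zscores, dtype=float) ** 2
    else:
        p = np.asarray(pvals, dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


@dataclass
class LdscFit:
    """Univariate LD score regression fit."""

    intercept: float
    h2: float
    se_intercept: float
    se_h2: float
    M: int
    mean_chi2: float
    n_blocks: int


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    sw = np.sqrt(w)
    design = np.column_stack([np.ones_like(x), x]) * sw[:, None]
    coef, *_ = np.linalg.lstsq(design, y * sw, rcond=None)
    return float(coef[0]), float(coef[1])


def ldsc_univariate(
    table: pd.DataFrame,
    N: int,
    M: int | None = None,
    n_blocks: int = 200,
    weighting: str = "irls",
) -> LdscFit:
    """Regress per-SNP chi-square on LD score to estimate h² and intercept.

    The slope ``s`` of the regression of χ² on ℓ estimates ``N·h2/M``,
    so ``h2 = s·M/N``; the intercept absorbs confounding and residual
    inflation.  Default weighting iterates inverse squared predicted
    means (``1/(2·(1 + s·ℓ)²)``, two passes) to tame the heavy right
    tail of chi-square noise; ``weighting="ols"`` fits unweighted (exact
    on noiseless toy input).  Standard errors come from a delete-one
    block jackknife over contiguous blocks.
    """
    x = table["ld_score"].to_numpy(dtype=float)
    y = table["chi2"].to_numpy(dtype=float)
    if M is None:
        M = table.attrs.get("M", len(x))
    if len(x) < 50:
        raise ValueError("ldsc_univariate requires at least 50 SNPs")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("degenerate LD-score variance")
    if weighting not in ("irls", "ols"):
        raise ValueError("weighting must be 'irls' or 'ols'")

    def fit(xs, ys) -> tuple[float, float]:
        w = np.ones_like(xs)
        a, b = _wls(xs, ys, w)
        if weighting == "irls":
            for _ in range(2):
                pred = 1.0 + max(b, 0.0) * xs
                w = 1.0 / (2.0 * np.maximum(pred, 1e-6) ** 2)
                a, b = _wls(xs, ys, w)
        return a, b

    a_full, b_full = fit(x, y)
    nb = int(min(n_blocks, len(x)))
    bounds = np.linspace(0, len(x), nb + 1).astype(int)
    jk = np.empty((nb, 2))
    for i in range(nb):
        mask = np.ones(len(x), dtype=bool)
        mask[bounds[i] : bounds[i + 1]] = False
        jk[i] = fit(x[mask], y[mask])
    jk_mean = jk.mean(axis=0)
    jk_var = (nb - 1) / nb * np.sum((jk - jk_mean) ** 2, axis=0)
    se_a, se_b = np.sqrt(jk_var)

    scale = M / N
    return LdscFit(
        intercept=a_full,
        h2=b_full * scale,
        se_intercept=float(se_a),
        se_h2=float(se_b * scale),
        M=int(M),
        mean_chi2=float(y.mean()),
        n_blocks=nb,
    )
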