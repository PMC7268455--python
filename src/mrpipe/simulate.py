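"""Synthetic two-sample GWAS data with known truth.

Generates the statistical structure that two-sample MR assumes: an
exposure GWAS and an independent binary-outcome GWAS sharing a set of
instrument SNPs, with per-SNP pleiotropic effects under several models;
per-consortium splits for meta-analysis tests; small genotype panels
with block LD for clumping; and LD-score/chi-square tables for LD score
regression.

Everything is generated directly on the summary scale (effect, SE,
p-value) rather than from individual-level data: SEs follow the standard
per-allele approximation ``se = 1/sqrt(2 f (1-f) n)``, with binary-trait
SEs further scaled by ``1/sqrt(cf (1-cf))`` for case fraction ``cf``.
This matches how real GWAS standard errors scale with frequency and
sample size and keeps simulation fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import SummaryDataset, TraitMeta, P_FLOOR

PLEIOTROPY_MODELS = ("none", "balanced", "directional", "inside_violating")


@dataclass
class SimTruth:
    """Generating parameters of one synthetic two-sample scenario.

    Defaults mirror a desk-scale version of a glioma-type study: a
    continuous exposure measured in ~100k individuals instrumented by 50
    genome-wide-significant SNPs, and a case-control outcome GWAS of
    11,240 subjects with 5739 cases (case fraction 0.51).

    ``pleiotropy_model`` controls the direct SNP-to-outcome effects α_j:

    - ``none``: α_j = 0
    - ``balanced``: α_j ~ N(0, pleio_sd) — zero mean, InSIDE holds
    - ``directional``: α_j ~ N(pleio_mean, pleio_sd) — nonzero mean
    - ``inside_violating``: α_j correlated with instrument strength γ_j
      (correlation ``inside_rho``), breaking the InSIDE assumption

    ``pleio_frac`` restricts pleiotropy to a random subset of SNPs (e.g.
    0.4 makes 40% of instruments invalid while the rest stay clean).
    """

    beta_causal: float = 0.0
    n_snps: int = 50
    pleiotropy_model: str = "none"
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    pleio_frac: float = 1.0
    gamma_dist: tuple[float, float] = (0.04, 0.01)
    inside_rho: float = 0.0
    n_exp: int = 100_000
    n_out: int = 11_240
    case_fraction: float = 5739 / 11_240
    seed: int = 0
    snp_prefix: str = "rs"

    def __post_init__(self) -> None:
        if self.pleiotropy_model not in PLEIOTROPY_MODELS:
            raise ValueError(f"unknown pleiotropy model {self.pleiotropy_model!r}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.pleiotropy_model == "none" and (self.pleio_mean != 0 or self.pleio_sd != 0):
            raise ValueError("pleiotropy 'none' requires pleio_mean = pleio_sd = 0")
        if self.pleiotropy_model == "balanced" and self.pleio_mean != 0:
            raise ValueError("balanced pleiotropy requires pleio_mean = 0")
        if not 0.0 <= self.pleio_frac <= 1.0:
            raise ValueError("pleio_frac must lie in [0, 1]")


def _draw_alpha(truth: SimTruth, gamma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Direct (pleiotropic) SNP effects on the outcome."""
    j = len(gamma)
    if truth.pleiotropy_model == "none":
        return np.zeros(j)
    if truth.pleiotropy_model in ("balanced", "directional"):
        alpha = rng.normal(truth.pleio_mean, truth.pleio_sd, j)
    else:
        # inside_violating: α has sd pleio_sd, mean pleio_mean and
        # correlation inside_rho with instrument strength γ
        rho = truth.inside_rho
        g_mean, g_sd = truth.gamma_dist
        eps = rng.normal(0.0, 1.0, j)
        std_gamma = (gamma - g_mean) / g_sd if g_sd > 0 else np.zeros(j)
        alpha = truth.pleio_mean + truth.pleio_sd * (
            rho * std_gamma + np.sqrt(max(0.0, 1 - rho**2)) * eps
        )
    if truth.pleio_frac < 1.0:
        n_invalid = int(round(truth.pleio_frac * j))
        invalid = rng.choice(j, n_invalid, replace=False)
        mask = np.zeros(j)
        mask[invalid] = 1.0
        alpha = alpha * mask
    return alpha


def _p_two_sided(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, P_FLOOR)


def _dataset(snp, chrom, pos, eaf, beta, se, n, meta) -> SummaryDataset:
    df = pd.DataFrame(
        {
            "SNP": snp,
            "CHR": chrom,
            "POS": pos,
            "EA": "A",
            "OA": "G",
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": _p_two_sided(beta, se),
            "N": n,
        }
    )
    return SummaryDataset(meta=meta, df=df)


def simulate_two_sample(
    truth: SimTruth, return_truth: bool = False
) -> tuple[SummaryDataset, SummaryDataset] | tuple[SummaryDataset, SummaryDataset, pd.DataFrame]:
    """Simulate exposure and outcome summary statistics for one scenario.

    For SNP j: instrument effect γ_j ~ N(gamma_dist), pleiotropic effect
    α_j per the pleiotropy model, true outcome effect
    Γ_j = beta_causal·γ_j + α_j.  Observed effects add independent
    Gaussian noise at the SEs implied by sample size and allele
    frequency; the two samples use independent noise streams.
    Identical ``truth`` (including seed) yields identical output.
    """
    rng = np.random.default_rng(truth.seed)
    j = truth.n_snps
    snp = np.array([f"{truth.snp_prefix}{i + 1}" for i in range(j)])
    chrom = np.array([str(1 + (i % 22)) for i in range(j)])
    pos = np.array([1_000_000 * (1 + i // 22) + 10_000 * i for i in range(j)], dtype=np.int64)

    eaf = rng.uniform(0.05, 0.95, j)
    gamma = rng.normal(truth.gamma_dist[0], truth.gamma_dist[1], j)
    alpha = _draw_alpha(truth, gamma, rng)
    big_gamma = truth.beta_causal * gamma + alpha

    se_exp = 1.0 / np.sqrt(2.0 * eaf * (1 - eaf) * truth.n_exp)
    cf = truth.case_fraction
    se_out = 1.0 / np.sqrt(2.0 * eaf * (1 - eaf) * truth.n_out * cf * (1 - cf))

    gamma_hat = gamma + rng.normal(0.0, se_exp)
    big_gamma_hat = big_gamma + rng.normal(0.0, se_out)

    exp_meta = TraitMeta(trait_name="exposure", trait_type="continuous",
                         n_total=truth.n_exp, unit_note="per SD")
    out_meta = TraitMeta(trait_name="outcome", trait_type="binary",
                         n_total=truth.n_out,
                         n_cases=int(round(cf * truth.n_out)),
                         case_fraction=cf,
                         unit_note="log odds")
    exposure = _dataset(snp, chrom, pos, eaf, gamma_hat, se_exp, truth.n_exp, exp_meta)
    outcome = _dataset(snp, chrom, pos, eaf, big_gamma_hat, se_out, truth.n_out, out_meta)
    if not return_truth:
        return exposure, outcome
    truth_df = pd.DataFrame({"SNP": snp, "gamma": gamma, "alpha": alpha, "Gamma": big_gamma})
    return exposure, outcome, truth_df


def split_consortia(ds: SummaryDataset, fractions, seed: int = 0) -> list[SummaryDataset]:
    """Split one GWAS into per-consortium studies at reduced sample size.

    Each sub-study keeps the same SNPs; its SE is the pooled SE inflated
    by ``1/sqrt(fraction)`` and its effect is the pooled effect plus
    conditional noise ``ξ_i − Σw_j ξ_j / Σw_j`` (ξ_i drawn at the
    sub-study SE, w the inverse-variance weights), so that each split
    has the correct marginal sampling variance while a fixed-effects
    inverse-variance meta-analysis of the splits reproduces the pooled
    estimate and SE exactly.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions <= 0):
        raise ValueError("fractions must be positive")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    se_pooled = ds.df["SE"].to_numpy()
    se_subs = [se_pooled / np.sqrt(f) for f in fractions]
    xi = np.stack([rng.normal(0.0, s) for s in se_subs])  # studies × SNPs
    w = np.stack([1.0 / s**2 for s in se_subs])
    xi_centered = xi - (w * xi).sum(axis=0) / w.sum(axis=0)
    out = []
    for i, f in enumerate(fractions):
        sub = ds.df.copy()
        beta_sub = sub["BETA"].to_numpy() + xi_centered[i]
        sub["BETA"] = beta_sub
        sub["SE"] = se_subs[i]
        sub["N"] = np.maximum((sub["N"].to_numpy() * f).round(), 1).astype(np.int64)
        sub["P"] = _p_two_sided(beta_sub, se_subs[i])
        m = ds.meta
        meta = TraitMeta(
            trait_name=f"{m.trait_name}_study{i + 1}",
            trait_type=m.trait_type,
            n_total=int(round(m.n_total * f)),
            n_cases=int(round(m.n_cases * f)) if m.n_cases is not None else None,
            case_fraction=m.case_fraction,
            unit_note=m.unit_note,
        )
        out.append(SummaryDataset(meta=meta, df=sub))
    return out


@dataclass
class LDPanel:
    """A small reference genotype panel with block-structured LD.

    ``genotypes`` holds dosages in {0,1,2}, individuals × SNPs.  SNPs
    within a block are exchangeably correlated; across blocks they are
    independent.  Stands in for an external reference panel when
    computing pairwise r² for clumping.
    """

    genotypes: np.ndarray
    snp_ids: list[str]
    freqs: np.ndarray
    blocks: list[tuple[int, float]] = field(default_factory=list)

    @property
    def n_ind(self) -> int:
        return self.genotypes.shape[0]

    def allele_freq(self) -> np.ndarray:
        return self.genotypes.mean(axis=0) / 2.0

    def r2_matrix(self) -> np.ndarray:
        g = self.genotypes.astype(float)
        sd = g.std(axis=0)
        if np.any(sd == 0):  # monomorphic columns: define r2 with self as 1, others 0
            r = np.zeros((g.shape[1], g.shape[1]))
            ok = sd > 0
            if ok.any():
                r[np.ix_(ok, ok)] = np.corrcoef(g[:, ok], rowvar=False)
            np.fill_diagonal(r, 1.0)
        else:
            r = np.corrcoef(g, rowvar=False)
            r = np.atleast_2d(r)
        return r**2

    def r2_lookup(self) -> dict[tuple[str, str], float]:
        """Pairwise r² keyed by unordered SNP-id pairs (both orders present)."""
        r2 = self.r2_matrix()
        ids = self.snp_ids
        out: dict[tuple[str, str], float] = {}
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                out[(ids[a], ids[b])] = float(r2[a, b])
                out[(ids[b], ids[a])] = float(r2[a, b])
        return out

    def save(self, prefix: str | Path) -> None:
        """Write dosages as TSV plus a sidecar allele-frequency file."""
        prefix = Path(prefix)
        pd.DataFrame(self.genotypes, columns=self.snp_ids).to_csv(
            prefix.with_suffix(".dosage.tsv"), sep="\t", index=False
        )
        pd.DataFrame({"SNP": self.snp_ids, "FREQ": self.freqs}).to_csv(
            prefix.with_suffix(".freq.tsv"), sep="\t", index=False
        )


def simulate_ld_panel(
    n_ind: int,
    blocks: list[tuple[int, float]],
    freqs=None,
    seed: int = 0,
    snp_ids: list[str] | None = None,
) -> LDPanel:
    """Simulate a genotype panel with exchangeable within-block LD.

    Each block uses a shared-haplotype copy model: a latent block
    haplotype allele is drawn at the block frequency, and each SNP copies
    it with probability ``within_r2 ** 0.25`` (else draws fresh), which
    makes every within-block pair of dosage columns correlate at
    r² ≈ within_r2.  ``within_r2 = 1`` duplicates columns exactly.
    SNPs inside a block share the block's allele frequency (the first
    SNP's entry in ``freqs``); the copy model cannot mix frequencies
    within a block without distorting the target correlation.
    """
    rng = np.random.default_rng(seed)
    n_snps = sum(size for size, _ in blocks)
    if freqs is None:
        freqs = rng.uniform(0.1, 0.9, n_snps)
    freqs = np.asarray(freqs, dtype=float)
    if len(freqs) != n_snps:
        raise ValueError("freqs length must equal total SNP count")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("allele frequencies must lie in (0,1)")
    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(n_snps)]

    haps = np.empty((2, n_ind, n_snps), dtype=np.int8)
    col = 0
    used_freqs = freqs.copy()
    for size, within_r2 in blocks:
        f = freqs[col]
        used_freqs[col : col + size] = f
        c = float(np.clip(within_r2, 0.0, 1.0)) ** 0.25
        for h in range(2):
            latent = rng.random(n_ind) < f
            copy = rng.random((n_ind, size)) < c
            fresh = rng.random((n_ind, size)) < f
            haps[h, :, col : col + size] = np.where(copy, latent[:, None], fresh)
        col += size
    genotypes = (haps[0] + haps[1]).astype(np.int8)
    return LDPanel(genotypes=genotypes, snp_ids=list(snp_ids), freqs=used_freqs, blocks=list(blocks))


def simulate_ldsc_inputs(
    M: int,
    h2: float,
    N: int,
    intercept: float = 1.0,
    ell_dist: tuple[float, float] = (1.0, 200.0),
    seed: int = 0,
    noiseless: bool = False,
) -> pd.DataFrame:
    """Per-SNP LD scores and GWAS chi-square statistics.

    Under the polygenic model the expected association chi-square at SNP
    j is ``intercept + N·h2·ℓ_j/M`` for LD score ℓ_j, M SNPs and sample
    size N.  Draws are squared normals with noncentrality matching that
    mean (``z² , z ~ N(√(mean−1), 1)``, the sampling model of a GWAS z
    statistic; means below 1 use a scaled central chi-square).  In
    ``noiseless`` mode each chi-square is set to its expectation exactly.
    LD scores are uniform over ``ell_dist``.
    """
    rng = np.random.default_rng(seed)
    ell = rng.uniform(ell_dist[0], ell_dist[1], M)
    mean_chi2 = intercept + N * h2 * ell / M
    if noiseless:
        chi2 = mean_chi2
    else:
        z = rng.normal(np.sqrt(np.maximum(mean_chi2 - 1.0, 0.0)), 1.0)
        chi2 = np.where(mean_chi2 >= 1.0, z**2, mean_chi2 * rng.chisquare(1, M))
    out = pd.DataFrame({"ld_score": ell, "chi2": chi2})
    out.attrs["N"] = N
    out.attrs["M"] = M
    return out
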