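"""Instrument construction: significance filter, LD clumping, harmonization.

An MR instrument is the set of SNPs robustly (P < 5e-8) and independently
(pairwise r² < 0.001) associated with the exposure, with exposure and
outcome effects expressed on a shared effect-allele frame.  Harmonization
follows the usual summary-data conventions: swapped alleles flip the
outcome effect sign and complement the frequency; strand-complement
codings are resolved for unambiguous SNPs; palindromic (A/T, C/G) SNPs
are kept only when allele frequency identifies the strand on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas_io import SummaryDataset, TraitMeta

logger = logging.getLogger("mrpipe")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PAIR_COLUMNS = ["SNP", "gamma", "se_gamma", "Gamma", "se_Gamma", "eaf", "pval_exposure", "status"]


@dataclass
class HarmonizedSet:
    """Paired exposure/outcome effects on a shared effect-allele frame.

    ``pairs`` holds the kept and flipped rows (the unit of all MR
    estimation: per-SNP exposure effect ``gamma`` and outcome effect
    ``Gamma`` with their SEs); ``audit`` records dropped SNPs and why.
    """

    exposure_meta: TraitMeta
    outcome_meta: TraitMeta
    pairs: pd.DataFrame
    audit: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["SNP", "status"]))

    def __post_init__(self) -> None:
        if self.pairs["SNP"].duplicated().any():
            raise ValueError("duplicated SNP ids in harmonized pairs")

    @property
    def n_snps(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_aligned(cls, exposure: SummaryDataset, outcome: SummaryDataset) -> "HarmonizedSet":
        """Pair two datasets that already share SNP order and allele coding.

        A fast path for simulated data (the generator emits both samples
        on one frame); real datasets should go through :func:`harmonize`.
        """
        e, o = exposure.df, outcome.df
        if len(e) != len(o) or not (e["SNP"].to_numpy() == o["SNP"].to_numpy()).all():
            raise ValueError("datasets do not share SNP order; use harmonize()")
        if not ((e["EA"].to_numpy() == o["EA"].to_numpy()).all()
                and (e["OA"].to_numpy() == o["OA"].to_numpy()).all()):
            raise ValueError("allele coding differs; use harmonize()")
        pairs = pd.DataFrame(
            {
                "SNP": e["SNP"].to_numpy(),
                "gamma": e["BETA"].to_numpy(float),
                "se_gamma": e["SE"].to_numpy(float),
                "Gamma": o["BETA"].to_numpy(float),
                "se_Gamma": o["SE"].to_numpy(float),
                "eaf": e["EAF"].to_numpy(float),
                "pval_exposure": e["P"].to_numpy(float),
                "status": "kept",
            }
        )
        return cls(exposure_meta=exposure.meta, outcome_meta=outcome.meta, pairs=pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(gamma, se_gamma, Gamma, se_Gamma) as float arrays."""
        p = self.pairs
        return (
            p["gamma"].to_numpy(float),
            p["se_gamma"].to_numpy(float),
            p["Gamma"].to_numpy(float),
            p["se_Gamma"].to_numpy(float),
        )

    def drop(self, snp_id: str) -> "HarmonizedSet":
        """A copy with one SNP removed (for leave-one-out)."""
        return HarmonizedSet(
            exposure_meta=self.exposure_meta,
            outcome_meta=self.outcome_meta,
            pairs=self.pairs.loc[self.pairs["SNP"] != snp_id].reset_index(drop=True),
            audit=self.audit,
        )

    def save(self, path: str | Path) -> None:
        """Pairs as TSV (status column); dropped-row audit alongside."""
        path = Path(path)
        self.pairs.to_csv(path, sep="\t", index=False)
        self.audit.to_csv(path.with_suffix(path.suffix + ".audit.tsv"), sep="\t", index=False)


def select_instruments(exposure: SummaryDataset, p_threshold: float = 5e-8) -> SummaryDataset:
    """SNPs associated with the exposure at ``P < p_threshold`` (strict),
    ordered by ascending p-value."""
    kept = exposure.df.loc[exposure.df["P"] < p_threshold]
    kept = kept.sort_values(["P", "CHR", "POS", "SNP"], kind="mergesort").reset_index(drop=True)
    return SummaryDataset(meta=exposure.meta, df=kept)


def _ld_getter(ld):
    """Normalise an LD source (panel, mapping or callable) to
    ``(get_r2(a, b), known(a, b))`` functions."""
    from .simulate import LDPanel

    if ld is None:  # explicit "no LD information": all pairs independent
        return (lambda a, b: 0.0), (lambda a, b: True)
    if isinstance(ld, LDPanel):
        ids = set(ld.snp_ids)
        table = ld.r2_lookup()
        return (lambda a, b: table.get((a, b), 0.0)), (lambda a, b: a in ids and b in ids)
    if callable(ld):
        return ld, (lambda a, b: True)
    table = dict(ld)

    def get(a, b):
        return table.get((a, b), table.get((b, a), 0.0))

    def known(a, b):
        return (a, b) in table or (b, a) in table

    return get, known


def clump(
    candidates: SummaryDataset,
    ld=None,
    r2_threshold: float = 0.001,
) -> SummaryDataset:
    """Greedy LD clumping: keep the most significant SNP, discard SNPs in
    LD with it (r² ≥ threshold), repeat.

    ``ld`` may be an :class:`~mrpipe.simulate.LDPanel`, a mapping keyed by
    SNP-id pairs, or a callable; pairs absent from the source are treated
    as r² = 0 with a logged warning.  Ties are broken deterministically
    by (pval, chrom, pos, snp_id).
    """
    get_r2, known = _ld_getter(ld)
    df = candidates.df.sort_values(["P", "CHR", "POS", "SNP"], kind="mergesort").reset_index(drop=True)
    remaining = list(df.index)
    kept_idx: list[int] = []
    missing = 0
    while remaining:
        top = remaining.pop(0)
        kept_idx.append(top)
        top_id = df.at[top, "SNP"]
        still = []
        for i in remaining:
            other = df.at[i, "SNP"]
            if not known(top_id, other):
                missing += 1
            if get_r2(top_id, other) < r2_threshold:
                still.append(i)
        remaining = still
    if missing:
        logger.warning("clump: %d SNP pair(s) absent from LD source, treated as r²=0", missing)
    out = df.loc[kept_idx].reset_index(drop=True)
    return SummaryDataset(meta=candidates.meta, df=out)


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def _freq_resolves(eaf_a: float, eaf_b: float, limit: float) -> bool:
    """Strand identifiable from frequency: both clear of 0.5 and agreeing."""
    same_side = (eaf_a - 0.5) * (eaf_b - 0.5) > 0
    outside = not (limit < eaf_a < 1 - limit) and not (limit < eaf_b < 1 - limit)
    return bool(same_side and outside)


def harmonize(
    instrument: SummaryDataset,
    outcome: SummaryDataset,
    palindrome_eaf_limit: float = 0.42,
) -> HarmonizedSet:
    """Align outcome effects to the instrument's effect-allele frame.

    Per SNP (matched on identifier): identical allele coding keeps the
    row; swapped coding flips the outcome effect sign and complements its
    frequency; a strand-complement coding is resolved the same way for
    non-palindromic SNPs.  Palindromic SNPs are retained only when both
    datasets' aligned frequencies fall on the same side of 0.5 and
    outside the ambiguity zone ``(limit, 1-limit)``.  SNPs absent from
    the outcome or with irreconcilable alleles are dropped with reasons.
    """
    out_ix = outcome.df.set_index("SNP")
    rows, audit = [], []
    for _, exp in instrument.df.iterrows():
        snp = exp["SNP"]
        if snp not in out_ix.index:
            audit.append({"SNP": snp, "status": "dropped_missing"})
            continue
        out = out_ix.loc[snp]
        ea, oa = exp["EA"], exp["OA"]
        o_ea, o_oa = out["EA"], out["OA"]
        palin = _is_palindromic(ea, oa)

        if (o_ea, o_oa) == (ea, oa):
            action = "kept"
        elif (o_ea, o_oa) == (oa, ea):
            action = "flipped"
        elif not palin and (_COMPLEMENT[o_ea], _COMPLEMENT[o_oa]) == (ea, oa):
            action = "kept"  # other strand, same orientation
        elif not palin and (_COMPLEMENT[o_ea], _COMPLEMENT[o_oa]) == (oa, ea):
            action = "flipped"
        else:
            audit.append({"SNP": snp, "status": "dropped_mismatch"})
            continue

        big_gamma = float(out["BETA"]) if action == "kept" else -float(out["BETA"])
        out_eaf = float(out["EAF"]) if action == "kept" else 1.0 - float(out["EAF"])

        if palin and not _freq_resolves(float(exp["EAF"]), out_eaf, palindrome_eaf_limit):
            audit.append({"SNP": snp, "status": "dropped_palindromic"})
            continue

        rows.append(
            {
                "SNP": snp,
                "gamma": float(exp["BETA"]),
                "se_gamma": float(exp["SE"]),
                "Gamma": big_gamma,
                "se_Gamma": float(out["SE"]),
                "eaf": float(exp["EAF"]),
                "pval_exposure": float(exp["P"]),
                "status": action,
            }
        )

    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    audit_df = pd.DataFrame(audit, columns=["SNP", "status"])
    if len(audit_df):
        logger.info(
            "harmonize: %d kept/flipped, dropped %s",
            len(pairs),
            audit_df["status"].value_counts().to_dict(),
        )
    return HarmonizedSet(
        exposure_meta=instrument.meta,
        outcome_meta=outcome.meta,
        pairs=pairs,
        audit=audit_df,
    )


def variance_explained(ds_or_z, n: int | None = None) -> float:
    """Instrument R²: per-SNP ``z²/(z² + n)`` summed over SNPs.

    Assumes independent SNPs (post-clumping).  Accepts a
    :class:`SummaryDataset` (uses per-row N unless ``n`` overrides) or an
    array of z statistics with an explicit ``n``.
    """
    if isinstance(ds_or_z, SummaryDataset):
        z = (ds_or_z.df["BETA"] / ds_or_z.df["SE"]).to_numpy(float)
        nn = float(n) if n is not None else ds_or_z.df["N"].to_numpy(float)
    else:
        if n is None:
            raise ValueError("n required when passing raw z scores")
        z = np.asarray(ds_or_z, dtype=float)
        nn = float(n)
    z2 = z**2
    return float(np.sum(z2 / (z2 + nn)))
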