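"""Data model and validated I/O for GWAS summary statistics.

A summary-statistics table holds one row per SNP with the nine canonical
fields used throughout two-sample MR: identifier, position, allele pair,
effect-allele frequency, effect size, its standard error, p-value and
sample size.  Effect sizes are per-allele: log odds for binary traits,
SD units for continuous traits.

Canonical column names are ``SNP CHR POS EA OA EAF BETA SE P N``; a
user-supplied column map translates other dialects on read.  Coordinates
are 1-based and alleles are upper-cased on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mrpipe")

#: canonical column order for summary-statistics tables
CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

_VALID_ALLELES = {"A", "C", "G", "T"}

#: smallest positive double; p-values of exactly 0 are floored here
P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass
class TraitMeta:
    """Metadata for one GWAS trait.

    ``trait_type`` drives downstream unit handling: binary traits carry
    case counts (needed for power and for the per-doubling odds-ratio
    rescaling); continuous traits are in SD units.
    """

    trait_name: str
    trait_type: str = "continuous"  # "continuous" | "binary"
    n_total: int = 0
    n_cases: int | None = None
    case_fraction: float | None = None
    unit_note: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.n_cases is None and self.case_fraction is None:
                raise ValueError("binary traits require n_cases or case_fraction")
            if self.case_fraction is None:
                self.case_fraction = self.n_cases / self.n_total
            elif self.n_cases is None and self.n_total:
                self.n_cases = int(round(self.case_fraction * self.n_total))
            if not 0.0 < self.case_fraction < 1.0:
                raise ValueError("case_fraction must lie in (0, 1)")


@dataclass
class SummaryDataset:
    """A validated table of per-SNP association records for one trait.

    ``df`` always carries the canonical columns; ``snp_id`` values are
    unique (first occurrence wins on duplicated identifiers).
    """

    meta: TraitMeta
    df: pd.DataFrame
    drop_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"summary table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "SummaryDataset":
        return replace(self, df=self.df.loc[mask].reset_index(drop=True))

    def lookup(self, snp_ids) -> pd.DataFrame:
        return self.df.set_index("SNP").reindex(snp_ids)


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["SNP"] = out["SNP"].astype(str)
    out["CHR"] = out["CHR"].astype(str)
    out["POS"] = pd.to_numeric(out["POS"], errors="coerce")
    for col in ("EAF", "BETA", "SE", "P", "N"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    out["EA"] = out["EA"].astype(str).str.upper()
    out["OA"] = out["OA"].astype(str).str.upper()
    return out


def validate_summary(df: pd.DataFrame, *, pval_tol: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Apply hard row invariants, dropping offending rows.

    Returns the clean frame and a per-reason drop count.  p-values of
    exactly 0 are floored to the smallest positive double (downstream
    code takes logs and normal quantiles).  Rows whose stored p-value is
    grossly inconsistent with the two-sided normal p implied by beta/se
    draw a warning only — public GWAS files are rounded.
    """
    df = _coerce(df)
    drops: dict[str, int] = {}

    def _drop(mask: pd.Series, reason: str) -> pd.Series:
        n = int(mask.sum())
        if n:
            drops[reason] = drops.get(reason, 0) + n
            logger.warning("dropping %d row(s): %s", n, reason)
        return ~mask

    keep = _drop(df[CANONICAL_COLUMNS].isna().any(axis=1), "missing_value")
    df = df.loc[keep]
    keep = _drop(~(df["SE"] > 0), "nonpositive_se")
    df = df.loc[keep]
    keep = _drop(~df["EA"].isin(_VALID_ALLELES) | ~df["OA"].isin(_VALID_ALLELES), "invalid_allele")
    df = df.loc[keep]
    keep = _drop(df["EA"] == df["OA"], "identical_alleles")
    df = df.loc[keep]
    keep = _drop(~((df["EAF"] > 0) & (df["EAF"] < 1)), "eaf_out_of_range")
    df = df.loc[keep]
    keep = _drop((df["P"] < 0) | (df["P"] > 1), "pval_out_of_range")
    df = df.loc[keep]
    keep = _drop(~(df["N"] > 0), "nonpositive_n")
    df = df.loc[keep]

    n_zero_p = int((df["P"] == 0).sum())
    if n_zero_p:
        logger.warning("flooring %d zero p-value(s) to %.3e", n_zero_p, P_FLOOR)
        df.loc[df["P"] == 0, "P"] = P_FLOOR

    dup = df["SNP"].duplicated(keep="first")
    if dup.any():
        drops["duplicate_snp_id"] = int(dup.sum())
        logger.warning("dropping %d duplicated snp id(s), keeping first", int(dup.sum()))
        df = df.loc[~dup]

    # soft check: stored p vs two-sided normal p from beta/se
    with np.errstate(all="ignore"):
        p_implied = 2.0 * stats.norm.sf(np.abs(df["BETA"] / df["SE"]))
    bad = np.abs(np.log10(np.maximum(p_implied, P_FLOOR)) -
                 np.log10(np.maximum(df["P"].to_numpy(), P_FLOOR))) > np.log10(1 / pval_tol)
    if bad.any():
        logger.warning("%d row(s) have p-values inconsistent with beta/se (kept)", int(bad.sum()))

    df["POS"] = df["POS"].astype(np.int64)
    return df.reset_index(drop=True), drops


def read_summary(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    meta: TraitMeta | None = None,
    sep: str = "\t",
) -> SummaryDataset:
    """Read a delimited summary-statistics file into a validated dataset.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    column_map:
        Mapping from canonical name (``SNP``, ``CHR``, ...) to the name
        used in the file; omitted entries default to the canonical name.
    meta:
        Trait metadata; if absent a continuous trait is assumed with
        ``n_total`` taken as the median per-SNP sample size.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    cmap = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = cmap.get(canon, canon)
        if src not in raw.columns:
            raise ValueError(f"mandatory column {canon!r} (file column {src!r}) not found in {path}")
        rename[src] = canon
    df = raw.rename(columns=rename)[CANONICAL_COLUMNS]
    df, drops = validate_summary(df)
    if df.empty:
        raise ValueError(f"no valid rows in {path}")
    if meta is None:
        meta = TraitMeta(trait_name=Path(path).stem, n_total=int(df["N"].median()))
    return SummaryDataset(meta=meta, df=df, drop_counts=drops)


def write_summary(ds: SummaryDataset, path: str | Path) -> None:
    """Write the canonical nine-field TSV, rows sorted by (CHR, POS)."""
    out = ds.df.sort_values(["CHR", "POS", "SNP"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, columns=CANONICAL_COLUMNS)


def zscore(obj) -> np.ndarray | float:
    """Wald z statistic beta/se for a dataset, frame, row or (beta, se) pair."""
    if isinstance(obj, SummaryDataset):
        return (obj.df["BETA"] / obj.df["SE"]).to_numpy()
    if isinstance(obj, pd.DataFrame):
        return (obj["BETA"] / obj["SE"]).to_numpy()
    beta, se = obj["BETA"], obj["SE"]
    if se <= 0:
        raise ValueError("se must be positive")
    return float(beta) / float(se)
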