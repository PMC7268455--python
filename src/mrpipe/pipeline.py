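"""End-to-end study orchestration over many exposures.

Mirrors the design of a many-risk-factor MR study: meta-analyse the
per-consortium outcome GWAS once, then for each exposure build the
instrument (significance filter, LD clumping, harmonization), estimate
the primary multiplicative random-effects IVW effect, convert to the OR
scale, tier the result against the Bonferroni-corrected and suggestive
thresholds, and — for rows meeting at least the suggestive tier — run
the full sensitivity battery.  Post-hoc power accompanies every row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gwas_io import SummaryDataset, TraitMeta, read_summary
from .meta import meta_analyze
from .instruments import select_instruments, clump, harmonize, variance_explained
from .estimators import ivw, egger, weighted_median, mode_based, to_odds_ratio
from .sensitivity import cochran_q, steiger, classify_concordance
from .prs import bonferroni, mr_power

logger = logging.getLogger("mrpipe")

#: documented column schema of the results table
RESULTS_COLUMNS = [
    "risk_factor", "subtype", "n_snp", "or", "ci_low", "ci_high", "pval", "tier",
    "egger_label", "wme_label", "mbe_label", "het_stat", "het_pval",
    "steiger_direction", "power", "note",
]


@dataclass
class ExposureSpec:
    """One exposure: a name, a summary-statistics source (path or
    in-memory dataset) and its trait type."""

    name: str
    source: str | Path | SummaryDataset
    trait_type: str = "continuous"
    case_fraction: float | None = None

    def load(self) -> SummaryDataset:
        import dataclasses

        if isinstance(self.source, SummaryDataset):
            ds = self.source
        else:
            ds = read_summary(self.source)
        if ds.meta.trait_type != self.trait_type:
            cf = self.case_fraction if self.case_fraction is not None else 0.5
            meta = TraitMeta(
                trait_name=self.name,
                trait_type=self.trait_type,
                n_total=ds.meta.n_total,
                case_fraction=cf if self.trait_type == "binary" else None,
            )
            ds = dataclasses.replace(ds, meta=meta)
        return ds


@dataclass
class AnalysisConfig:
    """Configuration of one subtype-level study across many exposures."""

    exposures: list[ExposureSpec]
    outcome_studies: list  # paths or SummaryDatasets (≥1; >1 are meta-analysed)
    subtype_label: str = "all"
    p_instrument: float = 5e-8
    r2_clump: float = 0.001
    prs_p: float = 1e-5
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    ld: object = None
    m_tests: int | None = None
    force_sensitivity: bool = False
    output_dir: str | Path | None = None
    outcome_meta: TraitMeta | None = None

    def __post_init__(self) -> None:
        if not self.exposures:
            raise ValueError("need at least one exposure")
        if not self.outcome_studies:
            raise ValueError("need at least one outcome study")
        if self.seed is None:
            raise ValueError("seed is required for reproducible bootstraps")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        exposures = [ExposureSpec(**e) for e in raw.pop("exposures")]
        return cls(exposures=exposures, **raw)


def _load_outcome(cfg: AnalysisConfig) -> SummaryDataset:
    studies = [
        s if isinstance(s, SummaryDataset) else read_summary(s, meta=cfg.outcome_meta)
        for s in cfg.outcome_studies
    ]
    if len(studies) == 1:
        return studies[0]
    pooled, _ = meta_analyze(studies, trait_name=f"outcome_{cfg.subtype_label}")
    return pooled


def _null_row(name: str, subtype: str, note: str) -> dict:
    row = {c: np.nan for c in RESULTS_COLUMNS}
    row.update(
        risk_factor=name, subtype=subtype, tier="skipped",
        egger_label="NA", wme_label="NA", mbe_label="NA",
        steiger_direction="NA", note=note,
    )
    return row


def run_study(cfg: AnalysisConfig) -> pd.DataFrame:
    """Run the full study and return one results row per exposure.

    Deterministic given the config: all bootstrap seeds derive from
    ``cfg.seed`` plus the exposure index.  An exposure whose instrument
    cannot be built yields a ``skipped`` row, never a crash.  Rows are
    sorted by ascending IVW p-value within the subtype (skipped rows
    last).
    """
    outcome = _load_outcome(cfg)
    m = cfg.m_tests if cfg.m_tests is not None else len(cfg.exposures)
    strict, _band = bonferroni(cfg.alpha, m)

    rows = []
    for i, spec in enumerate(cfg.exposures):
        try:
            rows.append(_analyse_one(cfg, spec, outcome, strict, seed=cfg.seed + 104729 * i))
        except Exception as exc:  # noqa: BLE001 - skipped row, not a crash
            logger.warning("exposure %s skipped: %s", spec.name, exc)
            rows.append(_null_row(spec.name, cfg.subtype_label, str(exc)))
    table = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    table = table.sort_values(
        ["subtype", "pval"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        tsv, text = render_table(table)
        (out / "results.tsv").write_text(tsv)
        (out / "results.txt").write_text(text)
    return table


def _analyse_one(
    cfg: AnalysisConfig, spec: ExposureSpec, outcome: SummaryDataset, strict: float, seed: int
) -> dict:
    exposure = spec.load()
    inst = select_instruments(exposure, cfg.p_instrument)
    if inst.n_snps == 0:
        return _null_row(spec.name, cfg.subtype_label, "no instrument SNPs at threshold")
    inst = clump(inst, cfg.ld, cfg.r2_clump)
    hs = harmonize(inst, outcome)
    if hs.n_snps == 0:
        return _null_row(spec.name, cfg.subtype_label, "no harmonizable SNPs")

    ivw_res = ivw(hs, model="multiplicative_random")
    or_, ci_lo, ci_hi = to_odds_ratio(ivw_res, exposure.meta)
    p = ivw_res.pval
    tier = "significant" if p < strict else ("suggestive" if p < cfg.alpha else "null")

    gamma, se_g, _, _ = hs.arrays()
    r2_inst = min(variance_explained(gamma / se_g, n=exposure.meta.n_total), 1.0)
    pw = mr_power(
        n_outcome=outcome.meta.n_total,
        case_fraction=outcome.meta.case_fraction,
        r2_instrument=r2_inst,
        beta_target=ivw_res.beta,
        alpha=cfg.alpha,
    ).power

    row = _null_row(spec.name, cfg.subtype_label, "")
    row.update(
        n_snp=hs.n_snps, **{"or": or_}, ci_low=ci_lo, ci_high=ci_hi, pval=p,
        tier=tier, power=pw, steiger_direction=steiger(hs).direction,
    )

    eligible = tier in ("significant", "suggestive") or cfg.force_sensitivity
    if eligible and hs.n_snps >= 3:
        egg = egger(hs)
        wme = weighted_median(hs, n_boot=cfg.n_boot, seed=seed)
        mbe = mode_based(hs, n_boot=cfg.n_boot, seed=seed + 1)
        q = cochran_q(hs)
        row.update(
            egger_label=classify_concordance(ivw_res, egg, cfg.alpha),
            wme_label=classify_concordance(ivw_res, wme, cfg.alpha),
            mbe_label=classify_concordance(ivw_res, mbe, cfg.alpha),
            het_stat=q.q, het_pval=q.pval,
        )
    elif eligible:
        row.update(note="too few SNPs for sensitivity battery")
    return row


def render_table(rows: pd.DataFrame) -> tuple[str, str]:
    """Render the results table as (TSV text, aligned plain text).

    Column order follows :data:`RESULTS_COLUMNS`; the aligned rendering
    formats ORs and CIs to two decimals and p-values in scientific
    notation, one line per exposure–subtype row.
    """
    table = rows.reindex(columns=RESULTS_COLUMNS)
    tsv = table.to_csv(sep="\t", index=False)

    disp = table.copy()
    for c in ("or", "ci_low", "ci_high", "het_stat", "power"):
        disp[c] = disp[c].map(lambda v: "NA" if pd.isna(v) else f"{v:.2f}")
    for c in ("pval", "het_pval"):
        disp[c] = disp[c].map(lambda v: "NA" if pd.isna(v) else f"{v:.2e}")
    disp["ci"] = disp["ci_low"] + " to " + disp["ci_high"]
    cols = [
        "risk_factor", "subtype", "n_snp", "or", "ci", "pval", "tier",
        "egger_label", "wme_label", "mbe_label", "het_stat", "het_pval",
        "steiger_direction", "power",
    ]
    text = disp[cols].to_string(index=False)
    return tsv, text + "\n"
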