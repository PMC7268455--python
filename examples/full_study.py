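"""Run an end-to-end multi-exposure study and print the results table.

Three synthetic exposures against one binary-outcome GWAS: a planted
strong risk factor (true beta 0.5), a null trait, and a trait with no
genome-wide-significant instrument (reported as skipped).  Each
exposure has its own instrument SNPs; the outcome GWAS covers all of
them with the true effects implied by each scenario.  Rows meeting at
least the suggestive tier get the sensitivity battery; every row
carries post-hoc power and a Steiger directionality verdict.  Tiers use
the Bonferroni-corrected threshold for a 36-trait family, as in a
many-risk-factor screen.
"""

import dataclasses

import pandas as pd

from mrpipe import (
    AnalysisConfig, ExposureSpec, SimTruth, simulate_two_sample,
    render_table, run_study,
)

scenarios = {
    "planted_risk_factor": SimTruth(beta_causal=0.5, n_snps=50, gamma_dist=(0.1, 0.03),
                                    n_exp=200_000, n_out=100_000, seed=101, snp_prefix="rsA"),
    "null_trait": SimTruth(beta_causal=0.0, n_snps=50, gamma_dist=(0.1, 0.03),
                           n_exp=200_000, n_out=100_000, seed=102, snp_prefix="rsB"),
    "uninstrumentable_trait": SimTruth(beta_causal=0.0, n_snps=50, gamma_dist=(0.0, 0.002),
                                       n_out=100_000, seed=103, snp_prefix="rsC"),
}

exposures, outcome_parts = [], []
for name, truth in scenarios.items():
    exp, out = simulate_two_sample(truth)
    exposures.append(ExposureSpec(name, exp))
    outcome_parts.append(out)
# one outcome GWAS covering every exposure's SNPs
outcome = dataclasses.replace(
    outcome_parts[0],
    df=pd.concat([o.df for o in outcome_parts], ignore_index=True),
)

cfg = AnalysisConfig(
    exposures=exposures,
    outcome_studies=[outcome],
    subtype_label="all",
    m_tests=36,
    n_boot=200,
    seed=7,
)
table = run_study(cfg)
_, text = render_table(table)
print(text)
print("tiers: significant < 0.05/36, suggestive < 0.05; "
      "'skipped' rows had no usable instrument")
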