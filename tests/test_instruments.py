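"""Instrument selection, LD clumping, harmonization."""

import numpy as np
import pandas as pd
import pytest

from mrpipe.gwas_io import SummaryDataset, TraitMeta
from mrpipe.instruments import (
    clump,
    harmonize,
    select_instruments,
    variance_explained,
)
from mrpipe.simulate import simulate_ld_panel
from conftest import make_summary_df


def _ds(df, name="exp", n_total=50_000):
    return SummaryDataset(meta=TraitMeta(name, n_total=n_total), df=df)


class TestSelect:
    def test_no_significant_snps_empty(self, rng):
        df = make_summary_df(rng, n=5)
        df["P"] = 0.5
        assert select_instruments(_ds(df)).n_snps == 0

    def test_threshold_is_strict(self, rng):
        df = make_summary_df(rng, n=3)
        df["P"] = [1e-9, 5e-8, 1e-7]
        kept = select_instruments(_ds(df), p_threshold=5e-8)
        assert list(kept.df["P"]) == [1e-9]

    def test_matches_brute_force_filter(self, rng):
        df = make_summary_df(rng, n=50)
        df["P"] = 10 ** rng.uniform(-12, 0, 50)
        kept = select_instruments(_ds(df), p_threshold=1e-5)
        expect = sorted(df.loc[df["P"] < 1e-5, "SNP"], key=lambda s: df.set_index("SNP").loc[s, "P"])
        assert list(kept.df["SNP"]) == expect
        assert kept.df["P"].is_monotonic_increasing


def _greedy_oracle(df, ld_map, thr):
    """Independent exhaustive greedy clump used as the reference."""
    pool = df.sort_values(["P", "CHR", "POS", "SNP"]).reset_index(drop=True)
    ids = list(pool["SNP"])
    kept = []
    while ids:
        top = ids.pop(0)
        kept.append(top)
        ids = [o for o in ids if ld_map.get((top, o), ld_map.get((o, top), 0.0)) < thr]
    return kept


class TestClump:
    def test_unlinked_snps_all_kept(self, rng):
        df = make_summary_df(rng, n=6)
        out = clump(_ds(df), ld=None, r2_threshold=0.001)
        assert out.n_snps == 6

    def test_duplicate_snp_removed_keeping_lowest_p(self, rng):
        df = make_summary_df(rng, n=2)
        df["P"] = [1e-10, 1e-9]
        out = clump(_ds(df), ld={("rs0", "rs1"): 1.0}, r2_threshold=0.001)
        assert list(out.df["SNP"]) == ["rs0"]

    def test_matches_brute_force_greedy(self, rng):
        for trial in range(5):
            df = make_summary_df(rng, n=10)
            df["P"] = 10 ** rng.uniform(-12, -2, 10)
            ld = {}
            ids = list(df["SNP"])
            for a in range(10):
                for b in range(a + 1, 10):
                    ld[(ids[a], ids[b])] = float(rng.uniform(0, 1) * (rng.random() < 0.4))
            got = clump(_ds(df), ld=ld, r2_threshold=0.3)
            assert list(got.df["SNP"]) == _greedy_oracle(df, ld, 0.3)

    def test_ld_panel_source_and_independence_of_output(self, rng):
        panel = simulate_ld_panel(500, blocks=[(5, 0.9), (5, 0.0)], seed=1)
        df = make_summary_df(rng, n=10)
        df["SNP"] = panel.snp_ids
        df["P"] = 10 ** rng.uniform(-12, -6, 10)
        out = clump(_ds(df), ld=panel, r2_threshold=0.1)
        r2 = panel.r2_lookup()
        kept = list(out.df["SNP"])
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert r2.get((kept[i], kept[j]), 0.0) < 0.1
        # greedy-optimal: first kept SNP is the global minimum p
        assert kept[0] == df.loc[df["P"].idxmin(), "SNP"]


class TestHarmonize:
    def _pair(self, rng, n=5):
        exp = make_summary_df(rng, n=n)
        out = exp.copy()
        out["BETA"] = rng.normal(0, 0.1, n)
        out["SE"] = rng.uniform(0.01, 0.05, n)
        return exp, out

    def test_identical_coding_all_kept_unchanged(self, rng):
        exp, out = self._pair(rng)
        hs = harmonize(_ds(exp), _ds(out, "outcome"))
        assert (hs.pairs["status"] == "kept").all()
        np.testing.assert_allclose(hs.pairs["Gamma"], out["BETA"])
        np.testing.assert_allclose(hs.pairs["gamma"], exp["BETA"])

    def test_swapped_alleles_flip_outcome(self, rng):
        exp, out = self._pair(rng, n=1)
        out["BETA"] = 0.3
        out["EA"], out["OA"] = exp["OA"], exp["EA"]
        out["EAF"] = 1 - exp["EAF"]
        hs = harmonize(_ds(exp), _ds(out, "outcome"))
        assert list(hs.pairs["status"]) == ["flipped"]
        assert hs.pairs.loc[0, "Gamma"] == pytest.approx(-0.3)

    def test_strand_complement_resolved_for_unambiguous_snp(self, rng):
        exp, out = self._pair(rng, n=1)  # A/G
        out["EA"], out["OA"] = "T", "C"  # other strand, same orientation
        hs = harmonize(_ds(exp), _ds(out, "outcome"))
        assert list(hs.pairs["status"]) == ["kept"]

    def test_palindromic_ambiguous_frequency_dropped(self, rng):
        exp, out = self._pair(rng, n=1)
        for df in (exp, out):
            df["EA"], df["OA"] = "A", "T"
        exp["EAF"] = 0.50
        hs = harmonize(_ds(exp), _ds(out, "outcome"))
        assert hs.n_snps == 0
        assert list(hs.audit["status"]) == ["dropped_palindromic"]

    def test_palindromic_clear_frequency_kept(self, rng):
        exp, out = self._pair(rng, n=1)
        for df in (exp, out):
            df["EA"], df["OA"] = "C", "G"
            df["EAF"] = 0.10
        hs = harmonize(_ds(exp), _ds(out, "outcome"))
        assert list(hs.pairs["status"]) == ["kept"]

    def test_missing_and_mismatch_audited_with_conservation(self, rng):
        exp, out = self._pair(rng, n=4)
        out = out.iloc[:3].copy()          # rs3 missing from outcome
        out.loc[0, ["EA", "OA"]] = ["C", "A"]  # irreconcilable vs A/G
        hs = harmonize(_ds(exp), _ds(out, "outcome"))
        statuses = list(hs.pairs["status"]) + list(hs.audit["status"])
        assert len(statuses) == 4
        assert sorted(hs.audit["status"]) == ["dropped_mismatch", "dropped_missing"]

    def test_idempotent(self, rng):
        """Harmonizing an already-harmonized pair changes nothing."""
        exp, out = self._pair(rng, n=6)
        hs1 = harmonize(_ds(exp), _ds(out, "outcome"))
        exp2 = exp.copy()
        out2 = out.copy()
        out2["BETA"] = hs1.pairs["Gamma"].to_numpy()
        hs2 = harmonize(_ds(exp2), _ds(out2, "outcome"))
        pd.testing.assert_frame_equal(hs1.pairs, hs2.pairs)


class TestVarianceExplained:
    def test_zero_z_zero_r2(self):
        assert variance_explained(np.zeros(5), n=1000) == 0.0

    def test_formula_fixed_point(self):
        assert variance_explained(np.array([np.sqrt(1000.0)]), n=1000) == pytest.approx(0.5)

    def test_simulated_contributions_recovered(self):
        """Each SNP's z²/(z²+n) tracks its true share of trait variance."""
        rng = np.random.default_rng(6)
        n, m, reps = 20_000, 10, 200
        beta = rng.uniform(0.05, 0.1, m)
        freq = rng.uniform(0.2, 0.8, m)
        var_snp = 2 * freq * (1 - freq) * beta**2
        true_r2 = var_snp.sum()  # trait variance ~1 by construction scale
        se = 1 / np.sqrt(2 * freq * (1 - freq) * n)
        est = np.array([
            variance_explained((beta + rng.normal(0, se)) / se, n=n) for _ in range(reps)
        ])
        mc_se = est.std(ddof=1) / np.sqrt(reps)
        # noise adds a small positive bias of order m/n; allow for it
        assert abs(est.mean() - (true_r2 + m / n)) < 3 * mc_se + 2e-4
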