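import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from musclemeth.core_io import ValidationError
from musclemeth.enrichment import (context_chi2, gene_set_test,
                                   overlap_resampling, sex_state_or,
                                   tfbs_enrichment)


class TestContextChi2:
    def test_identical_distributions_give_zero(self):
        status = pd.Series(["dmp"] * 40 + ["non"] * 40)
        category = pd.Series((["island"] * 20 + ["shore"] * 20) * 2)
        res = context_chi2(status, category)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_by_two_matches_closed_form(self):
        # table (10,20;20,10): chi2 = N(ad-bc)^2/(r1 r2 c1 c2) = 6.667
        status = pd.Series(["a"] * 30 + ["b"] * 30)
        category = pd.Series(["x"] * 10 + ["y"] * 20 + ["x"] * 20 + ["y"] * 10)
        res = context_chi2(status, category)
        assert res.chi2 == pytest.approx(60 * (10 * 10 - 20 * 20) ** 2 / 30 ** 4)
        assert res.p == pytest.approx(stats.chi2.sf(20 / 3, 1))
        assert res.p == pytest.approx(0.0098, abs=5e-4)

    def test_pearson_residual_squares_sum_to_chi2(self, rng):
        status = pd.Series(rng.choice(["a", "b", "c"], size=400))
        category = pd.Series(rng.choice(list("wxyz"), size=400))
        res = context_chi2(status, category)
        assert (res.pearson_residuals.to_numpy() ** 2).sum() == pytest.approx(res.chi2)

    def test_invariant_to_row_and_column_permutation(self, rng):
        status = pd.Series(rng.choice(["a", "b", "c"], size=300))
        category = pd.Series(rng.choice(["x", "y"], size=300))
        res1 = context_chi2(status, category)
        relabel = status.map({"a": "c", "b": "a", "c": "b"})
        res2 = context_chi2(relabel, category.map({"x": "y", "y": "x"}))
        assert res1.chi2 == pytest.approx(res2.chi2)


class TestSexStateOr:
    def test_reconstructed_published_table(self):
        # 56,813 DMPs, 38.7% in sex-discordant states; 576,832 non-DMPs, 32.4%
        n_dmp, n_non = 56_813, 576_832
        dmp_disc = round(0.387 * n_dmp)
        non_disc = round(0.324 * n_non)
        dmp_flag = pd.Series([True] * n_dmp + [False] * n_non)
        disc_flag = pd.Series([True] * dmp_disc + [False] * (n_dmp - dmp_disc)
                              + [True] * non_disc + [False] * (n_non - non_disc))
        res = sex_state_or(dmp_flag, disc_flag)
        assert res.odds_ratio == pytest.approx(0.76, abs=0.005)
        lo, hi = res.or_ci
        assert round(lo, 2) == 0.75 and round(hi, 2) == 0.77
        assert res.fisher_p < 2.2e-16

    def test_independent_flags_give_or_near_one(self, rng):
        dmp = pd.Series(rng.random(20_000) < 0.1)
        disc = pd.Series(rng.random(20_000) < 0.3)
        res = sex_state_or(dmp, disc)
        assert 0.9 < res.odds_ratio < 1.1

    def test_swapping_rows_inverts_or(self, rng):
        dmp = pd.Series(rng.random(5_000) < 0.2)
        disc = pd.Series(rng.random(5_000) < 0.4)
        res = sex_state_or(dmp, disc)
        res_swapped = sex_state_or(~dmp, disc)
        assert res_swapped.odds_ratio == pytest.approx(1.0 / res.odds_ratio)


def _probe_gene_map(probes_per_gene: dict) -> pd.Series:
    mapping = {}
    i = 0
    for gene, k in probes_per_gene.items():
        for _ in range(k):
            mapping[f"cg{i}"] = [gene]
            i += 1
    return pd.Series(mapping)


class TestGeneSetTest:
    def test_equal_probe_counts_reduces_to_hypergeometric(self):
        pg = _probe_gene_map({f"G{i}": 1 for i in range(40)})
        background = list(pg.index)
        sig = [f"cg{i}" for i in range(10)]           # genes G0..G9 significant
        gene_set = {"S": [f"G{i}" for i in range(5, 15)]}  # 5 of them in the set
        res = gene_set_test(sig, background, pg, gene_set, method="montecarlo",
                            n_iter=20_000, rng=1)
        exact = stats.hypergeom(40, 10, 10).sf(5 - 1)
        assert res["p"].iloc[0] == pytest.approx(exact, abs=0.02)

    def test_probe_rich_set_penalised_by_bias_adjustment(self):
        # the set holds the probe-richest genes; significance assigned by probe
        probes_per_gene = {f"R{i}": 30 for i in range(5)}
        probes_per_gene.update({f"P{i}": 2 for i in range(45)})
        pg = _probe_gene_map(probes_per_gene)
        background = list(pg.index)
        rng = np.random.default_rng(2)
        sig = list(rng.choice(background, size=60, replace=False))
        gene_set = {"rich": [f"R{i}" for i in range(5)]}
        adj = gene_set_test(sig, background, pg, gene_set, method="montecarlo",
                            n_iter=5_000, rng=3)["p"].iloc[0]
        sig_genes = {g for p in sig for g in pg[p]}
        n_universe, n_set = 50, 5
        obs = len(sig_genes & set(gene_set["rich"]))
        unadj = stats.hypergeom(n_universe, n_set, len(sig_genes)).sf(obs - 1)
        assert adj > 2 * unadj  # bias adjustment weakens the apparent enrichment

    def test_montecarlo_matches_exhaustive_enumeration(self):
        # 6-gene universe with unequal probe counts, enumerated exactly
        weights = {"A": 1, "B": 2, "C": 3, "D": 1, "E": 2, "F": 1}
        pg = _probe_gene_map(weights)
        background = list(pg.index)
        sig_genes = ["B", "C", "E"]  # 3 significant genes
        # one significant probe per significant gene is enough
        sig = [background[1], background[3], background[7]]
        gene_set = {"S": ["A", "B", "C"]}
        res = gene_set_test(sig, background, pg, gene_set, method="montecarlo",
                            n_iter=20_000, rng=4)
        observed = len(set(sig_genes) & set(gene_set["S"]))
        genes = list(weights)
        w = np.array([weights[g] for g in genes], dtype=float)
        p_exact = 0.0
        k = len(sig_genes)
        for perm in itertools.permutations(range(6), k):
            prob = 1.0
            remaining = w.sum()
            for j in perm:
                prob *= w[j] / remaining
                remaining -= w[j]
            overlap = len({genes[j] for j in perm} & set(gene_set["S"]))
            if overlap >= observed:
                p_exact += prob
        assert res["p"].iloc[0] == pytest.approx(p_exact, abs=0.01)

    def test_wallenius_agrees_with_montecarlo(self):
        pg = _probe_gene_map({f"G{i}": (3 if i < 10 else 1) for i in range(30)})
        background = list(pg.index)
        sig = [pid for pid in background[:12]]
        gene_set = {"S": [f"G{i}" for i in range(8)]}
        mc = gene_set_test(sig, background, pg, gene_set, method="montecarlo",
                           n_iter=20_000, rng=5)["p"].iloc[0]
        wa = gene_set_test(sig, background, pg, gene_set, method="wallenius")["p"].iloc[0]
        assert wa == pytest.approx(mc, abs=0.05)

    def test_reproducible_under_fixed_seed(self):
        pg = _probe_gene_map({f"G{i}": 2 for i in range(20)})
        background = list(pg.index)
        sig = background[:8]
        gs = {"S": [f"G{i}" for i in range(6)]}
        a = gene_set_test(sig, background, pg, gs, n_iter=2_000, rng=7)
        b = gene_set_test(sig, background, pg, gs, n_iter=2_000, rng=7)
        assert a["p"].iloc[0] == b["p"].iloc[0]

    def test_empty_background_raises(self):
        with pytest.raises(ValidationError):
            gene_set_test([], [], pd.Series(dtype=object), {"S": ["A"]})


def _annotation(n, spacing=100):
    return pd.DataFrame({
        "probe_id": [f"cg{i}" for i in range(n)],
        "chrom": "chr1",
        "pos": 1 + spacing * np.arange(n),
    })


class TestTfbsEnrichment:
    def test_interval_covering_everything_is_uninformative(self):
        ann = _annotation(200)
        bed = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10 ** 6]})
        out = tfbs_enrichment([f"cg{i}" for i in range(20)], {"TF": bed}, ann)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_planted_enrichment_detected(self, rng):
        ann = _annotation(5_000)
        dmps = [f"cg{i}" for i in range(200)]
        # intervals covering 80% of DMPs and ~10% of the background
        dmp_pos = ann.set_index("probe_id").loc[dmps[:160], "pos"]
        bg_pos = ann["pos"].iloc[rng.choice(np.arange(200, 5_000), 480, replace=False)]
        starts = np.concatenate([dmp_pos.to_numpy() - 1, bg_pos.to_numpy() - 1])
        bed = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 10})
        out = tfbs_enrichment(dmps, {"TF": bed}, ann)
        assert out["p"].iloc[0] < 1e-6

    def test_no_overlap_flagged_with_p_one(self):
        ann = _annotation(50)
        bed = pd.DataFrame({"chrom": ["chr9"], "start": [0], "end": [10]})
        out = tfbs_enrichment(["cg0"], {"TF": bed}, ann)
        assert out["p"].iloc[0] == 1.0 and bool(out["no_overlap"].iloc[0])

    def test_p_monotone_in_dmp_overlap_with_fixed_margins(self):
        # Fisher one-sided p decreases as the DMP-in-TFBS cell grows
        ps = []
        for a in (5, 10, 15):
            table = [[a, 20 - a], [20, 160]]
            ps.append(stats.fisher_exact(table, alternative="greater")[1])
        assert ps[0] > ps[1] > ps[2]


class TestOverlapResampling:
    def test_reference_equal_universe_gives_p_one(self):
        universe = [f"cg{i}" for i in range(100)]
        p, obs = overlap_resampling(universe[:10], universe, universe,
                                    n_iter=200, rng=0)
        assert p == pytest.approx(1.0)

    def test_disjoint_reference_uninformative(self):
        universe = [f"cg{i}" for i in range(200)]
        p, obs = overlap_resampling(universe[:5], universe[100:110], universe,
                                    n_iter=500, rng=1)
        assert obs == 0 and p > 0.9

    def test_planted_overlap_significant(self, rng):
        universe = [f"cg{i}" for i in range(10_000)]
        dmps = universe[:1_000]
        reference = universe[:100] + list(rng.choice(universe[1_000:], 400,
                                                     replace=False))
        p, obs = overlap_resampling(dmps, reference, universe, n_iter=2_000, rng=2)
        assert obs == 100
        assert p < 1e-3

    def test_reference_outside_universe_raises(self):
        with pytest.raises(ValidationError):
            overlap_resampling(["a"], ["zzz"], ["a", "b"], n_iter=10)
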