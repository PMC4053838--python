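"""Normalisation, dispersion moderation, the three LRTs, FDR, tallies,
enrichment and dosage estimation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from scipy import stats as sps

from wseq._nbglm import fit_nb_glm
from wseq import dimorphism as dm
from wseq.dimorphism import (
    DimorphismResult,
    DispersionEstimates,
    bh_adjust,
    classify_tallies,
    compute_fpkm,
    enrichment_fisher,
    estimate_dispersions,
    normalize_library_sizes,
    tmm_factors,
    z_dosage_ratio,
)
from wseq.synthetic import SimConfig, simulate_counts

from conftest import make_experiment


# ---------------------------------------------------------------------------
# GLM engine against an independent implementation
# ---------------------------------------------------------------------------


class TestNbGlmEngine:
    @pytest.mark.parametrize("phi", [0.01, 0.1, 0.5])
    def test_loglik_matches_statsmodels(self, phi):
        rng = np.random.default_rng(0)
        n = 8
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)]).astype(float)
        offset = np.log(rng.uniform(0.8e6, 1.2e6, n))
        mu = np.exp(X @ np.array([-10.0, 0.7]) + offset)
        Y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu)).astype(float)[None, :]
        mine = fit_nb_glm(Y, X, offset, phi)
        ref = sm.GLM(
            Y[0], X, family=sm.families.NegativeBinomial(alpha=phi), offset=offset
        ).fit()
        assert np.allclose(mine.beta[0], ref.params, atol=1e-5)
        assert np.isclose(mine.loglik[0], ref.llf, rtol=1e-8)

    def test_lrt_stat_equals_twice_loglik_difference(self):
        rng = np.random.default_rng(1)
        X_full = np.column_stack([np.ones(8), np.repeat([0, 1], 4)]).astype(float)
        X_red = X_full[:, :1]
        Y = rng.poisson(100, size=(20, 8)).astype(float)
        offset = np.zeros(8)
        full = fit_nb_glm(Y, X_full, offset, 0.05)
        red = fit_nb_glm(Y, X_red, offset, 0.05)
        stat = 2 * (full.loglik - red.loglik)
        assert (stat >= -1e-6).all()
        # independent check of the full-vs-reduced deviance on one gene
        fam = sm.families.NegativeBinomial(alpha=0.05)
        f = sm.GLM(Y[0], X_full, family=fam).fit()
        r = sm.GLM(Y[0], X_red, family=fam).fit()
        assert np.isclose(stat[0], 2 * (f.llf - r.llf), atol=1e-5)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((8, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_nb_glm(np.ones((1, 8)), X, np.zeros(8), 0.1)


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------


class TestTmm:
    def test_identical_samples_factor_one(self):
        exp = make_experiment({f"g{i}": [50 + i] * 8 for i in range(30)})
        assert np.allclose(tmm_factors(exp), 1.0)

    def test_doubled_sample_gets_factor_two(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, size=50)
        counts = {f"g{i}": [int(c)] * 8 for i, c in enumerate(base)}
        for i, c in enumerate(base):  # double the last sample exactly
            counts[f"g{i}"][-1] = int(2 * c)
        exp = make_experiment(counts)
        f = tmm_factors(exp)
        rel = f.iloc[-1] / f.iloc[0]
        assert abs(rel - 2.0) < 1e-6

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        counts = {f"g{i}": list(rng.integers(5, 500, 8)) for i in range(60)}
        exp = make_experiment(counts)
        f = tmm_factors(exp)
        perm = list(exp.counts.columns[::-1])
        exp2 = make_experiment({g: list(exp.counts.loc[g, perm]) for g in exp.counts.index})
        # sample names differ, but the factor of each column of data matches
        f2 = tmm_factors(exp2)
        assert np.allclose(f2.to_numpy(), f[perm].to_numpy())

    def test_all_zero_sample_rejected(self):
        counts = {f"g{i}": [10] * 7 + [0] for i in range(5)}
        exp = make_experiment(counts)
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(exp)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


class TestDispersions:
    def test_poisson_data_gives_small_common_dispersion(self):
        cfg = SimConfig(n_genes_per_class={"autosome": 2000},
                        dispersion_prior=1e-12, dispersion_sigma=0.0,
                        n_dimorphic_autosomal_per_tissue=0, n_tissue_de_genes=0,
                        seed=11)
        exp, _ = simulate_counts(cfg)
        disp = estimate_dispersions(exp)
        assert disp.common_dispersion < 0.05

    def test_recovery_at_phi_01(self):
        cfg = SimConfig(n_genes_per_class={"autosome": 2000},
                        dispersion_prior=0.1, dispersion_sigma=0.0,
                        n_dimorphic_autosomal_per_tissue=0, n_tissue_de_genes=0,
                        seed=12)
        exp, _ = simulate_counts(cfg)
        disp = estimate_dispersions(exp)
        assert 0.05 <= disp.common_dispersion <= 0.2

    def test_large_prior_weight_collapses_to_common(self):
        cfg = SimConfig(n_genes_per_class={"autosome": 300}, seed=13)
        exp, _ = simulate_counts(cfg)
        disp = estimate_dispersions(exp, prior_weight=1e9)
        assert np.allclose(
            disp.tagwise_dispersions, disp.common_dispersion, rtol=0.05
        )

    def test_shrinkage_direction(self, default_dispersions):
        tag = default_dispersions.tagwise_dispersions
        common = default_dispersions.common_dispersion
        # moderated values concentrate around the common value
        assert np.quantile(np.abs(np.log(tag / common)), 0.95) < np.log(4)

    def test_saturated_design_rejected(self):
        cfg = SimConfig(n_genes_per_class={"autosome": 50}, n_replicates=1,
                        seed=14)
        exp, _ = simulate_counts(cfg)
        with pytest.raises(ValueError, match="saturated"):
            estimate_dispersions(exp)


# ---------------------------------------------------------------------------
# the three LRTs
# ---------------------------------------------------------------------------


def _flat_disp(exp, phi=0.05):
    return DispersionEstimates(
        common_dispersion=phi,
        tagwise_dispersions=pd.Series(phi, index=exp.counts.index),
    )


class TestSexWithinTissue:
    def test_identical_sexes_give_null_result(self):
        exp = make_experiment({"g0": [100, 100, 100, 100, 80, 80, 80, 80],
                               "g1": [30, 40, 30, 40, 50, 60, 50, 60]})
        res = dm.test_sex_within_tissue(exp, _flat_disp(exp), "blastoderm")
        assert res.table.loc["g0", "log2fc"] == pytest.approx(0.0, abs=1e-9)
        assert res.table.loc["g0", "pvalue"] > 0.99

    def test_w_truth_genes_significant_in_both_tissues(
        self, default_sim, default_dispersions
    ):
        exp, truth = default_sim
        w = truth.genes.index[truth.genes.chrom_class.isin(("W", "W_random"))]
        for tissue in ("blastoderm", "gonad"):
            res = dm.test_sex_within_tissue(exp, default_dispersions, tissue)
            tab = res.table.loc[w]
            assert ((tab.qvalue < 0.05) & (tab.log2fc > 0)).all()

    def test_power_for_twofold_dimorphism_at_depth(self):
        # regression guard: 2-fold sex effect, mean >= 100, default dispersion
        cfg = SimConfig(n_genes_per_class={"autosome": 2000},
                        dimorphic_fold_change=2.0,
                        n_dimorphic_autosomal_per_tissue=150,
                        n_tissue_de_genes=0, seed=15)
        exp, truth = simulate_counts(cfg)
        disp = estimate_dispersions(exp)
        res = dm.test_sex_within_tissue(exp, disp, "blastoderm")
        g = truth.genes
        sel = g.is_dimorphic_blastoderm & (
            g.base_fpkm * g.length / 1000 * 20 >= 100
        )
        power = (res.table.loc[sel[sel].index, "pvalue"] < 0.05).mean()
        assert power >= 0.8

    def test_missing_sex_rejected(self, default_experiment, default_dispersions):
        females = default_experiment.samples(sex="F")
        sub = default_experiment.counts[females]
        import wseq.core as core

        exp = core.CountExperiment(
            counts=sub,
            design=default_experiment.design.loc[females],
            library_sizes=default_experiment.library_sizes[females],
        )
        with pytest.raises(ValueError, match="lacks"):
            dm.test_sex_within_tissue(exp, default_dispersions, "blastoderm")


class TestRatioDifference:
    def test_equal_ratio_with_tissue_shift_is_null(self):
        exp = make_experiment(
            {"g0": [200, 200, 100, 100, 2000, 2000, 1000, 1000]}
        )
        res = dm.test_ratio_difference(exp, _flat_disp(exp))
        assert res.table.loc["g0", "pvalue"] > 0.95

    def test_gonad_only_dimorphism_detected(self):
        # FOXL2-style: silent sex difference in blastoderm, strong in gonad
        counts = {"g0": [300, 300, 300, 300, 2400, 2400, 300, 300]}
        counts.update({f"bg{i}": [200] * 8 for i in range(20)})
        exp = make_experiment(counts)
        res = dm.test_ratio_difference(exp, _flat_disp(exp))
        assert res.table.loc["g0", "qvalue"] < 0.05
        assert res.table.loc["g0", "direction"] == "more-dimorphic-in-gonad"

    def test_null_calibration(self, null_sim, null_dispersions):
        res = dm.test_ratio_difference(null_sim[0], null_dispersions)
        frac = (res.table.pvalue < 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestTissueAverage:
    def test_flat_gene_is_null(self):
        exp = make_experiment({"g0": [120, 130, 120, 130, 120, 130, 120, 130]})
        res = dm.test_tissue_average(exp, _flat_disp(exp))
        assert res.table.loc["g0", "pvalue"] > 0.5

    def test_dmrt1_style_gene(self):
        # constant F:M ratio (1.6x male) but 5x higher in gonad
        counts = {"g0": [100, 100, 160, 160, 500, 500, 800, 800]}
        counts.update({f"bg{i}": [200] * 8 for i in range(20)})
        exp = make_experiment(counts)
        disp = _flat_disp(exp)
        tis = dm.test_tissue_average(exp, disp)
        ratio = dm.test_ratio_difference(exp, disp)
        assert tis.table.loc["g0", "qvalue"] < 0.05
        assert tis.table.loc["g0", "direction"] == "higher-in-gonad"
        assert ratio.table.loc["g0", "pvalue"] > 0.5

    def test_tissue_swap_flips_direction_preserves_p(self):
        rng = np.random.default_rng(3)
        counts = {f"g{i}": list(rng.integers(50, 500, 8)) for i in range(15)}
        exp = make_experiment(counts)
        res = dm.test_tissue_average(exp, _flat_disp(exp))
        design2 = exp.design.copy()
        design2["tissue"] = design2["tissue"].map(
            {"blastoderm": "gonad", "gonad": "blastoderm"}
        )
        import wseq.core as core

        exp2 = core.CountExperiment(
            counts=exp.counts, design=design2,
            library_sizes=exp.library_sizes, annotation=exp.annotation,
        )
        res2 = dm.test_tissue_average(exp2, _flat_disp(exp2))
        assert np.allclose(res.table.pvalue, res2.table.pvalue, rtol=1e-6)
        flipped = {"higher-in-gonad": "higher-in-blastoderm",
                   "higher-in-blastoderm": "higher-in-gonad"}
        assert (res.table.direction.map(flipped) == res2.table.direction).all()


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_bruteforce(p):
    """q_i = min over j with p_(j) >= p_i of p_(j) * m / rank(j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for out_rank, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(out_rank, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhAdjust:
    def test_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([]).size == 0

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_bruteforce_definition(self, p):
        assert np.allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests

        q_ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), q_ref, atol=1e-12)

    def test_q_at_least_p_and_monotone(self, null_sim, null_dispersions):
        res = dm.test_tissue_average(null_sim[0], null_dispersions)
        t = res.table.sort_values("pvalue")
        assert (t.qvalue >= t.pvalue - 1e-12).all()
        assert (np.diff(t.qvalue) >= -1e-12).all()


# ---------------------------------------------------------------------------
# tallies and enrichment
# ---------------------------------------------------------------------------


def _result_from(genes, test, q, direction):
    table = pd.DataFrame(
        {"log2fc": 1.0, "stat": 5.0, "pvalue": q, "qvalue": q,
         "direction": direction},
        index=pd.Index(genes, name="gene_id"),
    )
    return DimorphismResult(test=test, table=table)


class TestClassifyTallies:
    def test_hand_built_six_genes(self):
        genes = [f"g{i}" for i in range(6)]
        ann = pd.DataFrame(
            {"chrom_class": ["W", "W", "Z", "autosome", "autosome", "Un_random"],
             "length": 1000},
            index=pd.Index(genes, name="gene_id"),
        )
        res = {
            "sex_blastoderm": _result_from(
                genes, "sex_blastoderm",
                [0.01, 0.01, 0.01, 0.01, 0.5, 0.01],
                ["F", "F", "M", "M", "F", "F"],
            ),
            "sex_gonad": _result_from(
                genes, "sex_gonad", [0.5] * 6, ["F"] * 6
            ),
        }
        tally = classify_tallies(res, ann)
        sc = tally.sex_counts
        assert sc.loc[("sex_blastoderm", "F")].sum() == 3
        assert sc.loc[("sex_blastoderm", "M")].sum() == 2
        assert sc.loc[("sex_blastoderm", "F"), "W"] == 2
        assert sc.loc[("sex_blastoderm", "M"), "Z"] == 1
        assert tally.total_significant("sex_blastoderm") == 5

    def test_empty_significant_set(self):
        genes = ["a", "b"]
        ann = pd.DataFrame({"chrom_class": ["Z", "W"], "length": 1},
                           index=pd.Index(genes, name="gene_id"))
        res = {"sex_blastoderm": _result_from(genes, "sex_blastoderm",
                                              [0.9, 0.8], ["F", "M"])}
        tally = classify_tallies(res, ann)
        assert tally.sex_counts.to_numpy().sum() == 0

    def test_w_genes_all_female_biased(
        self, default_sim, default_dispersions
    ):
        exp, truth = default_sim
        res = {
            "sex_blastoderm": dm.test_sex_within_tissue(
                exp, default_dispersions, "blastoderm"
            ),
        }
        tally = classify_tallies(res, exp.annotation)
        sc = tally.sex_counts
        for cls in ("W", "W_random"):
            assert sc.loc[("sex_blastoderm", "M")].get(cls, 0) == 0
            assert sc.loc[("sex_blastoderm", "F"), cls] > 0

    def test_unannotated_gene_reported_and_excluded(self):
        genes = ["a", "b"]
        ann = pd.DataFrame({"chrom_class": ["Z"], "length": 1},
                           index=pd.Index(["a"], name="gene_id"))
        res = {"sex_blastoderm": _result_from(genes, "sex_blastoderm",
                                              [0.01, 0.01], ["F", "F"])}
        tally = classify_tallies(res, ann)
        assert tally.missing_annotation == ["b"]
        assert tally.sex_counts.to_numpy().sum() == 1


class TestEnrichmentFisher:
    def test_against_hypergeometric_sum(self):
        # membership table [[10, 90], [100, 9000]]
        universe = [f"g{i}" for i in range(9200)]
        sig = universe[:100]
        listed = universe[:10] + universe[100:190]
        _, p = enrichment_fisher(sig, listed, universe)
        # brute force: sum of hypergeometric probabilities <= P(observed)
        M, n, N = 9200, 100, 100  # universe, listed size, significant size
        rv = sps.hypergeom(M, len(listed), N)
        obs = rv.pmf(10)
        p_ref = sum(rv.pmf(k) for k in range(0, min(len(listed), N) + 1)
                    if rv.pmf(k) <= obs + 1e-12)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_list_equals_universe(self):
        universe = [f"g{i}" for i in range(50)]
        _, p = enrichment_fisher(universe[:5], universe, universe)
        assert p == pytest.approx(1.0)

    def test_null_resampling_is_uncalibrated_for_enrichment(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(500)]
        listed = universe[:40]
        pvals = []
        for _ in range(200):
            sig = list(rng.choice(universe, size=50, replace=False))
            pvals.append(enrichment_fisher(sig, listed, universe)[1])
        assert np.median(pvals) > 0.1

    def test_validation(self):
        with pytest.raises(ValueError, match="empty"):
            enrichment_fisher([], [], [])
        with pytest.raises(ValueError, match="subset"):
            enrichment_fisher(["a"], ["zzz"], ["a", "b"])


# ---------------------------------------------------------------------------
# FPKM and dosage
# ---------------------------------------------------------------------------


class TestFpkm:
    def test_arithmetic_identity(self):
        counts = pd.DataFrame({"s": [100, 0]}, index=["a", "b"])
        lengths = pd.Series([1000, 500], index=["a", "b"])
        libs = pd.Series([1e6], index=["s"])
        f = compute_fpkm(counts, lengths, libs)
        assert f.loc["a", "s"] == pytest.approx(100.0)
        assert f.loc["b", "s"] == 0.0

    def test_library_size_scaling(self):
        counts = pd.DataFrame({"s1": [100], "s2": [100]}, index=["a"])
        lengths = pd.Series([2000], index=["a"])
        libs = pd.Series([1e6, 2e6], index=["s1", "s2"])
        f = compute_fpkm(counts, lengths, libs)
        assert f.loc["a", "s1"] == pytest.approx(2 * f.loc["a", "s2"])

    def test_zero_length_rejected(self):
        counts = pd.DataFrame({"s": [1]}, index=["a"])
        with pytest.raises(ValueError, match="length"):
            compute_fpkm(counts, pd.Series([0], index=["a"]),
                         pd.Series([1e6], index=["s"]))


class TestZDosage:
    def test_compensated_simulation_near_one(self):
        cfg = SimConfig(n_genes_per_class={"autosome": 500, "Z": 300},
                        z_male_ratio=1.0, n_mhm_genes=0, seed=21,
                        n_dimorphic_autosomal_per_tissue=0, n_tissue_de_genes=0)
        exp, _ = simulate_counts(cfg)
        eff = normalize_library_sizes(exp)
        fpkm = compute_fpkm(exp.counts, exp.annotation["length"], eff)
        r = z_dosage_ratio(fpkm, exp.design, exp.annotation)
        assert ((r > 0.95) & (r < 1.05)).all()

    def test_sex_swap_inverts_ratio(self, default_experiment):
        exp = default_experiment
        eff = normalize_library_sizes(exp)
        fpkm = compute_fpkm(exp.counts, exp.annotation["length"], eff)
        r = z_dosage_ratio(fpkm, exp.design, exp.annotation)
        design2 = exp.design.copy()
        design2["sex"] = design2["sex"].map({"F": "M", "M": "F"})
        r2 = z_dosage_ratio(fpkm, design2, exp.annotation)
        assert np.allclose(r * r2, 1.0, atol=1e-9)

    def test_no_z_genes_rejected(self, default_experiment):
        exp = default_experiment
        fpkm = compute_fpkm(
            exp.counts, exp.annotation["length"], exp.library_sizes
        )
        auto_ann = exp.annotation[exp.annotation.chrom_class == "autosome"]
        with pytest.raises(ValueError, match="Z genes"):
            z_dosage_ratio(fpkm.loc[auto_ann.index], exp.design, auto_ann)
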