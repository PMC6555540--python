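"""Generator contracts: closed forms, noiseless recoveries, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgrmap import (
    GenomeMap,
    GimSimConfig,
    haldane_recomb,
    normalize_to_control,
    simulate_fluctuation,
    simulate_gim_cross,
    simulate_growth_curve,
    simulate_signal_table,
    simulate_spread_counts,
    yeast_genome,
)


class TestHaldane:
    def test_closed_form_at_random_distances(self):
        rng = np.random.default_rng(42)
        for d in rng.uniform(0, 500, size=20):
            expected = 0.5 * (1.0 - math.exp(-2.0 * d / 100.0))
            assert haldane_recomb(d) == pytest.approx(expected, abs=1e-12)

    def test_limits(self):
        assert haldane_recomb(0) == 0.0
        assert abs(haldane_recomb(1e9) - 0.5) < 1e-9

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            haldane_recomb(-1.0)

    @given(st.floats(min_value=0, max_value=1e4), st.floats(min_value=0, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_monotone(self, d1, d2):
        r1, r2 = haldane_recomb(d1), haldane_recomb(d2)
        # open upper bound mathematically; float rounding may touch 0.5
        assert 0.0 <= r1 <= 0.5
        if d1 <= d2:
            assert r1 <= r2


class TestGenomeMap:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenomeMap(chromosomes=(("a", 100), ("a", 200)))
        with pytest.raises(ValueError):
            GenomeMap(chromosomes=(("a", 0),))
        with pytest.raises(ValueError):
            GenomeMap(chromosomes=(("a", 100),), cm_per_kb=0)

    def test_yeast_genome_shape(self):
        g = yeast_genome()
        assert len(g.chromosomes) == 16
        assert g.cm_per_kb == 0.35
        assert sum(l for _, l in g.chromosomes) > 12e6  # genome-scale


class TestGimCross:
    def test_mixture_formula_exact(self, genome):
        """Noiseless query abundance equals the two-term growth mixture."""
        cfg = GimSimConfig(
            genome=genome, n_barcodes=500, suppressor_locus=("chr04", 700_000),
            noise_cv=0.0, seed=3,
        )
        tbl = simulate_gim_cross(cfg)
        fast = 2.0 ** (cfg.competition_time / cfg.tau_suppressed)
        slow = 2.0 ** (cfg.competition_time / cfg.tau_unsuppressed)
        for _, row in tbl.iterrows():
            if row["chrom"] == "chr04":
                d = abs(row["pos"] - 700_000) / 1000 * genome.cm_per_kb
                p = haldane_recomb(d)
            else:
                p = 0.5
            expected = p * fast + (1 - p) * slow
            assert row["query"] == pytest.approx(expected, rel=1e-12)
            assert row["control"] == pytest.approx(1.0, rel=1e-12)

    def test_linked_barcodes_depleted(self, noiseless_screen):
        cfg, tbl = noiseless_screen
        ratio = tbl["query"] / tbl["control"]
        near = tbl["chrom"] == cfg.suppressor_locus[0]
        d = np.abs(tbl.loc[near, "pos"] - cfg.suppressor_locus[1])
        closest = ratio[near].iloc[int(np.argmin(d.to_numpy()))]
        assert closest < ratio[~near].min()

    def test_no_selection_differential_gives_unit_ratio(self, genome):
        cfg = GimSimConfig(
            genome=genome, n_barcodes=200, suppressor_locus=("chr01", 100_000),
            tau_suppressed=180.0, tau_unsuppressed=180.0, noise_cv=0.0, seed=4,
        )
        tbl = simulate_gim_cross(cfg)
        # a fixed fitness-neutral pool grows uniformly: constant ratio
        ratio = tbl["query"] / tbl["control"]
        assert np.allclose(ratio, ratio.iloc[0])

    def test_ratio_monotone_in_distance(self, noiseless_screen):
        """Query/control ratio rises with genetic distance up to the plateau."""
        cfg, tbl = noiseless_screen
        chrom, locus = cfg.suppressor_locus
        sub = tbl[tbl["chrom"] == chrom]
        d = np.abs(sub["pos"] - locus).to_numpy()
        ratio = (sub["query"] / sub["control"]).to_numpy()[np.argsort(d)]
        assert np.all(np.diff(ratio) >= -1e-12)

    def test_query_locus_positive_control_depletes(self, genome):
        base = dict(genome=genome, n_barcodes=2000, noise_cv=0.0, seed=5,
                    suppressor_locus=("chr16", 500_000))
        plain = simulate_gim_cross(GimSimConfig(**base))
        with_q = simulate_gim_cross(GimSimConfig(**base, query_locus=("chr14", 300_000)))
        on_q = with_q["chrom"] == "chr14"
        assert (with_q.loc[on_q, "query"] <= plain.loc[on_q, "query"] + 1e-12).all()
        pd.testing.assert_frame_equal(plain[~on_q.to_numpy()], with_q[~on_q.to_numpy()])

    def test_invalid_locus_rejected(self, genome):
        with pytest.raises(ValueError):
            GimSimConfig(genome=genome, n_barcodes=100,
                         suppressor_locus=("chr01", 10**9))
        with pytest.raises(KeyError):
            GimSimConfig(genome=genome, n_barcodes=100,
                         suppressor_locus=("chrZZ", 100))

    def test_small_pool_warns(self, genome):
        with pytest.warns(UserWarning):
            simulate_gim_cross(GimSimConfig(
                genome=genome, n_barcodes=30, suppressor_locus=("chr01", 1000)))


class TestGrowthCurveGen:
    def test_exact_doublings(self):
        c = simulate_growth_curve(102.0, [0, 102, 204, 306], noise_cv=0.0)
        assert np.allclose(c.od / c.od[0], [1, 2, 4, 8])

    def test_half_doubling_closed_form(self):
        c = simulate_growth_curve(180.0, [0, 90, 180, 270], noise_cv=0.0)
        assert c.od[1] / c.od[0] == pytest.approx(2**0.5, rel=1e-12)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            simulate_growth_curve(0.0, [0, 1, 2, 3])


class TestSpreadCountsGen:
    def test_poisson_mean_recovery(self):
        sc = simulate_spread_counts(91.0, math.inf, n_genes=10_000, seed=1)
        se = math.sqrt(91.0 / 10_000)
        assert abs(sc.counts.mean() - 91.0) < 3 * se

    def test_poisson_variance_matches_mean(self):
        sc = simulate_spread_counts(21.0, math.inf, n_genes=20_000, seed=2)
        assert sc.counts.var() == pytest.approx(sc.counts.mean(), rel=0.1)

    def test_negative_binomial_overdispersed(self):
        sc = simulate_spread_counts(21.0, 2.0, n_genes=20_000, seed=3)
        # variance = m + m^2/k = 21 + 441/2 = 241.5
        assert sc.counts.var() == pytest.approx(241.5, rel=0.1)

    def test_single_gene_shape(self):
        sc = simulate_spread_counts(5.0, math.inf, n_genes=1, seed=4)
        assert sc.n_genes == 1 and sc.counts[0] >= 0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_spread_counts(-1.0)
        with pytest.raises(ValueError):
            simulate_spread_counts(5.0, n_genes=0)
        with pytest.raises(ValueError):
            simulate_spread_counts(5.0, dispersion=0.0)


class TestSignalTableGen:
    FOLDS = {
        "WT": {"18S.2": 1.0, "5S": 1.0},
        "M": {"18S.2": 3.0, "5S": 1.0},
    }

    def test_noiseless_fold_recovered_exactly(self):
        tbl = simulate_signal_table(self.FOLDS, "5S", n_replicates=2,
                                    noise_cv=0.0, seed=0)
        ns = normalize_to_control(tbl, "5S")
        m = ns[(ns["strain"] == "M") & (ns["probe"] == "18S.2")]["normalized"]
        wt = ns[(ns["strain"] == "WT") & (ns["probe"] == "18S.2")]["normalized"]
        assert np.allclose(m.to_numpy() / wt.to_numpy(), 3.0)

    def test_all_unit_folds_normalize_to_one(self):
        folds = {s: {"a": 1.0, "c": 1.0} for s in ("x", "y")}
        tbl = simulate_signal_table(folds, "c", n_replicates=3, noise_cv=0.0, seed=1)
        ns = normalize_to_control(tbl, "c")
        assert np.allclose(ns["normalized"], 1.0)

    def test_explicit_loading_multiplier_cancels(self):
        kwargs = dict(control_probe="5S", n_replicates=2, noise_cv=0.0,
                      loading_cv=0.0, seed=2)
        plain = simulate_signal_table(self.FOLDS, **kwargs)
        loaded = simulate_signal_table(self.FOLDS, loading={("M", 1): 2.7}, **kwargs)
        assert not np.allclose(plain["signal"], loaded["signal"])
        pd.testing.assert_frame_equal(
            normalize_to_control(plain, "5S"), normalize_to_control(loaded, "5S")
        )

    def test_missing_or_nonunit_control_rejected(self):
        with pytest.raises(ValueError):
            simulate_signal_table({"WT": {"18S.2": 1.0}}, "5S")
        with pytest.raises(ValueError):
            simulate_signal_table({"WT": {"5S": 2.0}}, "5S")


class TestFluctuationGen:
    def test_expected_uv_colonies(self):
        counts = [
            simulate_fluctuation(5e-6, 1e8, 10.0, 0.5, seed=s)[1].suppressor_colonies
            for s in range(50)
        ]
        # E = 1e8 * 0.5 * 5e-5 = 2500, sd ~ 50; mean of 50 draws is tight
        assert np.mean(counts) == pytest.approx(2500, rel=0.02)

    def test_unit_fold_matches_conditions(self):
        spont, uv = simulate_fluctuation(1e-4, 1e7, 1.0, 0.5, seed=7)
        f_s = spont.suppressor_colonies / spont.cells_plated
        f_u = uv.suppressor_colonies / (uv.cells_plated * uv.survival_fraction)
        assert f_u == pytest.approx(f_s, rel=0.2)

    def test_zero_frequency_degenerate(self):
        spont, uv = simulate_fluctuation(0.0, 1e6, 10.0, 0.5, seed=8)
        assert spont.suppressor_colonies == 0 and uv.suppressor_colonies == 0

    def test_impossible_uv_frequency_rejected(self):
        with pytest.raises(ValueError):
            simulate_fluctuation(0.2, 1e6, 10.0, 0.5)


class TestDeterminism:
    def test_same_seed_bitwise_equal_different_seed_not(self, genome):
        cfg = dict(genome=genome, n_barcodes=300, suppressor_locus=("chr02", 50_000))
        a = simulate_gim_cross(GimSimConfig(**cfg, seed=9))
        b = simulate_gim_cross(GimSimConfig(**cfg, seed=9))
        c = simulate_gim_cross(GimSimConfig(**cfg, seed=10))
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["query"], c["query"])

    def test_growth_and_counts_reproducible(self):
        t = np.linspace(0, 600, 10)
        a = simulate_growth_curve(135, t, 0.05, seed=1)
        b = simulate_growth_curve(135, t, 0.05, seed=1)
        c = simulate_growth_curve(135, t, 0.05, seed=2)
        assert np.array_equal(a.od, b.od) and not np.array_equal(a.od, c.od)
        x = simulate_spread_counts(21, n_genes=50, seed=1)
        y = simulate_spread_counts(21, n_genes=50, seed=1)
        assert np.array_equal(x.counts, y.counts)
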