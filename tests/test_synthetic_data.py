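import numpy as np
import pandas as pd
import pytest

from xqtl.synthetic_data import (
    CausalSpec,
    ChromSpec,
    SimConfig,
    apply_selection,
    genetic_map_for,
    sequence_pool,
    simulate_experiment,
    simulate_founder_panel,
    simulate_mosaic,
)


def _config(**kw):
    base = dict(
        chromosomes=[ChromSpec("chr1", 1_000_000, 2.0)],
        snp_density=100,
        cohort_size=50,
        pool_size_selected=20,
        pool_size_control=20,
        coverage=30,
        n_replicates=2,
        seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimConfig:
    def test_rejects_single_founder(self):
        with pytest.raises(ValueError):
            _config(n_founders=1)

    def test_rejects_zero_density(self):
        with pytest.raises(ValueError):
            _config(snp_density=0)

    def test_rejects_causal_off_chromosome(self):
        with pytest.raises(ValueError, match="outside"):
            _config(survival_model=CausalSpec("chr1", 2_000_000, (0.0,) * 8))

    def test_rejects_effect_length_mismatch(self):
        with pytest.raises(ValueError, match="founder_effects"):
            _config(survival_model=CausalSpec("chr1", 100, (0.0,) * 3))

    def test_rejects_nonfinite_effects(self):
        with pytest.raises(ValueError, match="finite"):
            CausalSpec("chr1", 100, (np.inf,) * 8)


class TestFounderPanel:
    def test_construction_contract(self):
        panel = simulate_founder_panel(_config())
        assert panel.n_snps == 100
        M = panel.matrix()
        assert set(np.unique(M)) <= {0.0, 1.0}
        # every SNP polymorphic
        assert (M.sum(1) > 0).all() and (M.sum(1) < panel.n_founders).all()

    def test_two_founders_forced_complementary(self):
        panel = simulate_founder_panel(_config(n_founders=2))
        M = panel.matrix()
        assert np.all(M.sum(1) == 1)  # exactly one of (0,1)/(1,0) per SNP

    def test_mean_allele_half(self):
        cfg = _config(chromosomes=[ChromSpec("chr1", 100_000_000, 2.0)], snp_density=100, seed=9)
        panel = simulate_founder_panel(cfg)  # 10,000 SNPs
        assert panel.n_snps == 10_000
        assert panel.matrix().mean() == pytest.approx(0.5, abs=0.02)

    def test_zero_snps_errors(self):
        cfg = _config(chromosomes=[ChromSpec("chr1", 1000, 2.0)], snp_density=1)
        with pytest.raises(ValueError, match="zero SNPs"):
            simulate_founder_panel(cfg)


class TestMosaic:
    def test_zero_rate_single_segment(self, rng):
        cfg = _config(breakpoint_rate=0.0)
        gmap = genetic_map_for(cfg)
        m = simulate_mosaic(gmap, cfg, rng)
        assert m.n_breakpoints("chr1") == 0

    def test_poisson_breakpoint_mean(self, rng):
        cfg = _config(chromosomes=[ChromSpec("chr1", 25_000_000, 2.0)], breakpoint_rate=0.5)
        gmap = genetic_map_for(cfg)  # ~50 cM
        counts = [simulate_mosaic(gmap, cfg, rng).n_breakpoints("chr1") for _ in range(1000)]
        assert np.mean(counts) == pytest.approx(25, abs=1.5)

    def test_marginal_founder_uniform(self, rng):
        cfg = _config(breakpoint_rate=0.5)
        gmap = genetic_map_for(cfg)
        hits = np.zeros(8)
        for _ in range(10_000):
            m = simulate_mosaic(gmap, cfg, rng)
            hits[m.founder_at("chr1", 1.0)] += 1
        np.testing.assert_allclose(hits / 10_000, 1 / 8, atol=0.02)

    def test_segments_tile_and_alternate(self, rng):
        cfg = _config(chromosomes=[ChromSpec("chr1", 25_000_000, 2.0)], breakpoint_rate=1.0)
        gmap = genetic_map_for(cfg)
        m = simulate_mosaic(gmap, cfg, rng)
        starts, founders = m.segments["chr1"]
        assert starts[0] == 0.0
        assert np.all(np.diff(starts) > 0)
        assert np.all(founders[:-1] != founders[1:])
        assert founders.min() >= 0 and founders.max() < 8


class TestSelection:
    @staticmethod
    def _population(n, cfg, rng):
        gmap = genetic_map_for(cfg)
        return [(simulate_mosaic(gmap, cfg, rng), simulate_mosaic(gmap, cfg, rng)) for _ in range(n)], gmap

    def test_null_survival_half(self, rng):
        cfg = _config()
        pop, gmap = self._population(1000, cfg, rng)
        causal = CausalSpec("chr1", 500_000, (0.0,) * 8, baseline_logit=0.0)
        _, _, frac = apply_selection(pop, causal, rng, gmap, n_control=100)
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_forced_carrier_selection(self, rng):
        cfg = _config()
        pop, gmap = self._population(300, cfg, rng)
        # +40 per copy overwhelms the -20 baseline: one copy -> logit +20 -> p ~ 1,
        # zero copies -> logit -20 -> p ~ 0, so survival is forced by carrier status
        causal = CausalSpec("chr1", 500_000, (40.0,) + (0.0,) * 7, baseline_logit=-20.0)
        selected, _, _ = apply_selection(pop, causal, rng, gmap, n_control=100)
        cm = float(gmap.interpolate_cm("chr1", 500_000))
        carriers = {
            i
            for i, (a, b) in enumerate(pop)
            if a.founder_at("chr1", cm) == 0 or b.founder_at("chr1", cm) == 0
        }
        assert set(selected) == carriers

    def test_baseline_gives_five_percent(self, rng):
        cfg = _config()
        pop, gmap = self._population(10_000, cfg, rng)
        causal = CausalSpec("chr1", 500_000, (0.0,) * 8, baseline_logit=-2.944)
        _, _, frac = apply_selection(pop, causal, rng, gmap, n_control=100)
        assert frac == pytest.approx(0.050, abs=0.007)

    def test_zero_survivors_error(self, rng):
        cfg = _config()
        pop, gmap = self._population(20, cfg, rng)
        causal = CausalSpec("chr1", 500_000, (0.0,) * 8, baseline_logit=-30.0)
        with pytest.raises(RuntimeError, match="baseline_logit"):
            apply_selection(pop, causal, rng, gmap, n_control=5)


class TestSequencePool:
    def test_pure_founder_pool_exact(self, rng):
        cfg = _config(breakpoint_rate=0.0)
        gmap = genetic_map_for(cfg)
        panel = simulate_founder_panel(cfg, np.random.default_rng(3))
        # a single-segment mosaic is homozygous founder-f everywhere
        m = simulate_mosaic(gmap, cfg, rng)
        f = m.founder_at("chr1", 0.5)
        pool = [(m, m)]
        s = sequence_pool(panel, pool, coverage=50, rng=rng)
        freq = s.ref_freq()
        ok = ~np.isnan(freq)
        np.testing.assert_array_equal(freq[ok], panel.matrix()[ok, f])

    def test_zero_coverage_all_missing(self, rng):
        cfg = _config(breakpoint_rate=0.0)
        gmap = genetic_map_for(cfg)
        panel = simulate_founder_panel(cfg, np.random.default_rng(3))
        m = simulate_mosaic(gmap, cfg, rng)
        s = sequence_pool(panel, [(m, m)], coverage=0, rng=rng)
        assert (s.depth() == 0).all()
        assert np.isnan(s.ref_freq()).all()

    def test_fifty_fifty_mix(self, rng):
        cfg = _config(n_founders=2, breakpoint_rate=0.0)
        gmap = genetic_map_for(cfg)
        panel = simulate_founder_panel(cfg, np.random.default_rng(3))
        # find one mosaic of each founder
        mosaics = {}
        while len(mosaics) < 2:
            m = simulate_mosaic(gmap, cfg, rng)
            mosaics[m.founder_at("chr1", 0.5)] = m
        pool = [(mosaics[0], mosaics[0]), (mosaics[1], mosaics[1])]
        s = sequence_pool(panel, pool, coverage=1000, rng=rng)
        # founders differ at every SNP (F=2 polymorphism), so q = 0.5 everywhere
        np.testing.assert_allclose(s.ref_freq(), 0.5, atol=0.05)

    def test_empty_pool_errors(self, rng):
        cfg = _config()
        panel = simulate_founder_panel(cfg)
        with pytest.raises(ValueError, match="empty"):
            sequence_pool(panel, [], 30, rng)


class TestExperiment:
    def test_determinism(self):
        cfg = _config(seed=123)
        p1, g1, s1, t1 = simulate_experiment(cfg)
        p2, g2, s2, t2 = simulate_experiment(cfg)
        pd.testing.assert_frame_equal(p1.table, p2.table)
        for a, b in zip(s1, s2):
            pd.testing.assert_frame_equal(a.counts, b.counts)
        np.testing.assert_array_equal(t1.freqs, t2.freqs)
        assert t1.survival_fractions == t2.survival_fractions

    def test_metadata_layout(self):
        cfg = _config(n_replicates=4)
        _, _, samples, truth = simulate_experiment(cfg)
        assert len(samples) == 8
        cells = {(s.replicate, s.sex, s.treatment) for s in samples}
        assert len(cells) == 8
        trts = [s.treatment for s in samples]
        assert trts.count("control") == 4 and trts.count("selected") == 4

    def test_truth_simplex(self):
        cfg = _config()
        _, _, _, truth = simulate_experiment(cfg)
        assert truth.freqs.min() >= 0
        np.testing.assert_allclose(truth.freqs.sum(axis=2), 1.0, atol=1e-9)

    def test_null_mean_difference_near_zero(self):
        cfg = _config(
            chromosomes=[ChromSpec("chr1", 10_000_000, 2.0)],
            cohort_size=200,
            pool_size_selected=80,
            pool_size_control=80,
            n_replicates=4,
            seed=5,
        )
        _, _, samples, truth = simulate_experiment(cfg)
        sel = [i for i, s in enumerate(samples) if s.treatment == "selected"]
        con = [i for i, s in enumerate(samples) if s.treatment == "control"]
        diffs = truth.freqs[sel].mean(0) - truth.freqs[con].mean(0)
        n = diffs.size
        se = diffs.std() / np.sqrt(truth.freqs.shape[1])  # windows correlated: generous
        assert abs(diffs.mean()) < 3 * max(se, 1e-3)

    def test_strong_effect_shifts_truth(self):
        eff = (8.0,) + (0.0,) * 7
        cfg = _config(
            chromosomes=[ChromSpec("chr1", 25_000_000, 2.0)],
            cohort_size=500,
            pool_size_selected=200,
            pool_size_control=200,
            n_replicates=2,
            seed=6,
            survival_model=CausalSpec("chr1", 12_500_000, eff, baseline_logit=-4.0),
        )
        _, gmap, samples, truth = simulate_experiment(cfg)
        g = truth.grid
        wi = (g["center_cM"] - 25.0).abs().idxmin()
        sel = [i for i, s in enumerate(samples) if s.treatment == "selected"]
        con = [i for i, s in enumerate(samples) if s.treatment == "control"]
        shift = truth.freqs[sel, wi, 0].mean() - truth.freqs[con, wi, 0].mean()
        assert shift > 0.1

    def test_effect_monotonicity(self):
        """Stronger causal effects produce larger truth-level shifts."""
        shifts = []
        for eff0 in (0.5, 2.0, 8.0):
            acc = []
            for seed in range(20):
                cfg = _config(
                    chromosomes=[ChromSpec("chr1", 10_000_000, 2.0)],
                    cohort_size=150,
                    pool_size_selected=60,
                    pool_size_control=60,
                    n_replicates=2,
                    seed=1000 + seed,
                    survival_model=CausalSpec(
                        "chr1", 5_000_000, (eff0,) + (0.0,) * 7, baseline_logit=-eff0 / 2
                    ),
                )
                _, _, samples, truth = simulate_experiment(cfg)
                g = truth.grid
                wi = (g["center_cM"] - 10.0).abs().idxmin()
                sel = [i for i, s in enumerate(samples) if s.treatment == "selected"]
                con = [i for i, s in enumerate(samples) if s.treatment == "control"]
                acc.append(truth.freqs[sel, wi, 0].mean() - truth.freqs[con, wi, 0].mean())
            shifts.append(np.mean(acc))
        assert shifts[0] < shifts[1] < shifts[2]

    def test_survival_fraction_recorded(self):
        cfg = _config(n_replicates=3)
        _, _, _, truth = simulate_experiment(cfg)
        assert len(truth.survival_fractions) == 3
        assert all(0 <= f <= 1 for f in truth.survival_fractions)

    def test_truth_json_round_trip(self, tmp_path):
        import json

        cfg = _config()
        _, _, _, truth = simulate_experiment(cfg)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        data = json.loads(path.read_text())
        assert data["causal"] is None
        assert len(data["freqs"]) == len(truth.sample_ids)
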