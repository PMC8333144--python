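import numpy as np
import pandas as pd
import pytest

from conftest import make_phenos, sad_noise
from fppfm.curve_basis import LOPBasis
from fppfm.funmap_core import FitOptions
from fppfm.io_data import PhenotypeSeries
from fppfm.qtl_scan import ScanEngine, find_regions, genome_scan, lrt_existence
from fppfm.qtl_scan import permutation_threshold
from fppfm.qtl_scan import test_pleiotropy as pleiotropy_lrt
from fppfm.qtl_scan import test_qxe as qxe_lrt
from fppfm.simulation_study import SimConfig, simulate_dataset, simulate_matrices

STAGES = ["pre", "dry", "wet"]


def sim(seed, n=60, m=50, h2=0.10, correlated=True):
    cfg = SimConfig(n_individuals=n, n_markers=m, heritability=h2,
                    correlated=correlated)
    Y, codes, truth = simulate_matrices(cfg, seed)
    return make_phenos(Y, STAGES, 10), codes, truth, cfg


class TestExistenceLRT:
    def test_identical_phenotypes_give_zero_lr(self, rng):
        # both genotype classes contain exactly the same set of trajectories
        half = np.linspace(0, 1, 30) + sad_noise(rng, 10, 30, 0.5, 0.4)
        Y = np.vstack([half, half])
        geno = np.array([0.0] * 10 + [2.0] * 10)
        ph = make_phenos(Y, STAGES, 10)
        lr, df, p = lrt_existence(ph, geno, FitOptions())
        assert lr < 1e-3
        assert p > 0.99

    def test_df_counting(self):
        phenos, codes, truth, cfg = sim(2, n=30)
        lr, df, p = lrt_existence(phenos, codes[0], FitOptions(order=4))
        assert df == 15  # (J-1) L S (k+1) = 1*1*3*5

    def test_engine_matches_exact_fit(self):
        phenos, codes, truth, cfg = sim(3, n=60)
        engine = ScanEngine(phenos, FitOptions())
        lr_vec, df, p = engine.lrt(codes[:10])
        for m in range(10):
            lr, df2, _ = lrt_existence(phenos, codes[m], FitOptions())
            assert df2 == df
            assert lr_vec[m] == pytest.approx(lr, abs=0.02)

    def test_null_calibration_at_nominal_level(self):
        """Existence LRT rejects ~5% of null markers at the chi-square 5%
        threshold (markers independent of the phenotype)."""
        n_rep, rejections = 400, 0
        rng = np.random.default_rng(99)
        base = np.sin(np.linspace(0, 3, 30))
        cfg = SimConfig(n_individuals=100, n_markers=10)
        layout = cfg.layout()
        for _ in range(n_rep):
            Y = base + sad_noise(rng, 100, 30, 0.6, 1.5)
            codes = np.where(rng.random(100) < 0.5, 2.0, 0.0)[None, :]
            engine = ScanEngine.from_matrix(Y, layout, FitOptions())
            _, _, p = engine.lrt(codes)
            rejections += int(p[0] < 0.05)
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * se + 1e-9


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum(self):
        phenos, codes, truth, cfg = sim(5, n=30, m=10)
        engine = ScanEngine(phenos, FitOptions())
        rng_lrs = []
        lr_star, _ = permutation_threshold(
            phenos, codes, n_perm=100, alpha=1.0, seed=3, engine=engine
        )
        lr_star95, _ = permutation_threshold(
            phenos, codes, n_perm=100, alpha=0.05, seed=3, engine=engine
        )
        assert lr_star <= lr_star95

    def test_bit_reproducible_given_seed(self):
        phenos, codes, truth, cfg = sim(6, n=30, m=10)
        a = permutation_threshold(phenos, codes, n_perm=120, alpha=0.05, seed=11)
        b = permutation_threshold(phenos, codes, n_perm=120, alpha=0.05, seed=11)
        assert a == b

    def test_threshold_insensitive_to_effect_size(self):
        """Permutation destroys the marker-phenotype association, so scaling
        the QTL effect does not shift the null threshold distribution."""
        phenos, codes, truth, cfg = sim(7, n=80, m=20, h2=0.05)
        lr1, _ = permutation_threshold(phenos, codes, n_perm=200, alpha=0.05, seed=2)
        # double the causal contrast
        inds, Y = phenos.to_matrix()
        g = codes[truth.causal_indices[0]]
        Y2 = Y + (g == 2.0)[:, None] * (truth.mean_QQ - truth.mean_qq)
        ph2 = make_phenos(Y2, STAGES, 10)
        lr2, _ = permutation_threshold(ph2, codes, n_perm=200, alpha=0.05, seed=2)
        assert abs(lr1 - lr2) / lr1 < 0.25

    def test_marker_mode(self):
        phenos, codes, truth, cfg = sim(8, n=30, m=10)
        lr_max, _ = permutation_threshold(
            phenos, codes, n_perm=100, alpha=0.05, seed=4, mode="max"
        )
        lr_per, _ = permutation_threshold(
            phenos, codes, n_perm=100, alpha=0.05, seed=4, mode="marker"
        )
        assert lr_per < lr_max  # per-marker quantile is less extreme than max-LR


class TestGenomeScan:
    def test_peak_is_causal_marker(self):
        phenos, genos, truth = simulate_dataset(
            SimConfig(n_individuals=100, n_markers=60, heritability=0.10), 21
        )
        result, regions = genome_scan(
            phenos, genos, FitOptions(), {"method": "bonferroni", "alpha": 0.05}
        )
        peak = result.table.loc[result.table["LR"].idxmax()]
        assert peak["bin_id"] == truth.causal_marker_ids[0]
        assert regions, "causal QTL should form a significant region"
        assert any(r.peak_bin == truth.causal_marker_ids[0] for r in regions)

    def test_permutation_threshold_path(self):
        phenos, genos, truth = simulate_dataset(
            SimConfig(n_individuals=80, n_markers=30, heritability=0.10), 22
        )
        result, regions = genome_scan(
            phenos, genos, FitOptions(),
            {"method": "permutation", "n_perm": 120, "alpha": 0.05, "seed": 9},
        )
        causal_lr = result.table.set_index("bin_id").loc[
            truth.causal_marker_ids[0], "LR"
        ]
        assert causal_lr > result.threshold_lr

    def test_marker_order_equivariance(self):
        """Relabelling marker order permutes scan rows identically."""
        phenos, codes, truth, cfg = sim(23, n=40, m=12)
        engine = ScanEngine(phenos, FitOptions())
        lr, _, _ = engine.lrt(codes)
        perm = np.random.default_rng(0).permutation(codes.shape[0])
        lr_p, _, _ = engine.lrt(codes[perm])
        assert np.allclose(lr_p, lr[perm], equal_nan=True)

    def test_regions_contiguous(self):
        tab = pd.DataFrame(
            {
                "bin_id": [f"b{i}" for i in range(6)],
                "chromosome": ["c1"] * 4 + ["c2"] * 2,
                "cM_min": [0, 1, 2, 3, 0, 1.0],
                "cM_max": [0, 1, 2, 3, 0, 1.0],
                "n_markers": 1,
                "LR": [50, 60, 10, 55, 70, 5.0],
                "df": 15,
                "p": [1e-6, 1e-7, 0.3, 5e-6, 1e-8, 0.6],
                "significant": [True, True, False, True, True, False],
            }
        )
        from fppfm.qtl_scan import ScanResult

        regions = find_regions(ScanResult(tab, 15, 45.0, 1e-4, "bonferroni"))
        assert len(regions) == 3
        first = regions[0]
        assert (first.cM_min, first.cM_max, first.n_bins) == (0.0, 1.0, 2)
        assert first.peak_bin == "b1"


def two_trait_series(seed, n, effect_second_trait):
    """Two traits on a shared grid; genotype affects trait curves as given."""
    rng = np.random.default_rng(seed)
    T = 30
    basis_t = np.linspace(0, 2, T)
    mu = np.sin(basis_t)
    geno = np.where(rng.random(n) < 0.5, 2.0, 0.0)
    delta = 0.8 * np.cos(basis_t)
    Y1 = mu + (geno == 2.0)[:, None] * delta + sad_noise(rng, n, T, 0.4, 0.3)
    delta2 = effect_second_trait
    Y2 = mu + (geno == 2.0)[:, None] * delta2 + sad_noise(rng, n, T, 0.4, 0.3)
    frames = []
    for trait, Y in (("t1", Y1), ("t2", Y2)):
        ph = make_phenos(Y, STAGES, 10, trait_id=trait)
        frames.append(ph.data)
    series = PhenotypeSeries(pd.concat(frames, ignore_index=True), STAGES)
    return series, geno


class TestPleiotropy:
    def test_duplicate_trait_gives_zero_lr(self):
        rng = np.random.default_rng(31)
        n, T = 40, 30
        Y = np.sin(np.linspace(0, 2, T)) + sad_noise(rng, n, T, 0.4, 0.3)
        geno = np.where(rng.random(n) < 0.5, 2.0, 0.0)
        frames = [make_phenos(Y, STAGES, 10, trait_id=t).data for t in ("t1", "t2")]
        series = PhenotypeSeries(pd.concat(frames, ignore_index=True), STAGES)
        lr, df, p = pleiotropy_lrt(series, geno, FitOptions(order=2))
        assert lr < 1e-3
        assert df == (2 - 1) * 2 * 3 * 3  # (L-1) J S (k+1)

    def test_distinct_trait_curves_detected(self):
        hits = 0
        for rep in range(10):
            delta2 = -0.8 * np.cos(np.linspace(0, 2, 30))  # opposite effect
            series, geno = two_trait_series(400 + rep, 200, delta2)
            lr, df, p = pleiotropy_lrt(series, geno, FitOptions(order=2))
            hits += int(p < 0.05)
        assert hits >= 9

    def test_single_trait_not_applicable(self):
        phenos, codes, truth, cfg = sim(33, n=20)
        with pytest.raises(ValueError, match="two traits"):
            pleiotropy_lrt(phenos, codes[0], FitOptions())


class TestQxE:
    def test_stage_constant_effect_gives_small_lr(self):
        """When genotype curves are identical across stages the Q-by-E LR is
        a null statistic (small relative to its chi-square df)."""
        rng = np.random.default_rng(41)
        n, T = 60, 30
        u = np.tile(np.linspace(-1, 1, 10), 3)  # same shape in every stage
        geno = np.where(rng.random(n) < 0.5, 2.0, 0.0)
        Y = u + (geno == 2.0)[:, None] * 0.5 * u + sad_noise(rng, n, T, 0.3, 0.2)
        ph = make_phenos(Y, STAGES, 10)
        lr, df, p = qxe_lrt(ph, geno, FitOptions(order=2))
        assert df == (3 - 1) * 2 * 1 * 3
        assert p > 0.001  # not significant: no stage-specific effect

    def test_recovery_only_effect_detected(self):
        """A genotype contrast confined to the third (recovery) stage is
        flagged as QTL-by-environment interaction at n = 60."""
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(500 + rep)
            n, T = 60, 30
            base = np.concatenate([np.linspace(0.5, 1, 10),
                                   np.linspace(1, 0.6, 10),
                                   0.6 + 0.8 * np.sin(np.pi * np.linspace(0, 1, 10))])
            effect = np.zeros(T)
            effect[20:] = 0.8 * np.sin(np.pi * np.linspace(0, 1, 10))
            geno = np.where(rng.random(n) < 0.5, 2.0, 0.0)
            Y = base + (geno == 2.0)[:, None] * effect + sad_noise(rng, n, T, 0.6, 0.4)
            ph = make_phenos(Y, STAGES, 10)
            lr, df, p = qxe_lrt(ph, geno, FitOptions(order=4))
            hits += int(p < 0.01)
        assert hits >= 8

    def test_single_stage_not_applicable(self, rng):
        Y = rng.standard_normal((20, 10))
        ph = make_phenos(Y, ["only"], 10)
        geno = np.array([0.0, 2.0] * 10)
        with pytest.raises(ValueError, match="two treatment stages"):
            qxe_lrt(ph, geno, FitOptions(order=2))
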