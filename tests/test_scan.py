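"""Likelihood engine, hypothesis fits, LR scan and permutation machinery."""

import numpy as np
import pytest

from allomap.datatypes import PAIR_PL, MeanModelParams, TraitPairData
from allomap.sad import SadParams
from allomap.scan import (
    PairDesign,
    ScanConfig,
    density_interaction_test,
    fit_model,
    genome_scan,
    lr_test,
    model_loglik,
    permutation_threshold,
)
from allomap.simulate import (
    SimDesign,
    _qtl_from_baseline,
    simulate_dataset,
)


def tiny_pair_data(n=6, th=3, tl=4, seed=0, sigma2=0.3, phi=(0.6, 0.3)):
    rng = np.random.default_rng(seed)
    times = {"high": np.arange(1.0, th + 1.0), "low": np.arange(1.0, tl + 1.0)}
    x = {d: 1.0 + 2.0 * rng.random((n, len(t))) for d, t in times.items()}
    y = {d: 2.0 * x[d] ** 0.9 + np.sqrt(sigma2) * rng.standard_normal(x[d].shape)
         for d in times}
    return TraitPairData(
        progeny_ids=[f"p{i}" for i in range(n)], pair=PAIR_PL,
        times=times, x=x, y=y,
    )


def shared_params(alpha=2.0, beta=0.9):
    mp = MeanModelParams()
    for j in (0, 1):
        mp.alpha[j] = {"high": alpha, "low": alpha}
        mp.beta[j] = {"high": beta, "low": beta}
    return mp


class TestModelLoglik:
    def test_single_progeny_on_curve_identity_cov(self):
        data = tiny_pair_data(n=1, sigma2=0.0)
        mp = shared_params()
        sad = SadParams(phi_high=0.0, phi_low=0.0, sigma2=1.0)
        ll = model_loglik(data, np.array([0]), mp, sad)
        assert ll == pytest.approx(-(3 + 4) / 2 * np.log(2 * np.pi))

    def test_duplicating_progenies_doubles_loglik(self):
        data = tiny_pair_data(n=5, seed=3)
        mp = shared_params()
        sad = SadParams(phi_high=0.5, phi_low=0.2, sigma2=0.4)
        ll1 = model_loglik(data, np.zeros(5, dtype=int), mp, sad)
        doubled = TraitPairData(
            progeny_ids=data.progeny_ids * 2, pair=data.pair, times=data.times,
            x={d: np.vstack([data.x[d]] * 2) for d in data.x},
            y={d: np.vstack([data.y[d]] * 2) for d in data.y},
        )
        ll2 = model_loglik(doubled, np.zeros(10, dtype=int), mp, sad)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_engine_matches_dense_oracle_random_instances(self):
        # whitened-kernel likelihood vs naive dense MVN evaluation
        for seed in range(5):
            data = tiny_pair_data(n=8, th=4, tl=4, seed=seed, sigma2=0.5)
            geno = np.arange(8) % 2
            fit = fit_model(data, geno, "H1", ScanConfig(n_starts=1))
            dense = model_loglik(data, geno, fit.mean_params, fit.sad_params)
            assert fit.loglik == pytest.approx(dense, abs=1e-8)

    def test_engine_matches_dense_oracle_with_missing_weeks(self):
        data = tiny_pair_data(n=10, th=4, tl=4, seed=9, sigma2=0.5)
        rng = np.random.default_rng(1)
        for d in ("high", "low"):
            mask = rng.random(data.y[d].shape) < 0.2
            data.y[d][mask] = np.nan
        geno = np.arange(10) % 2
        fit = fit_model(data, geno, "H1", ScanConfig(n_starts=1))
        dense = model_loglik(data, geno, fit.mean_params, fit.sad_params)
        assert fit.loglik == pytest.approx(dense, abs=1e-8)


class TestFitModel:
    def test_noiseless_recovery_per_genotype_per_density(self):
        d = SimDesign(seed=31, n_progeny=40, n_chrom=1, snps_per_chrom=4)
        d.sad = {"PL": SadParams(0.8, 0.8, 0.0), "LA": SadParams(0.8, 0.8, 0.0)}
        d.qtls = [_qtl_from_baseline(1, "PL", d.baselines["PL"], 0.2, beta_effect=0.1)]
        gm, traits, truth = simulate_dataset(d)
        data = TraitPairData.from_traits(traits, PAIR_PL)
        fit = fit_model(data, gm.codes[1].astype(int), "H1")
        q = truth["qtls"][0]
        for j in (0, 1):
            for dd in ("high", "low"):
                assert fit.mean_params.alpha[j][dd] == pytest.approx(
                    q["alpha"][str(j)][dd], abs=1e-4
                )
                assert fit.mean_params.beta[j][dd] == pytest.approx(
                    q["beta"][str(j)][dd], abs=1e-4
                )

    def test_h1_at_least_h0(self, pl_design, paper_like, fast_config):
        gm, _, _ = paper_like
        for s in (0, 7, 19):
            geno = gm.codes[s].astype(int)
            f1 = fit_model(pl_design, geno, "H1", fast_config)
            f0 = fit_model(pl_design, np.zeros_like(geno), "H0-pooled", fast_config)
            assert f1.loglik >= f0.loglik - 1e-6

    def test_unknown_hypothesis_rejected(self, pl_design):
        with pytest.raises(ValueError):
            fit_model(pl_design, np.zeros(pl_design.n_progeny, dtype=int), "H2")


class TestLrTest:
    def test_monomorphic_snp_skipped(self, pl_design):
        rec = lr_test(pl_design, np.zeros(pl_design.n_progeny, dtype=int), snp_id="mono")
        assert rec.skipped

    def test_null_lrs_moderate(self, pl_design, rng, fast_config):
        # random labels on null data: median LR below the 4-df chi2 95% point
        lrs = []
        for _ in range(12):
            geno = (rng.random(pl_design.n_progeny) < 0.5).astype(int)
            rec = lr_test(pl_design, geno, config=fast_config)
            if not rec.skipped:
                lrs.append(rec.lr)
        assert np.median(lrs) < 9.49

    def test_causal_snp_large_lr(self, paper_like, fast_config):
        gm, traits, truth = paper_like
        design = PairDesign(TraitPairData.from_traits(traits, PAIR_PL))
        idx = [q for q in truth["qtls"] if q["pair"] == "PL"][0]["snp_index"]
        rec = lr_test(design, gm.codes[idx].astype(int), config=fast_config)
        null_rec = lr_test(design, gm.codes[-1].astype(int), config=fast_config)
        assert rec.lr > 4 * max(null_rec.lr, 1.0)

    def test_missing_genotypes_refit_h0_on_same_subset(self, pl_design, fast_config):
        geno = (np.arange(pl_design.n_progeny) % 2).astype(int)
        geno_missing = geno.copy()
        geno_missing[:6] = -1
        rec = lr_test(pl_design, geno_missing, config=fast_config)
        assert rec.n_excluded == 6
        assert rec.lr >= 0.0
        # logL0 differs from the full-data H0 because the subset changed
        full_h0 = fit_model(pl_design, np.zeros(pl_design.n_progeny, dtype=int),
                            "H0-pooled", fast_config)
        assert rec.logl0 != pytest.approx(full_h0.loglik, abs=1e-6)


class TestGenomeScan:
    def test_one_record_per_snp_and_determinism(self, paper_like, fast_config):
        gm, traits, _ = paper_like
        sub = gm.subset_snps(np.arange(25))
        r1 = genome_scan(sub, traits, PAIR_PL, fast_config)
        r2 = genome_scan(sub, traits, PAIR_PL, fast_config)
        assert len(r1) == 25
        assert [r.lr for r in r1] == [r.lr for r in r2]

    def test_linked_snps_show_elevated_lr(self, paper_like, fast_config):
        gm, traits, truth = paper_like
        idx = [q for q in truth["qtls"] if q["pair"] == "PL"][0]["snp_index"]
        sub = gm.subset_snps(np.arange(max(idx - 2, 0), idx + 3))
        recs = genome_scan(sub, traits, PAIR_PL, fast_config)
        off = genome_scan(gm.subset_snps(np.arange(120, 125)), traits, PAIR_PL,
                          fast_config)
        assert min(r.lr for r in recs) > max(r.lr for r in off)

    def test_empty_matrix_rejected(self, paper_like, fast_config):
        gm, traits, _ = paper_like
        empty = gm.subset_snps(np.zeros(gm.n_snps, dtype=bool))
        with pytest.raises(ValueError):
            genome_scan(empty, traits, PAIR_PL, fast_config)

    def test_disjoint_progenies_rejected(self, paper_like, fast_config):
        gm, traits, _ = paper_like
        renamed = type(traits)(
            progeny_ids=[f"other{i}" for i in range(traits.n_progeny)],
            times=traits.times, values=traits.values,
        )
        with pytest.raises(ValueError):
            genome_scan(gm, renamed, PAIR_PL, fast_config)


class TestPermutation:
    def test_level_one_gives_min_of_maxima(self, paper_like, fast_config):
        gm, traits, _ = paper_like
        sub = gm.subset_snps(np.arange(5))
        res = permutation_threshold(sub, traits, PAIR_PL, n_perm=5, level=1.0,
                                    seed=1, config=fast_config)
        assert res.lr_threshold == pytest.approx(res.max_lr.min())

    def test_same_seed_same_threshold(self, paper_like, fast_config):
        gm, traits, _ = paper_like
        sub = gm.subset_snps(np.arange(5))
        a = permutation_threshold(sub, traits, PAIR_PL, 10, 0.1, seed=7,
                                  config=fast_config)
        b = permutation_threshold(sub, traits, PAIR_PL, 10, 0.1, seed=7,
                                  config=fast_config)
        assert a.lr_threshold == b.lr_threshold
        assert np.array_equal(a.max_lr, b.max_lr)

    def test_insufficient_permutations_rejected(self, paper_like):
        gm, traits, _ = paper_like
        with pytest.raises(ValueError):
            permutation_threshold(gm, traits, PAIR_PL, n_perm=5, level=0.01, seed=1)


class TestDensityInteraction:
    def test_h1_reused_loglik_consistent(self, paper_like, fast_config):
        gm, traits, truth = paper_like
        design = PairDesign(TraitPairData.from_traits(traits, PAIR_PL))
        idx = [q for q in truth["qtls"] if q["pair"] == "PL"][0]["snp_index"]
        geno = gm.codes[idx].astype(int)
        h1 = fit_model(design, geno, "H1", fast_config)
        lr_cached = density_interaction_test(design, geno, h1_fit=h1, config=fast_config)
        lr_fresh = density_interaction_test(design, geno, config=fast_config)
        assert lr_cached == pytest.approx(lr_fresh, abs=1e-5)
        assert lr_cached >= 0.0

    def test_density_specific_effect_detected(self, fast_config):
        # same parameters in both densities -> small interaction LR;
        # density-specific beta -> large
        base = SimDesign(seed=41, n_progeny=150, n_chrom=1, snps_per_chrom=4)
        q_null = _qtl_from_baseline(1, "PL", base.baselines["PL"], 0.15)
        for j in (0, 1):  # force identical parameters across densities
            for part in (q_null.alpha, q_null.beta):
                m = np.sqrt(part[j]["high"] * part[j]["low"])
                part[j]["high"] = part[j]["low"] = m
        base.qtls = [q_null]
        gm, traits, _ = simulate_dataset(base)
        design = PairDesign(TraitPairData.from_traits(traits, PAIR_PL))
        lr_null = density_interaction_test(design, gm.codes[1].astype(int),
                                           config=fast_config)

        alt = SimDesign(seed=42, n_progeny=150, n_chrom=1, snps_per_chrom=4)
        q_alt = _qtl_from_baseline(1, "PL", alt.baselines["PL"], 0.15)
        q_alt.beta[1]["high"] += 0.15  # genotype 1 steeper only at high density
        alt.qtls = [q_alt]
        gm2, traits2, _ = simulate_dataset(alt)
        design2 = PairDesign(TraitPairData.from_traits(traits2, PAIR_PL))
        lr_alt = density_interaction_test(design2, gm2.codes[1].astype(int),
                                          config=fast_config)
        assert lr_alt > lr_null
        assert lr_alt > 13.28  # 4-df chi2 0.99 quantile
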