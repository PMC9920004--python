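"""Generator statistical structure: RIL linkage, growth, SAD residuals."""

import json

import numpy as np
import pytest

from allomap.datatypes import MISSING
from allomap.sad import SadParams, assemble_joint_covariance
from allomap.simulate import (
    SimDesign,
    default_qtls,
    make_paper_like_dataset,
    simulate_dataset,
    simulate_predictor_growth,
    simulate_response_from_allometry,
    simulate_ril_genotypes,
    truth_from_json,
    truth_to_json,
)


class TestRilGenotypes:
    def test_zero_recombination_identical_columns(self):
        d = SimDesign(seed=1, n_progeny=30, n_chrom=1, snps_per_chrom=10,
                      recomb_fraction=0.0)
        gm = simulate_ril_genotypes(d)
        assert np.all(gm.codes == gm.codes[0])

    def test_free_recombination_decorrelates(self):
        d = SimDesign(seed=2, n_progeny=2000, n_chrom=1, snps_per_chrom=5,
                      recomb_fraction=0.5)
        gm = simulate_ril_genotypes(d)
        for s in range(4):
            r = np.corrcoef(gm.codes[s], gm.codes[s + 1])[0, 1]
            assert abs(r) < 0.1

    def test_marginal_frequency_half(self):
        d = SimDesign(seed=3, n_progeny=10_000, n_chrom=1, snps_per_chrom=6,
                      recomb_fraction=0.2)
        gm = simulate_ril_genotypes(d)
        freq0 = (gm.codes == 0).mean(axis=1)
        assert np.all(np.abs(freq0 - 0.5) < 0.015)

    def test_linkage_decay_with_distance(self):
        d = SimDesign(seed=4, n_progeny=3000, n_chrom=1, snps_per_chrom=40,
                      recomb_fraction=0.05)
        gm = simulate_ril_genotypes(d)
        r_near = np.corrcoef(gm.codes[0], gm.codes[1])[0, 1]
        r_far = np.corrcoef(gm.codes[0], gm.codes[30])[0, 1]
        assert r_near > 0.8 > abs(r_far)

    def test_invalid_recombination_rejected(self):
        with pytest.raises(ValueError):
            SimDesign(recomb_fraction=0.7)

    def test_no_missing_and_homozygous_codes(self, paper_like):
        gm, _, _ = paper_like
        assert np.all(np.isin(gm.codes, (0, 1)))
        assert not np.any(gm.codes == MISSING)


class TestPredictorGrowth:
    def test_zero_variation_identical_trajectories(self):
        d = SimDesign(seed=5, n_progeny=10)
        d.growth.sd_logK = 0.0
        d.growth.sd_logr = 0.0
        x = simulate_predictor_growth(d)
        for dd in ("high", "low"):
            assert np.allclose(x[dd], x[dd][0])

    def test_approaches_asymptote(self):
        d = SimDesign(seed=6, n_progeny=5)
        d.growth.sd_logK = 0.0
        d.growth.sd_logr = 0.0
        d.times_low = np.array([1.0, 2.0, 30.0])
        x = simulate_predictor_growth(d)
        assert np.all(np.abs(x["low"][:, -1] - d.growth.low.K) < 0.01 * d.growth.low.K)

    def test_positive_and_increasing(self, paper_like):
        _, traits, _ = paper_like
        d = SimDesign(seed=11)
        x = simulate_predictor_growth(d)
        for dd in ("high", "low"):
            assert np.all(x[dd] > 0)
            assert np.all(np.diff(x[dd], axis=1) > 0)


class TestResponseFromAllometry:
    def setup_method(self):
        self.times = {"high": np.arange(1.0, 5.0), "low": np.arange(1.0, 6.0)}
        rng = np.random.default_rng(0)
        self.x = {d: 1.0 + rng.random((6, len(t))) for d, t in self.times.items()}

    def test_noiseless_is_exact_power_law(self):
        alpha = {0: {"high": 2.0, "low": 2.2}, 1: {"high": 2.5, "low": 2.7}}
        beta = {0: {"high": 0.9, "low": 0.9}, 1: {"high": 1.1, "low": 1.1}}
        geno = np.array([0, 1, 0, 1, 0, 1])
        y = simulate_response_from_allometry(
            self.x, geno, alpha, beta, SadParams(0.5, 0.5, 0.0),
            np.random.default_rng(1), self.times,
        )
        for d in ("high", "low"):
            for i, j in enumerate(geno):
                assert np.allclose(y[d][i], alpha[j][d] * self.x[d][i] ** beta[j][d])

    def test_alpha_shift_moves_mean_curve(self):
        alpha = {0: {"high": 1.0, "low": 1.0}, 1: {"high": 3.0, "low": 3.0}}
        beta = {0: {"high": 1.0, "low": 1.0}, 1: {"high": 1.0, "low": 1.0}}
        x = {d: np.ones_like(v) * 2.0 for d, v in self.x.items()}
        y = simulate_response_from_allometry(
            x, np.array([0, 1, 0, 1, 0, 1]), alpha, beta,
            SadParams(0.5, 0.5, 0.0), np.random.default_rng(1), self.times,
        )
        assert np.allclose(y["high"][1] - y["high"][0], (3.0 - 1.0) * 2.0)

    def test_residual_covariance_matches_assembly(self):
        # Monte Carlo covariance of generated residuals vs assembled Sigma
        sad = SadParams(phi_high=0.7, phi_low=0.4, sigma2=1.0)
        alpha = {j: {"high": 2.0, "low": 2.0} for j in (0, 1)}
        beta = {j: {"high": 1.0, "low": 1.0} for j in (0, 1)}
        n = 5000
        x = {d: np.ones((n, len(t))) for d, t in self.times.items()}
        y = simulate_response_from_allometry(
            x, np.zeros(n, dtype=int), alpha, beta, sad,
            np.random.default_rng(7), self.times,
        )
        resid = np.hstack([y["high"] - 2.0, y["low"] - 2.0])
        emp = np.cov(resid.T)
        sigma = assemble_joint_covariance(self.times["high"], self.times["low"], sad).sigma
        scale = np.sqrt(np.outer(np.diag(sigma), np.diag(sigma)))
        assert np.max(np.abs(emp - sigma) / scale) < 0.08

    def test_nonpositive_predictor_rejected(self):
        x = {d: v.copy() for d, v in self.x.items()}
        x["high"][0, 0] = 0.0
        with pytest.raises(ValueError):
            simulate_response_from_allometry(
                x, np.zeros(6, dtype=int),
                {j: {"high": 1.0, "low": 1.0} for j in (0, 1)},
                {j: {"high": 1.0, "low": 1.0} for j in (0, 1)},
                SadParams(0.5, 0.5, 1.0), np.random.default_rng(1), self.times,
            )


class TestPaperLikeDataset:
    def test_design_shapes(self, paper_like):
        gm, traits, truth = paper_like
        assert gm.codes.shape == (150, 84)
        assert traits.values["high"].shape == (84, 3, 7)
        assert traits.values["low"].shape == (84, 3, 8)
        assert len(truth["qtls"]) == 2

    def test_default_snp_count(self):
        d = SimDesign()
        assert d.n_snps == 2000

    def test_determinism(self):
        a = make_paper_like_dataset(seed=21, snps_per_chrom=10)
        b = make_paper_like_dataset(seed=21, snps_per_chrom=10)
        assert np.array_equal(a[0].codes, b[0].codes)
        for d in ("high", "low"):
            assert np.array_equal(a[1].values[d], b[1].values[d])
        assert a[2] == b[2]

    def test_snp_count_does_not_perturb_phenotypes(self):
        a = make_paper_like_dataset(seed=22, snps_per_chrom=10)
        b = make_paper_like_dataset(seed=22, snps_per_chrom=40)
        for d in ("high", "low"):
            assert np.array_equal(a[1].values[d], b[1].values[d])
        # causal columns are pinned too
        ia = [q["snp_index"] for q in a[2]["qtls"]]
        ib = [q["snp_index"] for q in b[2]["qtls"]]
        assert np.array_equal(a[0].codes[ia], b[0].codes[ib])

    def test_causal_snp_in_linkage_with_neighbours(self):
        gm, _, truth = make_paper_like_dataset(seed=23, snps_per_chrom=40)
        idx = truth["qtls"][0]["snp_index"]
        r = np.corrcoef(gm.codes[idx], gm.codes[idx + 1])[0, 1]
        assert r > 0.7

    def test_truth_round_trips_through_json(self, tmp_path, paper_like):
        _, _, truth = paper_like
        path = tmp_path / "truth.json"
        truth_to_json(truth, path)
        assert truth_from_json(path) == json.loads(json.dumps(truth))
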