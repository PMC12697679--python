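import json
import math

import numpy as np
import pytest

from racoon.calibration_tree import TreeConfig
from racoon.exceptions import DataError, ParameterError
from racoon.node_calibration import (CalibModel, CalibrationConfig,
                                     CalibrationHistogram, GaussianMixtureParams,
                                     build_histogram, ensemble_predict,
                                     estimate_fraction, fit_node_gmms, fit_racoon,
                                     fraction_sample_size)
from racoon.synthetic_data import paper_like_config, generate_table


class TestFractionSampleSize:
    def test_default_bernoulli_rule(self):
        # 95% CI of half-width 0.05, no prior on p -> n = 385
        assert fraction_sample_size() == 385

    def test_looser_interval_needs_fewer_samples(self):
        assert fraction_sample_size(half_width=0.1) < 385


class TestEstimateFraction:
    def test_all_pathogenic_node(self):
        frac, _ = estimate_fraction(np.ones(2000), rng=np.random.default_rng(0))
        assert frac == 1.0

    def test_census_when_node_smaller_than_sample(self):
        y = np.array([1.0, 0.0, 0.0, 1.0])
        frac, idx = estimate_fraction(y, n_p=500)
        assert frac == 0.5 and len(idx) == 4

    def test_estimate_within_binomial_error(self):
        rng = np.random.default_rng(1)
        p = 0.3
        se = math.sqrt(p * (1 - p) / 500)
        errs = []
        for seed in range(20):
            y = (np.random.default_rng(seed).random(10_000) < p).astype(float)
            frac, idx = estimate_fraction(y, 500, np.random.default_rng(seed))
            assert len(idx) == 500
            errs.append(abs(frac - y.mean()))
        # each sample-based estimate within 3 SE of its node rate, almost surely
        assert np.mean([e < 3 * se for e in errs]) >= 0.95


class TestFitNodeGmms:
    def test_parameter_recovery_on_known_mixture(self):
        rng = np.random.default_rng(2)
        truth = GaussianMixtureParams([0.4, 0.6], [-10.0, -4.0], [1.0, 1.0])
        scores = truth.sample(8000, rng)
        labels = np.concatenate([np.zeros(4000), np.ones(4000)])
        benign, pathogenic = fit_node_gmms(scores, labels, n_gmm=4000, seed=3)
        for fitted in (benign, pathogenic):
            np.testing.assert_allclose(fitted.sorted_by_mean().means,
                                       truth.means, atol=0.1)

    def test_insufficient_class_count_rejected(self):
        with pytest.raises(DataError):
            fit_node_gmms(np.zeros(100), np.ones(100), n_gmm=400)

    def test_same_seed_identical_parameters(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(-6, 2, 2000)
        labels = (rng.random(2000) < 0.5).astype(float)
        a = fit_node_gmms(scores, labels, n_gmm=400, seed=9)
        b = fit_node_gmms(scores, labels, n_gmm=400, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.means, y.means)
            np.testing.assert_array_equal(x.weights, y.weights)

    def test_degenerate_class_falls_back_to_point_component(self):
        scores = np.concatenate([np.full(500, -3.0), np.random.default_rng(5).normal(size=500)])
        labels = np.concatenate([np.zeros(500), np.ones(500)])
        with pytest.warns(UserWarning, match="degenerate"):
            benign, _ = fit_node_gmms(scores, labels, n_gmm=500, seed=0)
        assert benign.means[0] == -3.0

    def test_reused_fraction_sample_is_respected(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(-6, 2, 3000)
        labels = (rng.random(3000) < 0.5).astype(float)
        frac, idx = estimate_fraction(labels, 500, np.random.default_rng(0))
        # must not raise, and be deterministic with the same reuse set
        a = fit_node_gmms(scores, labels, reuse_idx=idx, n_gmm=400, seed=1)
        b = fit_node_gmms(scores, labels, reuse_idx=idx, n_gmm=400, seed=1)
        np.testing.assert_array_equal(a[0].means, b[0].means)


class TestBuildHistogram:
    gmm_lo = GaussianMixtureParams([0.5, 0.5], [-10.0, -13.0], [2.0, 2.0])
    gmm_hi = GaussianMixtureParams([0.5, 0.5], [-4.0, -6.0], [2.0, 2.0])

    def test_zero_fraction_gives_all_zero_bins(self):
        h = build_histogram(self.gmm_hi, self.gmm_lo, 0.0,
                            rng=np.random.default_rng(0))
        assert (h.bin_fraction == 0).all()

    def test_identical_mixtures_give_flat_fraction(self):
        p = 0.3
        n_sample, n_bins = 40_000, 50
        h = build_histogram(self.gmm_hi, self.gmm_hi, p, n_sample, n_bins,
                            np.random.default_rng(1))
        bound = 3 * math.sqrt(p * (1 - p) / (n_sample / n_bins))
        assert np.abs(h.bin_fraction - p).max() < bound

    def test_separated_mixtures_give_monotone_map(self):
        # pathogenic mass far below benign: fraction must fall with score,
        # up to the resolution of a 10x oversampled reference
        h = build_histogram(self.gmm_hi, self.gmm_lo, 0.4,
                            n_sample=400_000, n_bins=50,
                            rng=np.random.default_rng(2))
        diffs = np.diff(h.bin_fraction)
        assert (diffs <= 0.02).all()  # non-increasing up to sampling noise

    def test_probability_conservation(self):
        frac = 0.37
        n_sample = 40_000
        rng = np.random.default_rng(3)
        h = build_histogram(self.gmm_hi, self.gmm_lo, frac, n_sample, 50, rng)
        # reconstruct per-bin counts from a replayed draw
        rng2 = np.random.default_rng(3)
        n_path = int(round(n_sample * frac))
        draws = np.concatenate([self.gmm_lo.sample(n_path, rng2),
                                self.gmm_hi.sample(n_sample - n_path, rng2)])
        idx = h.bin_index(draws)
        counts = np.bincount(idx, minlength=h.n_bins)
        assert (counts * h.bin_fraction).sum() == pytest.approx(n_path)

    def test_equal_frequency_counts_differ_by_at_most_one(self):
        h = build_histogram(self.gmm_hi, self.gmm_lo, 0.5, 10_000, 50,
                            np.random.default_rng(4))
        rng2 = np.random.default_rng(4)
        draws = np.concatenate([self.gmm_lo.sample(5000, rng2),
                                self.gmm_hi.sample(5000, rng2)])
        counts = np.bincount(h.bin_index(draws), minlength=h.n_bins)
        assert counts.max() - counts.min() <= 1

    def test_too_many_bins_rejected(self):
        with pytest.raises(DataError):
            build_histogram(self.gmm_hi, self.gmm_lo, 0.5, n_sample=10, n_bins=50)

    def test_sentinel_edges_clamp_out_of_range_scores(self):
        h = build_histogram(self.gmm_hi, self.gmm_lo, 0.5,
                            rng=np.random.default_rng(5))
        assert h.lookup(-1e9) == h.bin_fraction[0]
        assert h.lookup(+1e9) == h.bin_fraction[-1]


class TestFitRacoon:
    def test_all_nodes_calibrated(self, fitted_model):
        for n in fitted_model.root.walk():
            assert n.fraction is not None
            assert n.gmm_benign is not None and n.gmm_pathogenic is not None
            assert n.histogram is not None and n.histogram.n_bins >= 2

    def test_same_seed_byte_identical_model(self, synthetic_table):
        a = fit_racoon(synthetic_table, CalibrationConfig(seed=3), timestamp="t")
        b = fit_racoon(synthetic_table, CalibrationConfig(seed=3), timestamp="t")
        assert a.to_json() == b.to_json()

    def test_unlabeled_table_rejected(self, toy_table):
        with pytest.raises(DataError):
            fit_racoon(toy_table)

    def test_node_priors_recovered_within_binomial_error(self, fitted_model):
        # the estimated fraction of each calibrated node is a 500-draw
        # Bernoulli sample of the node's empirical rate
        se = math.sqrt(0.5 * 0.5 / 500)
        for n in fitted_model.root.walk():
            node_rate = n.n_pathogenic / n.n_total
            assert abs(n.fraction - node_rate) < 3 * se

    def test_json_round_trip_is_exact(self, fitted_model, tmp_path):
        path = tmp_path / "model.json"
        fitted_model.to_json(path)
        back = CalibModel.from_json(path)
        assert back.to_json() == fitted_model.to_json()
        doc = json.loads(path.read_text())
        assert doc["nodes"][0]["histogram"]["edges"][0] == "-inf"


class TestMapVariant:
    def test_missing_attribute_uses_pre_split_node(self, fitted_model):
        # find a node that splits on ppi; a missing ppi must stop there
        target = next(n for n in fitted_model.root.walk()
                      if n.split_attr == "ppi" and n.children)
        attrs = {a: v for a, v in target.path}
        attrs["ppi"] = None
        for a in ("disordered", "sulfur_binding", "long_protein"):
            attrs.setdefault(a, False)
        prob, path = fitted_model.map_variant(attrs, -7.0)
        assert path == target.path
        assert prob == pytest.approx(float(target.histogram.lookup(-7.0)))

    def test_extreme_scores_fall_into_terminal_bins(self, fitted_model):
        attrs = {"long_protein": False, "disordered": False,
                 "sulfur_binding": False, "ppi": False}
        node_probs = []
        for score in (-1e6, 1e6):
            p, _ = fitted_model.map_variant(attrs, score)
            node_probs.append(p)
        # very negative LLR = strongly pathogenic; very positive = benign
        assert node_probs[0] > node_probs[1]

    def test_full_path_lookup_matches_leaf_histogram(self, fitted_model):
        leaf = next(n for n in fitted_model.root.walk() if n.is_leaf())
        attrs = dict(leaf.path)
        for a in ("disordered", "sulfur_binding", "ppi", "long_protein"):
            attrs.setdefault(a, False)
        score = -8.5
        prob, path = fitted_model.map_variant(attrs, score)
        # independent lookup: scan the leaf's edges by hand
        edges = leaf.histogram.edges
        b = 0
        while not (edges[b] <= score < edges[b + 1]):
            b += 1
        assert prob == leaf.histogram.bin_fraction[b]


class TestEnsemble:
    @staticmethod
    def _models(synthetic_table, n, base_seed=100):
        small = generate_table(paper_like_config(n_variants=20_000, seed=50))
        return [fit_racoon(small, CalibrationConfig(seed=base_seed + i))
                for i in range(n)]

    def test_identical_models_have_zero_sd(self, synthetic_table):
        m = self._models(synthetic_table, 1)[0]
        attrs = {"long_protein": True, "disordered": False,
                 "sulfur_binding": False, "ppi": False}
        med, sd = ensemble_predict([m] * 10, attrs, -7.0, keep=6)
        assert sd == 0.0
        assert med == pytest.approx(m.map_variant(attrs, -7.0)[0])

    def test_keep_all_is_plain_median(self, synthetic_table):
        models = self._models(synthetic_table, 5)
        attrs = {"long_protein": False, "disordered": True,
                 "sulfur_binding": False, "ppi": False}
        probs = [m.map_variant(attrs, -7.0)[0] for m in models]
        med, _ = ensemble_predict(models, attrs, -7.0, keep=5)
        assert med == pytest.approx(np.median(probs))
        assert min(probs) <= med <= max(probs)

    def test_keep_larger_than_pool_rejected(self, synthetic_table):
        models = self._models(synthetic_table, 2)
        with pytest.raises(ParameterError):
            ensemble_predict(models, {}, -7.0, keep=3)
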