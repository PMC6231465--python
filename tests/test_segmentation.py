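import numpy as np
import pytest

from _oracles import (enumerate_forward_loglik, enumerate_viterbi,
                      path_log_prob)
from conftest import make_table
from milupop.genome_io import ScaffoldSet
from milupop.segmentation import (DensityTrack, HmmModel, SegmentationError,
                                  fit_hmm, fit_mixture, forward_loglik,
                                  summarize_segmentation, viterbi_decode,
                                  viterbi_path, window_density)
from milupop.simulate import SimConfig, simulate_hmm_windows


def toy_model(initial=(0.6, 0.4), trans=((0.7, 0.3), (0.4, 0.6)),
              means=(0.0, 1.0), sds=(0.5, 0.8)):
    return HmmModel(initial=np.array(initial), transitions=np.array(trans),
                    means=np.array(means), sds=np.array(sds))


class TestWindowDensity:
    def test_uniform_snp_lattice_gives_unit_density(self):
        pos = np.arange(1, 500_001, 1000)          # one SNP per kb
        t = make_table(pos, np.zeros((len(pos), 1), np.int8), scaffold="s")
        track = window_density(t, ScaffoldSet(("s",), (500_000,)))
        assert np.allclose(track.densities["s"], 1.0)

    def test_short_scaffold_excluded_and_window_count(self):
        t = make_table([1000], [[0]], scaffold="long")
        scf = ScaffoldSet(("long", "short"), (400_000, 250_000))
        track = window_density(t, scf)
        assert "short" not in track.densities
        assert len(track.starts["long"]) == 101   # floor((400k-200k)/2k)+1

    def test_count_additivity_over_variant_subsets(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(400_000, 3000, replace=False)) + 1
        scf = ScaffoldSet(("s",), (400_000,))
        half = rng.random(3000) < 0.5
        def dens(p):
            t = make_table(p, np.zeros((len(p), 1), np.int8), scaffold="s")
            return window_density(t, scf).densities["s"]
        assert np.allclose(dens(pos), dens(pos[half]) + dens(pos[~half]))


class TestMixture:
    def test_separated_point_masses(self):
        x = np.array([0.0] * 50 + [2.0] * 50)
        fit = fit_mixture(x, seed=0)
        assert np.allclose(fit.weights, [0.5, 0.5], atol=1e-6)
        assert np.allclose(fit.means, [0.0, 2.0], atol=1e-6)

    def test_recovers_two_regime_simulation(self):
        rng = np.random.default_rng(21)
        x = np.concatenate([rng.normal(0.03, 0.02, 5000),
                            rng.normal(1.26, 0.30, 5000)])
        fit = fit_mixture(x, seed=0)
        assert np.all(np.abs(fit.means - [0.03, 1.26]) / [0.03, 1.26] < 0.05)
        assert fit.converged

    def test_loglik_non_decreasing_in_iterations(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(4, 1, 300)])
        lls = [fit_mixture(x, seed=0, max_iter=k, n_restarts=1,
                           tol=0.0).log_likelihood for k in (2, 4, 8, 16, 64)]
        assert np.all(np.diff(lls) >= -1e-9)

    def test_invariant_to_order_and_relabeling(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0.05, 0.02, 400),
                            rng.normal(1.0, 0.2, 400)])
        track_a = DensityTrack(window=1, step=1, min_scaffold=0,
                               densities={"a": x[:500], "b": x[500:]})
        track_b = DensityTrack(window=1, step=1, min_scaffold=0,
                               densities={"zz": x[::-1]})
        fa, fb = fit_mixture(track_a, seed=0), fit_mixture(track_b, seed=0)
        assert np.allclose(fa.means, fb.means, rtol=1e-6)

    def test_matches_sklearn_loglikelihood(self):
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0.1, 0.05, 1000),
                            rng.normal(1.2, 0.3, 1000)])
        ours = fit_mixture(x, seed=0)
        sk = GaussianMixture(2, n_init=3, random_state=0, tol=1e-8,
                             reg_covar=1e-10).fit(x[:, None])
        assert ours.log_likelihood >= sk.score(x[:, None]) * len(x) - 1e-3

    def test_degenerate_input_rejected(self):
        with pytest.raises(SegmentationError, match="single-regime"):
            fit_mixture(np.full(100, 0.5), seed=0)


class TestHmm:
    def test_forward_equals_exhaustive_path_sum(self):
        model = toy_model()
        obs = np.array([0.1, 0.9, 1.3, -0.2])
        ours = forward_loglik(model, obs)
        brute = enumerate_forward_loglik(model.initial, model.transitions,
                                         model.means, model.sds, obs)
        assert abs(ours - brute) < 1e-10

    def test_matches_hmmlearn_score_and_decode(self):
        from hmmlearn.hmm import GaussianHMM
        model = toy_model()
        rng = np.random.default_rng(3)
        obs = rng.normal(0.5, 1.0, 200)
        hm = GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        hm.startprob_ = model.initial
        hm.transmat_ = model.transitions
        hm.means_ = model.means[:, None]
        hm.covars_ = (model.sds**2)[:, None]
        assert abs(forward_loglik(model, obs) - hm.score(obs[:, None])) < 1e-8
        assert np.array_equal(viterbi_path(model, obs),
                              hm.decode(obs[:, None])[1])

    def test_baum_welch_loglik_non_decreasing(self):
        dens, _ = simulate_hmm_windows(2000, seed=5)
        mix = fit_mixture(dens, seed=0)
        lls = [fit_hmm([dens], mix, max_iter=k, tol=0.0).log_likelihood
               for k in (2, 4, 8, 16)]
        assert np.all(np.diff(lls) >= -1e-6)

    def test_parameter_recovery_from_simulation(self):
        dens, states = simulate_hmm_windows(20_000, seed=17)
        model = fit_hmm([dens], fit_mixture(dens, seed=0))
        assert np.all(np.abs(model.means - [0.03, 1.26]) / [0.03, 1.26] < 0.05)
        assert abs(model.transitions[0, 0] - 0.995) / 0.995 < 0.02
        acc = (viterbi_path(model, dens) == states).mean()
        assert acc >= 0.95


class TestViterbi:
    def test_equals_exhaustive_argmax_on_toys(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            model = toy_model(means=(0.0, float(rng.uniform(0.2, 2.0))))
            obs = rng.normal(0.5, 1.0, 4)
            brute, _ = enumerate_viterbi(model.initial, model.transitions,
                                         model.means, model.sds, obs)
            assert np.array_equal(viterbi_path(model, obs), brute)

    def test_tie_broken_to_low_state(self):
        model = HmmModel(initial=np.array([0.5, 0.5]),
                         transitions=np.full((2, 2), 0.5),
                         means=np.array([1.0, 1.0]), sds=np.array([0.5, 0.5]))
        path = viterbi_path(model, np.array([0.3, 1.8, 0.9, 1.1]))
        assert np.all(path == 0)

    def test_path_beats_random_alternatives(self):
        rng = np.random.default_rng(23)
        model = toy_model()
        obs = rng.normal(0.5, 1.0, 30)
        best = viterbi_path(model, obs)
        lp_best = path_log_prob(model, obs, best)
        for _ in range(50):
            alt = rng.integers(0, 2, 30)
            assert lp_best >= path_log_prob(model, obs, alt) - 1e-12

    def test_accuracy_monotone_in_mean_separation(self):
        accs = []
        for mean_high in (0.13, 0.4, 1.26):
            dens, states = simulate_hmm_windows(
                5000, means=(0.03, mean_high), seed=29)
            model = HmmModel(initial=np.array([0.5, 0.5]),
                             transitions=np.array([[0.995, 0.005],
                                                   [0.005, 0.995]]),
                             means=np.array([0.03, mean_high]),
                             sds=np.array([0.02, 0.30]))
            accs.append((viterbi_path(model, dens) == states).mean())
        assert accs[0] <= accs[1] <= accs[2]


class TestSummarize:
    def _track_and_segments(self, states, step=1000, window=1000):
        track = DensityTrack(window=window, step=step, min_scaffold=0,
                             starts={"s": np.arange(len(states)) * step},
                             densities={"s": np.asarray(states, float)},
                             scaffold_lengths={"s": len(states) * step})
        model = HmmModel(initial=np.array([0.5, 0.5]),
                         transitions=np.array([[0.9, 0.1], [0.1, 0.9]]),
                         means=np.array([0.0, 1.0]), sds=np.array([0.1, 0.1]))
        return track, viterbi_decode(model, track)

    def test_single_state_genome(self):
        track, segs = self._track_and_segments([0.0] * 10)
        t = make_table([1500], [[1]], scaffold="s")
        s = summarize_segmentation(segs, t)
        assert s.fraction_genome_L == 1.0 and s.fraction_snps_L == 1.0

    def test_snp_fraction_direct_count(self):
        # L on windows 0-4, H on 5-9 (step intervals [0,5000) and [5000,10000))
        track, segs = self._track_and_segments([0.0] * 5 + [1.0] * 5)
        pos = [100, 200, 300, 6000, 7000, 7100, 8000, 9000, 9500, 9900]
        t = make_table(pos, np.ones((10, 1), np.int8), scaffold="s")
        s = summarize_segmentation(segs, t)
        assert s.fraction_snps_L == pytest.approx(0.3)
        assert s.mean_het_L == pytest.approx(3 / 5.0)   # 3 hets / 5 kb
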