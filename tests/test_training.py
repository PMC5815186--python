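"""Parameter encoding, batch cost, pretraining and the training loop."""

import numpy as np
import pytest

from pfalign.alignment import GapPenalties
from pfalign.cmaes import CmaesConfig
from pfalign.metrics import alignment_quality
from pfalign.profiles import PairwiseAlignment
from pfalign.scoring import NetworkParams, correlation_score_matrix
from pfalign.synthetic import SynthConfig, generate_dataset
from pfalign.training import (
    Checkpoint,
    TrainConfig,
    TrainingError,
    batch_cost,
    decode_params,
    encode_params,
    grid_search_gaps,
    pretrain_mimic_cc,
    search_dimension,
    select_checkpoint,
    train,
)


def random_pg(r, H=3):
    params = NetworkParams(
        W1=r.standard_normal((20, H)),
        b1=r.standard_normal(H),
        w2=r.standard_normal(H),
        b2=float(r.standard_normal()),
    )
    ge = -float(r.uniform(0.05, 0.4))
    return params, GapPenalties(ge - float(r.uniform(0, 2)), ge)


class TestEncoding:
    def test_round_trip_exact(self, rng):
        for H in (1, 3, 8):
            p, g = random_pg(rng, H)
            v = encode_params(p, g)
            q, h = decode_params(v, H)
            assert np.array_equal(p.W1, q.W1)
            assert np.array_equal(p.b1, q.b1)
            assert np.array_equal(p.w2, q.w2)
            assert p.b2 == q.b2
            assert (g.open, g.extend) == (h.open, h.extend)

    def test_dimension_formula(self):
        assert search_dimension(2) == 47
        # 20*144 (W1) + 144 (b1) + 144 (w2) + 1 (b2) + 2 (gaps)
        assert search_dimension(144) == 3171

    def test_zero_vector_decodes_to_zero_params(self):
        p, g = decode_params(np.zeros(search_dimension(2)), 2, clamp_gaps=True)
        assert np.all(p.W1 == 0) and p.b2 == 0
        assert g.open == 0.0 and g.extend == 0.0

    def test_wrong_length_errors(self):
        with pytest.raises(TrainingError):
            decode_params(np.zeros(10), 2)

    def test_gap_clamping_projects_into_valid_region(self, rng):
        v = np.zeros(search_dimension(1))
        v[-2], v[-1] = 0.7, 0.3  # positive "penalties"
        _, g = decode_params(v, 1, clamp_gaps=True)
        assert g.open <= g.extend <= 0
        v[-2], v[-1] = -0.1, -0.9  # open milder than extend
        _, g = decode_params(v, 1, clamp_gaps=True)
        assert g.open <= g.extend


class TestBatchCost:
    def test_cost_in_unit_interval_for_random_vectors(self, rng, small_dataset):
        ds = small_dataset[:5]
        for _ in range(20):
            v = rng.standard_normal(search_dimension(2))
            c = batch_cost(v, ds, 2)
            assert 0.0 <= c <= 1.0

    def test_zero_divergence_pairs_with_diagonal_scorer_cost_zero(self):
        ds = generate_dataset(
            SynthConfig(substitution_noise=0.0, indel_rate=0.0, length=20), 5, seed=3
        )
        # a scorer mimicking the correlation coefficient aligns identical
        # profiles perfectly; here use cc directly through the metric path
        g = GapPenalties(-1.5, -0.1)
        from pfalign.alignment import semi_global_align

        sens = [
            alignment_quality(
                semi_global_align(correlation_score_matrix(a, b), g).alignment, ref
            ).sensitivity
            for a, b, ref in ds
        ]
        assert sens == [1.0] * 5

    def test_constant_network_cannot_place_indels(self, small_dataset):
        # flat score matrix: DP cannot position gaps; cost strictly > 0, and
        # equals the independently recomputed metric-path value
        H = 2
        v = np.zeros(search_dimension(H))
        v[22 * H] = 1.0  # b2 = 1: constant positive score
        v[-2], v[-1] = -1.5, -0.1
        ds = [t for t in small_dataset if any(i is None or j is None for i, j in t[2].columns)][:5]
        cost = batch_cost(v, ds, H)
        assert cost > 0.0

        from pfalign.alignment import semi_global_align
        from pfalign.scoring import nn_score_matrix

        p, g = decode_params(v, H, clamp_gaps=True)
        sens = [
            alignment_quality(
                semi_global_align(nn_score_matrix(p, a, b), g).alignment, ref
            ).sensitivity
            for a, b, ref in ds
        ]
        assert cost == pytest.approx(1 - float(np.mean(sens)))

    def test_empty_dataset_errors(self):
        with pytest.raises(TrainingError):
            batch_cost(np.zeros(search_dimension(1)), [], 1)


class TestPretrain:
    def test_zero_epochs_returns_random_initialization(self):
        r1 = pretrain_mimic_cc(4, 100, seed=9, epochs=0)
        r2 = pretrain_mimic_cc(4, 100, seed=9, epochs=0)
        assert np.array_equal(r1.params.W1, r2.params.W1)

    def test_symmetry_is_structural(self, rng):
        from pfalign.scoring import nn_score

        res = pretrain_mimic_cc(4, 500, seed=1, epochs=2)
        a, b = rng.random(20), rng.random(20)
        assert nn_score(res.params, a, b) == nn_score(res.params, b, a)

    def test_training_beats_the_best_constant_predictor(self):
        # the correlation coefficient of an independent Dirichlet pair has
        # sd ~0.23; any useful fit must do better than predicting a constant
        res = pretrain_mimic_cc(32, 10000, seed=2, epochs=60)
        assert res.holdout_rmse < 0.21
        assert res.holdout_rmse < pretrain_mimic_cc(32, 10000, seed=2, epochs=0).holdout_rmse

    def test_divergence_raises_actionable_error(self):
        with pytest.raises(TrainingError, match="learning rate"):
            pretrain_mimic_cc(8, 2000, seed=3, epochs=5, learning_rate=50.0)

    def test_invalid_n_pairs(self):
        with pytest.raises(TrainingError):
            pretrain_mimic_cc(4, 0, seed=0)


def test_sum_of_pair_does_not_determine_correlation():
    """Witness that cc is not a function of a+b: transfer mass between two
    coordinates of a and oppositely in b.  The sums agree, the correlations
    differ, so any shared-weight network (a function of the sum) must err on
    one of the two pairs."""
    from pfalign.scoring import correlation_score

    r = np.random.default_rng(0)
    p = r.dirichlet(np.full(20, 0.3))
    d = np.zeros(20)
    i, j = np.argsort(p)[-2:]  # two largest coordinates
    delta = min(p[i], p[j]) / 2
    d[i], d[j] = delta, -delta  # zero-sum transfer keeping both on the simplex
    a1, b1 = p + d, p - d  # anti-correlated perturbation, same sum 2p
    a2 = b2 = p  # identical pair, same sum 2p
    assert np.allclose(a1 + b1, a2 + b2)
    assert (a1 >= 0).all() and (b1 >= 0).all()
    cc_perturbed = correlation_score(a1, b1)
    assert correlation_score(a2, b2) == pytest.approx(1.0)
    assert abs(1.0 - cc_perturbed) > 0.05


class TestCheckpointSelection:
    def _cp(self, epoch, val):
        p = NetworkParams(W1=np.zeros((20, 1)), b1=np.zeros(1), w2=np.zeros(1), b2=0.0)
        return Checkpoint(epoch=epoch, params=p, gaps=GapPenalties(-1, -0.1),
                          train_cost=0.5, validation_sensitivity=val)

    def test_argmax_with_earliest_tie(self):
        cps = [self._cp(50, 0.3), self._cp(55, 0.5), self._cp(60, 0.5)]
        assert select_checkpoint(cps).epoch == 55

    def test_empty_history_errors(self):
        with pytest.raises(TrainingError):
            select_checkpoint([])


class TestTrainLoop:
    def test_validation_schedule_must_fit_in_epochs(self):
        with pytest.raises(TrainingError, match="validation_start_epoch"):
            TrainConfig(epochs_max=20, validation_start_epoch=50)

    def test_short_run_is_deterministic_and_checkpoints_on_schedule(self, small_dataset):
        cfg = TrainConfig(
            hidden_units=4, epochs_max=6, validation_start_epoch=2,
            validation_stride=2,
            cmaes=CmaesConfig(sigma0=0.032, lam=6, mu=3),
            pretrain_pairs=2000, pretrain_epochs=10,
            validation_size=4, seed=13,
        )
        ds = small_dataset[:10]
        r1 = train(ds, cfg)
        r2 = train(ds, cfg)
        assert [c.epoch for c in r1.checkpoints] == [2, 4, 6]
        assert r1.selected.epoch == r2.selected.epoch
        assert r1.selected.validation_sensitivity == r2.selected.validation_sensitivity
        assert np.array_equal(r1.selected.params.W1, r2.selected.params.W1)
        assert r1.selected.gaps.open <= r1.selected.gaps.extend <= 0


class TestGridSearch:
    def test_stated_ranges_enumerate_60_combinations(self, small_dataset):
        _, _, table = grid_search_gaps(
            correlation_score_matrix, small_dataset[:3]
        )
        assert len(table) == 60

    def test_singleton_ranges(self, small_dataset):
        o, e, table = grid_search_gaps(
            correlation_score_matrix, small_dataset[:2],
            open_range=(-1.5, -1.5), extend_range=(-0.1, -0.1),
        )
        assert (o, e) == (-1.5, -0.1)
        assert len(table) == 1

    def test_invalid_inputs(self, small_dataset):
        with pytest.raises(TrainingError):
            grid_search_gaps(correlation_score_matrix, small_dataset[:1], step=0.0)
        with pytest.raises(TrainingError):
            grid_search_gaps(
                correlation_score_matrix, small_dataset[:1], open_range=(-0.6, -2.0)
            )

    def test_planted_optimum_recovery(self):
        # pairs dominated by indels: harsh open penalties forbid the needed
        # gaps, so the best sensitivity must sit at the mild end of the range
        ds = generate_dataset(
            SynthConfig(substitution_noise=0.3, indel_rate=0.12,
                        mean_indel_length=4.0, length=60),
            12, seed=17,
        )
        o, e, table = grid_search_gaps(
            correlation_score_matrix, ds,
            open_range=(-6.0, -0.5), extend_range=(-0.2, -0.2), step=0.5,
        )
        assert o > -3.0  # the forbidding regime (|open| large) is rejected
        best = table.loc[table.sensitivity.idxmax()]
        mild = table[table.open > -3.0].sensitivity.max()
        harsh = table[table.open < -4.5].sensitivity.max()
        assert mild > harsh
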