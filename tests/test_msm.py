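"""MSM estimation, validation, flux decomposition and NAC classification."""

import numpy as np
import pytest
from scipy import linalg

from halokin import (
    NacCriteria,
    binary_contact_featurize,
    ck_test,
    classify_nac,
    cluster_microstates,
    estimate_transition_model,
    generate_markov_trajectories,
    implied_timescales,
    macrostate_population,
    pathway_fractions,
    tica,
)
from halokin.msm import stationary_distribution


class TestContactFeaturize:
    def test_strict_cutoff_boundary(self):
        feats = binary_contact_featurize(np.array([[7.99, 8.00]]), cutoff=8.0)
        assert feats.tolist() == [[1, 0]]

    def test_far_distances_all_zero(self):
        assert not binary_contact_featurize(np.full((3, 4), 50.0)).any()

    def test_hand_table(self):
        assert binary_contact_featurize(
            np.array([[7.0, 9.0], [8.0, 1.0]])
        ).tolist() == [[1, 0], [0, 1]]

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            binary_contact_featurize(np.array([[-1.0]]))


class TestTica:
    def test_recovers_informative_axis(self):
        """A slow oscillation buried among white-noise dims loads component 1."""
        rng = np.random.default_rng(0)
        n = 20_000
        slow = np.sin(2 * np.pi * np.arange(n) / 500.0)
        X = np.column_stack([slow + 0.1 * rng.normal(size=n),
                             rng.normal(size=n), rng.normal(size=n)])
        model, _ = tica(X, lag=10, n_components=2)
        v = model.components[:, 0]
        cosine = abs(v[0]) / np.linalg.norm(v)
        assert cosine > 0.95
        assert model.eigenvalues[0] > 0.9

    def test_white_noise_eigenvalues_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100_000, 3))
        model, _ = tica(X, lag=5, n_components=3)
        assert np.max(np.abs(model.eigenvalues)) < 0.1

    def test_matches_dense_generalized_eigensolver(self):
        """Small 2-D series: eigenpairs equal the brute-force solution."""
        rng = np.random.default_rng(2)
        n, lag = 500, 3
        X = np.cumsum(rng.normal(size=(n, 2)), axis=0) * 0.05 + rng.normal(size=(n, 2))
        model, proj = tica(X, lag=lag, n_components=2)

        A, B = X[:-lag], X[lag:]
        m = (A.sum(0) + B.sum(0)) / (2 * len(A))
        Ac, Bc = A - m, B - m
        C0 = (Ac.T @ Ac + Bc.T @ Bc) / (2 * len(A))
        Ct = (Ac.T @ Bc + Bc.T @ Ac) / (2 * len(A))
        evals, _ = linalg.eigh(Ct, C0)
        assert model.eigenvalues == pytest.approx(np.sort(evals)[::-1], abs=1e-8)

    def test_dimension_contract(self):
        with pytest.raises(ValueError, match="exceeds"):
            tica(np.random.default_rng(0).normal(size=(100, 2)), lag=1, n_components=3)


class TestClustering:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.2, (500, 2)), rng.normal(8, 0.2, (500, 2))])
        truth = np.repeat([0, 1], 500)
        labels, centers = cluster_microstates(X, 2, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) > 0.99
        assert centers.shape == (2, 2)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(300, 2))
        a, _ = cluster_microstates(X, 5, seed=7)
        b, _ = cluster_microstates(X, 5, seed=7)
        assert np.array_equal(a, b)

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            cluster_microstates(np.zeros((5, 2)), 6, seed=0)


class TestTransitionModel:
    def test_hand_counted_example(self):
        model = estimate_transition_model([np.array([0, 0, 1, 1, 0])], lag=1)
        assert model.count_matrix.tolist() == [[1, 1], [1, 1]]
        assert model.transition_matrix.tolist() == [[0.5, 0.5], [0.5, 0.5]]

    def test_sampled_chain_recovery(self):
        T = np.array([[0.9, 0.1], [0.8, 0.2]])
        ts = generate_markov_trajectories(T, 100_000, seed=21)
        model = estimate_transition_model(ts.state_sequences, lag=1)
        assert np.max(np.abs(model.transition_matrix - T)) < 0.02
        assert model.equilibrium_distribution == pytest.approx([8 / 9, 1 / 9], abs=0.02)

    def test_rows_stochastic_and_pi_fixed_point(self):
        T = np.array([[0.7, 0.2, 0.1], [0.3, 0.5, 0.2], [0.1, 0.1, 0.8]])
        ts = generate_markov_trajectories(T, 20_000, seed=5)
        for reversible in (False, True):
            model = estimate_transition_model(ts.state_sequences, 1, reversible=reversible)
            Tm, pi = model.transition_matrix, model.equilibrium_distribution
            assert Tm.sum(axis=1) == pytest.approx(np.ones(3), abs=1e-10)
            assert np.max(np.abs(pi @ Tm - pi)) < 1e-8

    def test_reversible_satisfies_detailed_balance(self):
        T = np.array([[0.9, 0.1], [0.8, 0.2]])
        ts = generate_markov_trajectories(T, 50_000, seed=8)
        model = estimate_transition_model(ts.state_sequences, 1, reversible=True)
        pi, Tm = model.equilibrium_distribution, model.transition_matrix
        flux = pi[:, None] * Tm
        assert np.max(np.abs(flux - flux.T)) < 1e-8

    def test_constant_trajectory_degenerate(self):
        with pytest.raises(ValueError, match="single state"):
            estimate_transition_model([np.zeros(100, dtype=int)], 1)
        model = estimate_transition_model(
            [np.zeros(100, dtype=int)], 1, allow_single_state=True
        )
        assert model.n_states == 1

    def test_disconnected_states_dropped(self):
        # states {0,1} communicate; state 2 is a one-way sink tail
        dtraj = np.array([0, 1, 0, 1, 1, 0, 2, 2, 2])
        model = estimate_transition_model([dtraj], 1)
        assert set(model.active_set.tolist()) <= {0, 1, 2}
        assert model.dropped_states.size > 0


class TestImpliedTimescales:
    def test_closed_form_two_state(self):
        # deterministic-ish chain built directly from eigenvalue 0.5 at lag 1
        T = np.array([[0.75, 0.25], [0.25, 0.75]])  # lambda2 = 0.5
        ts = generate_markov_trajectories(T, 200_000, seed=13)
        its = implied_timescales(ts.state_sequences, [1])
        assert its[1][0] == pytest.approx(1 / np.log(2), rel=0.05)

    def test_lambda_near_one_reported_infinite(self):
        from halokin.msm import timescales_from_eigenvalues

        ts = timescales_from_eigenvalues([1.0, 0.999999, -0.2], lag=1)
        assert np.isinf(ts[0])
        assert ts[1] > 1e5          # lambda -> 1 diverges
        assert np.isnan(ts[2])      # negative eigenvalue has no timescale
        # a nearly decoupled two-block trajectory shows a huge (finite) t2
        dtraj = np.concatenate(
            [np.zeros(5000, dtype=int), np.ones(5000, dtype=int), np.zeros(5000, dtype=int)]
        )
        its = implied_timescales([dtraj], [1], n_timescales=1)
        assert its[1][0] > 1000

    def test_markovian_chain_flat_curves(self):
        T = np.array([[0.95, 0.05], [0.10, 0.90]])
        ts = generate_markov_trajectories(T, 200_000, seed=17)
        its = implied_timescales(ts.state_sequences, [1, 2, 5, 10])
        t2 = np.array([its[lag][0] for lag in (1, 2, 5, 10)])
        ref = -1 / np.log(0.85)  # lambda2 of the generating chain
        assert np.all(np.abs(t2 - ref) / ref < 0.1)


class TestChapmanKolmogorov:
    def test_exact_chain_small_discrepancy(self):
        T = np.array([[0.9, 0.1], [0.8, 0.2]])
        ts = generate_markov_trajectories(T, 100_000, seed=19)
        model = estimate_transition_model(ts.state_sequences, 1)
        res = ck_test(ts.state_sequences, model, factors=(2,))
        assert res[2]["max_discrepancy"] < 0.03

    def test_deterministic_cycle_exact(self):
        dtraj = np.tile([0, 1, 2], 2000)
        model = estimate_transition_model([dtraj], 1)
        res = ck_test([dtraj], model, factors=(2, 3))
        for k in (2, 3):
            assert res[k]["max_discrepancy"] < 1e-12

    def test_non_markovian_series_flagged(self):
        """A hidden-state process violates CK well above the Markov baseline."""
        rng = np.random.default_rng(23)
        # hidden 4-state cycle observed through a 2-state lumping
        hidden = np.arange(100_000) % 4
        obs = (hidden // 2).astype(int)
        obs = np.where(rng.random(obs.size) < 0.02, 1 - obs, obs)  # slight noise
        model = estimate_transition_model([obs], 1)
        res = ck_test([obs], model, factors=(2,))
        assert res[2]["max_discrepancy"] > 0.1


def _mc_channel_fractions(T, source, sink, channel_of, n_steps=1_000_000, seed=0):
    """Monte-Carlo oracle: classify each reactive excursion by the state
    entered at its final departure from the source."""
    ts = generate_markov_trajectories(T, n_steps, seed=seed)
    s = ts.state_sequences[0]
    counts: dict[str, int] = {}
    last_exit_channel = None
    in_transit = False
    for prev, cur in zip(s[:-1], s[1:]):
        if prev == source and cur != source:
            last_exit_channel = "direct" if cur == sink else channel_of[cur]
            in_transit = True
        if in_transit and cur == sink:
            counts[last_exit_channel] = counts.get(last_exit_channel, 0) + 1
            in_transit = False
        if cur == source:
            in_transit = False
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}, total


class TestPathwayFractions:
    def _model(self, T):
        return __import__("halokin.msm", fromlist=["TransitionModel"]).TransitionModel(
            count_matrix=np.zeros_like(T),
            transition_matrix=T,
            equilibrium_distribution=stationary_distribution(T),
            lag=1,
            active_set=np.arange(T.shape[0]),
            n_states_total=T.shape[0],
        )

    def test_single_channel_fraction_one(self):
        T = np.array([[0.8, 0.2, 0.0], [0.3, 0.4, 0.3], [0.2, 0.2, 0.6]])
        fr = pathway_fractions(self._model(T), [0], [2], {1: "main"})
        assert fr == pytest.approx({"main": 1.0})

    def test_symmetric_channels_half_half(self):
        T = np.array(
            [
                [0.6, 0.2, 0.2, 0.0],
                [0.3, 0.4, 0.0, 0.3],
                [0.3, 0.0, 0.4, 0.3],
                [0.1, 0.2, 0.2, 0.5],
            ]
        )
        fr = pathway_fractions(self._model(T), [0], [3], {1: "p1", 2: "p3"})
        assert fr["p1"] == pytest.approx(0.5, abs=1e-12)
        assert fr["p3"] == pytest.approx(0.5, abs=1e-12)

    def test_asymmetric_chain_matches_path_sampling(self):
        """TPT flux decomposition agrees with brute-force path counting."""
        T = np.array(
            [
                [0.50, 0.35, 0.15, 0.00],
                [0.25, 0.45, 0.00, 0.30],
                [0.40, 0.00, 0.45, 0.15],
                [0.05, 0.15, 0.10, 0.70],
            ]
        )
        model = self._model(T)
        fr = pathway_fractions(model, [0], [3], {1: "p1", 2: "p3"})
        mc, n_paths = _mc_channel_fractions(
            T, 0, 3, {1: "p1", 2: "p3"}, n_steps=400_000, seed=31
        )
        for ch in ("p1", "p3"):
            sd = np.sqrt(fr[ch] * (1 - fr[ch]) / n_paths)
            assert abs(fr[ch] - mc[ch]) < 3 * sd

    def test_unreachable_sink_rejected(self):
        T = np.array([[0.9, 0.1, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]])
        # state 2 absorbs but is never entered from {0,1}
        with pytest.raises(ValueError, match="unreachable|flux"):
            pathway_fractions(self._model(T), [0], [2], {1: "p1"})

    def test_unmapped_intermediate_rejected(self):
        T = np.array(
            [
                [0.6, 0.2, 0.2, 0.0],
                [0.3, 0.4, 0.0, 0.3],
                [0.3, 0.0, 0.4, 0.3],
                [0.1, 0.2, 0.2, 0.5],
            ]
        )
        with pytest.raises(ValueError, match="channel"):
            pathway_fractions(self._model(T), [0], [3], {1: "p1"})


class TestNacClassification:
    @pytest.mark.parametrize(
        "distance,angle,expected",
        [
            (3.41, 170.0, True),   # distance boundary inclusive
            (3.41, 157.0, True),   # angle boundary inclusive
            (3.41, 180.0, True),
            (3.42, 170.0, False),
            (3.0, 156.9, False),
            (10.0, 170.0, False),
            (2.9, 140.0, False),
        ],
    )
    def test_boundary_behavior(self, distance, angle, expected):
        mask, _ = classify_nac(np.array([[distance, angle]]))
        assert bool(mask[0]) is expected

    def test_invalid_angle_rejected(self):
        with pytest.raises(ValueError, match="angle"):
            classify_nac(np.array([[3.0, 190.0]]))

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            NacCriteria(max_distance=-1.0)
        with pytest.raises(ValueError):
            NacCriteria(angle_min=170.0, angle_max=150.0)


class TestMacrostatePopulation:
    def _two_state_model(self):
        T = np.array([[0.9, 0.1], [0.8, 0.2]])
        ts = generate_markov_trajectories(T, 50_000, seed=37)
        return estimate_transition_model(ts.state_sequences, 1)

    def test_full_set_is_one(self):
        model = self._two_state_model()
        assert macrostate_population(model, [0, 1]) == pytest.approx(1.0)

    def test_stationary_eigenvector_value(self):
        model = self._two_state_model()
        assert macrostate_population(model, [0]) == pytest.approx(8 / 9, abs=0.02)

    def test_complementary_sets_sum_to_one(self):
        model = self._two_state_model()
        assert macrostate_population(model, [0]) + macrostate_population(
            model, [1]
        ) == pytest.approx(1.0)

    def test_conditional_population(self):
        model = self._two_state_model()
        assert macrostate_population(model, [0], reference_set=[0, 1]) == pytest.approx(
            macrostate_population(model, [0])
        )

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            macrostate_population(self._two_state_model(), [])


class TestFullPipeline:
    def test_slowest_timescale_recovered_end_to_end(self):
        """featurize -> TICA -> cluster -> estimate on emissions from a known
        3-state chain recovers the slowest implied timescale within 15%."""
        T = np.array(
            [
                [0.97, 0.02, 0.01],
                [0.02, 0.96, 0.02],
                [0.01, 0.02, 0.97],
            ]
        )
        ref_ts = -1 / np.log(np.sort(np.linalg.eigvals(T).real)[-2])
        means = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0], [0.0, 4.0, 0.0]])
        ts = generate_markov_trajectories(
            T, 100_000, emission_spec={"means": means, "sd": 0.5}, seed=41
        )
        _, proj = tica(ts.feature_emissions, lag=5, n_components=2)
        labels, _ = cluster_microstates(proj, 6, seed=0)
        its = implied_timescales([labels], [1], n_timescales=1)
        assert its[1][0] == pytest.approx(ref_ts, rel=0.15)
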