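import itertools

import numpy as np
import pytest

from phaseflow.phase_hmm import (
    PhaseAnnotation,
    PhaseHMM,
    annotation_from_labels,
    baum_welch,
    estimate_emissions,
    estimate_transitions,
    fit_supervised,
    forward_argmax,
    initial_distribution,
    load_annotations,
    load_hmm,
    sample_sequence,
    save_annotations,
    save_hmm,
    viterbi_decode,
)
from phaseflow.synthetic import make_left_to_right_hmm


def _random_ltr_hmm(rng, Q, A):
    T = np.zeros((Q, Q))
    for q in range(Q - 1):
        stay = rng.uniform(0.2, 0.9)
        T[q, q], T[q, q + 1] = stay, 1 - stay
    T[Q - 1, Q - 1] = 1.0
    E = rng.dirichlet(np.ones(A), size=Q)
    return PhaseHMM(Q=Q, A=A, T=T, pi=initial_distribution(Q), E=E)


class TestPhaseAnnotation:
    def test_labels_round_trip(self):
        ann = PhaseAnnotation("w", [(1, 0, 3), (2, 3, 2), (3, 5, 4)])
        labels = ann.to_labels()
        assert labels.tolist() == [1, 1, 1, 2, 2, 3, 3, 3, 3]
        assert annotation_from_labels(labels, "w").segments == ann.segments

    @pytest.mark.parametrize(
        "segments",
        [
            [(2, 0, 3)],               # does not start at phase 1
            [(1, 0, 3), (3, 3, 2)],    # skips phase 2
            [(1, 0, 3), (2, 4, 2)],    # gap between segments
            [(1, 0, 0)],               # zero length
        ],
    )
    def test_invalid_segments_rejected(self, segments):
        with pytest.raises(ValueError):
            PhaseAnnotation("w", segments)

    def test_csv_round_trip(self, tmp_path):
        anns = [
            PhaseAnnotation("a", [(1, 0, 5), (2, 5, 3)]),
            PhaseAnnotation("b", [(1, 0, 2), (2, 2, 2), (3, 4, 6)]),
        ]
        save_annotations(anns, tmp_path / "ann.csv")
        loaded = {a.workflow_id: a for a in load_annotations(tmp_path / "ann.csv")}
        assert loaded["a"].segments == anns[0].segments
        assert loaded["b"].segments == anns[1].segments


class TestEstimateTransitions:
    def test_hand_counted_example(self):
        ann = annotation_from_labels([1, 1, 1, 2, 2])
        T = estimate_transitions([ann], Q=2)
        assert T[0, 0] == pytest.approx(2 / 3)
        assert T[0, 1] == pytest.approx(1 / 3)
        assert T[1, 1] == 1.0  # absorbing last state

    def test_one_second_phases_always_advance(self):
        ann = annotation_from_labels([1, 2, 3, 4])
        T = estimate_transitions([ann], Q=4)
        for q in range(3):
            assert T[q, q + 1] == 1.0

    def test_matches_counting_oracle(self, rng):
        anns = []
        for w in range(5):
            durations = rng.integers(1, 8, size=6)
            labels = np.concatenate([np.full(d, p + 1) for p, d in enumerate(durations)])
            anns.append(annotation_from_labels(labels, f"w{w}"))
        T = estimate_transitions(anns, Q=6)
        self_c = np.zeros(6)
        out_c = np.zeros(6)
        for ann in anns:
            lab = ann.to_labels() - 1
            for a, b in zip(lab[:-1], lab[1:]):
                out_c[a] += 1
                if a == b:
                    self_c[a] += 1
        for q in range(5):
            assert T[q, q] == pytest.approx(self_c[q] / out_c[q])
            assert T[q, q + 1] == pytest.approx(1 - self_c[q] / out_c[q])
        assert np.allclose(T.sum(axis=1), 1.0)

    def test_missing_phase_rejected(self):
        ann = annotation_from_labels([1, 1, 2, 2])
        with pytest.raises(ValueError):
            estimate_transitions([ann], Q=4)


class TestInitialDistribution:
    def test_mass_on_first_phase(self):
        pi = initial_distribution(12)
        assert pi[0] == 1.0 and pi.sum() == 1.0 and len(pi) == 12
        assert np.array_equal(initial_distribution(1), [1.0])


class TestEstimateEmissions:
    def test_raw_ratio_with_epsilon_denominator(self):
        # state 1 holds 4 seconds, 3 of symbol 0 (A = 2)
        ann = annotation_from_labels([1, 1, 1, 1, 2])
        syms = np.array([0, 0, 0, 1, 1])
        raw = estimate_emissions([ann], [syms], A=2, epsilon=1e-4, floor=False)
        assert raw[0, 0] == pytest.approx(3 / (4 + 1e-4))
        assert raw[0, 1] == pytest.approx(1 / (4 + 1e-4))

    def test_flooring_preserves_dominance_and_normalizes(self):
        ann = annotation_from_labels([1, 1, 1, 2])
        syms = np.array([2, 2, 2, 0])
        E = estimate_emissions([ann], [syms], A=4)
        assert np.allclose(E.sum(axis=1), 1.0)
        assert (E > 0).all()
        assert E[0].argmax() == 2 and E[0, 2] > max(E[0, [0, 1, 3]])

    def test_matches_counting_oracle(self, rng):
        labels = np.sort(rng.integers(1, 4, size=40))
        labels[0] = 1
        ann = annotation_from_labels(labels)
        syms = rng.integers(0, 5, size=40)
        raw = estimate_emissions([ann], [syms], A=5, floor=False)
        for q in range(1, 4):
            n_q = (labels == q).sum()
            for a in range(5):
                count = ((labels == q) & (syms == a)).sum()
                assert raw[q - 1, a] == pytest.approx(count / (n_q + 1e-4))

    def test_length_mismatch_rejected(self):
        ann = annotation_from_labels([1, 1, 2])
        with pytest.raises(ValueError):
            estimate_emissions([ann], [np.array([0, 1])], A=2)


class TestBaumWelch:
    def test_hand_executed_single_iteration(self):
        """One EM step on a 2-state, 2-symbol, 3-observation toy matches an
        explicit forward-backward computation done independently here."""
        T = np.array([[0.7, 0.3], [0.0, 1.0]])
        E = np.array([[0.8, 0.2], [0.3, 0.7]])
        pi = np.array([1.0, 0.0])
        hmm = PhaseHMM(Q=2, A=2, T=T, pi=pi, E=E)
        obs = [0, 1, 1]

        # --- independent unscaled forward-backward ---
        alpha = np.zeros((3, 2))
        alpha[0] = pi * E[:, obs[0]]
        for t in (1, 2):
            alpha[t] = (alpha[t - 1] @ T) * E[:, obs[t]]
        beta = np.ones((3, 2))
        for t in (1, 0):
            beta[t] = T @ (E[:, obs[t + 1]] * beta[t + 1])
        Z = alpha[-1].sum()
        gamma = alpha * beta / Z
        xi = np.zeros((2, 2))
        for t in (0, 1):
            xi += alpha[t][:, None] * T * (E[:, obs[t + 1]] * beta[t + 1])[None, :] / Z
        T_exp = xi / gamma[:-1].sum(axis=0)[:, None]
        T_exp[1] = [0.0, 1.0]  # absorbing state, no outgoing mass observed
        E_exp = np.zeros((2, 2))
        for t, o in enumerate(obs):
            E_exp[:, o] += gamma[t]
        E_exp /= gamma.sum(axis=0)[:, None]

        res = baum_welch(hmm, [np.array(obs)], max_iter=1, floor_emissions=False)
        assert np.allclose(res.hmm.T, T_exp / T_exp.sum(axis=1, keepdims=True), atol=1e-10)
        assert np.allclose(res.hmm.E, E_exp, atol=1e-10)
        assert res.log_likelihoods[0] == pytest.approx(np.log(Z))

    def test_self_consistency_on_model_generated_data(self):
        """Parameters barely move after one EM step on abundant data drawn
        from the model itself."""
        rng = np.random.default_rng(0)
        hmm = make_left_to_right_hmm(Q=4, A=8, mean_duration=25, seed=3)
        seqs = [sample_sequence(hmm, 120, rng)[0] for _ in range(40)]
        res = baum_welch(hmm, seqs, max_iter=1, floor_emissions=False)
        assert np.abs(res.hmm.T - hmm.T).max() < 0.02
        assert np.abs(res.hmm.E - hmm.E).max() < 0.02

    def test_log_likelihood_nondecreasing(self, rng):
        for trial in range(5):
            hmm = _random_ltr_hmm(rng, Q=3, A=4)
            seqs = [sample_sequence(hmm, 60, rng)[0] for _ in range(3)]
            # start EM from a perturbed model
            start = fit_supervised(
                [annotation_from_labels(sample_sequence(hmm, 60, rng)[1])],
                [sample_sequence(hmm, 60, rng)[0]], Q=3, A=4)
            res = baum_welch(start, seqs, max_iter=30)
            assert np.all(np.diff(res.log_likelihoods) >= -1e-6)

    def test_structural_zeros_preserved(self, rng):
        hmm = _random_ltr_hmm(rng, Q=5, A=6)
        seqs = [sample_sequence(hmm, 80, rng)[0] for _ in range(4)]
        res = baum_welch(hmm, seqs, max_iter=20)
        T = res.hmm.T
        for q in range(5):
            for q2 in range(5):
                if q2 not in (q, q + 1):
                    assert T[q, q2] == 0.0
        assert T[4, 4] == 1.0

    def test_symbol_outside_alphabet_rejected(self, rng):
        hmm = _random_ltr_hmm(rng, Q=2, A=3)
        with pytest.raises(ValueError):
            baum_welch(hmm, [np.array([0, 3])])

    def test_agrees_with_hmmlearn(self, rng):
        """Independent cross-check of the EM fixed point against hmmlearn."""
        from hmmlearn.hmm import CategoricalHMM

        hmm = _random_ltr_hmm(rng, Q=3, A=4)
        seqs = [sample_sequence(hmm, 100, rng)[0] for _ in range(3)]
        res = baum_welch(hmm, seqs, max_iter=5, tol=0, floor_emissions=False)

        ref = CategoricalHMM(n_components=3, n_features=4, init_params="",
                             params="te", n_iter=5, tol=0, implementation="scaling")
        ref.startprob_ = hmm.pi.copy()
        ref.transmat_ = hmm.T.copy()
        ref.emissionprob_ = hmm.E.copy()
        X = np.concatenate(seqs)[:, None]
        ref.fit(X, lengths=[len(s) for s in seqs])
        assert np.allclose(res.hmm.T, ref.transmat_, atol=1e-6)
        assert np.allclose(res.hmm.E, ref.emissionprob_, atol=1e-6)


class TestViterbi:
    def test_single_state_all_phase_one(self):
        hmm = PhaseHMM(Q=1, A=3, T=np.array([[1.0]]), pi=np.array([1.0]),
                       E=np.array([[0.2, 0.3, 0.5]]))
        assert viterbi_decode(hmm, [0, 2, 1, 1]).tolist() == [1, 1, 1, 1]

    def test_deterministic_emissions_recover_path(self, rng):
        Q = 4
        E = np.eye(Q)
        T = np.zeros((Q, Q))
        for q in range(Q - 1):
            T[q, q], T[q, q + 1] = 0.5, 0.5
        T[Q - 1, Q - 1] = 1.0
        hmm = PhaseHMM(Q=Q, A=Q, T=T, pi=initial_distribution(Q), E=E)
        syms, labels = sample_sequence(hmm, 30, rng)
        assert np.array_equal(viterbi_decode(hmm, syms), labels)

    def test_matches_exhaustive_enumeration(self, rng):
        """Viterbi equals brute-force argmax over all 3^8 candidate paths
        across 100 random left-to-right models."""
        for _ in range(100):
            hmm = _random_ltr_hmm(rng, Q=3, A=4)
            obs = rng.integers(0, 4, size=8)
            best_lp, best_path = -np.inf, None
            for path in itertools.product(range(3), repeat=8):
                lp = np.log(hmm.pi[path[0]]) if hmm.pi[path[0]] > 0 else -np.inf
                lp += np.log(hmm.E[path[0], obs[0]])
                for t in range(1, 8):
                    p = hmm.T[path[t - 1], path[t]]
                    if p == 0:
                        lp = -np.inf
                        break
                    lp += np.log(p) + np.log(hmm.E[path[t], obs[t]])
                if lp > best_lp:
                    best_lp, best_path = lp, path
            decoded = viterbi_decode(hmm, obs) - 1
            assert np.array_equal(decoded, best_path)

    def test_decoded_labels_monotone_unit_steps(self, rng):
        for _ in range(20):
            hmm = _random_ltr_hmm(rng, Q=5, A=6)
            obs = rng.integers(0, 6, size=40)
            labels = viterbi_decode(hmm, obs)
            steps = np.diff(labels)
            assert ((steps == 0) | (steps == 1)).all()
            assert labels[0] == 1

    def test_forward_argmax_matches_filtering_oracle(self, rng):
        hmm = _random_ltr_hmm(rng, Q=4, A=5)
        obs = rng.integers(0, 5, size=30)
        labels = forward_argmax(hmm, obs)
        # brute-force filtering: renormalized alpha recursion
        alpha = hmm.pi * hmm.E[:, obs[0]]
        expected = [alpha.argmax()]
        for o in obs[1:]:
            alpha = (alpha @ hmm.T) * hmm.E[:, o]
            alpha = alpha / alpha.sum()
            expected.append(alpha.argmax())
        assert np.array_equal(labels - 1, expected)

    def test_agrees_with_hmmlearn_decoder(self, rng):
        from hmmlearn.hmm import CategoricalHMM

        hmm = _random_ltr_hmm(rng, Q=4, A=5)
        obs = rng.integers(0, 5, size=50)
        ref = CategoricalHMM(n_components=4, n_features=5, init_params="")
        ref.startprob_ = hmm.pi
        ref.transmat_ = hmm.T
        ref.emissionprob_ = hmm.E
        _, ref_path = ref.decode(obs[:, None], algorithm="viterbi")
        assert np.array_equal(viterbi_decode(hmm, obs) - 1, ref_path)


class TestModelValidation:
    def test_left_to_right_structure_enforced(self):
        T = np.array([[0.5, 0.3, 0.2], [0, 0.5, 0.5], [0, 0, 1.0]])
        with pytest.raises(ValueError):
            PhaseHMM(Q=3, A=2, T=T, pi=initial_distribution(3),
                     E=np.full((3, 2), 0.5))

    def test_hmm_round_trip(self, tmp_path, rng):
        hmm = _random_ltr_hmm(rng, Q=3, A=4)
        save_hmm(hmm, tmp_path / "hmm.npz")
        loaded = load_hmm(tmp_path / "hmm.npz")
        assert np.array_equal(hmm.T, loaded.T)
        assert np.array_equal(hmm.E, loaded.E)

    def test_sampling_deterministic_given_seed(self):
        hmm = make_left_to_right_hmm(Q=3, A=5, mean_duration=10, seed=0)
        a = sample_sequence(hmm, 50, np.random.default_rng(5))
        b = sample_sequence(hmm, 50, np.random.default_rng(5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
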