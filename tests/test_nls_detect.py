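import numpy as np
import pytest

from nactk.nls_detect import (
    AA20,
    HmmParams,
    ZeroProbabilityError,
    call_nls,
    default_hmm_params,
    forward_backward,
    intervals_from_mask,
    posterior,
    viterbi,
)
from nactk.sequence_io import SequenceRecord

from conftest import enumerate_hmm


def prot(residues, pid="p"):
    return SequenceRecord(id=pid, residues=residues)


def params_no_bg_k():
    """BG cannot emit K; NLS uniform."""
    emission = np.full((2, 20), 0.05)
    k = AA20.index("K")
    emission[0, k] = 0.0
    emission[0] /= emission[0].sum()
    return HmmParams(
        initial=np.array([0.5, 0.5]),
        transition=np.array([[0.9, 0.1], [0.1, 0.9]]),
        emission=emission,
    )


def random_params(rng):
    initial = rng.dirichlet([1, 1])
    transition = np.vstack([rng.dirichlet([1, 1]), rng.dirichlet([1, 1])])
    emission = np.vstack([rng.dirichlet(np.ones(20)), rng.dirichlet(np.ones(20))])
    return HmmParams(initial=initial, transition=transition, emission=emission)


class TestParams:
    def test_row_sums_validated(self):
        with pytest.raises(ValueError, match="sums"):
            HmmParams(
                initial=np.array([0.5, 0.6]),
                transition=np.eye(2),
                emission=np.full((2, 20), 0.05),
            )

    def test_default_params_valid(self):
        p = default_hmm_params()
        assert p.transition[0, 0] == pytest.approx(0.99)
        assert p.emission[1, AA20.index("K")] == pytest.approx(0.30)


class TestViterbi:
    def test_forced_path_when_bg_cannot_emit(self):
        path = viterbi(prot("KKK"), params_no_bg_k())
        assert path == [1, 1, 1]

    def test_uniform_emissions_favor_bg(self):
        params = HmmParams(
            initial=np.array([0.99, 0.01]),
            transition=np.array([[0.99, 0.01], [0.5, 0.5]]),
            emission=np.full((2, 20), 0.05),
        )
        assert viterbi(prot("ACDEFGHIK"), params) == [0] * 9

    def test_ties_break_toward_bg(self):
        params = HmmParams(
            initial=np.array([0.5, 0.5]),
            transition=np.full((2, 2), 0.5),
            emission=np.full((2, 20), 0.05),
        )
        assert viterbi(prot("MKV"), params) == [0, 0, 0]

    def test_path_probability_matches_enumeration(self):
        rng = np.random.default_rng(101)
        for _ in range(150):
            params = random_params(rng)
            length = int(rng.integers(1, 11))
            seq = "".join(rng.choice(list(AA20), length))
            symbols = [AA20.index(c) for c in seq]
            best, _ = enumerate_hmm(symbols, params)
            path = viterbi(prot(seq), params)
            p = params.initial[path[0]] * params.emission[path[0], symbols[0]]
            for t in range(1, length):
                p *= params.transition[path[t - 1], path[t]]
                p *= params.emission[path[t], symbols[t]]
            assert p == pytest.approx(best, rel=1e-9)


class TestPosterior:
    def test_symmetric_single_position(self):
        params = HmmParams(
            initial=np.array([0.5, 0.5]),
            transition=np.full((2, 2), 0.5),
            emission=np.full((2, 20), 0.05),
        )
        assert posterior(prot("M"), params)[0] == pytest.approx(0.5)

    def test_certain_state_when_bg_cannot_emit(self):
        post = posterior(prot("AKA"), params_no_bg_k())
        assert post[1] == pytest.approx(1.0)

    def test_marginals_match_enumeration(self):
        rng = np.random.default_rng(202)
        for _ in range(150):
            params = random_params(rng)
            length = int(rng.integers(1, 11))
            seq = "".join(rng.choice(list(AA20), length))
            symbols = [AA20.index(c) for c in seq]
            _, marg = enumerate_hmm(symbols, params)
            post = posterior(prot(seq), params)
            assert np.allclose(post, marg, atol=1e-9)

    def test_posteriors_sum_to_one(self):
        post, _ = forward_backward(prot("MKVRRKAA"), default_hmm_params())
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_likelihood_matches_enumeration(self):
        rng = np.random.default_rng(303)
        params = random_params(rng)
        seq = "".join(rng.choice(list(AA20), 8))
        symbols = [AA20.index(c) for c in seq]
        total = 0.0
        for code in range(2 ** 8):
            path = [(code >> t) & 1 for t in range(8)]
            p = params.initial[path[0]] * params.emission[path[0], symbols[0]]
            for t in range(1, 8):
                p *= params.transition[path[t - 1], path[t]]
                p *= params.emission[path[t], symbols[t]]
            total += p
        _, loglik = forward_backward(prot(seq), params)
        assert loglik == pytest.approx(np.log(total), abs=1e-9)


class TestCallNls:
    def test_run_rule_with_min_length(self):
        post = np.array([0.1, 0.5, 0.6, 0.5, 0.5, 0.2])
        assert intervals_from_mask(post >= 0.4, min_len=4) == [(2, 5)]

    def test_high_cutoff_on_flat_posteriors_yields_nothing(self):
        calls = call_nls(prot("ACDEFGHIACDEFGHI"), cutoff=0.99)
        assert calls == []

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(31)
        params = default_hmm_params()
        for _ in range(10):
            seq = "".join(rng.choice(list(AA20 + "KKRR"), 80))
            lengths = []
            for cutoff in (0.2, 0.4, 0.6, 0.8):
                calls = call_nls(prot(seq), params, cutoff=cutoff, min_len=1)
                lengths.append(sum(c.end - c.start + 1 for c in calls))
            assert all(a >= b for a, b in zip(lengths, lengths[1:]))

    def test_deterministic(self):
        seq = prot("MKVRRRRKKAAADDDEEKRKRA")
        a = call_nls(seq)
        b = call_nls(seq)
        assert a == b

    def test_planted_high_basic_segments_are_detected(self, small_proteome):
        """Planted NLS containing a basic run >= 4 are overlapped by a call."""
        import re

        records, truth = small_proteome
        rec_by_id = {r.id: r for r in records}
        params = default_hmm_params()
        cache = {}
        total = found = 0
        for row in truth[truth.feature == "nls"].itertuples():
            if max(len(m.group()) for m in re.finditer(r"[KR]+", row.segment)) < 4:
                continue
            if row.protein_id not in cache:
                cache[row.protein_id] = call_nls(rec_by_id[row.protein_id], params)
            total += 1
            found += any(
                c.start <= row.end and c.end >= row.start
                for c in cache[row.protein_id]
            )
        assert total > 0 and found / total >= 0.95

    def test_zero_probability_sequence_reported(self):
        emission = np.zeros((2, 20))
        emission[:, 0] = 1.0  # only 'A' can ever be emitted
        params = HmmParams(
            initial=np.array([0.5, 0.5]),
            transition=np.full((2, 2), 0.5),
            emission=emission,
        )
        with pytest.raises(ZeroProbabilityError):
            posterior(prot("MKV"), params)
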