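import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nactk.nls_classify import (
    NlsCall,
    assign_terminal,
    classify_nls,
    collapse_linkers,
    find_basic_clusters,
    merge_clusters,
    signature_census,
)
from nactk.nls_detect import NlsInterval
from nactk.synthetic_data import NLS_CLASSES, make_nls_segment

BIPARTITE_EXEMPLAR = "KRPAATKKAGQAKKKK"


class TestClusters:
    def test_bipartite_exemplar_maximal_runs(self):
        clusters = find_basic_clusters(BIPARTITE_EXEMPLAR)
        assert [(c.start, c.end) for c in clusters] == [(1, 2), (7, 8), (13, 16)]

    def test_no_basics_no_clusters(self):
        assert find_basic_clusters("AAAA") == []

    def test_single_run(self):
        clusters = find_basic_clusters("KKKK")
        assert [(c.start, c.end) for c in clusters] == [(1, 4)]

    def test_exemplar_merges_to_two_clusters(self):
        clusters = merge_clusters(
            find_basic_clusters(BIPARTITE_EXEMPLAR), BIPARTITE_EXEMPLAR
        )
        assert [(c.start, c.end) for c in clusters] == [(1, 2), (7, 16)]
        # the merged C-proximal cluster keeps KKKK as its core run
        assert (clusters[1].core_start, clusters[1].core_end) == (13, 16)


class TestClassify:
    @pytest.mark.parametrize(
        "segment,expected",
        [
            ("KKKK", "mono_I"),
            ("KKAK", "mono_II"),
            (BIPARTITE_EXEMPLAR, "bipartite"),
            ("KKKAAAAAAKKAAAAAAAKKK", "multipartite"),
            ("KRAWAAAF", "class_III"),
            ("PAAKRK", "class_IV"),
            ("AAAAAA", "unclassified"),
            ("KK", "unclassified"),  # too short
        ],
    )
    def test_taxonomy_rules(self, segment, expected):
        assert classify_nls(segment) == expected

    def test_long_mono_i_runs_stay_mono_i(self):
        assert classify_nls("K" * 15) == "mono_I"

    def test_planted_class_recovery_is_exact(self):
        """Every planted NLS of every class classifies as planted."""
        rng = np.random.default_rng(77)
        for cls in NLS_CLASSES:
            for _ in range(40):
                segment = make_nls_segment(cls, rng)
                assert classify_nls(segment) == cls, (cls, segment)

    def test_linker_substitution_invariance(self):
        """Replacing a linker residue with another non-basic residue never
        changes the class (geometric classes, no K-R adjacency)."""
        rng = np.random.default_rng(88)
        for cls in ("mono_I", "mono_II", "bipartite", "multipartite"):
            for _ in range(20):
                segment = make_nls_segment(cls, rng)
                base = classify_nls(segment)
                linker_positions = [
                    i for i, c in enumerate(segment) if c not in "KR"
                ]
                if not linker_positions:
                    continue
                i = linker_positions[rng.integers(len(linker_positions))]
                for sub in "AGSTQNHMC":
                    mutated = segment[:i] + sub + segment[i + 1 :]
                    assert classify_nls(mutated) == base


class TestCollapse:
    def test_exemplar_signature(self):
        assert collapse_linkers(BIPARTITE_EXEMPLAR) == "KRKKKKKK"

    def test_fixed_point_on_pure_basic(self):
        assert collapse_linkers("RKRRK") == "RKRRK"

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=60))
    def test_idempotence_and_alphabet(self, s):
        collapsed = collapse_linkers(s)
        assert collapse_linkers(collapsed) == collapsed
        assert set(collapsed) <= {"K", "R"}
        assert len(collapsed) == s.count("K") + s.count("R")


class TestTerminal:
    @pytest.mark.parametrize(
        "start,end,length,expected",
        [(5, 15, 100, "N"), (80, 90, 100, "C"), (45, 55, 100, "N")],
    )
    def test_midpoint_rule(self, start, end, length, expected):
        assert assign_terminal(start, end, length) == expected

    def test_interval_outside_protein_rejected(self):
        with pytest.raises(ValueError):
            assign_terminal(5, 200, 100)


def _call(signature, terminal, pid="p"):
    interval = NlsInterval(protein_id=pid, start=1, end=len(signature),
                           decoder="posterior", mean_posterior=0.9)
    return NlsCall(
        protein_id=pid, interval=interval, segment=signature,
        nls_class="mono_I", clusters=[], terminal=terminal,
    )


class TestCensus:
    def test_shared_and_unique_counting(self):
        calls = [_call("KKK", "N"), _call("KRK", "N"), _call("KKK", "C")]
        signatures, summary = signature_census(calls)
        assert summary.n_shared == 1
        assert summary.n_only_n == 1
        assert summary.n_only_c == 0
        by_sig = {s.signature: s for s in signatures}
        assert by_sig["KKK"].count_n_terminal == 1
        assert by_sig["KKK"].count_c_terminal == 1

    def test_empty_input_all_zero(self):
        signatures, summary = signature_census([])
        assert signatures == []
        assert (summary.n_unique_n, summary.n_unique_c, summary.n_shared) == (0, 0, 0)

    def test_total_conservation(self):
        rng = np.random.default_rng(12)
        calls = [
            _call("".join(rng.choice(list("KR"), rng.integers(2, 6))),
                  "N" if rng.random() < 0.5 else "C")
            for _ in range(50)
        ]
        signatures, _ = signature_census(calls)
        assert sum(s.count_n_terminal + s.count_c_terminal for s in signatures) == 50

    def test_planted_signature_multiset_recovered(self, small_proteome):
        """Census equals the truth-table signature multiset exactly."""
        records, truth = small_proteome
        rec_by_id = {r.id: r for r in records}
        calls = []
        expected = {}
        for row in truth[truth.feature == "nls"].itertuples():
            segment = row.segment
            sig = collapse_linkers(segment)
            terminal = assign_terminal(
                row.start, row.end, len(rec_by_id[row.protein_id].residues)
            )
            expected[(sig, terminal)] = expected.get((sig, terminal), 0) + 1
            interval = NlsInterval(
                protein_id=row.protein_id, start=row.start, end=row.end,
                decoder="posterior", mean_posterior=1.0,
            )
            calls.append(
                NlsCall(
                    protein_id=row.protein_id, interval=interval, segment=segment,
                    nls_class=row.nls_class, clusters=[], terminal=terminal,
                )
            )
        signatures, _ = signature_census(calls)
        observed = {}
        for s in signatures:
            if s.count_n_terminal:
                observed[(s.signature, "N")] = s.count_n_terminal
            if s.count_c_terminal:
                observed[(s.signature, "C")] = s.count_c_terminal
        assert observed == expected
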