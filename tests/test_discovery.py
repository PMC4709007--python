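"""Motif discovery: k-mer enumeration, weighted sampling, the three searches."""

import itertools

import numpy as np
import pytest

from probmotif import (
    DiscoveryConfig,
    SequenceRecord,
    build_count_matrix,
    build_profile,
    consensus,
    enumerate_valid_kmers,
    gibbs_search,
    greedy_search,
    likelihood,
    mismatch_score,
    multi_restart,
    randomized_search,
    weighted_kmer_choice,
)
from probmotif.discovery import _SeqWindows

from conftest import PLANTED_CONSENSUS, hamming, make_record


class TestEnumerateValidKmers:
    def test_non_canonical_windows_excluded(self):
        kmers = enumerate_valid_kmers(make_record("ACDX"), 2)
        assert [k.text for k in kmers] == ["AC", "CD"]

    def test_too_short_sequence(self):
        assert enumerate_valid_kmers(make_record("AC"), 3) == []

    def test_sliding_window_order_and_offsets(self):
        kmers = enumerate_valid_kmers(make_record("ACDE"), 2)
        assert [(k.text, k.start) for k in kmers] == [("AC", 0), ("CD", 1), ("DE", 2)]
        for km in kmers:
            assert make_record("ACDE").residues[km.start : km.start + 2] == km.text


class TestWeightedChoice:
    def test_forced_choice_on_exact_length(self, k1_profile, rng):
        P = build_profile(build_count_matrix([], 3), M=20)
        km = weighted_kmer_choice(make_record("WHQ"), P, rng)
        assert km.text == "WHQ" and km.start == 0

    def test_equal_phi_is_a_fair_coin(self, rng):
        # "AA" and "AA": two identical windows of "AAA" -> equal phi
        P = build_profile(build_count_matrix(["AC"], 2), M=1)
        seq = make_record("AAA")
        picks = [weighted_kmer_choice(seq, P, rng).start for _ in range(10_000)]
        freq = np.mean([p == 0 for p in picks])
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_frequencies_match_normalized_phi(self, rng):
        # profile from {"AA"}: phi("AA")=4, phi("AC")=phi("CA")=2, phi("CC")=1
        P = build_profile(build_count_matrix(["AA"], 2), M=1)
        seq = make_record("AAC")  # windows AA (phi 4) and AC (phi 2)
        expect = likelihood(P, "AA") / (likelihood(P, "AA") + likelihood(P, "AC"))
        picks = [weighted_kmer_choice(seq, P, rng).start for _ in range(10_000)]
        freq = np.mean([p == 0 for p in picks])
        assert abs(freq - expect) < 3 * np.sqrt(expect * (1 - expect) / 10_000)

    def test_no_valid_kmer_errors(self, rng):
        P = build_profile(build_count_matrix([], 3), M=20)
        with pytest.raises(ValueError):
            weighted_kmer_choice(make_record("AX"), P, rng)


def _forced_set():
    return [make_record("WHQLK", rid=f"s{i}") for i in range(3)]


@pytest.mark.parametrize("algorithm", ["gibbs", "randomized", "greedy"])
def test_forced_selection_when_sequences_have_length_k(algorithm):
    """With exactly one window per sequence, every search returns it."""
    seqs = [make_record("WHQLK", rid=f"s{i}") for i in range(4)]
    config = DiscoveryConfig(k=5, iterations=50, restarts=1, algorithm=algorithm, seed=9)
    result = multi_restart(seqs, config)
    assert [km.text for km in result.selected] == ["WHQLK"] * 4
    assert result.consensus == "WHQLK"
    assert result.mismatch_score == 0
    np.testing.assert_array_equal(
        result.profile.probs, build_profile(build_count_matrix(["WHQLK"] * 4, 5), 4).probs
    )


@pytest.mark.parametrize("algorithm", ["gibbs", "randomized", "greedy"])
def test_determinism_under_fixed_seed(benchmark, algorithm):
    _, training, _, _ = benchmark
    subset = training[:12]
    config = DiscoveryConfig(
        k=20, iterations=150, restarts=2, algorithm=algorithm, seed=77
    )
    a = multi_restart(subset, config)
    b = multi_restart(subset, config)
    assert [km.text for km in a.selected] == [km.text for km in b.selected]
    assert a.consensus == b.consensus and a.mismatch_score == b.mismatch_score
    np.testing.assert_array_equal(a.profile.probs, b.profile.probs)


def test_selection_validity_postcondition(benchmark):
    _, training, _, _ = benchmark
    result = gibbs_search(training[:20], DiscoveryConfig(k=20, iterations=200, seed=5))
    by_id = {rec.id: rec for rec in training}
    for km in result.selected:
        src = by_id[km.source_id].residues
        assert src[km.start : km.start + 20] == km.text


def test_short_sequences_are_skipped_and_reported():
    seqs = [make_record("WHQLKWHQLK", rid="long1"),
            make_record("WHQLKWHQLK", rid="long2"),
            make_record("AC", rid="short")]
    result = gibbs_search(seqs, DiscoveryConfig(k=5, iterations=20, seed=1))
    assert result.skipped_ids == ["short"]
    assert len(result.selected) == 2


def test_fewer_than_two_eligible_sequences_errors():
    seqs = [make_record("WHQLK", rid="a"), make_record("AC", rid="b")]
    with pytest.raises(ValueError, match=">= 2"):
        gibbs_search(seqs, DiscoveryConfig(k=5, iterations=10, seed=0))


class TestRandomized:
    def test_identical_sequences_reach_zero_mismatch(self):
        seqs = [make_record("MKDEWHQLKGSS", rid=f"s{i}") for i in range(5)]
        result = randomized_search(seqs, DiscoveryConfig(k=6, seed=3))
        assert result.mismatch_score == 0

    def test_planted_motif_recovery(self, benchmark):
        _, training, _, _ = benchmark
        config = DiscoveryConfig(k=20, restarts=20, algorithm="randomized", seed=11)
        result = multi_restart(training, config)
        assert hamming(result.consensus, PLANTED_CONSENSUS) <= 2


class TestGreedy:
    def test_identical_sequences(self):
        seqs = [make_record("MKDEWHQLK", rid=f"s{i}") for i in range(3)]
        result = greedy_search(seqs, DiscoveryConfig(k=4, seed=0))
        assert result.mismatch_score == 0
        starts = {km.start for km in result.selected}
        assert len(starts) == 1  # same window picked in every copy

    def test_matches_brute_force_seed_path_enumeration(self):
        """Independent oracle: enumerate every greedy seed path by hand."""
        s1, s2 = make_record("ACDEAC", rid="a"), make_record("CDEACD", rid="b")
        k = 3
        win1 = [s1.residues[i : i + k] for i in range(len(s1.residues) - k + 1)]
        win2 = [s2.residues[i : i + k] for i in range(len(s2.residues) - k + 1)]

        def phi(profile_kmers, text):
            # paper-mode profile of the partial selection, linear arithmetic
            M = len(profile_kmers)
            p = 1.0
            for i, ch in enumerate(text):
                m = sum(km[i] == ch for km in profile_kmers)
                p *= (m + 1) / M
            return p

        best = None
        for seed_km in win1:
            sel = [seed_km]
            scores = [phi(sel, w) for w in win2]
            sel.append(win2[int(np.argmax(scores))])
            cons = consensus(build_count_matrix(sel, k))
            score = mismatch_score(cons, sel)
            if best is None or score < best[0]:
                best = (score, sel)

        result = greedy_search([s1, s2], DiscoveryConfig(k=3, seed=0))
        assert result.mismatch_score == best[0]
        assert [km.text for km in result.selected] == best[1]

    def test_exact_recovery_on_clean_signal(self):
        from probmotif.synthetic import SyntheticSpec, make_benchmark

        spec = SyntheticSpec(n_planted=20, subs_per_instance=0,
                             n_background=0, n_carriers=0, seed=8)
        training, _, _ = make_benchmark(spec)
        result = greedy_search(training, DiscoveryConfig(k=20, seed=0))
        assert result.consensus == PLANTED_CONSENSUS
        assert result.mismatch_score == 0


class TestMultiRestart:
    def test_single_restart_equals_single_run(self, benchmark):
        _, training, _, _ = benchmark
        subset = training[:10]
        config = DiscoveryConfig(k=20, iterations=100, restarts=1, seed=4)
        a = multi_restart(subset, config)
        b = gibbs_search(subset, DiscoveryConfig(k=20, iterations=100, seed=4))
        assert [km.text for km in a.selected] == [km.text for km in b.selected]

    def test_returns_minimum_mismatch_restart(self, benchmark):
        _, training, _, _ = benchmark
        subset = training[:15]
        config = DiscoveryConfig(k=20, iterations=300, restarts=5, seed=21)
        best = multi_restart(subset, config)
        singles = [
            gibbs_search(subset, DiscoveryConfig(k=20, iterations=300, seed=21 + r))
            for r in range(5)
        ]
        scores = [s.mismatch_score for s in singles]
        assert best.mismatch_score == min(scores)
        assert best.restart_index == int(np.argmin(scores))  # earliest on ties


def test_gibbs_improves_on_initial_selection(benchmark):
    """Returned mismatch <= initial random selection's in >=95% of seeds."""
    _, training, _, _ = benchmark
    subset = training[:30]
    k = 20
    wins = [_SeqWindows(rec, k) for rec in subset]
    improved = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        init = [win.kmer(int(rng.integers(win.n))) for win in wins]
        cons0 = consensus(build_count_matrix(init, k))
        score0 = mismatch_score(cons0, init)
        result = gibbs_search(subset, DiscoveryConfig(k=k, iterations=1000, seed=seed))
        improved += result.mismatch_score <= score0
    assert improved >= 0.95 * n_seeds


def test_algorithm_agreement_on_clean_planted_data():
    from probmotif.synthetic import SyntheticSpec, make_benchmark

    # full training-set size and restart count: fewer sequences/restarts can
    # leave the stochastic searches in a phase-shifted local optimum
    spec = SyntheticSpec(n_planted=100, subs_per_instance=0,
                         n_background=0, n_carriers=0, seed=13)
    training, _, _ = make_benchmark(spec)
    consensi = {
        alg: multi_restart(
            training,
            DiscoveryConfig(k=20, iterations=2000, restarts=20, algorithm=alg, seed=2),
        ).consensus
        for alg in ("gibbs", "randomized", "greedy")
    }
    assert len(set(consensi.values())) == 1
    assert consensi["gibbs"] == PLANTED_CONSENSUS


def test_biased_initial_profile_is_accepted(benchmark):
    """A biased first sampling distribution still yields a valid result."""
    _, training, _, _ = benchmark
    subset = training[:10]
    bias = build_profile(build_count_matrix([], 20), M=len(subset))
    probs = bias.probs.copy()
    probs[:, 9] = 1e-6
    from probmotif.core import AA_INDEX, ProfileMatrix

    probs[AA_INDEX["H"], 9] = 1.0  # absolutely conserved histidine at position 10
    biased = ProfileMatrix(k=20, M=len(subset), probs=probs)
    config = DiscoveryConfig(k=20, iterations=200, seed=6, bias_profile=biased)
    result = gibbs_search(subset, config)
    assert len(result.selected) == len(subset)
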