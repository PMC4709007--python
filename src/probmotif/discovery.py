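"""Motif discovery: Gibbs sampling, randomized and greedy searches.

All three algorithms select one k-mer per training sequence and summarize the
selection as a pseudocount profile matrix. They differ in how the selection is
refined:

* **Gibbs** — per iteration, one sequence is chosen uniformly at random and its
  k-mer re-sampled with probability proportional to phi under the current
  profile; N iterations, no early stopping.
* **Randomized** — from a random start, every sequence's k-mer is replaced by
  its profile-most-probable k-mer and the profile rebuilt, until the selection
  reaches a fixed point (or an iteration cap).
* **Greedy** — deterministic: for each seed k-mer of the first sequence, grow
  the selection sequence-by-sequence, always taking the profile-most-probable
  k-mer under the profile of the selection so far.

Restart selection ranks the candidate results by the total number of
mismatches between each result's consensus and its selected k-mers, and keeps
the minimum (ties break to the earliest restart).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    Kmer,
    ProfileMatrix,
    SequenceRecord,
    build_count_matrix,
    build_profile,
    consensus,
    encode,
    mismatch_score,
    N_AA,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscoveryConfig:
    """Tunable parameters of a motif-discovery run."""

    k: int = 20
    iterations: int = 2000  # Gibbs iteration count N
    restarts: int = 20
    algorithm: str = "gibbs"  # gibbs | randomized | greedy
    seed: int = 0
    gibbs_holdout: bool = False
    bias_profile: ProfileMatrix | None = None
    max_randomized_iters: int = 1000

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.algorithm not in ("gibbs", "randomized", "greedy"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class MotifResult:
    """Outcome of one discovery run (or the best of several restarts)."""

    selected: list[Kmer]
    profile: ProfileMatrix
    consensus: str
    mismatch_score: int
    config: DiscoveryConfig
    restart_index: int = 0
    skipped_ids: list[str] = field(default_factory=list)


class _SeqWindows:
    """Precomputed valid k-mer windows of one sequence.

    ``idx[w, i]`` is the alphabet code of position *i* of valid window *w*;
    window w starts at ``starts[w]`` (0-based). Built once per sequence and
    reused across all Gibbs iterations.
    """

    __slots__ = ("record", "starts", "idx")

    def __init__(self, record: SequenceRecord, k: int):
        self.record = record
        codes = encode(record.residues)
        n_win = len(codes) - k + 1
        if n_win <= 0:
            self.starts = np.empty(0, dtype=np.intp)
            self.idx = np.empty((0, k), dtype=np.intp)
            return
        invalid = (codes < 0).astype(np.int64)
        csum = np.concatenate(([0], np.cumsum(invalid)))
        ok = (csum[k:] - csum[:-k]) == 0  # windows free of non-canonical letters
        self.starts = np.nonzero(ok)[0].astype(np.intp)
        self.idx = codes[self.starts[:, None] + np.arange(k)]

    @property
    def n(self) -> int:
        return len(self.starts)

    def kmer(self, w: int) -> Kmer:
        start = int(self.starts[w])
        k = self.idx.shape[1]
        return Kmer(
            text=self.record.residues[start : start + k],
            source_id=self.record.id,
            start=start,
        )

    def log10_phis(self, log10_probs: np.ndarray) -> np.ndarray:
        """log10 phi of every valid window under the given 20 x k log-profile."""
        return log10_probs[self.idx, np.arange(self.idx.shape[1])].sum(axis=1)


def enumerate_valid_kmers(seq: SequenceRecord, k: int) -> list[Kmer]:
    """All length-k windows containing only canonical residues, left to right."""
    win = _SeqWindows(seq, k)
    return [win.kmer(w) for w in range(win.n)]


def _weighted_choice_index(log10_phis: np.ndarray, rng: np.random.Generator) -> int:
    """Sample a window index with probability phi / sum(phi), one rng variate."""
    w = 10.0 ** (log10_phis - log10_phis.max())
    cdf = np.cumsum(w)
    u = rng.random() * cdf[-1]
    return int(np.searchsorted(cdf, u, side="right").clip(0, len(cdf) - 1))


def weighted_kmer_choice(
    seq: SequenceRecord, P: ProfileMatrix, rng: np.random.Generator
) -> Kmer:
    """Sample one valid k-mer of *seq* with probability proportional to phi."""
    win = _SeqWindows(seq, P.k)
    if win.n == 0:
        raise ValueError(f"sequence {seq.id!r} has no valid k-mer of length {P.k}")
    return win.kmer(_weighted_choice_index(win.log10_phis(P.log10_probs), rng))


def _prepare(seqs: list[SequenceRecord], k: int) -> tuple[list[_SeqWindows], list[str]]:
    eligible, skipped = [], []
    for rec in seqs:
        win = _SeqWindows(rec, k)
        if win.n > 0:
            eligible.append(win)
        else:
            skipped.append(rec.id)
            logger.debug("skipping %s: no valid %d-mer", rec.id, k)
    if skipped:
        logger.info("excluded %d/%d sequences with no valid k-mer", len(skipped), len(seqs))
    if len(eligible) < 2:
        raise ValueError(
            f"need >= 2 training sequences with a valid {k}-mer, got {len(eligible)}"
        )
    return eligible, skipped


def _counts_from_windows(wins: list[_SeqWindows], picks: np.ndarray, k: int) -> np.ndarray:
    counts = np.zeros((N_AA, k), dtype=np.int64)
    cols = np.arange(k)
    for win, w in zip(wins, picks):
        counts[win.idx[w], cols] += 1
    return counts


def _finish(
    wins: list[_SeqWindows],
    picks: np.ndarray,
    config: DiscoveryConfig,
    skipped: list[str],
    restart_index: int = 0,
) -> MotifResult:
    selected = [win.kmer(int(w)) for win, w in zip(wins, picks)]
    cm = build_count_matrix(selected, config.k)
    prof = build_profile(
        cm,
        M=len(selected),
        mode="paper",
        provenance={
            "algorithm": config.algorithm,
            "seed": config.seed,
            "iterations": config.iterations,
            "restart_index": restart_index,
        },
    )
    cons = consensus(cm)
    return MotifResult(
        selected=selected,
        profile=prof,
        consensus=cons,
        mismatch_score=mismatch_score(cons, selected),
        config=config,
        restart_index=restart_index,
        skipped_ids=skipped,
    )


def gibbs_search(seqs: list[SequenceRecord], config: DiscoveryConfig) -> MotifResult:
    """Gibbs sampler: N single-sequence re-samplings weighted by phi."""
    wins, skipped = _prepare(seqs, config.k)
    rng = np.random.default_rng(config.seed)
    M = len(wins)
    cols = np.arange(config.k)

    picks = np.array([rng.integers(w.n) for w in wins], dtype=np.intp)
    counts = _counts_from_windows(wins, picks, config.k)

    bias_log10 = None
    if config.bias_profile is not None:
        if config.bias_profile.k != config.k:
            raise ValueError("bias profile k does not match config.k")
        bias_log10 = config.bias_profile.log10_probs

    for it in range(config.iterations):
        s = int(rng.integers(M))
        win = wins[s]
        if config.gibbs_holdout:
            # leave-one-out variant: drop this sequence's k-mer before scoring
            counts[win.idx[picks[s]], cols] -= 1
        if it == 0 and bias_log10 is not None:
            log10_probs = bias_log10
        else:
            # paper-mode profile of the current selection, in log space
            log10_probs = np.log10((counts + 1.0) / M)
        new_w = _weighted_choice_index(win.log10_phis(log10_probs), rng)
        if not config.gibbs_holdout:
            counts[win.idx[picks[s]], cols] -= 1
        counts[win.idx[new_w], cols] += 1
        picks[s] = new_w

    return _finish(wins, picks, config, skipped)


def randomized_search(seqs: list[SequenceRecord], config: DiscoveryConfig) -> MotifResult:
    """Iterate profile-most-probable replacement to a selection fixed point."""
    wins, skipped = _prepare(seqs, config.k)
    rng = np.random.default_rng(config.seed)
    M = len(wins)

    picks = np.array([rng.integers(w.n) for w in wins], dtype=np.intp)
    for _ in range(config.max_randomized_iters):
        counts = _counts_from_windows(wins, picks, config.k)
        log10_probs = np.log10((counts + 1.0) / M)
        new_picks = np.array(
            [int(np.argmax(w.log10_phis(log10_probs))) for w in wins], dtype=np.intp
        )
        if np.array_equal(new_picks, picks):
            break
        picks = new_picks

    return _finish(wins, picks, config, skipped)


def greedy_search(seqs: list[SequenceRecord], config: DiscoveryConfig) -> MotifResult:
    """Deterministic greedy growth seeded by every k-mer of the first sequence.

    While the selection is growing, the pseudocount denominator is the number
    of sequences selected so far; the returned profile is rebuilt with the full
    training-set size.
    """
    wins, skipped = _prepare(seqs, config.k)
    k = config.k
    cols = np.arange(k)

    best_picks: np.ndarray | None = None
    best_score: int | None = None
    for seed_w in range(wins[0].n):
        counts = np.zeros((N_AA, k), dtype=np.int64)
        counts[wins[0].idx[seed_w], cols] += 1
        picks = [seed_w]
        for win in wins[1:]:
            log10_probs = np.log10((counts + 1.0) / len(picks))
            w = int(np.argmax(win.log10_phis(log10_probs)))
            counts[win.idx[w], cols] += 1
            picks.append(w)
        kmers = [win.kmer(w) for win, w in zip(wins, picks)]
        cons = consensus(build_count_matrix(kmers, k))
        score = mismatch_score(cons, kmers)
        if best_score is None or score < best_score:
            best_score = score
            best_picks = np.array(picks, dtype=np.intp)

    assert best_picks is not None
    return _finish(wins, best_picks, config, skipped)


_ALGORITHMS = {
    "gibbs": gibbs_search,
    "randomized": randomized_search,
    "greedy": greedy_search,
}


def multi_restart(seqs: list[SequenceRecord], config: DiscoveryConfig) -> MotifResult:
    """Run the configured algorithm R times; keep the minimum-mismatch result.

    Restart r runs with sub-seed ``config.seed + r``; ties between equal
    mismatch scores resolve to the lowest restart index.
    """
    best: MotifResult | None = None
    for r in range(config.restarts):
        sub = replace(config, seed=config.seed + r)
        result = _ALGORITHMS[config.algorithm](seqs, sub)
        result.restart_index = r
        result.profile.provenance["restart_index"] = r
        result.profile.provenance["seed"] = config.seed
        if best is None or result.mismatch_score < best.mismatch_score:
            best = result
    assert best is not None
    return best
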