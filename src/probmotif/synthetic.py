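"""Planted-motif synthetic data with known ground truth.

Background proteins are i.i.d. draws from a stated residue-frequency vector
(uniform by default). A *planted* sequence carries one degenerate motif
instance: the consensus with exactly *s* positions substituted, overwriting a
random window. Because every planted window is recorded, recovery and
detection can be scored exactly — no external family or proteome downloads
are needed to exercise discovery and scanning end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .core import ALPHABET, N_AA, SequenceRecord


class PlantedInstance(NamedTuple):
    """Ground truth for one planted motif occurrence (0-based start)."""

    id: str
    start: int
    text: str


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic benchmark.

    Defaults mirror the package's standard study conditions: a 20-residue
    consensus planted with 2 substitutions per instance into 100 training
    sequences, and a decoy proteome of 2000 clean background proteins plus
    5 motif carriers.
    """

    planted_consensus: str = "DFKKVDPHVHQLKGSSSSIG"
    n_planted: int = 100
    subs_per_instance: int = 2
    n_background: int = 2000
    n_carriers: int = 5
    length_range: tuple[int, int] = (80, 160)
    background_freqs: tuple[float, ...] = field(default=tuple([0.05] * N_AA))
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.background_freqs, dtype=np.float64)
        if freqs.shape != (N_AA,) or (freqs < 0).any():
            raise ValueError("background_freqs must be 20 non-negative values")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("background_freqs must sum to 1")
        k = len(self.planted_consensus)
        if any(c not in ALPHABET for c in self.planted_consensus):
            raise ValueError("planted consensus must use canonical residues")
        if not 0 <= self.subs_per_instance <= k:
            raise ValueError("subs_per_instance must be in [0, k]")
        if self.length_range[0] < k or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must satisfy k <= min <= max")

    @property
    def k(self) -> int:
        return len(self.planted_consensus)


def generate_background(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    n: int | None = None,
    prefix: str = "bg",
) -> list[SequenceRecord]:
    """*n* i.i.d. background proteins, lengths uniform in ``length_range``."""
    n = spec.n_background if n is None else n
    freqs = np.asarray(spec.background_freqs)
    lo, hi = spec.length_range
    alphabet = np.array(list(ALPHABET))
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(alphabet[rng.choice(N_AA, size=length, p=freqs)])
        records.append(
            SequenceRecord(id=f"{prefix}_{i + 1:04d}", residues=residues)
        )
    return records


def plant_motif(
    seqs: list[SequenceRecord],
    consensus: str,
    s: int,
    rng: np.random.Generator,
) -> tuple[list[SequenceRecord], list[PlantedInstance]]:
    """Overwrite a random window of every sequence with a degenerate instance.

    Each instance is the consensus with exactly *s* distinct positions
    replaced by a uniformly chosen *different* residue, so every instance sits
    at Hamming distance exactly *s* from the consensus.
    """
    k = len(consensus)
    if s > k:
        raise ValueError(f"s={s} exceeds motif length k={k}")
    planted_seqs: list[SequenceRecord] = []
    truth: list[PlantedInstance] = []
    for rec in seqs:
        if len(rec.residues) < k:
            raise ValueError(f"sequence {rec.id!r} shorter than motif length {k}")
        instance = list(consensus)
        for pos in rng.choice(k, size=s, replace=False):
            alternatives = [c for c in ALPHABET if c != consensus[pos]]
            instance[pos] = alternatives[int(rng.integers(len(alternatives)))]
        text = "".join(instance)
        start = int(rng.integers(len(rec.residues) - k + 1))
        residues = rec.residues[:start] + text + rec.residues[start + k :]
        planted_seqs.append(
            SequenceRecord(
                id=rec.id, residues=residues, description=rec.description
            )
        )
        truth.append(PlantedInstance(id=rec.id, start=start, text=text))
    return planted_seqs, truth


def make_benchmark(
    spec: SyntheticSpec,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[PlantedInstance]]:
    """Bundle a planted training set with a decoy proteome.

    Returns ``(training_set, decoy_proteome, ground_truth)``: ``n_planted``
    training sequences each carrying one instance; a proteome of
    ``n_background`` clean decoys plus ``n_carriers`` carriers; and the full
    list of planted windows (training and carriers).
    """
    rng = np.random.default_rng(spec.seed)
    train_bg = generate_background(spec, rng, n=spec.n_planted, prefix="train")
    training, truth = plant_motif(
        train_bg, spec.planted_consensus, spec.subs_per_instance, rng
    )
    decoys = generate_background(spec, rng, n=spec.n_background, prefix="bg")
    carrier_bg = generate_background(spec, rng, n=spec.n_carriers, prefix="carrier")
    carriers, carrier_truth = plant_motif(
        carrier_bg, spec.planted_consensus, spec.subs_per_instance, rng
    )
    return training, decoys + carriers, truth + carrier_truth
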