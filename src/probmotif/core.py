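"""Profile matrices and k-mer likelihood scoring.

The motif model is an indel-free position-specific probability matrix over the
20 canonical amino acids. Given a training set of M sequences, one selected
k-mer per sequence gives occurrence counts ``m[j, i]`` (residue *j* at motif
position *i*); the profile entry is ``P[j][i] = (m[j][i] + 1) / M`` — a +1
pseudocount keeps every entry positive, so no k-mer has zero likelihood. The
likelihood of a k-mer ``X = (x_1, ..., x_k)`` is

    phi(X) = prod_i P[x_i][i]

All internal arithmetic is carried out on log10 entries: proteome-scale phi
values routinely fall below 1e-50, where linear-space products underflow.

Note the paper-faithful profile columns sum to (M + 20) / M, slightly above 1;
``mode="normalized"`` divides by (M + 20) instead, giving true per-column
probability distributions. The two modes give identical rankings — phi values
differ by the constant factor ((M + 20) / M) ** k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Canonical amino acids, fixed row order for every matrix in the package.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue letter -> matrix row index.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

N_AA: int = 20

# Fast letter->row lookup table over the byte range; -1 marks non-canonical.
_CODE_TABLE = np.full(128, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _CODE_TABLE[ord(_aa)] = _i

GAP_CHARS = "-.*"


class NonCanonicalResidueError(ValueError):
    """A k-mer contains a letter outside the 20-residue alphabet."""


def sanitize_residues(raw: str) -> str:
    """Uppercase *raw* and strip gaps ('-', '.'), stops ('*') and whitespace.

    Non-canonical letters (X, B, Z, U, ...) are *kept*; they are excluded
    later at the k-mer level, where a matrix row is actually required.
    """
    out = []
    for ch in raw.upper():
        if ch in GAP_CHARS or ch.isspace():
            continue
        out.append(ch)
    return "".join(out)


def encode(text: str) -> np.ndarray:
    """Encode residues as row indices; non-canonical letters map to -1."""
    b = np.frombuffer(text.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODE_TABLE[np.minimum(b, 127)]
    return codes.astype(np.intp)


def encode_strict(text: str) -> np.ndarray:
    codes = encode(text)
    if (codes < 0).any():
        bad = sorted({ch for ch in text if ch not in AA_INDEX})
        raise NonCanonicalResidueError(
            f"non-canonical residue(s) {bad} in {text!r}"
        )
    return codes


@dataclass(frozen=True)
class SequenceRecord:
    """One protein (or reference-domain) sequence, post-sanitization."""

    id: str
    residues: str
    description: str = ""
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if any(c in GAP_CHARS or c.isspace() for c in self.residues):
            raise ValueError(f"unsanitized residues in record {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Kmer:
    """A length-k window of a source sequence."""

    text: str
    source_id: str
    start: int  # 0-based offset in the source sequence

    def __len__(self) -> int:
        return len(self.text)


@dataclass(frozen=True)
class CountMatrix:
    """20 x k occurrence counts of selected k-mers."""

    k: int
    counts: np.ndarray  # (20, k) non-negative ints
    n_kmers: int

    def __post_init__(self) -> None:
        if self.counts.shape != (N_AA, self.k):
            raise ValueError(f"counts must be (20, {self.k})")


def build_count_matrix(kmers: Sequence[Kmer | str], k: int) -> CountMatrix:
    """Tally residue occurrences per position over *kmers*.

    Every k-mer must have length k and contain only canonical letters;
    callers are expected to pre-filter (see discovery.enumerate_valid_kmers).
    """
    counts = np.zeros((N_AA, k), dtype=np.int64)
    n = 0
    cols = np.arange(k)
    for km in kmers:
        text = km.text if isinstance(km, Kmer) else km
        if len(text) != k:
            raise ValueError(f"k-mer {text!r} has length {len(text)}, expected {k}")
        codes = encode_strict(text)
        counts[codes, cols] += 1
        n += 1
    return CountMatrix(k=k, counts=counts, n_kmers=n)


@dataclass
class ProfileMatrix:
    """Pseudocount probability matrix P with its scoring machinery.

    mode="paper":       P = (m + 1) / M        (columns sum to (M+20)/M)
    mode="normalized":  P = (m + 1) / (M + 20) (columns sum to 1)
    """

    k: int
    M: int
    probs: np.ndarray  # (20, k) positive floats
    mode: str = "paper"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (N_AA, self.k):
            raise ValueError(f"probs must be (20, {self.k})")
        if self.mode not in ("paper", "normalized"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if (self.probs <= 0).any():
            raise ValueError("profile entries must be positive")
        self._log10 = np.log10(self.probs)

    @property
    def log10_probs(self) -> np.ndarray:
        return self._log10

    def log10_phi_codes(self, codes: np.ndarray) -> float:
        """log10 phi for an already-encoded k-mer (no validation)."""
        return float(self._log10[codes, np.arange(self.k)].sum())


def build_profile(
    counts: CountMatrix, M: int, mode: str = "paper", provenance: dict | None = None
) -> ProfileMatrix:
    """Turn occurrence counts into the pseudocount profile matrix."""
    if M < 1:
        raise ValueError("empty training set (M must be >= 1)")
    denom = M if mode == "paper" else M + N_AA
    probs = (counts.counts + 1.0) / denom
    return ProfileMatrix(
        k=counts.k, M=M, probs=probs, mode=mode, provenance=provenance or {}
    )


def log10_likelihood(P: ProfileMatrix, kmer_text: str) -> float:
    """log10 phi(X) = sum_i log10 P[x_i][i]."""
    if len(kmer_text) != P.k:
        raise ValueError(
            f"k-mer length {len(kmer_text)} does not match profile k={P.k}"
        )
    codes = encode_strict(kmer_text)
    return P.log10_phi_codes(codes)


def likelihood(P: ProfileMatrix, kmer_text: str) -> float:
    """phi(X), the product of per-position profile entries."""
    return 10.0 ** log10_likelihood(P, kmer_text)


def consensus(matrix: CountMatrix | ProfileMatrix) -> str:
    """Per-column most likely residue; ties break to the earliest alphabet letter."""
    values = matrix.counts if isinstance(matrix, CountMatrix) else matrix.probs
    rows = np.argmax(values, axis=0)  # argmax takes the first maximal row
    return "".join(ALPHABET[r] for r in rows)


def mismatch_score(cons: str, kmers: Iterable[Kmer | str]) -> int:
    """Total Hamming distance between the consensus and every selected k-mer."""
    total = 0
    for km in kmers:
        text = km.text if isinstance(km, Kmer) else km
        if len(text) != len(cons):
            raise ValueError(
                f"k-mer {text!r} length {len(text)} != consensus length {len(cons)}"
            )
        total += sum(a != b for a, b in zip(cons, text))
    return total


def column_information(counts: CountMatrix, M: int) -> np.ndarray:
    """Per-column information content in bits: log2(20) - H(column).

    Frequencies are the *normalized* pseudocount frequencies
    f = (m + 1) / (M + 20) regardless of profile mode — entropy of an
    unnormalized column is undefined. Values lie in [0, log2 20].
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    f = (counts.counts + 1.0) / (M + N_AA)
    return np.log2(N_AA) + (f * np.log2(f)).sum(axis=0)
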