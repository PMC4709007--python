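"""Proteome scanning, ranking, outlier calling and negative controls.

Every protein in a proteome is represented by its *profile-most-probable
k-mer* — the window maximizing phi under a trained profile matrix. The ranked
log10 phi distribution is then screened for high-likelihood outliers by two
criteria:

* **iqr3** — log10 phi strictly above Q3 + 3·IQR of the proteome's own
  distribution (a per-proteome, relative threshold);
* **ref5** — phi strictly above the 5th percentile of the phi values the
  matrix assigns to its *own* training family (an absolute threshold,
  independent of the proteome scanned).

The column-scrambling control permutes profile columns (preserving each
column's residue composition) and measures how often a motif-free matrix
still produces outliers — an empirical false-positive rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ProfileMatrix, SequenceRecord
from .discovery import _SeqWindows

logger = logging.getLogger(__name__)


@dataclass
class ScanHit:
    """Best-scoring k-mer of one protein. ``start`` is 0-based internally."""

    protein_id: str
    description: str
    kmer_text: str
    start: int
    phi: float
    log10_phi: float
    rank: int | None = None
    outlier: dict[str, bool] = field(default_factory=dict)
    duplicate_of: str | None = None

    @property
    def start_1based(self) -> int:
        return self.start + 1


@dataclass(frozen=True)
class ThresholdResult:
    """An outlier cutoff on the log10 phi scale, with its derivation."""

    method: str  # "iqr3" | "ref5"
    cutoff_log10: float
    q1: float | None = None
    q2: float | None = None
    q3: float | None = None
    iqr: float | None = None
    reference_size: int | None = None


@dataclass
class OutlierReport:
    thresholds: dict[str, ThresholdResult]
    hits: list[ScanHit]
    dedup_applied: bool = False
    control_fpr: float | None = None

    def flagged(self, method: str) -> list[ScanHit]:
        return [h for h in self.hits if h.outlier.get(method, False)]


def best_kmer(P: ProfileMatrix, seq: SequenceRecord) -> ScanHit | None:
    """The phi-maximal valid k-mer of *seq* (leftmost on ties), or None."""
    win = _SeqWindows(seq, P.k)
    return _best_from_windows(P, win)


def _best_from_windows(P: ProfileMatrix, win: _SeqWindows) -> ScanHit | None:
    if win.n == 0:
        return None
    lp = win.log10_phis(P.log10_probs)
    w = int(np.argmax(lp))  # first maximum = leftmost tie
    km = win.kmer(w)
    return ScanHit(
        protein_id=win.record.id,
        description=win.record.description,
        kmer_text=km.text,
        start=km.start,
        phi=10.0 ** float(lp[w]),
        log10_phi=float(lp[w]),
    )


def _scan_windows(P: ProfileMatrix, wins: list[_SeqWindows]) -> list[ScanHit]:
    hits = [h for h in (_best_from_windows(P, w) for w in wins) if h is not None]
    if not hits:
        raise ValueError("no scannable protein in proteome")
    hits.sort(key=lambda h: (-h.log10_phi, h.protein_id))
    for i, h in enumerate(hits, start=1):
        h.rank = i
    return hits


def scan_proteome(P: ProfileMatrix, proteome: list[SequenceRecord]) -> list[ScanHit]:
    """One ranked hit per scannable protein, descending phi (ties by id)."""
    if not proteome:
        raise ValueError("empty proteome")
    wins = [_SeqWindows(rec, P.k) for rec in proteome]
    skipped = [w.record.id for w in wins if w.n == 0]
    if skipped:
        logger.info("skipped %d/%d proteins with no valid k-mer", len(skipped), len(proteome))
        for sid in skipped:
            logger.debug("skipped protein %s", sid)
    return _scan_windows(P, [w for w in wins if w.n > 0])


def threshold_3iqr(log10_phis: np.ndarray | list[float]) -> ThresholdResult:
    """Tukey-style upper fence Q3 + 3·IQR on the log10 phi distribution.

    Quartiles use linear interpolation between order statistics.
    """
    vals = np.asarray(log10_phis, dtype=np.float64)
    if vals.size < 4:
        raise ValueError("distribution too small (need >= 4 values)")
    q1, q2, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    return ThresholdResult(
        method="iqr3",
        cutoff_log10=float(q3 + 3.0 * iqr),
        q1=float(q1),
        q2=float(q2),
        q3=float(q3),
        iqr=float(iqr),
    )


def threshold_ref5(P: ProfileMatrix, reference: list[SequenceRecord]) -> ThresholdResult:
    """5th percentile of log10 phi of the matrix applied back to its reference set."""
    if not reference:
        raise ValueError("empty reference set")
    if len(reference) < 20:
        logger.warning(
            "reference set has only %d sequences; the 5th percentile is unstable",
            len(reference),
        )
    vals = []
    for rec in reference:
        hit = best_kmer(P, rec)
        if hit is not None:
            vals.append(hit.log10_phi)
    if not vals:
        raise ValueError("no reference sequence has a valid k-mer")
    cutoff = float(np.percentile(np.asarray(vals), 5))
    return ThresholdResult(method="ref5", cutoff_log10=cutoff, reference_size=len(vals))


def call_outliers(
    hits: list[ScanHit],
    thresholds: dict[str, ThresholdResult] | list[ThresholdResult],
    dedup: bool = False,
) -> OutlierReport:
    """Flag hits strictly exceeding each threshold; optionally mark duplicates.

    Duplicates are hits with an identical k-mer and phi equal to within 1e-12
    relative; only the first by protein id keeps its flags, the rest carry
    ``duplicate_of``. (UniProt splice variants typically surface this way.)
    """
    if isinstance(thresholds, list):
        thresholds = {t.method: t for t in thresholds}

    for h in hits:
        h.duplicate_of = None
        h.outlier = {
            m: h.log10_phi > t.cutoff_log10 for m, t in thresholds.items()
        }

    if dedup:
        by_kmer: dict[str, list[ScanHit]] = {}
        for h in hits:
            by_kmer.setdefault(h.kmer_text, []).append(h)
        for group in by_kmer.values():
            group.sort(key=lambda h: h.protein_id)
            keeper = group[0]
            for other in group[1:]:
                denom = max(abs(keeper.phi), abs(other.phi))
                if denom == 0 or abs(keeper.phi - other.phi) <= 1e-12 * denom:
                    other.duplicate_of = keeper.protein_id
                    other.outlier = {m: False for m in other.outlier}

    return OutlierReport(thresholds=dict(thresholds), hits=hits, dedup_applied=dedup)


def scramble_columns(P: ProfileMatrix, rng: np.random.Generator) -> ProfileMatrix:
    """Permute profile columns uniformly at random.

    Each column's 20 values travel together, so per-position residue
    composition is preserved while positional order — the motif itself — is
    destroyed.
    """
    perm = rng.permutation(P.k)
    return ProfileMatrix(
        k=P.k,
        M=P.M,
        probs=P.probs[:, perm],
        mode=P.mode,
        provenance={**P.provenance, "scrambled": True},
    )


def scrambled_control(
    P: ProfileMatrix,
    proteome: list[SequenceRecord],
    n_scrambles: int = 100,
    threshold_method: str = "iqr3",
    rng: np.random.Generator | None = None,
    reference: list[SequenceRecord] | None = None,
) -> tuple[float, list[int]]:
    """False-positive rate (percent) of column-scrambled matrices.

    Each scramble re-scans the proteome and recomputes the outlier threshold;
    the rate is total outlier calls / (n_scrambles x scanned proteins) x 100.
    Returns (rate_percent, per-scramble outlier counts).
    """
    if n_scrambles < 1:
        raise ValueError("n_scrambles must be >= 1")
    if threshold_method not in ("iqr3", "ref5"):
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    if threshold_method == "ref5" and reference is None:
        raise ValueError("ref5 control needs the reference sequence set")
    rng = np.random.default_rng() if rng is None else rng

    wins = [w for w in (_SeqWindows(rec, P.k) for rec in proteome) if w.n > 0]
    if not wins:
        raise ValueError("no scannable protein in proteome")

    counts = []
    for _ in range(n_scrambles):
        Ps = scramble_columns(P, rng)
        hits = _scan_windows(Ps, wins)
        if threshold_method == "iqr3":
            thr = threshold_3iqr([h.log10_phi for h in hits])
        else:
            thr = threshold_ref5(Ps, reference)  # type: ignore[arg-type]
        counts.append(sum(h.log10_phi > thr.cutoff_log10 for h in hits))

    rate = 100.0 * sum(counts) / (n_scrambles * len(wins))
    return rate, counts


def restrict_n_terminal(
    proteome: list[SequenceRecord], k: int
) -> list[SequenceRecord]:
    """Restrict each protein to residues 2..k+1 (1-based), after the initiator.

    Proteins too short to supply k residues past position 1 are dropped.
    Used as a negative control: a domain not anchored at the N terminus
    should vanish from this artificially truncated proteome.
    """
    out = []
    dropped = 0
    for rec in proteome:
        if len(rec.residues) >= k + 1:
            out.append(
                SequenceRecord(
                    id=rec.id,
                    residues=rec.residues[1 : 1 + k],
                    description=rec.description,
                    source=rec.source,
                )
            )
        else:
            dropped += 1
            logger.debug("dropped %s: too short for 2..%d restriction", rec.id, k + 1)
    if dropped:
        logger.info("dropped %d proteins shorter than %d residues", dropped, k + 1)
    return out
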