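# Methods

## Model and assumptions

The motif model is a 20 × k position-specific probability matrix over the
canonical amino acids, with a linear topology: no insertion or deletion
states, no transition probabilities. A motif occurrence is always exactly k
contiguous residues. This is a strong assumption — it trades the generality
of a profile HMM for a model with a single free structural parameter (k) that
can be trained on ~10² sequences in seconds. It is appropriate for compact,
helix-borne motifs such as the HPt relay-histidine segment, and inappropriate
for domains whose family alignment requires indels inside the conserved core.

Training selects one k-mer per reference sequence; the profile entry is
`P[j][i] = (m_ji + 1) / M` where `m_ji` counts selected k-mers with residue
*j* at position *i*, M is the training-set size, and +1 is a pseudocount. In
this (default, `mode="paper"`) parameterization columns sum to (M + 20) / M,
slightly above one, so φ is a likelihood score rather than a normalized
probability over k-mers. `mode="normalized"` (`(m + 1) / (M + 20)`) gives
true per-column distributions; the two differ by the constant factor
((M + 20) / M)^k per k-mer and produce identical rankings. The default is
kept unnormalized so φ values are directly comparable with prior work using
this convention.

All likelihood arithmetic is in log10 space. Proteome scans produce φ values
below 1e-50, where linear-space products underflow; sums of log10 entries
keep every score finite, and φ is exponentiated only for reporting.

## Discovery algorithms

**Gibbs** (default): after a uniform-random initial k-mer per sequence, each
of N iterations picks one sequence uniformly at random and re-samples its
k-mer with probability φ(k-mer)/Σφ over all its valid windows, under the
profile of the current selection. N is fixed (default 2000, adequate for
k = 20 and ~100–300 training sequences; larger sets need larger N);
convergence is observed, not enforced. The sampling profile includes the
chosen sequence's own current k-mer by default; `gibbs_holdout=True` removes
its counts first (the statistically standard leave-one-out form) while
keeping the denominator at M, preserving the pseudocount scale. A
`bias_profile` may replace the profile used for the first draw — e.g. a
matrix with an absolutely conserved histidine at a chosen position — to steer
the sampler toward a phase of interest.

**Randomized**: replace every sequence's k-mer with its profile-most-probable
k-mer and rebuild the profile, iterating to a selection fixed point (capped
at `max_randomized_iters`, default 1000).

**Greedy**: fully deterministic; for each seed k-mer of the first sequence,
grow the selection sequence-by-sequence, always taking the
profile-most-probable k-mer under the profile of the selection so far. While
growing, the pseudocount denominator is the current selection size r (the
fixed-M formula would overweight pseudocounts early); the returned profile is
rebuilt with the full M.

**Restarts**: the configured algorithm runs R times (default 20) with
sub-seed `seed + r`; the result minimizing the total Hamming distance between
its consensus and its selected k-mers wins, ties to the earliest restart.
Restart r re-randomizes both the initial selection and the iteration order.

All stochastic searches are bit-reproducible given the seed. Sequences with
no valid window (shorter than k, or every window containing a non-canonical
letter) are excluded up front and listed in `skipped_ids`.

## Scanning and outlier criteria

Each protein's representative is its φ-maximal valid window (leftmost on
ties); proteins are ranked by descending φ, ties broken by protein id so the
ranking is independent of input order. Windows containing non-canonical
letters (X, B, Z, J, U, O) are excluded — no matrix row exists for them.

* **iqr3**: cutoff Q3 + 3·IQR of the scanned proteome's log10 φ values.
  Quartiles use linear interpolation between order statistics (the common
  statistical-software default; recorded in `ThresholdResult` for
  transparency). Being relative, this criterion adapts to each proteome but
  can flag borderline proteins in proteomes with no true motif.
* **ref5**: the 5th percentile of log10 φ of the matrix applied back to its
  own reference family. The percentile is interpolated on the log scale,
  where the distribution is examined and filtered. This absolute cutoff is
  usually stricter and is meaningful for single sequences, not just whole
  proteomes. With fewer than 20 reference sequences the percentile is
  unstable and a warning is emitted.

Both criteria use strict inequality: a hit exactly at the cutoff is not an
outlier. Optional deduplication collapses hits with identical k-mer text and
φ equal to within 1e-12 relative (splice variants and redundant database
entries); gene-level annotation is not available in plain FASTA, so
identity of mapped genes is not part of the duplicate key — duplicates are
annotated (`duplicate_of`), never silently dropped.

Coordinates are 0-based half-open internally and 1-based inclusive in all
reports, following UniProt convention.

## Negative controls

`scramble_columns` permutes profile columns uniformly at random (identity
included; at k = 20 its probability, 1/20!, is negligible), preserving each
column's composition while destroying positional structure.
`scrambled_control` repeats scramble → scan → threshold → count
(default 100 scrambles) and reports total calls / (scrambles × proteins) as a
percentage. `restrict_n_terminal` is the complementary control: scanning only
residues 2..k+1 of every protein should lose any motif not anchored at the N
terminus.

## Synthetic benchmark

The generator emulates the two inputs the pipeline needs: a reference family
(background sequences each carrying one planted instance — the consensus with
exactly s positions substituted, substitutes drawn uniformly from the 19
alternatives) and a decoy proteome (clean background plus a few carriers).
Defaults are the package's standard study conditions: a 20-residue consensus,
100 training sequences with s = 2, and 2000 decoys of length 80–160 plus 5
carriers, background residues i.i.d. uniform (0.05 each).

What this does *not* emulate: real amino-acid composition bias,
low-complexity runs, paralog families, or correlated columns. Passing the
synthetic benchmark shows the algorithms recover and detect a planted signal
under the model's own null; it does not bound false-positive rates on real
proteomes, whose composition deviates from i.i.d. A frequency vector
estimated from any FASTA can be supplied for a more realistic null.

The i.i.d. uniform background is deliberately the hardest case for the
scrambling control (every column of a trained profile has similar
composition), so the measured synthetic false-positive rate is conservative
in that one respect.

## Numerical choices and tie-breaks

* Alphabet row order fixed at ACDEFGHIKLMNPQRSTVWY; consensus argmax ties
  break to the earliest letter in that order.
* Weighted sampling consumes one uniform variate per draw (inverse-CDF on the
  normalized φ vector, computed from log10 values shifted by their maximum).
* Matrix TSV serialization writes `repr(float)`, so write → read round trips
  are bit-exact.
* Information content per column is log2(20) + Σ f·log2 f with normalized
  frequencies f = (m + 1) / (M + 20) in either profile mode; the entropy of
  an unnormalized column is undefined.

## Known limitations

* Phase shifts: with few training sequences or few restarts, the stochastic
  searches can converge to a consensus offset by one or two positions
  (mismatch-score ranking strongly penalizes this, and 20 restarts on ≥100
  sequences recover the planted phase in ≥95% of runs, but the failure mode
  exists). No column-shift move is implemented.
* k is fixed by the user; there is no motif-width optimization.
* The iqr3 criterion is distribution-relative and will flag the extreme tail
  of any proteome, motif or not; pair it with the ref5 cutoff and the
  scrambling control before interpreting candidates.
* Problem sizes in the test suite and acceptance script (100 training
  sequences, 2000-protein decoy proteomes, 20 master seeds, 100 scrambles)
  are the package's chosen standard benchmark conditions; real proteome scans
  (~3 × 10⁴ proteins) run in seconds per proteome with the same code paths.
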