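# Methods

## The detection grammar

EF-hand identification is often done with profile/database searches
(InterProScan, PSI-BLAST, profile HMMs). `efscan` instead encodes the
canonical EF-hand's structural description directly as a sequence
grammar, which makes every call explainable and every threshold
user-visible. The motif is taken as 29 residues — entering helix
(residues 1–9), coordination loop (10–21), exiting helix — and a
candidate loop is any 12-residue window around which a full 29-residue
motif fits (`require_full_motif_window`, on by default; helix content is
*not* evaluated, the window requirement is purely positional).

Checks on the loop, all configurable (`PatternConfig`):

- hard: position 1 ∈ {D,E,N,S}; position 12 ∈ {D,E}. These supply the
  first and last coordinating oxygens; a window failing either is never
  reported.
- scored (default `min_scored_matches = 3` of 4): position 3 ∈ oxygen
  donors {D,E,N,Q,S,T}; position 5 ∈ donors ∪ {G}; position 6 = G (the
  conserved turn glycine); position 9 ∈ donors ∪ {G}.
- position 7 coordinates through its backbone carbonyl, so no residue
  constraint is imposed there.
- `X` (unknown residue) fails any check it sits in: unknown chemistry is
  never credited.

Overlapping passing windows are resolved greedily left-to-right: a
candidate is dropped if its 12-mer overlaps an already-accepted loop.
This prevents double-counting a single physical loop; `all_candidates`
exposes the raw window set for benchmarking. Coordinates are 0-based
half-open in the API and 1-based inclusive in all written reports.

This grammar is a reconstruction from the motif's structural
description, not a community-standard pattern; users wanting different
specificity should tighten or loosen the residue sets and
`min_scored_matches`.

### Specificity of the defaults

The default grammar is deliberately permissive (sensitivity-leaning).
On uniform random background the per-window acceptance probability is
P(pos1)·P(pos12)·P(≥3 of 4 scored) = 0.2 · 0.1 · 0.0478 ≈ 9.6×10⁻⁴, i.e.
roughly 9 accepted windows per 10,000 residues after overlap resolution
— and the measured false-positive rate on synthetic background matches
this calculation (≈8.5–10 per 10k across seeds). Real proteomes are not
uniform-random, but the order of magnitude carries over. Surveys that
need high specificity should require all four scored checks and/or
restrict position 1 to {D}; the histogram and tier outputs recompute
unchanged.

## IQ motifs

The scanner matches the 11-position consensus (I/L/V)QxxxRxxxx(R/K)
exhaustively at every offset, overlaps included. Full IQ repeats span
~25 residues of amphipathic helix; that context is intentionally not
modelled — the consensus match is the deliverable, as in the worked
IQ1 example (yeast myosin V peptide `AILLQTNIRALWKREYYRAA`, exactly one
match, `LQTNIRALWKR` at 1-based position 4).

## Consensus profile and affinity tiers

Reference CaM coordination loops are aligned column-wise without gaps
(canonical loops are fixed at 12 residues, which keeps the procedure
deterministic and alignment-free). Each column stores relative residue
frequencies; the consensus residue is the column majority with ties
broken by the fixed ordering `DENQSTGAVLIMFWYHKRCP` (oxygen donors
first, so sparse-column ties prefer coordination-competent residues).

The packaged default reference set is a **constructed stand-in**
(`data/cam_reference_loops.synthetic.tsv`): the four canonical animal
CaM loops replicated over ten pseudo-organism labels with sparse
non-critical variation, 40 loops total, mimicking how strongly real CaM
loops are conserved. It yields the consensus `DKDGDGTIDTEE`. It is
user-replaceable (FASTA or two-column TSV) and clearly labelled
synthetic; any serious survey should swap in curated loops.

Classification compares a loop to the consensus **string** at the five
critical positions {1,3,5,7,9} (the positions tied to variation in
measured binding constants; position 12 is excluded by default but the
set is configurable). Column frequencies are retained for users who
want frequency-weighted scoring, but the tier call itself uses plain
identity, the simpler and more reproducible reading.

Tier partition: the three printed anchor statements (strong at 100%
identity, medium below 70%, low below 50%) leave 80% unassigned, and
five positions only produce multiples of 20%. The classifier uses the
unique total partition consistent with all three anchors — **strong =
100% exactly; low < 50%; medium = [50%, 100%)** — so 0.8 and 0.6 are
medium, 0.4 and below are low. Binding-constant ranges are attached as
qualitative strings (`1e4-1e7`, `<1e4`, `<1e2`), never point estimates:
the underlying calibration against measured CaM constants is
approximate by nature.

## Survey summaries

`run_survey` composes read → optional length filter → scan → classify
and emits a per-hit table, the EF-hands-per-protein histogram
(zero-hit proteins count only toward the total) and a pairing
annotation: EF-hands function as paired units, so even counts ≥2 are
"paired within protein", odd counts ≥3 are flagged as putative homo-/
heterodimer pairing (the calpain/S100 pattern), and single hands are
noted as such. The length filter retains 100–2200 aa inclusive — very
short fragments and very long multidomain giants otherwise distort
downstream alignment-based analyses. Run metadata isolates the
timestamp (the only non-deterministic field) and records a SHA-256
digest of the scan configuration.

`pairwise_identity` performs a global Needleman–Wunsch alignment with
affine gaps via Biopython's `PairwiseAligner` (match 1, mismatch 0, gap
open −10, gap extend −0.5 — configurable) and reports
100 × identical pairs / alignment length, **gap columns included in the
denominator**; of co-optimal alignments the aligner's first is used,
which is deterministic for fixed inputs. The identity formula is stated
here precisely because percent-identity values are not comparable
across tools that choose different denominators.

## Synthetic proteomes and what they do (not) show

`generate_proteome` draws background residues i.i.d. from a uniform
distribution over the 20 standard residues (a proteome-frequency table
can be supplied instead), then embeds, per protein, a requested number
of 29-residue EF-hand motifs and optional IQ 11-mers at uniformly
sampled non-overlapping offsets (≥12-residue spacing, so no scan window
spans two placements). Each embedded loop is the reference consensus
mutated at exactly *k* sampled critical positions:

- *affinity mutations* (positions 3/5/7/9) replace the consensus
  residue with a different residue that still satisfies the scanner's
  scored set — the motif stays detectable, only its identity fraction
  (hence tier, via (5−k)/5) changes;
- *detectability mutations* (position 1, drawn at
  `detectability_mutation_rate`, or forced when k = 5) use a residue
  outside the required set; such motifs are marked scanner-invisible in
  the truth table and excluded from recovery scoring.

Because random flanks can by chance form an earlier-starting passing
window overlapping an embedded loop (which greedy resolution would then
shadow), the generator redraws the ≤11 flank residues immediately
upstream of each visible loop until no competing window exists. This
makes the ground-truth promise "visible ⇒ recovered at the recorded
position" true by construction; motif-free sequence is never touched,
so false-positive measurements are unaffected.

Benchmark conditions used by tests and `scripts/acceptance.py`: 500
proteins of 100–800 aa (typical proteome-scale protein lengths), 300
embedded motifs (250 proteins with one, 15 with two, 5 with four, 230
without), mutation load uniform over k ∈ {0..4}, IQ rate 0.1 —
small enough to run in seconds, large enough that every tier and count
class is exercised. Expected outcomes: 100% sensitivity on visible
motifs, 100% tier recovery, background FPR ≈ 9/10k (see above).

What passing these benchmarks does **not** show: performance on real
proteomes. Real sequences have biased composition, repeats, and
divergent non-canonical EF-hands (S100-type N-terminal hands,
pseudo-hands) that the generator does not emulate; tier calls on real
loops inherit whatever reference set the user supplies.

## Numerical and degenerate-input choices

- Ties in consensus columns: fixed residue ordering, first wins (exact,
  no floating-point comparison involved; column frequencies sum to 1
  within 1e-9 by construction).
- `classify_affinity` validates its domain [0,1]; boundary 0.5 is
  medium, exactly 1.0 is strong.
- Empty FASTA, all-invalid records, duplicate ids, wrong-length loops,
  infeasible placement requests all raise typed errors early.
- All randomness flows through one `numpy.random.default_rng(seed)`;
  identical configs and seeds reproduce identical FASTA bytes and truth
  tables across runs and platforms.

## Known limitations

- The grammar detects canonical EF-hands only; non-canonical hands,
  zinc fingers and other metal motifs are out of scope.
- The worked target/template identity example (a CaM-like protein
  versus a CaM template, ≈65% identity) requires fetching the two
  sequences from NCBI/RCSB at run time (`efscan.remote`); the package
  deliberately does not bundle third-party database sequences.
- Affinity tiers are qualitative; no quantitative Kd/Ka regression,
  no structure-based prediction, no cooperativity between paired hands.
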