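# efscan

Proteome-wide survey of **EF-hand** Ca²⁺-binding motifs and **IQ**
(calmodulin-binding) motifs in protein sequences, with a
calmodulin-loop consensus profile and qualitative Ca²⁺-binding-affinity
tiers for every detected loop.

## Who it is for

Researchers cataloguing calcium-signalling proteins in a proteome: which
proteins carry EF-hands, how many per protein (EF-hands function as
pairs, so odd counts hint at dimerization), which loops are likely
strong, medium or weak Ca²⁺ binders, and which proteins carry IQ motifs
that recruit calmodulin.

## The model

The canonical EF-hand is a ~29-residue helix–loop–helix unit whose
12-residue coordination loop chelates Ca²⁺ through oxygen ligands at
loop positions 1, 3, 5, 7, 9 and 12 (backbone carbonyl at 7, so no
residue preference there; a conserved Gly at loop position 6 forms the
turn). The scanner evaluates every admissible 12-residue window with an
explicit grammar:

- **hard constraints** — position 1 ∈ {D,E,N,S}, position 12 ∈ {D,E};
- **scored checks** — position 3 ∈ {D,E,N,Q,S,T}, 5 ∈ {D,E,N,Q,S,T,G},
  6 = G, 9 ∈ {D,E,N,Q,S,T,G}; a hit needs ≥ 3 of 4 (configurable);
- greedy left-to-right resolution of overlapping loops.

Affinity tiers come from a consensus over reference calmodulin loops
(all four CaM loops bind Ca²⁺ strongly). For a detected loop with
identity fraction *f* at the five critical positions {1,3,5,7,9} against
the consensus:

| identity *f* | tier | binding constant |
|---|---|---|
| *f* = 1.0 | strong | 1e4–1e7 |
| 0.5 ≤ *f* < 1.0 | medium | <1e4 |
| *f* < 0.5 | low | <1e2 |

IQ motifs are matched exhaustively against (I/L/V)QxxxRxxxx(R/K).

A seeded synthetic-proteome generator embeds consensus-derived loops
with a known number of critical-position mutations (hence a known tier)
into random background, recording every placement, so scanner
sensitivity, tier recovery and the false-positive rate are measurable
against ground truth.

## Worked example

```python
from efscan import ProteinRecord, scan_ef_hands, affinity_of_loop, \
    build_consensus, default_reference_loops

profile = build_consensus(default_reference_loops())
print(profile.consensus)            # DKDGDGTIDTEE

protein = ProteinRecord(id="demo1",
    sequence="AAELAAAFKEA" + "DKDGDGTITTKE" + "FAAELRHAM")
(hit,) = scan_ef_hands(protein)
print(hit.loop_seq, hit.score)      # DKDGDGTITTKE 4
call = affinity_of_loop(hit.loop_seq, profile)
print(call.tier, call.ka_range)     # strong 1e4-1e7
```

The embedded loop passes both hard constraints and all four scored
checks (score 4/4); it matches the consensus at all five critical
positions, so it is called a strong Ca²⁺ binder with a binding constant
in the calmodulin range. The `examples/` directory holds one short
script per capability (scanning, IQ matching, tier classification, full
survey, benchmarking, pairwise identity); each prints its results with a
line of interpretation.

A thin CLI wraps the same functions:

```bash
efscan scan --fasta proteome.fa --out hits.tsv
efscan affinity --hits hits.tsv --fasta proteome.fa --out affinity.tsv
efscan survey --fasta proteome.fa --out-dir report/
efscan simulate --config sim.yaml --out-fasta sim.fa --out-truth truth.tsv
efscan identity --a target.fa --b template.fa --range-a 28-171 --range-b 4-147
```

Note: the packaged reference loop set is a constructed stand-in built
from the canonical animal CaM loop repertoire (see
`efscan/data/cam_reference_loops.synthetic.tsv`); supply your own
curated loops via `--ref-loops` / `load_reference_loops` for production
use.

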