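"""Calmodulin-loop consensus profiling and Ca2+-affinity tier classification.

Calmodulin (CaM) is the benchmark high-affinity EF-hand protein: all four
of its coordination loops bind Ca2+ strongly, and the loops are nearly
invariant across eukaryotes.  Aligning a reference set of CaM coordination
loops column-wise (they are all exactly 12 residues, so the alignment is
gap-free) yields a consensus string and per-column residue frequencies.

The affinity call for an arbitrary EF-hand loop is then purely positional:
of the five critical loop positions (1, 3, 5, 7, 9 — the positions whose
residues track variation in measured Ca2+-binding constants), how many are
identical to the consensus?  Identity at all five marks a strong binder
with a binding constant in the CaM range (~1e4-1e7 M^-1); partial identity
marks medium (<1e4) and poor identity low (<1e2).  The numeric ranges are
qualitative bounds taken from measured CaM binding constants, never point
estimates.

Tier partition.  The three printed thresholds (strong at 100%, medium
below 70%, low below 50%) do not by themselves cover 80% identity, and
five positions only ever yield multiples of 20%.  The classifier therefore
uses the unique total partition consistent with all three statements:
strong = exactly 100%, low = below 50%, medium = everything in [50%, 100%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .motif_scan import ALPHABET, LOOP_LENGTH, EFHandHit

#: Fixed residue ordering used to break per-column frequency ties
#: (earlier residue wins).  Oxygen donors first, then by rough chemical
#: grouping, so that ties in sparse columns prefer coordination-competent
#: residues.
TIE_ORDER = "DENQSTGAVLIMFWYHKRCP"

#: The five loop positions linked to Ca2+-binding-constant variation.
CRITICAL_POSITIONS = frozenset({1, 3, 5, 7, 9})

KA_RANGES = {"strong": "1e4-1e7", "medium": "<1e4", "low": "<1e2"}

#: Packaged default reference loops (a constructed stand-in; see
#: :func:`default_reference_loops`).
DEFAULT_REFERENCE_PATH = Path(__file__).parent / "data" / "cam_reference_loops.synthetic.tsv"


@dataclass(frozen=True)
class ReferenceLoopSet:
    """A set of 12-residue CaM coordination loops with provenance labels."""

    loops: tuple[str, ...]
    source_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.loops) != len(self.source_labels):
            raise ValueError("loops and source_labels must have equal length")
        if len(self.loops) < 2:
            raise ValueError("at least 2 reference loops are required")
        for label, loop in zip(self.source_labels, self.loops):
            _validate_loop(loop, what=f"reference loop {label!r}")


def _validate_loop(loop: str, what: str = "loop") -> None:
    if len(loop) != LOOP_LENGTH:
        raise ValueError(f"{what} {loop!r} has length {len(loop)}, expected {LOOP_LENGTH}")
    bad = set(loop) - ALPHABET
    if bad:
        raise ValueError(f"{what} {loop!r} contains invalid residues {sorted(bad)!r}")


@dataclass(frozen=True)
class ConsensusProfile:
    """Column-wise residue frequencies and majority consensus over loops.

    ``frequencies`` is a tuple of 12 mappings residue -> relative
    frequency (each column sums to 1); ``consensus[k]`` is the most
    frequent residue in column k, ties broken by :data:`TIE_ORDER`.
    """

    frequencies: tuple[Mapping[str, float], ...]
    consensus: str
    critical_positions: frozenset[int] = CRITICAL_POSITIONS
    n_loops: int = 0


@dataclass(frozen=True)
class AffinityCall:
    """Tier assignment for one EF-hand loop."""

    tier: str
    identity_fraction: float
    ka_range: str
    matched_positions: frozenset[int]


def build_consensus(
    refs: ReferenceLoopSet,
    critical_positions: Iterable[int] = CRITICAL_POSITIONS,
) -> ConsensusProfile:
    """Build the gap-free columnar consensus profile over reference loops.

    Each of the 12 columns gets the relative frequency of every residue
    observed there; the consensus residue is the per-column majority, with
    ties resolved by the fixed ordering :data:`TIE_ORDER` (first wins).
    """
    critical = frozenset(int(p) for p in critical_positions)
    if not critical <= set(range(1, LOOP_LENGTH + 1)):
        raise ValueError(f"critical positions {sorted(critical)} outside 1..{LOOP_LENGTH}")
    n = len(refs.loops)
    freqs: list[dict[str, float]] = []
    consensus_chars: list[str] = []
    for col in range(LOOP_LENGTH):
        counts: dict[str, int] = {}
        for loop in refs.loops:
            counts[loop[col]] = counts.get(loop[col], 0) + 1
        colfreq = {res: c / n for res, c in counts.items()}
        best = max(counts, key=lambda r: (counts[r], -_tie_rank(r)))
        freqs.append(colfreq)
        consensus_chars.append(best)
    return ConsensusProfile(
        frequencies=tuple(freqs),
        consensus="".join(consensus_chars),
        critical_positions=critical,
        n_loops=n,
    )


def _tie_rank(residue: str) -> int:
    try:
        return TIE_ORDER.index(residue)
    except ValueError:  # X or other non-standard: always loses ties
        return len(TIE_ORDER)


def critical_identity(
    loop: str, profile: ConsensusProfile
) -> tuple[float, frozenset[int]]:
    """Fraction of critical positions where ``loop`` matches the consensus.

    Positions are 1-based loop positions.  Returns
    ``(identity_fraction, matched_positions)``.
    """
    _validate_loop(loop)
    matched = frozenset(
        p for p in profile.critical_positions if loop[p - 1] == profile.consensus[p - 1]
    )
    return len(matched) / len(profile.critical_positions), matched


def classify_affinity(
    identity_fraction: float,
    matched_positions: Iterable[int] = (),
) -> AffinityCall:
    """Map a critical-position identity fraction to an affinity tier.

    strong  iff identity_fraction == 1.0   (Ka ~ 1e4-1e7, the CaM range)
    low     iff identity_fraction <  0.5   (Ka < 1e2)
    medium  otherwise, i.e. [0.5, 1.0)     (Ka < 1e4)
    """
    if not 0.0 <= identity_fraction <= 1.0:
        raise ValueError(f"identity fraction {identity_fraction} outside [0, 1]")
    if identity_fraction == 1.0:
        tier = "strong"
    elif identity_fraction < 0.5:
        tier = "low"
    else:
        tier = "medium"
    return AffinityCall(
        tier=tier,
        identity_fraction=identity_fraction,
        ka_range=KA_RANGES[tier],
        matched_positions=frozenset(int(p) for p in matched_positions),
    )


def affinity_of_loop(loop: str, profile: ConsensusProfile) -> AffinityCall:
    """Classify one 12-residue loop against the consensus profile."""
    fraction, matched = critical_identity(loop, profile)
    return classify_affinity(fraction, matched)


def affinity_of_protein(
    hits: Sequence[EFHandHit], profile: ConsensusProfile
) -> list[AffinityCall]:
    """Classify each hit's loop independently, preserving hit order."""
    return [affinity_of_loop(h.loop_seq, profile) for h in hits]


def tier_rank(tier: str) -> int:
    """Ordinal rank of a tier: low < medium < strong."""
    return ("low", "medium", "strong").index(tier)


def load_reference_loops(path: str | Path) -> ReferenceLoopSet:
    """Load reference loops from FASTA or two-column TSV (label, loop).

    Format is decided by content: lines starting with ``>`` mean FASTA;
    otherwise tab-separated ``label<TAB>loop`` with optional ``#`` comments
    and an optional header line whose second column is not a valid loop.
    """
    path = Path(path)
    text = path.read_text()
    labels: list[str] = []
    loops: list[str] = []
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            loops.append(str(rec.seq).upper())
    else:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed reference-loop line: {line!r}")
            label, loop = parts[0], parts[1].upper()
            if label.lower() in ("label", "source") and len(loop) != LOOP_LENGTH:
                continue  # header row
            labels.append(label)
            loops.append(loop)
    return ReferenceLoopSet(loops=tuple(loops), source_labels=tuple(labels))


def default_reference_loops() -> ReferenceLoopSet:
    """The packaged default CaM reference loop set.

    This is a constructed (synthetic) stand-in emulating the canonical
    animal calmodulin loop repertoire — the four coordination loops
    (DKDGDGTITTKE, DADGNGTIDFPE, DKDGNGYISAAE, DIDGDGQVNYEE) replicated
    across ten pseudo-organism labels with sparse variation at
    non-critical positions, mirroring how strongly real CaM loops are
    conserved.  It is not a curated database extract; replace it with your
    own loop set (FASTA or TSV) for production use.
    """
    return load_reference_loops(DEFAULT_REFERENCE_PATH)


def write_affinity_tsv(
    hits: Sequence[EFHandHit], calls: Sequence[AffinityCall], path: str | Path
) -> None:
    """Write per-hit affinity calls as TSV (1-based loop coordinates)."""
    if len(hits) != len(calls):
        raise ValueError("hits and calls must align one-to-one")
    lines = [
        "protein_id\tloop_start_1based\tloop_seq\tidentity_fraction\t"
        "matched_positions\ttier\tka_range"
    ]
    for h, c in zip(hits, calls):
        matched = ",".join(str(p) for p in sorted(c.matched_positions))
        lines.append(
            f"{h.protein_id}\t{h.loop_start + 1}\t{h.loop_seq}\t"
            f"{c.identity_fraction:.1f}\t{matched}\t{c.tier}\t{c.ka_range}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
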