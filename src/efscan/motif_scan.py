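"""Detection of canonical EF-hand and IQ motifs in protein sequences.

The canonical EF-hand is a ~29-residue helix-loop-helix unit: an entering
helix (motif residues 1-9), a 12-residue Ca2+ coordination loop (motif
residues 10-21) and an exiting helix.  Within the loop, positions 1, 3, 5,
7, 9 and 12 supply the oxygen ligands that chelate the Ca2+ ion: side-chain
oxygens at 1, 3, 5 and 12, a backbone carbonyl at 7 (hence no residue
preference there) and a water-bridged side chain at 9; a glycine at loop
position 6 (motif residue 15) provides the sharp turn.

The scanner implements that structural description as an explicit,
configurable sequence grammar evaluated on every admissible 12-residue
window: hard constraints at loop positions 1 and 12 plus a minimum number
of satisfied "scored" checks at positions 3, 5, 6 and 9.  It is a
self-contained alternative to profile/database searches (InterProScan,
PSI-BLAST) and is deliberately transparent: every residue set and the score
threshold are user-configurable.

IQ motifs - the calmodulin-binding consensus (I/L/V)QxxxRxxxx(R/K) found in
myosins and many signalling proteins - are matched exhaustively at every
offset; the ~25-residue helical context of a full IQ repeat is not
modelled.

Coordinates are 0-based half-open internally; written reports use 1-based
inclusive coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes plus X (unknown).
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Standard residues only (no X); used by the synthetic generator.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Side chains able to donate a coordinating oxygen.
OXYGEN_DONORS = frozenset("DENQST")

#: EF-hand motif span in residues (helix E + loop + helix F).
MOTIF_LENGTH = 29

#: Coordination loop length and its offset within the motif (residues 10-21).
LOOP_LENGTH = 12
LOOP_OFFSET = 9

IQ_LENGTH = 11


class InputError(ValueError):
    """Raised for missing or empty sequence input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with its FASTA identity.

    ``id`` is the first whitespace-delimited token of the header;
    ``description`` the remainder.  ``sequence`` is uppercase over the 20
    standard codes plus X.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _residue_set(residues: Iterable[str]) -> frozenset[str]:
    s = frozenset("".join(residues).upper())
    bad = s - ALPHABET
    if bad:
        raise ValueError(f"invalid residues in pattern set: {sorted(bad)!r}")
    return s


@dataclass(frozen=True)
class PatternConfig:
    """Residue grammar for the EF-hand coordination loop.

    ``required_positions`` are hard constraints (1-based loop position ->
    allowed residues); a window failing any of them is never a hit.
    ``scored_checks`` are soft constraints counted into ``score``; a hit
    needs ``score >= min_scored_matches``.  With
    ``require_full_motif_window`` on, a loop is only considered when a full
    29-residue motif fits around it (loop = motif residues 10-21).

    An X at any checked position fails that check: an unknown residue
    cannot be asserted to satisfy the coordination chemistry.
    """

    oxygen_donor_set: frozenset[str] = OXYGEN_DONORS
    required_positions: Mapping[int, frozenset[str]] = field(
        default_factory=lambda: {1: frozenset("DENS"), 12: frozenset("DE")}
    )
    scored_checks: tuple[tuple[int, frozenset[str]], ...] = field(
        default_factory=lambda: (
            (3, OXYGEN_DONORS),
            (5, OXYGEN_DONORS | {"G"}),
            (6, frozenset("G")),
            (9, OXYGEN_DONORS | {"G"}),
        )
    )
    min_scored_matches: int = 3
    require_full_motif_window: bool = True

    def __post_init__(self) -> None:
        for pos in list(self.required_positions) + [p for p, _ in self.scored_checks]:
            if not 1 <= pos <= LOOP_LENGTH:
                raise ValueError(f"loop position {pos} outside 1..{LOOP_LENGTH}")
        if not 0 <= self.min_scored_matches <= len(self.scored_checks):
            raise ValueError(
                "min_scored_matches must lie in 0..len(scored_checks), got "
                f"{self.min_scored_matches}"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "PatternConfig":
        """Build from a plain mapping (e.g. parsed YAML) mirroring the fields."""
        kwargs = {}
        if "oxygen_donor_set" in d:
            kwargs["oxygen_donor_set"] = _residue_set(d["oxygen_donor_set"])
        if "required_positions" in d:
            kwargs["required_positions"] = {
                int(k): _residue_set(v) for k, v in d["required_positions"].items()
            }
        if "scored_checks" in d:
            kwargs["scored_checks"] = tuple(
                (int(p), _residue_set(s)) for p, s in d["scored_checks"]
            )
        if "min_scored_matches" in d:
            kwargs["min_scored_matches"] = int(d["min_scored_matches"])
        if "require_full_motif_window" in d:
            kwargs["require_full_motif_window"] = bool(d["require_full_motif_window"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        """Plain-data form (YAML/JSON friendly), canonically ordered."""
        return {
            "oxygen_donor_set": "".join(sorted(self.oxygen_donor_set)),
            "required_positions": {
                p: "".join(sorted(s)) for p, s in sorted(self.required_positions.items())
            },
            "scored_checks": [
                [p, "".join(sorted(s))] for p, s in self.scored_checks
            ],
            "min_scored_matches": self.min_scored_matches,
            "require_full_motif_window": self.require_full_motif_window,
        }


@dataclass(frozen=True)
class EFHandHit:
    """A detected EF-hand candidate.

    ``motif_start`` is the 0-based index of motif residue 1 and
    ``loop_start`` that of loop position 1 (``motif_start + 9``).
    ``constraint_flags`` holds one boolean per check, keyed
    ``req<pos>``/``scored<pos>``; ``score`` counts satisfied scored checks.
    """

    protein_id: str
    motif_start: int
    loop_start: int
    loop_seq: str
    constraint_flags: Mapping[str, bool]
    score: int


@dataclass(frozen=True)
class IQMotifHit:
    """An 11-residue window matching (I/L/V)QxxxRxxxx(R/K)."""

    protein_id: str
    start: int
    matched_seq: str


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are uppercased.  A record containing characters outside the
    20 standard codes + X is rejected with a logged warning rather than
    silently altered.  Raises :class:`InputError` if the file is missing or
    yields no valid record.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - ALPHABET
        if not seq or bad:
            logger.warning(
                "rejecting record %r: %s", rec.id,
                "empty sequence" if not seq else f"invalid residues {sorted(bad)}",
            )
            continue
        if rec.id in seen:
            raise InputError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise InputError(f"no valid FASTA records in {path}")
    return records


def evaluate_loop_window(
    sequence: str, loop_start: int, config: PatternConfig
) -> tuple[dict[str, bool], int, bool]:
    """Evaluate one candidate loop window against the grammar.

    Returns ``(flags, score, passes)`` where ``flags`` maps check name to
    outcome, ``score`` counts satisfied scored checks, and ``passes`` is
    True iff all required checks hold and ``score >= min_scored_matches``.
    The caller guarantees ``sequence[loop_start:loop_start+12]`` is in range.
    """
    window = sequence[loop_start : loop_start + LOOP_LENGTH]
    flags: dict[str, bool] = {}
    required_ok = True
    for pos, allowed in sorted(config.required_positions.items()):
        ok = window[pos - 1] in allowed
        flags[f"req{pos}"] = ok
        required_ok &= ok
    score = 0
    for pos, allowed in config.scored_checks:
        ok = window[pos - 1] in allowed
        flags[f"scored{pos}"] = ok
        score += ok
    return flags, score, required_ok and score >= config.min_scored_matches


def _candidate_loop_starts(length: int, config: PatternConfig) -> range:
    if config.require_full_motif_window:
        # motif_start >= 0 and motif_start + 29 <= length
        return range(LOOP_OFFSET, length - (MOTIF_LENGTH - LOOP_OFFSET) + 1)
    return range(0, length - LOOP_LENGTH + 1)


def scan_ef_hands(
    protein: ProteinRecord,
    config: PatternConfig | None = None,
    *,
    all_candidates: bool = False,
) -> list[EFHandHit]:
    """Scan one protein for canonical EF-hand coordination loops.

    Every admissible 12-residue window is evaluated against ``config``.
    Passing windows become hits; overlapping candidate loops are resolved
    greedily left-to-right (a candidate is dropped when its 12-mer overlaps
    an already-accepted loop) so that one physical loop is never counted
    twice.  Set ``all_candidates=True`` to keep every raw passing window.
    Hits are sorted by ``loop_start``.
    """
    config = config or PatternConfig()
    seq = protein.sequence
    hits: list[EFHandHit] = []
    last_end = -1  # exclusive end of last accepted loop
    for loop_start in _candidate_loop_starts(len(seq), config):
        flags, score, passes = evaluate_loop_window(seq, loop_start, config)
        if not passes:
            continue
        if not all_candidates and loop_start < last_end:
            continue  # overlaps an accepted loop
        hits.append(
            EFHandHit(
                protein_id=protein.id,
                motif_start=loop_start - LOOP_OFFSET,
                loop_start=loop_start,
                loop_seq=seq[loop_start : loop_start + LOOP_LENGTH],
                constraint_flags=flags,
                score=score,
            )
        )
        if not all_candidates:
            last_end = loop_start + LOOP_LENGTH
    return hits


def _iq_window_matches(window: str) -> bool:
    return (
        window[0] in "ILV"
        and window[1] == "Q"
        and window[5] == "R"
        and window[10] in "RK"
    )


def scan_iq_motifs(protein: ProteinRecord) -> list[IQMotifHit]:
    """Report every 11-residue window matching the IQ consensus.

    Overlapping matches are all reported; the scan is an exhaustive
    per-offset check of (I/L/V)QxxxRxxxx(R/K).
    """
    seq = protein.sequence
    return [
        IQMotifHit(protein_id=protein.id, start=i, matched_seq=seq[i : i + IQ_LENGTH])
        for i in range(len(seq) - IQ_LENGTH + 1)
        if _iq_window_matches(seq[i : i + IQ_LENGTH])
    ]


def filter_by_length(
    records: Sequence[ProteinRecord], min_len: int = 100, max_len: int = 2200
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Split records into (retained, excluded) by sequence length.

    Records shorter than ``min_len`` or longer than ``max_len`` are
    excluded; the boundaries themselves are retained ("less than 100" /
    "more than 2200" read literally).  Input order is preserved in both
    outputs.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    retained, excluded = [], []
    for rec in records:
        (retained if min_len <= len(rec) <= max_len else excluded).append(rec)
    return retained, excluded


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    lines: list[str] = []
    for rec in records:
        header = f">{rec.id} {rec.description}".rstrip()
        lines.append(header)
        lines.extend(rec.sequence[i : i + width] for i in range(0, len(rec), width))
    Path(path).write_text("\n".join(lines) + "\n")


def format_flags(flags: Mapping[str, bool]) -> str:
    """Render constraint flags as semicolon-joined ``key=0/1`` pairs."""
    return ";".join(f"{k}={int(v)}" for k, v in flags.items())


def write_hits_tsv(hits: Iterable[EFHandHit], path: str | Path) -> None:
    """Write EF-hand hits as TSV with 1-based coordinates."""
    lines = [
        "protein_id\tmotif_start_1based\tloop_start_1based\tloop_seq\tscore\tconstraint_flags"
    ]
    for h in hits:
        lines.append(
            f"{h.protein_id}\t{h.motif_start + 1}\t{h.loop_start + 1}\t"
            f"{h.loop_seq}\t{h.score}\t{format_flags(h.constraint_flags)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
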