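"""Proteome-wide EF-hand survey: scan, classify, summarise.

Composes the motif scanner and the affinity classifier over a whole FASTA
proteome and produces the survey-level summaries:

* per-hit table (scan columns joined with affinity columns),
* the EF-hands-per-protein histogram,
* pairing annotation — EF-hands work as paired units, so a protein with an
  even count >= 2 can pair its hands internally, while an odd count >= 3
  suggests the unpaired hand completes its pair across a homo- or
  heterodimer interface (as in calpain or S100 proteins),
* a global pairwise-identity utility for target/template comparisons.

All outputs are deterministic for fixed inputs; the run metadata isolates
the only non-deterministic field (the timestamp) and records a digest of
the scan configuration so runs are auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align

from . import affinity as aff
from .motif_scan import (
    EFHandHit,
    InputError,
    PatternConfig,
    ProteinRecord,
    filter_by_length,
    format_flags,
    read_fasta,
    scan_ef_hands,
)

HIT_COLUMNS = [
    "protein_id",
    "motif_start_1based",
    "loop_start_1based",
    "loop_seq",
    "score",
    "constraint_flags",
    "identity_fraction",
    "matched_positions",
    "tier",
    "ka_range",
]


@dataclass(frozen=True)
class EFHandCountHistogram:
    """Distribution of EF-hand counts per protein (zero-hit proteins excluded)."""

    counts: Mapping[int, int]
    n_proteins_with_hits: int
    n_proteins_total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_proteins_with_hits:
            raise ValueError("histogram counts inconsistent with n_proteins_with_hits")
        if self.n_proteins_with_hits > self.n_proteins_total:
            raise ValueError("more proteins with hits than proteins total")


@dataclass(frozen=True)
class PairingAnnotation:
    protein_id: str
    n_ef_hands: int
    parity: str
    note: str


@dataclass(frozen=True)
class SurveyReport:
    """Full survey output: per-hit rows, histogram, pairing, metadata."""

    hits: pd.DataFrame  # HIT_COLUMNS
    histogram: EFHandCountHistogram
    pairing: tuple[PairingAnnotation, ...]
    metadata: dict = field(default_factory=dict)


def count_histogram(
    hits_by_protein: Mapping[str, int], n_proteins_total: int | None = None
) -> EFHandCountHistogram:
    """Tally proteins by their EF-hand count.

    ``hits_by_protein`` maps protein id -> number of EF-hands (zero
    allowed; zero-count proteins contribute only to the total).
    """
    counts: dict[int, int] = {}
    with_hits = 0
    for n in hits_by_protein.values():
        if n > 0:
            counts[n] = counts.get(n, 0) + 1
            with_hits += 1
    total = len(hits_by_protein) if n_proteins_total is None else n_proteins_total
    return EFHandCountHistogram(
        counts=dict(sorted(counts.items())),
        n_proteins_with_hits=with_hits,
        n_proteins_total=total,
    )


def pairing_annotation(protein_id: str, n_ef_hands: int) -> PairingAnnotation:
    """Annotate a protein's EF-hand count with the pairing interpretation."""
    if n_ef_hands < 1:
        raise ValueError(f"n_ef_hands must be >= 1, got {n_ef_hands}")
    parity = "even" if n_ef_hands % 2 == 0 else "odd"
    if n_ef_hands == 1:
        note = "single EF-hand"
    elif parity == "even":
        note = "paired within protein"
    else:
        note = "putative homo-/heterodimer pairing"
    return PairingAnnotation(
        protein_id=protein_id, n_ef_hands=n_ef_hands, parity=parity, note=note
    )


def survey_records(
    records: Sequence[ProteinRecord],
    config: PatternConfig | None = None,
    refs: aff.ReferenceLoopSet | None = None,
    critical_positions=aff.CRITICAL_POSITIONS,
) -> SurveyReport:
    """Run scan + affinity over in-memory records and summarise."""
    config = config or PatternConfig()
    refs = refs or aff.default_reference_loops()
    profile = aff.build_consensus(refs, critical_positions)

    rows = []
    n_hits_by_protein: dict[str, int] = {}
    for rec in records:
        hits = scan_ef_hands(rec, config)
        calls = aff.affinity_of_protein(hits, profile)
        n_hits_by_protein[rec.id] = len(hits)
        for h, c in zip(hits, calls):
            rows.append(
                {
                    "protein_id": h.protein_id,
                    "motif_start_1based": h.motif_start + 1,
                    "loop_start_1based": h.loop_start + 1,
                    "loop_seq": h.loop_seq,
                    "score": h.score,
                    "constraint_flags": format_flags(h.constraint_flags),
                    "identity_fraction": c.identity_fraction,
                    "matched_positions": ",".join(
                        str(p) for p in sorted(c.matched_positions)
                    ),
                    "tier": c.tier,
                    "ka_range": c.ka_range,
                }
            )
    hits_df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    histogram = count_histogram(n_hits_by_protein)
    pairing = tuple(
        pairing_annotation(pid, n)
        for pid, n in n_hits_by_protein.items()
        if n > 0
    )
    metadata = {
        "config_digest": config_digest(config),
        "n_reference_loops": profile.n_loops,
        "consensus": profile.consensus,
        "critical_positions": sorted(profile.critical_positions),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return SurveyReport(hits=hits_df, histogram=histogram, pairing=pairing, metadata=metadata)


def run_survey(
    fasta: str | Path,
    config: PatternConfig | None = None,
    refs: aff.ReferenceLoopSet | None = None,
    length_filter: bool = True,
    min_len: int = 100,
    max_len: int = 2200,
) -> SurveyReport:
    """End-to-end survey of a FASTA proteome.

    Pipeline: read FASTA -> optional length filter (keep 100..2200 aa,
    boundaries inclusive) -> EF-hand scan per record -> affinity call per
    hit -> histogram + pairing annotation.  Proteins with zero hits appear
    only in the totals.
    """
    records = read_fasta(fasta)
    n_excluded = 0
    if length_filter:
        records, excluded = filter_by_length(records, min_len, max_len)
        n_excluded = len(excluded)
        if not records:
            raise InputError("no records remain after length filtering")
    report = survey_records(records, config, refs)
    report.metadata.update(
        {
            "input_file": str(fasta),
            "length_filter": bool(length_filter),
            "n_excluded_by_length": n_excluded,
        }
    )
    return report


def config_digest(config: PatternConfig) -> str:
    """Stable SHA-256 digest of the scan configuration (audit trail)."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_report(report: SurveyReport, out_dir: str | Path) -> None:
    """Write hits.tsv, affinity.tsv, histogram.tsv, pairing.tsv, run.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scan_cols = HIT_COLUMNS[:6]
    report.hits[scan_cols].to_csv(out / "hits.tsv", sep="\t", index=False)
    aff_cols = [
        "protein_id", "loop_start_1based", "loop_seq",
        "identity_fraction", "matched_positions", "tier", "ka_range",
    ]
    report.hits[aff_cols].to_csv(out / "affinity.tsv", sep="\t", index=False)
    hist_lines = ["n_ef_hands\tn_proteins"] + [
        f"{k}\t{v}" for k, v in report.histogram.counts.items()
    ]
    (out / "histogram.tsv").write_text("\n".join(hist_lines) + "\n")
    pair_lines = ["protein_id\tn_ef_hands\tparity\tnote"] + [
        f"{p.protein_id}\t{p.n_ef_hands}\t{p.parity}\t{p.note}" for p in report.pairing
    ]
    (out / "pairing.tsv").write_text("\n".join(pair_lines) + "\n")
    meta = dict(report.metadata)
    meta.update(
        {
            "n_proteins_total": report.histogram.n_proteins_total,
            "n_proteins_with_hits": report.histogram.n_proteins_with_hits,
            "n_hits": int(len(report.hits)),
        }
    )
    (out / "run.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> float:
    """Percent identity from a global affine-gap alignment.

    A Needleman-Wunsch global alignment maximising the given scores is
    computed (Biopython's PairwiseAligner); identity is 100 x identical
    aligned pairs / alignment length, with gap columns counted in the
    denominator.  Of co-optimal alignments the aligner's first is taken,
    which is deterministic for fixed inputs.  Symmetric in its arguments
    and 100 exactly iff the sequences are identical.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap_open,
        extend_gap_score=gap_extend,
    )
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length
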