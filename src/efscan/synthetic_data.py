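"""Seeded synthetic proteomes with ground-truth motif placements.

The generator emulates the statistical shape of a proteome-wide EF-hand
survey input: mostly random background sequence, a controlled number of
embedded canonical EF-hand motifs whose coordination loops carry a known
number of critical-position mutations (hence a known affinity tier), and
optional IQ motifs matching the (I/L/V)QxxxRxxxx(R/K) consensus.  Every
placement is recorded in a ground-truth table, so scanner sensitivity,
classifier tier recovery and the empirical false-positive rate can each be
measured against known labels without any external data.

Mutation semantics
------------------
*Affinity* mutations target loop positions 3, 5, 7 and 9: the replacement
residue differs from the consensus (breaking critical-position identity)
but, at the scored positions 3/5/9, stays inside the scanner's allowed
residue set — so the motif remains detectable and only its tier changes.
*Detectability* mutations target loop position 1 with a residue outside
the scanner's required set; such motifs are marked scanner-invisible in
the truth table and excluded from recovery scoring.

Recoverability guarantee
------------------------
Ground truth promises that every scanner-visible embedded motif is
recovered at its recorded position under the scan configuration.  Random
flanking residues can, by chance, form an earlier-starting passing window
that overlaps an embedded loop and would shadow it under greedy
left-to-right overlap resolution; the generator therefore redraws the few
flank residues immediately upstream of each embedded loop until no such
competing window exists.  Motif-free sequence is never touched, so
false-positive-rate estimates on background are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import affinity as aff
from .motif_scan import (
    IQ_LENGTH,
    LOOP_LENGTH,
    LOOP_OFFSET,
    MOTIF_LENGTH,
    STANDARD_RESIDUES,
    EFHandHit,
    PatternConfig,
    ProteinRecord,
    evaluate_loop_window,
    scan_ef_hands,
)

#: Minimum spacing kept between embedded elements (EF 29-mers, IQ 11-mers)
#: so that no window can span residues of two different placements.
PLACEMENT_MARGIN = 12

AFFINITY_POSITIONS = (3, 5, 7, 9)
DETECTABILITY_POSITION = 1


class ConfigurationError(ValueError):
    """Raised when the requested synthetic proteome is infeasible."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic proteome.

    ``per_protein_motif_counts`` is either an explicit list (one count per
    protein) or a probability mapping over counts 0..8 sampled per
    protein.  ``mutation_load`` is a probability mapping over the number
    of critical-position mutations k per embedded motif (affinity
    mutations on positions 3/5/7/9; a fifth mutation spills onto position
    1 and makes the motif scanner-invisible, as does an explicit
    detectability mutation drawn at ``detectability_mutation_rate``).
    """

    n_proteins: int = 500
    length_range: tuple[int, int] = (100, 800)
    per_protein_motif_counts: Sequence[int] | Mapping[int, float] | None = None
    mutation_load: Mapping[int, float] = field(
        default_factory=lambda: {k: 0.2 for k in range(5)}
    )
    detectability_mutation_rate: float = 0.0
    iq_motif_rate: float = 0.1
    background_frequencies: Mapping[str, float] | None = None  # None = uniform
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"bad length_range {self.length_range}")
        if isinstance(self.per_protein_motif_counts, Sequence) and len(
            self.per_protein_motif_counts
        ) != self.n_proteins:
            raise ConfigurationError(
                "explicit per_protein_motif_counts must have one entry per protein"
            )
        for k in self.mutation_load:
            if not 0 <= k <= 5:
                raise ConfigurationError(f"mutation load k={k} outside 0..5")
        if not 0 <= self.iq_motif_rate <= 1:
            raise ConfigurationError("iq_motif_rate outside [0, 1]")


@dataclass(frozen=True)
class EFMotifTruth:
    protein_id: str
    motif_start: int  # 0-based
    loop_seq: str
    k_mutations: int
    intended_tier: str
    scanner_visible: bool

    @property
    def loop_start(self) -> int:
        return self.motif_start + LOOP_OFFSET


@dataclass(frozen=True)
class IQMotifTruth:
    protein_id: str
    start: int  # 0-based
    matched_seq: str


@dataclass(frozen=True)
class GroundTruth:
    ef_motifs: tuple[EFMotifTruth, ...]
    iq_motifs: tuple[IQMotifTruth, ...]


def _required_length(n_ef: int, with_iq: bool) -> int:
    sizes = [MOTIF_LENGTH] * n_ef + ([IQ_LENGTH] if with_iq else [])
    if not sizes:
        return 1
    return sum(sizes) + PLACEMENT_MARGIN * (len(sizes) - 1)


def _place_items(
    rng: np.random.Generator, length: int, sizes: Sequence[int]
) -> list[int]:
    """Non-overlapping starts (margin enforced) at uniform admissible offsets."""
    if not sizes:
        return []
    occupied = sum(sizes) + PLACEMENT_MARGIN * (len(sizes) - 1)
    free = length - occupied
    if free < 0:
        raise ConfigurationError(
            f"cannot place items of sizes {list(sizes)} in length {length}"
        )
    offsets = np.sort(rng.integers(0, free + 1, size=len(sizes)))
    starts = []
    base = 0
    for off, size in zip(offsets, sizes):
        starts.append(int(off) + base)
        base += size + PLACEMENT_MARGIN
    return starts


def _background(rng: np.random.Generator, n: int, residues: str, probs) -> list[str]:
    return list(rng.choice(list(residues), size=n, p=probs))


def _mutate_loop(
    rng: np.random.Generator,
    consensus: str,
    k: int,
    config: PatternConfig,
    force_invisible: bool,
) -> tuple[str, int, bool]:
    """Mutate the consensus loop at critical positions.

    Returns (loop, total critical mutations, scanner_visible).  Affinity
    mutations (positions 3/5/7/9) preserve detectability; a fifth mutation
    or ``force_invisible`` hits position 1 with a residue outside the
    required set.
    """
    loop = list(consensus)
    n_affinity = min(k, len(AFFINITY_POSITIONS))
    positions = sorted(
        int(p) for p in rng.choice(AFFINITY_POSITIONS, size=n_affinity, replace=False)
    )
    scored = dict(config.scored_checks)
    for pos in positions:
        cons = consensus[pos - 1]
        if pos in scored:
            pool = sorted(scored[pos] - {cons})
        else:  # backbone-coordinating position: any substitution breaks identity
            pool = sorted(set(STANDARD_RESIDUES) - {cons})
        loop[pos - 1] = str(rng.choice(pool))
    visible = True
    total = n_affinity
    if k > len(AFFINITY_POSITIONS) or force_invisible:
        pos = DETECTABILITY_POSITION
        cons = consensus[pos - 1]
        allowed = config.required_positions.get(pos, frozenset())
        pool = sorted(set(STANDARD_RESIDUES) - set(allowed) - {cons})
        loop[pos - 1] = str(rng.choice(pool))
        visible = False
        if k > len(AFFINITY_POSITIONS):
            total = k
        else:
            total += 1
    return "".join(loop), total, visible


def _competing_window_starts(
    seq: list[str], loop_start: int, length: int, config: PatternConfig
) -> list[int]:
    """Earlier-starting passing windows that overlap the loop at loop_start."""
    if config.require_full_motif_window:
        lo_limit = LOOP_OFFSET
        hi_limit = length - (MOTIF_LENGTH - LOOP_OFFSET)
    else:
        lo_limit, hi_limit = 0, length - LOOP_LENGTH
    s = "".join(seq)
    out = []
    for ls in range(max(lo_limit, loop_start - (LOOP_LENGTH - 1)), loop_start):
        if ls > hi_limit:
            break
        _, _, passes = evaluate_loop_window(s, ls, config)
        if passes:
            out.append(ls)
    return out


def _sample_count(rng, requested_counts, index) -> int:
    if requested_counts is None:
        return 0
    if isinstance(requested_counts, Mapping):
        ks = sorted(requested_counts)
        probs = np.array([requested_counts[k] for k in ks], dtype=float)
        probs = probs / probs.sum()
        return int(rng.choice(ks, p=probs))
    return int(requested_counts[index])


def generate_proteome(
    config: SyntheticConfig,
    scan_config: PatternConfig | None = None,
    refs: aff.ReferenceLoopSet | None = None,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Generate a synthetic proteome plus its ground-truth table.

    Embedded EF-hand loops are the consensus of ``refs`` (the packaged
    default set unless given) mutated at exactly k sampled critical
    positions; each motif's intended tier follows from its identity
    fraction (5-k)/5.  Identical configs and seeds produce identical
    output bytes.
    """
    scan_config = scan_config or PatternConfig()
    refs = refs or aff.default_reference_loops()
    profile = aff.build_consensus(refs)
    consensus = profile.consensus

    rng = np.random.default_rng(config.seed)
    if config.background_frequencies is None:
        residues, probs = STANDARD_RESIDUES, None
    else:
        residues = "".join(sorted(config.background_frequencies))
        p = np.array([config.background_frequencies[r] for r in residues], float)
        probs = p / p.sum()

    lo, hi = config.length_range
    requested_counts = config.per_protein_motif_counts
    if requested_counts is None:
        requested_counts = {0: 0.4, 1: 0.4, 2: 0.12, 3: 0.05, 4: 0.03}

    # validate feasibility of the largest conceivable request up front
    max_count = (
        max(requested_counts) if isinstance(requested_counts, Mapping) else max(requested_counts, default=0)
    )
    if _required_length(int(max_count), with_iq=True) > hi:
        raise ConfigurationError(
            f"{max_count} motifs (+IQ) cannot fit within max length {hi}"
        )

    mut_ks = sorted(config.mutation_load)
    mut_probs = np.array([config.mutation_load[k] for k in mut_ks], float)
    mut_probs = mut_probs / mut_probs.sum()

    records: list[ProteinRecord] = []
    ef_truth: list[EFMotifTruth] = []
    iq_truth: list[IQMotifTruth] = []
    width = max(4, len(str(config.n_proteins)))
    for i in range(config.n_proteins):
        pid = f"synth{i + 1:0{width}d}"
        n_ef = _sample_count(rng, requested_counts, i)
        with_iq = bool(rng.random() < config.iq_motif_rate)
        needed = _required_length(n_ef, with_iq)
        length = int(rng.integers(max(lo, needed), hi + 1)) if max(lo, needed) <= hi else 0
        if length == 0:
            raise ConfigurationError(
                f"protein {pid}: {n_ef} motifs do not fit in length range {config.length_range}"
            )

        sizes = [MOTIF_LENGTH] * n_ef + ([IQ_LENGTH] if with_iq else [])
        kinds = ["ef"] * n_ef + (["iq"] if with_iq else [])
        order = rng.permutation(len(sizes)) if sizes else np.array([], dtype=int)
        starts = _place_items(rng, length, [sizes[j] for j in order])
        placements = sorted(
            (start, kinds[j]) for start, j in zip(starts, order)
        )

        seq = _background(rng, length, residues, probs)
        guard_regions: list[tuple[int, int, int]] = []  # (loop_start, flank_lo, flank_hi)
        for start, kind in placements:
            if kind == "iq":
                iq = list(rng.choice(list(residues), size=IQ_LENGTH, p=probs))
                iq[0] = str(rng.choice(list("ILV")))
                iq[1] = "Q"
                iq[5] = "R"
                iq[10] = str(rng.choice(list("RK")))
                seq[start : start + IQ_LENGTH] = iq
                iq_truth.append(IQMotifTruth(pid, start, "".join(iq)))
                continue
            k = int(rng.choice(mut_ks, p=mut_probs))
            force_invisible = bool(rng.random() < config.detectability_mutation_rate)
            loop, k_total, visible = _mutate_loop(
                rng, consensus, k, scan_config, force_invisible
            )
            loop_start = start + LOOP_OFFSET
            seq[loop_start : loop_start + LOOP_LENGTH] = list(loop)
            tier = aff.classify_affinity((5 - k_total) / 5).tier
            ef_truth.append(
                EFMotifTruth(pid, start, loop, k_total, tier, visible)
            )
            if visible:
                guard_regions.append((loop_start, max(0, start - 2), start + LOOP_OFFSET))

        # recoverability guarantee: no earlier-starting passing window may
        # overlap a visible embedded loop (it would shadow it under greedy
        # left-to-right resolution)
        for loop_start, flank_lo, flank_hi in guard_regions:
            for _ in range(500):
                if not _competing_window_starts(seq, loop_start, length, scan_config):
                    break
                redraw = _background(rng, flank_hi - flank_lo, residues, probs)
                seq[flank_lo:flank_hi] = redraw
            else:
                raise RuntimeError(
                    f"could not clear competing windows upstream of {pid}:{loop_start}"
                )

        records.append(
            ProteinRecord(
                id=pid,
                sequence="".join(seq),
                description=f"synthetic n_ef={n_ef} iq={int(with_iq)}",
            )
        )
    return records, GroundTruth(tuple(ef_truth), tuple(iq_truth))


TRUTH_HEADER = (
    "record_type\tprotein_id\tstart_1based\tsequence\tk_mutations\t"
    "intended_tier\tscanner_visible"
)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the ground-truth table as TSV (1-based coordinates)."""
    lines = [TRUTH_HEADER]
    for m in truth.ef_motifs:
        lines.append(
            f"ef\t{m.protein_id}\t{m.motif_start + 1}\t{m.loop_seq}\t"
            f"{m.k_mutations}\t{m.intended_tier}\t{int(m.scanner_visible)}"
        )
    for q in truth.iq_motifs:
        lines.append(f"iq\t{q.protein_id}\t{q.start + 1}\t{q.matched_seq}\t.\t.\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> GroundTruth:
    """Read a ground-truth TSV written by :func:`write_truth`."""
    ef: list[EFMotifTruth] = []
    iq: list[IQMotifTruth] = []
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != TRUTH_HEADER:
        raise ValueError(f"unrecognised truth file header in {path}")
    for line in lines[1:]:
        kind, pid, start1, seqs, k, tier, vis = line.split("\t")
        if kind == "ef":
            ef.append(
                EFMotifTruth(pid, int(start1) - 1, seqs, int(k), tier, vis == "1")
            )
        elif kind == "iq":
            iq.append(IQMotifTruth(pid, int(start1) - 1, seqs))
        else:
            raise ValueError(f"unknown truth record type {kind!r}")
    return GroundTruth(tuple(ef), tuple(iq))


@dataclass(frozen=True)
class RecoveryScore:
    """Scanner/classifier performance against ground truth."""

    n_visible: int
    n_recovered: int
    n_tier_correct: int
    n_false_positives: int
    background_residues: int

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.n_recovered / self.n_visible if self.n_visible else float("nan")

    @property
    def tier_recovery_pct(self) -> float:
        return 100.0 * self.n_tier_correct / self.n_recovered if self.n_recovered else float("nan")

    @property
    def fpr_per_10k(self) -> float:
        if not self.background_residues:
            return float("nan")
        return 1e4 * self.n_false_positives / self.background_residues


def score_recovery(
    records: Sequence[ProteinRecord],
    truth: GroundTruth,
    scan_config: PatternConfig | None = None,
    refs: aff.ReferenceLoopSet | None = None,
) -> RecoveryScore:
    """Measure scanner sensitivity, tier recovery and background FPR.

    Sensitivity counts scanner-visible embedded motifs recovered at their
    recorded loop position; tier recovery compares each recovered hit's
    affinity call with the intended tier.  The false-positive rate is
    estimated from accepted hits in proteins that contain no embedded
    EF-hand motif, per 10,000 background residues.
    """
    scan_config = scan_config or PatternConfig()
    refs = refs or aff.default_reference_loops()
    profile = aff.build_consensus(refs)

    truth_by_protein: dict[str, list[EFMotifTruth]] = {}
    for m in truth.ef_motifs:
        truth_by_protein.setdefault(m.protein_id, []).append(m)

    n_visible = n_recovered = n_tier = n_fp = 0
    bg_residues = 0
    for rec in records:
        hits = scan_ef_hands(rec, scan_config)
        motifs = truth_by_protein.get(rec.id, [])
        if not motifs:
            bg_residues += len(rec)
            n_fp += len(hits)
            continue
        hits_by_start: dict[int, EFHandHit] = {h.loop_start: h for h in hits}
        for m in motifs:
            if not m.scanner_visible:
                continue
            n_visible += 1
            hit = hits_by_start.get(m.loop_start)
            if hit is None:
                continue
            n_recovered += 1
            call = aff.affinity_of_loop(hit.loop_seq, profile)
            n_tier += call.tier == m.intended_tier
    return RecoveryScore(n_visible, n_recovered, n_tier, n_fp, bg_residues)
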