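import re

import pytest

from efscan import affinity as aff
from efscan.motif_scan import LOOP_LENGTH, LOOP_OFFSET, MOTIF_LENGTH, PatternConfig

CANONICAL_LOOP = "DKDGDGTITTKE"


@pytest.fixture(scope="session")
def default_refs():
    return aff.default_reference_loops()


@pytest.fixture(scope="session")
def default_profile(default_refs):
    return aff.build_consensus(default_refs)


@pytest.fixture
def canonical_profile():
    """Profile whose consensus is exactly the canonical CaM loop I."""
    refs = aff.ReferenceLoopSet(
        loops=(CANONICAL_LOOP, CANONICAL_LOOP), source_labels=("a", "b")
    )
    return aff.build_consensus(refs)


@pytest.fixture
def make_fasta(tmp_path):
    def _write(text, name="input.fa"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


def brute_force_ef_windows(sequence: str, config: PatternConfig | None = None):
    """Independent exhaustive EF-hand window checker (oracle).

    Re-derives admissibility and the residue checks directly from the
    grammar definition, without calling the scanner.
    """
    config = config or PatternConfig()
    L = len(sequence)
    if config.require_full_motif_window:
        starts = range(LOOP_OFFSET, L - (MOTIF_LENGTH - LOOP_OFFSET) + 1)
    else:
        starts = range(0, L - LOOP_LENGTH + 1)
    passing = []
    for ls in starts:
        w = sequence[ls : ls + LOOP_LENGTH]
        if any(w[p - 1] not in allowed for p, allowed in config.required_positions.items()):
            continue
        score = sum(w[p - 1] in allowed for p, allowed in config.scored_checks)
        if score >= config.min_scored_matches:
            passing.append(ls)
    return passing


IQ_REGEX = re.compile(r"(?=([ILV]Q...R....[RK]))")


def brute_force_iq_starts(sequence: str):
    """Independent IQ consensus matcher (regex with overlap lookahead)."""
    return [m.start() for m in IQ_REGEX.finditer(sequence)]
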