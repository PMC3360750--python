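"""Retrieval of the worked-example sequences from public databases.

The target/template identity worked example compares a *C. elegans*
CaM-like protein (NCBI GI 37699821, residues 28-171) with the *Drosophila
melanogaster* calmodulin template (PDB 2BKH chain B, residues 4-147).
Neither sequence ships with the package (they belong to NCBI/RCSB), so
this module fetches them over HTTP on demand.  All functions raise
:class:`RemoteUnavailableError` promptly when the network cannot be
reached.
"""

from __future__ import annotations

import urllib.error
import urllib.request

NCBI_EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=protein&id={id}&rettype=fasta&retmode=text"
)
RCSB_FASTA = "https://www.rcsb.org/fasta/entry/{pdb_id}"

TIMEOUT_S = 15.0


class RemoteUnavailableError(RuntimeError):
    """The sequence database could not be reached."""


def _fetch_text(url: str) -> str:
    try:
        with urllib.request.urlopen(url, timeout=TIMEOUT_S) as resp:
            return resp.read().decode()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise RemoteUnavailableError(f"cannot fetch {url}: {exc}") from exc


def _parse_fasta_text(text: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    current = None
    for line in text.splitlines():
        if line.startswith(">"):
            current = line[1:].strip()
            seqs[current] = ""
        elif current is not None:
            seqs[current] += line.strip()
    if not seqs:
        raise RemoteUnavailableError("fetched document contained no FASTA records")
    return seqs


def fetch_ncbi_protein(gi_or_accession: str) -> str:
    """Fetch one protein sequence from NCBI by GI number or accession."""
    seqs = _parse_fasta_text(_fetch_text(NCBI_EFETCH.format(id=gi_or_accession)))
    return next(iter(seqs.values())).upper()


def fetch_pdb_chain(pdb_id: str, chain: str) -> str:
    """Fetch one chain's sequence from the RCSB entry FASTA."""
    seqs = _parse_fasta_text(_fetch_text(RCSB_FASTA.format(pdb_id=pdb_id.upper())))
    for header, seq in seqs.items():
        # RCSB headers look like "2BKH_1|Chains A, B|Calmodulin|..."
        parts = header.split("|")
        if len(parts) >= 2:
            chains = parts[1].replace("Chains", "").replace("Chain", "")
            if chain.upper() in [c.strip().split("[")[0] for c in chains.split(",")]:
                return seq.upper()
    raise RemoteUnavailableError(f"chain {chain} not found in PDB entry {pdb_id}")


def fetch_table1_sequences() -> tuple[str, str]:
    """Fetch the worked-example target and template subsequences.

    Returns (target, template): GI 37699821 residues 28-171 and PDB 2BKH
    chain B residues 4-147 (both 1-based inclusive).
    """
    target = fetch_ncbi_protein("37699821")[27:171]
    template = fetch_pdb_chain("2BKH", "B")[3:147]
    return target, template
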