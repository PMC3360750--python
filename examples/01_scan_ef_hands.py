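"""Scan a single protein for canonical EF-hand coordination loops."""

from efscan import ProteinRecord, scan_ef_hands

# helix E (11 aa) + canonical CaM coordination loop + start of helix F
protein = ProteinRecord(
    id="demo1",
    sequence="AAELAAAFKEA" + "DKDGDGTITTKE" + "FAAELRHAM",
)

for hit in scan_ef_hands(protein):
    print(
        f"{hit.protein_id}: motif at {hit.motif_start + 1}, "
        f"loop {hit.loop_seq} at {hit.loop_start + 1}, score {hit.score}/4"
    )
    print("  checks:", {k: int(v) for k, v in hit.constraint_flags.items()})

# The single hit is the embedded loop: D at loop position 1 and E at 12
# satisfy the hard constraints, and D/D/G/T at positions 3/5/6/9 satisfy
# all four scored oxygen-coordination checks (score 4 of 4).
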