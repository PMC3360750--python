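"""Match the IQ (calmodulin-binding) consensus in a peptide.

The IQ1 motif of yeast myosin V is a classic calmodulin-binding segment;
exactly one window matches (I/L/V)QxxxRxxxx(R/K).
"""

from efscan import ProteinRecord, scan_iq_motifs

peptide = ProteinRecord(id="IQ1", sequence="AILLQTNIRALWKREYYRAA")

for hit in scan_iq_motifs(peptide):
    print(f"{hit.protein_id}: IQ consensus match {hit.matched_seq} at position {hit.start + 1}")

# Prints one match, LQTNIRALWKR at position 4: L satisfies the I/L/V
# anchor, Q follows, R sits at consensus position 6 and R at position 11.
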