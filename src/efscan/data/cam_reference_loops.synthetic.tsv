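# Synthetic default calmodulin reference loop set (constructed stand-in).
# 40 coordination loops = the canonical animal CaM loop repertoire (EF1-EF4)
# replicated over ten pseudo-organism labels, with sparse substitutions at
# non-critical positions to mimic real CaM loop conservation.  Not a curated
# database extract; replace with your own loops (FASTA or TSV) for real use.
# Columns: label <TAB> loop (12 residues).
label	loop
synthOrg01|CaM_EF1	DKDGDGTITTKE
synthOrg01|CaM_EF2	DADGNGTIDFPE
synthOrg01|CaM_EF3	DKDGNGYISAAE
synthOrg01|CaM_EF4	DIDGDGQVNYEE
synthOrg02|CaM_EF1	DKDGDGTITTKE
synthOrg02|CaM_EF2	DADGNGTIDFPE
synthOrg02|CaM_EF3	DKDGNGYISAAE
synthOrg02|CaM_EF4	DIDGDGQVNYEE
synthOrg03|CaM_EF1	DKDGDGTITTKE
synthOrg03|CaM_EF2	DADGNGTIDFPE
synthOrg03|CaM_EF3	DKDGNGYISAAE
synthOrg03|CaM_EF4	DIDGDGQVNYEE
synthOrg04|CaM_EF1	DKDGDGTITTKE
synthOrg04|CaM_EF2	DADGNGTIDFPE
synthOrg04|CaM_EF3	DKDGNGYISAAE
synthOrg04|CaM_EF4	DIDGDGQVNYEE
synthOrg05|CaM_EF1	DKDGDGTITTKE
synthOrg05|CaM_EF2	DADGNGTIDFPE
synthOrg05|CaM_EF3	DKDGNGYISAAE
synthOrg05|CaM_EF4	DIDGDGQVNYEE
synthOrg06|CaM_EF1	DKDGDGTITTKE
synthOrg06|CaM_EF2	DADGNGTIDFPE
synthOrg06|CaM_EF3	DKDGNGYISAAE
synthOrg06|CaM_EF4	DIDGDGQVNYEE
synthOrg07|CaM_EF1	DKDGDGTITTRE
synthOrg07|CaM_EF2	DADGNGTIDFPE
synthOrg07|CaM_EF3	DKDGNGYISAAE
synthOrg07|CaM_EF4	DIDGDGQVNYEE
synthOrg08|CaM_EF1	DKDGDGTITTKE
synthOrg08|CaM_EF2	DSDGNGTIDFPE
synthOrg08|CaM_EF3	DKDGNGYISAAE
synthOrg08|CaM_EF4	DIDGDGQVNYEE
synthOrg09|CaM_EF1	DKDGDGTITTKE
synthOrg09|CaM_EF2	DADGNGTIDFPE
synthOrg09|CaM_EF3	DKDGNGYLSAAE
synthOrg09|CaM_EF4	DIDGDGQVNYEE
synthOrg10|CaM_EF1	DKDGDGTITTKE
synthOrg10|CaM_EF2	DADGNGTIDFPE
synthOrg10|CaM_EF3	DKDGNGYISAAE
synthOrg10|CaM_EF4	DVDGDGQVNYEE
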