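"""Percent identity between two sequences by global affine-gap alignment.

The survey's worked example compares a CaM-like target against a CaM
template; here two diverged toy calmodulin fragments illustrate the
calculation (identical pairs / alignment length, gaps included).
"""

from efscan import pairwise_identity

template = "ADQLTEEQIAEFKEAFSLFDKDGDGTITTKELGTVMRSL"
target = "SEELTEEQIAEYKEAFSLFDKDGGGTITTKELGTVMRSL"

pid = pairwise_identity(target, template)
print(f"global identity: {pid:.1f}%")
print(f"self identity:   {pairwise_identity(template, template):.1f}%")

# Identity uses match=1/mismatch=0 with affine gaps (open -10, extend
# -0.5); the denominator is the full alignment length, so gap columns
# dilute identity exactly as aligned mismatches do.
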