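"""Classify EF-hand loops into Ca2+-affinity tiers against the CaM consensus."""

from efscan import affinity_of_loop, build_consensus, default_reference_loops

refs = default_reference_loops()
profile = build_consensus(refs)
print(f"consensus over {profile.n_loops} reference loops: {profile.consensus}")
print(f"critical positions: {sorted(profile.critical_positions)}")

loops = {
    "pristine consensus": profile.consensus,
    "one critical mutation": "DKEGDGTIDTEE",   # position 3 D->E
    "three critical mutations": "AKAGAGTIDTEE",  # positions 1, 3, 5
}
for name, loop in loops.items():
    call = affinity_of_loop(loop, profile)
    print(
        f"{loop} ({name}): identity {call.identity_fraction:.1f}, "
        f"tier {call.tier}, Ka {call.ka_range}"
    )

# Identity is counted only at the five critical positions: 5/5 -> strong
# (Ka in the CaM range 1e4-1e7), 4/5 -> medium (<1e4), 2/5 -> low (<1e2).
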