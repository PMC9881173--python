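"""Build a divergent repeat pair and locate its mismatched sites.

The reporter carries two tandem 287-bp repeats; the divergent variants
plant 3 (1% divergence) or 8 (3% divergence) equally spaced
substitutions in the GFP-side repeat.
"""

from rmdkit import (
    construct_divergent_repeat,
    detect_divergent_sites,
    divergence_percent,
    random_repeat,
)

seq = random_repeat(287, seed=17)
for n in (3, 8):
    pair = construct_divergent_repeat(seq, n, seed=17)
    sites = detect_divergent_sites(pair)
    pct = divergence_percent(len(sites), len(pair))
    print(f"{n} planted substitutions -> {len(sites)} sites, {pct}% divergence")
    for s in sites:
        print(f"  rank {s.rank}: offset {s.offset:3d}  {s.top_base}->{s.bottom_base}")

# Each rank counts from the Cdkn1A-proximal end; offsets are 0-based
# positions in the repeat. 8/287 rounds to 3% and 3/287 to 1%, matching
# the reporter design labels.
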