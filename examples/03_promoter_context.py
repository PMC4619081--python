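"""Promoter proximity of promoter-like exons: CAGE, ChIA-PET, chromHMM.

Generates a synthetic bundle, then asks for each planted promoter-like
exon whether the nearest used TSS (CAGE cluster with score >= 1) is closer
in the higher-inclusion cell, whether the exon has a Pol-II ChIA-PET loop,
and whether it shares a chromatin-state run with its TSS.
"""

from exonchrom import (
    compare_tss_proximity,
    count_chia_pet_interactions,
    distance_to_used_tss,
    same_state_extension,
)
from exonchrom.simulate import SimConfig, simulate_bundle

cfg = SimConfig(n_genes=40, frac_regulated=0.6, frac_promoter_like=0.5,
                alt_tss_fraction=0.45, seed=11)
bundle = simulate_bundle(cfg)
pl = bundle.truth[bundle.truth["promoter_like"]]
cells = cfg.cells

d_hi, d_lo, loops_hi, shared = [], [], 0, 0
for row in pl.itertuples(index=False):
    exon = bundle.exons[row.exon_id]
    hi = row.c_higher
    lo = cells[0] if hi == cells[1] else cells[1]
    dh, cl_hi = distance_to_used_tss(exon, bundle.cage[hi])
    dl, _ = distance_to_used_tss(exon, bundle.cage[lo])
    d_hi.append(dh)
    d_lo.append(dl)
    n_links, has = count_chia_pet_interactions(exon, bundle.links[hi])
    loops_hi += int(has)
    if cl_hi is not None:
        shared += int(same_state_extension(exon, cl_hi.interval.midpoint,
                                           bundle.segmentation[hi]))

print(f"promoter-like exon comparisons: {len(pl)}")
print("nearest used TSS:", compare_tss_proximity(d_hi, d_lo))
print(f"with a Pol-II loop in C-higher: {loops_hi}/{len(pl)}")
print(f"sharing a chromatin-state run with their TSS (C-higher): {shared}/{len(pl)}")
# 'closer_in_Chigher' counts exons whose active TSS moved closer in the
# cell where the exon is more included (alternative-TSS usage).
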