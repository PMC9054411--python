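"""Extract the 43-feature radiomic block of one contrast phase.

Each phase yields 12 first-order intensity statistics, 24 texture features
(GLCM + GLRLM + GLZSM, averaged over the in-plane directions 0/45/90/135
degrees) and 7 morphology descriptors of the tumor shape.
"""

from tacerad import PhantomConfig, generate_cohort, phase_block

stacks, _ = generate_cohort(
    PhantomConfig(n_per_class=2, grid=(32, 32, 32), radius_range_mm=(6, 10), seed=0))
block = phase_block(stacks[0], "arterial_mid", G=64)

print(f"phase {block.phase_id}: {len(block.as_dict())} features "
      f"({block.n_directional_evaluations} directional texture evaluations averaged to 24)")
for group, feats in (("first-order", block.first_order),
                     ("texture", block.texture),
                     ("morphology", block.morphology)):
    print(f"\n{group} ({len(feats)}):")
    for name, value in list(feats.items())[:4]:
        print(f"  {name:40s} {value:12.4f}")
    if len(feats) > 4:
        print(f"  ... {len(feats) - 4} more")
# Entropy/energy describe the gray-level histogram, GLCM contrast the local
# intensity variation, zone emphases the blob structure, sphericity how
# close the tumor shape is to a ball.
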