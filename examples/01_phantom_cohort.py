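"""Generate a synthetic multiphase tumor cohort and inspect its structure.

The phantom emulates a balanced treatment-response cohort: each case is an
ellipsoidal tumor imaged at four contrast phases, with responders washing
in/out strongly and non-responders staying flat but more heterogeneous.
"""

from tacerad import PhantomConfig, generate_cohort

cfg = PhantomConfig(n_per_class=4, grid=(32, 32, 32), radius_range_mm=(6, 10), seed=0)
stacks, truth = generate_cohort(cfg)

print(f"{len(stacks)} cases, grid {cfg.grid}, phases per case: {len(stacks[0].phases)}")
print(truth.to_string(index=False))

case = stacks[0]
m = case.mask.mask
print(f"\ncase {case.case_id}: {case.mask.n_voxels} tumor voxels, RECIST {case.recist}")
for pid, vol in case.phases.items():
    print(f"  {pid:16s} mean in-mask intensity {vol.voxels[m].mean():7.2f}")
# Responders show a strong arterial wash-in (mean jumps from ~100 to ~165
# between the early and mid arterial phases) followed by wash-out.
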