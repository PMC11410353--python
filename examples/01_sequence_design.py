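"""Generate a full oddball session plan and check its design counts.

Each block opens with 16 habituation standards, then alternates runs of 4-9
standards with single deviants (40 deviants over 271 standards), and closes
with one final standard; a session holds each of the six deviant conditions
three times with no condition repeated back to back.
"""

import oddwave as ow

plan = ow.build_session(master_seed=7, participant_id="demo")
ow.mark_analyzable(plan)
df = plan.to_frame()

print(f"blocks: {len(plan.blocks)}   total trials: {plan.n_trials}")
print(f"block order: {' '.join(plan.block_types())}")

block0 = plan.blocks[0]
runs = block0.run_lengths_before_deviants()
print(f"\nfirst block ({block0.block_type}): {len(block0.trials)} trials, "
      f"{block0.n_deviants} deviants")
print(f"standard-run lengths before deviants: min={min(runs)} max={max(runs)} "
      f"sum={sum(runs)}")

analyzable = df[(df.role == "deviant") & df.analyzable].groupby("block_type").size()
print("\nanalyzable deviants per condition (40-1 per block x 3 blocks):")
print(analyzable.to_string())
# 328 trials/block and 117 analyzable deviants per condition are the
# fingerprints of the design; any deviation means a constraint was violated.
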