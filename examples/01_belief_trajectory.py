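"""Track an ideal learner's beliefs across probability reversals.

Generates the reversal-learning task (tones probabilistically coupled to
rotation directions, with the coupling alternating between blocks), feeds
the tone-rotation contingencies through the hierarchical Gaussian filter,
and prints how the learner's contingency estimate follows each reversal.
"""

import perceptlearn as pl
from perceptlearn.hgf import HGFParams, hgf_filter
from perceptlearn.observer import contingency_inputs

seq = pl.generate_sequence(seed=42)
inputs = contingency_inputs(seq, None)  # ambiguous trials carry no input
traj = hgf_filter(inputs, HGFParams())

df = traj.to_frame()
df["block_id"] = [t.block_id for t in seq]

print("Belief in the (high tone -> leftward) contingency, end of each block:")
for block_id, chunk in df.groupby("block_id"):
    print(f"  block {block_id:2d} ({len(chunk):2d} trials): "
          f"mu1hat = {chunk['mu1hat'].iloc[-1]:.3f}")

print(f"\nFinal volatility estimate mu3 = {df['mu3'].iloc[-1]:+.3f}")
print("mu1hat should swing toward 1 and 0 on alternating blocks as the "
      "learner re-adapts after every reversal.")
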