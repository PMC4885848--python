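"""Simulate one observer and measure their perceptual biases.

A synthetic observer combines three learned expectations -- the
tone-rotation association, priming by the previous unambiguous percept,
and memory of the previous ambiguous percept -- with the (absent) stereo
evidence on ambiguous trials.  The script simulates a full session and
prints the resulting congruency biases and motor adaptation.
"""

import perceptlearn as pl
from perceptlearn.behavior import (
    label_expectations, motor_adaptation, perceptual_bias,
)
from perceptlearn.observer import ObserverParams

seq = pl.generate_sequence(seed=7)
params = ObserverParams()  # pi_a = pi_p = pi_s = 0.5, pi_stereo = 2.5
records = pl.simulate_observer(seq, params, rng_seed=7)

labels = label_expectations(seq, records)
print("Percept biases toward the expected direction (ambiguous trials):")
for source in ("assoc", "priming", "memory"):
    b = perceptual_bias(labels, source)
    print(f"  {source:8s}: {b.bias_percent:+6.1f}%  "
          f"({b.n_congruent} congruent vs {b.n_incongruent} incongruent)")

adapt = motor_adaptation(seq, records)
print(f"\nMotor adaptation (unambiguous trials): {adapt:+.3f}")
print("Negative values mean faster responses when the stimulus matched "
      "the learned association.")
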