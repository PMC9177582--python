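"""The 16-state seeding network and its rate generator.

Enumerates the states (bone/lung/liver/brain flags with their 1-16
indices), shows the rate of a couple of transitions, and builds the 16x16
generator Q of the continuous-time Markov chain (Q[i, j] = rate of moving
from state j+1 to state i+1; columns sum to zero).
"""

import numpy as np

import metaspread as ms

print("index  bone lung liver brain")
for s in ms.enumerate_states():
    print(f"{s.index:5d}  {s.bone:4d} {s.lung:4d} {s.liver:5d} {s.brain:5d}")

theta = ms.DEFAULT_TRUE_RATES
s = ms.MetastasisState.from_index
print(f"\nrate 1 -> 5 (add bone):            {ms.transition_rate(s(1), s(5), theta)}")
print(f"rate 4 -> 6 (lung adds liver):     {ms.transition_rate(s(4), s(6), theta)}")
print("  (= tuli + luli: primary plus secondary seeding once the lung is positive)")

Q = ms.build_generator(theta)
print(f"\ngenerator column sums (all ~0): max |sum| = {np.abs(Q.sum(axis=0)).max():.2e}")
print(f"allowed transitions (positive entries): {(Q > 0).sum()}")
print("\nDOT export available via ms.to_dot(); edge list via ms.edge_list(theta).")
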