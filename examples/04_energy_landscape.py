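"""Fit a pairwise maximum-entropy model and extract brain states.

Binarized activity of 8 brain networks is modelled with the Boltzmann
distribution P(V) ~ exp(-E(V)); local minima of the energy over the 256
activity patterns are the brain states, and every pattern drains to one of
them by steepest descent.  Here we sample from a planted two-state model,
refit from the samples alone, and recover the states: one with FPN_A + DMN
+ limbic active (State1, the behaviourally optimal profile) and its
complement (State2).
"""

import numpy as np

from gradstate import fit_mem, fit_quality, planted_two_state_model
from gradstate.mem import build_landscape, label_named_states
from gradstate.simulate import gen_network_series

truth = planted_two_state_model()
binary, _bold = gen_network_series(truth, volumes=6_000, dwell_control=8, seed=2)
print(f"sampled {binary.shape[0]} volumes of {binary.shape[1]}-network "
      f"binary activity from the planted model")

model = fit_mem(binary)
print(f"gradient ascent converged in {model.n_iter} iterations "
      f"(max moment mismatch {model.max_moment_mismatch:.1e})")
print(f"appearance-probability fit: Pearson r = {fit_quality(binary, model):.3f}")

scape = build_landscape(model)
names = label_named_states(scape.minima)
print(f"local energy minima found: {len(scape.minima)}")
for m in scape.minima:
    active = [scape.networks[i] for i in range(8) if (int(m) >> i) & 1]
    basin_mass = float(scape.probabilities[scape.basin == m].sum())
    print(f"  pattern {int(m):3d} ({names[int(m)]:6s}): "
          f"E = {scape.energies[m]:+.2f}, basin probability {basin_mass:.2f}, "
          f"active: {', '.join(active) or 'none'}")
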