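"""Assign raw button presses to gradCPT trials.

In the gradCPT, scenes cross-fade every 800 ms, so a press does not point
to a unique trial.  This example shows the coherence convention (what the
participant saw at the moment of the press) and the iterative assignment:
an unambiguous press stays with its trial, a surplus press moves to a free
neighbour, and a press between two silent trials goes to the closest —
unless that neighbour is a no-go mountain, which keeps the benefit of the
doubt.
"""

import numpy as np

from gradstate import TrialStream, assign_presses, error_counts, rt_to_coherence

cur, prev = rt_to_coherence(0.720, isi=0.8)
print(f"a press 720 ms after transition onset saw {cur:.0%} of the current "
      f"scene and {prev:.0%} of the previous one")

stream = TrialStream(
    onsets=np.arange(6) * 0.8,
    categories=np.array(["city", "city", "mountain", "city", "city", "city"]),
    scene_ids=np.array(["c1", "c2", "m1", "c3", "c1", "c4"]),
    isi=0.8,
)
# trial 0: two presses (fastest wins, the other moves to trial 1);
# a press 0.5*isi into trial 3 is ambiguous between mountain 2 and city 3
presses = [0.60, 0.96, 2.80, 4.20]
series = assign_presses(stream, presses)

for t in range(stream.n_trials):
    rt = f"{series.rts[t]:.2f} s" if not np.isnan(series.rts[t]) else "  --  "
    print(f"trial {t} ({stream.categories[t]:>8}): RT {rt}  "
          f"{series.classification[t]}")

counts = error_counts(series)
print(f"omission rate {counts['omission_rate']:.2f}, "
      f"commission rate {counts['commission_rate']:.2f} "
      f"(mountain spared: the ambiguous press went to the city)")
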