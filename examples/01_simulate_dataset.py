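"""Generate a small synthetic gradCPT-with-fMRI dataset with ground truth.

Builds the planted two-state brain model, samples one participant's run of
network activity and state-dependent behaviour, and writes a BIDS-style
events table.  The printed numbers are the planted world: which brain state
generated each trial, and the omission/commission structure of the run.
"""

import numpy as np

from gradstate import (
    SimConfig,
    StateBehavior,
    ExGaussParams,
    gen_behavior,
    gen_network_series,
    gen_trial_stream,
    planted_two_state_model,
)
from gradstate.mem import build_landscape, label_named_states, pattern_index
from gradstate.simulate import write_events_table

model = planted_two_state_model()
scape = build_landscape(model)
names = label_named_states(scape.minima)
print("planted brain states:", {int(k): v for k, v in names.items()})

cfg = SimConfig(
    n_trials_per_run=300,
    mem_truth=model,
    state_params={
        7: StateBehavior(ExGaussParams(0.80, 0.08, 0.05), omission_rate=0.03,
                         commission_rate=0.25),
        248: StateBehavior(ExGaussParams(0.80, 0.12, 0.05), omission_rate=0.06,
                           commission_rate=0.35),
    },
    seed=1,
)

rng = np.random.default_rng(cfg.seed)
stream = gen_trial_stream(cfg.n_trials_per_run, cfg.isi, cfg.p_mountain, rng)
binary, bold = gen_network_series(model, cfg.volumes_per_run, cfg.dwell_control, rng)
true_states = scape.basin[pattern_index(binary)]
presses, truth = gen_behavior(stream, true_states, cfg, rng)

df = write_events_table(stream, truth.trial_rts, "events_run-01.tsv")
print(f"wrote events_run-01.tsv with {len(df)} trials, {len(presses)} presses")

occupancy = {names[int(s)]: float(np.mean(truth.trial_states == s))
             for s in scape.minima}
print("fraction of trials generated in each state:", occupancy)
n_resp = int(np.sum(~np.isnan(truth.trial_rts)))
print(f"responded trials: {n_resp}; mean planted RT "
      f"{np.nanmean(truth.trial_rts):.3f} s (mu + tau of the mixed states)")
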