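"""How coarser sampling degrades the behavior classification.

Subsamples a 5-min synthetic track at longer regular intervals, re-selects
the radius dynamically for each, re-classifies, and scores per-state
agreement with the native-interval analysis over the retained fixes.
Because rest bouts (hours) far outlast search bouts (tens of minutes),
rest survives coarse sampling while search degrades.
"""

from rstrack import SimConfig, run_resolution_experiment, simulate_track

track = simulate_track(SimConfig(n_points=2000, seed=0))
table = run_resolution_experiment(track, intervals_min=(5, 10, 20, 30, 60, 120))

cols = ["interval_min", "n_retained", "radius_R", "overall",
        "agree_transit", "agree_ars", "agree_rest"]
print(table[cols].round(3).to_string(index=False))
print(
    "\nagree_<state>: fraction of retained fixes with that reference state\n"
    "that keep it in the subsampled analysis. Agreement is 1 at the native\n"
    "interval by construction; past the ~30-min search bout length, search\n"
    "(ars) agreement falls away faster than rest agreement."
)
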