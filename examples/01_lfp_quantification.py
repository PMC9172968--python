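"""Quantify epileptiform activity in simulated LFP traces.

Simulates a burst-free "wildtype" trace and a "mutant" trace carrying
polyspiking bursts, then runs the full quantification chain: band-pass +
notch conditioning, 3x-baseline / 100 ms event detection, Welch PSD with
10-Hz banding, and the 20-50 Hz summary statistic.
"""

from seizmap import lfp, synthetic

wt_rec, _ = synthetic.simulate_lfp(
    synthetic.LFPSimConfig(duration=60.0, n_events=0, seed=1)
)
mut_rec, truth = synthetic.simulate_lfp(
    synthetic.LFPSimConfig(duration=60.0, n_events=12, event_amplitude_factor=5.0, seed=2)
)

for name, rec in [("wildtype", wt_rec), ("mutant", mut_rec)]:
    events, table, summary = lfp.quantify_recording(rec)
    print(f"{name}: {len(events)} epileptiform events, "
          f"20-50 Hz mean power {summary:.4g}")

print(f"(ground truth: mutant trace carries {len(truth.intervals)} planted bursts)")

groups = {
    "wt": [lfp.quantify_recording(wt_rec)[2]],
    "mut": [lfp.quantify_recording(mut_rec)[2]],
}
for g in lfp.normalize_to_reference(groups, "wt"):
    print(f"{g.group}: {g.normalized_mean_percent:.1f}% of wildtype band power")
# The mutant's 20-50 Hz power is several-fold the wildtype's: the band that
# characterizes polyspiking discharges dominates its spectrum.
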