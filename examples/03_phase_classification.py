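"""Cell-cycle phase durations from the oscillating TF network.

Simulates the cln1d_cln2d double knockout's TF-target fixture, reduces the
network to TFs whose mean target trajectory is periodic, and calls the
first-cycle G1/S, S/G2, G2/M and M/G1 transitions from spline-smoothed,
order-validated target peaks. The double knockout's generating preset has a
short G1 (12.3 min) and a strongly extended merged G2/M block (48 min).
"""

from perioscope import periodicity, preprocess, synthetic, tf_phase

reference = synthetic.simulate_reference_set(200, seed=1)
cal = periodicity.calibrate_cutoffs(
    periodicity.fit_expression_matrix(
        preprocess.preprocess_counts(reference, min_total=0.0)
    ),
    fnr=0.2,
)

preset = synthetic.make_strain_preset("cln1d_cln2d")
net, counts = synthetic.simulate_tf_network(preset, seed=1)
fc = preprocess.preprocess_counts(counts)

filtered = tf_phase.filter_oscillating_tfs(net, fc, score_cutoff=cal.score_cutoff)
print(f"retained TFs: {sorted(filtered.tf_scores)}")

groups = [(name, list(tfs)) for name, tfs in synthetic.CLASSIFICATION_GROUPS]
ann = tf_phase.classify_phases(groups, filtered, fc, strain=preset.name)
for name, t in ann.transitions.items():
    print(f"  {name} transition at {t:.1f} min")
for phase, dur in ann.durations.items():
    print(f"  {phase} duration: {dur:.1f} min")
print(f"generating schedule (G1, S, G2M): {preset.phase_schedule}")
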