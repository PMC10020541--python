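"""Score a synthetic time course and locate the tipping point.

Generates a 60-gene network with a 10-gene planted module that destabilises
at time t3, computes the global single-sample landscape entropy (SLE) for
every treated sample against the matched controls, and reports the per-time
curve.  The peak of the curve is the estimated critical (pre-transition)
time point.
"""

from dnbsle import (
    SyntheticConfig,
    detect_tipping_point,
    generate_network,
    simulate_timecourse,
    sle_curve,
)

config = SyntheticConfig(seed=7)
network, module = generate_network(config)
data, truth = simulate_timecourse(network, module, config)

curve = sle_curve(network, data)
print("time   mean SLE   SEM")
for t in curve.time_labels:
    print(f"{t:5s}  {curve.mean(t):.5f}   {curve.sem(t):.5f}")

peak = detect_tipping_point(curve)
print(f"\ndetected tipping point: {peak}  (planted: {truth.t_star})")
print(
    "Each mean is the average perturbation the treated samples at that time\n"
    "inflict on the control correlation structure; the peak marks the\n"
    "estimated critical state. With only 4 replicates per cohort the curve\n"
    "is noisy and the peak call can miss the planted time."
)
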