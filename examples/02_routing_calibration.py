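"""Calibrate flexor via-point routing against reference moment-arm curves.

Generates the 20-curve reference set (FDP over MCP/PIP/DIP and FDS over
MCP/PIP, digits 2-5) with literature-scale means, fits the palmar depth
of every via point per muscle and digit, and summarizes the per-curve
NMAE distribution.
"""

from jfisim import gen_hand_fixture, gen_moment_arm_reference, optimize_routing, summarize_fit

model, _ = gen_hand_fixture()
references = gen_moment_arm_reference(seed=0)  # noise-free surrogate curves

nmae_values = []
for muscle in ("FDP", "FDS"):
    fit = optimize_routing(model, muscle, references)
    nmae_values += fit.nmae_values
    for (digit, m, joint), (mae, val) in sorted(fit.per_curve.items()):
        print(f"  {m} digit {digit} {joint}: MAE = {mae * 1e3:5.2f} mm, "
              f"NMAE = {val:5.2f} %")

s = summarize_fit(nmae_values, thresholds=(5.0, 25.0))
print(f"\n{s['n']} curves: NMAE min {s['min']:.2f} %, max {s['max']:.2f} %, "
      f"{s['count_below'][5.0]} below 5 %, {s['count_below'][25.0]} below 25 %")
# NMAE is the mean absolute arm deviation normalized by the mean measured
# arm, so a curve below 5 % transfers joint torques with < 5 % error.
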