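"""Evaluate the published velocity-increment standard.

Looks up means, SDs, centiles and Z-scores for the five biometry
measures, locates each measure's peak velocity, and expresses head
growth as a percentage of the attained term size.
"""

import fetalvelocity as fv

# Median (50th-centile) weekly growth at selected gestational ages
for b, ga in [("HC", 16), ("AC", 16), ("FL", 16), ("HC", 28), ("HC", 34)]:
    print(f"{b} median velocity at {ga} wk: {fv.mean_velocity(b, ga):6.2f} mm/wk")

# Centile envelope and a Z-score: an HC gaining 10.5 mm/wk at 20 weeks
c3 = fv.centile_velocity("HC", 20, 3)
c97 = fv.centile_velocity("HC", 20, 97)
z = fv.zscore_velocity("HC", 20, 10.5)
print(f"\nHC at 20 wk: C3={c3:.2f}, C97={c97:.2f} mm/wk; 10.5 mm/wk is Z={z:+.2f}")
print("(Z < 0: growing slower than the median fetus, still inside the C3-C97 envelope)")

# Peak velocity: boundary peak at 16 wk except the biparietal diameter
print("\nPeak mean velocity (continuous argmax over 16-38 wk):")
for b in ("HC", "BPD", "OFD", "AC", "FL"):
    ga, v = fv.peak_velocity(b)
    print(f"  {b:3s}: {v:5.2f} mm/wk at {ga:.1f} wk")

# Relative growth: weekly HC gain as % of the 334 mm attained size at term
for ga in (16, 33, 38):
    pct = fv.percent_of_term_size("HC", ga, term_size_mm=334.0)
    print(f"HC gain at {ga} wk = {pct:.1f}% of term size per week")
print("(head growth falls from ~3.7%/wk at 16 wk to <1%/wk near term)")
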