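"""Conditional velocity: adjust serial Z-scores for regression to the mean.

A fetus starting small is expected to drift back toward the median even
when perfectly healthy; the conditional SD score (cSDS) measures how the
second visit compares with that expectation rather than with the median.
"""

import fetalvelocity as fv

# Z-score correlation between visits: exponential decay over a 10-week scale
model = fv.ExponentialCorrelation(range_=10.0, shape=1.0)
print(f"correlation of Z at 20 and 25 wk: {fv.correlation(model, 20, 25):.3f}")

scenarios = {
    "tracking the median": [(16, 0.0), (21, 0.0), (26, 0.0), (31, 0.0)],
    "possible microcephaly": [(16, -0.8), (21, -1.6), (26, -2.4), (31, -3.1)],
    "small but tracking": [(16, -1.5), (21, -1.4), (26, -1.6), (31, -1.5)],
    "possible macrosomia": [(16, 0.4), (21, 1.2), (26, 2.1), (31, 2.9)],
}

for name, series in scenarios.items():
    out = fv.assess_trajectory(series, model)
    csds = ", ".join(f"{c:+.2f}" for c in out["csds"])
    print(f"{name:22s} cSDS per interval: {csds}   flags: {list(out['flag'])}")

print("\ncSDS ~ N(0,1) under normal growth: persistent |cSDS| > 2 signals growth")
print("faster/slower than expected given the previous visit, while the 'small")
print("but tracking' fetus stays unremarkable despite Z ~ -1.5 at every visit.")
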