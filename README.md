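# fetalvelocity

Tools for assessing **fetal growth velocity** — how fast the fetal head
circumference (HC), biparietal diameter (BPD), occipitofrontal diameter
(OFD), abdominal circumference (AC) and femur length (FL) grow between
ultrasound visits — against the international velocity-increment
standards derived from the INTERGROWTH-21st low-risk longitudinal
cohort. It is written for perinatal epidemiologists and clinical
researchers who need chart evaluation, velocity scoring and chart
construction as importable Python, with a thin command line for batch
work.

Size and growth are not the same thing: a fetus can sit at an
unremarkable size centile while growing far too slowly. The package
covers the full velocity workflow:

- **Standards** — evaluate the published fractional polynomial mean and
  SD models; centiles, Z-scores, peak velocity, percent-of-term-size;
  reproduce the printed charts cell for cell.
- **Increments** — turn longitudinal scan records into velocity
  observations, `v = (Y2 − Y1)/(t2 − t1)` mm/wk carried at the
  mid-interval gestational age, with triplicate averaging and
  configurable pairing policies.
- **Conditional velocity** — conditional SD scores
  `cSDS = (Z2 − r·Z1)/√(1 − r²)` that adjust serial distance-standard
  Z-scores for regression to the mean, with pluggable correlation
  models (parametric exponential family or a user correlation table).
- **Chart construction** — exhaustive Royston–Altman fractional
  polynomial regression of the mean, absolute-residual regression of
  the SD, and goodness-of-fit diagnostics (per-week empirical vs fitted
  centiles, residual q-q data, centile coverage).
- **Synthetic cohorts** — a protocol-faithful longitudinal cohort
  simulator (scan every 5 ± 1 weeks in six visit windows, 4–6 scans per
  fetus, masked triplicates) with known ground truth, so the whole
  pipeline is testable without any data download.

## The model

For each biometry the standard is a pair of fractional polynomial (FP)
curves in gestational age *t* (weeks):

    mean(t) = b0 + b1·H1(t/10) + b2·H2(t/10)        [mm/wk]
    sd(t)   = c0 + c1·G(t or t/10)                  [mm/wk]

where the basis terms H, G are powers from {−2, −1, −0.5, 0, 0.5, 1, 2,
3}, a power of 0 denotes ln x and a repeated power p contributes x^p and
x^p·ln x. Centiles follow the normal model `mean + z·sd` with
z = ±1.88, ±1.645, ±1.28 and 0 for the 3rd/5th/10th/50th/90th/95th/97th
centiles, valid over 16–38 completed weeks. The chart-construction
pipeline fits the same families to paired increments by least squares
over every admissible power combination.

## A worked example

```python
>>> import fetalvelocity as fv
>>> fv.mean_velocity("HC", 16)          # median HC gain at 16 weeks
12.236374130260764
>>> fv.centile_velocity("HC", 20, 3)    # 3rd-centile envelope at 20 weeks
10.043440614442614
>>> fv.zscore_velocity("HC", 20, 10.5)  # an observed 10.5 mm/wk scores
-1.4306870550149016
>>> fv.peak_velocity("BPD")             # BPD peaks mid-trimester
(19.37090207462507, 3.2432026504764093)
>>> fv.percent_of_term_size("HC", 38, 334.0)
0.8180000549971459
```

The first number says the median fetus gains ~12.2 mm of head
circumference per week at 16 weeks; the Z-score of −1.43 means
10.5 mm/wk at 20 weeks is slow but still inside the 3rd–97th centile
envelope; head growth near term has fallen to 0.8% of the attained term
size per week. `examples/` holds one short narrative script per
capability (chart evaluation, scan scoring, conditional assessment,
simulate-and-refit); each prints the numbers it computes and what they
mean. The same operations are available from the shell:

```
fetalvelocity tables -o charts/          # the five published chart CSVs
fetalvelocity velocity scans.csv -o v.csv
fetalvelocity simulate -n 500 --seed 1 -o scans.csv
```

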