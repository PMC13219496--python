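# cici-cal

Calibration of Hi-C contact signals against absolute chromosomal contact
frequencies, tested end to end on a synthetic generator of engineered-loop
cell populations.

## The problem

Hi-C reports *relative* ligation counts between genomic loci; it does not by
itself say in what fraction of cells two loci actually touch. Chemically
induced chromosomal interactions (CICI) make that calibration possible: a
rapamycin-dependent dimerization tethers two tagged loci, creating a stable
loop in a known, tunable fraction *p* of cells. Imaging the two fluorescent
dots gives an **absolute contact frequency** — the fraction of cells whose
dots stay co-localized (x–y distance < 0.4 µm) across three consecutive
frames — and mixing fixed induced/uninduced cells at ratio *r* dials that
frequency to `p(r) = r·p₊ + (1−r)·p₋`. Regressing the Hi-C junction signal
*s* on the measured frequency *f*,

    s = m·f + b        (OLS per locus pair)

yields a slope *m* that converts any Hi-C signal into a fraction of cells in
contact, `f = s/m̄` with `m̄` the average slope of the intra-chromosomal
pairs. Around this sit the questions the package quantifies: how small a *p*
is detectable at ~18 M contacts (3-SD junction-window rule), whether intra-
and inter-chromosomal pairs calibrate with the same slope, and whether a
static loop creates a TAD-like insulation signature.

Everything runs on a bundled synthetic model — an isotropic Gaussian chain
with RMS separation `R(s) = R0·(s/s0)^ν` (R0 = 300 nm at s0 = 40 kb,
ν = 0.5), a 100 nm tether scale for looped pairs, a 250 nm Hi-C capture
radius, Ornstein–Uhlenbeck dot dynamics for time-lapse imaging, and
multinomial read sampling with per-bin biases — so every estimator can be
checked against known ground truth. The same functions apply unchanged to
real matrices supplied in the package's plain-text COO format.

## Worked example

```python
from cici_cal import *
from cici_cal.presets import demo_bins, demo_model, demo_pairs
from cici_cal.hicsim import JunctionSpec

model, bins, pair = demo_model(), demo_bins(seed=7), demo_pairs()["pair1"]

# image 2000 cells, 65% of which carry the loop
pop = sample_population(pair, 0.65, 2000, model, seed=11)
tracks = simulate_timelapse(pop, seed=12)
est = continuous_contact_frequency(tracks)          # threshold 0.4 um, 3 frames
print(est.p_hat, est.ci_low, est.ci_high)
# 0.670  0.641  0.698    (true p = 0.65 inside the Wilson interval)

# a ~18M-contact Hi-C library of the same population, processed
m = simulate_hic(bins, [JunctionSpec(pair, 0.65)], model, 18_000_000, seed=1)
m, = normalize_to_smallest([m])
m = restriction_site_correction(m)
kr_balance(m)
print(junction_signal(m, pair, use_weights=True))
# 0.0369   (mean balanced signal, 30 kb x 30 kb window at the junction)
```

The numbered scripts under `analysis/` run the full study on the demo
conditions and print their findings; run them in order:

```sh
python analysis/01_imaging_contact_frequency.py   # estimator vs ground truth
python analysis/02_mixture_titration.py           # frequency linear in ratio
python analysis/03_hic_calibration.py             # signal vs frequency fits
python analysis/04_distance_decay_conversion.py   # genome-wide frequencies
python analysis/05_detection_limit.py             # 3-SD sensitivity analysis
python analysis/06_insulation_and_footprint.py    # no-TAD check, footprints
```

Representative output (step 03): slopes 0.0550/0.0541/0.0575 for the three
pairs, all R² > 0.99, inter/intra slope ratio 0.96 — junction signal is
linear in contact frequency with no intra/inter bias. Step 05 finds the 3-SD
rule detects loops in as few as 2% of cells at 18 M contacts. Tables land in
`results/`.

A `cici-cal` CLI wraps the same functions
(`cici-cal simulate | imaging-freq | hic-process | calibrate | run-all`);
`cici-cal run-all --config configs/demo.json --out out/` reproduces the whole
pipeline from one config.

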