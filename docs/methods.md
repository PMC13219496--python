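# Methods

## The generative model

The package treats a cell population as a two-component mixture for each
engineered locus pair. A fraction *p* of cells ("looped") hold the two loci
tethered; the rest ("free") carry them at their native polymer separation.
All 3D separation vectors are isotropic Gaussian:

| state | per-axis sd (nm) | rationale |
|---|---|---|
| looped | `tether_rms/√3`, tether_rms = 100 | tethered pairs must sit far below the 0.4 µm imaging threshold, matching the ~62–69% continuous co-localization observed under full induction |
| free, intra | `R(s)/√3`, `R(s) = R0·(s/s0)^ν` | Gaussian chain anchored at R0 = 300 nm for s0 = 40 kb (midpoint of the 250–350 nm range measured for that separation in budding yeast); ν = 0.5 is the ideal-chain exponent |
| free, inter | `inter_rms/√3`, inter_rms = 1400 | order of the yeast nuclear diameter; gives a percent-level continuous-contact background |

Hi-C capture is a hard sphere of radius `r_c` (default 250 nm, midpoint of
the 100–400 nm estimates): the capture probability of a pair with per-axis
sd σ is the Maxwell CDF `erf(x) − (2x/√π)e^(−x²)`, `x = r_c/(σ√2)`. The x–y
projected distance used by the imaging estimator follows the Rayleigh CDF
`1 − exp(−t²/2σ²)`. These two closed forms are the package's analytic
oracles; both are verified against brute-force Monte Carlo in the tests.

All parameters are fields of `PolymerModel` and configurable; defaults were
fixed once from the ranges above and are never tuned per analysis.

## Demo study conditions

The bundled conditions mirror the experimental design at desk scale: a
four-chromosome 3.3 Mb genome at 10 kb bins (yeast-like proportions, small
enough that every analysis runs in seconds), two intra-chromosomal pairs at
400 kb separation plus one inter-chromosomal pair, induced loop fraction
p₊ = 0.65 over a stable background p₋ = 0.02, titration ratios
{0, 0.25, 0.5, 0.75, 1}, 2000 imaged cells per condition, and 18 M contacts
per Hi-C library with two replicates.

The 400 kb intra separation is a deliberate choice: under the chain model
plus localization noise it produces ~23% single-frame co-localization and
~1% three-frame continuous background in uninduced cells — the regime the
continuous-contact criterion exists to handle (observed uninduced ranges are
16–26% per frame and 0.6–4% continuous).

## Imaging estimator

Dot tracks evolve per axis as a stationary Ornstein–Uhlenbeck process with
relaxation time τ = 60 s, so the 240 s frame interval leaves consecutive
frames nearly independent (autocorrelation e^(−4) ≈ 0.02); transient free
encounters therefore almost never persist three frames. Observed coordinates
add N(0, 50 nm) localization noise per axis per dot, and each dot is
detected per frame with probability 0.9. τ for uninduced encounter kinetics
is not experimentally constrained; it is a modeling choice exposed in the
config.

A cell is **in contact** iff both dots are detected and their x–y distance
is strictly below 0.4 µm in all k = 3 consecutive frames (the first three by
default; an any-window mode exists). A cell enters the denominator only if
both dots are detected in all k frames; a lenient mode (co-localization
required only on detected frames, ≥ 2 of them) tolerates dot loss but is not
the default, since the reference definition is ambiguous on this point. The
95% interval is Wilson (Clopper–Pearson available). Note the estimator
measures *continuous co-localization*, which for close intra pairs includes
a transient-encounter contribution on top of the loop fraction; on the demo
inter pair this bias is ≈ 0.002 and negligible against binomial noise.

## Hi-C simulation and processing

Expected bin-pair weights multiply the capture probability (junction square:
`p·P_loop + (1−p)·P_free` over a ±1-bin square emulating the ~10 kb arrays),
a log-normal per-bin bias (log-sd 0.2, drawn per library; replicates of one
family can share a vector), and restriction-site density (Poisson, mean
39 sites/10 kb as for a 4-bp cutter). Counts are multinomial with the exact
library total. Diagonal bins use an effective separation of half a bin.

Processing follows the reference order: merge replicates → scale to the
smallest library total (a downsampling mode exists) → divide by
site-density products (total-preserving, zero-site bins masked) →
Knight–Ruiz balancing. KR is the inner-outer Newton/conjugate-gradient
iteration of the published fast-balancing algorithm, run to a row-sum CV
≤ 1e−6 and normalized to mean balanced row sum 1; non-convergence raises
with diagnostics rather than returning partial weights.

**Junction signal** is the mean over the 30 kb × 30 kb window (±15 kb)
centered on the junction bin pair, on balanced counts. The ±10 kb reading of
the window definition is available via `half_window_bp=10_000`; windows at
chromosome edges are clipped with a warning.

**Difference significance**: the plus−minus map in a ±100 kb span around the
junction is compared against a background of bin pairs at the same genomic
separation on the same chromosome (intra) or the whole chromosome pair
(inter), excluding pairs jointly within 100 kb of both junction loci (pairs
sharing only one coordinate with the junction neighbourhood carry no loop
signal and remain background — on a small genome excluding them entirely
would empty the strata). Significance is difference > mean + 3·SD; contiguous
significant runs through the junction give the footprint extents.

**Insulation** is the multi-depth diamond score (depths 30–100 kb, step
10 kb): per depth the mean of `[i−d, i) × (i, i+d]`, aggregated as the mean
over depths of log2(score / chromosome-wide mean), undefined within
max-depth of chromosome ends. The looped-vs-free comparison runs on
read-count-normalized (unbalanced) maps, matching how the insulation
comparison is defined for this design; balancing would redistribute the
junction's row-sum excess into the anchor neighbourhood and register a
spurious insulation shift that is an artifact of the correction, not of
chromatin structure.

## Calibration

Fits are unweighted OLS of junction signal on measured frequency with free
intercept, replicates entering as individual points (weighted fits on means
are opt-in). Two-point designs use the closed-form interpolation.
Background subtraction (the 0%-ratio signal over the same window) may
produce negative signals; they are retained. The conversion default is
through-origin `f = s/m̄`; because the free-encounter baseline gives the
fits a small positive intercept, the intercept-subtracting mode
`f = (s−b̄)/m̄` is computed alongside wherever curves are written, and is
the mode used in the round-trip recovery test. Balanced signals are on the
mean-row-sum-1 scale, so signals from libraries of different depth are
directly comparable after balancing.

The inter/intra slope-ratio test resamples replicate points within each
frequency level of each pair (2000 bootstrap draws, percentile 95% CI).

The detection limit operationalizes sensitivity as: junction 30 kb window
mean of the plus−minus map (after normalization and site correction)
exceeding the mean + 3·SD of window means at matched positions; a loop
fraction is detected when at least half of 10 replicate library pairs are
significant, and the limit is the smallest detected grid point.

## Numerical and design notes

- Every stochastic function takes an explicit seed (or derives one from a
  single pipeline seed via `SeedSequence.spawn` in fixed stage order);
  pipeline summaries are byte-identical across runs and embed a config hash.
- Balancing introduces a mild concavity in junction signal vs p at high loop
  strength on small genomes (the loop inflates its anchors' row sums, so KR
  suppresses their weights). Within the titration range (f ≤ 0.65) the
  effect stays inside the linearity the analyses assert (R² > 0.99,
  round-trip bias < 0.03); it grows if calibration is extrapolated to p = 1.
- The two-block insulation oracle has a two-bin tie at the boundary because
  the diamond excludes the central bin asymmetrically; tests accept either.
- Matrices are stored dense in memory (≲ 2000 bins is the intended scale);
  the on-disk format is sparse upper-triangle COO TSV plus a bins TSV.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure the analyses rely on —
two-component mixtures, distance decay, multiplicative biases, read
sampling, imaging noise and dropout, transient-encounter dynamics — so
passing tests demonstrate that the estimators and the calibration logic are
correct and well-calibrated under that model. It does not emulate
loop-extrusion or polymer dynamics beyond the Gaussian chain, crosslinking
chemistry (capture is a hard sphere; real capture radii are soft and
condition-dependent), chromatin-state-dependent biases, or segmental
heterogeneity of real genomes. Absolute numbers that depend on those
choices — e.g. the ~60% calibrated contact frequency at 40 kb, or the 2%
detection limit (real data: detection in <10% of cells) — characterize the
model, not the organism; the *properties* (linearity, unbiasedness,
locality of the loop footprint, insulation invariance) are the transferable
results.
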