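# Methods

This note documents the models, statistics and numerical choices behind
`riboreporter`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic data do and do not
establish about real plate runs.

## Reporter time-course preprocessing

A plate run yields, per well, luminescence (RLU) and OD600 on a shared
nominal grid (default 20-min spacing; runs of 30–60 h give ≥ 90 points).
Processing order:

1. **Blank subtraction.** The per-timepoint mean over all blank wells is
   subtracted from every sample well — from luminescence *and* from OD,
   since the medium both luminesces slightly and absorbs at 600 nm.
   Negative corrected values are retained by default (`negative_policy=
   "keep"`): clipping at zero would bias upward every summation statistic
   whose signal hovers near background. A `clip_zero` policy exists for
   display.
2. **Growth gating.** Each well is cropped to start at its *first* reading
   with OD600 ≥ `od_start_threshold` (default 0.1), on its own clock.
   Wells of one comparison may therefore start at different absolute
   times; all downstream statistics align wells by post-crop index, not by
   absolute time. Wells that never reach the gate are emptied with a
   warning and excluded.
3. **Length harmonization.** All wells of one comparison are truncated to
   the minimum post-crop length, keeping each series' first points, so
   total-activity sums use the same number of timepoints everywhere.
4. **Plateau OD.** Stationary-phase biomass is summarized as the mean of
   the last `plateau_tail_points` OD readings (default 58). Shorter series
   are averaged whole, with a warning. A constant tail returns the
   constant exactly (the mean is short-circuited to avoid accumulating
   one-ulp rounding in the sum).

No interpolation or resampling is ever performed: all wells of a plate are
measured on one instrument schedule, and resampling would silently change
the summation statistic. Files with unequal grids load with a warning and
are the user's responsibility.

## Fold induction and its uncertainty

Per well, total activity is `F = Σ_{i=m..n} lum(i)/OD(i)` over post-crop
indices; `m` defaults to the first post-crop, post-harmonization index and
`n` to the last. Fold induction compares the triplicate means,
`FI = av(F_x)/av(F_0)` — with-ligand over without-ligand, so induction
gives FI > 1. Uncertainty combines the two triplicates' relative sample
SDs in quadrature, `σ_FI = FI·sqrt((σ_F0/avF_0)² + (σ_Fx/avF_x)²)`, the
first-order propagation for a ratio of independent quantities. This is
accurate to a few percent for coefficients of variation up to ~0.1, which
the tests verify against a 10,000-draw lognormal Monte-Carlo ratio
distribution. SDs are n−1 sample SDs throughout; groups of fewer than two
wells are rejected (the SD is undefined), and a non-positive
without-ligand mean total makes FI undefined and raises.

Division by OD uses a validity floor of 1e−4: ODs below it are treated as
errors rather than clipped, because clipping would produce unbounded
lum/OD spikes that dominate the sums.

**Peak expression** is located on *raw* luminescence and then divided by
the same timepoint's OD — this differs from the maximum of the normalized
series and is the primary definition here; ties break to the earliest
timepoint. **Average expression** is the ratio of means (mean of all lum
readings over mean of all OD readings across the triplicate), not the mean
of per-timepoint ratios, which would up-weight low-OD early points.

## Above-background windows

For constructs whose signal is close to background, FI is computed on a
restricted window: a rolling block pools `k` consecutive timepoints across
the triplicate (k chosen so a block holds ~`rolling_points` readings; the
default 9 means 3 timepoints × 3 wells ≈ 1 h at 20-min sampling), and a
block is above background when the mean of its nine readings exceeds their
sample SD. Blocks advance one timepoint at a time — overlapping blocks are
the conservative reading and maximize temporal resolution — and maximal
runs of above-background blocks must span at least `persistence_hours`
(default 2 h) of grid time to count. Windows are reported as
`(start_time, end_time)` and can also be supplied manually in
`"22h00-29h20"` form. Restricting to the full range reproduces the
unrestricted FI bit-for-bit.

## The plate simulator

The simulator produces the statistical structure the analysis assumes,
with defaults chosen to look like a typical assay of this kind:

| parameter | default | meaning |
|---|---|---|
| growth | lag 2 h, rate 0.5 h⁻¹, K = 1.0, OD₀ = 0.06 | logistic biomass |
| riboswitch | leak 0.04, K_D 50 µM, Hill 2 | dose response to intracellular F⁻ |
| fluoride | import 20 µM·h⁻¹·mM⁻¹, export Vmax 400 µM·h⁻¹, Km 100 µM, pump τ 1 h | intracellular dynamics |
| noise | lum CV 5 %, OD SD 0.003 | multiplicative lognormal / additive |
| geometry | triplicates at 0/8/16/31/62 mM + 3 blanks, 30 h at 20 min | 91 points per well |

Luminescence is `promoter_strength × response(F_in) × OD × lognormal
noise`, zero before a 2-h onset; i.e. expression is per-cell rate times
biomass — the simplest model under which lum/OD normalization is
meaningful. No luciferase maturation or decay kinetics are modeled.

Intracellular fluoride follows `dF/dt = k_imp·F_media − Vmax·E(t)·F/(Km+F)`
with `E(t) = 1 − exp(−t/τ)`: import is passive and proportional to the
media concentration, export is saturable, and export *capacity* ramps up
with a delay, as a cell inducing its fluoride exporters would. Two
consequences match the qualitative biology: the media concentration needed
to hold intracellular fluoride near the ~50 µM K_D is in the mM range, and
the solution overshoots before relaxing — a damped excursion that shows up
as non-monotone expression. The rate constants are not measured
quantities; they were chosen once to produce those two features and are
exposed as config. Integration uses `scipy.integrate.solve_ivp` (RK45,
rtol 1e−8), cross-checked in tests against a fine-step explicit Euler
oracle. An optional `toxicity` factor scales growth rate down in
proportion to mean relative expression (OFF by default) to illustrate
reporter-burden collapse.

`config_for_induction_ratio(R)` fixes the leak and solves the saturating
ON/OFF expression ratio to equal `R`, so parameter-recovery studies have a
known truth; with 62 mM media the dose response saturates within the first
hour and the pipeline's FI estimate recovers `R` with < 5 % bias at 5 %
measurement CV.

What passing simulator-based tests does **not** show: real wells have
correlated noise (position/temperature gradients), condensation artifacts,
luciferase substrate depletion, and host-specific riboswitch behavior;
none of these are emulated, so recovery results here bound estimator
behavior under the stated noise model only.

## Cloning arithmetic

Coordinates are 0-based, half-open, top strand; a cut at coordinate c
separates `seq[:c]` from `seq[c:]`. Enzyme definitions (recognition in
IUPAC alphabet, top/bottom cut offsets measured from the recognition start
on the enzyme's reading strand) ship as an editable TSV derived from
REBASE; a custom table can be supplied. Site scanning expands IUPAC codes
to character classes and uses overlapping regex lookahead on both strands;
palindromic recognitions are reported once; circular scanning wraps the
origin. Reverse-strand cuts mirror through the match (our top-strand cut
is the enzyme's bottom-strand offset). Digests are computed from
top-strand cut coordinates, which conserves total fragment length by
construction — and the tests assert it on random backbones.

Overlap derivation for a double digestion requires each enzyme to cut
exactly once, excises between the cuts, and returns the flanking backbone
substrings (defaults 17 nt left, 21 nt right; the right length is a
per-call parameter since 21–24 nt are all workable). Translational fusion
appends the chosen start codon and the first 2 nt of the reporter's second
codon to the regulatory element, regenerating the junction the type IIS
cut produces; the design report verifies a zero-nucleotide gap and that
the fused ORF translates to the reporter protein from codon 2 onward.
Insert validation fails inserts under 40 bp — short fragments (18–21 bp)
are known to assemble poorly, and 40 bp is a deliberately conservative
documented floor — and warns about internal backbone-enzyme sites, which
would need domestication.

The real reporter plasmid's full sequence is not bundled; all tests run on
synthetic backbones engineered with the same site architecture (two MCSs
flanking the promoter slot, the type IIS recognition placed on the reverse
strand inside reporter codons 5–7 so its top-strand cut lands immediately
after the 2nd nucleotide of codon 2).

## Reproducibility

All randomness flows through `numpy.random.default_rng(seed)`; a fixed
seed makes simulated plates byte-identical on disk (floats are written at
repr precision and read back with round-trip parsing). Pipeline bundles
embed a hash of the analysis-relevant configuration plus the seed, and
re-running a config writes byte-identical outputs. `scripts/acceptance.py`
recomputes every headline quantity from fresh simulations at the problem
sizes stated in its docstrings (50 seeds per recovery ratio, 10,000
Monte-Carlo draws, 100 random backbones), sizes chosen to keep the whole
script under a few seconds on one CPU while leaving sampling error well
inside the asserted margins.
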