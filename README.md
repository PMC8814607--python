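# riboreporter

Analysis toolkit for **riboswitch-dampened luciferase reporter assays** in
bacteria, aimed at labs that use a fluoride riboswitch (or any inducible
5′UTR element) between a potent promoter and a `luxCDABE` reporter to keep
expression at viable levels during cloning and to re-induce it on demand.
The package covers the three things such an experiment needs on the
computational side:

1. **Time-course analysis** of microplate luminescence/OD600 runs
   (20-min sampling over 30–60 h): per-timepoint blank subtraction,
   per-well cropping at the OD600 = 0.1 growth gate, harmonization of
   timepoint counts across compared wells, plateau-OD estimation, and the
   fold-induction statistic with propagated uncertainty.
2. **A synthetic plate simulator** — logistic growth, a mechanistic
   intracellular-fluoride model (passive import, saturable export whose
   capacity ramps up with a delay, hence µM-range riboswitch K_D but
   mM-range media thresholds and a transient overshoot), a Hill-type
   riboswitch dose response, and multiplicative measurement noise — so the
   entire pipeline is testable without instrument data.
3. **Cloning arithmetic** for the reporter backbone: IUPAC restriction-site
   scanning, type IIS cut-position computation into the reporter's second
   codon, Gibson-assembly overlap derivation (17 nt left / 21–24 nt right),
   scar-free translational-fusion design with a free choice of start codon,
   and insert validation (very short inserts assemble poorly and are
   rejected).

## The statistic

For a technical triplicate without ligand and one with `x` mM fluoride,
each well's OD-normalized luminescence is summed over the shared post-crop
timepoints *m..n*:

```
F = Σ_{i=m}^{n} (lum/OD)(i)          per well
FI = av(F_x) / av(F_0)               fold induction (with / without ligand)
σ_FI = FI · sqrt( (σ_F0/av F_0)² + (σ_Fx/av F_x)² )
```

Standard deviations are sample (n−1) SDs of the per-well totals. For
constructs whose signal sits close to background, the summation window can
be restricted to the span where the 1-h rolling mean of triplicate
luminescence (nine data points at 20-min sampling) exceeds its SD for at
least 2 h in a row; windows like `22h00-29h20` can also be supplied
directly. Peak expression (max raw RLU divided by the same timepoint's OD)
and average expression (ratio of triplicate means, not mean of ratios) are
reported alongside.

## Worked example

Simulate a plate whose riboswitch is programmed with a 25-fold ON/OFF
ratio, then analyze it:

```python
from riboreporter import ReporterAssay, config_for_induction_ratio, write_plate

cfg = config_for_induction_ratio(25.0, fluoride_mM=(0.0, 31.0, 62.0), seed=42)
write_plate(cfg, "plate.csv", "layout.yaml")

res = ReporterAssay.from_csv("plate.csv", "layout.yaml").fit()
print(res.summary())
```

```
Riboswitch reporter assay — fold induction of total luciferase activity

       group0         groupx  ligand_mM    FI  sigma_FI  m  n
P1_FRS_lux_F0 P1_FRS_lux_F31         31 25.08    0.1918  0 80
P1_FRS_lux_F0 P1_FRS_lux_F62         62 25.17    0.2872  0 80

well replicate_group  crop_start_min  n_points  plateau_od
  A1   P1_FRS_lux_F0             200        81      0.9817
  A2   P1_FRS_lux_F0             200        81      0.9822
  ...
```

Both fluoride concentrations sit far above the dose-response midpoint, so
the estimated fold inductions (25.08 ± 0.19 and 25.17 ± 0.29) recover the
programmed 25-fold ratio within noise. Wells enter the analysis once they
reach OD600 = 0.1 (here at 200 min), all series are truncated to the
shortest post-crop length (81 points, so the summation runs over indices
m=0..n=80), and the plateau OD (~0.98) is the mean of the last 58 OD
readings.

The same workflow is available from the shell:

```sh
riboreporter simulate --config sim.yaml -o plate.csv --layout-out layout.yaml --seed 42
riboreporter validate --data plate.csv --layout layout.yaml
riboreporter analyze  --data plate.csv --layout layout.yaml -o results/
riboreporter design fuse --element el.fa --start GTG --luxc luxc.fa -o insert.fa
```

Exit codes: 0 ok, 1 data/format error, 2 configuration error.

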