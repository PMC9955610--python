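# bcivalidate

A validation toolkit for morphometric **body-condition indices (BCIs)**
in reptiles and other vertebrates, built around the workflow used to
evaluate condition indices in a large invasive lizard population:
compute the standard family of mass–length indices, detect allometric
size classes with segmented regression, test the statistical
assumptions the indices rely on, and measure how well each index
actually tracks dissected fat stores.

## The problem

Field ecologists estimate an animal's energy reserves ("condition")
from its body mass *M* and a length measurement *L* (snout–vent length,
SVL, for lizards), because direct fat measurement requires sacrificing
the animal. Dozens of indices exist; whether any of them tracks real
fat stores in a given population is an empirical question. When
necropsy data with dissected coelomic fat masses *F* are available,
each index can be validated against fat-store measures — and checked
for the size bias that makes an index track *length* rather than
*condition*.

## What the package computes

**Eleven condition indices** per animal, from the classical ratio
family through residual (regression) indices to the scaled mass index:

- ratio indices `M/L`, `M/L²` (Quetelet), `M/L³` (Fulton's K),
  `M/prM` (relative), `ln M/ln L`, `ln M/ln prM`;
- vertical residuals of OLS, major-axis (MA) and standardized
  major-axis (SMA) regressions of ln *M* on ln *L*, and of the SMA
  regression of *M* on *L*³;
- the scaled mass index SMI = *M*·(L₀/Lᵢ)^b, with the scaling exponent
  b from the SMA fit of ln *M* on ln *L* and L₀ the mean length.

**Three fat-store measures** to validate them against: percent fat
(100·F/M), scaled fat (the SMI transformation applied to *F*), and
residual fat (SMA residuals of ln *F* on ln *L*).

**Type II regression engines.** Allometric slopes are estimated by SMA
(slope = sign(r)·sd(y)/sd(x)) and MA as well as OLS, with 95%
confidence intervals and a likelihood-ratio test for a common SMA
slope across groups (sexes, size classes).

**Size-class detection.** The raw mass–length relationship is fit with
a broken-line GLM: the mean is continuous piecewise-linear in SVL with
breakpoints ψ estimated by iterative linearization, and the number of
breakpoints is chosen by BIC over k = 0…10 with a Bonferroni-corrected
significance guard on the slope changes. Size classes are the
half-open intervals between breakpoints.

**Assumption battery.** Ramsey's RESET (linearity), Breusch–Pagan
(homoscedasticity), Shapiro–Wilk (normality of residuals), D'Agostino
skewness and Anscombe–Glynn kurtosis, plus the Fulton slope check
(does the SMA slope CI contain the isometric value 3.0).

**Validation report.** Kendall's τ and OLS adjusted r² of every index
against every fat measure and against SVL, a BCI × BCI τ correlation
matrix, and a ranking of indices by adjusted r² against percent fat
with size-bias flags.

**Synthetic data generator.** Because necropsy datasets are rarely
public, the package ships a generator that reproduces the statistical
structure such data exhibit — ln-mass vs ln-SVL allometry with SMA
slope ≈ 3.13 at correlation ≈ 0.995, steep but weakly correlated fat
allometry (slope ≈ 6.91, r² ≈ 0.37), a three-segment raw-scale
mass–length curve with breakpoints near 20.2 and 30.0 cm, occasional
zero-fat animals, and the quality flags the cleaning stage removes.
Every analysis stage is therefore testable end-to-end with no
downloads.

## Worked example

Simulate a raw intake dataset of 883 animals with the segmented
mass–length curve and run the whole pipeline:

```bash
bcivalidate run --seed 42 --n 883 --out out/
```

or equivalently in Python:

```python
from bcivalidate import GeneratorConfig, SegmentedMassModel, RunConfig, run_full

cfg = RunConfig(
    generator=GeneratorConfig(n=883, seed=42, mass_model=SegmentedMassModel()),
    out_dir="out",
)
bundle = run_full(cfg)

report = bundle["clean"][1]
print(report.n_retained, dict(report.excluded))
model = bundle["size_classes"]
print(model.k, model.psi, model.psi_se)
```

which prints

```
458 {'incomplete_necropsy': 8, 'unknown_sex': 8, 'abnormal': 8,
     'days_held_gt_max': 392, 'zero_fat': 9}
2 [20.0  29.6] [0.38 0.26]
```

Reading: of 883 simulated animals, 458 survive the exclusion rules
(most are dropped for spending more than 4 days in captivity before
necropsy — the dominant exclusion in real intake streams); the
breakpoint selector then recovers a two-breakpoint (three size class)
mass–length curve, with breakpoint estimates 20.0 ± 0.38 cm and
29.6 ± 0.26 cm around the generating values 20.2 and 30.0 cm.
`out/` now holds the cleaning report, the breakpoints with their BIC
trace, the per-animal index table, the assumption batteries and the
validation reports (whole-dataset and per size class) as TSV/JSON,
plus a diagnostic plot of binned mass means against the allometric and
segmented curves.

Under this generator fat is only weakly coupled to mass at a given
length, and the validation report shows what weak coupling looks like:
the best index explains only a few percent of the variation in percent
fat and most indices are flagged as size-biased — exactly the pattern
that motivates validating an index before trusting it.

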