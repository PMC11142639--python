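# gocquant

Quantification of somatic–germline contact in the ovarian follicle.

A growing mammalian oocyte stays in physical contact with its surrounding
granulosa cells through **transzonal projections (TZPs)** — thin,
filopodium-like processes that the granulosa cells extend across the
~7 µm zona pellucida to the oocyte surface, where adherens junctions and
gap junctions form. Experiments that perturb this contact (for example,
depleting a signalling factor in the granulosa cells) are read out by a
characteristic battery of image-derived measurements. `gocquant`
implements that battery as a reusable, tested pipeline:

* **Equatorial TZP counting** — sample the fluorescence along the closed
  circle in the middle of the zona pellucida of an equatorial confocal
  section; every sample that exceeds the oocyte-cytoplasm background and is
  strictly higher than both circular neighbours counts as one TZP; the
  count is normalized to the oocyte diameter (TZPs/µm).
* **3D morphometrics** — membrane-based cell segmentation with a 100 µm³
  volume filter; cell volume *V*, surface area *A* (marching-cubes mesh),
  and Wadell sphericity Ψ = π¹ᐟ³(6V)²ᐟ³/A; TZP traces as 3D polylines with
  arc length *L*, mean width (floored at 0.1 µm), discretization into
  evenly spaced spots, and the orientation statistic
  **Δ = d(start) − d(tip)** (signed distance to the oocyte surface;
  Δ > 0 means the tip points toward the oocyte).
* **FRAP coupling** — gap-junctional transfer measured as the recovery
  ratio R = F(final)/F(pre-bleach) of calcein fluorescence in a bleached
  oocyte, with a two-compartment exchange simulator
  (R(t) = 1 − b·e^(−kt)) and a least-squares rate fit.
* **Study statistics** — EdU labelling fractions, relative qPCR expression
  by 2^(−ΔΔCt) with *Rpl19* normalization, percent change
  100·(mean_ref − mean_test)/mean_ref, mean ± SEM summaries, and one-/
  two-sample two-tailed t-tests.
* **Synthetic ground truth** — a generator for 2D equatorial sections, 3D
  complexes, and two-group experiments with imposed effect sizes, so every
  stage is validated against exact known answers.

## Worked example

```python
from gocquant import (GOCSpec, generate_goc_2d, count_equatorial_tzps,
                      GroupEffectSpec, simulate_group_experiment,
                      experiment_table, t_test, summarize_group,
                      percent_change, simulate_frap, normalize_trace)

# 1. a noisy synthetic equatorial section, counted blind against its truth
spec = GOCSpec(n_tzp=40, noise_sd=30.0, seed=42)
image, truth = generate_goc_2d(spec)
result = count_equatorial_tzps(image, truth.oocyte)
print(f"TZP count: {result.raw_count} (truth {truth.n_tzp}), "
      f"{result.normalized_count:.3f} per um of oocyte diameter")

# 2. a two-group experiment with an imposed -35% TZPs-per-cell effect
geff = GroupEffectSpec(n_per_group=25, effect_tzp_count=-0.35, seed=42)
table = experiment_table(simulate_group_experiment(geff))
ctrl = table[table.group == "control"]["n_tzp"]
treat = table[table.group == "treated"]["n_tzp"]
for vals, g in ((ctrl, "control"), (treat, "treated")):
    s = summarize_group(vals, g)
    print(f"{s.label}: {s.mean:.2f} +/- {s.sem:.2f} TZPs per cell (n={s.n})")
report = t_test(ctrl, treat)
print(f"percent change: {report.percent_change:.1f}%  "
      f"t={report.t:.2f}, df={report.df:.0f}, p={report.p:.2g}")

# 3. FRAP closed form
R = normalize_trace(simulate_frap(k=0.1, bleach_fraction=1.0)).recovery_ratio
print(f"FRAP recovery ratio (k=0.1/s, full bleach, 60 s): {R:.4f}")
print(f"printed-mean check: {percent_change(323.2, 242.6):.1f}% volume decrease")
```

prints

```
TZP count: 40 (truth 40), 0.667 per um of oocyte diameter
control: 16.40 +/- 0.76 TZPs per cell (n=25)
treated: 10.16 +/- 0.62 TZPs per cell (n=25)
percent change: 38.0%  t=6.35, df=48, p=7.3e-08
FRAP recovery ratio (k=0.1/s, full bleach, 60 s): 0.9975
printed-mean check: 24.9% volume decrease
```

The counter recovers the true 40 TZPs despite read noise at 20% of the
signal contrast; the imposed 35% reduction is recovered (38% in this
single replicate, 35.3% averaged over 100 replicates) and is highly
significant at n = 25 cells per group; the FRAP ratio matches the
analytic value 1 − e⁻⁶ = 0.9975.

## Command line

Every stage is also a `gocquant` subcommand:

```sh
gocquant simulate --seed 1 --out-dir sim/           # image + truth + SWC
gocquant count-tzp --image sim/equatorial.tif \
    --center 51.15,51.15 --radius 30 --zona 7 --out counts.csv
gocquant filaments --swc traces.swc --oocyte 0,0,0,30 --out metrics.csv
gocquant cells --image stack.tif --channel gfp --threshold 75 --out cells.csv
gocquant frap --traces traces.csv --out frap.csv
gocquant ddct --ct ct.csv --ref Rpl19 --calibrator ctrl --out folds.csv
gocquant stats --table metrics.csv --group-col group --value-col n_tzp \
    --test two_sample --out stats.csv
gocquant run --out-dir demo/ --seed 17              # full demo pipeline
```

`gocquant run` executes simulate → count → group experiment → FRAP →
statistics from one YAML/JSON config; outputs are stamped with the config
hash and package version.

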