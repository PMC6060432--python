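# glucofret

Quantification of intracellular glucose dynamics in neurons from
ratiometric FRET biosensor time-lapse movies, plus single-cell RT-mPCR
occurrence statistics — with a calibrated synthetic-data generator so
the whole pipeline is testable end to end without any raw recordings.

## The problem

Genetically encoded FRET glucose sensors (the FLII12Pglu family) report
cytosolic glucose as a YFP/CFP emission ratio R. In acute-slice
experiments, neurons expressing the sensor are imaged every 15 s while
the bath glucose is stepped (2.5 → 10 mM to probe uptake, 2.5 → 0.2 mM
to probe elimination) or metabolic inhibitors are applied (IAA to block
glycolysis, 6-AN to block the pentose phosphate pathway). Changes are
expressed per cell as the baseline-relative percent ratio
(R − R₀)/R₀ × 100, with R₀ the mean ratio over the 10 min control
baseline. Such recordings are used to compare glucose handling between
wild-type (non-Tg) and Alzheimer-model (3xTg-AD) pyramidal cells; the
same cells are profiled by single-cell multiplex RT-PCR for a 13-gene
panel of glucose-metabolism transcripts, and per-gene detection
frequencies are compared between genotypes by Fisher's exact test.

This package implements that workflow for people who analyse (or
simulate) such data:

- **imaging** — translation registration of the two channels (phase
  correlation on the summed image, subpixel), pixelwise acceptor/donor
  ratio images with a donor intensity floor, and mean-ratio traces over
  nucleus-excluded somatic ROIs;
- **traces** — baseline linear drift correction, relative ratio
  (R − R₀)/R₀ in percent, a sliding five-point median filter for
  transient focus artifacts, timepoint read-outs, windowed OLS slopes
  (%/min), and group mean ± SEM summaries;
- **stats** — from-scratch two-sided Fisher exact test
  (point-probability rule, exact rational arithmetic) and Mann-Whitney
  U (exact enumeration for small tie-free samples, tie-corrected normal
  approximation otherwise), plus integer-percent reporting
  (round half away from zero);
- **expression** — occurrence analysis over the gene panel, boolean
  composite features ("GluT1 OR GluT3", "GluT1 only", ...), and a
  deterministic reconstruction of the published 59-cell cohort
  (31 non-Tg + 28 3xTg-AD) from its reported marginal counts;
- **synthetic** — a minimal glucose kinetics model (facilitated
  symmetric-carrier transport, hexokinase-gated consumption with
  glycolysis/PPP/hexosamine terms), a saturating sensor response
  R(G) = r_min + (r_max − r_min)·G/(K_d + G), and a movie renderer that
  injects photobleaching, stage drift, photon noise and focus artifacts
  with known ground truth.

The kinetic model is

    dG/dt = v_t [ G_ext/(K_t + G_ext) − G/(K_t + G) ]
            − gate_HK(t) · [ v_gly + v_ppp·ppp_on(t) + v_hbp(t) ] · G/(K_c + G)

where IAA closes the hexokinase gate first-order (glucose-6-phosphate
build-up) and, in the 3xTg-AD parameter set, transiently opens a
hexosamine-pathway flux — reproducing the delayed glucose accumulation
under glycolysis blockade and the genotype-specific dip-then-rise
response. Shipped defaults are calibrated so non-Tg cells show a
−2 %/min relative-ratio slope 2–7 min into glucose restriction and
about +10% after 50 min of the 10 mM step.

## Worked example

```python
from glucofret import (reference_cohort, compare_genotypes,
                       RunConfig, run_experiment)

# occurrence analysis of the 59-cell RT-mPCR cohort
for r in compare_genotypes(reference_cohort(), ["Gys1", "GluT1 OR GluT3"]):
    print(f"{r.feature}: nonTg {r.k1}/{r.n1} ({r.percent1}%), "
          f"3xTgAD {r.k2}/{r.n2} ({r.percent2}%), p = {r.fisher_p:.4f}")

# full synthetic pipeline: simulate, render movies, register, extract,
# drift-correct, slope per cell, Mann-Whitney genotype comparison
rep = run_experiment(RunConfig(protocol="restriction", n_cells=8, seed=42))
for gt, g in rep["genotypes"].items():
    print(f"{gt}: slope = {g['slope_mean']:.2f} +/- {g['slope_sem']:.2f} "
          f"%/min (n = {g['n_cells']})")
```

prints

```
Gys1: nonTg 0/31 (0%), 3xTgAD 2/28 (7%), p = 0.2209
GluT1 OR GluT3: nonTg 17/31 (55%), 3xTgAD 10/28 (36%), p = 0.1925
nonTg: slope = -1.98 +/- 0.06 %/min (n = 8)
3xTgAD: slope = -1.62 +/- 0.12 %/min (n = 8)
```

Gys1 (glycogen synthase) is never detected in non-Tg cells and rarely
in 3xTg-AD cells; the exact two-sided p = 0.2209 is the closed form
378/1711 for that table. The pipeline slopes recover the calibrated
−2 %/min elimination rate from noisy rendered movies; the genotype
difference in this small simulated cohort reflects the 3xTg-AD
parameter set's altered consumption mix.

The same functionality is exposed on the command line:

```sh
glucofret simulate --protocol restriction --genotype nonTg --seed 1 --out movie/
glucofret analyze extract --movie movie/ --rois movie/ --out traces.csv
glucofret analyze traces --traces traces.csv --protocol restriction --out summary.csv
glucofret stats fisher --table 0,31,2,26
glucofret expression fixture --out cells.csv
glucofret run --protocol restriction --n-cells 20 --seed 1 --out results/
```

## Layout

```
src/glucofret/
  synthetic.py    kinetics model, sensor response, movie renderer
  imaging.py      registration, ratio images, ROI trace extraction
  traces.py       drift correction, relative ratios, slopes, summaries
  stats.py        Fisher exact, Mann-Whitney U, percent reporting
  expression.py   gene panel, occurrence analysis, 59-cell cohort
  pipeline.py     end-to-end driver with provenance
  cli.py          `glucofret` command line
docs/methods.md   model, calibration, numerical choices, limitations
```
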