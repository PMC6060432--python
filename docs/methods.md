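# Methods

## Scope and data model

The package analyses two-channel (donor CFP / acceptor YFP) time-lapse
stacks of neurons expressing a FRET glucose sensor, sampled every 15 s,
under superfusion protocols that change bath glucose or apply metabolic
inhibitors after a 10 min control baseline. Because no raw recordings
are distributed, a synthetic-data module generates movies with known
ground truth; every pipeline guarantee below is stated, and tested,
against that ground truth. What passing tests establish is therefore
recovery of known truth under the modelled corruptions — not
performance on real microscope data, whose artifacts (bleed-through,
focal plane curvature, motion beyond translation, biological
heterogeneity of sensor expression) are deliberately out of scope.

## Glucose kinetics model

Intracellular free glucose G (mM) follows a single-pool ODE:

    dG/dt = v_t [ G_ext/(K_t + G_ext) − G/(K_t + G) ]
            − gate_HK(t) · [ v_gly + v_ppp · ppp_on(t) + v_hbp(t) ] · G/(K_c + G)

- Transport is a symmetric facilitative carrier (same Michaelis constant
  inward and outward), so with consumption off the pool equilibrates at
  the bath concentration.
- Consumption lumps hexokinase and everything downstream into one
  saturable term with one flux knob per pathway: glycolysis (v_gly),
  pentose phosphate shunt (v_ppp), and a transient hexosamine flux
  (v_hbp). This is the smallest structure with an interpretable knob per
  experimentally separable pathway; there are no explicit G6P/F6P pools.
- IAA (glycolysis blockade) causes glucose-6-phosphate accumulation
  that inhibits hexokinase; this is abstracted as a first-order gate,
  gate_HK = exp(−(t − t_IAA)/τ_HK), multiplying all consumption. The
  gate produces the delayed glucose accumulation seen under IAA.
- In the 3xTg-AD parameter set, IAA onset also opens a transient
  hexosamine-pathway flux v_hbp(t) = v_hbp_max · s_hbp ·
  exp(−(t − t_IAA)/τ_HBP); its interaction with the closing hexokinase
  gate yields the biphasic dip-then-rise. Non-transgenic cells have
  s_hbp = 0 and can never dip below baseline under IAA — this ordering
  is asserted, not calibrated.
- 6-AN zeroes the pentose phosphate term instantly.

Genotype differences enter only as non-negative scale factors on the
pathway fluxes (3xTg-AD: glycolysis ×1.75, PPP ×0.25, hexosamine
transient on). The model does not attempt to reproduce the faster
late-phase glucose accumulation of 3xTg-AD cells under IAA, which would
require genotype-dependent transport or gating kinetics; only the shape
ordering (biphasic vs monotone, deeper combined-inhibition dip) is
claimed.

### Default parameters (shipped in `data/default_params.yaml`)

| parameter | value | unit | meaning |
|---|---|---|---|
| v_transport | 0.0732 | mM/min | carrier capacity |
| k_transport | 0.872 | mM | carrier half-saturation |
| v_glycolysis | 0.0202 | mM/min | glycolytic flux knob |
| v_ppp | 0.0166 | mM/min | pentose phosphate flux knob |
| v_hbp_max | 0.03 | mM/min | transient hexosamine flux |
| k_consume | 0.0163 | mM | consumption half-saturation |
| tau_hk_inhibition | 18 | min | hexokinase gate closure under IAA |
| tau_hbp_transient | 8 | min | hexosamine transient decay |
| sensor k_d | 0.7 | mM | ratio half-saturation |
| sensor r_min, r_max | 1.0, 1.872 | — | ratio bounds |

The four rate/saturation constants and the sensor span were calibrated
jointly (least squares over the protocol set) so that the
non-transgenic defaults give a −2.0 %/min relative-ratio slope in the
2–7 min window after 2.5 → 0.2 mM restriction and +10.2% at 50 min of
the 2.5 → 10 mM step, with the remaining restriction/step timepoints
falling near their expected magnitudes (−20% at 20 min of restriction,
+4.4% at 10 min of the step). These are calibration targets of the
generator's defaults, not claims about any real dataset. The sensor's
affinity is a convention consistent with the sensor family's "700"
naming (0.7 mM); its dynamic range is arbitrary because only relative
ratios propagate downstream. At baseline (2.5 mM bath) the model rests
at G ≈ 0.31 mM with ~55%/45% of consumption through the
glycolysis/PPP knobs.

### Integration

Fixed-step classical RK4 at a 1 s internal step, with every protocol
event time inserted into the step grid so no step straddles a
discontinuity, resampled to the 15 s acquisition grid by linear
interpolation. The dynamics are far from stiff at these rates (fastest
time scale ≳ minutes), so a fixed step is accurate to ~1e-10 and
guarantees bit-reproducibility. The exact model satisfies
G ≤ max(G₀, G_ext); the integrator raises an explicit error if that
bound (×1.1 + 1) is crossed or a non-finite value appears, rather than
returning NaN. G is clamped at 0 against round-off undershoot
(consumption vanishes at G = 0 in the exact model).

## Movie rendering

Cells are soft-edged ellipses (logistic edge profile, ~1 px wide) with
a dimmed nucleus, on a zero background. The acceptor image equals the
donor image times the cell's ratio pixelwise, so with corruptions off
the ROI-mean ratio equals the ground truth exactly — this identity
anchors the pipeline's end-to-end tests at 1e-6 relative. Corruptions,
each drawn from a named substream of one integer seed:

- **photobleaching**: per-channel linear intensity decay (fraction/min);
  donor-only bleach b makes the measured ratio follow R/(1 − b·t),
  used as a closed-form oracle;
- **stage drift**: a per-frame (dx, dy) path applied analytically to
  the cell geometry (no interpolation of rendered images);
- **photon noise**: Gaussian with variance = read² + scale·intensity —
  the Gaussian approximation to Poisson shot noise at camera-count
  scales, which keeps the renderer analytically checkable;
- **transient focus artifacts**: with a per-frame probability, both
  channels are Gaussian-blurred and the acceptor gains ×1.15,
  producing the sharp single-frame ratio spikes the median filter is
  designed to remove.

Overlapping somata are rejected so ROI ground truth stays unambiguous.

## Imaging pipeline

Registration is translation-only phase correlation (upsampled
cross-correlation, subpixel) estimated once per frame on the
donor+acceptor sum and applied identically to both channels with
bilinear interpolation; rotation is out of scope because slice drift is
translation-dominated. Edge pixels pulled in from outside the field are
filled with the frame median and marked invalid; invalid pixels are
excluded from all ROI means. An all-zero frame is flagged and inherits
the previous frame's shift. Measured recovery on the synthetic scenes:
integer drift exact, random sub-pixel walks ≈ 0.015 px RMS (bound
asserted: 0.25 px).

Ratio images are computed pixelwise (acceptor/donor where the donor
exceeds a floor, defaulting to 1% of the frame's 99th-percentile donor
intensity) and then averaged over the cytosolic ROI — soma minus
nucleus, the nucleus being largely sensor-free. Pixelwise-then-average
was chosen over ratio-of-means because the acquisition convention is to
divide registered images before measuring; on the synthetic scenes
(ratio constant within a cell) the two coincide, so this choice is not
separately testable here and is flagged for sensitivity analysis on
real data. Frames with no defined cytosolic pixel yield missing values,
never interpolated.

## Trace analysis

Processing order is fixed and tested: **drift-correct → normalize →
(median-filter for display and timepoint read-outs)**. The drift line
is fitted by least squares to the baseline window only — fitting
through stimulus periods would absorb real signal — then extrapolated
and subtracted with the baseline mean restored, which preserves any
post-event step exactly. Normalization divides by the baseline mean R₀
(in percent), making the baseline mean identically zero. The five-point
sliding median shrinks symmetrically at the trace edges (3-point, then
passthrough), so constants are preserved and no padding is invented.

Slopes are ordinary least squares over a configurable post-event window
(default 2–7 min), in %/min, with missing samples dropped. The traces
module documents unfiltered traces as the slope input (filtering is for
artifact removal, not trend estimation); the end-to-end driver defaults
to filtered slopes because its default scenes include focus artifacts,
whose single-frame spikes otherwise bias an unfiltered OLS slope by up
to ~0.5 %/min. Both choices are one config switch apart.

Timepoint read-outs take the sample nearest to (event + t), with exact
ties resolved to the earlier sample. Group summaries are per-timepoint
mean and SEM = sd/√n over cells with defined values.

### Known systematics

- **Multiplicative bleach vs additive correction.** Differential
  photobleaching multiplies the ratio by a slowly growing factor;
  subtracting a baseline-fitted line leaves a residual that scales the
  signal amplitude (~2% relative on restriction slopes at the default
  gentle bleach rates, growing with recording length and bleach rate).
  This limitation is shared by any linear-baseline workflow; the
  statistical acceptance checks therefore separate stochastic
  corruptions (noise, drift) from this deterministic one.
- **Artifacts inside the baseline window.** A spike among the baseline
  samples tilts the fitted drift line, and extrapolation over a 40–60
  min recording amplifies the tilt into a late-timepoint offset of a
  few percent (lever-arm effect). A robust (e.g. Theil–Sen) baseline
  fit would mitigate this; it is not implemented, and the acceptance
  measurements exclude artifacts for this reason while artifact removal
  itself is tested on the median filter.

## Statistics

**Fisher's exact test** is two-sided by the point-probability rule: all
2×2 tables with the observed margins are enumerated and the
probabilities of those no more probable than the observed table are
summed, in exact `Fraction` arithmetic (no tail misclassification from
floating-point ties; exactness verified against independent enumeration
for all cohort tables and random tables to N = 80). One-sided tails are
also reported: published occurrence analyses occasionally print a
one-sided tail, and for two of the cohort's phosphofructokinase
comparisons the reported values correspond to P(X ≥ k) rather than the
two-sided p (0.3598 vs 0.6060, and 0.3874 vs 0.5914); the package
reports both so either convention can be checked.

**Mann-Whitney U** reports U = min(U₁, U₂) from midrank sums. The exact
two-sided p is 2·P(U ≤ U_obs) from the full null distribution (2-D
dynamic programme over rank assignments; requires tie-free data); the
normal mode applies the tie-corrected variance with continuity
correction. `auto` selects exact for tie-free samples of at most 10
each. Exact mode agrees with brute-force enumeration for n ≤ 7 and with
the normal mode to < 0.01 at n ≥ 20.

**Integer percents** round half away from zero using integer
arithmetic, matching reported detection frequencies (9/31 → 29%,
26/31 → 84%). Two reported values in the source cohort (2/31 as "7%",
11/31 as "36%") are inconsistent with any single rounding rule and are
treated as reporting errata; the package returns 6% and 35%.

## The 59-cell expression cohort

`reference_cohort()` reconstructs the published single-cell RT-mPCR
dataset (31 non-Tg, 28 3xTg-AD; 13-gene panel with amplicon sizes as
metadata) from its reported marginal detection counts plus the fully
determined GluT1/GluT3 joint distribution (both / only-GluT1 /
only-GluT3 / neither = 7/2/8/14 in non-Tg and 1/4/5/18 in 3xTg-AD).
Joint structure among the other genes was never reported; detections
are assigned to the first k cells of each group in a fixed order, i.e.
the fill-in is synthetic with independent marginals, and any analysis
relying on cross-gene co-detection outside the GluT pair is explicitly
unsupported. All marginals, composites and Fisher p-values on this
cohort are deterministic statistics of the reported contingency tables.

## End-to-end driver

`run_experiment` simulates a cohort per genotype (per-cell lognormal
jitter, σ = 0.1, on the transport and consumption fluxes — matching the
few-percent SEMs typical of such group traces), renders fields of up to
5 cells with noise/drift/bleach/artifacts, and runs the full analysis.
Problem sizes default to 20 cells per genotype and one field of view
per 5 cells; the acceptance script uses 10–20 cells per measurement,
which keeps a full run under a minute while holding group SEMs near
0.05 %/min on slopes. All randomness descends from one config seed via
named substreams; reports embed a SHA-256 config hash, the seed and the
package version, and identical configs reproduce byte-identical output
files.
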