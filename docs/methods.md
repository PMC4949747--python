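# Methods

This note documents the models, numerical choices and limitations behind
`napesrm`: what each stage computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Structural model and mass arithmetic

A NAPE is modeled as a diacyl glycerophosphoethanolamine body plus an
amide-linked N-acyl chain. The body is summarized by total O-acyl carbons
`C` and double bonds `D` (species level) or by the two sn-chains
(molecular level); the N-acyl chain is `n:dn`. The neutral composition

    C(C+n+5) H(2C−2D+2n−2dn+8) N O9 P

was derived once from the structure — glycerol backbone, two O-acyl esters,
a phosphodiester to ethanolamine, and the N-acyl amide, i.e. five
condensation waters leaving the assembled parts — and frozen as the
closed form. Because published sources rarely print this formula, the test
suite carries an independent oracle that assembles the molecule atom by
atom from its parts with a separately hand-typed atomic-mass table; the
closed form must agree exactly on randomized species, and the formula minus
the N-acyl increment must reproduce the textbook dioleoyl-PE formula
C41H78NO8P.

Masses are monoisotopic throughout (atomic masses from the NIST table via
pyteomics). Adduct shifts include the electron mass:
`[M+H]+` +1.007276 Da, `[M+NH4]+` +18.033823 Da, `[M−H]−` −1.007276 Da.
With 2-m/z quadrupole windows the monoisotopic/average distinction is not
operationally critical, but monoisotopic matches MS practice and keeps
positive/negative conventions consistent to sub-mDa.

Shorthand parsing accepts the Unicode hyphens that typeset documents
produce and tolerates double-bond position/geometry annotations
(`18:1(9Z)`), which are discarded with a logged warning — mass arithmetic
is position-blind. sn-position assignment is bookkeeping only; it never
affects composition, fragments or retention.

## Transition design

Positive-mode CID of the protonated (or ammoniated) precursor cleaves the
C–O bonds on either side of the phosphate. Both resulting product ions
contain the N-acyl chain and nothing of the O-acyls:

* **F1** — protonated N-acyl-phosphoethanolamine, neutral
  `C(n+2) H(2n−2dn+6) N O5 P`;
* **F2** — F1 minus a phosphate-side neutral loss. The default is H3PO4,
  giving the dehydrated N-acylethanolamine-type ion; HPO3 (giving the
  protonated N-acylethanolamine) is selectable. The two options differ by
  exactly one water. Published spectra were not machine-readable here, so
  the H-transfer bookkeeping could not be confirmed against a reference
  figure; the default is therefore a documented, configurable choice.

The method table carries exactly two transitions per species: F1 as
quantifier (the phosphate-containing, more NAPE-specific fragment) and F2
as qualifier. Precursor adduct defaults to `M+H` (with `M+NH4`
selectable), collision energy to a uniform 20 eV, retention windows to
3 min centered on the predicted retention time, Q1/Q3 windows to 2 m/z.

Isobar analysis groups species whose precursor m/z values fall within a
tolerance of the group minimum (default: half the Q1 window). A pair in a
group is *resolvable* when no product ion of one species falls within the
Q3 tolerance of any product of the other — by construction this separates
any isomers that differ in the N-acyl chain, and only those. Scheduling
statistics count, per time point, how many transition windows are open;
per-transition dwell is the cycle time (default 1.0 s, a typical triple-
quadrupole value; instruments are not modeled further) divided by the
concurrency at that transition's window center.

## Retention model

Reversed-phase retention is fit as

    rt = b0 + bC·(C+n) + bDB·(D+dn)     [minutes]

by unweighted ordinary least squares. This is the bivariate generalization
of the equivalent-carbon-number rule; a fixed ECN corresponds to
`bDB/bC = −k`, and leaving both coefficients free avoids committing to a
`k` that no reference value pins down. Fitting requires at least three
observations with variation in both predictors; a rank-deficient design is
an error naming the missing variation, and physically surprising signs
(`bC ≤ 0` or `bDB ≥ 0`) warn without failing. Predictions are clipped to
the run length (default 18 min, matching a 15-min gradient plus hold) with
a warning. Outlier flagging compares residuals against `k`×residual-SD
using the *unclipped* linear prediction, with a 1 ns-scale floor so that
noiseless fits (residual SD 0) do not flag floating-point dust.

Isobaric isomers with equal `(C+n, D+dn)` totals necessarily receive equal
predicted retention. Real isomer trios separate partially; that separation
is below this model's resolution and is not claimed by it.

## Synthetic-data generator

The simulator emulates a scheduled SRM acquisition with known ground
truth. Per transition it produces a uniform grid over the run
(default 0.5 s sampling, 18 min run) with:

* a Gaussian peak at the transition's scheduled window center plus a
  per-species retention jitter (default SD 1 s) shared by both transitions
  of a species, so the pair genuinely co-elutes;
* peak area = amount × response factor, scaled by the species' F2/F1 ion
  ratio (default 0.35) on the qualifier. The default response factor is
  2000 counts·s/pmol, sized so the 50-pmol internal standard gives a
  ~10⁴-count peak over single-digit noise, as on a modern instrument;
* a flat chemical background (default 4× the noise SD) plus Gaussian
  baseline noise (default SD 5 counts), the sum clipped at zero. The
  background level matters: without it, zero-clipping concentrates half
  the baseline samples at exactly zero and any robust scale estimate of
  the baseline collapses, which is a distortion of the estimator rather
  than of the chemistry. With the default background, clipping is a rare
  tail event and trace minima remain ≥ 0;
* hard zeros outside the transition's retention window (scheduled
  acquisition);
* optionally, one lognormal recovery factor per sample (mean 1, CV
  `prep_cv`) applied to every species *including* the internal standard.
  This reproduces the error structure of liquid- and solid-phase
  extraction, whose yield varies per sample but affects the whole
  extract — precisely the variability a one-point internal-standard
  calibration cancels.

Calibration series derive per-sample seeds deterministically from
(base seed, level index, replicate index) via `numpy` `SeedSequence`;
identical seeds give byte-identical traces. Interference injection adds a
second Gaussian to exactly one transition (an isobar sharing the precursor
and one product ion), masked to the acquisition window.

What the generator does **not** emulate: peak tailing and shape drift, ion
suppression and matrix effects, chemical-noise structure (the background
is flat and white), carryover, detector saturation, per-species uncorrelated
response drift, and retention drift across a batch. Consequently, passing
the simulation-twin tests shows the pipeline's arithmetic and logic are
correct under the stated error model; it does not certify performance on
real extracts, where sample preparation dominates the error budget.

## Peak processing and quantification

* **Noise**: robust SD = 1.4826 × median absolute deviation of the
  peak-free region, restricted to the acquisition window (outside it the
  scheduled trace is hard zeros, not baseline). S/N = peak height over
  this SD, reported as a capped sentinel (10⁶) when the estimate is
  exactly zero (noiseless traces).
* **Detection**: local maxima above baseline + 3 SD whose immediate
  neighbors also clear baseline + 2 SD — i.e. the signal must stay
  elevated for ≥ 3 consecutive samples, which single-sample noise spikes
  essentially never do (measured false-positive rate ≪ 1 % per 3-min
  window at the 3-SD threshold). Apexes are refined by parabolic
  interpolation through the top three samples. Bounds walk outward to
  baseline + 1 SD, or stop at the valley when the signal climbs ≥ 3 SD
  back out of its running minimum (partially separated neighbors);
  candidates whose apex lies inside a taller peak's bounds are treated as
  flank bumps and suppressed.
* **Integration**: trapezoidal, in counts·seconds. For raw bounds the
  baseline is the chord between bound endpoints (3-sample medians). For
  detected peaks on scheduled traces the subtracted baseline is the robust
  level of the surrounding window — a deliberate refinement over the
  chord, since a chord hung on two noisy endpoints multiplies its level
  error by the full peak width and dominated the ion-ratio error budget
  for small peaks. Negative net areas clip to zero.
* **Confirmation**: a species is detected when the quantifier has a peak,
  the qualifier co-elutes within 0.05 min, and the qualifier/quantifier
  area ratio lies within ±30 % (relative) of the expected ion ratio; every
  failed criterion is named in the result flags. The ratio uses *mirrored
  integration* — the qualifier integrated over the quantifier's bounds —
  so bound-placement noise cancels between the transitions, and a
  partially co-eluting interferent on the qualifier visibly inflates the
  ratio. Both tolerances are invented defaults exposed in the
  configuration; no reference values exist for them. A widely separated
  interferent instead shows up as an RT mismatch (or, if it dominates the
  window, as the selected peak itself), not as an ion-ratio failure.
* **Quantification**: one-point internal-standard calibration,
  `conc = (area / area_IS) × n_IS / m_tissue` in pmol/g (defaults: 50 pmol
  IS, 0.1 g tissue). Quantification uses the quantifier only; the
  qualifier confirms identity. Scaling all traces by a common factor
  leaves every concentration unchanged. The assay is a fixed-list targeted
  method; no multiple-testing correction applies.
* **Validation statistics**: unweighted OLS of response ratio on nominal
  concentration (slope, intercept, R²); accuracy = mean
  100·|back-calculated − nominal|/nominal per QC level (absolute
  deviation reported; the signed value is available from the back-
  calculation); precision = 100·SD/mean over replicates; LLOQ = lowest
  calibration level at which every replicate is detected with S/N ≥ 10.
  Whether a reference S/N criterion means SD-based or peak-to-peak noise
  is ambiguous in general; the MAD-SD definition here is a documented
  choice.

## Problem sizes and acceptance quantities

`scripts/acceptance.py` uses: a 78-species method (72 endogenous
candidates from 12 brain-typical PE bodies × 6 N-acyl chains, plus the
five N-17:0 validation analytes and the internal standard) for counting
and scheduling; the 6-species validation method for the simulation twin —
9 calibration levels (10–2300 pmol/g) × 3 replicates at 5 % preparation
CV, QC triplicates at 50/400/1400 pmol/g, 15 precision replicates at
500 pmol/g. These sizes mirror a realistic validation campaign while
keeping the full run in seconds. Relative response factors for the five
validation analytes span 0.52–1.13 of the internal standard's, the spread
per-analyte calibration slopes typically show.

## Known limitations

* Quantification accuracy for endogenous species is bounded by the
  single-IS assumption (equal response to the IS); species-dependent
  response is simulated and visible as a proportional bias, exactly as in
  any one-point label-free calibration.
* The retention model is linear and gradient-blind; strongly curved
  retention, positional-isomer effects and run-to-run drift are out of
  scope.
* The peak model is a pure Gaussian; integration bounds and S/N behave
  differently on strongly tailed peaks.
* Ether/plasmalogen NAPEs, isotopologue distributions and average-mass
  mode are not modeled.
* mzML/vendor formats are not read or written; long-format CSV is the
  interchange contract.
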