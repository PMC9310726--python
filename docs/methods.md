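# Methods

## The complexity measure

Per epoch the pipeline computes a normalized LZ78 complexity:

1. **Detrend.** A least-squares straight line is removed from the epoch.
   Linear detrending (rather than mean subtraction) removes slow drift
   that would otherwise bias the zero-threshold binarization; mean-only
   subtraction remains available (`binarize(..., detrend="mean")`).
   Residuals within 1e−12·max|x| of zero are treated as ties and map to
   bit 0, so the result is deterministic and an exact ramp binarizes to
   the all-zero sequence despite floating-point rounding.
2. **Binarize.** bit = 1 where the residual is positive, else 0.
3. **LZ78 parse.** The standard word-dictionary scan: the current phrase
   grows while it matches a dictionary entry; on the first mismatch the
   extended phrase joins the dictionary and the scan restarts. A trailing
   phrase that exhausts the sequence while still matching counts as one
   additional phrase (the usual convention; it changes *L* by at most 1).
4. **Normalize.** C = L·log₂L/T, with C = 0 for L ≤ 1. This is the
   standard finite-length LZ78 normalization — phrase count times the
   per-phrase code length, per input symbol. At T = 5120 it yields ≈ 0.13
   for a constant signal (101 phrases), ≈ 0.20 for strict alternation,
   and ≈ 1.2 for i.i.d. bits; awake ECoG sits around 0.5–0.7.

C is invariant to positive rescaling and to any added linear trend, and is
reproducible bit-exactly from the binary sequence. The parser is verified
against an independently written brute-force dictionary parser,
exhaustively on all binary strings up to length 14 and on 1000 random
strings of length 5120.

## Preprocessing

* **Band-pass 0.5–200 Hz**, 4th-order Butterworth applied forward and
  backward (`sosfiltfilt`). The zero-phase realization is chosen because
  phase shifts would move zero crossings and hence the binarization. The
  acquisition hardware's own 0.1–500 Hz filter is a property of the
  recordings, not re-applied.
* **Epoching** into half-open windows [k·T, (k+1)·T), default T = 5120
  samples; a trailing remainder is dropped, never padded (padding with a
  constant would deflate the phrase count).
* **Artifact rejection.** The original workflow removed epochs with gross
  movement artifacts by visual inspection; the deterministic stand-in
  here drops any epoch whose peak |amplitude| (after median centering)
  exceeds z_max = 6 times the MAD-based scale (1.4826·MAD) of the
  channel's full-session signal. The rule is order-invariant and logged
  per epoch. It models only amplitude excursions — not line noise,
  electrode pops with small amplitude, or muscle contamination.

## Synthetic data

Two generation modes cover different testing needs.

**Signal mode** builds each epoch as a weighted sum of four ingredients:
a slow oscillation (random frequency 0.5–4 Hz, random phase), spindle
activity (7–14 Hz carrier gated by a two-state on/off envelope with
exponential 1 s bursts and 3 s gaps), narrowband gamma (30–45 Hz filtered
noise) and 1/f broadband noise, scaled to ~50 µV. The default per-state
weights make slow-wave sleep slow-dominated, light sleep intermediate
with spindles, and wakefulness/REM broadband- and gamma-dominated and
nearly identical. With these defaults the per-state complexity means are
SWS ≈ 0.26 < LS ≈ 0.46 < W ≈ REM ≈ 0.68, i.e. wake-like states inside
the empirically observed 0.4–0.8 envelope, and the W–REM gap is the
smallest of all state gaps. A per-cat lognormal jitter (sd 0.05) on the
mixture weights supplies between-animal variability; cortices can be
marked "flat" to emulate a region whose complexity does not track state.

**Direct-value mode** draws per-epoch complexity straight from the
hierarchical linear model

C_ijk = β₀ + β₁·d̃ + β₂·d̃² + stim·δ + u_cat,i + u_sess,ij + ε_ijk,

with d̃ the dose centred at 7.5 mg/kg (which decorrelates the linear and
quadratic terms over the 0/5/10/15 grid), u and ε zero-mean Gaussian.
Defaults: β₀ = 0.62, inverted-U curvature β₂ = −0.0008 per (mg/kg)²
(shape presets flip or zero β₁/β₂), σ_cat = 0.01, σ_session = 0.005,
σ_ε = 0.02, 5 cats, 4 sessions per dose nested in cat, 60 epochs per
session. These effect and variance magnitudes are of the order of the
between-state differences the complexity scale exhibits and give the
design comfortable power at its native size.

What the generator does **not** emulate: volume conduction and
cross-channel correlation, EMG/ECG artifacts, non-Gaussian heavy-tailed
epochs, true spectral shapes of cat cortex (the targets are qualitative),
and state transitions within an epoch. Passing tests therefore
demonstrate that the pipeline recovers structure it is pointed at, not
that real recordings meet the model's assumptions.

## Statistics

* **Cohen's d** uses the (n−1)-weighted pooled SD.
* **ANOVA/Tukey** uses the studentized-range distribution
  (Tukey–Kramer under mild imbalance); with two groups the adjusted p
  equals the two-sample equal-variance t-test p.
* **Mixed models.** Polynomial fixed effects in the state code
  (W=0, LS=1, SWS=2, REM=3, the ordering of the sleep-depth progression;
  complexity is U-shaped in this coordinate) or the centred dose, with
  random intercepts per cat, plus session-nested-in-cat when sessions
  repeat. Estimation by statsmodels `MixedLM`. Models entering a BIC
  comparison are fitted by **maximum likelihood**, because REML
  likelihoods are not comparable across fixed-effect structures; REML is
  available where variance components themselves are the target.
  BIC = −2·logL + k·ln n with k = fixed coefficients + variance
  components + residual. The default optimizer is retried with Powell
  when it fails to converge or returns a non-finite likelihood;
  convergence is recorded on every fit.
* **Bayes factors.** BF_ab = exp((BIC_b − BIC_a)/2), the
  unit-information-prior approximation; BF > 5 is labelled substantial.
  The log-BF is capped at ±700 so overwhelming evidence stays finite.
  This is an approximation to a Bayes factor, not a sampled-posterior
  one, and no multiple-comparison correction is applied across cortices.
* **Stimulation model.** Dose enters as a categorical factor alongside
  the stimulation flag and their interaction. Each term is scored by a
  BF against the model without it (interaction vs the additive model;
  each main effect vs the other-main-effect-only model), by η² =
  SS_term/SS_total from the type-II OLS decomposition of the fixed
  effects, and by the term's Wald p in the full mixed fit. A term is
  called *reliable* only when p < 0.01 **and** BF > 5 — p-values and BFs
  can disagree, and the conjunction is the conservative reading.
* **Shape labels.** "inverted-U" when the quadratic beats the linear
  model with BF > 5 and β₂ < 0; "U" with β₂ > 0; "cubic" when the cubic
  beats both linear and quadratic substantially; otherwise "linear".

## Problem sizes and numerical choices

The test-suite replicate study (type-I and power check of the
quadratic-vs-linear selection) runs 100 flat-truth and 100 inverted-U
datasets at the generator's native size (4800 rows each). Other unit
tests use scaled-down configurations (2–3 cats, 8–20 epochs) since the
properties they check are size-independent. Determinism is enforced by
seeding every generator through `numpy.random.SeedSequence` spawning and
writing reports with a fixed float format, so a configuration + seed
reproduces every CSV byte for byte.

## Known limitations

* The artifact rule is an amplitude criterion only; on real data it
  complements, not replaces, visual screening.
* The BIC/BF approximation can be coarse for small n or boundary variance
  estimates (a boundary estimate is flagged by a warning).
* η² is a fixed-effects variance fraction; other η² variants (partial,
  random-effect-adjusted) would give different numbers.
* EDF reading requires the optional `mne` dependency and trusts the EDF
  header's sampling rate; hierarchy labels come from a JSON sidecar.
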