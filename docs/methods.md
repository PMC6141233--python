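# Methods

This note documents the models, estimators, numerical choices and known
limitations behind each stage of the pipeline, and what the synthetic
generators do and do not emulate.

## Sinusoidal analysis

A trace is strain ε(t) (fraction of muscle length) and stress σ(t)
(kN/m², i.e. kPa) on a uniform grid. The complex modulus at the drive
frequency is estimated by least-squares projection of both strain and
stress onto {1, sin 2πft, cos 2πft} over an analysis window of whole
cycles; the modulus is the ratio of the stress and strain phasors, so it
is independent of the phase origin and of a DC offset. On integer-cycle
windows this projection coincides with the DFT coefficient at the drive
frequency (tested against that oracle). The first **2 cycles** are
dropped as transient settling; the window length is otherwise every
remaining whole cycle. Strain residual power above **10%** of the strain
amplitude raises a harmonic-distortion warning rather than an error,
since mild distortion biases but does not invalidate the estimate.

Work per cycle per volume is W(f) = −π ε₀² E″(f) (J/m³; the 10³ factor
converts kPa to J/m³) and P = W·f. Spectrum summaries report the
optimum at a measured grid frequency — no interpolation — matching the
discrete 50-frequency protocol; a dense-grid argmax oracle is used only
in tests. High-frequency stiffness is E′ at the grid point nearest
500 Hz and errors out if no point lies within 10%. Isometric tension
plateaus are the latest window (≥20% of the trace) whose fitted slope is
below 1%/s of the window mean.

Units: moduli and tension are handled in kN/m² throughout. Published
tables of this kind often omit units, so no unit-level agreement with
any particular table is claimed; rate constants and ratios are
unit-free.

## Three-process modulus fit

The model Y(f) = A(2πif/α)^k − B·if/(b+if) + C·if/(c+if) is fit by
minimizing the summed squared complex residual with
`scipy.optimize.least_squares` (TRF, bounds A,B,C ∈ [0,10⁶], k ∈ [0,0.5],
b ∈ [0.1, 5000] Hz). Choices that matter:

- **α fixed at 1 Hz.** With k free, A and α enter only through A/α^k, so
  they are jointly unidentifiable; α is therefore a fixed reference.
- **k** is bounded to [0, 0.5] and initialized at 0.12, typical of the
  passive power-law background of insect fibers.
- **b ≤ c by construction.** The optimizer parameterizes c = b + δ with
  δ ≥ 0, removing the label ambiguity rather than repairing it after the
  fact.
- **Multi-start.** One heuristic start (b at the viscous-modulus
  minimum, c = 5b, amplitudes from the spectrum's range) plus n
  log-uniform random starts (default 8); lowest-SSE converged solution
  wins, ties (relative SSE < 10⁻⁹) broken toward the smallest c for
  determinism.
- **Default fit band 5–650 Hz**, configurable. The lowest measured
  frequencies are excluded because the power-law background and slow
  drift dominate the phase there.
- **Unweighted complex residuals** — no evidence for any other weighting.
- **Identifiability flag.** After fitting, a nested power-law-only model
  (B = C = 0) is refit; if it matches the full model's SSE, the
  exponential processes are flagged unidentifiable (e.g. on a constant
  spectrum).

Noiseless round trips recover all six parameters to well under 1%.
Under 2% multiplicative spectrum noise a 60-seed characterization gives:
2πb within 5% in ~95% of runs; 2πc — whose corner (~856 Hz) lies at the
top of the measured band — within 5% in only ~68% and within 15% in
~97%. Tests assert that computed characterization, not an aspirational
tighter one.

## Work loops

Cycles are delimited by upward zero-crossings of mean-subtracted strain;
crossing times are interpolated and snapped to the nearest sample so
float noise at the sine zeros cannot shift a boundary. Work generated /
absorbed are trapezoidal sums over shortening / lengthening steps
(dL = 0 steps contribute to neither); net work equals the signed loop
area (verified against shoelace-formula and analytic-ellipse oracles),
and reversing traversal swaps the components and negates the net. A
cycle is rejected as open when its strain endpoints differ by more than
1% of the excursion or its duration deviates from the drive period by
more than max(1%, 1.5 samples).

The measurement cycle defaults to **8** (cycle-to-cycle energetics are
consistent from cycle 7 onward; the choice is exposed as `--cycle`).
The amplitude × frequency grid search is exhaustive, scans in sorted
order and replaces the incumbent only on strictly larger power, so it is
invariant to grid ordering; an all-absorbing grid returns the
least-negative cell with a flag. The muscle-length protocol stretches in
2% steps until the relative power gain is ≤ 3% (boundary inclusive, so a
gain of exactly 3% stops).

## Cross-bridge ensemble simulator

Each of n independent bridges is detached or attached. Attachment occurs
at rate f_att with initial strain uniform on [−d/2, +d/2] (no better
informed attachment-strain distribution exists for this system);
detachment at rate g₀·exp(−x/δ), capped at 10·g₀, optionally scaled by
1/(1 + K_ATP/[ATP]). An attached bridge carries force κ(x + d) with x
advected by the imposed length change (muscle strain × half-sarcomere
length). Stress is the summed force over a half-sarcomere
cross-sectional area.

**Why signed strain dependence.** With the attachment distribution
symmetric, an even (|x|) detachment law has zero first-order modulation
and the linearized response is a single absorbing Lorentzian — no
work-producing process exists at any parameter setting. A signed law
(detachment slowing under stretch) is the classic delayed-tension /
stretch-activation mechanism: stretch transiently raises the attached
number with a lag set by attachment-side kinetics. It makes the fitted
work-producing rate 2πb track f_att and the work-absorbing rate 2πc
track detachment, which is exactly the mechanistic interpretation the
analysis is built around. The 10·g₀ cap bounds the tau-leap step; a
bridge past that strain detaches within a step regardless, so only the
sub-step timing of already-immediate events is coarsened.

**Numerics.** Fixed-step tau-leap Bernoulli updates with
Δt = 0.02/max(rates), rounded down to divide the output sample period; a
caller-supplied Δt above 0.1/max(rates) is rejected. The ensemble starts
at its isometric steady state and is settled for 5/(f_att + g₀) before
recording. All draws flow through one seeded `default_rng`, making every
trace bit-reproducible.

**Defaults** describe a fast, low-duty flight-muscle myosin: f_att =
200 s⁻¹, g₀ = 2000 s⁻¹ (duty ratio 0.09), κ = 2 pN/nm, d = 5 nm,
half-sarcomere 1700 nm, area 5×10⁵ nm² (isometric stress a few kN/m²).
With these defaults the strain-independent ensemble's single relaxation
rate (≈ g₀) agrees with f_att + g₀ within the duty ratio, i.e. within
~9%, which is why the linearization checks hold at the 15% tolerance
without tuning.

**What the simulator does not emulate:** no spatially explicit sarcomere
lattice, no thin-filament (calcium) regulation, no super-relaxed state,
no filament compliance, no multi-state biochemistry — so quantitative
agreement with real fiber moduli is not expected, only the qualitative
rate-constant mechanics that the tests assert.

## Dose–response fits

Michaelis–Menten fits use `scipy.optimize.curve_fit`, unweighted,
initialized at vmax₀ = max(y) and km₀ = first concentration reaching
half of max(y), with K_m bounded to 100× the largest concentration. A
fitted K_m above 10× the largest tested concentration is flagged: such
data never approach saturation and cannot pin the parameter. Basal
activity is subtracted before fitting (identical to fitting
pre-subtracted data). Catalytic efficiency is reported both as the ratio
of pooled fit parameters and, when replicate preparations exist, as the
mean of per-replicate ratios — the two estimators differ and reports
label which is shown. f_max vs [ATP] can be fit pooled or per fiber
(both modes provided; which a given study used is usually not
recoverable). f_max vs [Pi] is ordinary least squares with a t-test on
the slope.

## Cardiac analysis

Beats are prominence-filtered diameter minima (prominence ≥ 25% of the
5th–95th percentile range); a beat needs a diastolic plateau (≥3 samples
above 85% of the global excursion) on both sides, which discards beats
truncated at trace edges. Per beat: DD = median of the pre-trough
plateau (median resists noise spikes); **SD = median of the deep-systole
region** (samples within 25% of the excursion above the raw minimum) —
on noiseless flat-bottomed beats this equals the minimum exactly, and
under noise it avoids the ~2σ low bias of a minimum taken over a
~20-sample systolic plateau, which alone would exhaust the 2% recovery
tolerance at 2% noise; HP = trough-to-trough; SI = contiguous time below
SD + 15% of the excursion, with interpolated threshold crossings. The
15% SI threshold is a configuration constant, not a physiological claim:
absolute SI values are only meaningful relative to the same threshold,
so the validation surface uses synthetic recovery and monotone
comparisons, never absolute agreement with any published SI.

The synthetic heart trace is a DD baseline with raised-cosine-edged
rectangular dips (edge width 10% of SI — kymograms motivate a smoothed
square pulse, not a specific equation); the pulse is sized so that SI
measured at the 15% threshold equals the requested value, making
generator and analyzer consistent by construction. Fractional shortening
and SI/HP are computed from mean diameters and intervals by default
(per-beat averaging is available); heart period is reported but carries
no absolute target since a heart's HP depends on the preparation.

The relaxation assay computes per-heart diameter gains after calcium
chelation and after blebbistatin, with paired t-tests within genotype
and equal-variance unpaired t-tests between genotypes; all-equal deltas
flag zero variance instead of fabricating a statistic.

## Behavior

Flight index = (6U + 4H + 2D)/T, scale-invariant in the counts. Wingbeat
frequency is the dominant peak of a Welch spectrum (quarter-second Hann
segments) inside 80–300 Hz — a band covering both 15 °C and 22 °C
values — refined by parabolic interpolation; a peak below 5× the median
band power means no wingbeat. Welch averaging matters: on a raw
periodogram the maximum over ~200 noise bins is typically 7–8× the
median, so a raw-spectrum threshold cannot separate noise from signal.

## Structure contacts

Distances are minima over the charged side-chain atom cross product
(Lys NZ; Arg NE/NH1/NH2; Asp OD1/OD2; Glu OE1/OE2) — whether published
contact distances are heavy-atom minima or named-atom distances is
rarely stated, so the minimum convention is adopted and documented. The
salt-bridge cutoff defaults to **4.0 Å** (3.0–3.2 Å contacts count as
bridges, 4.5–5.7 Å contacts as lost), configurable. Residues without
formal charge (e.g. Asn) fall back to polar side-chain N/O for the
distance but can never classify as bridges. Homology models are not
rebuilt here; published distances anchor the semantics and the tests run
on constructed coordinates.

## Statistics and reporting

Equal-variance (classic Student) two-sample t-tests are used throughout
rather than Welch — mirroring, not improving, the field's convention —
plus paired t-tests, one-way ANOVA with Bonferroni-adjusted pairwise
follow-ups (p·m capped at 1), and two-way between-subjects ANOVA
(whether age should be treated as repeated measures is ambiguous in
typical designs; between-subjects is implemented and documented). Stars:
* p<0.05, ** p<0.01, *** p<0.001. Percent changes round half away from
zero for text reporting. The cohort report attaches a source operation
id to every cell and serializes deterministically (sorted keys), so
re-runs with the same seed and config are byte-identical.

## Problem sizes used in validation

The test suite and acceptance checks run ensembles of 600–800 bridges,
5–10 cycles per frequency, 9–13 frequencies per spectrum and 3–5 seeds
per condition, with 200-replicate bias studies and 2000-replicate null
calibrations; these sizes give Monte-Carlo standard errors comfortably
inside every asserted tolerance while keeping the full suite in the
minutes range on a single core.

## Known limitations

- The two-state ensemble cannot separate the work-producing and
  work-absorbing corners as widely as real fibers do (real b ≪ c needs
  ≥3 biochemical states), so its fitted b and c are closer together than
  experimental values; tests assert trends, not separation.
- 2πc recovered from noisy 0.5–650 Hz spectra is weakly constrained
  (corner above the band); see the fit section's error characterization.
- Trace ingestion assumes pre-extracted diameter traces and normalized
  stress/strain; video processing, image segmentation and series-
  compliance corrections are out of scope.
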