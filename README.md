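# flymech

Integrative analysis of insect flight-muscle mechanics and *Drosophila*
cardiac physiology: sinusoidal fiber analysis with three-process
complex-modulus fitting, work-loop energetics, cross-bridge ensemble
simulation, enzyme and fiber dose–response fits, M-mode heart metrics,
flight behavior indices, and salt-bridge geometry on atomic models.

## Who this is for

Muscle physiologists and cardiac-model researchers who record
length/force traces from skinned fibers, heart-wall diameter traces from
M-mode kymograms, ATPase dose–response tables, or flight-assay counts,
and want a tested, scriptable pipeline from raw delimited-text
recordings to the summary quantities the field reports — plus a
stochastic cross-bridge simulator that generates realistic synthetic
versions of every one of those inputs for validation and power analysis.

## The models at the core

**Sinusoidal analysis.** A fiber driven by a small sinusoidal length
change ε(t) = ε₀ sin 2πft responds with stress whose in-phase and
quadrature components define the complex modulus Y(f) = E′(f) + i E″(f).
Net work per cycle per volume is W(f) = −π ε₀² E″(f) (positive when the
fiber does work on the apparatus) and power is P(f) = W(f)·f. The
spectrum is fit with the three-process form

    Y(f) = A (2πif/α)^k − B·if/(b + if) + C·if/(c + if)

whose characteristic frequencies, converted to angular rates **2πb** and
**2πc**, are apparent rate constants of the cross-bridge cycle: 2πb
reflects myosin attachment and the power stroke, 2πc reflects
detachment.

**Work loops.** Large-amplitude cycles are integrated directly:
work generated = ∫F(−dL) over shortening, work absorbed = ∫F dL over
lengthening, net work = their difference (the signed loop area,
counter-clockwise = work-producing), power = net work × frequency.

**Cross-bridge ensemble.** A Monte-Carlo ensemble of independent
two-state bridges (attach at rate f_att; detach at rate
g₀·exp(−x/δ), slowing under stretch; force κ(x + d) per attached
bridge) generates all fiber inputs and reproduces the mechanistic
picture above: the fitted work-absorbing rate tracks detachment, the
work-producing rate tracks attachment, and isometric tension tracks the
duty ratio f_att/(f_att + g₀).

**Dose–response, cardiac, behavior, structure.** Michaelis–Menten fits
(V_max, K_m, catalytic efficiency V_max/K_m) for ATPase vs [actin] and
f_max vs [ATP]; linear regression for f_max vs [Pi]; beat-level DD, SD,
fractional shortening, heart period, systolic interval and SI/HP from
diameter traces, plus the EGTA/blebbistatin relaxation assay; flight
index (6U + 4H + 2D)/T and wingbeat frequency; minimum charged-atom
distances and salt-bridge classification on PDB coordinates.

## Worked example

Forward-model a control fiber's 50-frequency sweep, extract the modulus
spectrum from the traces, and refit the three-process model:

```python
import numpy as np
import flymech as fm

control = fm.NyquistFit(A=339, k=0.12, alpha=1.0,
                        B=741, b=1036 / (2 * np.pi),
                        C=923, c=5376 / (2 * np.pi))
freqs = np.logspace(np.log10(0.5), np.log10(650), 50)
traces = [fm.gen_linear_trace(control,
                              fm.SyntheticProtocol(kind="sinusoid",
                                                   frequency=float(f),
                                                   n_cycles=8))
          for f in freqs]
spectrum = fm.sweep_spectrum(traces)
summary = fm.summarize_spectrum(spectrum)
fit = fm.fit_nyquist(spectrum, seed=0)
print(f"f_max  = {summary.f_max:6.1f} Hz   peak power = {summary.power_max:.2f} W/m^3")
print(f"f_Wmax = {summary.f_wmax:6.1f} Hz   peak work  = {summary.work_max:.3f} J/m^3")
print(f"2*pi*b = {fit.two_pi_b:7.1f} 1/s   2*pi*c = {fit.two_pi_c:7.1f} 1/s")
```

prints

```
f_max  =  130.0 Hz   peak power = 51.80 W/m^3
f_Wmax =  112.3 Hz   peak work  = 0.423 J/m^3
2*pi*b =  1036.0 1/s   2*pi*c =  5376.0 1/s
```

The optimal oscillation frequency for power (130 Hz here) sits above the
optimum for work because power weights work by frequency; both rate
constants are recovered exactly from the noiseless traces, confirming
the trace → spectrum → fit chain is self-consistent. Comparing against
a second fit with heterozygote-like parameters reports the rate-constant
contrasts the analysis is designed to detect:

```python
contrast = fm.rate_constant_contrast(fit, mutant_fit)
# attachment-side rate change: +30%
```

A command-line surface mirrors the library:
`flymech simulate | sinusoidal | nyquist-fit | workloop | dose-response |
cardiac | flight | contacts | report` (see `flymech --help`).

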