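# cdbind

Quantitative analysis of 1:1 host–guest inclusion complexes, built around
the three experiments routinely combined to characterise a cyclodextrin
complex of a small hydrophobic guest:

1. **Continuous-variation ¹H NMR titration** (Job plot) — stoichiometry
   from the location of the maximum of |Δδ|·[X] versus the mole fraction
   r = [X]/([H]+[G]), and a global least-squares fit of the association
   constant K across multiple protons under fast exchange.
2. **Isothermal titration calorimetry (ITC)** — single-class-of-sites
   (independent-sites) isotherm fit of the integrated injection heats,
   yielding the stoichiometry n, the association constant K and the molar
   enthalpy ΔH, with ΔG = −RT ln K and TΔS = ΔH − ΔG derived.
3. **DPPH antiradical kinetics** — scavenging % = 100·(A_c − A_s)/A_c at
   517 nm over timed reads, summarised and compared between the free
   antioxidant and its inclusion complex to detect sustained release.

Seed-controlled synthetic generators emulate each experimental design
(11 continuous-variation samples at 10 mM total; 25 × 10 µL injections of
4 mM guest into a 1 mL cell of 1 mM host at 25 °C; 15 absorbance reads at
30 s intervals), so every stage of the pipeline can be validated by
round-trip parameter recovery without instrument data.

## The models

All stages share the mass-action 1:1 equilibrium H + G ⇌ HG. At totals
[H], [G] and association constant K (M⁻¹) the complex concentration is the
root of K([H]−c)([G]−c) = c in [0, min([H],[G])], evaluated in the
cancellation-safe product form

    c = 2[H][G] / (b + √(b² − 4[H][G])),   b = [H] + [G] + 1/K.

**NMR.** Under fast exchange a proton j of sample i shows
Δδ(i,j) = δ_free(j) − δ_obs(i,j) = Δδc(j)·c_i/[X]_i, where Δδc(j) is the
complexation-induced shift amplitude and [X] the total of the species
bearing j. The fit minimises E = Σᵢⱼ (Δδ(i,j) − Δδ_calc(i,j))² over K and
the Δδc(j); for fixed K the amplitudes are linear, so the problem reduces
to a deterministic 1-D search over log₁₀ K (log grid + golden-section
refinement). The reported correlation factor r is the Pearson correlation
of pooled observed versus calculated Δδ.

**ITC.** With n identical independent sites the cumulative heat is
Q = ΔH·V₀·c(n·M_t, X_t, K); per-injection heats are differences of Q at
the post-injection concentrations under a sequential well-mixed overflow
dilution model, plus the heat carried out by the displaced volume. The fit
searches (log₁₀ K, n) with ΔH profiled out in closed form.

## Worked example

Simulate a continuous-variation series (known K = 6181 M⁻¹, 0.001 ppm
shift noise), then infer stoichiometry and refit K:

```
$ cdbind simulate-nmr --seed 7 --out cv
wrote cv.csv (11 samples, 8 protons; truth K = 6181 M^-1)
$ cdbind jobplot cv.csv cv_assignments.csv --out job.json
r_max = 0.500 -> stoichiometry 1:1
$ cdbind fit-nmr cv.csv cv_assignments.csv --out fit.json
K = 6163 M^-1  (E = 6.05e-05 ppm^2, r = 0.9999, n_points = 88, converged = True)
```

The Job curve peaks at mole fraction 0.500, the 1:1 signature, and the
fitted K lands within 0.3% of the generator's ground truth; E is the
residual sum of squares (ppm²) over the 88 pooled (sample, proton) points.

The calorimetric stage, at 1% heat noise:

```
$ cdbind simulate-itc --seed 7 --noise 0.01 --out itc
wrote itc.csv (25 injections; truth n = 1.098, K = 3920 M^-1, dH = -2.36 kJ/mol)
$ cdbind fit-itc itc.csv --config itc_protocol.yaml --out itcfit.json
n = 1.115, K = 3781 M^-1, dH = -2.372 kJ/mol; dG = -20.42, TdS = 18.05 kJ/mol (enthalpy-and-entropy-driven)
```

The fitted triple reproduces the generating parameters to a few percent,
and the decomposition shows a spontaneous (ΔG < 0), entropy-dominated
(|ΔH| < |TΔS|) association — the signature of hydrophobically driven
inclusion. Finally the kinetics comparison:

```
$ cdbind simulate-dpph --seed 7 --out dpph
wrote dpph.csv (6 traces)
$ cdbind dpph-compare dpph.csv --config dpph_config.yaml --out cmp.json
125uM: free endpoint 44.7% vs complex 24.8%; sustained release = True
250uM: free endpoint 79.7% vs complex 43.7%; sustained release = True
62.5uM: free endpoint 25.0% vs complex 13.7%; sustained release = True
```

At every concentration the complex ends the assay below the free compound
and starts slower — the sustained-release signature of an inclusion
complex metering out its guest.

The same functionality is available as a library (`import cdbind`); see
`docs/methods.md` for the models, parameter defaults and numerical
choices.

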