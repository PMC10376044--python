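# Methods

## Scope and model assumptions

`cdbind` treats a single 1:1 association H + G ⇌ HG between a host (a
cyclodextrin-type macrocycle) and a guest, under ideal-solution
assumptions: concentrations stand in for activities, and no cooperative,
1:2/2:1, or competitive equilibria are modelled. All computation is SI
internally (M, L, J/mol); boundaries report in the conventional units
(mM, µJ, kJ/mol, ppm).

The complex concentration at totals H, G and constant K is the smaller
root of the mass-action quadratic, the only root in [0, min(H, G)]. It is
evaluated in the product form c = 2HG/(b + √(b² − 4HG)) with
b = H + G + 1/K, which is algebraically identical to (b − √(b² − 4HG))/2
but avoids catastrophic cancellation when 4HG ≪ b² (weak binding, strongly
unequal totals). Note that the *forward* residual K(H−c)(G−c) − c is
ill-conditioned to evaluate in double precision near saturation (large K):
the accuracy of the root is therefore stated, and tested, as a backward
error — the Newton correction |R/R′| is below 10⁻¹⁰·c — together with
agreement with an independent bisection solve.

Thermodynamics uses R = 8.314462618 J mol⁻¹ K⁻¹ (CODATA) and represents
25 °C as 298.15 K. ΔG = −RT ln K, TΔS = ΔH − ΔG (exact by construction).
The driving-force label is assigned by the signs of the two favorable
terms: `enthalpy-and-entropy-driven` (ΔH < 0, TΔS > 0), `enthalpy-driven`,
`entropy-driven`, and — because the three conventional labels do not cover
ΔH ≥ 0 with TΔS ≤ 0 — a fourth label `unfavorable` for that non-binding
region. A separate flag marks entropy domination (|ΔH| < |TΔS|), the
conventional indicator of hydrophobically driven inclusion.

## NMR continuous-variation analysis

A series holds [H]t + [G]t constant while the mole fraction sweeps (0, 1).
Fast exchange is assumed: each proton shows one population-weighted
resonance, so Δδ(i,j) = δ_free(j) − δ_obs(i,j) = Δδc(j)·c_i/[X]_i. The
sign convention keeps Δδ signed (amplitudes may be negative for downfield
movers); the Job ordinate uses |Δδ|·[X] so host and guest protons overlay
on one axis.

**Job plot.** The peak of each proton's curve is located by a parabola
fitted through all points with ordinate ≥ 80% of the maximum (at least
three; if the threshold selects fewer, the top three points are used).
The reported r_max is the median of the per-proton vertices. Stoichiometry
bands make the inference total and testable: r_max ∈ [0.45, 0.55] → 1:1,
[0.30, 0.37] → 1:2, [0.63, 0.70] → 2:1, otherwise indeterminate. Samples
where the observed species is absent (series endpoints) carry no resonance
and are excluded rather than treated as Δδ = 0.

**Association-constant fit.** The loss E = Σᵢⱼ(Δδ − Δδ_calc)² is
conditionally linear: for fixed K, Δδc(j) = Σᵢ x_ij Δδ_ij / Σᵢ x²_ij with
x_ij = c_i/[X]_i. The outer problem over log₁₀ K (default bounds
[10⁰, 10⁷] M⁻¹) is solved by a deterministic 200-point log-spaced grid
scan followed by golden-section refinement of the bracketing triple
(`scipy.optimize.minimize_scalar`, bounded fallback if the bracket is
degenerate). No random initialisation is used; the 1-D exhaustive scan
makes the search global at negligible cost. A fit whose optimum lands on a
grid boundary is flagged non-converged. The single reported correlation
factor is the Pearson correlation of the pooled (observed, calculated) Δδ
pairs across all protons — the only single-number definition consistent
with a multi-proton fit.

**Proton selection.** By default the fit uses every proton whose largest
|Δδ| is at least 3× the shift-noise estimate. The noise is estimated from
the data as the pooled robust sd of second differences of each proton's
Δδ curve ordered by mole fraction (σ ≈ std(Δ²)/√6): second differencing
annihilates the locally linear part of the smooth binding curve, leaving
noise. An explicit proton list overrides the selection.

Identifiability guards: all-zero shift changes, or a series with a single
composition, raise errors rather than returning a meaningless K.

## ITC analysis

**Dilution bookkeeping.** The cell is a fixed-volume overflow cell: each
injection of volume dv displaces an equal volume of well-mixed content, so
M_t ← M_t(1 − dv/V₀) and X_t ← X_t(1 − dv/V₀) + X_syr·dv/V₀, applied
sequentially (exact geometric dilution rather than the lumped ΔV/2V₀
approximation some vendor software uses; at 10 µL into 1 mL the difference
is far below fit uncertainty).

**Isotherm.** With n identical independent sites per macromolecule the
bound-ligand concentration equals the 1:1 equilibrium complex at site
total n·M_t, and the cumulative heat is Q = ΔH·V₀·c(n·M_t, X_t, K) — the
standard single-class-of-sites (Wiseman) closed form. Per-injection heats
are dq_i = Q(i) − Q(i−1) + (dv_i/V₀)(Q(i) + Q(i−1))/2, evaluated at
post-injection concentrations; the last term is the heat carried out with
the displaced volume and can be switched off.

**Fit.** Bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) over (log₁₀ K, n), with ΔH profiled out in closed
form at every iterate (the model is linear in ΔH). Defaults: start at
K = 10³ M⁻¹, n = 1; bounds log₁₀ K ∈ [0, 9], n ∈ [0.05, 20]. A control
(blank-titration) series, when present, is subtracted elementwise before
fitting. Convergence requires optimizer success and no parameter pinned at
a bound. ΔG and TΔS are derived at the protocol temperature.

The experiment operates at Wiseman c = nKM₀ ≈ 4 for the default
parameters — a shallow isotherm in which K is genuinely weakly determined;
at 2% heat noise individual experiments recover K with a median error of
~8% but occasional 30–40% excursions. Recovery tests therefore assert
median behaviour over replicate seeds, not single draws.

## DPPH kinetics

Scavenging % = 100(A_control − A_sample)/A_control against a single
per-assay control read; time-resolved control drift is not modelled.
Negative scavenging is preserved (not clamped) so blank problems stay
visible. Trace summaries: endpoint scavenging at the final read; initial
slope from a straight-line fit of the first three reads (%/s); time to 90%
of the endpoint by linear interpolation with the implicit origin (0 s, 0%)
prepended; and a quasi-linearity flag set when the R² of a straight-line
fit over the full trace is ≥ 0.98 — an operational threshold chosen to
make the qualitative notion testable. The free-vs-complex verdict
`sustained_release` requires both a lower complex endpoint and a smaller
complex initial slope.

## Synthetic generators

The generators reproduce the study designs with all randomness drawn from
a `numpy` Generator seeded by the caller; outputs are bit-reproducible per
seed.

- **NMR** (defaults): K = 6181 M⁻¹; 11 samples, guest mole fractions
  equally spaced over the open interval (0, 1) (r_i = i/12) at 10 mM
  total; Gaussian shift noise sd 0.001 ppm, a typical read precision at
  500 MHz. Free shifts for the six guest protons are the tabulated
  experimental values; the host H3/H5 free shifts (3.830/3.520 ppm) are
  conventional placeholder constants, configurable, since the interior
  cavity protons were not tabulated. Amplitudes Δδc default to
  0.05–0.30 ppm with the hydrazone-adjacent proton largest and one
  negative host amplitude to exercise the sign convention.
- **ITC** (defaults): n = 1.098, K = 3920 M⁻¹, ΔH = −2.36 kJ/mol under
  25 × 10 µL of 4 mM titrant into a 1.0 mL cell of 1 mM host at
  298.15 K. The instrument's active cell volume is not part of the
  published protocol; 1.0 mL (the nominal volume of this instrument
  family) is the configurable default, shared between generator and
  fitter so recovery tests are self-consistent. Heat noise is Gaussian
  with sd defaulting to 2% of the largest |heat|.
- **DPPH** (defaults): 15 reads at 30 s; control absorbance 1.0 AU;
  absorbance noise sd 0.002 AU. Free compound: S(t) = S_max(1 − e^(−k_f t))
  with k_f = 0.02 s⁻¹ (90% of plateau near 115 s, matching a fast
  antioxidant that finishes within ~150 s). Complex: consecutive
  first-order release-then-scavenge,
  S(t) = S_max[1 − (k_f e^(−k_r t) − k_r e^(−k_f t))/(k_f − k_r)] with
  k_r = 0.002 s⁻¹. Equal rates are rejected (the confluent limit is not
  implemented). Plateau levels 25/45/80% at 62.5/125/250 µM are chosen as
  realistic concentration-dependent endpoints; no numeric plateau values
  are published for this system. These kinetic forms are invented test
  scaffolding — they encode the qualitative fast-plateau vs
  sustained-release contrast, not a fitted mechanism.

What the generators do **not** emulate: spectrometer line shapes and peak
overlap, baseline/integration error in calorimetric peaks, instrument
drift, correlated noise, or concentration errors. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to every artefact of real instrument data.

## Problem sizes and determinism

All analyses are desk-scale: the full test suite (including 10⁴-draw
root-accuracy sweeps, 50 simulated NMR series and 40 simulated titrations)
runs in well under a minute on one CPU. Every stochastic test fixes its
seed; the two optimisers are deterministic by construction (grid + golden
section; trust-region least squares from a fixed start).

## Known limitations

- Only 1:1 binding; the Job-plot bands flag 1:2/2:1 but no such isotherm
  is fitted.
- The NMR fit weights all protons equally (unweighted least squares);
  heteroscedastic shift errors are not modelled.
- ITC concentrations are taken as exact (no error-in-variables
  correction), and baseline construction/peak integration is upstream of
  this package — it consumes integrated heats.
- The DPPH module summarises kinetics; it does not estimate IC50 or fit
  mechanistic rate laws.
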