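# Methods

## Scope and model assumptions

The package analyses ¹H-¹⁵N HSQC titrations and ¹⁵N-CPMG relaxation
dispersion under three standing assumptions:

1. **Single-site binding in fast exchange.** Each observed amide peak is
   the population-weighted average of the free and bound positions, so its
   displacement is proportional to the bound fraction. Multi-site binding,
   cooperative binding and slow-exchange (peak-doubling) titrations are
   out of scope; non-linear peak trajectories are a diagnostic the user
   must notice, not something the fitter detects.
2. **Two-site conformational exchange with equal intrinsic relaxation.**
   Dispersion curves are modelled as exchange between a major state *a*
   and a minor state *b* with R2a⁰ = R2b⁰. State-specific intrinsic rates,
   three-site exchange and off-resonance R1ρ effects are not modelled.
3. **Consistent assignments across states.** Peak tracking across
   titration points is assumed solved upstream; residues that disappear on
   binding (exchange broadening) are carried as `missing_flag` rather than
   deleted, so perturbation statistics are never silently biased.

## Binding isotherm and global fit

The bound fraction uses the quadratic closed form in *total*
concentrations, f = (b − √(b² − 4[L]t[P]t))/(2[P]t) with
b = [P]t + [L]t + Kd. It reduces to the hyperbola [L]/([L]+Kd) when
[P]t ≪ Kd (relative deviation < 1% for [P]t < Kd/100, property-tested) and
remains exact in the tight-binding regime [P]t > Kd.

`global_kd_fit` minimizes the stacked residuals
Δδ_max(r)·f(Pᵢ, Lᵢ; Kd) − Δδ_obs(r, i) with a trust-region-reflective
least-squares solver (via lmfit). Numerical choices:

- **Kd in log₁₀ space**, bounded to [10⁻², 10⁷] μM: the supported regimes
  span ~10 μM to >10 mM and a log parameterization keeps the step size
  scale-free. The reported Kd_sd is the delta-method transform of the
  log-space standard error.
- **Initialization**: Kd at the midpoint of the ligand concentrations;
  each Δδ_max at the residue's final-point Δδ_obs (a lower bound on the
  saturation shift, adequate for a monotone one-parameter-per-residue
  model). The objective is well-behaved enough here that multi-start was
  unnecessary (unlike the dispersion fit below).
- Residues with an all-zero curve are dropped with a warning; a fit that
  exhausts its iteration budget returns `converged=False` instead of
  raising.
- Titration points carry per-point [P]t; dilution correction across the
  series is the caller's responsibility.

The ¹⁵N weight in the compounded shift is 0.2 (configurable), applied
identically in the titration and projection stages so the whole pipeline
uses one shift metric.

## Projection analysis

Displacement vectors live in the (Δδ_H, 0.2·Δδ_N) ppm plane — the same
scaling as the compounded shift, chosen so that direction comparisons and
magnitude filters are mutually consistent. cos θ is clipped to [−1, 1]
against rounding; zero-length vectors make the angle undefined and the
residue excluded with a reason, never NaN-propagated.

The "similar perturbation" clause of the coordinated definition is
operationalized as X ∈ [1/X_tol, X_tol] with X_tol = 2 by default — a
deliberately permissive band, surfaced as an explicit argument, since only
the cos θ ≥ 0.9 part of the definition is sharply quantitative. The
Δδ_obs > 0.05 ppm filter passes a residue when *either* bound state clears
it (also an explicit argument).

## CPMG: closed form, oracle, and the τcp convention

The Carver-Richards expression implemented is, with Δω = 2π·δω_ppm·ν_N
(ν_N = 0.10136767 × the ¹H field — the gyromagnetic-ratio magnitude
ratio), Ψ = kex² − Δω², ζ = −2Δω·kex·(pa − pb):

    D± = ½[±1 + (Ψ + 2Δω²)/√(Ψ² + ζ²)]
    η± = (δ/√2)·√(±Ψ + √(Ψ² + ζ²))
    R2eff(δ) = R2⁰ + ½[kex − (1/δ)·arccosh(D₊ cosh η₊ − D₋ cos η₋)]

where δ is the delay between successive 180° pulses. For η₊ > 300 the
arccosh is evaluated in log form (arccosh z → ln 2z) to avoid cosh
overflow during optimizer excursions; arccosh arguments that round below 1
are clamped with a warning.

The independent check is a Bloch-McConnell propagation: the two-site
transverse magnetization evolves under L = K − R2⁰·1 − i·diag(0, Δω)
between pulses, each 180° pulse conjugates the complex magnetization, and
one echo block is δ/2 − 180° − δ/2, so successive pulses are separated by
exactly δ. This operational definition pins the τcp convention: τcp ≡ δ.
Curves are conventionally plotted against 1/τcp.

The oracle's default output is the **asymptotic decay rate of the echo
train** — −ln|λ_max|/(2δ) from the dominant eigenvalue of the linear
two-echo propagator (an echo is an antilinear map; two echoes compose to a
linear one). This is the quantity the closed form models, and the two
routes agree to better than 0.05 s⁻¹ (in practice ~10⁻¹² s⁻¹) over the
supported box pa ∈ [0.9, 0.99], kex ∈ [200, 4000] s⁻¹, δω ∈ [0.5, 5] ppm
at both fields and all acquisition delays. A `mode="finite"` variant
propagates the actual n = T/δ echoes of a 40 ms constant-time period and
returns the major-peak amplitude ratio; at small n this retains
minor-eigenmode and projection contributions that the closed form omits —
up to several s⁻¹ in slow exchange with large δω — which is a property of
finite constant-time experiments, not an implementation discrepancy.
Fitting real intensity-derived data in that corner of parameter space
inherits this model error; the supported box above is where the closed
form is trustworthy.

Duplicate delays in the acquisition grid (0.714 and 2.50 ms, ×2) are kept
as independent observations in fits (they inform the noise level) and
averaged only inside the ΔR2 screen. The screen itself is strict:
ΔR2 = 2.0 s⁻¹ exactly does not count as dispersive.

`dual_field_fit` shares (pa, kex, δω_ppm) across fields with one R2⁰ per
field, and multi-starts a bounded least-squares fit over the grid
kex ∈ {200, 600, 1500, 3000} s⁻¹ × pa ∈ {0.90, 0.95, 0.99} ×
δω ∈ {1, 3, 5} ppm (36 starts), keeping the best reduced χ². The
Carver-Richards objective is multi-modal; single-start fits silently land
in wrong basins. kex is fitted in log₁₀ space. Single-field input
completes but is flagged: pa and δω are jointly unidentifiable there (only
the combination pa·pb·Δω² is constrained in fast exchange), so only kex
should be trusted from such fits.

## Dynamics comparison and structural annotation

The change classifier is a total function on the 2³ flag combinations;
coordinated gain/loss and unchanged are symmetric under swapping the two
ligand labels, uncoordinated is preserved as a class. The comparison is
deliberately qualitative — no attempt is made to compare signs or
magnitudes of Δω between states.

Distal annotation uses the minimum over all **heavy-atom** pairs between a
residue and any catalytic residue, with a strict > 6 Å cutoff. Heavy-atom
minimum is the stricter, more common contact definition; switching to
Cα-only would enlarge distances and should be done consciously by the
caller (the cutoff and atom selection are arguments). Catalytic residues
are always supplied by the caller because author numbering differs across
homologs.

## Consensus mapping

Residue→column maps are built from the gapped alignment by cumulative
non-gap counting; 1-based on both sides, '-' and '.' accepted as gaps. The
map is a strictly increasing bijection onto non-gap columns
(property-tested); inverting a gap column yields an explicit no-residue
signal rather than an exception.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of their spec (NumPy `default_rng` on the
spec's seed).

- **Titrations**: peaks move as apo + f·Δδ_vector with the compounded
  saturation shift drawn uniformly from 0.1–0.4 ppm and a uniformly random
  direction in the scaled shift plane; Gaussian position noise
  σ_H = 0.002 ppm, σ_N = 0.01 ppm per state (typical HSQC precision).
  Protein concentration defaults to 300 μM (mid-range of 150–450 μM
  samples); ratio grids are evenly spaced from 0 (apo) to the regime's
  maximum ratio, 7 points by default.
- **Dispersion**: forward Carver-Richards evaluation on the acquisition
  grid (0.625, 0.714 ×2, 1.0, 1.25, 1.67, 2.0, 2.50 ×2, 3.33, 5.0, 10 ms;
  T = 40 ms) at 500 and 800 MHz plus Gaussian R2eff noise σ = 0.3 s⁻¹.
  Dispersive residues default to pa = 0.95, kex = 1500 s⁻¹, δω = 2.5 ppm
  (ΔR2 far above the 2 s⁻¹ screen); non-dispersive residues have δω = 0.
- **Three-state studies** plant per-residue projection classes
  (coordinated: common direction within 10°, magnitude ratio 0.75–1.35;
  uncoordinated: 40–140° divergence; excluded: Δδ_obs ≈ 0.01 ppm) and
  dynamics classes (via per-state δω), and emit the truth table.

What the generators do **not** emulate: peak overlap and mis-tracking,
exchange broadening mid-titration, baseline/phase artifacts, correlated
(non-Gaussian) intensity noise, protein dilution across points, spectral
lineshapes. Passing recovery tests therefore demonstrates the estimators
are correct and well-conditioned under the stated statistical model, not
that real spectra of comparable quality will behave as cleanly.

## Validation summary (all computed by the test suite / acceptance script)

- Noiseless generator→fitter loops recover their truth to < 0.1%.
- With realistic noise, global Kd fits over 20 residues recover generative
  constants spanning 72.9 μM – 10.32 mM within a few percent and within
  the fit's 95% interval (six regimes, `scripts/acceptance.py`).
- Closed form vs Bloch-McConnell oracle: max deviation < 0.05 s⁻¹ over the
  250-point grid.
- ≥ 95% of planted projection and dynamics classes are recovered at
  default noise in the three-state study.

Problem sizes (20-residue titrations, single-residue dispersion fits,
24–48-residue studies) were chosen as representative of per-protein NMR
datasets of this kind.

## Known limitations

- The ΔR2 screen is a hard threshold; residues hovering near 2 s⁻¹
  flicker between classes under noise, and no multiple-comparison control
  is applied across residues.
- Kd and Δδ_max are jointly weakly identified when saturation is far from
  reached (the very-weak regime): the fit then reports honestly widened
  uncertainties rather than failing.
- CHESPA vector scaling (0.2·Δδ_N) is a convention; alternative weights
  change |X| but not the sign structure or the cos θ ordering.
- The finite-train vs asymptotic-rate distinction above matters for
  quantitative work in slow exchange; the package exposes both so users
  can measure the gap for their parameters.
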