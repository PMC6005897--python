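# nmrbind

Analysis pipeline for protein–ligand binding studied by solution NMR:
chemical-shift titrations, chemical shift projection analysis (CHESPA), and
¹⁵N-CPMG relaxation dispersion. It was built for comparative studies of
pancreatic-type ribonucleases binding mononucleotide ligands (3′-UMP at the
pyrimidine B₁ subsite, 5′-AMP at the purine B₂ subsite), but every stage is
generic over assigned ¹H-¹⁵N peak lists.

## What it computes

**Chemical-shift perturbations and Kd.** For each residue the compounded
perturbation between a ligand-bound and the apo state is

    Δδ_obs = √( (Δδ_H² + (0.2·Δδ_N)²) / 2 )   [ppm]

In fast exchange Δδ_obs tracks the bound fraction of the single-site
equilibrium, given in total concentrations by the quadratic isotherm

    f = ( [P]t + [L]t + Kd − √(([P]t + [L]t + Kd)² − 4[L]t[P]t) ) / (2[P]t)

`global_kd_fit` fits Δδ_obs(r, i) = Δδ_max(r)·f(Pᵢ, Lᵢ; Kd) simultaneously
over all affected residues (Δδ_obs > 0.05 ppm) with one shared Kd,
returning the fit's standard deviations. The quadratic form remains valid
in the tight-binding regime [P]t > Kd where the hyperbola fails.

**CHESPA.** For each residue the displacement vectors A (apo→bound-1) and
B (apo→bound-2) in the (Δδ_H, 0.2·Δδ_N) plane are compared through

    cos θ = A·B / (|A||B|)        X = A·B / |B|²

Residues move in a *coordinated* way when cos θ ≥ 0.9 with similar
magnitudes for both ligands, *uncoordinated* when cos θ < 0.9; residues
below the 0.05 ppm filter are excluded.

**CPMG relaxation dispersion.** R2eff is obtained from constant-time
intensities (R2eff = −ln(I/I₀)/T), screened for dispersion
(ΔR2 = R2eff(τcp = 10 ms) − R2eff(τcp = 0.625 ms) > 2 s⁻¹), and fitted —
jointly at 500 and 800 MHz — to the full Carver-Richards closed form for
two-site exchange (parameters pa, kex, Δω, per-field R2⁰). An independent
Bloch-McConnell matrix-exponential propagation of the echo train validates
the closed form to < 0.05 s⁻¹.

**Coordinated dynamics.** Per-residue dispersion flags across apo and the
two bound states classify dynamical changes (gain/loss in *both* bound
states = coordinated; in exactly one = uncoordinated), are overlaid with
the CHESPA classes, and can be annotated as distal/proximal to catalytic
residues (> 6 Å minimum heavy-atom distance) from a coordinate file.

A seeded synthetic-data module generates titrations, dispersion curves and
full three-state studies with planted ground truth, so the entire pipeline
is testable without spectrometer data.

## Worked example

```python
import nmrbind as nb
from nmrbind.synthetic import TitrationSpec, generate_titration, ratio_grid

spec = TitrationSpec(Kd_true=455.9, ratios=ratio_grid(18.0), seed=1)
series = generate_titration(spec)                      # 20 residues, 300 µM protein
csp = nb.compute_csp(series.apo, series.saturated)     # Δδ_obs at ratio 1:18
affected = nb.select_affected_residues(csp, threshold=0.05)
fit = nb.global_kd_fit(series, affected)
print(f"Kd = {fit.Kd:.1f} +/- {fit.Kd_sd:.1f} uM "
      f"({fit.n_residues} residues, converged={fit.converged})")
```

prints

```
Kd = 456.3 +/- 2.9 uM (20 residues, converged=True)
```

i.e. the global fit recovers the 455.9 μM generative dissociation constant
to 0.1% under realistic peak-position noise (σ_H = 0.002, σ_N = 0.01 ppm),
with a fit uncertainty that covers the truth.

The same pipeline runs from the shell:

```sh
nmrbind run-all --seed 5 --out results/
nmrbind simulate --kind titration --kd 300 --seed 1 --out sim/
nmrbind titrate --series-dir sim/ --out kd.json
```

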