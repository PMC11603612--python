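# Methods

## Model compounds

Each titratable site couples a titration coordinate λ (0 = protonated,
1 = deprotonated) to a one-dimensional harmonic environment coordinate x:

    V(x, λ) = (1−λ)·V_A(x) + λ·[V_B(x) + ΔΔG_env] + V^pH(λ) + V^barrier(λ)

with V_A = ½k_A(x−x_A)², V_B = ½k_B(x−x_B)².  The pH term is the linear
thermodynamic form V^pH = ln(10)·k_B·T·(pKa_ref − pH)·λ, which fixes the
end-state free-energy gap to the Henderson–Hasselbalch value; end-state
localization is supplied by the quartic barrier V^barrier = 16hλ²(1−λ)²,
which vanishes at λ ∈ {0,1}, peaks at h for λ = ½ and confines λ outside
[0, 1].  With these choices the true pKa is closed-form:

    pKa_true = pKa_ref + [ΔΔG_env + ½k_BT·ln(k_B_curv/k_A_curv)] / (k_BT·ln10)

(the log term is the entropic correction for unequal end-state
curvatures).  `analytic_pka` implements this and is cross-checked against
direct Boltzmann quadrature in the tests.

By default the two environment wells share curvature (k = 100 kJ·mol⁻¹,
mass 1 kJ·mol⁻¹·ps²) and are displaced by 0.2 λ-units at zero offset.  The
displacement changes no free energy (equal Gaussian integrals) but makes
the environment exert a genuinely fluctuating force on λ.  This matters:
with fully decoupled wells the λ subsystem is a deterministic
Nosé–Hoover chain on an isolated one-degree-of-freedom double well, which
exhibits sticky, heavy-tailed basin dwell times — an ergodicity artifact
of the low-dimensional toy, not of the method, which in its intended
setting couples λ to thousands of solvent degrees of freedom.

Histidine-like sites carry three λ coordinates — an unphysical protonated
reference state (no pH term) and two neutral tautomers biased by their
microscopic pKas (defaults 6.53 and 6.92, macroscopic pKa 6.38) — under a
flat-bottomed restraint on δ = |Σλ − 1|:

    V_rest = A·(1 + tanh((δ − w_flat)/w_switch))/2

with A = 200 kJ/mol, w_flat = 0.2, w_switch = 0.05.  A is ≫ k_B·T_λ even
at 1500 K (≈ 12.5 kJ/mol) so excursions beyond ±0.2 are rare, while the
flat bottom leaves the physically relevant Σλ = 1 manifold unbiased.

### Buried-residue gate

A buried residue is emulated by a conformational "gate" coordinate g
(mass 10) with potential 16·h_g·g²(1−g)² + 25·S(g), where
S(g) = 1/(1 + e^{(g−0.7)/0.05}) indicates the closed state.  The switch
sits past the barrier top, so the escape barrier seen from the closed well
equals h_g (`gate_height`); the closed well lies 25 kJ/mol above the open
well, so the 300 K equilibrium is essentially all-open.  The site's
environment offset is multiplied by S(g): with a large offset
(100 kJ/mol in the bundled scenario) the site can only titrate once the
gate has opened, and the true pKa (by quadrature over g,
`analytic_pka_gated`) is within a few hundredths of pKa_ref.  Runs start
gate-closed, which is what traps the standard baseline.

## Dynamics

All coordinates are propagated by velocity Verlet at dt = 0.002 ps.  In
`ph_afed` mode every λ (sites and buffers) carries an independent
Nosé–Hoover chain at its T_λ and every environment/gate coordinate one at
the physical temperature (chain length 4, time constant τ = 0.5 ps,
Suzuki–Yoshida order 4 → 3 weights, 5 inner multiple steps, chain masses
Q_j = k_B·T·τ²), applied as half-steps before and after the Verlet update
("side" scheme).  In `standard` mode a single stochastic velocity-rescaling
thermostat controls the pooled kinetic energy of all coordinates at the
physical temperature and λ masses are set to 5 — the conventional CpHMD
baseline.  (A global rescaling thermostat cannot equilibrate relative
temperatures of weakly coupled coordinates; the per-group temperature
columns make this "hot/cold zone" pathology visible, which is one of the
motivations for massive thermostatting.)

Presets: surface residues T_λ = 750 K, m_λ = 750, V_barrier = 10 kJ/mol;
buried residues T_λ = 1500 K, m_λ = 1500, V_barrier = 22 kJ/mol.  λ masses
are in kJ·mol⁻¹·ps² per λ-unit², so these literature values are used
verbatim.

### Charge constraint and buffers

Charge neutrality is enforced each step by a SHAKE-like projection onto
Σαᵢλᵢ = const (α_site = N_p(q_A − q_B), target fixed by the initial
state), followed by a RATTLE-like velocity projection — without the
latter, per-λ kinetic temperatures are ill-defined.  Ten flat-potential
buffer λ coordinates per titratable residue absorb the released charge.
Buffer α values are deliberately large (−2Σα_site each): the constraint
removes one kinetic degree of freedom, distributed across coordinates in
proportion to αᵢ²/mᵢ, and with the buffer block dominating Σα² the
projections act almost entirely on the buffers.  Since their potential is
flat, that perturbation has no configurational consequence, and the
titratable λ momenta stay nearly Maxwellian — the stated purpose of the
buffer construction.  Small buffer α values (α_site/N or /√N) were found
to leak the constraint into the site λ and visibly distort its sampled
distribution.  Exact per-coordinate temperature control under a constraint
is impossible with independent thermostats; the residual mismatch at the
site λ is ~2% with this design.

### d-AFED driving

A gate CV can be tethered (k = 1000 kJ/mol) to an extended variable s held
at T_s = 1000 K by a Langevin (BAOAB) integrator with γ = 5 ps⁻¹.  The
literature mass for s is quoted in mixed units; internally s has mass
100 kJ·mol⁻¹·ps², making it ~3–4× slower than the gate (adiabatic
driving) while crossing the 40 kJ/mol gate barrier in a few hundred ps.
The tether is removable: k = 0 reproduces the undriven trajectory
bitwise.

## Analysis

Frames classify as protonated (λ < 0.2), deprotonated (λ > 0.8) or mixed;
mixed frames are excluded from counts and reported separately.  The count
ratio observed at T_λ is reweighted as r^{T_λ/T} — exact when the λ
marginal is Boltzmann in the physical-temperature free-energy profile,
i.e. under adiabatic separation.  For histidine the two neutral tautomer
counts pool into the deprotonated class.  The first 10% of frames of every
run are discarded as equilibration (runs start fully protonated).

Per-replicate titration curves are fit with the generalized
Henderson–Hasselbalch model.  For trajectory-derived data the fit is
performed in the model's logit parameterization, logit f = n·ln10·(pH −
pKa), as a weighted linear regression: the reweighted log count ratio
carries approximately Gaussian noise of magnitude (T_λ/T)·√(1/v_p + 1/v_d)
(v = number of maximal basin visits, a renewal-statistics estimate), which
in fraction space becomes multiplicative and heavy-tailed.  Fraction-space
weighted least squares (`fit_hh`, used for externally supplied titration
points) is exactly equivalent on clean data but was found to be fragile
against the rare-long-dwell outliers of short runs.  The reported pKa is
the mean over replicate fits ± their standard deviation.

At the desk-scale budget used throughout (2·10⁵ steps = 400 ps per run,
6 pH × 3 replicates), a surface-preset site crosses its λ barrier only
~5–15 times per run, so single-point log-ratios carry ~0.5-nat noise and
the recovered pKa mean has a seed-to-seed spread of roughly 0.05–0.3 pKa
units.  This is the honest statistical limit of runs 25× shorter than
production-scale titrations; the tests that assert 0.1-unit recovery are
correspondingly at the edge of that spread.

The two-site coupled model fits the summed proton count
⟨P⟩ = (2x² + K₁x)/(x² + K₁x + K₁K₂), x = 10^−pH, in stepwise constants.
For two *independent* sites the stepwise constants differ from the site
pKas by log10(1 + 10^−Δ) (Δ = pKa separation) — at Δ = 2 that is 0.0043,
so recovery of (3.0, 5.0) is exact only up to this structural offset; the
tests assert the exact transformed values.

Prediction metrics are MUE, RMSE and Pearson r, rounded only at
presentation; the bundled HEWL benchmark table reproduces its published
error footers.

## Problem sizes

Tests and the acceptance script use 2·10⁵-step production runs (the
package's desk-scale standard, a 400 ps analogue of nanosecond-scale
production titrations), 10⁵-step integrator checks, and 10⁶-step runs for
distribution, adiabaticity and buried-residue contrast checks.  A full
reference-compound scan takes ~3 minutes on one CPU.

## Known limitations

- The environment is a single harmonic coordinate: no explicit solvent,
  electrostatics, or conformational entropy beyond the gate; passing tests
  validate the sampling machinery and the analysis stack, not force-field
  accuracy on real proteins.
- Eq-8-style reweighting assumes adiabatic separation; with d-AFED active
  the gate populations are tempered at T_s, which biases gated-site pKa
  estimates by a few hundredths of a unit (open-well-dominant design keeps
  this small).
- Mixed-state frames are excluded rather than reweighted into the basins;
  the titration table keeps the mixed fraction so such a scheme could be
  added downstream.
- The stochastic-rescaling baseline shares one thermostat across weakly
  coupled coordinates and therefore equilibrates their relative
  temperatures only through physical coupling — reproducing, deliberately,
  the known weakness of global thermostats in this setting.
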