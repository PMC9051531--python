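# Methods

## The model

`brushdpd` simulates a polydisperse polymer brush — chains of several
polymerization degrees end-grafted to a planar surface — immersed in
explicit solvent and compressed by a second, flat surface standing in for
the (locally flat) tip of an AFM probe. The working question is mechanical:
when the *grafting* surface is made stiffer while the brush itself is left
untouched, how does the force on the compressing tip change, and can the
surface contribution be separated from the brush contribution?

The dynamics are dissipative particle dynamics (DPD) in standard reduced
units (bead mass = cutoff r_c = thermal energy kT = 1). Beads interact
through the soft conservative repulsion

    F_C = a_ij (1 − r/r_c) ê,        r < r_c,

plus the pairwise thermostat: a dissipative force −γ w²(r) (ê·v_ij) ê and a
random force σ w(r) θ_ij ê /√δt with w(r) = 1 − r/r_c. Fluctuation–
dissipation fixes σ² = 2γkT and is enforced at construction; parameter sets
violating it are rejected. Chains are bead–spring polymers: consecutive
beads joined by a finitely extensible spring

    F_bond = −k r / (1 − (r/R₀)²),

with no separate hard-core term — the DPD repulsion keeps beads apart, the
common softened form of the bead–spring model in DPD work. A harmonic
option (F = −k(r − r₀)) is provided and tested.

Both confining surfaces are structureless soft walls with the linear ramp
force law

    F_w(z) = a_w (1 − z/z_C),        z < z_C,  else 0,

directed into the fluid; `a_w` is the wall stiffness and z_C the wall
cutoff. The grafting wall's a_w is the swept variable; the tip wall's a_w
is fixed across a sweep. x and y are periodic; z is bounded by the walls.

Integration uses the modified velocity-Verlet scheme with velocity
prediction factor λ. Grafted anchor beads are frozen at z = 0 but continue
to exert forces. The random-force deviate θ_ij is produced by a
counter-based hash of (seed, step, pair), so any trajectory is bitwise
reproducible and independent of thread or iteration order.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| ρ (bead density) | 3 | r_c⁻³ | canonical DPD water-like parameterization |
| a_ij (all pairs) | 78.3 | kT/r_c | standard repulsion at ρ = 3; solvent–monomer equal to like pairs (athermal good solvent) |
| γ / σ | 4.5 / 3.0 | — | classic thermostat pair satisfying σ² = 2γkT |
| δt | 0.03 | DPD time | common production step; guard rejects δt > 0.05 |
| λ | 0.5 | — | textbook prediction factor |
| bond (FENE) | k = 30, R₀ = 1.5 | kT/r_c², r_c | keeps bonds < r_c scale without a hard core |
| wall z_C | 1.0 | r_c | wall range of order the interaction range |
| tip a_w | 250 | kT/r_c | fixed mid-range stiffness for the probe |
| T (calibration) | 300 | K | documented constant for the reduced↔physical map |

All are overridable through the YAML config. These are the package's own
defaults chosen from standard DPD practice; the physical claims the tests
make (ordering, scaling, regime structure) do not hinge on their exact
values.

Known numerical behaviour of these defaults: the Groot–Warren integrator
at δt = 0.03, λ = 0.5 equilibrates to a kinetic temperature ~2–2.5% above
the target — the familiar DPD timestep bias. Measurements that compare two
pressure estimators or test the ideal-gas law are therefore run at
δt = 0.01, where the discretization bias sits well below the statistical
resolution; production sweeps, which only ever compare pressures measured
the same way at the same δt, use 0.03.

## Unit mapping

One anchor — a wall stiffness known both in reduced force units and in
nanonewtons — fixes the linear reduced↔physical map, because reduced force
carries units of kT/r_c. With the anchor (150 ↔ 0.96 nN) at 300 K the
force scale is 0.0064 nN and the implied cutoff length r_c ≈ 0.647 nm;
the stiffest wall (400) then maps to 2.56 nN. The cutoff length converts
grafting densities quoted in chains/nm² into integer chain counts
(rounded half-up, so builder populations are deterministic).

## Compression protocol

A sweep visits a strictly decreasing list of wall separations h for each
grafting-wall stiffness. Constant chemical potential is implemented as a
constant-density reservoir: on each compression step exactly
N − round(ρ·Lx·Ly·h_new) solvent beads are removed, drawn at random
(seeded) from the solvent nearest the tip; brush beads are never removed,
so brush composition and bond topology are byte-identical across the whole
sweep, and stiffness is the only variable. A grand-canonical
insertion/deletion variant would be the rigorous alternative; the density-
matching rule matches the operational description of the experiment
(solvent count reduced on compression) without Monte-Carlo machinery.

Each stage runs a short warm-up at δt/6 (freshly clamped or built
configurations can contain near-overlaps whose force spikes would
overextend FENE bonds at full step), then equilibration, then production
during which P_zz is sampled. P_zz is measured two independent ways:

* **wall**: total z-force the fluid exerts on the tip wall divided by the
  lateral area;
* **virial**: (Σ m v_z² + Σ_pairs f_z z_ij + wall boundary terms)/V, with
  only conservative and bond forces in the pair sum (the dissipative and
  random channels average to zero). The wall boundary term — each wall's
  force times distance from its own plane — closes the mechanical-balance
  identity exactly, anchors included (anchors sit at z = 0 and contribute
  nothing).

The two estimators agree within statistical error on equilibrated runs at
small δt; this cross-check is part of the test suite.

Uncertainties are standard errors from block averaging (10 blocks), which
absorbs sample autocorrelation.

## Analysis chain

The bulk reference P_B is ⟨P_zz⟩ at the widest scheduled separation, where
the brush is unperturbed; the disjoining pressure is Π(h) = P_zz(h) − P_B
(zero at the widest point by construction). The Derjaguin approximation
converts plane–plane pressure into sphere–plane force per probe radius:

    F/R (h) = 2π ∫_h^{h_max} Π(h′) dh′,

evaluated by the trapezoid rule on the sampled grid. The 2π prefactor is
the sphere–plane convention; it cancels in every amplitude ratio, which is
why the headline statistic is prefactor-independent.

The unperturbed brush thickness L is taken from the first moment of the
combined brush concentration profile, L = 2⟨z⟩ — exact for a step profile
and standard for brushes; an r.m.s. variant (√3·z_rms) and the bare first
moment are also available, recorded in `definition_tag` so results are
auditable. Downstream fits use only the ratio h/L.

A polydisperse brush with one dense short population and two longer sparse
ones compresses in two regimes: a strong regime for h/L < 1 dominated by
the short chains and a weak regime for 1 ≤ h/L ≤ 2 carried by the longer
chains. The boundary point h/L = 1 is assigned to the weak regime (the
weak range being the closed interval). Each regime is fitted with the
Alexander–de Gennes exponential

    F/R = b · exp(−2π h / L_decay),

with the decay fixed (L_decay = L for strong, L′ = 3.3 L for weak) and the
amplitude b the single free parameter — a weighted linear least-squares
problem with inverse-variance weights when SEMs are available. Points with
non-positive force are excluded with a warning. The stiffness ratio

    r = b_hard / b_soft

equals the force ratio at every separation within a regime because the
exponential factors cancel; it is the indentation-independent measure of
how much stiffening the grafting surface amplifies the measured force, and
is proportional to the ratio of the surfaces' Young's moduli.

The analytic AdG forms are also provided: the exact expression
Π = Γ^{3/2} kT [(L/h)^{9/4} − (h/L)^{3/4}] (valid h/L < 1) and the
exponential approximation Π = 100 Γ^{3/2} kT e^{−2πh/L}. Dense evaluation
shows the approximation is within ~10% of the exact form for
0.25 ≤ h/L ≤ 0.6, but deviates −23% at h/L = 0.2 and −19% near h/L ≈ 0.78
before re-crossing around 0.9; the property tests assert these measured
bounds rather than a tighter band the mathematics does not support.

## Synthetic data and what passing tests show

The fixture generator produces three kinds of inputs: a tiny polydisperse
brush, a brush-free solvent slab, and synthetic force tables drawn from
the exponential brush law with multiplicative Gaussian noise. The
synthetic tables emulate the *shape* and noise level of force–compression
data; they do not emulate correlated sampling noise, drift, or the
near-contact upturn of real force curves, so fit-recovery results bound
estimator bias under ideal exponential decay only.

Simulation-based checks run at desk scale: slabs of ~900–1300 beads on
6×6 r_c² boxes, stages of 1.5–3×10³ steps, eight separations and two
stiffnesses. These sizes were chosen so the full suite runs on a single
CPU in minutes; they are large enough for the qualitative claims tested
(force ordering with wall stiffness, monotone force growth under
compression, near-parabolic brush profiles, log-linear force decay) but
far too small to reproduce published force-curve amplitudes, which also
depend on parameter values not printed in any source available to this
package. The printed amplitudes enter only through the analysis-chain
worked examples.

## Numerical choices and degenerate inputs

* Exactly overlapping beads (r = 0) repel along +x — a deterministic
  tie-break for a measure-zero event; the soft potential is finite there.
* A bead behind a wall plane feels the clamped contact force a_w; a bead
  that nonetheless leaves [0, h] is reflected elastically and counted.
* FENE bonds at or beyond R₀ raise an error naming the bond rather than
  integrating a divergent force.
* Chain counts and solvent-removal counts round half-up; ties in solvent
  selection are broken by the seeded stage RNG.
* Initial chains are straight with 0.1 r_c lateral jitter; chains longer
  than the slab are built at compressed spacing with a warning.
* Anchor placement enforces a 0.5 r_c minimum lateral spacing by rejection
  sampling; an over-packed surface raises a build error.

## Known limitations

* No electrostatics, angle potentials, shear, or decompression branch.
* The constant-μ scheme is density matching, not particle exchange; very
  strong compressions are bounded by the available solvent.
* The wall-force P_zz estimator inherits an O(δt²) bias near steep walls;
  compare estimators only at small δt.
* The stiffness ratio is reported as a dimensionless amplitude ratio; no
  conversion to absolute Young's moduli is attempted.
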