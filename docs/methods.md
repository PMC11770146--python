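# Methods

This note documents the models behind `depdisc`, the provenance of every
default, the numerical choices, and the limits of what the test suite can
establish.

## Circuit model

**Lumped elements.** The receiver disc is an LC tank: the printed coil's
inductance L (a measured input — see "Coil inductance" below) against the sum
C = C_electrode + C_coil + C_add. The two geometric terms are parallel-plate
estimates: C_electrode = n·2εhl/d_electrode treats each of the n finger pairs
as facing plates of height h (copper thickness) and length l separated by the
gap, with ε of whatever covers the fingers (the aqueous sample, ε_r ≈ 80, for
an uncovered array); C_coil = επ(r_out² − r_in²)/d_coil treats the coil's two
copper layers as an annular capacitor through the board (FR4, ε_r 4.5,
d_coil = board thickness 1 mm). These are order-of-magnitude design aids; when
a measured resonance curve exists, the preferred route is to invert
f = 1/(2π√(LC)) and store the result as a *parasitic override*
(`ReceiverTank.c_parasitic_override`). For the reference device that
inversion gives 35 pF from the observed 12.5 MHz bare peak, and adding the
450 pF stock capacitor predicts 3.37 MHz — consistent with the measured
3.5 MHz to ~4%.

**Coupled sweep.** The frequency response comes from the standard two-mesh
equations of magnetically coupled circuits: source resistance plus the
transmitter coil (R₁, L₁) on the primary; the receiver coil (R₂, L₂) in
series with the total tank capacitance on the secondary; mutual term jωM,
M = k√(L₁L₂). Per frequency this is a 2×2 complex linear solve; the receiver
voltage is taken across the capacitance, i.e. the electrodes are a purely
capacitive load. This is the simplest topology that reproduces a single
resonant receiver peak; it deliberately omits the sample's conductive loading
of the electrodes (uncharacterised) and any amplifier bandwidth model — the
transmitter-voltage droop seen with real amplifiers at high frequency enters
only through the source resistance. A genuine consequence of the coupling
worth knowing when testing: the receiver peak sits above the closed-form
1/(2π√(LC)) by a relative detuning of order k²/2 (reflected impedance), so
the closed form is recovered only in the joint low-loss *and* weak-coupling
limit.

**Calibration.** The physical device's k and coil resistances are never
known a priori; `fit_coupling_and_loss` fits them to a measured receiver
curve by bounded least squares (k ∈ [0, 1], R > 0, initial k = 0.3, R = 5 Ω,
`scipy.optimize.least_squares`). On noise-free synthetic curves the recovery
is exact to machine precision; the acceptance script exercises 20 randomized
cases. Without such a fit the absolute receiver voltage (e.g. a measured
55.6 Vpp at resonance) cannot be predicted, only its resonance frequency.

**Coil inductance.** The device documentation quotes the measured coil
inductance with an mH prefix, but 4.6 mH together with 35 pF would resonate
near 397 kHz, irreconcilable with the observed 12.5 MHz; 4.6 µH reproduces it
exactly. The fixtures therefore store 4.6 µH and treat the printed prefix as
a typo. No inductance-from-geometry formula is offered: the printed coil
geometry (13 turns at 2 mm pitch inside a 6 mm annulus) is only realisable
split across layers in an unstated way, so any spiral-inductor formula would
be guesswork; L is a measured input.

## Dielectrophoresis

Complex permittivity ε\*(f) = ε − jσ/(2πf); Clausius–Mossotti factor
K(f) = (ε_p\* − ε_m\*)/(ε_p\* + 2ε_m\*); time-averaged force on a
homogeneous sphere F = 2πr³ε_m·Re[K]·∇|E|², with E the field amplitude set
by the electrode potentials (below). Re[K] ∈ [−1/2, 1]; positive values pull
toward the field maxima at electrode edges (pDEP), negative push away. The
crossover-frequency finder brackets the single Maxwell–Wagner sign change on
a coarse log grid and bisects; a 10⁶-point brute-force scan is the test
oracle. ε₀ = 8.8541878128e−12 F/m. Spectra use log-spaced grids (they span
decades).

**Material parameters.** The experiments under study give no dielectric data
for the bead, yeast or water samples, so the fixtures carry documented
effective values:

- *DI water*: ε_r 80, σ = 2·10⁻⁴ S/m — practical deionised water exposed to
  air, not the 5.5·10⁻⁶ S/m theoretical limit.
- *Polystyrene beads (5 µm, carboxyl-modified)*: ε_r 2.55 and an **effective**
  conductivity 0.1 S/m standing in for bulk plus surface conduction. The
  value is chosen so the model reproduces the experimentally observed
  attraction of the beads to the electrode edges at 7 MHz (it puts the
  crossover at ≈16 MHz, hence Re[K] = +0.58 at 7 MHz). Textbook surface
  conductances (~1 nS) on a 2.5 µm radius would give σ_eff ≈ 10⁻³ S/m and
  *negative* DEP at 7 MHz, contradicting that observation; the discrepancy is
  real and unresolved, and quantitative bead predictions should not be read
  off this fixture. Density 1050 kg/m³ (standard polystyrene).
- *Baker's yeast*: a single-shell cell model is deliberately out of scope, so
  yeast is a homogeneous sphere with placeholder effective ε_r 60,
  σ 0.25 S/m, r 3 µm — values that make Re[K] ≈ +0.97 at 3.5 MHz in
  low-conductivity water, matching the observed attraction to electrode
  edges. Only this sign/qualitative behaviour is asserted anywhere.

## Electrode field

One periodic unit cell of the interdigitated array in 2D cross-section
(fingers long compared with the gap): a +V_pp/4 finger, a gap, a −V_pp/4
finger, a gap, so neighbouring fingers differ by V_pp peak-to-peak. Laplace's
equation with Dirichlet electrode segments on the floor, Neumann (insulating)
floor gaps and top wall, periodic sides. Copper relief is flattened onto the
boundary — a stated approximation, since h = 35 µm is not truly small against
the 125 µm gap. The medium is homogeneous, so its permittivity does not
affect the field *shape*; electrode polarisation screening is neglected.

Discretisation: 5-point finite differences, square-ish cells
(`resolution` nodes per period; the vertical count follows from the channel
height, floor 8), assembled sparse and solved directly
(`scipy.sparse.linalg.spsolve`); the discrete residual is verified below
1e−8 after the solve. E by central differences (periodic laterally,
one-sided at walls); |E|² and then ∇|E|² by the same stencils. Bilinear
interpolation serves off-node queries, exact at nodes, periodic in x.

Verified properties: the parallel-plate degenerate case reproduces |E| = V/g
to ~1e−13; φ obeys the discrete maximum principle; |E|² is maximal within
two cells of a finger edge (the mechanism that collects particles at edges);
solutions scale exactly with voltage (linearity), which `FieldMap.scaled`
exploits so one solve serves every drive level; the field at a fixed interior
height changes <2% between 128 and 256 nodes/period. The nodal field *at*
the electrode edge itself diverges with refinement — the corner singularity —
so pointwise convergence is only claimed away from the floor. Default
channel height 100 µm (not documented for the experiments; configurable).

## Particle transport

Overdamped dynamics: 5 µm beads in water have Re ~ 10⁻⁴ and momentum
relaxation ~ µs, so velocity is force/(6πµr) instantaneously. Forces: the
time-averaged DEP term (MHz drive period ≪ transport timescale) plus a
constant centrifugal body force (4/3)πr³(ρ_p − ρ_m)ω²R along the unit cell's
lateral axis — fingers are assumed perpendicular to the disc radius, the
electrode region sits at R = 25 mm from the spin axis by default (not
documented for the device; configurable). Gravity normal to the disc,
Coriolis/Euler forces, particle–particle dipole chaining and channel flow
are all out of scope.

Integration is explicit Euler. By default the step adapts to ~0.2 grid cells
of motion; a user-fixed dt is honoured, with halve-and-retry if a step would
exceed 10 cells. Outcomes: **trapped** when the particle is within 1.5
lateral grid cells of a finger edge and either its speed falls below
0.1 µm/s or it stays confined within a quarter-cell for 20 consecutive steps
— the confinement clause regularises the speed criterion at the edge
attractor, where the discretised (singular) field keeps the pointwise speed
finite while the particle rattles in the last cell; **washed** when the
cumulative lateral drift exceeds 5 periods; **undecided** at t_max (default
120 s). All thresholds are keyword-configurable.

Oracles: at zero voltage the drift speed equals the closed-form
(2/9)Δρ·ω²R·r²/µ to machine precision (constant force, Euler-exact); the
minimum holding voltage found by bisection (±2%, one field solve rescaled by
V²) doubles when ω²R quadruples, as the F_DEP ∝ V² vs F_c ∝ ω²R balance
demands; a negative-DEP particle over edge-maxima geometry is never trapped
(∞ sentinel).

## Workflow and configuration

`run_design` executes: capacitance estimate → resonance → recommended C_add
to hit the drive frequency (the design move: resonate where you drive) →
coupled sweep → K(f) at the drive frequency → unit-cell field solve → trap
check — and reports everything with a provenance block (config hash, seed,
version). The electrodes in the workflow are driven at the *predicted*
received voltage from the sweep, so an uncoupled (k = 0) case correctly
reports zero voltage and full washout; the standalone `trap-check` command
instead uses the configured `applied_v_pp` (useful when the electrode
voltage was measured, as it was for the validation experiments: 20 Vpp
applied / 12 Vpp received non-resonantly, 18 Vpp applied / 55 Vpp at
resonance). Configs are TOML with unit-suffixed keys, unknown keys rejected,
and errors naming the dotted field path; the pipeline is deterministic, so
identical config + seed give identical reports.

## Problem sizes

Defaults chosen for interactive use: 64 nodes/period field solves (convergence
documented above), 9-start trapping lattices, 250–2000-point sweeps, 20
fit-recovery cases and 10⁴ material draws in the acceptance study. All are
parameters, not limits.

## Known limitations

- The link model cannot predict absolute receiver voltage without a fitted k
  and R; only resonance positions are predictive from geometry alone.
- Flat-electrode approximation (h/gap ≈ 0.3 ignored); 2D cross-section only.
- Homogeneous-sphere dielectrics; no shelled cells, no electrode
  polarisation, no electrothermal or AC-electroosmotic flow.
- The bead fixture's effective conductivity encodes an observed behaviour,
  not an independent measurement (see Material parameters).
- Trap/wash outcomes are single-particle; the experimentally visible pearl
  chains arise from dipole–dipole interactions the model does not include.
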