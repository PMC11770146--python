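# depdisc

Design and simulation toolkit for **dielectrophoresis (DEP) on printed circuit
boards powered by resonant inductive power transfer**, as used in centrifugal
(lab-on-a-disc) microfluidics.

## The problem

DEP moves polarizable particles and cells with non-uniform AC electric fields.
PCB-manufactured interdigitated electrodes are cheap, but their ≥100 µm gaps
demand drive voltages beyond ordinary function generators — and on a spinning
disc there is no wired path to the electrodes at all. Both problems are solved
at once by a wireless resonant link: a stationary transmitter coil couples
into a receiver coil printed on the disc, and the receiver coil together with
the capacitance of the on-disc structures forms an LC tank whose resonance
boosts the electrode voltage far above the source amplitude.

`depdisc` models this chain end to end, for the engineer designing such a
disc:

1. **Circuit** (`depdisc.circuit`) — tank capacitance estimates
   C = C_electrode + C_coil + C_add with C_electrode = n·2εhl/d and
   C_coil = επ(r_out² − r_in²)/d, the resonance f = 1/(2π√(LC)) and its
   inversions, link quantities M = k√(L₁L₂), Q = 2πfL/R,
   η = k²Q₁Q₂/(1 + k²Q₁Q₂), a coupled two-mesh frequency-domain solver for
   the transmitter/receiver voltage curves, and a least-squares calibration
   of (k, R) against measured sweeps.
2. **DEP physics** (`depdisc.dep`) — complex permittivity
   ε\*(f) = ε − jσ/(2πf), the Clausius–Mossotti factor
   K(f) = (ε_p\* − ε_m\*)/(ε_p\* + 2ε_m\*), crossover frequencies, and the
   time-averaged force **F**_DEP = 2πr³ε_m·Re[K]·∇|E|².
3. **Field** (`depdisc.field`) — finite-difference Laplace solve of one
   periodic unit cell of the interdigitated array, yielding |E|² and ∇|E|².
4. **Transport** (`depdisc.trajectory`) — overdamped motion under DEP,
   Stokes drag and the centrifugal body force (4/3)πr³Δρ·ω²R, classified
   into *trapped* (held at an electrode edge) versus *washed* (swept away by
   the spin), plus minimum-holding-voltage design curves.
5. **Workflow** (`depdisc.workflow`, `depdisc.cli`) — a TOML-configured
   pipeline running all stages and emitting a JSON design report.

## Worked example

The reference device has a 13-turn, 4.6 µH receiver coil whose bare tank
(parasitic capacitance only) resonates near 12.5 MHz. To run DEP at a more
favourable 3.5 MHz, ask for the capacitor to solder across the receiver:

```console
$ depdisc design-resonance --inductance-h 4.6e-6 --c-parasitic-f 35e-12 --target-hz 3.5e6
{"bare_resonance_hz": 12543166.685511459, "recommended_c_add_f": 4.145172300014986e-10,
 "achieved_resonance_hz": 3499999.9999999995, "c_total_f": 4.4951723000149857e-10}
```

i.e. the bare tank resonates at 12.54 MHz, and adding ≈415 pF (a stock
450 pF part lands at 3.37 MHz) brings it to the 3.5 MHz target.

Will 5 µm polystyrene beads stay on the electrodes while the disc spins at
1000 RPM? Generate the shipped bead preset and check, with and without drive:

```console
$ depdisc make-fixture polystyrene_beads --out beads.toml
$ depdisc trap-check --config beads.toml --n-starts 9
{"trapped_fraction": 1.0, "outcomes": ["trapped", ..., "trapped"],
 "rpm": 1000.0, "v_pp": 20.0, "frequency_hz": 7000000.0}
$ depdisc trap-check --config beads.toml --vpp 0.001 --n-starts 9
{"trapped_fraction": 0.0, "outcomes": ["washed", ..., "washed"],
 "rpm": 1000.0, "v_pp": 0.001, "frequency_hz": 7000000.0}
```

With the 7 MHz, 20 Vpp drive every start position is pulled to an electrode
edge (the beads' effective Re[K] = +0.58 at 7 MHz → positive DEP); with the
drive essentially off, the centrifugal force washes every bead out. The full
pipeline — capacitances, resonance, recommended capacitor, sweep,
Clausius–Mossotti factor, field solve, trap check — runs with
`depdisc run-all --config beads.toml --out report.json`.

From Python the same objects compose directly:

```python
from depdisc import resonance_frequency, clausius_mossotti
from depdisc.fixtures import make_fixture

case = make_fixture("polystyrene_beads")
print(resonance_frequency(4.6e-6, 485e-12))        # 3369537.9 Hz
print(clausius_mossotti(case.suspension.particle,  # (0.5757-0.6634j)
                        case.suspension.medium, 7e6))
```

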