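# Methods

## Model

Every cell is a passive compartmental model.  A morphology is a tree of
sections, each an ordered chain of 3D reconstruction points with local
diameters; membrane area between consecutive points is the lateral frustum
area π(r₁+r₂)·√(L² + (r₂−r₁)²).  A single-point soma is treated as a
cylinder with length equal to its diameter (area πd²); multi-point somata use
the frustum formula directly.  Compartments carry c = area·c_m,spec and
g = area/r_m,spec toward a common leak reversal e_pas; axial resistance
between adjacent compartment centers is the series sum of the two facing
half-segment resistances, each integrated exactly over the tapered frusta
(R = R_i·L/(π·r_a·r_b) per linear-taper piece).  The voltage-clamp electrode
is an ideal source in series with Rs entering one compartment; pipette
capacitance is not modeled (assumed neutralized).

Spatial discretization follows the d_lambda rule: per section, the AC length
constant at a reference frequency f_ref is
λ_f = 10⁵·½·√(d/(π·f_ref·R_i·c_m)) (λ in µm for d in µm, R_i in Ω·cm, c_m in
µF/cm²), evaluated at the length-weighted mean diameter, and nseg is the
smallest odd integer making every segment shorter than d_lambda·λ_f.
Compartments sit at segment centers.

Gap junctions are ohmic conductances linking the compartments nearest two
chosen reconstruction points of neighboring cells.  Networks place identical
translated copies of one cell on a trapezoidal hexagonal 5×5 grid (interior
cells have six neighbors).  For each pair, N = 20 contact points are sampled
(seeded, without replacement) from the reconstruction points whose XZ
projection falls in a half-open 120° sector facing the neighbor (apex at the
unweighted point center of mass) and whose depth lies in a height band
covering the deeper half of the sub-somatic span; the two point sets are
sorted by depth and paired by rank, each contact receiving the pairwise
conductance divided by N.  Edge cells receive the same complement of
contacts per missing neighbor, clamped to e_pas ("open boundary").

## Estimation

The Sine+DC inversion is implemented exactly as the closed-form three-element
solution (see README).  Phase and current components are obtained by
quadrature projection/least squares over an integer number of cycles — exact
for noiseless sampled sines and free of optimizer nondeterminism, replacing
generic curve fitting.  Windows that do not span whole cycles are rejected
(spectral leakage would bias I_DC).  Per-cycle series can be block-averaged
(default 10 cycles) and low-pass filtered (zero-phase 4th-order Butterworth,
20 Hz corner — only the corner frequency is prescribed; the filter family is
our choice).  Δ-measurements subtract a pre-stimulus window mean (1600 ms)
from a post-stimulus window mean (400 ms).  E_rev of the DC current is
explicit configuration: −60 mV (the leak reversal) for simulations, −15 mV
as the physiological-recording preset; a mismatch between E_rev and the true
reversal is the leading source of G_t bias.  Estimates violating the
inversion's preconditions (B ≤ 0, A ≤ G_t) are flagged invalid, never
clipped — dendritic-recording protocols legitimately produce negative ΔCm.

Two engines compute the components.  The time-domain engine integrates
C·dV/dt = −G·V + b(t) with fixed-step Crank–Nicolson (backward Euler
available), initialized at the DC steady state; 1 µs steps for single cells,
5 µs or 100 points per cycle for networks.  The frequency-domain engine
solves the phasor system (G + iωC)v = e·g_s and reads the input admittance
Y(f) seen through Rs; A = Re Y, B = Im Y, and G_t follows from Y(0).  Both
use the same mesh, so their agreement (tested at <0.2%, observed ~10⁻⁵)
isolates the integrator rather than the discretization.  Parameter sweeps
default to the frequency-domain engine; a sampled step is treated by
Crank–Nicolson as acting half a sample early, which the step-response test
accounts for.

## Synthetic morphologies

The published reconstructions are proprietary, so a generator produces
AII-like stand-ins constrained only by the published emulation targets:

- soma: 8 µm cylinder (length = diameter) at the origin, long axis Y;
- one apical dendrite, 22 µm, tapering 2.5 → 1.2 µm, descending;
- 18 lobular appendages (2 µm bulges on 0.5 µm stalks) at path distances
  evenly spanning 6–39 µm from the soma center; distal distances are reached
  by laterally running stalk processes (15° below horizontal) rather than by
  deeper placement, keeping the total depth (~66 µm) compatible with a
  realistic inner-plexiform-layer thickness;
- an arboreal subtree of recursive binary branching (6 orders, per-order
  length 14→7 µm, diameter 1.0→0.35 µm, pitch steepening 30°→80° from
  vertical) descending from the apical tip;
- a final global scaling of non-soma diameters calibrates the total area to
  2073 µm² (root-finding, matched to machine precision; the acceptance
  tolerance is 2%).

Azimuthal angles are the only randomized quantities (single seeded RNG), so
the electrotonic structure is seed-independent and every experiment is
reproducible.  The generator emulates area, lobular path distances and
passive totals — it does **not** reproduce unpublished branch statistics,
varicosity shapes, spines, or the meandering of real dendrites.  A green
test on these cells therefore establishes that the estimator and solver
behave as published for a cell of this size and electrotonic class, not that
any particular biological cell would give identical numbers.  Passive
presets follow the published per-cell best fits (c_m 0.864/0.868/0.9016
µF/cm², r_m 43/25/36 kΩ·cm², R_i 223/223/224 Ω·cm, e_pas −60 mV).

RC fixtures (e.g. the 6 pF calibration model cell) are built as single
compartments whose area and specific parameters produce the requested totals
exactly.  Trace noise is white Gaussian on the current channel, seeded.

## Numerical choices and defaults

| parameter | default | why |
|---|---|---|
| d_lambda, f_ref | 0.01, 100 Hz | second-order mesh; 0.01 is converged (<0.5% admittance shift on further refinement) across 100 Hz–10 kHz, whereas 0.1 leaves ~1–7% at kHz frequencies |
| dt (single cell) | 1 µs | matches the published temporal resolution; halving changes Cm estimates <0.1% |
| dt (network) | 5 µs / 100 pts per cycle | published network setting |
| sine amplitude, V_hold | ±15 mV from −80 mV | published protocol; the linear model makes estimates amplitude-independent |
| Rs grid | 1, 50, 250 MΩ | published sweep; noiseless estimates differ <1% |
| ZAP | c = 2, 5 Hz–2.5 kHz over 1 s, 200 ms pads, time-reversed | the published chirp constants are unrecoverable; c = 2 gives a linear frequency sweep hitting the stated endpoints |
| fitting window | final 10 cycles after settling | the published per-run window is unstated; clamp settling is ~Rs·C ≈ 1 ms |

Degenerate inputs: zero-length sections are collapsed (warning) into a
single zero-area compartment; sector sampling raises a named error when a
sector holds fewer candidates than contacts; sine windows with fewer than
two cycles, undersampled commands (<20 samples/cycle) and non-integer cycle
windows are rejected.

## Variable-step integration replaced

The published single-cell simulations used a variable-step solver (absolute
tolerance 0.0001, units unstated).  Fixed-step Crank–Nicolson with an
explicit convergence check replaces it here: traces become bitwise
reproducible, and the published control (results insensitive to tolerance)
is superseded by the dt-halving test.

## Known limitations

- No active conductances (the voltage-gated Ca²⁺ currents probed
  experimentally by ZAP stimuli are out of scope; only the waveform and
  ΔF/F arithmetic are provided), no temperature dependence, no gap-junction
  rectification, no explicit ON-cone bipolar cells in the network.
- Quantities that depend on unpublished reconstruction detail are reproduced
  as patterns, not curves.  Two documented deviations on the synthetic
  cells: residual network coupling at exactly 2 kHz is 1.1–1.7% for the two
  strongest junctional conductances (the published reading is "no
  influence" at plot resolution), and dendritic recordings show negative
  ΔCm at 100 Hz for a minority (4/18) rather than a majority of lobular
  appendages — both plausibly reflect synthetic stalks/dendrites being
  electrically tighter than real branching processes.
- The soma-area convention (cylinder, length = diameter) and the unweighted
  point center of mass are documented choices where the source material is
  silent; both are configurable at the call sites that consume them.
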