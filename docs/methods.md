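# Methods

## Scan construction

The scan abscissa is the unitless scaling factor *i* applied to a
normalized Cartesian normal-mode vector: coords(i) = eq + i·d, with d the
3N-component displacement renormalized to unit L2 norm (the original norm
is kept as metadata, so vectors imported from any engine dialect —
mass-weighted, engine-normalized — give identical scans). No conversion to
mass-weighted or dimensionless normal coordinates is performed; an optional
helper reports the mass-weighted displacement length for comparison across
modes. Translational/rotational contamination is not projected out: vectors
are displaced exactly as given.

The default grid is −0.10 ≤ i ≤ +0.10 in 0.01 steps (21 points including
i = 0). A ±1.0 grid is constructible but warns: displacements that large
distort typical organic molecules beyond the regime a quadratic analysis
can describe. Displaced-geometry files are named `mode{MM}_i{+/-0.NN}.xyz`;
scan order is defined by the manifest CSV (`file,mode,i`), not by lexical
file order, since ASCII sign characters do not sort numerically.

## Quadratic fitting and anharmonicity metrics

Each state's scan is fitted with y = ai² + bi + c by unweighted least
squares (`numpy.polynomial` internally; an independent normal-equations
solve is used as the test oracle). Statistics per fit: RMSD =
√(Σ residual²/n) with plain n (not n − 3), and R² = 1 − SS_res/SS_tot,
reported as 1 for a constant scan with zero residuals.

Normalized ratios: ground RMSD/E_average = RMSD / mean(y); excited =
RMSD / (mean(y) − E_vert). All energies are referenced to the ground state
at i = 0, so subtracting the vertical excitation energy E_vert leaves the
distortion-induced energy change in the denominator — without it, modes
that barely change the energy would appear spuriously well-fitted.
E_vert defaults to E_S1(0) − E_S0(0) of the scan itself (exact for the
shared equilibrium geometry) and can be overridden with a fixed value when
a molecule-wide constant is preferred.

The relaxation energy λ = E_S1(0) − min E_S1 probes Franck–Condon
activity. By default both terms are evaluated on the fitted parabola, the
minimum over the scanned interval only (vertex value if the vertex lies
inside the grid, else the lower fitted endpoint); for a concave fit
(a ≤ 0) the raw minimum data point is used and the fallback is flagged in
the output, keeping the choice auditable per mode. λ is clamped at ≥ 0.
For an exact fit with an interior vertex, λ = b²/(4a).

## Crossing detection and 1D diabatization

A crossing between two excited states is an interior local minimum of
|E_b − E_a| below a gap threshold (default 0.15 eV — small enough to
reject genuinely separated states, large enough to admit near-degenerate
minima sampled ~0.005 off the true crossing on a 0.01-spaced grid).
Endpoint minima are rejected: a gap still shrinking at the grid edge is
not evidence of a crossing inside the scanned range. The crossing-point
energy is the mean of the two states at the minimum-gap grid point
(linear interpolation between neighboring points is available as an
option); ΔE_CI/S1min subtracts the minimum of the pointwise-lower state
over the grid.

Diabatization relabels the two states beyond the crossing on its side of
i = 0, leaving the other side untouched (crossings are handled
independently per side). Without wavefunction data, electronic character
is operationalized by smoothness: the swap is accepted iff it reduces the
summed quadratic-fit RMSD of the two curves. Because the exact crossing
may fall on or between grid points, both candidate swap origins (the
minimum-gap point and its outward neighbor) are tried and the better one
kept; ties leave the scan unchanged. This conserves the multiset of
energies at every grid point, is idempotent, and recovers the generator's
diabats exactly at zero coupling. A hook for per-point state-character
scalars (e.g., oscillator strengths) is a natural extension but is not
implemented; energies alone suffice for the 1D case.

## Mode-character categorization

Internal coordinates are perceived from covalent distances (bond when
r < 1.2 × sum of Cordero covalent radii): stretches per bond, bends per
bonded triple, proper torsions per bonded quadruple, and an out-of-plane
coordinate (signed distance of the center from its neighbors' plane) at
every exactly-3-coordinate atom. Each coordinate's first-order Cartesian
row — the Wilson-B row — is obtained by central finite differences
(h = 10⁻⁵ Å) of the coordinate value function; this is numerically
identical to the closed-form s-vectors to ~10⁻⁹ and avoids their many
sign conventions. A coordinate whose row is numerically degenerate (a
bend through a near-linear angle) is skipped.

A mode's contribution from each coordinate is the squared projection of
its unit displacement onto the unit B row, normalized over all
coordinates to sum to 100%. Stretch percentages are split by whether a
hydrogen participates. The mode's category is the motion type holding at
least the dominance threshold (default 60%, ties dominant), else MIX.
This is a fixed redundant-coordinate projection — no iterative selection
or optimization of the coordinate set — so it buckets modes by motion
type but does not reproduce any specific PED program's percentages.

## Thresholding and the eight cases

Flags are strict: metric > mean + k·SD over the mode population (k = 1 by
default; sample SD, ddof = 1, with population SD selectable — published
analyses rarely state which convention they used, so both are supported
and the choice is recorded in the run manifest). Thresholds are floored
at 10⁻⁹ (unitless ratios, and eV for λ) so that a population of exact
quadratics, whose residual spread is machine epsilon, never produces
flags. Crossing modes are flagged on their post-diabatization fits.

The three booleans (S₀ anharmonic, S₁ excess-anharmonic, FC active) map
to cases 1–8 in the fixed order: (T,T,T)→1, (T,T,F)→2, (T,F,T)→3,
(T,F,F)→4, (F,T,T)→5, (F,T,F)→6, (F,F,T)→7, (F,F,F)→8. The mapping is a
bijection from the flag cube, so the cases partition any population.

## Synthetic generator

`generate_two_state` evaluates S₀ plus the sorted eigenvalues of the 2×2
diabatic matrix [[V1, w],[w, V2]] on the grid; independent Gaussian noise
(default off) is added per point, after which S₁/S₂ are re-sorted to
preserve adiabatic ordering. Ground truth records the analytic curvature
of each potential at its minimum (k for harmonic, Dα² for Morse), the
diabatic relaxation energies V(0) − min V over the grid, the exact
crossing position (bracketed sign change of V1 − V2 refined by Brent's
method), and the per-point lower-diabat labels.

QM single-point energies carry no sampling noise; the Gaussian noise
model exists purely to stress fit robustness, and the pipeline's recovery
is quoted at 1 meV SD, about the scale of loose SCF convergence scatter.

The benchmark suite emulates one molecule's mode population: 56% plain
harmonic modes, 6% FC-shifted harmonic, 8% Morse-anharmonic S₁, 4% Morse
S₁ + FC shift, 8% both-states Morse with matched relative anharmonicity,
3%/2% excess-anharmonic without/with FC shift, and 6% zero-coupling
crossing scans whose diabats are harmonic (so they classify as plain
harmonic after correct relabeling). Parameter ranges — ground curvature
k₀ ∈ [35, 55] eV/i², excited/ground curvature ratio 0.8 (excited states
are uniformly softer), vertical offsets ΔE₁ ∈ [2.7, 3.2] eV,
ΔE₂ − ΔE₁ ∈ [0.8, 1.2] eV, FC shifts δ ∈ [0.07, 0.08], Morse α up to 3.3 —
keep grid-edge energies within ~1 eV of the minima, the regime ±0.1 scans
probe, and place every anomalous group's metric at least ~1.5× its
population mean + 1 SD threshold, so intended-case recovery is limited by
noise, not by marginal design. In non-crossing scenarios S₂ shares S₁'s
potential shape at a constant vertical separation; an S₂ of independent
shape can dip toward a steeply rising shifted-Morse S₁ at the grid edge
and create a real, unintended crossing.

What the generator does **not** emulate: mode–mode anharmonic coupling
(each scan is strictly 1D), Duschinsky rotation between state-specific
normal modes, geometry-dependent diabatic coupling, state-character
observables (oscillator strengths), and any specific molecule's spectrum
of 3N−6 coupled modes. Passing recovery tests therefore demonstrates the
statistical machinery — fitting, thresholding, relabeling — not the
quality of any electronic-structure method.

## Numerical choices and limitations

* Unit constants: 1 hartree = 27.211386245988 eV; 1 eV = 23.060548
  kcal/mol = 8065.544 cm⁻¹.
* Quadratic fits are unweighted; no higher-order or Morse fitting is
  offered — deviation from the quadratic *is* the anharmonicity probe.
* RMSD uses n in the denominator, not n − 3; with n = 21 the distinction
  rescales all ratios by a common √(21/18) and cannot change any flag.
* detect_crossing needs ≥ 5 grid points; fits need ≥ 3 distinct factors.
* The diabatization criterion can in principle prefer the adiabatic
  labeling when the true diabats are themselves strongly anharmonic on
  both branches; for quadratic-dominated diabats (the regime tested) the
  RMSD criterion and character continuity coincide.
* Acceptance-script problem sizes — 1000 random scans for the fit oracle,
  100 crossing draws, a 100-mode suite, 50 recovery draws — are the
  package's chosen benchmark sizes; all complete in seconds.
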