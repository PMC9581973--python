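# Methods

## Scope and model

The package quantifies the noncovalent interactions through which
single-stranded DNA incorporates ("dopes") into Alq3 crystals, and the
optical observables used to verify the doping. It deliberately does not run
molecular dynamics: trajectories are inputs (or synthetic stand-ins), and
the contribution is the geometric fingerprinting, the free-energy
estimation, and the spectral reductions downstream of them.

All internal lengths are nm, times ps, energies kJ/mol. Angstrom-based
formats (PDB, XYZ) are converted at the reader boundary. Coordinates are
treated as whole-molecule; if a periodic box is present, minimum-image
distances are used for pair distances. This assumes the cluster plus one
DNA strand fits one box and contacts are short-range, which holds for the
systems targeted.

## Interaction taxonomy

A ring plane is the least-squares plane of its atoms: centroid = unweighted
mean, normal = eigenvector of the smallest covariance eigenvalue, with a
fixed sign convention (positive z, ties broken by x then y). For two planes
the *vertical separation* is |Δc · n̂| with n̂ the sign-aligned bisector of
the two normals — symmetric in the rings and equal to the obvious value for
parallel rings. The stacking criterion itself is a bare distance threshold
(vertical separation < 0.45 nm); because that alone would admit distant
near-coplanar rings, a lateral guard requires the centroid distance to be
below cutoff + 0.3 nm. The guard is configurable and on by default; it is a
disclosed addition to the bare criterion.

Each Alq3 ligand (an 8-hydroxyquinolinate) is treated as a single fused
ring plane; "quinoline" throughout means the ligand unit. Hydrogen bonds
use D–A distance ≤ 0.35 nm and H–D–A angle ≤ 30°, the common defaults of
MD analysis tooling, both configurable. Intramolecular pairs are excluded
(the analysis targets Alq3–DNA bonds). A sanity check requires each donor
hydrogen within 0.25 nm of its heavy atom — loose enough that positional
noise never trips it, tight enough to catch topology errors.

Classification is per base-frame with fixed priority
TypeI > TypeII > HbondOnly > PiOnly > None:

* **Type I** — some Alq3 molecule k both stacks on and hydrogen-bonds to
  the base; among several candidates the smallest vertical separation wins.
* **Type II** — an H-bond with molecule k and a stack with k′ ≠ k.
* Otherwise H-bond only / π-π only / none.

The counting unit is the base-frame event: one label per base per analysed
frame, so the four counted categories partition the events and their
occurrence probabilities (count / total non-none count) sum to 1. Absolute
counts scale with the trajectory save stride; only the probabilities are
treated as reproducible statistics. Multiple H-bonds between one base and
one Alq3 count once for classification; raw bond counts are reported
separately by the lifetime machinery.

Continuous H-bond lifetime is the mean over maximal runs of consecutive
presence of (run length × dt); the optional intermittent correlation time
is the trapezoidal integral of the normalized presence autocorrelation.
Stacked-base statistics are the per-frame count of distinct bases with at
least one stack, reported mean ± population sd over frames.

The analysis window defaults to the trailing 10 ns of the trajectory
(stride 1); shorter trajectories are analysed whole.

## Energetics

Group–group nonbonded energy is a cutoff-truncated pair sum (default
1.2 nm): Coulomb f·q_iq_j/r with f = 138.935458 kJ nm mol⁻¹ e⁻², and
12-6 Lennard-Jones with Lorentz–Berthelot combination. No Ewald/PME is
implemented, so absolute electrostatics differ from lattice-summed engine
output; the sums are intended for trends and are verified against
brute-force oracles, not against engine values.

WHAM is the standard self-consistent iteration over harmonic umbrella
windows: histogram the pooled samples (default bin 0.02 nm), iterate the
window free energies until the largest change is below 1e-6 kJ/mol (cap
1e5 iterations), and report W(z) = −kT ln P(z) shifted to min 0. kT uses
k_B = 0.008314462618 kJ/mol/K at 298.15 K by default (≈2.4789 kJ/mol),
with a temperature override. Two numerical choices matter:

* All occupied bins drive the self-consistency, but the reported curve
  drops bins with fewer than 25 samples. −ln of a handful of counts
  carries ≳ kT/5 of noise, and such near-empty edge bins otherwise produce
  1–2 kJ/mol spikes that corrupt max(W)-based quantities. The threshold is
  configurable and applies equally to the direct Boltzmann-inversion
  estimator so the one-window identity holds bin for bin.
* With the default pulling protocol (40 windows, 0.15 nm spacing,
  k = 1000 kJ mol⁻¹ nm⁻², so window sd ≈ 0.05 nm at 3σ spacing), adjacent
  windows overlap only marginally and the stitched profile performs a
  small random walk whose amplitude scales as 1/√n per window. The
  umbrella generator therefore defaults to 50,000 samples per window,
  matching 10 ns of production sampled every 0.2 ps; at that size the
  stitching error is ≈0.1–0.2 kJ/mol across the span.

The binding energy of a PMF curve is the span between its highest and
lowest states, reported negative for favourable binding. Replicates are
combined as mean ± sd with the n−1 denominator, the convention for
replicate error bars.

## Photophysics

PL spectra are modelled as sums of Gaussian bands on the wavelength axis
(an energy-axis option was considered and not adopted; the axis choice is
disclosed here because fitted areas differ slightly between the two).
Initialization takes local maxima of a lightly smoothed spectrum; when
fewer maxima than requested peaks exist, the fallback centers are
{450, 512, 572} nm — the donor band of Alq3 (~512 nm) and acceptor band of
Cy3 (~572 nm) are the physically named bands, the 450 nm blue shoulder is
a fallback, not a measured value. Peak areas are analytic
(amplitude × sd × √(2π)). The emission ratio matches fitted peaks to the
requested band centers within ±15 nm.

FRET efficiency is E = 1 − I_DA/I_D from donor-band intensities with and
without acceptor; values outside [0, 1] are returned with a warning, never
silently clamped. Waveguide loss fits I(d) = I₀e^(−αd) with multiplicative
(log-scale) residuals by default, since waveguide noise is proportional —
this makes the default fit an exact log-linear regression; a linear-scale
nonlinear option exists. α < 0 (non-decaying series) is reported as 0 with
a flag.

## Synthetic data

The generators define the study conditions rather than approximating any
particular dataset:

* **Interaction trajectories.** ~100 idealized Alq3-like molecules (three
  planar fused-bicycle ligands of 0.14 nm bonds around an Al center, one
  phenolate-like acceptor oxygen per ligand) and a 20-mer strand of
  idealized hexagonal bases with one exocyclic donor (ND–HD) and acceptor
  (OA) each. Every base owns an isolated site on a 4 nm grid with a
  primary and a secondary Alq3 molecule; per frame its scheduled label is
  drawn i.i.d. from the configured fractions and its atoms are placed in a
  geometry that satisfies exactly that mode under the default criteria:
  stacks at 0.35 nm vertical separation, H-bonds at 0.29 nm / 10°,
  non-interacting bases parked > 0.6 nm away. Gaussian positional noise of
  configurable sd is applied to every atom afterwards. The default
  schedule (4/2/6/88% Type I/Type II/H-bond/π-π) is the thymine-strand
  regime of rare multisite events over dominant stacking.
* **Umbrella samples** are drawn exactly from the biased density
  ∝ exp(−[U(z) + k/2 (z−z_i)²]/kT) by inverse-CDF interpolation on a fine
  grid — no Langevin dynamics, so samples are uncorrelated and the window
  layout is the only protocol approximation.
* **Spectra** add proportional Gaussian noise (sd = fraction × local
  intensity), matching intensity-proportional PL detector noise; **decay
  series** use log-normal multiplicative noise.

All randomness flows through `numpy.random.default_rng` (PCG64); a fixed
seed reproduces outputs bit-identically.

What passing closed-loop tests show — and do not show — about real data:
the detectors and classifier are exact on geometries that satisfy the
criteria by construction and degrade gracefully (≥95% agreement at 0.02 nm
positional noise, failures concentrated in the fragile H-bond angle
criterion). They do not validate the criteria themselves against quantum
or experimental definitions of stacking/H-bonding, and the rigid idealized
templates carry none of the conformational correlation, solvent, or
backbone sterics of real trajectories. Likewise the WHAM tests certify the
estimator, not the sampling quality of any real pulling simulation.

## Problem sizes

Defaults used by the analysis drivers and acceptance script: 20 bases ×
500 frames × ~100 molecules (~3,600 atoms) for the interaction survey;
40 windows × 50,000 samples for WHAM; 321-point spectra; 20-point decay
series with 200 noise replicates for the loss-fit bias check. Each stage
completes in seconds on one CPU.

## Known limitations

* No PME/Ewald; absolute electrostatic energies are cutoff-truncated.
* No bootstrap/block error bars on PMFs (replicate sd only).
* The Type I tie-break (smallest vertical separation) is a convention;
  ties are not physically meaningful at the criterion level.
* H-bond criteria are purely geometric; no energetic or orbital check.
* Real-topology residue definitions ship for standard PDB nucleotide
  naming only; other force-field naming requires a YAML override.
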