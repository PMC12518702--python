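# Methods

## The problem being modelled

A flavin-dependent halogenase chlorinates tryptophan side chains of a
peptide substrate. Chemistry requires the indole C5 to sit near the
catalytic lysine's NZ with a favourable orientation, so regioselectivity
among several substrate Trp residues is governed by which Trp most stably
holds this catalytic pose. The package quantifies pose stability on
trajectory ensembles: per-Trp geometric observables, a bounded reaction
likelihood used as a rare-event progress coordinate, weighted-ensemble
sampling, and free-energy projections. Because real enzyme–substrate
trajectories are not shipped with the package, a synthetic generator
produces ensembles whose generating parameters are known exactly; every
analysis stage is validated by recovering them.

## Geometric observables

For each tracked Trp channel (identity 1/2/3, default labels
trp8/trp12/trp14 in substrate-core numbering):

* d — Euclidean distance Trp C5 ↔ Lys NZ, Å;
* θ — angle between the indole plane vector (CZ3→C5) and the lysine
  side-chain vector (CE→NZ), degrees in [0, 180]. The normalized dot
  product is clamped to [−1, 1] before arccos so floating-point rounding
  can never yield NaN; zero-length vectors raise a degenerate-geometry
  error rather than returning a junk angle.
* Anchors — Arg CZ ↔ Asp CG and Arg CZ ↔ peptide centre of mass. The COM
  is mass-weighted over all substrate-chain atoms present in the frame,
  with element masses inferred from the leading letter of the PDB atom
  name; an explicit selection can be configured instead.

Dissociation time is the earliest t such that d stays above a threshold
(default 12 Å) for a full persistence window (default 5 ns). The window
must be fully covered by data: brief excursions and end-of-series
truncation do not count. Both parameters are configuration — stable
channels fluctuate within ~7–10 Å, so 12 Å separates the basin from the
escape path by several stationary standard deviations, and 5 ns is long
against the 1 ns relaxation time of the bound-state fluctuations.

Trajectory input is a deliberately strict PDB subset (ATOM/HETATM,
MODEL/ENDMDL, TER, END; altloc blank or 'A'; insertion codes rejected;
author residue numbering kept verbatim) or a tidy geometry CSV. PDB
carries no time axis, so frames are stamped `frame_index × dt` with a
configurable saving interval (default 0.1 ns) — a bookkeeping convention,
not a physical claim.

## Reaction-likelihood score

S(d, θ) = exp(−(d−d₀)²/2σ_d²) · exp(−(θ−θ₀)²/2σ_θ²).

A separable-Gaussian form was chosen as the simplest smooth, bounded,
unimodal score with independent distance and angle tolerances; the
defaults d₀ = 8 Å, σ_d = 1.5 Å, θ₀ = 140°, σ_θ = 25° centre the peak on
the low-free-energy basin geometry where productive poses concentrate. All
four are configuration parameters. The per-frame reduction `best_trp`
returns the channel with maximal S; exact ties break to the lowest
identity so the reduction is deterministic and order-independent.

## Weighted-ensemble engine

Progress coordinates are (S, identity); bins are the Cartesian product of
half-open score intervals (top edge inclusive) and identity values.
Defaults: 10 uniform score bins × 3 identities, target 4 walkers per
occupied bin, τ = 0.5 ns — explicit configuration documented as this
package's choices.

Resampling follows the standard minimal-variance split/merge scheme:

* Split (under-occupied bins): repeatedly halve the heaviest walker into
  two equal-weight children until the bin reaches its target; genealogy is
  recorded via parent ids. Halving is exact in binary floating point.
* Merge (over-occupied bins): repeatedly merge the two lightest walkers;
  one survives with probability proportional to its weight and absorbs
  both weights.

Both moves preserve each walker's expected contribution, so weighted
ensemble averages are unbiased estimates of brute-force ensemble averages;
total weight is conserved to well below 1e-12 per run (asserted in tests
across seeds). A single named NumPy generator drives propagation and merge
decisions, so a run is bitwise-reproducible from its seed. Iterations are
1-based: "iteration 12" is the 12th post-resampling ensemble.

Unbiasedness is validated on an overdamped double-well diffusion toy
(U(x) = h(x²−1)², Euler–Maruyama, barrier h = 1.5, D = 0.5): the WE
estimate of trans-barrier occupancy after 4 time units, averaged over 20
seeds, agrees with a 50,000-trajectory direct ensemble within 3 combined
standard errors.

One caveat stated openly: for a memoryless escape (a jump process, as in
the synthetic kinetics below) WE does not accelerate the *first* escape —
no method can, without biasing the dynamics. Its value here is
amplification: once a walker reaches the rare unbound state it is split up
to the bin target in otherwise-empty low-score bins, multiplying the
weighted samples of the rare state. The enrichment test asserts exactly
this property (more rare-state samples per discovery than an equal plain
budget), not a first-passage speedup.

## Free-energy estimation

F = −kT·ln(p/p_max) over occupied cells of a weighted histogram
(default grids d ∈ [2, 20] Å at 0.5 Å, θ ∈ [0, 180]° at 5°, chosen to
resolve a basin near 7–9 Å / 140°); unoccupied cells are masked, the
minimum occupied F is 0 by construction. kT defaults to 0.593 kcal/mol
(298.15 K) and is configuration; outputs carry units through this
parameter.

KDE profiles use the weighted Gaussian kernel density
Σᵢ wᵢ φ((x−xᵢ)/h)/h. The "auto" bandwidth is Silverman's rule evaluated
at the Kish effective sample size n_eff = (Σw)²/Σw² — the appropriate
n for weighted data — with a fixed minimum bandwidth fallback (with
warning) for degenerate spreads.

Basins are local minima of F over the occupied mask (8-neighbourhood). A
candidate must lie strictly below at least one occupied neighbour, so flat
plateaus are not reported; candidates within `min_separation` cells
(Chebyshev) of a deeper accepted basin are suppressed.

Comparing basin depths *between* Trp channels requires a common reference:
`channel_surfaces` normalizes cell probabilities over all channels jointly
(weight that drifted outside the projected window still counts in the
normalization) and references every surface to the global maximum. Within
a single surface min F = 0 would hold by construction; across channels the
stably bound channel anchors the zero and a rarely bound channel's basin
floor sits strictly above it.

## Synthetic ensemble generator

Each Trp channel follows two-state kinetics:

* Bound: stationary Ornstein–Uhlenbeck fluctuation of (d, θ) about
  (basin_d, basin_theta) with spreads (sd_d, sd_theta) and relaxation time
  1 ns, using the exact discrete OU update (so statistics are independent
  of the sampling interval).
* Escape: exponential with rate k_off + leu_contact_rate, drawn in
  continuous time. The second term emulates displacement of the C-terminal
  Trp by transient contacts with its preceding Leu — modelled as an extra
  escape rate, not as explicit Leu atoms.
* Unbound: d drifts away linearly (default 2 Å/ns) with small residual
  noise; θ decorrelates to broad scatter about 90°. There is no rebinding.

Default study conditions: channels 1 and 2 share a stable basin at
(8 Å, 140°) with sd (0.8 Å, 8°) and a slow residual escape (1e-3/ns);
channel 3 has a broader basin (sd 1.2 Å, 14°) and a 40 ns mean escape time
(k_off = 0.005/ns + leu_contact_rate = 0.020/ns). Anchor distances are OU
processes centred at 8.5 Å (Arg–Asp) and 11 Å (Arg–COM).

The inverse-geometry constructor places Lys CE/NZ, per-channel Trp CZ3/C5,
Arg CZ, Asp CG and two adjustable peptide dummy atoms so that the geometry
stage recovers requested (d, θ) and anchor targets to ≤1e-6, then applies
a seeded random rigid rotation + translation; it underlies the exact
round-trip tests and the PDB fixtures. This is an emulation of the
phenomenology the analysis must detect — basins, escape, displacement —
not force-field physics: it has no solvent, no enzyme degrees of freedom,
no rebinding, and independent channels. Passing tests therefore
demonstrate that the *analysis stages* recover designed statistical
structure, not that any real system behaves this way.

## Dissociation-time recovery

Detected threshold crossings lag the latent escape by the deterministic
transit from basin to threshold, (12 − 8) Å / 2 Å/ns = 2 ns, which the
recovery analyses subtract. The recovery experiment uses 200 seeded
realizations with three iid dissociating channels each (600 events):
the sample mean of n exponential escape times has relative standard error
1/√n, so 600 events put the 10% recovery band at ≈2.4 standard errors,
whereas 200 events would leave it at 1.4. Series are 300 ns long, so
censoring (escape after the series end) affects ≲0.1% of events.

## Pipeline and problem sizes

The campaign driver expands a design of 4 starting configurations × 3
replicates = 12 runs, each seeded independently through a NumPy seed
sequence spawned from the master seed. Each configuration starts one Trp
channel bound at its basin and the others displaced (15 Å, 90°, unbound),
emulating systematically permuted starting poses. Per run: 20 initial
walkers, 12 WE iterations of τ = 0.5 ns, first 2 iterations discarded as
warm-up when pooling weighted samples. These sizes keep the whole campaign
under a few seconds on one core while leaving ≥100 weighted samples per
channel per run; they are the package's demonstration scale, and all of
them are configuration.

## Mass-spectrometry arithmetic

Atomic masses ship as a small versioned table (monoisotopic and standard
average values; proton 1.007276 Da, electron 0.000549 Da). Charged-species
masses are electron-corrected — required to match high-resolution ion
masses at the fourth decimal. Peptide formulas are residue compositions
plus one water, with terminal options (free/formyl N-terminus,
acid/amide C-terminus; amide→acid is +0.984 Da, which is how a +1 Da
C-terminal hydrolysis shows up in practice). Halogenation is a net H→X
substitution on Trp (+33.96103 Da per Cl, +77.91051 Da per Br); ring
regiochemistry is mass-invisible and out of scope, as are isotope
envelopes, adducts other than protons, and a/x/c/z or neutral-loss
fragment series.

Stoichiometry assignment matches each observed peak to the halogenation
count minimizing |observed − theoretical| within a tolerance. MALDI
figure captions mix rounding conventions — nominal values of unmodified
species often reflect average masses while halogenated ones reflect
monoisotopic — so the assigner can evaluate both tables and reports which
matched rather than silently choosing.

Site localization enumerates all placements of the species' halogen totals
over its Trp residues (at most one halogen per indole), scores each by the
number of observed peaks explained by its predicted singly protonated b/y
ladders, and returns *all* argmax placements: a multi-element result is an
explicit ambiguity statement, which is the correct reading of sparse
fragmentation data. The b/y complementarity identity
bᵢ(+1) + y₍n−i₎(+1) = [M+H]⁺ + proton holds exactly by construction and is
asserted property-style on random sequences.

## Known limitations

* The synthetic kinetics are one-way (no rebinding) and channels are
  independent; cooperative or compensatory substrate motions are not
  emulated.
* The WE engine has fixed bins (no adaptive/Voronoi binning), no
  work-manager parallelism, and no interoperability with external WE file
  formats.
* The score's Gaussian form and all sampling defaults are package choices;
  conclusions drawn from them are about the analysis machinery, not about
  any specific enzyme's energetics.
* Only singly protonated b/y fragments are predicted; localization
  confidence is a matched-peak count, not a probabilistic score.
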