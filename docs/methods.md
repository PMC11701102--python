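# Methods

This note documents the models, conventions and numerical choices behind
`ringstat`, in the order the pipeline runs them.

## Structure model and selections

Structures are flat ordered lists of atoms (chain, author residue number,
insertion code, atom name, element, position in Å, occupancy, B-factor,
HETATM flag). Parsing goes through gemmi; only MODEL 1 of multi-model files
is kept, and alternate locations are collapsed to the blank/"A" conformer
so that all geometry is single-conformer and deterministic. Hydrogens,
waters and HETATM records are read but excluded from geometric analyses
(anchors and paired Cα skip hydrogens/HETATM; contact detection uses heavy
protein atoms only). Residue ranges are author-numbered and inclusive on
both ends. PDB output is written in fixed columns with B-factors at two
decimals; coordinates therefore round-trip at the 10⁻³ Å column precision.

## Helical lattice parameters

Anchors are one point per spoke — by default the Cα of a user-chosen
residue of each spoke's γ-tubulin — supplied in ring order (chain order is
an explicit input; deposited chain naming is not assumed to follow the
ring).

Axis fitting proceeds in three deterministic steps:

1. **Initial direction.** Cross products of successive inter-anchor chords.
   For an ideal helix traversed in order, every vₖ × vₖ₊₁ has the same
   axial component while the in-plane components rotate and cancel in the
   mean, so this estimator is valid at any pitch. (The smallest-variance
   principal component — the best-fit circle normal — fails for steep
   helices whose axial extent exceeds their diameter; it is kept only as a
   fallback for degenerate input.) Collinear or coincident anchors raise a
   fit error.
2. **Initial centre.** A Kåsa algebraic circle fit of the anchors projected
   on the initial plane. The raw centroid is a poor seed for partial arcs,
   where it lies far inside the true centre and can put the subsequent
   refinement in a wrong basin (a shallow arc is locally consistent with a
   huge circle about a perpendicular axis).
3. **Refinement.** Levenberg–Marquardt least squares, first on the spread
   of radial distances (4 parameters: two direction tilts about the seed,
   two in-plane origin offsets), then against a full ideal-helix model
   (those 4 plus radius, twist, rise, phase and axial offset; residuals are
   the 3N coordinate differences). The second stage matters: for a ring
   spanning roughly one turn, the radial spread alone is second-order blind
   to axis tilt (a small tilt can be compensated by an origin shift),
   which leaves ~0.6° direction errors at 0.5 Å coordinate noise; the
   helix-model fit constrains the tilt through the rise pattern and brings
   the mean twist error at that noise level down to ~0.03°. The fitted
   helix model is used only for the axis; the reported statistics are
   computed from the anchors themselves.

The axis direction is signed so that the mean rise is non-negative (ties
broken toward +z, then +x, then +y), and the reported origin is the foot of
the centroid's perpendicular on the axis.

Given the axis, each anchor gets cylindrical coordinates (rᵢ, θᵢ, zᵢ).
Statistics follow the convention that *N* anchors define *N*−1 steps:
radius is summarised over all *N* points, twist and rise over the *N*−1
successive differences — for a 14-spoke ring, 13 values, matching the
descriptive n = 13 of the published lattice table. Step angles are wrapped
to (−180°, 180°], which assumes consecutive spokes advance monotonically by
less than half a turn (true for any ring lattice); the rotational sense
relative to the rise direction defines handedness, and twists are reported
as magnitudes in (0°, 360°) in that sense, so a mirror image flips
handedness and preserves magnitudes. SDs are population SDs (divisor *n*) —
these are descriptive spreads of a fixed lattice, not inferential errors —
matching a published twist of 27.6 ± 0.0° for an exact lattice.

Two lattices compare as compatible when every absolute parameter
difference is at most the sum of the two SDs. This is the descriptive sense
in which the 14-spoke ring (102.5 ± 1.5 Å, 27.6 ± 0.7°, 9.2 ± 0.8 Å) and
the 13-protofilament MT reference (101.8 ± 0.1 Å, 27.6 ± 0.0°,
9.6 ± 0.1 Å) are indistinguishable: differences 0.7 Å, 0.0°, 0.4 Å. No
significance test is implied.

## Superposition and displacement

Kabsch superposition (SVD with the determinant correction for proper
rotations) on Cα atoms paired by (chain, residue number, insertion code).
Residues present in only one model are dropped silently but counted in the
result — deposited models have unmodelled segments, and a pairing-level
report keeps those drops visible. `domain_rmsd` aligns and measures on the
same selection by default (published per-domain RMSDs state no separate
frame); an explicit alignment selection supports measuring the motion of
one block in the frame of another, which with the hinge generator recovers
the closed-form mobile-block RMSD to 10⁻⁹ Å.

Element displacement across systems is the distance between the Cα
centroids of the two measured selections after aligning on the shared
frame. Centroids (not per-residue means) make the metric robust when the
modelled helix lengths differ between systems; the two measured selections
need not pair.

## Interface contacts

Deposited models carry no hydrogens, so hydrogen bonds are scored by
distance and chemistry only: any N/O–N/O pair within 3.5 Å, flagged
backbone–backbone when both atoms are backbone N/O/OXT. Salt bridges are
side-chain N of Lys/Arg/His against side-chain carboxylate O of Asp/Glu
within 4.0 Å (histidine participation is switchable); hydrophobic contacts
are carbon–carbon pairs between apolar side chains (Ala, Val, Leu, Ile,
Met, Phe, Trp, Pro) within 4.5 Å. Each atom pair receives exactly one
label by precedence salt bridge > H-bond > hydrophobic. The cutoffs are
conventional mid-range values, not fitted to any structure; enlarging a
cutoff can only add contacts of that kind. Neighbour search uses a k-d
tree; output order is (residue₁, residue₂, distance) and symmetric under
swapping the chain arguments. The pocket finder restricts to hydrophobic
contacts from one probe residue's side-chain carbons and reports the
partner residue set.

## HX-MS relative protection

Uptake is back-exchange-corrected against the fully deuterated control:
(m_t − m₀)/(m₁₀₀ − m₀), clamped to [0, 1]. Charge states of the same
peptide are averaged (unweighted, on the centroid masses) per condition
before scoring; the alternative order (scoring per charge state, then
averaging) differs only at second order in the control masses and is not
exposed. Peptides are matched across conditions by (start, end, sequence).

Relative exchange and protection are percentages of the baseline exchange;
the two sum to 100 where baseline > 0. Protection above 100 is impossible
(uptake is non-negative), but deprotection gives negative values, which are
reported as such. A baseline of exactly 0 makes the relative statistics
undefined: such records carry NaN and are never shown (they cannot pass the
baseline filter). The display filter is inclusive — "minimum of 10 %
baseline exchange" reads as ≥ 10.0 % — flags only (`shown`), deletes
nothing, and is idempotent. A single labelling time point is assumed;
kinetic modelling is out of scope.

Per-residue consolidation averages relative exchange over all shown
peptides covering each residue (uniform weight per peptide, no length
normalisation); uncovered residues are NaN, and values can be written into
the B-factor column of a structure for colouring, with a sentinel for
uncovered residues.

## Gel stoichiometry

Within each replicate, molar ratio = (I/MW)/(I_ref/MW_ref); the
per-replicate division cancels lane-level loading and staining scale.
Molecular weights are user-supplied construct masses (kDa), because tagged
constructs differ from database masses. Ratios are summarised as mean ±
sample SD (divisor *n*−1) across replicates, matching mean ± SD over
biologically independent experiments; the reference's self-ratio is exactly
1 with SD 0.

## Synthetic generators

Each generator maps (spec, seed) to output deterministically — per-component
random streams are derived from the one seed via hashed spawn keys — and
stores its exact noise-free truth, so every analysis stage is tested by
recovery rather than against frozen copies of itself.

- **Rings**: one CA-only, single-residue chain per spoke at the exact
  lattice positions, optional rigid pose, isotropic Gaussian coordinate
  noise. Defaults are the study conditions: 14 spokes at 102.5 Å / 27.6° /
  9.2 Å, with a 13-protofilament MT reference at 101.8 Å / 27.6° / 9.6 Å.
  A decorated mode adds a short dummy helix per spoke for selection tests.
  What this does not emulate: real spokes are whole protein columns whose
  anchor uncertainty is anisotropic and position-dependent; passing tests
  show correct lattice recovery from anchor coordinates, not robustness to
  model-building error.
- **Hinge pairs**: a smooth synthetic Cα trace (coarse helix plus seeded
  jitter; 100 static + 160 mobile residues by default) duplicated with the
  mobile block rigidly rotated (default 12°) about an axis through the last
  static Cα. The implied mobile-block RMSD is stored exactly. This probes
  the superposition arithmetic, not the biology of a real interdomain
  hinge.
- **HX tables**: peptides tile the protein (default length 160, 10-mers
  every 4 residues); per-peptide truth is the mean of prescribed
  per-residue baseline-exchange and protection profiles. The default
  baseline sweeps 5–85 % so that some peptides fall below the display
  threshold, and a contiguous block carries 80 % protection, emulating one
  binding site. m₁₀₀ − m₀ equals the number of peptide bonds and Gaussian
  noise is applied to labelled centroids. Real data additionally have
  proline positions, replicate structure and EX1 behaviour — none modelled.
- **Gels**: intensity = replicate scale × ratio × MW × ε with ε lognormal,
  mean 1, coefficient of variation exactly `cv` (σ² = ln(1+cv²), mean
  offset −σ²/2); cv = 0 short-circuits to exact intensities. Default truth
  is the 1:1:2:2 complex composition at CV 5 %, 3 replicates, with nominal
  construct masses (97 / 98 / 52.5 / 68 kDa; Stu2 102 kDa available).

## Statistical note on small-replicate recovery checks

"Recovered within 3 SD" with *n* = 3 replicates uses a sample SD with two
degrees of freedom; the event |mean − truth| ≤ 3·SD is a t-style criterion
that fails in ~3.5 % of draws even for a perfect estimator. Recovery is
therefore asserted as coverage over many independent synthetic gels
(≥ 90 % over 50 seeds, against an expected ~96.5 %) plus exactness at zero
noise, rather than as a single-seed gamble.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic data at
the sizes above (14-spoke rings; 260-residue hinge chains; 38-peptide HX
tables; 4-protein, 3-replicate gels; 100-seed Monte-Carlo loops for noisy
recovery), which keeps a full run in seconds while exercising every stage
through its file formats. All randomness flows from a single seed;
reports embed tool version, parameters and input checksums.

## Known limitations

- mmCIF support covers the atom_site loop (coordinates, occupancy,
  B-factor), not assemblies, symmetry expansion or sequence categories.
- Hydrogen-bond detection has no angular term and no donor/acceptor
  disambiguation beyond element and atom-name class; π-stacking and
  cation-π interactions are not detected.
- The helix fit assumes one lattice; multi-start lattices, seam detection
  and flexible conformational analysis are out of scope.
- HX-MS processing starts from centroid masses; spectral processing,
  peptide identification and kinetic modelling are not included.
- Chain identifiers are written as single PDB columns; rings with more
  than 62 spokes are rejected by the generator and would need mmCIF
  output.
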