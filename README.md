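# ringstat

Quantitative structural statistics for microtubule-nucleating ring
assemblies, built around the *Candida albicans* cytoplasmic nucleation unit:
rings of γ-tubulin small complexes (γ-TuSCs, each a Spc97/Spc98/2×γ-tubulin
module) that template microtubule (MT) growth. Whether such a ring can
nucleate efficiently comes down to numbers — does its helical lattice match
the 13-protofilament MT lattice, how far do the GCP-family domains swing on
oligomerisation, which inter-chain contacts hold the ring together, where
does a binding partner protect against hydrogen exchange, and in what molar
ratio do the subunits assemble. `ringstat` implements each of those
measurements as a small, tested library with a matching CLI, plus synthetic
generators with exact ground truth so the whole pipeline is verifiable
without any downloads.

## What it computes

**Ring lattice geometry.** Given one anchor point per spoke (conventionally
the Cα of a fixed residue of each γ-tubulin, e.g. Gln12), `ringstat` fits
the helical axis and reports, as mean ± SD:

- radius *r* — distance of anchors to the axis (Å, over all *N* anchors),
- twist Δθ — rotation per spoke (degrees, over the *N*−1 steps),
- rise Δ*z* — axial increment per spoke (Å, over the *N*−1 steps),

and compares two lattices: they are flagged compatible when every
|Δparameter| ≤ SD₁ + SD₂. A 14-spoke ring with *r* ≈ 102.5 Å,
Δθ ≈ 27.6°, Δz ≈ 9.2 Å is geometrically indistinguishable from a fungal
13-protofilament MT (101.8 Å, 27.6°, 9.6 Å) — an MT-compatible, "closed"
nucleation template.

Axis fitting is two-stage: an initial direction from the cross products of
successive inter-spoke chords and a Kåsa circle fit for the centre, then
least-squares refinement against an ideal helix model. Noise-free lattices
are recovered to machine precision; at 0.5 Å coordinate noise the mean
twist error is ~0.03°.

**Domain motions.** Cα pairs matched by residue number are superposed with
the Kabsch algorithm; `domain_rmsd` reports the RMSD of any residue range
(optionally aligned on a different range), and
`displacement_after_alignment` measures how far an element's centroid moves
between two systems after aligning them on a shared frame — e.g. the
8–14 Å shift of receptor CM1-motif helices between fungal and human
γ-tubulin complexes.

**Interface contacts.** Distance-based classification of inter-chain atom
pairs (salt bridge > hydrogen bond > hydrophobic precedence; defaults
4.0 / 3.5 / 4.5 Å), with backbone–backbone H-bonds flagged and a
pocket-finder for probe residues such as a phenylalanine docked into a
neighbouring subunit.

**HX-MS relative protection.** From centroid masses (undeuterated m₀,
labelled m_t, fully deuterated m₁₀₀): uptake = (m_t − m₀)/(m₁₀₀ − m₀),
and for each peptide matched between baseline and ligand conditions

relative protection (%) = 100 · (baseline − ligand) / baseline,

so full protection by the ligand scores 100 %. Peptides under 10 % baseline
exchange are flagged not-shown; shown peptides are consolidated per residue
for painting onto a structure through the B-factor column.

**Gel stoichiometry.** Band intensities divided by molecular weight give
molar amounts; ratios to a reference subunit are computed within each
replicate and summarised as mean ± SD. The purified nucleation-unit complex
yields Spc97 : Spc98 : γ-tubulin : Spc72 ≈ 1 : 1 : 2 : 2.

## Worked example

Generate a 14-spoke synthetic ring at the published lattice parameters and
measure it back:

```sh
$ ringstat simulate ring --seed 1 --out ring_demo
wrote ring fixture to ring_demo/

$ ringstat geometry --structure ring_demo/ring.pdb \
    --chains A,B,C,D,E,F,G,H,I,J,K,L,M,N --residue 12 --atom CA \
    --out ring_geom.json
radius 102.5 ± 0.0 A; twist 27.6 ± 0.0 deg; rise 9.2 ± 0.0 A (right-handed, n=14)
```

The ring's 14 anchors sit 102.5 Å from the fitted axis and advance 27.6°
and 9.2 Å per spoke — 13 steps of 27.6° span 358.8°, so a 15th spoke would
overlap the first: the lockwasher geometry of an MT template. The JSON
report embeds the parameters used and the SHA-256 of the input, so every
number is recomputable from the report plus the input file.

The same pattern works for the other stages:

```sh
ringstat rmsd --a isolated.pdb --b ring.pdb --chain B --range 91:308
ringstat shift --a spc72.pdb --b cdk5rap2.pdb --align A:530:560 \
    --measure-a C:231:260 --measure-b C:51:80
ringstat contacts --structure ring.pdb --chain-a C --chain-b D
ringstat hxms --table hx_peptides.tsv --length 160
ringstat stoich --table gel_bands.tsv --reference Spc97
```

On deposited coordinate files the same commands reproduce the published
measurements (lattice parameters from the 14-spoked ring model, domain
RMSDs between the isolated and oligomerised γ-TuSC, the CM1–Spc98
hydrogen-bond network); chain lists are explicit inputs because deposited
chain naming need not follow the ring order.

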