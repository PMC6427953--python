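# Methods

This note documents the models, conventions and numerical choices behind
`hemetrics`, in the order of the analysis pipeline. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Canonical macrocycle and reference geometry

The porphyrin macrocycle is stored as 24 atoms in a fixed canonical order
(`NA, C1A, C2A, C3A, C4A, CHB, NB, …, C4D, CHA`), using PDB heme component
nomenclature. The order traverses one pyrrole quadrant at a time; note
that it is a *storage* order, not a bond path — meso carbons bond to the
α-carbons of adjacent pyrroles, never to the nitrogens, so the macrocycle
identity check is a graph test: under a 1.2–1.7 Å adjacency window the 24
atoms must realize exactly the 28 bonds of the porphine macrocycle
(connected, every atom on a ring), with no spurious contacts in the
window.

The ideal D4h reference places Fe at the origin, the ring in z = 0 and
pyrrole A on +x. Its orbit parameters (α-, β- and meso-carbon radii and
half-angles) are solved once, by least squares, from canonical porphine
bond lengths: Fe–N 2.010 Å, N–Cα 1.380 Å, Cα–Cβ 1.440 Å, Cβ–Cβ 1.355 Å,
Cα–meso 1.395 Å, pyrrole interior angle at N 105.7°. Only the relative
geometry matters for the decomposition; these constants set the scale of
nothing that is reported.

## Minimal-basis NSD

**Mode construction.** The six minimal-basis vectors are symmetry-adapted
z-weight patterns on the 24 atoms, one per out-of-plane irreducible
representation of D4h: saddling (B2u, β-carbon pairs alternating, built as
a class-weighted cos 2φ), ruffling (B1u, sin 2φ: meso carbons alternate
and pyrroles twist), doming (A2u, positive class weights largest on the
nitrogens), waving (Eg pair, cos φ and sin φ), propellering (A1u, every
pyrrole twisted with the same handedness). Each raw pattern is first
projected orthogonal to the rigid-body null space — the apparent
out-of-plane fields of a uniform z translation and of the two mean-plane
tilts, span{1, x_i, y_i} — exactly as true vibrational eigenvectors are
orthogonal to rigid-body motions; this makes the generator/decomposer
round trip exact, because mean-plane alignment removes precisely that
subspace. Gram–Schmidt then orthonormalizes in a fixed order. Within-irrep
weights (e.g. the Cα:Cβ ratio in saddling) are idealized qualitative
choices, not force-field eigenvector components; the published NSD
eigenvector table was not obtainable in this offline environment, so the
`static-table` source freezes this package's own construction (at full
float64 precision, to preserve the 1e-10 orthonormality invariant) and
serves as a drift guard for the constructive path rather than as external
data. Consequences: the static/group-theoretic overlap check passes at
≈1.0 by construction, and numerical agreement with amplitudes from the
original NSD software is expected to be close but not exact — the
qualitative ruffled-vs-saddled classification, which is what the
comparative analysis rests on, is insensitive to these weight choices.

**Sign conventions.** Amplitude signs are fixed by requiring positive
reference weights for NA (dom), CHA (ruf), C2A (sad), NA (wav_x), NB
(wav_y) and C1A (pro). They are convention-relative; plots use magnitudes.

**Alignment.** The mean plane is the least-squares plane of the 24
macrocycle atoms (Fe excluded), computed from the smallest-eigenvalue
direction of the coordinate covariance. The +z sign is chosen so the
Fe-to-proximal-ligand direction points along −z; without a known ligand,
the Fe out-of-plane displacement is used instead, but only when it exceeds
0.05 Å — below that, coordinate noise would make the sign a coin flip, so
a deterministic fallback (the right-handed normal of the canonical NA→NB
circulation) applies. One consequence, by design: for a strongly domed
core with no ligand, mirroring the structure leaves the doming amplitude
unchanged (doming is reported relative to the Fe side), whereas with the
iron in-plane every amplitude negates under reflection. In-plane rotation
then registers the four nitrogens onto the reference axes; it cannot
affect the amplitudes (z is untouched) and exists for reproducible aligned
coordinates only.

**Decomposition.** Amplitudes are orthonormal projections, which equal the
simultaneous least-squares fit of all six modes (verified against
`numpy.linalg.lstsq` as an independent oracle). The residual is computed
directly as ‖z − Σ d_k v_k‖ rather than via √(D_total² − D_min²), avoiding
catastrophic cancellation for near-pure minimal-basis distortions. The
extended (second-mode-per-irrep) basis of the NSD literature is a
deliberate stub.

## Heme-site geometry

All criteria are distance-based; crystal structures at the relevant
resolutions carry no hydrogens.

* Axial ligands: non-heme N/O/S atoms within 3.0 Å of Fe; waters with
  occupancy < 0.5 are ignored; side assignment by aligned-frame z sign,
  with the proximal side defined by the His ligand when one is present.
  The His ligation distance is reported to whichever of Nδ1/Nε2 is nearer
  the iron.
* Cross-link: minimal Lys-NZ-to-meso-carbon distance, reported when below
  the 1.8 Å covalent cutoff. The cross-linked meso carbon is identified
  operationally (whichever CHA–CHD carries the NZ); no IUPAC renumbering.
* Hydrogen bonds: N/O/S pairs within 3.5 Å, at least one partner in the
  focus selection, same-residue pairs excluded, contacts under 2.2 Å
  treated as covalent and excluded. Donor and acceptor roles are not
  distinguishable without hydrogens; pairs are reported unordered.
* Meso hybridization: requires exactly three covalent neighbours within
  1.8 Å (an un-cross-linked meso carbon in an H-less structure has two,
  and is reported indeterminate with the reason). The verdict is sp2-like
  when the bond-angle sum ≥ 355° and the displacement from the substituent
  plane ≤ 0.15 Å; sp3-like when the angle sum ≤ 345° (the ideal
  tetrahedral sum is 3 × 109.47° = 328.4°); otherwise indeterminate. All
  thresholds configurable.
* Pocket inventory: amino-acid residues with any atom within 8 Å of Fe,
  assigned to the side of their Fe-nearest atom, classified by a fixed
  table — hydrophobic {A V L I M F W P G C}, polar {S T N Q Y H}, charged
  {D E K R}.

## Sequence operations

Percent identity uses a global Needleman–Wunsch alignment (Biopython
`PairwiseAligner`), BLOSUM62, gap open 10, extend 0.5. The denominator
excludes terminal-gap columns and counts internal gaps as mismatches
(configurable); published identity figures rarely state their convention,
so cross-method agreement should be expected only to a couple of points.
Symmetry is guaranteed by canonically ordering the pair before alignment.
A column is fully conserved only when all sequences agree and none is
gapped — an absent residue is not conservation. Reports use 1-based
residue numbering, with helpers mapping alignment columns to residue
numbers of a named reference sequence. The motif language is literal amino
acids plus `X` as wildcard, matched non-overlapping left to right.

## Thermal unfolding

The model is van 't Hoff two-state (one transition) or sequential
three-state (two transitions) with ΔCp = 0: ΔG_i(T) = ΔH_i(1 − T/Tm_i)
(kelvin internally, Celsius at every interface), populations from the
Boltzmann expressions, and one linear baseline per state. Initialization
is automatic: transition guesses from the largest extrema of the
Savitzky–Golay-smoothed derivative, baselines from linear fits to the
first/last 15% of points, intermediate baseline from the median between
the transition guesses, ΔH started at 300 kJ/mol. Bounds keep Tm inside
the data range and ΔH in [5, 5000] kJ/mol. Non-convergence is a flagged
result (initial parameters, NaN standard errors), never an exception.
Two-transition fits are reordered so Tm1 < Tm2 and flagged
`overlapping-transitions` when the midpoint separation is below the mean
transition width 4RTm²/ΔH — the physical resolution limit, which also
catches two-transition fits forced onto single-step curves. Reported
standard errors are fit-covariance estimates and are labelled as such;
they are not replicate spreads. `MeltFit.fraction_denatured` is the
model-based normalized curve (monotone by construction);
`fraction_denatured(curve, fit)` normalizes the *observed* data by the
fitted baselines, clips to [0, 1], and raises a named error if the
baselines approach each other anywhere in the range.

## Synthetic data: what it does and does not establish

The porphyrin generator injects exact mode amplitudes (defaults of order
0.1–1 Å, the range observed for heme proteins) plus iid Gaussian
coordinate noise, and can decorate a site with an axial water at a chosen
Fe distance and a Lys-NZ pseudo-atom at a chosen distance from a named
meso carbon — the six-coordinate cross-linked (P460-like) and vacant
(c′-β-like) site archetypes. The melt generator draws from the same model
family the fitter assumes, with midpoints and enthalpies chosen to match
the published two-protein scenario (58.4 °C one-step; 64.4/94.1 °C
two-step) and 1%-of-amplitude noise. Green tests on these fixtures
establish the correctness of the measurement and fitting machinery —
round-trip exactness, oracle equivalence, invariances, recovery under
noise. They do not validate deposited coordinates, real B-factor/altloc
pathologies beyond the cases modelled, deviations of real unfolding from
the two-/three-state family, or scan-rate effects; fixtures built from
published distances are stand-ins and are named `synthetic` wherever they
appear.

## Known limitations

* Within-irrep mode weights are idealized (see above); absolute amplitude
  comparisons against other NSD implementations carry that caveat.
* The proximal/distal assignment needs either a His ligand or a displaced
  iron; for a perfectly planar, unligated, iron-centred core the sides are
  assigned by the deterministic handedness convention, which is arbitrary
  (though reproducible).
* Percent identity depends on alignment parameters at the level of a
  point or two; treat small differences accordingly.
* The two-transition model assumes sequential unfolding with a populated
  intermediate baseline; parallel or non-two-state mechanisms will fit but
  misreport ΔH.
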