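# Methods

This note documents the models, the synthetic data, the numerical choices,
and their limitations. Units: lengths in nm internally (Å on PDB I/O and in
H-bond/RMSD reporting, as is conventional), energies in kcal/mol.

## Structure model and I/O

Structures are ordered residue lists; each atom carries element,
coordinates, a hydrogen flag, a side-chain flag, a hydrogen-bond role
(donor / acceptor / both / none) and the serials of its attached hydrogens.
Roles are assigned from a built-in (residue name, atom name) table covering
the amino-acid and DNA-nucleotide names the generator emits; hydrogens are
attached to the nearest heavy atom of the same residue within 0.15 nm.
PDB v3.3 I/O is deliberately strict and minimal: ATOM/HETATM/TER/TITLE
records only, altloc '' or 'A' kept, insertion codes rejected, parse errors
name the offending line, serial/resseq overflow raises rather than falling
back to hybrid-36. Round-tripping preserves coordinates to the format's
3-decimal Å precision; annotations are re-derived from the table on read.

## Synthetic universe

The generator is the package's study system, not a test convenience; its
defaults define the conditions every downstream count assumes.

* **Receptor** — a homodimer of two-domain monomers. Domains are beads (one
  residue each) on a jittered FCC lattice inside a sphere: 110 residues per
  receptor-binding domain (RBD), 55 per heparin-binding domain (HBD),
  matching the real protein's domain sizes; bead spacing 0.55 nm keeps the
  1.5 nm elastic network connected without over-stiffening. The two RBDs
  pack as the dimer core; each HBD floats above, tethered by a 12-residue
  linker (sequence named RPKKDRARQENP after the natural interdomain
  linker). The built HBD–HBD COM distance (~5.5 nm) sits inside the 3–9 nm
  grid the ensembles span. Each residue has a Cα node plus 1–3 pseudo
  side-chain heavy atoms pointing radially outward, with one explicit
  hydrogen per donor; charged residues (R/K/D/E) carry ±1 formal charges on
  their terminal side-chain atoms.
* **Aptamers** — DNA residues have a phosphate backbone node plus fanned
  base atoms (the fan guarantees no donor hydrogen coincides with a sibling
  heavy atom). The quadruplex monomer carries a labelled 12-residue core
  built as three stacked 4-residue rings (after the three stacked quartet
  planes of a real G-quadruplex) plus a short tail; the plain monomer is an
  18-residue globule; the heterodimer joins one of each with a 10-thymine
  linker, role-tagged RBD-binder and HBD-binder.
* **Linkers** are helical bridge walks: a winding path between the two
  anchors with a sine radial envelope, seeded jitter, and bond-length
  relaxation. The winding is load-bearing: a *straight* bead chain is a
  torsional mechanism in a pairwise-spring network (rotation about the
  chain axis stretches nothing), which would contaminate the rigid-mode
  count; the permanent kinks remove that mechanism, and all generated
  structures show exactly 6 near-zero modes.
* **Fixtures.** Pose fixtures construct sandwich/side/hug geometries by
  anchored placement (a designated DNA heavy atom 0.25–0.36 nm from a
  designated side-chain heavy atom) and verify themselves against the
  classifier before returning. H-bond fixtures plant exactly n compliant
  donor–H···acceptor triplets (3.0 Å, 0°) plus max(n, 1) decoys per
  criterion (3.6 Å/10° and 3.0 Å/45°), spaced ≥ 1.2 nm so pairs cannot
  cross-match.

Everything is a pure function of (params, seed).

What the generator does **not** emulate: chemical bonding geometry,
sequence-dependent energetics, base pairing/stacking, counterions, LNA
chemistry (a residue tag at most), or realistic side-chain rotamers.
Passing tests therefore demonstrate that the *pipeline machinery* —
bookkeeping, filters, numerics, geometry — is correct under the stated
contracts, not that the energies or poses would be accurate on real
molecules.

## Elastic network and modes

Standard anisotropic network model: one node per residue (Cα for protein,
P for DNA — residue-level coarse-graining), cutoff 1.5 nm, uniform spring
constant γ = 1 (γ rescales eigenvalues but not mode shapes, so the choice
is immaterial downstream). Eigendecomposition is dense below 3N = 3000 and
shift-inverted Lanczos above. Rigid modes are eigenvalues below 10⁻⁸ of the
spectral maximum; a connected network yields exactly 6. The mode driving an
inter-domain distance is found by |cos| overlap with the unit-normalised
gradient of the COM–COM distance over node coordinates.

## Conformer generation

Restrained atomistic sampling is replaced by deterministic mode-following —
the central surrogacy decision of the package. The purpose of the biased
simulations in this protocol is only to realise prescribed inter-domain COM
distances along the softest collective coordinate; the surrogate does this
directly: minimise ½ aᵀΛa + ½k(d(a) − d*)² over the 20 lowest non-rigid
mode amplitudes *a* (Λ their eigenvalues, k = 1000 kJ mol⁻¹ nm⁻², the
restraint the protocol prescribes), apply the resulting per-residue
displacement rigidly to each residue's atoms. COM means the unweighted
heavy-atom centroid (mass weighting changes the result negligibly at this
resolution and is not used). Convergence tolerance is 0.05 nm; achieved
errors are ~0.005 nm. Driving fails explicitly (reporting the best achieved
distance) if the required RMS node displacement exceeds 5 nm, beyond which
the linear mode picture is meaningless.

Small-scale snapshots superpose the 10 lowest non-rigid modes of the input
structure with seeded Gaussian amplitudes at 0.1 nm RMS node displacement,
then restore the target distance by a scalar correction along the driving
mode (tolerance 2 × 0.05 nm). Snapshot 0 of every variant is the driven
structure itself. Snapshots are independent perturbations, not a
correlated trajectory; time labels are metadata only.

## Docking

Two-stage rigid docking with the receptor immobilized. Rotations: a
super-Fibonacci spiral on S³ (576 orientations at the 15° default, count
scaling as (15°/interval)³), with the member nearest the identity snapped
onto it. Translations: Katchalski–Katzir grids — receptor surface cells
weight 1, core cells (occupancy eroded by one layer) weight 9i, ligand
cells 1 — correlated by FFT; score = Re + Im of the cross-correlation =
surface contact − 9 × core overlap. The ten best translations per rotation
are re-scored on actual coordinates with a soft contact potential (+1 per
heavy-atom pair in 0.3–0.6 nm, −10 per pair under 0.25 nm) and only the
best survives per rotation; the knowledge-based re-scoring of the original
docking engine is proprietary and is *not* reproduced. No continuous local
optimization is performed at this stage. Ties break lexicographically by
(rotation index, translation index); the whole stage is deterministic.
Defaults are 15°/0.12 nm; the `coarse` preset (30°/0.3 nm) is used by the
campaign and tests.

## Selection

The attachment criteria are the formalisation of what was a manual
filtering step: contact means ≥ 1 (protein side-chain heavy atom, DNA heavy
atom) pair within 0.45 nm — the same rule the pose taxonomy uses — applied
between each aptamer binding unit and its designated domain set. Top-k
keeps the best min(k, passing) poses per variant pair, score-descending,
pose-id tie-broken. Docking scores follow the higher-is-better convention
internally. The campaign arithmetic is closed-form and exact:
(7·20)·(12·20) = 33600 docked pairs per heterodimer, 84 variant groups,
252/21 selections, 567 total for the 2-heterodimer + 3-monomer roster.

## MM/GBSA rescoring

Single-trajectory end-point energies with identical bound/free coordinates,
so intramolecular MM terms cancel identically and only the intermolecular
Coulomb (k = 332.0636 kcal Å mol⁻¹ e⁻², no cutoff) and 12-6
Lennard-Jones sums are computed. Polar solvation is Still-form pairwise GB,
f_GB = √(r² + RᵢRⱼ exp(−r²/4RᵢRⱼ)), with HCT pairwise-descreening
effective Born radii (screen factor 0.8, radii clamped positive for deeply
buried atoms); ε_in = 1, ε_out = 78.5, no salt. It reduces to the Born
formula for a single ion and to screened Coulomb at large separation —
both are test oracles. Nonpolar solvation is γ·SASA with
γ = 0.0072 kcal mol⁻¹ Å⁻² and zero offset (the classic choice); SASA is
Shrake–Rupley with a deterministic Fibonacci sphere (default 256 points;
the campaign uses 128), probe 0.14 nm, hydrogens included with small radii.
The solute entropy term is omitted, as is common when comparing closely
related ligands against one target.

The parameter set ("ForceFieldLite") is an element-based table (LJ σ/ε, GB
radii) with integer formal charges on charged side chains and phosphates.
ΔG values are therefore comparative across ligands of this pipeline, never
reproductions of published binding energies — stated prominently because it
is the package's largest simplification. The GB flavour and radii of the
reference protocol are unstated there; HCT+Still is this package's declared
choice.

Campaign rescoring scale: MM/GBSA is O(N²) per snapshot, so the default
campaign rescored the top 1 selected complex per ligand type with 2 relaxed
snapshots each — enough to exercise the full path and produce the report
table; the functions accept any pool size. Before rescoring, constructed
placements are relaxed by rigid-body translation of the ligand to a local
minimum of LJ + ε_out-screened Coulomb (the bare monopole attraction of a
polyanionic ligand would otherwise drag it into the repulsive wall).

## Analysis

* **H-bonds**: all inter-molecular donor–H···acceptor triplets with
  donor–acceptor ≤ 3.5 Å and H–donor–acceptor angle ≤ 30° — the angle at
  the *donor*, exactly as the criterion is stated, not a donor–H–acceptor
  linearity. Donors lacking hydrogens are skipped with a warning. The
  census counts multiplicities per residue (not binary presence) and
  averages over snapshots; key-residue defaults are the seven RBD residues
  (Y21, Y25, I43, N62, D63, E64, Q89) and ten basic HBD residues
  (R123–R165) known from the receptor's partner interfaces.
* **Pose taxonomy**: evidence is the unit × domain contact matrix at
  0.45 nm. Precedence: sandwich (some single unit contacts both HBDs) >
  hug (RBD-binder contacts both RBDs and the HBD-binder exactly one HBD) >
  side (HBD-binder contacts exactly one HBD, RBD-binder at most one RBD);
  otherwise unclassified. "Interior"/"outside" are prose in the source
  taxonomy; contacting both vs at most one RBD unit is this package's
  declared operationalization, and the precedence order resolves
  overlapping evidence. A missing unit (monomer) satisfies "at most one"
  vacuously but never "exactly one" — so an RBD-binding monomer that only
  touches one RBD is honestly `unclassified` rather than force-fitted.
* **RMSD**: Kabsch superposition via SVD with the determinant sign
  corrected (proper rotations only). The quadruplex-core distribution uses
  the 12 core residues' heavy atoms against the stored reference, 0.25 Å
  histogram bins; time courses use all heavy atoms against a designated
  reference snapshot.
* **Interface ("clash") area**: ΔSASA/2 between the transplanted aptamer
  and the reference partner after Kabsch superposition on a shared
  alignment group (e.g. the RBD core); a flag returns total ΔSASA instead.

## Campaign orchestration

`run_campaign` is config-driven and deterministic under a fixed seed. In
the default *fixture mode*, exhaustive per-snapshot-pair docking is
replaced by constructed attachment-compliant placements scored with the
same contact potential — enumeration counts, filtering, selection,
classification and rescoring run unchanged; this is what makes the
full-size campaign (75 600 enumerated pairs, 567 selections) run in well
under a minute. `fixture_mode=False` runs real coarse-preset FFT docking
per variant pair and is exercised in the tests on a minimal configuration.
Placements park the HBD-binder on an HBD's outer face and the RBD-binder on
the same monomer's lower outer flank, with the aptamer linker re-drawn
around the receptor body; each unit is first rotated so its bulk points
away from the receptor surface.

## Numerical notes and known limitations

* The restrained minimisation is convex in practice near the grid targets;
  the L-BFGS tolerance (1e-14 relative) makes results bit-reproducible.
* SASA quadrature converges non-monotonically (hard in/out point test);
  doubling the point count changes totals by < 0.5 % from 512 points on.
* Self-energies in GB use f_GB(0) = Rᵢ; the descreening clamp (effective
  radius ≤ 20 × the largest intrinsic radius) only engages for deeply
  buried atoms in dense synthetic cores.
* Grid projection rasterises heavy atoms only; the one-layer erosion core
  is the classic choice and is not tuned.
* The pipeline does not model solvent, ions, base pairing, flexibility
  during docking, or entropy; its energies rank poses and ligands within a
  campaign, nothing more.
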