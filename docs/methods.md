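# Methods

This note documents the models, conventions and numerical choices behind
`qmmmprep`, including the places where a convention had to be fixed by the
package rather than by the underlying theory.

## Structure model and bond perception

Atoms, residues and chains mirror PDB semantics (serial, name, element,
record type, chain/resseq/icode).  Parsing is gemmi-backed: first model
only, highest-occupancy alternate locations, elements inferred from atom
names when the element column is missing.  Writing is done in-package with
fixed-width records because round-trips must preserve the original serials.

The covalent bond graph is built template-first: bundled connectivity for
the 20 standard residues, ACE/NME and water; inter-residue peptide bonds
C(i)–N(i+1) when the residues are consecutive in the same chain and the
distance is below 2.0 Å; disulfides for SG–SG below 2.3 Å; and a
covalent-radius criterion (d ≤ 1.25·(r_a + r_b), radii from gemmi) for
ligands and unknown residues.  CONECT records are ignored so the graph does
not depend on deposition quality.  Hydrogen-name variants are normalized
(digit rotation 1HB→HB1, HN→H, and the HB1/HB2 ↔ HB2/HB3 methylene
convention shift); hydrogens that still match nothing are bonded to the
nearest heavy atom within 1.3 Å.

## Terminus capping

ACE/NME caps are constructed from ideal internal coordinates (amide C–N
1.335 Å, C=O 1.229 Å, C–C 1.522 Å, N–CH3 1.455 Å, sp² angles 120°, methyl
geometry tetrahedral), placed trans to the chain (180° dihedrals) for a
deterministic, clash-free result.  Charged termini are neutralized first —
H2/H3 and OXT are removed (an H1 left alone is renamed H) — because the cap
templates assume neutral amide attachment.  Capping never moves existing
atoms and is idempotent; cap residues get fresh serials and flanking resseq
numbers.

## Charge assignment

The packaged charge set emulates an Amber-family fixed-charge force field:
per-atom charges for the 20 standard residues (HIS as the neutral
N-epsilon tautomer), ACE/NME, monatomic ions, and rigid water models
(3-site default with qO = −0.834 e, qH = +0.417 e; 4-site models place the
negative charge on an extra point at r_EP along the H–O–H bisector, stored
as a pseudo-atom with element "EP" so every downstream stage treats it
uniformly; EP sites are excluded from QM geometries since they carry no
nucleus).  Every template's charges sum to the residue's formal integer
charge to 1e−6 e, which the library loader enforces — that invariant is
what makes both the integer-charge validation and the balanced boundary
schemes exact.  Users may substitute a CHARMM-style RESI topology or a
plain serial→charge table.

Integer validation compares each nonligand residue's charge sum with the
nearest integer at a default tolerance of 1e−3 e (force-field tables print
four decimals or more, so genuine assignments sit far inside this band
while a missing hydrogen, at ≥0.01 e, sits far outside).  Failures abort
the pipeline with the residue named and any template mismatches (missing or
extra atoms) listed, since they indicate structure-file errors.

## QM-region carving

Selection takes whole nonligand residues with any atom (hydrogens included)
within the cutoff of the seed — one ligand atom or, by default, the whole
ligand.  The boundary convention, fixed by this package at atom level: for
each maximal run j..k of selected residues in a chain, the QM side gains
C and O of residue j−1 and loses C and O of residue k, so both cuts are
Cα–C(carbonyl) bonds: CA(j−1)–C(j−1) with Q1 = C(j−1), and CA(k)–C(k) with
Q1 = CA(k).  An adjacent ACE/NME cap (or a chain terminus) is absorbed
instead of cut.  Waters and ions are never cut.  M1 is the MM atom of the
cut bond; M2/M3 are the two- and three-bond MM frontiers computed by
breadth-first search from Q1 restricted to the MM side, which makes the
shells exactly the 1/2/3-bond BFS frontiers by construction.

Cuts in close sequence proximity produce clashing link hydrogens.  The
absorption rule: while two QM runs in one chain are separated by at most
`gap_min` = 1 MM residue, or two link hydrogens are closer than 1.3 Å, the
intervening residues join the selection and the cuts are recomputed.  The
QM set only grows, so this terminates.  Both thresholds are configurable;
they are the smallest rules that prevent adjacent caps.

Link hydrogens sit on the Q1→M1 axis at
r(Q1–H) = r(Q1–M1) · r0(Q1–H)/r0(Q1–M1), with r0 defaults 1.090 Å (C–H)
and 1.522 Å (Cα–C) from standard Amber-family bond parameters, overridable
per force field.  At the reference bond length the link distance is exactly
r0(Q1–H).

The QM-region charge defaults to the sum of formal integer charges of every
residue with at least one atom in the QM set (multiplicity 1); both are
user-overridable.  Counting partially-included boundary residues at full
formal charge is a convention — the boundary atoms (C, O) carry little net
charge — and the option exists precisely because chemistry may dictate
otherwise.

## Boundary charge schemes

Nine data-driven schemes (a `SchemeDefinition` names the shells to zero,
the M1 move, and the q_bal target, so variants are configuration, not
code):

| scheme | zero | M1 move | q_bal target |
|--------|------|---------|--------------|
| Z1/Z2/Z3 | M1 / M1∪M2 / M1∪M2∪M3 | – | – |
| DZ1/DZ2/DZ3 | as Z1/Z2/Z3 | – | the zeroed residue's remaining atoms |
| RC | – | q0/n at each M1–M2 midpoint | – |
| BRC | M1 | – | + q_bal/n on each M2 atom |
| BRCD | – | 2q0/n at midpoints, −q0/n on each M2 atom | midpoints |

BRCD's construction conserves both the removed charge
(2q0 − q0 = q0) and its dipole contribution
(Σ 2q0/n·(M1+M2ᵢ)/2 − q0/n·M2ᵢ = q0·M1).

**q_bal bookkeeping.**  q_bal is "the charge that returns each cut residue
to its original integer charge".  Computing it against the residue's own
atoms alone breaks down whenever a cut's midpoints or M2 changes extend
into the neighboring residue — every C-terminal cut decrements N(k+1),
which belongs to residue k+1.  A short derivation with one C-terminal cut
and BRCD shows the residue-only ledger leaves the total off by 3q0/2.  The
engine therefore charges each cut with its *full ledger*: the M1 residue's
remaining MM atom charges, plus the midpoint charges the cut introduced,
plus the changes it made outside the residue; q_bal is the formal integer
charge minus that ledger.  With this accounting the final MM total is a sum
of integers — the defining property of a balanced scheme — which the
acceptance suite verifies to 1e−6 e over a randomized ensemble.  (After
clash absorption no two cuts share an M1 residue, so per-cut ledgers never
overlap.)

**DZ2/DZ3 fallback.**  Zeroing two or three shells can wipe out *every*
remaining MM atom of a boundary residue (a C-terminal cut residue retains
only C and O).  Its q_bal then goes to the nearest nonzeroed MM atoms found
by BFS outward from the residue's zeroed atoms.  This keeps the correction
as local as possible but can step one bond past the third shell; strict
three-bond locality is guaranteed for the Z, RC, BRC and BRCD schemes (the
DZ family is residue-local by definition).

## Input file emission

Atom order is fixed and documented because F-SAPT indices depend on it:
ligand atoms in file order, protein QM atoms in file order, link hydrogens
appended last in cut order.  Coordinates and charges are printed to six
decimals — below physical significance, above round-trip noise — with no
timestamps, so identical inputs give byte-identical files.  Three dialects
are emitted (Psi4-, NWChem- and Q-Chem-style: geometry block,
charge/multiplicity, external-charge block, method/basis, SCF convergence
10^−N with N = 6 by default, ghosts as Gh(X)/bqX/@X); user
`extra_keywords` are appended verbatim last so they override defaults.  A
`read_back` helper recovers the semantic content for cross-dialect
verification.  Counterpoise adds the partner monomer as ghosts (the
ligand-only file carries ghosts but, by default, no point charges — the
configurable reading of an open convention).  SAPT mode emits a single
two-monomer file (ligand = monomer A) and rejects counterpoise, which is
meaningless when the interaction energy is computed directly.

F-SAPT partitions: per-residue side-chain fragments (CA, HA + side chain),
per-peptide-bond fragments {C(i), O(i), N(i+1), H(i+1)}, cap methyl
fragments, per-water/ion fragments; each link hydrogen joins its Q1 atom's
fragment.  The fragment membership at atom level is this package's
convention; the partition is validated to cover each monomer index exactly
once.

## Templating

A template records, for every QM protein residue, its identity, the atom
names included, and a 5-residue neighborhood signature (resnames at offsets
−2..+2, chain ends padded with a sentinel).  Applying it to a congeneric
structure matches template residues to new residues by exact signature
equality, ranked by |Δresseq| (ties: same chain, then lower resseq), each
new residue used at most once; matching is order-independent because
records are processed in (chain, resseq) order.  Unmatched template
residues, unmatched new residues and all nonprotein atoms follow the
distance cutoff.  Cuts, shells and link atoms are always recomputed on the
resulting selection, so self-application is the identity on the QM residue
set.  No structural alignment is attempted; visual inspection of the two
regions remains advisable.

## Synthetic fixtures

The fixture generator emulates the prepared inputs the pipeline expects: a
capped multi-residue polypeptide in an extended conformation (φ = ψ = ω =
180°) built from ideal internal coordinates (N–Cα 1.458 Å, Cα–C 1.522 Å,
C–N 1.329 Å, tetrahedral/trigonal angles), a small rigid ligand (methanol-
or ethanol-like) whose nearest contact with a chosen residue is placed at
an exact target distance by bisection along the approach direction (tilting
away from the bulk when a neighboring side chain crowds the site), far-field
waters at ≥2.8 Å separation, and a per-atom charge table with exact integer
residue sums.  Default composition is poly-ALA with one ARG and one ASP so
charged residues are exercised; defaults of 5 residues, 4.0 Å ligand
distance and a 5 Å cutoff give a single-residue QM run with one cut at each
boundary.  Sequences are restricted to residues with z-matrix support
(rings — PRO, PHE, TYR, TRP, HIS — are parseable and chargeable but not
buildable).  Everything is deterministic under a fixed seed, and three
named corruptions (noninteger charge, deleted atom, renamed residue) exist
to exercise the validation path.

What the fixtures deliberately do not model: realistic conformations,
solvation shells, crystal contacts, alternate locations, or multi-chain
assemblies.  Passing tests therefore demonstrate the correctness of the
carving/charge/emission logic on well-formed inputs, not robustness to the
full pathology of deposited PDB files.

## Problem sizes and determinism

The test suite and the acceptance script run on fixtures of 4–30 residues
(≈60–340 atoms) — large enough to exercise multi-run selections, charged
residues, waters and every scheme, while keeping the whole suite in
seconds.  The production pipeline contains no randomness at all; only the
fixture generator takes a seed.  The run manifest records every option and
derived count needed to reproduce a run.

## Known limitations

- Charges come from packaged tables, not an on-the-fly derivation; exotic
  residues need a user topology.
- Ligand charges are never assigned (the ligand is fully QM by design);
  ligand formal charge is user input.
- mmCIF, NMR ensembles beyond the first model, and alternate locations
  beyond highest-occupancy selection are out of scope.
- The scheme registry ships the nine schemes above; other published
  variants can be added as `SchemeDefinition` records.
- Systems without a protein backbone (host–guest, nucleic acids) are not
  supported: the carving convention is defined on Cα–C bonds.
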