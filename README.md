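# qmmmprep

Automated preparation of QM/MM electrostatic-embedding input files for
protein:ligand interaction-energy calculations.

## The problem

Computing a protein:ligand interaction energy fully quantum-mechanically is
prohibitively expensive for systems beyond a few hundred atoms.  A practical
alternative treats the ligand and a small cluster of nearby protein residues
quantum-mechanically and represents the rest of the protein (plus waters and
ions) as fixed point charges that polarize the QM region — electrostatic
embedding in the QM/MM partition

```
E = E_QM + E_MM + E_QM/MM
```

where only the QM part is evaluated here; the input files prepare a
supermolecular interaction energy

```
E_int = E(P:L) − E(P) − E(L)
```

from three jobs (complex, protein, ligand), optionally with counterpoise
ghost atoms, or a single SAPT job that returns the interaction energy (and
its electrostatics/exchange/induction/dispersion components) directly.

Setting these calculations up by hand is tedious and error-prone: the QM
region boundary crosses covalent bonds, each severed bond needs a hydrogen
link atom, and the MM point charges next to every cut must be corrected to
avoid overpolarizing the QM wavefunction.  `qmmmprep` automates the whole
chain for anyone who runs Psi4-, NWChem- or Q-Chem-style electronic-structure
jobs on protein:ligand systems.

## What the pipeline does

1. **Parse** the PDB (gemmi-backed), identify the ligand (HETATM, not
   water/ion), build a covalent bond graph from bundled residue templates
   plus peptide/disulfide/distance rules.
2. **Cap** uncapped chain termini with ACE/NME groups built from ideal
   internal coordinates (charged termini are neutralized first).
3. **Assign charges** to every nonligand atom from a packaged Amber-family
   residue charge set, a user CHARMM-style RESI topology, or a plain
   serial→charge table; rigid 3-/4-site water models are supported (4-site
   models get an extra point on the HOH bisector).  Every residue must sum
   to its formal integer charge; violations abort with a per-residue report
   because they indicate PDB errors.
4. **Carve the QM region**: whole residues with any atom within the cutoff
   of the seed (one ligand atom or the whole ligand), then expand/shrink so
   every boundary falls on a Cα–C(carbonyl) bond.  Nearby cuts are merged by
   absorbing the intervening residues.  Every nonligand atom is classified
   as QM, Q1, M1, M2, M3 or MM (Q1 = the QM-side carbon of a cut; M1–M3 =
   MM atoms one/two/three bonds out).
5. **Place link atoms**: a hydrogen on each Q1→M1 axis at

   ```
   r(Q1–H) = r(Q1–M1) · r0(Q1–H) / r0(Q1–M1)
   ```

   using force-field equilibrium bond lengths r0.
6. **Correct boundary charges** under one of nine schemes: Z1/Z2/Z3 zero
   the first one/two/three MM shells; DZ1/DZ2/DZ3, BRC and BRCD additionally
   redistribute q_bal — the charge restoring each cut residue's integer
   charge — so the MM region keeps an integer total; RC/BRC/BRCD move the M1
   charge onto M1–M2 bond midpoints (BRCD preserving the bond dipoles).
7. **Write inputs** in three dialects, plus MOL2 charge export, a category
   audit CSV, F-SAPT functional-group partitions, and a machine-readable run
   manifest.  A stored QM-region **template** can be re-applied to a
   congeneric complex (5-residue-neighborhood matching) so both ligands see
   the same QM region.

## Worked example

Everything below is generated on the fly — no downloads.  Build a synthetic
complex (5-residue capped peptide, methanol-like ligand placed exactly
4 Å from the central residue) and run the pipeline:

```
$ qmmmprep make-fixture --n-residues 5 --seed 7 --out-prefix complex
wrote complex.pdb and complex.charges

$ qmmmprep run --set pdb_file=complex.pdb --set charge_overrides=complex.charges \
               --set cutoff=5.0 --set charge_scheme=BRC \
               --set method=hf --set basis=sto-3g
...
MM region: 66 point charges, total charge +0.000000 e (integer)
QM atoms (protein side, links included): 12
outputs written to complex_5A
```

The numbers mean: the 5 Å cutoff selected the central residue; carving kept
its atoms plus the preceding carbonyl (C, O) and dropped its own C, O,
giving 10 QM protein atoms plus 2 hydrogen link atoms (one per Cα–C cut) =
12; the balanced redistributed charge scheme (BRC) left the 66 remaining
point charges with an exactly integer total, as a balanced scheme must.
`complex_5A/` contains `ligand.psi4.in`, `protein.psi4.in`,
`complex.psi4.in` (geometry, charge/multiplicity, external charges, method
and basis), `charges.mol2`, `categories.csv`, `charge_audit.csv` and
`manifest.json`.

The same run is available programmatically:

```python
from qmmmprep import run_pipeline
result = run_pipeline({"pdb_file": "complex.pdb",
                       "charge_overrides": "complex.charges",
                       "cutoff": 5.0, "charge_scheme": "BRC"})
print(result.manifest["qm_atoms_protein"])   # 12
```

Looping a dictionary of options over cutoffs (e.g. 3–17 Å in 0.5 Å steps)
produces one directory per cutoff with a monotonically growing QM region.

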