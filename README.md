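# mutqprof

**From cohort mutation tables to quantum-chemistry-ready fragments and
electronic-perturbation descriptors.**

Tumour-sequencing cohorts yield hundreds of protein-level variants per gene
(p53 being the canonical example), but sequence and predicted structure alone
say little about how a point mutation redistributes local electron density —
the property that ultimately perturbs zinc coordination, DNA binding or
tetramerisation. `mutqprof` implements the desk side of a
mutation-to-quantum-descriptor pipeline:

1. **Variant profiling** — parse HGVSp strings (`p.R157H`) or translate raw
   coding sequences, apply each variant to a reference protein, classify it
   (missense / nonsense, conservative / non-conservative by BLOSUM62 score
   > 0, domain membership on a 1-based interval map), summarise the cohort
   and emit mutant FASTA for structure prediction.
2. **Structure handling** — read predicted-structure PDBs whose B-factor
   column carries per-residue pLDDT (0–100), flag low-confidence residues
   (strictly below 70 by default), superpose structures with the Kabsch
   algorithm, and cut a **±1-residue fragment** around the mutation site:
   severed peptide bonds are capped with hydrogens at 1.09 Å along the cut
   direction, and the fragment's net charge is the sum of pH-7 side-chain
   formal charges (Asp/Glu −1, Lys/Arg +1, His 0).
3. **Engine I/O** — emit byte-deterministic single-point input decks
   (B3LYP/6-31G*, SCF_CONVERGENCE 7, MAX_SCF_CYCLES 200, DIIS_GDM) in three
   flavours that differ in exactly one keyword — `CHELPG TRUE` (ESP charges),
   `NBO 1` (natural population analysis) or `PRINT_ORBITALS TRUE`
   (HOMO/LUMO) — and parse the corresponding output blocks back into
   per-atom charge sets and orbital spectra (hartree).
4. **Descriptors** — summed fragment charges, atom-aligned charge matrices,
   wild-type-referenced perturbations Δqᵢ = qᵢ(mut) − qᵢ(WT) with their L1
   norms ‖Δq‖₁ = Σ|Δqᵢ|, HOMO–LUMO gaps Δε = ε_LUMO − ε_HOMO (eV via
   27.2114 eV/hartree), and a PCA of the charge matrix.
5. **Fixtures** — seed-deterministic generators for every input: synthetic
   mutation cohorts, toy polypeptide PDBs with controlled pLDDT, mock engine
   outputs with known ground truth, and a classical point-charge ESP oracle
   (evaluate V = Σ qᵢ/rᵢ on a shell grid ≥ 3 Å from all nuclei, re-fit the
   charges by least squares). The whole pipeline therefore runs offline with
   no structure predictor and no DFT engine.

A bundled synthetic 393-residue reference protein carries the p53 domain map
(TAD1 1–40, TAD2 41–61, PRR 62–93, DBD 94–292, OD 323–356); substitute any
real sequence with `variant_profile.load_reference_fasta`.

## Worked example

```python
from mutqprof import variant_profile as vp, structure_model as sm
from mutqprof import qchem_io as qc, fixtures as fx

ref = fx.synthetic_reference()
_, records = fx.make_cohort(
    fx.SyntheticCohortSpec(n_records=256, seed=7, hotspots=((157, 60.0),)), ref)
s = vp.summarize_cohort(records, ref)
print(s.total_records, s.missense, s.nonsense, s.unique_variants,
      s.per_domain["DBD"], s.top_positions(1))
```

prints `256 212 44 235 149 [(157, 35)]`: of 256 records, 212 are missense
and 44 nonsense (235 distinct variants), 149 fall in the DNA-binding domain,
and the engineered hotspot at residue 157 recurs 35 times.

```python
model = sm.read_pdb(fx.make_toy_pdb(
    fx.ToyStructureSpec("MGAVLKDEFG", plddt=(88,)*5 + (55,)*2 + (90,)*3)))
frag = sm.extract_fragment(model, center=8)   # ±1 residue around E8
print(frag.window, frag.n_atoms, frag.n_caps, frag.net_charge)
deck = qc.write_qchem_input(frag, qc.QChemJobSpec(qc.JobFlavour.ESP))
```

prints `(7, 9) 14 2 -2`: the Asp7–Glu8–Phe9 window keeps 14 atoms (12
backbone atoms plus 2 cap hydrogens) and carries charge −2 (Asp −1, Glu −1).
The deck's `$molecule` block starts `-2 1` and its `$rem` block ends in
`CHELPG TRUE`.

The same steps are scriptable from the shell:

```bash
mutqprof simulate cohort --seed 1 --out sim/
mutqprof profile --csv-dir sim/ --out profile/
mutqprof fragment --pdb model.pdb --center 157 --out-xyz frag.xyz
mutqprof qcgen --xyz frag.xyz --charge -2 --flavour esp --out job.in
mutqprof qcparse --out job.out --what chelpg
mutqprof descriptors --parsed outputs/ --wt WT --out desc/
```

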