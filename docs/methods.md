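# Methods

This note documents the scientific choices behind `mutqprof`: what each
stage computes, the defaults and why, what the synthetic generators emulate,
and the known limitations.

## Variant model

A mutation record is a protein-level single-residue event: reference
residue, 1-based position, alternate residue (or a stop, written `*`). The
parser accepts one- and three-letter codes with an optional `p.` prefix and
`Ter`/`*` stops; `=` marks an explicitly synonymous change. A bare position
with no alternate allele (`R196`) is rejected rather than guessed — an
ambiguous record silently coerced to missense or nonsense would corrupt
every downstream count. Coding sequences are translated with the standard
genetic code, stopping at (and excluding) the first stop codon, and mutant
proteins are diffed against the reference: one substitution → missense, a
proper matching prefix → nonsense at the first missing residue, identity →
synonymous, anything else → `other`.

Applying a record to the reference enforces consistency (the record's
reference residue must match the sequence) and yields: same-length sequence
with one substitution (missense), the `position − 1` prefix (nonsense), or
the unchanged sequence (synonymous). Truncating therefore equals nonsense by
construction, and the summary reports length change truthfully.

**Conservation.** The field's convention — adopted here because no single
threshold is universal — is that a substitution is conservative iff its
BLOSUM62 log-odds score is strictly positive. This places Arg→His (score 0),
the most recurrent substitution in p53 cancer cohorts, on the
non-conservative side, which matches how such cohorts are usually described.
BLOSUM62 comes from Biopython's bundled matrices; no network access is
involved.

**Domains.** Residue intervals are 1-based inclusive. The bundled p53 map
is TAD1 1–40, TAD2 41–61, PRR 62–93, DBD 94–292, OD 323–356; positions
293–322 and 357–393 are "inter-domain", positions beyond 393
"out-of-range". Domain assignment is total on positive integers, so the
domain counters, the inter-domain counter, the out-of-range counter and an
`unlocalized` counter (records that carry no residue position at all, e.g.
complex CDS-derived changes) partition the cohort exactly. For cohorts in
which every record has a position — all generator output — `unlocalized`
is zero.

**Uniqueness.** Variants are keyed on (reference residue, position,
alternate); sample multiplicity lives in the FASTA manifest. The FASTA
writer deduplicates on that key, orders entries by (position, alternate),
wraps at 60 columns and uses the first-seen sample id in the header.

## Structures, confidence and fragments

PDB reading is a strict fixed-column parser (serial 7–11, name 13–16,
resSeq 23–26, x/y/z 31–54, B-factor 61–66): only ATOM records of the first
model and first chain are kept, HETATM records are skipped, and malformed
fields raise an error carrying the line number. Predicted models store
per-residue pLDDT (0–100) in the B-factor column; the confidence profile is
the per-residue mean with residues *strictly below* the threshold flagged.
The default threshold of 70 follows the common usage of ~70 as the boundary
below which predicted backbones stop being reliable; it is configurable.

RMSD uses the closed-form Kabsch construction: remove centroids, SVD of the
cross-covariance, determinant-sign correction to exclude reflections. The
test suite checks it against a brute-force numerical minimisation over
rotation vectors.

**Fragments.** A quantum calculation on a whole predicted protein would be
dominated by low-confidence regions and is computationally out of reach, so
the electronic analysis is restricted to the residues around the mutation:
the default window is ±1 residue (configurable half-width), clipped at
chain termini, keeping *all* atoms of every window residue. Peptide bonds
severed at the window edges are capped with a single hydrogen placed along
the unit vector from the cut backbone atom (N on the N-side, C on the
C-side) toward the removed neighbour, at 1.09 Å — the simplest deterministic
link-atom scheme; capping never moves existing atoms. Interior windows get
2 caps, terminal windows 1, whole-chain fragments 0.

**Charge and spin.** Net fragment charge is the sum of pH-7 formal
side-chain charges over window residues (Asp/Glu −1, Lys/Arg +1, His and
all others 0); termini are treated as capped and neutral, and no pKa
calculation is attempted. The computed integer charge is recorded as-is
rather than forced to zero. Multiplicity is fixed at 1; deck emission warns
when the implied electron count is odd (as it is for the backbone-only toy
fragments) instead of silently producing an invalid closed-shell job.

**Replicates.** Stochastic structure predictors are run several times per
mutant; the manifest holds five replicate slots by default and selects the
representative as the replicate with the highest mean pLDDT, ties broken by
file order — a deterministic criterion chosen because "pick the most
confident model" is the natural single-structure reduction.

## Engine decks and output dialect

All three job flavours are single-point B3LYP/6-31G* jobs (SCF convergence
10⁻⁷, 200 cycle cap, DIIS_GDM, symmetry ignored, no reorientation — the
small split-valence basis trades accuracy for cohort-scale throughput) and
differ in exactly one keyword: `CHELPG TRUE`, `NBO 1` or `PRINT_ORBITALS
TRUE`. The basis is written `6-31G*` with an ASCII hyphen. `$rem` values are
emitted uppercase, two-column, single-space separated, shared keys first in
fixed order and the flavour key last, so decks are byte-stable golden files.

The parsers accept a documented minimal dialect: a `Ground-State ChElPG Net
Atomic Charges` table of (index, element, charge); a `Summary of Natural
Population Analysis` table of (element, index, natural charge); an `Orbital
Energies (a.u.)` section with `-- Occupied --` / `-- Virtual --` sub-blocks.
Tables must be closed by their ruled line — a truncated block is an error,
not a short answer. Atom indices must be consecutive from 1. Energies stay
in hartree internally; eV displays use 27.2114 eV/hartree. HOMO, LUMO and
the gap are always recomputed from the energy lists, never read from
summary text.

## Descriptors

Fragments of different mutants can differ in atom count, and no atom-level
correspondence is defined across mutants; alignment is therefore index-wise
on the canonical atom ordering (residue order, then within-residue file
order). Charge matrices are NaN-padded to the widest fragment; Δq against
wild type is truncated to the common prefix with its length recorded
(`n_common`). ‖Δq‖₁ is the headline perturbation magnitude: it grows with
any charge redistribution, is zero exactly for the wild-type self-reference,
and obeys the triangle inequality (property-tested). PCA is a column-centred
SVD with column-mean imputation of missing cells — the simplest defensible
treatment — and a deterministic sign convention (each component's
largest-magnitude loading is positive). Figures are deliberately out of the
tested contract: the descriptor writers emit TSVs and any plotting is left
to the user.

## Synthetic data: what it does and does not emulate

The generators make the pipeline testable offline; they emulate *interfaces
and bookkeeping*, not physics or biology.

* **Reference protein** — a fixed 393-residue synthetic sequence (internal
  seed, never varied) with the p53 domain map. It preserves length and
  domain structure but not the real residue identities, so position-specific
  biochemistry (zinc-binding cysteines, hotspot arginines) is not
  represented.
* **Cohorts** — records drawn per the spec'd missense/nonsense weights
  (default 0.8/0.2, matching the roughly 4:1 ratio typical of tumour-
  suppressor cohorts), positions uniform unless hotspot multipliers are
  given, a small resampling rate (0.02) so some samples carry two records.
  Generated records are always consistent with the reference, so parser
  round-trips and partition laws are exact; real tables contain records the
  pipeline must classify as `other`, which the CSV reader handles but the
  generator does not produce.
* **Toy structures** — ideal extended backbones (N–Cα 1.46 Å, Cα–C 1.52 Å,
  peptide C–N 1.33 Å, carbonyl O 1.23 Å out of plane; optional Gaussian
  jitter), backbone-only because every contract downstream (windows, caps,
  charges, decks) keys on residue identity and backbone atoms. No secondary
  structure, no side chains, no realistic pLDDT autocorrelation — passing
  tests show the machinery is correct, not that predictions are good.
* **Mock engine outputs** — ground-truth charges constrained to sum exactly
  to the declared total, orbital stacks with deep levels below −1.5 hartree
  and gaps of 0.18–0.30 hartree, NPA fragment sums concentrated in
  0.4–0.5 with a tail toward 0.7. These mirror the descriptor-level
  statistics of a small missense feasibility cohort (28 mutants + wild type,
  the shipped demo size) but carry no quantum mechanics: per-atom charges
  are independent draws, so cross-atom correlation structure is absent and
  PCA on mock data shows no dominant component.
* **ESP oracle** — classical point charges only: V = Σ qᵢ/rᵢ evaluated on a
  golden-spiral shell grid kept ≥ 3 Å from every nucleus (ESP fits are
  unreliable closer in), followed by a least-squares re-fit. It validates
  the charges-from-potential concept and the conditioning checks
  (coincident sites and underdetermined grids are rejected), not any
  density-functional result.

## Numerical choices and problem sizes

Tolerances: Kabsch vs minimisation oracle 10⁻⁶; L1/Δ brute-force agreement
10⁻¹²; PCA reconstruction 10⁻⁸; ESP recovery 10⁻⁶ with normal-equation
residuals below 10⁻¹⁰; charge-sum conservation 10⁻⁴ (the precision of the
printed charge tables). Cap-geometry checks allow 10⁻³ Å, the resolution of
PDB coordinate columns. The default test and acceptance runs use cohorts of
60–256 records, 1,000 cohort seeds for the partition laws, 10-atom
superposition pairs and a 28-mutant descriptor cohort — sizes chosen so the
statistical assertions (binomial bounds, partition identities) are sharp
while the whole suite runs in seconds.

## Known limitations

* No structure prediction, MSA, PAE interpretation, energy minimisation or
  solvent model; no execution of any quantum-chemistry engine.
* Protonation is table-based at pH 7; His is always neutral.
* Hydrogen capping is the minimal link-atom rule; no ACE/NME caps.
* Index-wise charge alignment is a convention, not a physical atom mapping;
  descriptors comparing fragments of different composition inherit that
  caveat.
* Only single-residue events are modelled: no indels (other than
  stop-truncation), no splice or frameshift variants, no multi-nucleotide
  codon logic.
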