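# Methods

This note documents the models and procedures implemented in `zincredox`,
the parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions that make
results reproducible.

## Proteome ingestion and non-redundancy filtering

Input is a tab-separated UniProt-export dialect (configurable column-name
map; sequences optionally in a FASTA companion keyed by accession). The
non-redundancy filter applies five rules in a fixed order: (1) drop
entries flagged as fragments; (2) drop isoform accessions (UniProt
`-<n>` suffix), keeping canonical entries; (3) collapse exact
(case-normalised) duplicate sequences; (4) collapse records sharing a
non-empty (gene name, EC number) pair to one representative; (5) within a
gene, keep only reviewed entries when any exist, otherwise the single
longest sequence. Rule 4 is deliberately read as *de-duplication* —
keeping one representative rather than deleting the whole group — since
deleting every member would defeat the purpose of redundancy removal;
records with an empty gene name or EC number are never grouped, so absent
keys cannot merge unrelated proteins.

All collapses keep the lexicographically smallest accession among equals
(for rule 5's unreviewed branch: longest sequence first, then smallest
accession). Records are processed in accession order, which makes the
filter deterministic and independent of input ordering, and idempotent:
`filter(filter(P)) = filter(P)`. Every removed record is logged once with
the first rule that fired.

## Zinc-binding calls and coordination classes

Six evidence channels are scanned per protein: GO molecular-function
terms (substring "zinc", case-insensitive), cofactor text ("Zn"),
binding-site ligand labels ("Zn", contributing (position, residue)
pairs), zinc-finger regions (presence), keywords ("zinc"), and
structure-derived zinc-site tables joined through PDB cross-references.
The verdict is the union over channels — one positive source suffices —
because the annotation channels are complementary and incomplete in
different ways; per-source provenance is retained for audit, and the
positive set is therefore monotone in the set of sources consulted.
Substring matching is restricted to term names (not definitions) to limit
false positives.

A coordination site is classified from the multiset of its ligand
residues: {C,C,C,C} → C4, {C,C,C,H} → C3H1, {C,C,H,H} → C2H2, anything
else (1–8 ligands) → Other. When UniProt-derived sites and structure
tables disagree, both are kept and classified separately; no precedence
is imposed.

## Motif statistics and positional enrichment

The scanner reports every window with cysteines exactly three (CxxC) or
four (CxxxC) positions apart, overlaps included — compound arrangements
such as CxxxC-CxxC sharing a cysteine yield two hits. `x` matches any
residue including cysteine, so `CCCC` contains a single CxxC.

Positional enrichment around zinc-binding residues uses 13-mer windows
(±6 residues); windows truncated by a terminus are removed, duplicate
windows are collapsed, and each (offset, residue) cell is tested with a
one-sided binomial tail P(X ≥ k | n, f_bg) where f_bg is the residue's
frequency in the whole filtered proteome. Significance is raw p < 0.05
with **no multiple-testing correction** — a deliberate, documented caveat:
with 13 positions × 20 residues, a few nominally significant cells are
expected by chance, so results should be read as descriptive screening,
not confirmatory inference.

## Redoxome integration

Oxidation measurements are percentages of reversibly oxidized peptide per
cysteine site and condition, validated to [0, 100]. Normalisation is an
exact per-site subtraction of the internal control condition (LOG for
aging series, the untreated/wild-type sample for stress series), so
adding a constant to all of a site's conditions leaves Δ unchanged.
Stress responders are sites with Δ strictly above 7 percentage points.
The "percentage points" reading (rather than relative percent) matches
the scale on which the data are expressed.

Kinetic classification of aging profiles is a transparent rule set
replacing upstream hierarchical clustering whose exact algorithm is not
available: constitutively high when every value exceeds 70 %; otherwise
the first timepoint at which the rise over the LOG baseline reaches the
threshold decides early (day0/day3), middle (day6) or late (day9), with
everything else mixed. The rise threshold defaults to 15 percentage
points — large enough to clear measurement noise of a few points,
small enough to catch the early-oxidation trajectories whose day-0 rises
are ≈ 20 points — and is configurable; externally supplied cluster
labels can be carried as an override column. Profiles tolerate missing
timepoints down to three.

Paralog-ambiguous peptide labels (`RPS27A/B`) expand to both paralogs for
joins and category membership but count once in protein-level tallies.
Cross-dataset joins are inner joins on (accession, cysteine position)
with this expansion applied symmetrically. Group medians use the midpoint
convention for even counts.

## Depletion-abundance classification

Trajectories are log2 fold changes versus the shift to zinc-deficient
medium; thresholds of strictly greater than +0.5 (Up) and strictly less
than −0.5 (Down) are applied to the supplied scale without
transformation. The overlap table crosses the regulation class with
ribosomal membership, CxxC content, double-motif content (≥ 2 hits of
either pattern) and zinc-binding status.

## Structural geometry

A minimal fixed-column PDB reader handles ATOM/HETATM/MODEL/ENDMDL,
yielding one atom table plus one coordinate frame per model; malformed
coordinate fields raise errors carrying the line number. Pocket detection
collects Cys Sγ, His Nδ1/Nε2 and Asp/Glu carboxylate oxygens within 3 Å
of each zinc (nearest atom per residue), a tight cutoff typical of
inner-sphere Zn–ligand bonds. The separate 4 Å threshold classifies a
pocket or frame as Released once any ligand distance strictly exceeds it
(exactly 4.0 Å is still Bound); detection and release thresholds are kept
distinct because a partially disrupted site can hold some ligands near
2.3 Å while one sulfur has withdrawn beyond binding range. Oxidized
cysteine residue names (CSO, CSX, CSD, OCS, CYM) are treated as cysteine
variants via an alias list.

Superposition is the closed-form Kabsch solution (SVD with determinant
correction so reflections are excluded, as required for chiral
molecules); inputs must be ≥ 3 non-collinear paired points. Pocket RMSD
windows select Cα atoms within ±6 residues of each coordinating
cysteine, merged across overlaps and truncated at chain termini, in the
author numbering of the coordinate file; fitting is Cα-only.

SASA is Shrake–Rupley with probe radius 1.4 Å and a deterministic
Fibonacci (golden-angle) sphere lattice — seed-free, so values are
bit-stable at a fixed point count (default 960; an isolated atom returns
exactly 4π(r+w)²). Van der Waals radii default to C 1.70, N 1.55, O 1.52,
S 1.80, H 1.20, Zn 1.39, P 1.80 Å and are configurable, as published radii
sets differ at the few-percent level. Cluster exposure is the ratio of
the cluster atoms' SASA in full context (shielded) to the same sum with
all other atoms removed (isolated); it lies in (0, 1] up to sampling
tolerance.

## Synthetic data and what it does (not) show

Generators are pure functions of parameters and seed; reruns are
byte-identical. Class counts are allocated by largest-remainder rounding
rather than per-item coin flips, so planted fractions are recovered
exactly.

*Proteomes.* Default 12 % zinc-binding proteins — the annotated ZBP
fraction of the human proteome — each carrying one CxxC motif plus
consistent annotations (a zinc GO term and binding-site rows at the motif
cysteines); CxxC carriers total 20 % and CxxxC carriers 5 % by default,
reflecting the high motif prevalence of complex eukaryotic proteomes.
Background sequence excludes cysteine, and optional extra cysteines are
planted ≥ 5 residues from any other, so scanned motif counts equal
planted counts exactly. Lengths are uniform on 80–400 residues.

*Oxidation.* Five class templates over (LOG, day0, day3, day6, day9): the
middle/late templates follow the low-basal → ~40 % by day 6 → high day 9
trend of zinc-binding CxxC proteins; a separate ribosomal template rises
early and reaches ~79 % at day 9 (LOG basal set to 12 %, below the
diauxic-shift value, so it classifies as early-oxidized). Default
recovery-mix templates sit well clear of the rule boundaries; Gaussian
noise (clipped to [0, 100]) is added per point. With σ = 3 points the
classifier recovers ≥ 90 % of planted classes; noise-free recovery is
exact.

*Abundance.* Template trajectories over 0–16 h include a transient-up
shape (immediate rise by 4 h, steep decline to Down by 16 h) mimicking
the ribosomal response to zinc depletion, alongside monotone up, down and
flat shapes.

*Structures.* A zinc at the origin with four ligands at exactly the
planted distance (default 2.33 Å, inside the 2.3–2.6 Å band of bound
Zn–S pairs) along tetrahedral directions, a Cα per ligand residue, and a
random carbon shell at 7–11 Å. Coordinates are quantized to the PDB's
3-decimal precision *before* truth is derived, so parsed structures
reproduce the planted geometry bit-exactly. A drift schedule moves the
first ligand outward across frames to model oxidative zinc release.

What passing on synthetic data does **not** show: real proteomes have
correlated annotation errors, incomplete curation, isoform ambiguity
beyond accession suffixes and non-uniform residue composition; real
redox datasets have peptide-level artifacts (missed cleavages, shared
peptides) that the site-level generator ignores; toy structures have no
backbone connectivity, crystallographic disorder or solvent. The
generators validate the *pipeline logic*, not biological conclusions.

## Problem sizes and numerical conventions

Default verification sizes — 1 000 random sequences for the scanner
oracle, 1 000 synthetic proteins / oxidation sites, 50 superposition
instances, 960 sphere points — give exact or tightly-bounded checks
while keeping the full suite fast on a single CPU. Ties are always broken
lexicographically; medians use midpoints; boundary semantics are strict
(> 7 points, > 0.5 / < −0.5, > 4 Å) wherever the defining rule says
"above"/"below". Seeds are propagated explicitly; nothing in the package
draws from global random state.

## Known limitations

- The kinetic classifier encodes the *described semantics* of upstream
  oxidation clusters, not the original clustering algorithm; agreement
  with externally clustered labels is not guaranteed near rule
  boundaries.
- Enrichment p-values are uncorrected by design (see above).
- The PDB reader is a coordinate reader only: no mmCIF, no altLoc
  handling beyond taking records as given, no connectivity.
- Zinc-site detection relies on annotation or explicit Zn atoms; the
  package does not predict unannotated sites.
- Pocket detection assumes one ligand atom per residue (the nearest);
  bidentate carboxylate coordination is counted once.
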