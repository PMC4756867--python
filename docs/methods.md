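# Methods

## Data model

A cleavage record is one scissile-bond event: peptidase identifier,
substrate accession and name, the 1-based residue number of the P1 residue
in the substrate's full coding sequence (UniProt convention; the bond lies
between P1 and P1+1), the P4–P4′ window, a cleavage class (physiological,
pathological, non-physiological, synthetic, theoretical, unclassified),
and optional residue range, evidence, kinetics (Km, kcat, kcat/Km),
reference and sequence checksum.

Window slots hold one-letter amino-acid codes, `X`, or EMPTY. `X` stands
for any non-standard residue or a blocking/reporter group (the original
token, e.g. `Abz` or `EDDnp`, is preserved in `group_labels` for display);
EMPTY marks positions beyond a terminus or absent from a short synthetic
substrate, and may occur only as contiguous runs at the window's outer
edges. P1 is never EMPTY. All scoring treats `X` slots as `X` — a
deliberate information floor: nothing downstream may pretend to know what
a blocking group "really" is.

The collection TSV dialect is UTF-8, tab-separated, `.` for absent
optional fields, the window serialised as 8 tokens joined by `-` with
EMPTY rendered as the empty string. Peptidase name and activity class are
denormalised onto record rows so that `parse ∘ write` is the identity on
normalised collections, including the peptidase registry. Malformed data
lines are collected as issues, never silently dropped; unknown cleavage
classes are stored as `unclassified` with an issue.

## Reliability score

The score is the average percentage pairwise difference between windows
of the same peptidase. Pair rules where the definition is silent (chosen
so identical collections score exactly 0 and maximally distinct ones
exactly 100, and documented here as this package's convention):
`X` vs `X` and EMPTY vs EMPTY are no difference; `X` vs residue and EMPTY
vs residue are differences. The number of positions considered is the
count of pockets occupied in ≥ 1 record — computed from the data, not
looked up from the activity class, which is used only for display
masking. Bands: ≥ 75 green, ≥ 50 yellow, else red, evaluated on the raw
(unrounded) score. The score is permutation-invariant by construction and
verified against an independently coded exhaustive double loop.

## Preference calling

Percentages use total cleavages n as the denominator, not per-pocket
occupancy; occupancy is carried alongside so sparse exopeptidase pockets
remain interpretable. The preference threshold is 50%, the floor of the
lowest shade bin (50–59, 60–69, 70–79, 80–89, 90+); the shade band is
taken from the combined percentage of the listed residues (or the group
sum), capped at 100. Precedence: a single residue at ≥ 50% always beats a
group symbol; a group is called only when its sum reaches 50% *and*
exceeds the best single residue. Group ties break by a fixed symbol order
(λ, @, +, −, Σ, Ω); residue ties break by higher count then alphabetical
one-letter code. Negative preferences (up to two residues with zero count
in the pocket, rarest in the whole matrix first, then alphabetical) are
emitted only at n ≥ 200, because rare residues such as Cys and Trp are
absent from small collections by chance alone. Profiles from < 40
cleavages carry a low-confidence flag; logo/matrix display requires
≥ 10 cleavages.

Matrix display uses decile bins floor(pct/10) capped at 10 (so a 100%
cell gets its own bin rather than sharing 90–99), and rows are ordered by
physico-chemical grouping (ILV, FWY, DE, RHK, ACGS, NQMPT, X). Residues
with zero count in every pocket are flagged unobserved-anywhere. Logo
heights use plain Shannon information content R = log₂20 − H over the
observed standard residues (X excluded; zero-occupancy pockets get zero
heights) with no small-sample correction — collections this tool targets
are small enough that a correction would suggest spurious precision, and
the heights are exported as data for any renderer rather than baked into
an image (an optional matplotlib rendering exists behind a flag).

## Conservation analysis

Alignments are consumed pre-computed (aligned FASTA, one file per
substrate accession, emulating a UniRef50-cluster alignment); generating
them is upstream infrastructure. Gap-aware coordinate mapping places
reference residue k at the alignment column containing the k-th non-gap
character of the reference row; window slots beyond the termini are
absent and score 0.

The allowed set for a pocket pools the standard residues observed there
across all the peptidase's records *excluding the query cleavage itself*
(same accession and P1 position) — a substitution must be sanctioned by
at least one other substrate. Other cleavages of the same substrate still
contribute. All cleavage classes pool by default; a CLI flag restricts by
class. `X` never enters an allowed set.

Row calls: gap → gap; any character outside the 20 standard amino acids
(X, B, Z, U…) → undetermined; equal to the reference → identical; in the
allowed set → acceptable; else unacceptable. Only unacceptable calls are
counted, and gaps/undetermined never count — the conservative choice:
absence of information is not evidence against conservation. Homologue
count includes the reference row. Consequences worth knowing:
enlarging the collection can only shrink counts (monotonicity), and a
high count at a no-preference pocket can simply mean the homologues share
a substitution to a residue never yet offered to the peptidase — raw
counts are reported without any correction for this, and users should
inspect the rendered alignment in such cases.

Batch output columns follow the results-file field order (identifier,
total cleavages known, accession, homologues, cleavage position, eight
per-pocket counts) plus a local file locator for the annotated alignment
and a per-item status; items without an alignment are emitted with status
`no-alignment`, not dropped. Submission files are limited to 5000
cleavage lines and 10 MB, the published service limits.

## UniProt ingest

Flat-file parsing is delegated to Biopython's SwissProt reader.
Taxonomy division comes from the lineage's top rank (Bacteria/Archaea →
prokaryote, Eukaryota → eukaryote, Viruses → virus). Initiator-Met
removal maps to the configured methionyl-aminopeptidase id for
prokaryotes and to the M24 family for eukaryotes (either cytosolic MetAP
may act); signal-peptide removal to signal peptidase (prokaryote) or the
signal-peptidase complex (eukaryote); viral entries take the eukaryote
mapping since host machinery processes them. Transit-peptide and
propeptide/chain/peptide boundaries are emitted unmapped unless a mapping
is configured. All identifiers are configuration (`IngestConfig`), not
hard-coded.

A feature is treated as predicted — and skipped, since theoretical
cleavages are not collected — when its evidence or note contains any of a
configurable marker list (ECO:0000250/255/256/259, "by similarity",
"potential", "predicted"). Unknown (`?`) endpoints flag the feature and
are never coerced to numbers. Emitted records carry class physiological,
windows sliced from the entry sequence, and the entry checksum, so they
pass the drift QC against their own entry by construction. The QC check
fails exactly when a stored non-X slot disagrees with the current
sequence (the mismatching pockets are named) or the stored checksum
differs from the entry's (catching revisions outside the window).

## Synthetic-data generators

`simulate_collection` draws windows i.i.d. from per-pocket categorical
distributions: uniform over the 20 standard residues by default, with
planted masses and exclusions per pocket, and EMPTY forced at the pockets
an exopeptidase class masks. Each record gets a distinct synthetic
accession so self-exclusion logic behaves as it would on real data.
Default study conditions used by the tests and the acceptance sweeps:
n = 200 records and planted masses ≥ 60% for preference recovery
(comfortably above the 50% calling threshold under binomial noise at that
n), n = 190…210 sweeps for the negative-preference gate, n = 30…50 for
the confidence gate.

`simulate_orthologues` copies a reference (supplied or drawn uniformly,
default length 120), then, in non-reference rows only, applies uniform
substitutions, single-residue deletions and geometric-length insertions
at configured rates; the P4–P4′ window is held invariant by default, and
planted substitutions override every other process and land exactly where
stated. Insertions open gap columns in all other rows, exercising the
gap-aware column mapping; the reference row never carries indels, so its
coordinates are stable — a documented simplification. No empirical
substitution matrix is used: the generator exists to test counting logic
with known ground truth, not to mimic evolution. Consequently, passing
tests demonstrate correctness of the bookkeeping (mapping, exclusion,
counting, thresholds) on data of known structure; they say nothing about
how often real cleavage sites are conserved, about paralogue
contamination in real clusters, or about alignment quality — all
properties of the input data, not of this package.

All generators are pure functions of their spec (seed included) using a
single PCG64 stream; identical specs give byte-identical outputs.

## Numerical and degenerate-case choices

* Scores and percentages are exact rational arithmetic in floating point
  (counts divided once); the oracle-equivalence tests assert 1e-9.
* Reliability requires ≥ 2 records; matrices require ≥ 1 record; both
  raise informative errors below that.
* A cleavage at the penultimate residue has a full prime side; a P1 at
  the final residue is rejected everywhere (no P1′ residue exists).
* Duplicate records (same peptidase/substrate/position from different
  references) are kept as data and collapsed only in displays
  (processing maps collapse per position; batch rows are per submission
  line).
* Malformed identifiers are data issues, not exceptions, so a collection
  with a few bad rows is still analysable.

## Known limitations

* The negative-preference and confidence thresholds are fixed constants
  of the displayed analysis, not estimated quantities.
* Unacceptable-replacement counts are raw; no normalisation for rare
  residues, paralogues within a cluster, or fragmentary genome-derived
  rows is attempted (users are pointed at the rendered alignment).
* Family-level identifiers of the single-digit form (e.g. `S1`) are not
  accepted by the identifier pattern; the processing-event defaults only
  need three-character families (M24, S26).
* The simulator's uniform substitution model makes planted designs
  recoverable exactly, which is the point, but precludes using it to
  benchmark sensitivity on realistic divergence.
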