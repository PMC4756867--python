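# cleavekit

Analysis toolkit for peptidase substrate-cleavage collections: the kind of
dataset in which each row records that a given peptidase hydrolysed a given
substrate after a given residue, together with the eight residues P4–P4′
around the scissile bond (Schechter–Berger nomenclature: P4…P1 N-terminal
of the bond occupy enzyme pockets S4…S1, P1′…P4′ C-terminal occupy
S1′…S4′). It is written for degradomics and protease-biology groups who
curate or consume such collections and want to

* profile a peptidase's specificity (occurrence matrices, decile shading,
  sequence-logo weights, symbolic per-pocket preference calls);
* quantify how trustworthy that profile is (a pairwise-difference
  *reliability score* that is low when the substrate set is a
  near-homogeneous scanning series);
* assess whether a particular cleavage site is physiologically plausible,
  by counting *unacceptable replacements* across an orthologue alignment —
  substitutions at P4–P4′ never observed in that binding pocket in any
  other substrate of the same peptidase;
* ingest processing events (initiator-Met removal, signal/transit
  peptides, propeptide and mature-chain boundaries) from UniProt/SwissProt
  flat files, with sequence-drift quality control;
* generate seeded synthetic collections and alignments so every analysis
  is testable offline.

## The statistics at the core

**Specificity matrix and logo.** For a peptidase with *n* cleavages, the
count c(a, p) of amino acid *a* in pocket *p* is displayed as a percentage
of *n* and decile-shaded. Logo letter heights are WebLogo-style: relative
frequencies at the pocket scaled by the information content
R = log₂20 − H, with H the Shannon entropy of the pocket's distribution.

**Reliability score.** All n(n−1)/2 unordered pairs of P4–P4′ windows are
compared; non-standard residues are masked to X first. The score is

    100 × (total pairwise differences) / (n_pairs × n_positions)

where n_positions is the number of pockets occupied in at least one record
— *calculated, not assumed*: 8 for typical endopeptidase sets, 5 for
amino-/carboxypeptidases, 6 for dipeptidyl-/peptidyl-dipeptidases, 2 for
dipeptidases. Scores ≥ 75 band green (diverse substrates, preferences
trustworthy), 50–74 yellow, < 50 red.

**Preference calling.** Per unmasked pocket (pockets that cannot exist for
an activity class — P4–P2 for an aminopeptidase, P2′–P4′ for a
carboxypeptidase — are masked): a single residue reaching 50% of cleavages
is preferred (a second is listed only if it also reaches 50%); otherwise a
physico-chemical group whose summed share reaches 50% and beats the best
single residue is called by symbol (λ aliphatic ILV, @ aromatic FWY,
\+ acidic DE, − basic RHK, Σ small ACGS, Ω other NQMPT); otherwise, for
collections of ≥ 200 cleavages, up to two never-observed residues are
reported as negative preferences. Profiles from < 40 cleavages always
carry a low-confidence caution, and logo/matrix displays require ≥ 10.

**Conservation scoring.** For a submitted cleavage (peptidase, substrate
accession, P1 position), each homologue row of the substrate's alignment
is classified at the eight window columns: identical / acceptable (seen in
that pocket in another substrate of the peptidase) / unacceptable / 
undetermined (X or ambiguity code) / gap. Only *unacceptable* calls are
counted; all-zero counts mean the site is conserved in the sense the
peptidase cares about.

## Worked example

```python
from cleavekit import MeropsId, SubmissionItem, analyse_cleavage
from cleavekit.simulate import (
    OrthologueSpec, ProfileSpec, simulate_collection, simulate_orthologues,
)
from cleavekit.specificity import build_matrix, call_preferences, reliability_score

# 250 synthetic cleavages for one endopeptidase: Leu planted at 62% in P1',
# Trp/Cys never offered in P2, Trp never in P1', Cys never in P2'
coll = simulate_collection(ProfileSpec.uniform(
    250, seed=11, peptidase="M12.217",
    planted={"P1'": {"L": 0.62, "V": 0.15}},
    exclude={"P2": ["W", "C"], "P1'": ["W"], "P2'": ["C"]},
))

rel = reliability_score(coll, "M12.217")
print(f"score={rel.score:.2f} band={rel.band} positions={rel.n_positions_considered}")
print(call_preferences(build_matrix(coll, "M12.217"), "endopeptidase").to_tsv())

# an orthologue alignment whose rows 1-2 carry Trp at P1' and row 3 Cys at P2'
aln = simulate_orthologues(OrthologueSpec(
    n_rows=10, seed=5, p1_position=60, length=150,
    substitution_prob=0.08, indel_prob=0.03,
    planted=[(1, "P1'", "W"), (2, "P1'", "W"), (3, "P2'", "C")],
    reference_id="Q00001",
))
res = analyse_cleavage(coll, aln, SubmissionItem(MeropsId("M12.217"), "Q00001", 60))
print("unacceptable P4..P4':", res.unacceptable_counts)
```

prints

```
score=89.86 band=green positions=8
pocket	state	residues	shade_band
P4	none	.	.
P3	none	.	.
P2	negative	CW	.
P1	none	.	.
P1'	preferred	L	60-69
P2'	negative	C	.
P3'	none	.	.
P4'	none	.	.

unacceptable P4..P4': (0, 0, 0, 0, 2, 1, 0, 0)
```

The reliability score is high (random windows are diverse), the planted
P1′ preference for Leu is called with its 60–69% shade band, the
never-offered residues surface as negative preferences, and the three
planted disallowed substitutions — and nothing else — are counted at P1′
and P2′.

The same operations are available from the shell:

```sh
cleavekit reliability --collection collection.tsv --peptidase M12.217
cleavekit preferences --collection collection.tsv --peptidase M12.217
cleavekit analyse-substrates --submission sites.tsv \
    --collection collection.tsv --alignments alignments/ --out results.tsv
```

`analyse-substrates` writes one row per submitted site: peptidase, total
cleavages known, substrate accession, homologue count, cleavage position,
the eight per-pocket unacceptable counts, and a locator for the annotated
alignment rendering.

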