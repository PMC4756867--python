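"""Cleavage-site conservation scoring across orthologue alignments.

The idea: a cleavage site in a protein substrate is most likely to be
physiologically relevant when it is conserved in close homologues — not
merely as sequence identity, but in terms of which residues the
peptidase's binding pockets are known to accept. A substitution at a
P4-P4' position is *acceptable* if that amino acid has been observed in
the same pocket in at least one other substrate of the same peptidase,
and *unacceptable* otherwise. For each submitted cleavage this module
counts, per pocket, the aligned homologue rows carrying an unacceptable
replacement.

Alignments are consumed pre-computed (aligned FASTA, one cluster per
substrate accession, emulating a UniRef50 cluster alignment); building
them is upstream infrastructure.
"""

from __future__ import annotations

import enum
import io
import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, TextIO, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from cleavekit.cleavage_store import (
    AMINO_ACIDS,
    POCKETS,
    CleavageCollection,
    CleavageRecord,
    MeropsId,
)

__all__ = [
    "MAX_SUBMISSION_LINES",
    "MAX_SUBMISSION_BYTES",
    "GAP_CHARS",
    "SubmissionError",
    "SubmissionItem",
    "Submission",
    "OrthologueAlignment",
    "ResidueCall",
    "ConservationResult",
    "RESULT_COLUMNS",
    "parse_submission",
    "allowed_residues",
    "map_window_columns",
    "classify_substitution",
    "analyse_cleavage",
    "run_batch",
    "render_alignment",
]

#: Published service limits for one submission file.
MAX_SUBMISSION_LINES = 5000
MAX_SUBMISSION_BYTES = 10 * 2**20

GAP_CHARS = frozenset("-.")


class SubmissionError(ValueError):
    """Whole-file rejection (over the line or byte limit)."""


@dataclass(frozen=True)
class SubmissionItem:
    """One requested analysis: peptidase, substrate accession, P1 position."""

    peptidase: MeropsId
    substrate_accession: str
    p1_position: int


@dataclass
class Submission:
    items: list[SubmissionItem]
    issues: list[str] = field(default_factory=list)


def parse_submission(source: Union[str, os.PathLike, TextIO]) -> Submission:
    """Parse a three-column submission file (tab- or whitespace-separated).

    Each data line carries the peptidase identifier, the substrate's
    UniProt accession, and the 1-based position of the P1 residue in the
    full coding sequence. A single header line is tolerated. Files over
    5000 data lines or 10 MiB are rejected outright
    (:class:`SubmissionError`); malformed lines become per-line issues.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source.read()
    if len(text.encode("utf-8")) > MAX_SUBMISSION_BYTES:
        raise SubmissionError(
            f"submission exceeds the {MAX_SUBMISSION_BYTES // 2**20} MB file-size limit"
        )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if lines and _looks_like_header(lines[0]):
        lines = lines[1:]
    if len(lines) > MAX_SUBMISSION_LINES:
        raise SubmissionError(
            f"submission has {len(lines)} cleavages; the limit is {MAX_SUBMISSION_LINES}"
        )
    sub = Submission(items=[])
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 3:
            sub.issues.append(f"line {lineno}: expected 3 fields, got {len(fields)}")
            continue
        pep = MeropsId(fields[0].strip())
        if not pep.is_valid:
            sub.issues.append(f"line {lineno}: malformed peptidase identifier {fields[0]!r}")
            continue
        try:
            pos = int(fields[2])
        except ValueError:
            sub.issues.append(f"line {lineno}: bad cleavage position {fields[2]!r}")
            continue
        if pos < 1:
            sub.issues.append(f"line {lineno}: cleavage position must be >= 1")
            continue
        sub.items.append(SubmissionItem(pep, fields[1].strip(), pos))
    return sub


def _looks_like_header(line: str) -> bool:
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 3:
        return True
    try:
        int(fields[-1])
    except ValueError:
        return True
    return not MeropsId(fields[0].strip()).is_valid


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass
class OrthologueAlignment:
    """A gapped alignment of one substrate and its homologues.

    ``rows`` maps sequence id to gapped sequence (all the same length);
    the reference row is the substrate whose cleavage is scored, and
    ungapping it reproduces the raw substrate sequence.
    """

    reference_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if self.reference_id not in self.rows:
            raise ValueError(f"reference row {self.reference_id!r} missing from alignment")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")

    @property
    def column_count(self) -> int:
        return len(self.rows[self.reference_id])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ungapped_reference(self) -> str:
        return "".join(c for c in self.rows[self.reference_id] if c not in GAP_CHARS)

    @classmethod
    def from_fasta(
        cls, source: Union[str, os.PathLike, TextIO], reference_id: Optional[str] = None
    ) -> "OrthologueAlignment":
        """Load an aligned FASTA; the first record is the reference unless
        ``reference_id`` says otherwise."""
        rows: dict[str, str] = {}
        first = None
        for rec in SeqIO.parse(source, "fasta"):
            if first is None:
                first = rec.id
            rows[rec.id] = str(rec.seq).upper()
        if not rows:
            raise ValueError("no sequences in aligned FASTA")
        return cls(reference_id=reference_id or first, rows=rows)

    def to_fasta(self, target: Union[str, os.PathLike, TextIO]) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.rows.items()
        ]
        SeqIO.write(records, target, "fasta")


def map_window_columns(
    alignment: OrthologueAlignment, p1_position: int
) -> list[Optional[int]]:
    """Map the P4-P4' reference positions to 1-based alignment columns.

    Gap-aware: the k-th non-gap character of the reference row sits in the
    column holding reference residue k. Window slots beyond the reference
    termini are ``None`` (the pocket does not exist for this cleavage).
    """
    ref = alignment.rows[alignment.reference_id]
    cols = [i + 1 for i, c in enumerate(ref) if c not in GAP_CHARS]
    n = len(cols)
    if not 1 <= p1_position <= n:
        raise ValueError(
            f"p1_position {p1_position} outside ungapped reference (length {n})"
        )
    out: list[Optional[int]] = []
    for pos in range(p1_position - 3, p1_position + 5):
        out.append(cols[pos - 1] if 1 <= pos <= n else None)
    return out


class ResidueCall(str, enum.Enum):
    IDENTICAL = "identical"
    ACCEPTABLE = "acceptable"
    UNACCEPTABLE = "unacceptable"
    UNDETERMINED = "undetermined"
    GAP = "gap"


def classify_substitution(
    observed: str, reference: str, allowed: frozenset[str] | set[str]
) -> ResidueCall:
    """Classify one aligned residue against the reference and allowed set.

    Gap characters are ``gap``; residues outside the 20 standard amino
    acids (X and ambiguity codes) are ``undetermined`` — never counted as
    unacceptable, since their identity is simply unknown.
    """
    obs = observed.upper()
    if obs in GAP_CHARS:
        return ResidueCall.GAP
    if obs not in AMINO_ACIDS:
        return ResidueCall.UNDETERMINED
    if obs == reference.upper():
        return ResidueCall.IDENTICAL
    if obs in allowed:
        return ResidueCall.ACCEPTABLE
    return ResidueCall.UNACCEPTABLE


def allowed_residues(
    collection: CleavageCollection,
    peptidase: Union[MeropsId, str],
    pocket: Union[int, str],
    exclude: Optional[Union[CleavageRecord, tuple[str, int]]] = None,
) -> frozenset[str]:
    """Amino acids known to occupy one pocket in the peptidase's substrates.

    Pools the standard residues observed (non-X, non-EMPTY) at the pocket
    across all the peptidase's cleavage records, excluding the query
    cleavage itself (same substrate accession and P1 position) so that a
    substitution is only sanctioned by *other* substrates. X never enters
    the set.
    """
    idx = pocket if isinstance(pocket, int) else POCKETS.index(pocket)
    if exclude is not None and isinstance(exclude, CleavageRecord):
        exclude = (exclude.substrate_accession, exclude.p1_position)
    records = collection.records_for(peptidase)
    if not records:
        code = peptidase.code if isinstance(peptidase, MeropsId) else peptidase
        warnings.warn(f"no cleavage records for peptidase {code}; allowed set is empty")
        return frozenset()
    out = set()
    for r in records:
        if exclude is not None and (r.substrate_accession, r.p1_position) == exclude:
            continue
        slot = r.window.slots[idx]
        if slot in AMINO_ACIDS:
            out.add(slot)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


@dataclass
class ConservationResult:
    """One results row: how poorly conserved is this cleavage site?"""

    peptidase: MeropsId
    total_cleavages_known: int
    substrate_accession: str
    n_homologues: int
    p1_position: int
    unacceptable_counts: tuple[int, ...]  # P4 .. P4'
    alignment_locator: str
    calls: dict[str, tuple[Optional[ResidueCall], ...]] = field(default_factory=dict)


def analyse_cleavage(
    collection: CleavageCollection,
    alignment: OrthologueAlignment,
    item: SubmissionItem,
) -> ConservationResult:
    """Count unacceptable replacements at P4-P4' across the alignment.

    Per pocket, the count is the number of *non-reference* rows whose
    residue at the mapped column is classified unacceptable; identical,
    acceptable, undetermined and gap calls never count. ``n_homologues``
    is the total number of rows in the alignment, reference included.
    Pockets that fall beyond the reference termini score 0.
    """
    if item.substrate_accession != alignment.reference_id:
        raise ValueError(
            f"alignment reference {alignment.reference_id!r} does not match "
            f"submission accession {item.substrate_accession!r}"
        )
    records = collection.records_for(item.peptidase)
    total_known = len(records)
    if total_known == 0:
        warnings.warn(f"peptidase {item.peptidase} unknown to the collection")

    columns = map_window_columns(alignment, item.p1_position)
    ref_row = alignment.rows[alignment.reference_id]
    allowed_sets: list[frozenset[str]] = []
    for i in range(8):
        if total_known == 0:
            allowed_sets.append(frozenset())
        else:
            allowed_sets.append(
                allowed_residues(
                    collection,
                    item.peptidase,
                    i,
                    exclude=(item.substrate_accession, item.p1_position),
                )
            )

    counts = [0] * 8
    calls: dict[str, tuple[Optional[ResidueCall], ...]] = {}
    for row_id, row_seq in alignment.rows.items():
        row_calls: list[Optional[ResidueCall]] = []
        for i, col in enumerate(columns):
            if col is None:
                row_calls.append(None)
                continue
            reference = ref_row[col - 1]
            call = classify_substitution(row_seq[col - 1], reference, allowed_sets[i])
            row_calls.append(call)
            if row_id != alignment.reference_id and call is ResidueCall.UNACCEPTABLE:
                counts[i] += 1
        calls[row_id] = tuple(row_calls)

    locator = f"{item.substrate_accession}_{item.p1_position}_{item.peptidase.code}.aln.txt"
    return ConservationResult(
        peptidase=item.peptidase,
        total_cleavages_known=total_known,
        substrate_accession=item.substrate_accession,
        n_homologues=alignment.n_rows,
        p1_position=item.p1_position,
        unacceptable_counts=tuple(counts),
        alignment_locator=locator,
        calls=calls,
    )


#: Results-table columns, in the published field order; the final column
#: is a local file locator for the rendered alignment.
RESULT_COLUMNS = [
    "MEROPS identifier",
    "Total cleavages known",
    "Substrate UniProt accession",
    "Homologues",
    "Cleaved at",
    "P4 count",
    "P3 count",
    "P2 count",
    "P1 count",
    "P1' count",
    "P2' count",
    "P3' count",
    "P4' count",
    "Alignment",
    "Status",
]


def run_batch(
    submission: Sequence[SubmissionItem],
    collection: CleavageCollection,
    alignment_source: Mapping[str, OrthologueAlignment],
) -> pd.DataFrame:
    """Score every submission item; one output row per item, in file order.

    Items whose accession has no alignment are emitted with status
    ``no-alignment`` rather than dropped. The result is deterministic:
    the same inputs always produce a byte-identical TSV via
    :func:`batch_to_tsv`.
    """
    rows = []
    for item in submission:
        aln = alignment_source.get(item.substrate_accession)
        if aln is None:
            rows.append(
                [item.peptidase.code, len(collection.records_for(item.peptidase)),
                 item.substrate_accession, "", item.p1_position,
                 *[""] * 8, "", "no-alignment"]
            )
            continue
        try:
            res = analyse_cleavage(collection, aln, item)
        except ValueError as exc:
            rows.append(
                [item.peptidase.code, len(collection.records_for(item.peptidase)),
                 item.substrate_accession, aln.n_rows, item.p1_position,
                 *[""] * 8, "", f"error: {exc}"]
            )
            continue
        rows.append(
            [res.peptidase.code, res.total_cleavages_known, res.substrate_accession,
             res.n_homologues, res.p1_position, *res.unacceptable_counts,
             res.alignment_locator, "ok"]
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def batch_to_tsv(table: pd.DataFrame) -> str:
    buf = io.StringIO()
    table.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Display
# ---------------------------------------------------------------------------

_MARKUP = {
    ResidueCall.IDENTICAL: "={}=",
    ResidueCall.ACCEPTABLE: "+{}+",
    ResidueCall.UNACCEPTABLE: "!{}!",
    ResidueCall.UNDETERMINED: "?{}?",
    ResidueCall.GAP: " {} ",
}


def render_alignment(
    alignment: OrthologueAlignment,
    item: SubmissionItem,
    collection: CleavageCollection,
) -> str:
    """Annotated text block for one analysed cleavage.

    Each row shows its P4-P4' residues with call markup: ``=X=``
    identical to the reference, ``+X+`` acceptable (seen in that pocket
    in another substrate), ``!X!`` unacceptable, ``?X?`` undetermined;
    gaps are bare. The reference row is marked with ``>``.
    """
    res = analyse_cleavage(collection, alignment, item)
    width = max(len(r) for r in alignment.rows) + 2
    lines = [
        f"# {item.substrate_accession} cleaved after residue {item.p1_position} "
        f"by {item.peptidase.code}",
        f"# homologues: {res.n_homologues}; unacceptable per pocket "
        f"{dict(zip(POCKETS, res.unacceptable_counts))}",
        "#" + " " * (width + 1) + "  ".join(f"{p:^3}" for p in POCKETS),
    ]
    columns = map_window_columns(alignment, item.p1_position)
    for row_id, row_seq in alignment.rows.items():
        marks = []
        for col, call in zip(columns, res.calls[row_id]):
            if col is None:
                marks.append(" . ")
            else:
                marks.append(_MARKUP[call].format(row_seq[col - 1]))
        prefix = ">" if row_id == alignment.reference_id else " "
        lines.append(f"{prefix} {row_id:<{width}}" + "  ".join(marks))
    return "\n".join(lines) + "\n"
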