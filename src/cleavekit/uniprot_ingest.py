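"""Derive processing-event cleavage records from SwissProt annotations.

Reviewed UniProt entries annotate post-translational processing —
removal of the initiating methionine, signal and transit peptides,
propeptides, and mature chains/peptides excised from precursors. Each
such boundary implies a scissile bond, and where the responsible enzyme
class is known from the feature kind it can be mapped to a peptidase
identifier:

* initiator-Met removal -> methionyl aminopeptidase for a prokaryote, or
  the M24 family for a eukaryote (either cytosolic MetAP may act);
* signal-peptide removal -> signal peptidase (prokaryote) or the signal
  peptidase complex (eukaryote); viral precursors are processed by host
  machinery and take the eukaryote mapping;
* transit peptides and chain/peptide/propeptide boundaries -> left
  unmapped unless a mapping is configured, since the responsible
  peptidase is generally unknown.

Features whose evidence marks them as predicted rather than observed
(ECO inference codes, "by similarity", "potential") are skipped:
theoretical cleavages are not collected. The concrete peptidase
identifiers are configuration, not hard-coded.

Flat-file parsing is delegated to :mod:`Bio.SwissProt`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, TextIO, Union

from Bio import SwissProt
from Bio.SeqFeature import UnknownPosition

from cleavekit.cleavage_store import (
    CleavageRecord,
    MeropsId,
    extract_window,
)

__all__ = [
    "PROCESSING_FEATURE_KINDS",
    "DEFAULT_PREDICTED_MARKERS",
    "IngestConfig",
    "ProcessingFeature",
    "UniProtEntry",
    "QcReport",
    "parse_flatfile",
    "derive_processing_cleavages",
    "qc_window_check",
]

PROCESSING_FEATURE_KINDS = ("INIT_MET", "SIGNAL", "TRANSIT", "PROPEP", "CHAIN", "PEPTIDE")

#: Evidence/description substrings (case-insensitive) that mark a feature
#: as predicted rather than experimentally observed. ECO:0000250 is
#: "by similarity", ECO:0000255/256/259 are sequence-analysis inferences.
DEFAULT_PREDICTED_MARKERS = (
    "eco:0000250",
    "eco:0000255",
    "eco:0000256",
    "eco:0000259",
    "by similarity",
    "potential",
    "predicted",
)


@dataclass(frozen=True)
class IngestConfig:
    """Peptidase-identifier mappings for automatically derived cleavages."""

    met_aminopeptidase_prokaryote: str = "M24.001"
    met_aminopeptidase_eukaryote: str = "M24"  # family: either MetAP may act
    signal_peptidase_prokaryote: str = "S26.001"
    signal_peptidase_complex: str = "S26"
    transit_peptidase: Optional[str] = None  # usually unknown -> unmapped
    predicted_markers: tuple[str, ...] = DEFAULT_PREDICTED_MARKERS


@dataclass(frozen=True)
class ProcessingFeature:
    kind: str
    start: Optional[int]  # 1-based inclusive; None when unknown ('?')
    end: Optional[int]
    description: str = ""
    evidence_is_predicted: bool = False

    @property
    def has_unknown_endpoint(self) -> bool:
        return self.start is None or self.end is None


@dataclass
class UniProtEntry:
    accession: str
    sequence: str
    taxonomy_division: str  # prokaryote | eukaryote | virus | unknown
    features: list[ProcessingFeature] = field(default_factory=list)
    checksum: Optional[str] = None


def _division(lineage: list[str]) -> str:
    if not lineage:
        return "unknown"
    top = lineage[0].strip().rstrip(".")
    if top in ("Bacteria", "Archaea"):
        return "prokaryote"
    if top == "Eukaryota":
        return "eukaryote"
    if top == "Viruses":
        return "virus"
    return "unknown"


def parse_flatfile(source: Union[str, os.PathLike, TextIO]) -> UniProtEntry:
    """Parse one UniProt flat-file (DAT) entry.

    Positions are converted to 1-based inclusive coordinates; ``?``
    endpoints become ``None`` and flag the feature, never coerced to
    numbers. Only processing-relevant feature kinds are kept.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            record = SwissProt.read(fh)
    else:
        record = SwissProt.read(source)

    marker_check = tuple(m.lower() for m in DEFAULT_PREDICTED_MARKERS)
    features: list[ProcessingFeature] = []
    for feat in record.features:
        if feat.type not in PROCESSING_FEATURE_KINDS:
            continue
        start = (
            None
            if isinstance(feat.location.start, UnknownPosition)
            else int(feat.location.start) + 1
        )
        end = (
            None
            if isinstance(feat.location.end, UnknownPosition)
            else int(feat.location.end)
        )
        note = str(feat.qualifiers.get("note", ""))
        evidence = str(feat.qualifiers.get("evidence", ""))
        blob = f"{note} {evidence}".lower()
        features.append(
            ProcessingFeature(
                kind=feat.type,
                start=start,
                end=end,
                description=note,
                evidence_is_predicted=any(m in blob for m in marker_check),
            )
        )
    return UniProtEntry(
        accession=record.accessions[0] if record.accessions else "",
        sequence=record.sequence,
        taxonomy_division=_division(record.organism_classification),
        features=features,
        checksum=record.seqinfo[2] if record.seqinfo else None,
    )


def derive_processing_cleavages(
    entry: UniProtEntry, config: IngestConfig = IngestConfig()
) -> tuple[list[CleavageRecord], list[str]]:
    """Turn processing features into cleavage records.

    Returns ``(records, skipped)`` where ``skipped`` explains every
    feature that produced nothing (predicted evidence, unknown endpoint,
    boundary with no P1' residue, duplicate bond). All emitted records
    are physiological, carry windows sliced from the entry sequence, and
    pass :func:`qc_window_check` against the entry by construction.
    """
    records: list[CleavageRecord] = []
    skipped: list[str] = []
    seen: set[tuple[Optional[str], int]] = set()
    seq = entry.sequence
    n = len(seq)
    prokaryote = entry.taxonomy_division == "prokaryote"

    def emit(p1: int, peptidase_code: Optional[str], why: str) -> None:
        key = (peptidase_code, p1)
        if key in seen:
            skipped.append(f"{why}: duplicate bond after residue {p1}")
            return
        if p1 < 1:
            skipped.append(f"{why}: bond after residue {p1} has no P1 residue")
            return
        if p1 >= n:
            skipped.append(f"{why}: bond after residue {p1} has no P1' residue")
            return
        seen.add(key)
        records.append(
            CleavageRecord(
                peptidase=MeropsId(peptidase_code) if peptidase_code else None,
                substrate_accession=entry.accession,
                substrate_name=entry.accession,
                p1_position=p1,
                window=extract_window(seq, p1),
                cleavage_class="physiological",
                evidence=why,
                checksum=entry.checksum,
            )
        )

    for feat in entry.features:
        tag = f"{feat.kind} {feat.start}..{feat.end}"
        if feat.evidence_is_predicted:
            skipped.append(f"{tag}: predicted evidence, not collected")
            continue
        if feat.has_unknown_endpoint:
            skipped.append(f"{tag}: unknown endpoint")
            continue
        if feat.kind == "INIT_MET":
            code = (
                config.met_aminopeptidase_prokaryote
                if prokaryote
                else config.met_aminopeptidase_eukaryote
            )
            emit(1, code, "initiator methionine removal")
        elif feat.kind == "SIGNAL":
            code = (
                config.signal_peptidase_prokaryote
                if prokaryote
                else config.signal_peptidase_complex
            )
            emit(feat.end, code, "signal peptide removal")
        elif feat.kind == "TRANSIT":
            emit(feat.end, config.transit_peptidase, "transit peptide removal")
        else:  # PROPEP / CHAIN / PEPTIDE: both boundaries imply bonds
            emit(feat.start - 1, None, f"{feat.kind.lower()} N-terminal boundary")
            emit(feat.end, None, f"{feat.kind.lower()} C-terminal boundary")
    return records, skipped


@dataclass(frozen=True)
class QcReport:
    passed: bool
    mismatched_pockets: tuple[str, ...] = ()
    checksum_drift: bool = False

    def __str__(self) -> str:
        if self.passed:
            return "pass"
        parts = []
        if self.mismatched_pockets:
            parts.append("window mismatch at " + ",".join(self.mismatched_pockets))
        if self.checksum_drift:
            parts.append("sequence checksum drift")
        return "fail: " + "; ".join(parts)


def qc_window_check(record: CleavageRecord, entry: UniProtEntry) -> QcReport:
    """Check a stored record against the current entry sequence.

    Fails when any stored non-X, non-EMPTY window slot disagrees with the
    residue now at that position, or when the stored sequence checksum
    differs from the entry's (detecting upstream sequence revisions even
    outside the window).
    """
    if record.substrate_accession != entry.accession:
        raise ValueError(
            f"record is for {record.substrate_accession}, entry is {entry.accession}"
        )
    from cleavekit.cleavage_store import validate_record

    issues = validate_record(record, sequence=entry.sequence)
    pockets = tuple(
        msg.split("window mismatch at ", 1)[1].split(":", 1)[0]
        for msg in issues
        if msg.startswith("window mismatch at ")
    )
    drift = (
        record.checksum is not None
        and entry.checksum is not None
        and record.checksum != entry.checksum
    )
    return QcReport(passed=not pockets and not drift, mismatched_pockets=pockets,
                    checksum_drift=drift)
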