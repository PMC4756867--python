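"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import pytest

from cleavekit.cleavage_store import (
    EMPTY,
    CleavageCollection,
    CleavageRecord,
    CleavageWindow,
    MeropsId,
    PeptidaseEntry,
)


def make_record(
    window: str,
    peptidase: str = "M10.003",
    accession: str = "P00001",
    p1: int = 10,
    cleavage_class: str = "physiological",
    **kwargs,
) -> CleavageRecord:
    """Build a record from a compact window string ("CDEFGHIK"; '.' = EMPTY)."""
    tokens = [EMPTY if c == "." else c for c in window]
    return CleavageRecord(
        peptidase=MeropsId(peptidase),
        substrate_accession=accession,
        substrate_name=accession,
        p1_position=p1,
        window=CleavageWindow.from_tokens(tokens),
        cleavage_class=cleavage_class,
        **kwargs,
    )


def make_collection(records, activity_class: str = "endopeptidase") -> CleavageCollection:
    coll = CleavageCollection(records=list(records))
    for r in coll.records:
        if r.peptidase and r.peptidase.code not in coll.peptidases:
            coll.peptidases[r.peptidase.code] = PeptidaseEntry(
                id=r.peptidase, name=r.peptidase.code, activity_class=activity_class
            )
    return coll


def brute_force_reliability(windows: list[tuple[str, ...]]) -> tuple[float, int]:
    """Independent double-loop oracle for the pairwise-difference score.

    Returns (score percent, positions considered). Deliberately naive:
    explicit loops, no sharing with the implementation.
    """
    considered = [i for i in range(8) if any(w[i] != EMPTY for w in windows)]
    n = len(windows)
    pairs = 0
    diffs = 0
    for a in range(n):
        for b in range(n):
            if b <= a:
                continue
            pairs += 1
            for i in considered:
                if windows[a][i] != windows[b][i]:
                    diffs += 1
    return 100.0 * diffs / (pairs * len(considered)), len(considered)


def scan_column_oracle(gapped_row: str, residue_number: int) -> int:
    """Linear-scan oracle: 1-based column of the k-th non-gap character."""
    seen = 0
    for col, ch in enumerate(gapped_row, start=1):
        if ch not in "-.":
            seen += 1
            if seen == residue_number:
                return col
    raise IndexError(residue_number)


@pytest.fixture
def trio_collection() -> CleavageCollection:
    """Three hand-written endopeptidase cleavages of two substrates."""
    return make_collection(
        [
            make_record("CDEFGHIK", accession="P00001", p1=10),
            make_record("ADEFGHIK", accession="P00002", p1=25),
            make_record("CDEFSAIK", accession="P00002", p1=80),
        ]
    )
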