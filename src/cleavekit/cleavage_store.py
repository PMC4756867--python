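"""Data model and I/O for substrate-cleavage collections.

A *cleavage record* describes one scissile-bond event: which peptidase
hydrolysed which substrate, the residue number of the P1 residue in the
substrate's full (UniProt) coding sequence, and the eight residues
occupying the binding pockets P4-P4' around the bond (Schechter-Berger
nomenclature: P4..P1 N-terminal of the bond, P1'..P4' C-terminal).

Window slots hold a one-letter amino-acid code, ``X`` for a non-standard
residue or a blocking/reporter group (the original token is preserved in
``group_labels``), or :data:`EMPTY` for a position beyond a terminus or
absent from a short synthetic substrate.

Coordinates are 1-based and intervals inclusive, matching UniProt feature
conventions; the scissile bond lies between ``p1_position`` and
``p1_position + 1``.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union

__all__ = [
    "EMPTY",
    "AMINO_ACIDS",
    "POCKETS",
    "CLEAVAGE_CLASSES",
    "ACTIVITY_CLASSES",
    "MASKED_POCKETS",
    "CollectionFormatError",
    "MeropsId",
    "CleavageWindow",
    "Kinetics",
    "CleavageRecord",
    "PeptidaseEntry",
    "CleavageCollection",
    "ProcessingMap",
    "parse_collection",
    "write_collection",
    "extract_window",
    "validate_record",
    "substrate_map",
]

#: Slot value for a pocket beyond a terminus / absent from a short substrate.
EMPTY = ""

#: The 20 standard amino acids, one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Pocket labels in window order (index 3 is P1; the bond follows it).
POCKETS = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")

#: Closed vocabulary for how a cleavage is classified.
CLEAVAGE_CLASSES = frozenset(
    {
        "physiological",
        "pathological",
        "non-physiological",
        "synthetic",
        "theoretical",
        "unclassified",
    }
)

ACTIVITY_CLASSES = (
    "endopeptidase",
    "aminopeptidase",
    "carboxypeptidase",
    "dipeptidyl-peptidase",
    "peptidyl-dipeptidase",
    "dipeptidase",
)

#: Pockets that cannot exist structurally for each activity class
#: (window indices). An aminopeptidase cuts after residue 1, so P4-P2
#: are always beyond the N-terminus; a carboxypeptidase releases the
#: C-terminal residue, so P2'-P4' never exist; and so on.
MASKED_POCKETS: dict[str, frozenset[int]] = {
    "endopeptidase": frozenset(),
    "aminopeptidase": frozenset({0, 1, 2}),
    "carboxypeptidase": frozenset({5, 6, 7}),
    "dipeptidyl-peptidase": frozenset({0, 1}),
    "peptidyl-dipeptidase": frozenset({6, 7}),
    "dipeptidase": frozenset({0, 1, 2, 5, 6, 7}),
}

_PEPTIDASE_RE = re.compile(r"^[A-Z][A-Za-z0-9]{2}\.[A-Za-z0-9]{3}$")
_FAMILY_RE = re.compile(r"^[A-Z][A-Za-z0-9]{2,3}$")

_ABSENT = "."  # TSV token for an absent optional field


class CollectionFormatError(ValueError):
    """Raised when a collection stream cannot be interpreted at all."""


@dataclass(frozen=True)
class MeropsId:
    """Hierarchical peptidase identifier, e.g. ``M12.217``.

    Peptidase-level codes are catalytic-type letter + family digits, a
    dot, and a three-character peptidase code (``A01.004``, ``U9G.075``).
    Family-level codes lack the dotted suffix (``M24``). Construction is
    lenient; use :attr:`is_valid` / :func:`validate_record` to report
    malformed codes as data issues rather than exceptions.
    """

    code: str

    @property
    def is_valid(self) -> bool:
        return bool(_PEPTIDASE_RE.match(self.code) or _FAMILY_RE.match(self.code))

    @property
    def is_family(self) -> bool:
        return bool(_FAMILY_RE.match(self.code))

    @property
    def family(self) -> str:
        """Family-level prefix (``M12`` for ``M12.217``)."""
        return self.code.split(".", 1)[0]

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.code


def _normalise_slot(token: str) -> tuple[str, Optional[str]]:
    """Map a raw slot token to (canonical slot, preserved label)."""
    if token == EMPTY:
        return EMPTY, None
    upper = token.upper()
    if len(upper) == 1 and (upper in AMINO_ACIDS or upper == "X"):
        label = token if token != upper else None
        return upper, label
    # multi-character or unknown symbol: blocking/reporter group or
    # non-standard residue -> X, original token kept for display
    return "X", token


@dataclass(frozen=True)
class CleavageWindow:
    """The P4-P4' residues around one scissile bond.

    ``slots`` is an 8-tuple over {one-letter amino acid, ``"X"``,
    :data:`EMPTY`}; ``group_labels`` preserves original tokens for slots
    normalised to ``X`` (blocking/reporter groups, unusual residues).
    """

    slots: tuple[str, ...]
    group_labels: tuple[Optional[str], ...] = (None,) * 8

    def __post_init__(self) -> None:
        if len(self.slots) != 8:
            raise ValueError(f"window needs 8 slots, got {len(self.slots)}")
        if len(self.group_labels) != 8:
            raise ValueError("group_labels needs 8 entries")
        for s in self.slots:
            if s != EMPTY and not (len(s) == 1 and (s in AMINO_ACIDS or s == "X")):
                raise ValueError(f"bad window slot {s!r}")
        if self.slots[3] == EMPTY:
            raise ValueError("P1 slot may not be empty")
        # EMPTY only as contiguous runs at the outer edges
        for i in range(3):
            if self.slots[i] != EMPTY and any(s == EMPTY for s in self.slots[i + 1 : 3]):
                raise ValueError("EMPTY slots must be contiguous from the P4 edge")
        for i in range(4, 8):
            if self.slots[i] == EMPTY and any(s != EMPTY for s in self.slots[i + 1 :]):
                raise ValueError("EMPTY slots must be contiguous to the P4' edge")

    @classmethod
    def from_tokens(cls, tokens: Iterable[str]) -> "CleavageWindow":
        """Build a window from raw tokens, normalising unknown symbols to X."""
        tokens = list(tokens)
        if len(tokens) != 8:
            raise ValueError(f"window needs 8 tokens, got {len(tokens)}")
        slots, labels = zip(*(_normalise_slot(t) for t in tokens))
        return cls(tuple(slots), tuple(labels))

    @classmethod
    def from_string(cls, text: str) -> "CleavageWindow":
        """Parse the serialised form: 8 tokens joined by ``-``, EMPTY as ''."""
        return cls.from_tokens(text.split("-"))

    def to_string(self) -> str:
        return "-".join(self.slots)

    def masked(self) -> tuple[str, ...]:
        """Slots with every non-standard residue already collapsed to X."""
        return self.slots


@dataclass(frozen=True)
class Kinetics:
    km: Optional[float] = None
    kcat: Optional[float] = None
    kcat_over_km: Optional[float] = None


@dataclass
class CleavageRecord:
    """One annotated scissile-bond event."""

    peptidase: Optional[MeropsId]
    substrate_accession: str
    substrate_name: str
    p1_position: int
    window: CleavageWindow
    cleavage_class: str = "unclassified"
    residue_range: Optional[tuple[int, int]] = None
    evidence: Optional[str] = None
    kinetics: Optional[Kinetics] = None
    reference_id: Optional[str] = None
    checksum: Optional[str] = None

    def __post_init__(self) -> None:
        if self.p1_position < 1:
            raise ValueError("p1_position must be >= 1")
        if self.cleavage_class not in CLEAVAGE_CLASSES:
            raise ValueError(f"unknown cleavage class {self.cleavage_class!r}")
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not (lo <= self.p1_position < hi):
                raise ValueError(
                    "p1_position must lie inside residue_range with a P1' residue"
                )


@dataclass(frozen=True)
class PeptidaseEntry:
    id: MeropsId
    name: str
    activity_class: str = "endopeptidase"

    def __post_init__(self) -> None:
        if self.activity_class not in ACTIVITY_CLASSES:
            raise ValueError(f"unknown activity class {self.activity_class!r}")

    @property
    def masked_pockets(self) -> frozenset[int]:
        return MASKED_POCKETS[self.activity_class]


@dataclass
class CleavageCollection:
    """A set of cleavage records plus the peptidase registry and sequences."""

    records: list[CleavageRecord] = field(default_factory=list)
    peptidases: dict[str, PeptidaseEntry] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)
    issues: list[str] = field(default_factory=list)

    def records_for(self, peptidase: Union[MeropsId, str]) -> list[CleavageRecord]:
        code = peptidase.code if isinstance(peptidase, MeropsId) else peptidase
        return [
            r for r in self.records if r.peptidase is not None and r.peptidase.code == code
        ]

    def unregistered_peptidases(self) -> set[str]:
        """Peptidase codes referenced by records but absent from the registry."""
        return {
            r.peptidase.code
            for r in self.records
            if r.peptidase is not None and r.peptidase.code not in self.peptidases
        }

    def activity_class_of(self, peptidase: Union[MeropsId, str]) -> str:
        code = peptidase.code if isinstance(peptidase, MeropsId) else peptidase
        entry = self.peptidases.get(code)
        return entry.activity_class if entry is not None else "endopeptidase"


# ---------------------------------------------------------------------------
# TSV serialisation
# ---------------------------------------------------------------------------

_COLUMNS = [
    "peptidase",
    "peptidase_name",
    "activity_class",
    "substrate_accession",
    "substrate_name",
    "p1_position",
    "residue_range",
    "window",
    "cleavage_class",
    "evidence",
    "km",
    "kcat",
    "kcat_over_km",
    "reference_id",
    "checksum",
]

_REQUIRED = {"peptidase", "substrate_accession", "p1_position", "window", "cleavage_class"}


def _opt(token: str) -> Optional[str]:
    return None if token == _ABSENT or token == "" else token


def _fmt(value) -> str:
    if value is None:
        return _ABSENT
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _as_stream(source: Union[str, os.PathLike, TextIO]) -> TextIO:
    if isinstance(source, (str, os.PathLike)):
        return open(source, "r", encoding="utf-8")
    return source


def parse_collection(source: Union[str, os.PathLike, TextIO]) -> CleavageCollection:
    """Read a cleavage-collection TSV.

    The dialect is UTF-8, tab-separated, ``.`` for absent optional fields,
    the window serialised as 8 tokens joined by ``-`` with EMPTY rendered
    as the empty string. Malformed data lines are collected in
    ``collection.issues`` (with their line number) rather than silently
    dropped; a missing required column or an empty stream raises
    :class:`CollectionFormatError`.
    """
    stream = _as_stream(source)
    header_line = stream.readline()
    if not header_line:
        raise CollectionFormatError("empty collection stream")
    header = header_line.rstrip("\n").split("\t")
    missing = _REQUIRED - set(header)
    if missing:
        raise CollectionFormatError(f"missing required columns: {sorted(missing)}")
    idx = {name: i for i, name in enumerate(header)}

    coll = CleavageCollection()
    for lineno, raw in enumerate(stream, start=2):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            coll.issues.append(f"line {lineno}: expected {len(header)} fields, got {len(fields)}")
            continue

        def get(name: str) -> Optional[str]:
            i = idx.get(name)
            return _opt(fields[i]) if i is not None else None

        try:
            window = CleavageWindow.from_string(get("window") or "")
        except ValueError as exc:
            coll.issues.append(f"line {lineno}: bad window: {exc}")
            continue

        klass = (get("cleavage_class") or "unclassified").lower()
        if klass not in CLEAVAGE_CLASSES:
            coll.issues.append(f"line {lineno}: unknown cleavage class {klass!r}, stored as unclassified")
            klass = "unclassified"

        pep_code = get("peptidase")
        peptidase = MeropsId(pep_code) if pep_code is not None else None
        if peptidase is not None and not peptidase.is_valid:
            coll.issues.append(f"line {lineno}: malformed peptidase identifier {pep_code!r}")

        rng_token = get("residue_range")
        residue_range: Optional[tuple[int, int]] = None
        if rng_token is not None:
            try:
                lo, hi = rng_token.split("-")
                residue_range = (int(lo), int(hi))
            except ValueError:
                coll.issues.append(f"line {lineno}: bad residue_range {rng_token!r}")
                continue

        km, kcat, kratio = get("km"), get("kcat"), get("kcat_over_km")
        kinetics = None
        if any(v is not None for v in (km, kcat, kratio)):
            kinetics = Kinetics(
                km=float(km) if km else None,
                kcat=float(kcat) if kcat else None,
                kcat_over_km=float(kratio) if kratio else None,
            )

        try:
            record = CleavageRecord(
                peptidase=peptidase,
                substrate_accession=get("substrate_accession") or "",
                substrate_name=get("substrate_name") or "",
                p1_position=int(get("p1_position") or 0),
                residue_range=residue_range,
                window=window,
                cleavage_class=klass,
                evidence=get("evidence"),
                kinetics=kinetics,
                reference_id=get("reference_id"),
                checksum=get("checksum"),
            )
        except ValueError as exc:
            coll.issues.append(f"line {lineno}: {exc}")
            continue
        coll.records.append(record)

        if peptidase is not None and peptidase.code not in coll.peptidases:
            activity = get("activity_class")
            if activity is not None:
                try:
                    coll.peptidases[peptidase.code] = PeptidaseEntry(
                        id=peptidase,
                        name=get("peptidase_name") or peptidase.code,
                        activity_class=activity,
                    )
                except ValueError as exc:
                    coll.issues.append(f"line {lineno}: {exc}")

    if isinstance(source, (str, os.PathLike)):
        stream.close()
    return coll


def write_collection(collection: CleavageCollection) -> str:
    """Serialise a collection to the TSV dialect read by :func:`parse_collection`.

    ``parse_collection(write_collection(c))`` reproduces ``c``
    record-for-record on the normalised form.
    """
    out = io.StringIO()
    out.write("\t".join(_COLUMNS) + "\n")
    for r in collection.records:
        entry = (
            collection.peptidases.get(r.peptidase.code) if r.peptidase is not None else None
        )
        k = r.kinetics or Kinetics()
        row = [
            _fmt(r.peptidase.code if r.peptidase else None),
            _fmt(entry.name if entry else None),
            _fmt(entry.activity_class if entry else None),
            r.substrate_accession,
            _fmt(r.substrate_name or None),
            str(r.p1_position),
            _fmt(f"{r.residue_range[0]}-{r.residue_range[1]}" if r.residue_range else None),
            r.window.to_string(),
            r.cleavage_class,
            _fmt(r.evidence),
            _fmt(k.km),
            _fmt(k.kcat),
            _fmt(k.kcat_over_km),
            _fmt(r.reference_id),
            _fmt(r.checksum),
        ]
        out.write("\t".join(row) + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Window extraction and validation
# ---------------------------------------------------------------------------


def extract_window(sequence: str, p1_position: int) -> CleavageWindow:
    """Slice the P4-P4' window around ``p1_position`` (1-based).

    Slots map to sequence positions ``p1-3 .. p1+4``; positions before
    residue 1 or past the last residue become EMPTY. ``p1_position`` must
    leave at least one residue on the prime side (a scissile bond needs a
    P1').
    """
    n = len(sequence)
    if not 1 <= p1_position < n:
        raise ValueError(
            f"p1_position {p1_position} out of range for sequence of length {n} "
            "(P1 needs a following P1' residue)"
        )
    tokens = []
    for pos in range(p1_position - 3, p1_position + 5):
        tokens.append(sequence[pos - 1] if 1 <= pos <= n else EMPTY)
    return CleavageWindow.from_tokens(tokens)


def validate_record(
    record: CleavageRecord, sequence: Optional[str] = None
) -> list[str]:
    """Quality-control a record; issues are data, not exceptions.

    Checks the peptidase identifier pattern, that P1 lies inside the
    stored residue range, and — when the current substrate sequence is
    supplied — that every non-X, non-EMPTY window slot still matches the
    sequence (drift detection after upstream sequence revisions). Slots
    stored as ``X`` are wildcards and never mismatch.
    """
    issues: list[str] = []
    if record.peptidase is not None and not record.peptidase.is_valid:
        issues.append(f"malformed peptidase identifier {record.peptidase.code!r}")
    if record.residue_range is not None:
        lo, hi = record.residue_range
        if not (lo <= record.p1_position < hi):
            issues.append(
                f"p1_position {record.p1_position} outside residue range {lo}-{hi}"
            )
    if sequence is not None:
        try:
            current = extract_window(sequence, record.p1_position)
        except ValueError as exc:
            issues.append(str(exc))
            return issues
        for i, (stored, now) in enumerate(zip(record.window.slots, current.slots)):
            if stored in (EMPTY, "X"):
                continue
            if stored != now:
                issues.append(
                    f"window mismatch at {POCKETS[i]}: stored {stored}, sequence has "
                    f"{now or 'no residue'}"
                )
    return issues


# ---------------------------------------------------------------------------
# Substrate-centric processing maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CleavageSite:
    p1_position: int
    peptidases: tuple[str, ...]  # sorted codes; "?" for unmapped
    classes: frozenset[str]


@dataclass
class ProcessingMap:
    """Where one substrate is cut, and the fragments this implies."""

    accession: str
    sequence_length: Optional[int]
    sites: list[CleavageSite]

    @property
    def fragments(self) -> list[tuple[int, Optional[int]]]:
        """Inclusive intervals between successive scissile bonds.

        Cutting after each P1 position partitions ``[1, L]``; when the
        substrate length is unknown the final fragment is open-ended.
        """
        bounds = [0] + [s.p1_position for s in self.sites]
        frags: list[tuple[int, Optional[int]]] = []
        for lo, hi in zip(bounds, bounds[1:]):
            frags.append((lo + 1, hi))
        frags.append((bounds[-1] + 1, self.sequence_length))
        return frags

    def filter(self, cleavage_class: str) -> "ProcessingMap":
        """Restrict the map to sites carrying the given cleavage class."""
        kept = [s for s in self.sites if cleavage_class in s.classes]
        return ProcessingMap(self.accession, self.sequence_length, kept)

    def render(self, sequence: Optional[str] = None, width: int = 60) -> str:
        """Text display with ``+`` marking each scissile bond."""
        lines = [f"# {self.accession}: {len(self.sites)} cleavage site(s)"]
        for s in self.sites:
            lines.append(
                f"  after {s.p1_position:>6d}  +  {','.join(s.peptidases)}"
                f"  [{'/'.join(sorted(s.classes))}]"
            )
        if sequence:
            cut_after = {s.p1_position for s in self.sites}
            marked = "".join(
                ch + ("+" if (i + 1) in cut_after else "") for i, ch in enumerate(sequence)
            )
            for i in range(0, len(marked), width):
                lines.append(marked[i : i + width])
        return "\n".join(lines) + "\n"


def substrate_map(
    collection: CleavageCollection,
    accession: str,
    cleavage_class: Optional[str] = None,
) -> ProcessingMap:
    """Build the processing map for one substrate accession.

    Sites are sorted by position; several peptidases cutting the same
    bond collapse to one site listing them all. An accession with no
    records yields an empty map. ``cleavage_class`` restricts the map to
    sites of that class.
    """
    per_pos: dict[int, tuple[set[str], set[str]]] = {}
    for r in collection.records:
        if r.substrate_accession != accession:
            continue
        if cleavage_class is not None and r.cleavage_class != cleavage_class:
            continue
        peps, classes = per_pos.setdefault(r.p1_position, (set(), set()))
        peps.add(r.peptidase.code if r.peptidase else "?")
        classes.add(r.cleavage_class)
    sites = [
        CleavageSite(pos, tuple(sorted(peps)), frozenset(classes))
        for pos, (peps, classes) in sorted(per_pos.items())
    ]
    length = len(collection.sequences[accession]) if accession in collection.sequences else None
    return ProcessingMap(accession, length, sites)
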