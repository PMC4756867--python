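"""Seeded synthetic-data generators.

Every analysis in this package can be exercised without any network
access: :func:`simulate_collection` draws cleavage collections from a
planted per-pocket amino-acid distribution (so preference calling and
reliability scoring can be checked against known ground truth), and
:func:`simulate_orthologues` builds gapped orthologue alignments with
controlled substitution/indel rates, a conserved cleavage window, and
exactly-planted substitutions (so conservation counts can be checked
against the planted design).

All generators are pure functions of their spec, seed included: the same
spec yields byte-identical output on every run and platform. Indels are
inserted only in non-reference rows, keeping reference coordinates
stable. Substitutions are drawn uniformly over the other 19 residues; no
empirical substitution matrix is used — the point is to test counting
logic, not to mimic evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from cleavekit.cleavage_store import (
    AMINO_ACIDS,
    EMPTY,
    MASKED_POCKETS,
    POCKETS,
    CleavageCollection,
    CleavageRecord,
    CleavageWindow,
    MeropsId,
    PeptidaseEntry,
)
from cleavekit.conservation import OrthologueAlignment

__all__ = [
    "ProfileSpec",
    "OrthologueSpec",
    "simulate_collection",
    "simulate_orthologues",
    "pocket_distribution",
]


def pocket_distribution(
    planted: Optional[Mapping[str, float]] = None,
    exclude: Sequence[str] = (),
    empty_mass: float = 0.0,
) -> dict[str, float]:
    """Build one pocket's categorical distribution.

    ``planted`` residues take their stated mass; the remainder is spread
    uniformly over the other standard residues, minus ``exclude``;
    ``empty_mass`` (for exopeptidase-style pockets) goes to EMPTY.
    """
    planted = dict(planted or {})
    background = [a for a in AMINO_ACIDS if a not in planted and a not in exclude]
    rest = 1.0 - sum(planted.values()) - empty_mass
    if rest < -1e-9 or (rest > 1e-9 and not background):
        raise ValueError("pocket masses do not sum to 1")
    dist = {a: rest / len(background) for a in background} if background else {}
    dist.update(planted)
    if empty_mass > 0:
        dist[EMPTY] = empty_mass
    return dist


@dataclass
class ProfileSpec:
    """Generating distribution for a synthetic cleavage collection."""

    n_records: int
    seed: int
    activity_class: str = "endopeptidase"
    #: one categorical distribution per pocket, P4..P4'; None -> uniform
    #: over the 20 standard residues (masked pockets of the activity
    #: class always come out EMPTY).
    distributions: Optional[list[Optional[dict[str, float]]]] = None
    peptidase: str = "X01.001"
    cleavage_class: str = "physiological"

    def __post_init__(self) -> None:
        if self.distributions is None:
            self.distributions = [None] * 8
        if len(self.distributions) != 8:
            raise ValueError("need one distribution per pocket (8)")
        for i, dist in enumerate(self.distributions):
            if dist is None:
                continue
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"pocket {POCKETS[i]} masses sum to {total}, not 1")
            if i == 3 and dist.get(EMPTY, 0.0) > 0:
                raise ValueError("P1 may not carry EMPTY mass")

    @classmethod
    def uniform(
        cls,
        n_records: int,
        seed: int,
        activity_class: str = "endopeptidase",
        exclude: Optional[Mapping[str, Sequence[str]]] = None,
        planted: Optional[Mapping[str, Mapping[str, float]]] = None,
        peptidase: str = "X01.001",
    ) -> "ProfileSpec":
        """Uniform background with optional per-pocket exclusions/plants.

        ``exclude``/``planted`` are keyed by pocket label (``"P2'"`` etc.).
        Pockets masked by the activity class are generated EMPTY.
        """
        masked = MASKED_POCKETS[activity_class]
        dists: list[Optional[dict[str, float]]] = []
        exclude = exclude or {}
        planted = planted or {}
        for i, label in enumerate(POCKETS):
            if i in masked:
                dists.append({EMPTY: 1.0})
            elif label in exclude or label in planted:
                dists.append(
                    pocket_distribution(
                        planted.get(label), exclude=tuple(exclude.get(label, ()))
                    )
                )
            else:
                dists.append(None)
        return cls(
            n_records=n_records,
            seed=seed,
            activity_class=activity_class,
            distributions=dists,
            peptidase=peptidase,
        )


def simulate_collection(spec: ProfileSpec) -> CleavageCollection:
    """Draw a collection of i.i.d. windows from the spec's distributions."""
    rng = np.random.default_rng(spec.seed)
    uniform = {a: 1.0 / len(AMINO_ACIDS) for a in AMINO_ACIDS}
    columns: list[np.ndarray] = []
    for dist in spec.distributions or []:
        d = dist if dist is not None else uniform
        symbols = np.array(list(d.keys()), dtype=object)
        probs = np.array(list(d.values()), dtype=float)
        probs = probs / probs.sum()
        columns.append(rng.choice(symbols, size=spec.n_records, p=probs))

    pep = MeropsId(spec.peptidase)
    coll = CleavageCollection(
        peptidases={
            pep.code: PeptidaseEntry(id=pep, name=f"synthetic {pep.code}",
                                     activity_class=spec.activity_class)
        }
    )
    for k in range(spec.n_records):
        window = CleavageWindow.from_tokens([str(columns[i][k]) for i in range(8)])
        coll.records.append(
            CleavageRecord(
                peptidase=pep,
                substrate_accession=f"SYN{k:05d}",
                substrate_name=f"synthetic substrate {k}",
                p1_position=10,
                window=window,
                cleavage_class=spec.cleavage_class,
            )
        )
    return coll


@dataclass
class OrthologueSpec:
    """Generating process for a synthetic orthologue alignment."""

    n_rows: int
    seed: int
    p1_position: int
    reference: Optional[str] = None  # explicit reference sequence ...
    length: int = 120                # ... or draw one of this length
    substitution_prob: float = 0.05
    indel_prob: float = 0.0
    max_indel_len: int = 3
    #: reference positions (1-based) held invariant in every row except
    #: where a substitution is planted; by default the P4-P4' window.
    conserved_positions: Optional[frozenset[int]] = None
    #: exact substitutions: (row index >=1, pocket label, residue)
    planted: list[tuple[int, str, str]] = field(default_factory=list)
    reference_id: str = "QUERY"

    def window_positions(self, ref_len: int) -> frozenset[int]:
        return frozenset(
            p for p in range(self.p1_position - 3, self.p1_position + 5) if 1 <= p <= ref_len
        )


def simulate_orthologues(spec: OrthologueSpec) -> OrthologueAlignment:
    """Build a gapped alignment around a conserved cleavage window.

    Non-reference rows accumulate uniform substitutions, deletions (gap
    in that row) and insertions (gap columns opened in all other rows)
    at the configured rates; positions in ``conserved_positions`` are
    never touched, except that ``planted`` substitutions override every
    other process and land exactly where stated. The reference row never
    carries indels, so its residue coordinates are stable.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.reference is not None:
        ref = spec.reference.upper()
    else:
        ref = "".join(rng.choice(list(AMINO_ACIDS), size=spec.length))
    n = len(ref)
    if not 1 <= spec.p1_position < n:
        raise ValueError("p1_position must leave a P1' residue in the reference")
    conserved = (
        spec.conserved_positions
        if spec.conserved_positions is not None
        else spec.window_positions(n)
    )

    # planted substitutions, resolved to (row, 1-based ref position, residue)
    planted: dict[tuple[int, int], str] = {}
    for row, pocket, residue in spec.planted:
        # pocket order P4..P1 maps to p1-3..p1; P1'..P4' to p1+1..p1+4
        idx = POCKETS.index(pocket)
        pos = spec.p1_position - 3 + idx if idx <= 3 else spec.p1_position + (idx - 3)
        if not 1 <= pos <= n:
            raise ValueError(f"planted pocket {pocket} falls outside the reference")
        if not 1 <= row < spec.n_rows:
            raise ValueError(f"planted row {row} out of range (1..{spec.n_rows - 1})")
        planted[(row, pos)] = residue.upper()

    alphabet = list(AMINO_ACIDS)
    # per-row residue state and deletion mask; insertions collected per slot
    row_chars: list[list[str]] = []
    insertions: list[dict[int, str]] = []  # per row: slot (0..n) -> inserted run
    for r in range(spec.n_rows):
        chars = list(ref)
        ins: dict[int, str] = {}
        if r > 0:  # row 0 is the reference
            for j in range(n):
                pos = j + 1
                if (r, pos) in planted:
                    continue
                if pos in conserved:
                    continue
                if rng.random() < spec.substitution_prob:
                    choices = [a for a in alphabet if a != chars[j]]
                    chars[j] = str(rng.choice(choices))
                if spec.indel_prob > 0 and rng.random() < spec.indel_prob / 2:
                    chars[j] = "-"
                if spec.indel_prob > 0 and rng.random() < spec.indel_prob / 2:
                    k = int(rng.integers(1, spec.max_indel_len + 1))
                    ins[pos] = "".join(rng.choice(alphabet, size=k))
            for (row, pos), residue in planted.items():
                if row == r:
                    chars[pos - 1] = residue
        row_chars.append(chars)
        insertions.append(ins)

    # lay out columns: for each inter-residue slot, the widest insertion wins
    slot_width = [0] * (n + 1)
    for ins in insertions:
        for slot, run in ins.items():
            slot_width[slot] = max(slot_width[slot], len(run))

    names = [spec.reference_id] + [f"HOM{r:04d}" for r in range(1, spec.n_rows)]
    rows: dict[str, str] = {}
    for r, name in enumerate(names):
        parts: list[str] = []
        for j in range(n + 1):
            if j > 0:
                parts.append(row_chars[r][j - 1])
            w = slot_width[j]
            if w:
                run = insertions[r].get(j, "")
                parts.append(run + "-" * (w - len(run)))
        rows[name] = "".join(parts)
    return OrthologueAlignment(reference_id=spec.reference_id, rows=rows)
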