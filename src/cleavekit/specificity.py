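"""Specificity matrices, logo weights, reliability scores and preference calls.

For one peptidase, the occurrences of each amino acid in the binding
pockets P4-P4' across all its known cleavages form a 21 x 8 specificity
matrix (20 standard residues plus X). From it this module derives:

* a decile-shaded display matrix (percentages of total cleavages);
* WebLogo-style letter heights (relative frequency scaled by Shannon
  information content, R = log2(20) - H);
* a symbolic preference profile: per pocket, one or two preferred amino
  acids, a group symbol when a physico-chemical group dominates, or
  negative preferences (residues never observed) for richly sampled
  peptidases;
* a reliability score: the average percentage pairwise difference between
  the windows of all substrate pairs, which is low when substrates are
  near-identical (e.g. scanning series of one synthetic template) and
  high when they are diverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from cleavekit.cleavage_store import (
    AMINO_ACIDS,
    EMPTY,
    MASKED_POCKETS,
    POCKETS,
    CleavageCollection,
    MeropsId,
)

__all__ = [
    "DISPLAY_ORDER",
    "AMINO_ACID_GROUPS",
    "GROUP_ORDER",
    "SpecificityMatrix",
    "PocketCall",
    "PreferenceProfile",
    "ShadedMatrix",
    "ReliabilityResult",
    "build_matrix",
    "shade_matrix",
    "logo_weights",
    "reliability_score",
    "reliability_band",
    "call_preferences",
    "low_confidence_flag",
    "specificity_display_gate",
    "MIN_CLEAVAGES_FOR_DISPLAY",
    "MIN_CLEAVAGES_CONFIDENT",
    "MIN_CLEAVAGES_NEGATIVE",
]

#: Fixed display row order: amino acids with similar properties grouped
#: (aliphatic, aromatic, acidic, basic, small, other), X last.
DISPLAY_ORDER = list("ILVFWYDERHKACGSNQMPT") + ["X"]

#: Physico-chemical groups and their published table symbols.
AMINO_ACID_GROUPS: dict[str, frozenset[str]] = {
    "λ": frozenset("ILV"),   # λ aliphatic
    "@": frozenset("FWY"),        # aromatic
    "+": frozenset("DE"),         # acidic
    "−": frozenset("RHK"),   # − basic
    "Σ": frozenset("ACGS"),  # Σ small
    "Ω": frozenset("NQMPT"), # Ω other
}

#: Deterministic precedence when two group sums tie.
GROUP_ORDER = ["λ", "@", "+", "−", "Σ", "Ω"]

#: A specificity display (logo + matrix) is only meaningful from this many
#: cleavages.
MIN_CLEAVAGES_FOR_DISPLAY = 10

#: Below this many cleavages every profile carries a low-confidence caution.
MIN_CLEAVAGES_CONFIDENT = 40

#: Negative (never-observed) preferences are reported only at or above this
#: many cleavages, because rare residues (Cys, Trp) are otherwise absent by
#: chance.
MIN_CLEAVAGES_NEGATIVE = 200

#: Minimum fraction of cleavages required to call a pocket preference.
PREFERENCE_THRESHOLD_PCT = 50.0


@dataclass
class SpecificityMatrix:
    """Per-pocket amino-acid occurrence counts for one peptidase.

    ``counts`` is indexed by residue (:data:`DISPLAY_ORDER`) with one
    column per pocket; ``occupancy`` counts non-EMPTY observations per
    pocket, so column sums equal occupancy and occupancy at P1 equals
    ``n_cleavages``.
    """

    peptidase: MeropsId
    n_cleavages: int
    counts: pd.DataFrame
    occupancy: pd.Series

    def percentages(self) -> pd.DataFrame:
        """Each count as a percentage of total cleavages (not occupancy)."""
        return self.counts / self.n_cleavages * 100.0

    def to_tsv(self) -> str:
        out = self.counts.copy()
        out.loc["<occupancy>"] = self.occupancy
        return out.to_csv(sep="\t", index_label="residue")


def build_matrix(
    collection: CleavageCollection, peptidase: Union[MeropsId, str]
) -> SpecificityMatrix:
    """Tally every non-EMPTY window slot of the peptidase's records.

    X (non-standard residue / blocking group) is tallied in its own row.
    Raises ``ValueError`` when the collection holds no records for the
    peptidase.
    """
    records = collection.records_for(peptidase)
    code = peptidase.code if isinstance(peptidase, MeropsId) else peptidase
    if not records:
        raise ValueError(f"no cleavage records for peptidase {code}")
    counts = pd.DataFrame(0, index=DISPLAY_ORDER, columns=list(POCKETS), dtype=int)
    occupancy = pd.Series(0, index=list(POCKETS), dtype=int)
    for r in records:
        for i, slot in enumerate(r.window.slots):
            if slot == EMPTY:
                continue
            counts.loc[slot, POCKETS[i]] += 1
            occupancy[POCKETS[i]] += 1
    return SpecificityMatrix(
        peptidase=MeropsId(code), n_cleavages=len(records), counts=counts, occupancy=occupancy
    )


@dataclass
class ShadedMatrix:
    """Decile-binned display form of a specificity matrix."""

    bins: pd.DataFrame  # int bin per cell: floor(pct / 10), capped at 10
    unobserved: frozenset[str]  # residues with zero count in every pocket


def shade_matrix(matrix: SpecificityMatrix) -> ShadedMatrix:
    """Assign each cell its tenth-percentile shade bin.

    The bin is ``floor(pct / 10)`` of the percentage of total cleavages,
    capped at 10. Standard amino acids never seen in any pocket are
    flagged unobserved-anywhere (rendered white-on-black in the website
    display this mirrors).
    """
    pct = matrix.percentages()
    bins = np.floor(pct / 10.0).clip(upper=10).astype(int)
    observed = matrix.counts.sum(axis=1)
    unobserved = frozenset(a for a in AMINO_ACIDS if observed.get(a, 0) == 0)
    return ShadedMatrix(bins=bins, unobserved=unobserved)


def logo_weights(matrix: SpecificityMatrix) -> pd.DataFrame:
    """WebLogo-style letter heights per pocket.

    Relative frequencies over the observed standard residues (X excluded)
    are scaled by the information content R = log2(20) - H, where H is
    the Shannon entropy of the pocket's frequency distribution. A pocket
    with zero occupancy gets all-zero heights. Columns are the pockets
    S4-S4', conventionally numbered 1-8 on a logo's x-axis. No
    small-sample correction is applied.
    """
    aa_rows = [a for a in DISPLAY_ORDER if a != "X"]
    heights = pd.DataFrame(0.0, index=aa_rows, columns=list(POCKETS))
    for pocket in POCKETS:
        col = matrix.counts.loc[aa_rows, pocket]
        total = int(col.sum())
        if total == 0:
            continue
        freqs = col / total
        nz = freqs[freqs > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        info = math.log2(20) - entropy
        heights[pocket] = freqs * info
    return heights


# ---------------------------------------------------------------------------
# Reliability score
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReliabilityResult:
    score: float  # percent, 0-100
    band: str  # green / yellow / red
    n_positions_considered: int
    n_cleavages: int


def reliability_band(score: float) -> str:
    """Traffic-light band for a reliability score.

    >= 75 green (diverse substrates, preferences trustworthy), 50-74
    yellow (a proportion of similar substrates), < 50 red (treat the
    inferred preferences with caution).
    """
    if score >= 75.0:
        return "green"
    if score >= 50.0:
        return "yellow"
    return "red"


def reliability_score(
    collection: CleavageCollection, peptidase: Union[MeropsId, str]
) -> ReliabilityResult:
    """Average percentage pairwise window difference over all substrates.

    All n(n-1)/2 unordered pairs of the peptidase's windows are compared
    at every *considered* pocket — a pocket counts as considered when it
    is occupied (non-EMPTY) in at least one record, so the number of
    positions is calculated, not assumed from the activity class: 8 for a
    typical endopeptidase set, 5 for amino-/carboxypeptidases, 6 for
    dipeptidyl-/peptidyl-dipeptidases, 2 for dipeptidases. Non-standard
    residues have already been normalised to X in storage; X vs X and
    EMPTY vs EMPTY do not differ, any other unequal pair does. The score
    is ``100 * total_differences / (n_pairs * n_positions)``.
    """
    records = collection.records_for(peptidase)
    code = peptidase.code if isinstance(peptidase, MeropsId) else peptidase
    if len(records) < 2:
        raise ValueError(
            f"reliability score needs >= 2 records for {code}, have {len(records)}"
        )
    windows = [r.window.slots for r in records]
    considered = [i for i in range(8) if any(w[i] != EMPTY for w in windows)]
    n_positions = len(considered)
    n = len(windows)
    n_pairs = n * (n - 1) // 2
    total = 0
    for a in range(n):
        wa = windows[a]
        for b in range(a + 1, n):
            wb = windows[b]
            total += sum(1 for i in considered if wa[i] != wb[i])
    score = 100.0 * total / (n_pairs * n_positions)
    return ReliabilityResult(
        score=score,
        band=reliability_band(score),
        n_positions_considered=n_positions,
        n_cleavages=n,
    )


# ---------------------------------------------------------------------------
# Preference calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PocketCall:
    """The called state of one binding pocket."""

    state: str  # masked | preferred | negative | none
    residues: tuple[str, ...] = ()  # <=2 amino acids, or one group symbol
    shade_band: Optional[str] = None  # 50-59 | 60-69 | 70-79 | 80-89 | 90+


@dataclass
class PreferenceProfile:
    peptidase: MeropsId
    n_cleavages: int
    pockets: dict[str, PocketCall]  # keyed by pocket label
    reliability_score: Optional[float] = None
    reliability_band: Optional[str] = None
    low_confidence: bool = True

    def to_tsv(self) -> str:
        lines = ["pocket\tstate\tresidues\tshade_band"]
        for label in POCKETS:
            c = self.pockets[label]
            lines.append(
                f"{label}\t{c.state}\t{''.join(c.residues) or '.'}\t{c.shade_band or '.'}"
            )
        return "\n".join(lines) + "\n"


def _shade_band_label(pct: float) -> str:
    if pct >= 90.0:
        return "90+"
    lo = int(pct // 10) * 10
    return f"{lo}-{lo + 9}"


def low_confidence_flag(n_cleavages: int) -> bool:
    """True when fewer cleavages are known than specificity analysis needs."""
    return n_cleavages < MIN_CLEAVAGES_CONFIDENT


def specificity_display_gate(n_cleavages: int) -> bool:
    """True when enough cleavages are known to emit a logo/matrix display."""
    return n_cleavages >= MIN_CLEAVAGES_FOR_DISPLAY


def call_preferences(
    matrix: SpecificityMatrix,
    activity_class: str = "endopeptidase",
    score: Optional[float] = None,
) -> PreferenceProfile:
    """Derive the symbolic preference profile from a specificity matrix.

    Per unmasked pocket, with p(a) = count(a) / n_cleavages * 100:

    1. if the best single amino acid reaches 50%, it is preferred; a
       second is listed only when it also reaches 50% on its own;
    2. otherwise, if a physico-chemical group's summed percentage reaches
       50% *and* exceeds the best single residue, the group symbol is
       preferred;
    3. otherwise, when 200 or more cleavages are known, up to two amino
       acids with zero count in the pocket are reported as negative
       preferences (rarest in the whole matrix first, then alphabetical);
    4. otherwise no call.

    Pockets that cannot exist for the activity class (e.g. P4-P2 for an
    aminopeptidase) are masked regardless of counts. The shade band
    records the combined percentage of the listed residues (or the group
    sum), binned as 50-59 ... 90+.
    """
    masked = MASKED_POCKETS[activity_class]
    n = matrix.n_cleavages
    whole_matrix_freq = matrix.counts.loc[list(AMINO_ACIDS)].sum(axis=1)
    pockets: dict[str, PocketCall] = {}
    for i, label in enumerate(POCKETS):
        if i in masked:
            pockets[label] = PocketCall(state="masked")
            continue
        col = matrix.counts.loc[list(AMINO_ACIDS), label]
        pct = col / n * 100.0
        # sort by count descending, then alphabetical
        ranked = sorted(AMINO_ACIDS, key=lambda a: (-col[a], a))
        best, best_pct = ranked[0], float(pct[ranked[0]])

        if best_pct >= PREFERENCE_THRESHOLD_PCT:
            listed = [best]
            second_pct = float(pct[ranked[1]])
            if second_pct >= PREFERENCE_THRESHOLD_PCT:
                listed.append(ranked[1])
            combined = min(float(pct[listed].sum()), 100.0)
            pockets[label] = PocketCall(
                state="preferred",
                residues=tuple(listed),
                shade_band=_shade_band_label(combined),
            )
            continue

        group_sums = {
            sym: float(pct[list(members)].sum())
            for sym, members in AMINO_ACID_GROUPS.items()
        }
        best_sym = max(GROUP_ORDER, key=lambda s: (group_sums[s], -GROUP_ORDER.index(s)))
        if group_sums[best_sym] >= PREFERENCE_THRESHOLD_PCT and group_sums[best_sym] > best_pct:
            pockets[label] = PocketCall(
                state="preferred",
                residues=(best_sym,),
                shade_band=_shade_band_label(min(group_sums[best_sym], 100.0)),
            )
            continue

        if n >= MIN_CLEAVAGES_NEGATIVE:
            never = [a for a in AMINO_ACIDS if col[a] == 0]
            if never:
                never.sort(key=lambda a: (whole_matrix_freq[a], a))
                pockets[label] = PocketCall(state="negative", residues=tuple(never[:2]))
                continue

        pockets[label] = PocketCall(state="none")

    return PreferenceProfile(
        peptidase=matrix.peptidase,
        n_cleavages=n,
        pockets=pockets,
        reliability_score=score,
        reliability_band=reliability_band(score) if score is not None else None,
        low_confidence=low_confidence_flag(n),
    )


def plot_logo(matrix: SpecificityMatrix, path: str) -> None:
    """Render the logo to PNG/SVG (extension decides the format).

    Letter contributions are drawn as stacked, labelled bars per pocket
    (largest on top), y-axis in bits. Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    heights = logo_weights(matrix)
    fig, ax = plt.subplots(figsize=(8, 3))
    cmap = plt.get_cmap("tab20")
    colors = {aa: cmap(i % 20) for i, aa in enumerate(sorted(AMINO_ACIDS))}
    for x, pocket in enumerate(POCKETS, start=1):
        col = heights[pocket].sort_values()
        y = 0.0
        for aa, h in col.items():
            if h <= 0:
                continue
            ax.bar(x, h, bottom=y, width=0.85, color=colors[aa], edgecolor="white")
            if h > 0.12:
                ax.text(x, y + h / 2, aa, ha="center", va="center", fontsize=9)
            y += h
    ax.set_xlim(0.4, 8.6)
    ax.set_ylim(0, math.log2(20))
    ax.set_xticks(range(1, 9))
    ax.set_ylabel("bits")
    ax.set_title(str(matrix.peptidase))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
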