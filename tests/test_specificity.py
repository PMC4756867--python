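"""Specificity matrices, logos, reliability scoring and preference calls."""

from __future__ import annotations

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleavekit.cleavage_store import AMINO_ACIDS
from cleavekit.specificity import (
    AMINO_ACID_GROUPS,
    build_matrix,
    call_preferences,
    logo_weights,
    low_confidence_flag,
    reliability_band,
    reliability_score,
    shade_matrix,
    specificity_display_gate,
)
from cleavekit.simulate import ProfileSpec, simulate_collection
from tests.conftest import brute_force_reliability, make_collection, make_record


class TestBuildMatrix:
    def test_identical_windows_count_and_percentage(self):
        coll = make_collection([make_record("GAAAKAAA", accession=f"P{i}") for i in range(10)])
        m = build_matrix(coll, "M10.003")
        assert m.counts.loc["G", "P4"] == 10
        assert m.percentages().loc["G", "P4"] == 100.0

    def test_split_p1_counts(self):
        coll = make_collection(
            [make_record("AAARAAAA", accession="P1"), make_record("AAAKAAAA", accession="P2")]
        )
        m = build_matrix(coll, "M10.003")
        assert m.counts.loc["R", "P1"] == 1 and m.counts.loc["K", "P1"] == 1
        assert m.percentages().loc["R", "P1"] == 50.0

    def test_empty_slots_excluded_from_occupancy(self):
        coll = make_collection(
            [make_record("...AKAAA", accession=f"P{i}") for i in range(4)],
            activity_class="aminopeptidase",
        )
        m = build_matrix(coll, "M10.003")
        assert m.occupancy["P4"] == 0 and m.occupancy["P2"] == 0
        assert (m.counts["P4"] == 0).all()
        assert m.occupancy["P1"] == m.n_cleavages == 4

    def test_x_tallied_in_own_row(self):
        coll = make_collection([make_record("XAAAKAAA", accession="P1")])
        m = build_matrix(coll, "M10.003")
        assert m.counts.loc["X", "P4"] == 1

    def test_no_records_raises_naming_peptidase(self):
        coll = make_collection([make_record("AAAAKAAA")])
        with pytest.raises(ValueError, match="C14.003"):
            build_matrix(coll, "C14.003")

    def test_column_sums_equal_occupancy(self, trio_collection):
        m = build_matrix(trio_collection, "M10.003")
        assert (m.counts.sum(axis=0) == m.occupancy).all()


class TestShadeMatrix:
    def test_full_preference_capped_at_bin_ten(self):
        coll = make_collection([make_record("GAAAKAAA", accession=f"P{i}") for i in range(10)])
        shaded = shade_matrix(build_matrix(coll, "M10.003"))
        assert shaded.bins.loc["G", "P4"] == 10

    def test_floor_rule_just_below_decile(self):
        # 1 of 11 records -> 9.09% -> bin 0; 2 of 11 -> 18.2% -> bin 1
        records = [make_record("GAAAKAAA", accession=f"P{i}") for i in range(9)]
        records += [make_record("WAAAKAAA", accession="P9"),
                    make_record("WWAAKAAA", accession="P10")]
        shaded = shade_matrix(build_matrix(make_collection(records), "M10.003"))
        assert shaded.bins.loc["W", "P3"] == 0
        assert shaded.bins.loc["W", "P4"] == 1

    def test_unobserved_anywhere_flag(self):
        coll = make_collection([make_record("GAAAKAAA", accession="P1")])
        shaded = shade_matrix(build_matrix(coll, "M10.003"))
        assert "W" in shaded.unobserved
        assert "G" not in shaded.unobserved and "A" not in shaded.unobserved


class TestLogoWeights:
    def test_single_residue_pocket_reaches_max_bits(self):
        coll = make_collection([make_record("GAAAKAAA", accession=f"P{i}") for i in range(5)])
        h = logo_weights(build_matrix(coll, "M10.003"))
        assert h.loc["G", "P4"] == pytest.approx(math.log2(20))
        assert h.drop("G")["P4"].sum() == 0

    def test_uniform_pocket_has_zero_information(self):
        records = [
            make_record(f"{aa}AAAKAAA", accession=f"P{i}")
            for i, aa in enumerate(AMINO_ACIDS)
        ]
        h = logo_weights(build_matrix(make_collection(records), "M10.003"))
        assert h["P4"].abs().sum() == pytest.approx(0.0, abs=1e-12)

    def test_skewed_pocket_matches_hand_entropy(self):
        # counts A:3, L:1 -> freqs .75/.25; independent arithmetic below
        records = [make_record("AAAAKAAA", accession=f"P{i}") for i in range(3)]
        records.append(make_record("LAAAKAAA", accession="P3"))
        h = logo_weights(build_matrix(make_collection(records), "M10.003"))
        entropy = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        info = math.log2(20) - entropy
        assert h.loc["A", "P4"] == pytest.approx(0.75 * info)
        assert h.loc["L", "P4"] == pytest.approx(0.25 * info)

    def test_zero_occupancy_pocket_all_zero(self):
        coll = make_collection(
            [make_record("...AKAAA", accession=f"P{i}") for i in range(3)]
        )
        h = logo_weights(build_matrix(coll, "M10.003"))
        assert (h["P4"] == 0).all()

    def test_x_excluded_from_heights(self):
        coll = make_collection(
            [make_record("XAAAKAAA", accession="P1"), make_record("GAAAKAAA", accession="P2")]
        )
        h = logo_weights(build_matrix(coll, "M10.003"))
        assert "X" not in h.index
        # only G observed among standard residues at P4 -> full information
        assert h.loc["G", "P4"] == pytest.approx(math.log2(20))


class TestReliabilityScore:
    def test_identical_windows_score_zero_red(self):
        coll = make_collection(
            [make_record("CDEFGHIK", accession="P1"), make_record("CDEFGHIK", accession="P2")]
        )
        res = reliability_score(coll, "M10.003")
        assert res.score == 0.0 and res.band == "red"

    def test_fully_distinct_windows_score_hundred(self):
        coll = make_collection(
            [make_record("CDEFGHIK", accession="P1"), make_record("LMNPQRST", accession="P2")]
        )
        res = reliability_score(coll, "M10.003")
        assert res.score == 100.0 and res.band == "green"

    def test_single_record_errors(self):
        coll = make_collection([make_record("CDEFGHIK")])
        with pytest.raises(ValueError):
            reliability_score(coll, "M10.003")

    def test_x_masking_pair_rules(self):
        # X vs X no difference; X vs residue difference
        coll = make_collection(
            [make_record("XDEFGHIK", accession="P1"), make_record("XDEFGHIX", accession="P2")]
        )
        res = reliability_score(coll, "M10.003")
        # differs only at P4' (K vs X); P4 X==X
        assert res.score == pytest.approx(100.0 / 8)

    def test_empty_vs_residue_is_difference(self):
        coll = make_collection(
            [make_record("..EFGHIK", accession="P1"), make_record("CDEFGHIK", accession="P2")]
        )
        res = reliability_score(coll, "M10.003")
        assert res.n_positions_considered == 8
        assert res.score == pytest.approx(100.0 * 2 / 8)

    @pytest.mark.parametrize(
        "activity,expected",
        [
            ("endopeptidase", 8),
            ("aminopeptidase", 5),
            ("carboxypeptidase", 5),
            ("dipeptidyl-peptidase", 6),
            ("peptidyl-dipeptidase", 6),
            ("dipeptidase", 2),
        ],
    )
    def test_positions_considered_is_calculated_not_assumed(self, activity, expected):
        coll = simulate_collection(ProfileSpec.uniform(6, seed=11, activity_class=activity))
        assert reliability_score(coll, "X01.001").n_positions_considered == expected

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, derandomize=True)
    def test_matches_exhaustive_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 8)
        records = []
        for k in range(n):
            slots = [rng.choice(AMINO_ACIDS + "X") for _ in range(8)]
            records.append(make_record("".join(slots), accession=f"P{k}"))
        coll = make_collection(records)
        res = reliability_score(coll, "M10.003")
        expected, n_pos = brute_force_reliability([r.window.slots for r in records])
        assert res.score == pytest.approx(expected, abs=1e-9)
        assert res.n_positions_considered == n_pos

    def test_invariant_under_record_permutation(self):
        rng = random.Random(7)
        records = [
            make_record("".join(rng.choice(AMINO_ACIDS) for _ in range(8)), accession=f"P{k}")
            for k in range(6)
        ]
        coll = make_collection(records)
        baseline = reliability_score(coll, "M10.003").score
        shuffled = records[::-1]
        assert reliability_score(make_collection(shuffled), "M10.003").score == baseline


class TestBands:
    @pytest.mark.parametrize(
        "score,band",
        [(75.0, "green"), (74.9, "yellow"), (50.0, "yellow"), (49.9, "red"),
         (100.0, "green"), (0.0, "red")],
    )
    def test_band_boundaries(self, score, band):
        assert reliability_band(score) == band


class TestGates:
    @pytest.mark.parametrize("n,flag", [(0, True), (39, True), (40, False), (400, False)])
    def test_low_confidence_below_forty(self, n, flag):
        assert low_confidence_flag(n) is flag

    @pytest.mark.parametrize("n,shown", [(9, False), (10, True), (556, True)])
    def test_display_needs_ten_cleavages(self, n, shown):
        assert specificity_display_gate(n) is shown


class TestCallPreferences:
    def _profile(self, planted=None, exclude=None, n=200, seed=0, activity="endopeptidase"):
        spec = ProfileSpec.uniform(
            n, seed=seed, activity_class=activity, planted=planted, exclude=exclude
        )
        coll = simulate_collection(spec)
        return call_preferences(build_matrix(coll, "X01.001"), activity)

    def test_dominant_single_residue_called_with_band(self):
        prof = self._profile(planted={"P1": {"K": 0.95}})
        call = prof.pockets["P1"]
        assert call.state == "preferred" and call.residues == ("K",)
        assert call.shade_band == "90+"

    def test_group_beats_weak_singles(self):
        prof = self._profile(planted={"P1": {"I": 0.30, "L": 0.25, "V": 0.20}})
        call = prof.pockets["P1"]
        assert call.state == "preferred" and call.residues == ("λ",)
        assert call.shade_band in ("70-79", "80-89")

    def test_two_residues_listed_only_when_each_reaches_half(self):
        # exactly 50/50 split: both listed
        records = [make_record("AAARAAAA", accession=f"P{i}") for i in range(100)]
        records += [make_record("AAAKAAAA", accession=f"Q{i}") for i in range(100)]
        prof = call_preferences(build_matrix(make_collection(records), "M10.003"))
        assert set(prof.pockets["P1"].residues) == {"K", "R"}
        # 60/40 split: only the majority residue listed
        records = [make_record("AAARAAAA", accession=f"P{i}") for i in range(120)]
        records += [make_record("AAAKAAAA", accession=f"Q{i}") for i in range(80)]
        prof = call_preferences(build_matrix(make_collection(records), "M10.003"))
        assert prof.pockets["P1"].residues == ("R",)

    def test_no_negative_call_below_two_hundred(self):
        prof = self._profile(exclude={"P2": ["W"]}, n=150)
        assert prof.pockets["P2"].state == "none"

    def test_negative_call_at_two_hundred(self):
        prof = self._profile(exclude={"P2": ["W"]}, n=200)
        call = prof.pockets["P2"]
        assert call.state == "negative" and "W" in call.residues
        assert len(call.residues) <= 2

    def test_carboxypeptidase_prime_pockets_masked(self):
        prof = self._profile(activity="carboxypeptidase", n=50)
        for label in ("P2'", "P3'", "P4'"):
            assert prof.pockets[label].state == "masked"
        assert prof.pockets["P1"].state != "masked"

    def test_single_over_group_precedence(self):
        # K alone >= 50% -> the call is K even though the basic group
        # (R,H,K) sums higher; a symbol never displaces a dominant single
        prof = self._profile(planted={"P1": {"K": 0.60, "R": 0.30}})
        call = prof.pockets["P1"]
        assert call.residues == ("K",)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True)
    def test_group_symbol_never_called_when_single_dominates(self, seed):
        rng = random.Random(seed)
        aa = rng.choice(AMINO_ACIDS)
        mass = rng.uniform(0.55, 0.95)
        coll = simulate_collection(
            ProfileSpec.uniform(120, seed=seed, planted={"P3": {aa: mass}})
        )
        m = build_matrix(coll, "X01.001")
        call = call_preferences(m, "endopeptidase").pockets["P3"]
        pct = m.percentages().loc[aa, "P3"]
        if pct >= 50.0:
            assert call.state == "preferred"
            assert call.residues[0] == aa
            assert call.residues[0] not in AMINO_ACID_GROUPS

    def test_profile_carries_reliability_and_confidence(self):
        coll = simulate_collection(ProfileSpec.uniform(30, seed=9))
        m = build_matrix(coll, "X01.001")
        prof = call_preferences(m, "endopeptidase", score=81.25)
        assert prof.reliability_score == 81.25 and prof.reliability_band == "green"
        assert prof.low_confidence is True
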