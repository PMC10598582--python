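"""Column classification, empirical p-values and the discovery scan."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caaskit import (
    Alignment,
    DiscoveryGroups,
    Pattern,
    classify_chars,
    classify_column,
    classify_matrix,
    discover,
    encode_alignment,
    position_pvalue,
    profile_column,
)
from conftest import AA20, brute_force_caas, random_alignment


def _aln(cols_by_species):
    return Alignment("t", cols_by_species)


class TestProfileColumn:
    def test_counts_residues(self, four_species_groups):
        aln = _aln({"sp1": "L", "sp2": "L", "sp3": "V", "sp4": "V"})
        prof = profile_column(aln, 0, four_species_groups)
        assert sorted(prof.fg_residues) == ["L", "L"]
        assert sorted(prof.bg_residues) == ["V", "V"]
        assert prof.fg_missing == 0 and prof.bg_missing == 0

    def test_gap_counts_as_missing(self, four_species_groups):
        aln = _aln({"sp1": "L", "sp2": "-", "sp3": "V", "sp4": "V"})
        prof = profile_column(aln, 0, four_species_groups)
        assert prof.fg_residues == ("L",)
        assert prof.fg_gaps == 1 and prof.fg_missing == 1

    def test_unknown_counts_as_missing(self, four_species_groups):
        aln = _aln({"sp1": "X", "sp2": "X", "sp3": "V", "sp4": "V"})
        prof = profile_column(aln, 0, four_species_groups)
        assert prof.fg_residues == ()
        assert prof.fg_unknown == 2

    def test_partition_invariant(self, four_species_groups):
        aln = _aln({"sp1": "L", "sp2": "-", "sp3": "X", "sp4": "V"})
        prof = profile_column(aln, 0, four_species_groups)
        assert len(prof.fg_residues) + prof.fg_missing == 2
        assert len(prof.bg_residues) + prof.bg_missing == 2

    def test_absent_species_is_named(self, four_species_groups):
        aln = _aln({"sp1": "L", "sp2": "L", "sp3": "V"})
        with pytest.raises(ValueError, match="sp4"):
            profile_column(aln, 0, four_species_groups)


class TestClassifyColumn:
    @pytest.mark.parametrize(
        "fg, bg, expected",
        [
            ("LL", "VV", Pattern.P1),
            ("LL", "VI", Pattern.P2),
            ("LV", "II", Pattern.P3),
            ("LV", "LL", None),  # shared residue violates condition 1
            ("LV", "IM", None),  # neither group monomorphic
            ("LL", "LL", None),
        ],
    )
    def test_pattern_taxonomy(self, fg, bg, expected):
        assert classify_chars(list(fg), list(bg)) is expected

    def test_tolerance_failure_blocks_classification(self, four_species_groups):
        aln = _aln({"sp1": "L", "sp2": "-", "sp3": "V", "sp4": "V"})
        prof = profile_column(aln, 0, four_species_groups)
        assert classify_column(prof, four_species_groups) is None

    def test_tolerance_admits_column_with_gap(self):
        groups = DiscoveryGroups(
            fg=frozenset({"sp1", "sp2"}), bg=frozenset({"sp3", "sp4"}), max_fg_gaps=1
        )
        aln = _aln({"sp1": "L", "sp2": "-", "sp3": "V", "sp4": "V"})
        prof = profile_column(aln, 0, groups)
        assert classify_column(prof, groups) is Pattern.P1

    def test_all_missing_group_is_never_caas(self):
        groups = DiscoveryGroups(
            fg=frozenset({"sp1", "sp2", "sp3"}), bg=frozenset({"sp4", "sp5"}),
            max_fg_gaps=2, max_fg_missing=2,
        )
        aln = _aln({"sp1": "-", "sp2": "-", "sp3": "X", "sp4": "V", "sp5": "V"})
        prof = profile_column(aln, 0, groups)
        assert classify_column(prof, groups) is None


class TestPositionPvalue:
    def test_exact_enumeration(self, aass_alignment, four_species_groups):
        p = position_pvalue(aass_alignment, 0, four_species_groups, mode="exact")
        assert p == pytest.approx(2 / 6)

    def test_invariant_column_has_zero_noise(self, four_species_groups):
        aln = _aln({"sp1": "A", "sp2": "A", "sp3": "A", "sp4": "A"})
        assert position_pvalue(aln, 0, four_species_groups, mode="exact") == 0.0

    def test_montecarlo_near_exact(self, aass_alignment, four_species_groups):
        cycles = 10_000
        p = position_pvalue(
            aass_alignment, 0, four_species_groups, mode="mc", cycles=cycles, seed=3
        )
        se = np.sqrt((1 / 3) * (2 / 3) / cycles)
        assert abs(p - 1 / 3) < 3 * se + 1 / cycles

    def test_montecarlo_never_zero(self, four_species_groups):
        aln = _aln({"sp1": "A", "sp2": "A", "sp3": "A", "sp4": "A"})
        p = position_pvalue(aln, 0, four_species_groups, mode="mc", cycles=100, seed=0)
        assert 0 < p <= 1

    def test_auto_mode_enumerates_small_pools(self, aass_alignment, four_species_groups):
        assert position_pvalue(aass_alignment, 0, four_species_groups, mode="auto") == 2 / 6

    def test_pool_too_small_rejected(self, aass_alignment, four_species_groups):
        with pytest.raises(ValueError, match="pool"):
            position_pvalue(
                aass_alignment, 0, four_species_groups, pool=["sp1", "sp2", "sp3"]
            )


class TestDiscover:
    def test_single_caas_column_reported(self, four_species_groups):
        aln = _aln({"sp1": "AAL", "sp2": "AAL", "sp3": "AAV", "sp4": "ASV"})
        records = discover(aln, four_species_groups, pvalue_mode="off")
        assert [(r.position, r.pattern) for r in records] == [(2, Pattern.P1)]

    def test_pattern_filter(self, four_species_groups):
        aln = _aln({"sp1": "L", "sp2": "L", "sp3": "V", "sp4": "I"})  # P2 only
        assert discover(aln, four_species_groups, patterns={Pattern.P1},
                        pvalue_mode="off") == []

    def test_invariant_alignment_yields_nothing(self, four_species_groups):
        aln = _aln({sp: "LLLL" for sp in ("sp1", "sp2", "sp3", "sp4")})
        assert discover(aln, four_species_groups, pvalue_mode="off") == []

    def test_matches_brute_force_on_random_alignments(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n_sp = int(rng.integers(4, 9))
            aln = random_alignment(
                seed=int(rng.integers(2**31)), n_species=n_sp,
                n_columns=int(rng.integers(20, 51)),
                alphabet="ACDEF", missing_rate=0.05,
            )
            names = sorted(aln.sequences)
            groups = DiscoveryGroups(fg=frozenset(names[:2]), bg=frozenset(names[2:4]))
            got = {(r.position, r.pattern.value)
                   for r in discover(aln, groups, pvalue_mode="off")}
            assert got == brute_force_caas(aln, groups)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1),
       n_species=st.integers(4, 8),
       n_columns=st.integers(5, 30))
def test_swapping_groups_maps_p2_to_p3(seed, n_species, n_columns):
    """FG/BG swap preserves P1 and no-CAAS and exchanges P2 with P3."""
    aln = random_alignment(seed, n_species, n_columns, alphabet="ACDE")
    names = sorted(aln.sequences)
    groups = DiscoveryGroups(fg=frozenset(names[:2]), bg=frozenset(names[2:4]))
    swapped = DiscoveryGroups(fg=groups.bg, bg=groups.fg)
    fwd = {r.position: r.pattern for r in discover(aln, groups, pvalue_mode="off")}
    rev = {r.position: r.pattern for r in discover(aln, swapped, pvalue_mode="off")}
    mapping = {Pattern.P1: Pattern.P1, Pattern.P2: Pattern.P3, Pattern.P3: Pattern.P2}
    assert rev == {pos: mapping[pat] for pos, pat in fwd.items()}


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), tol=st.integers(0, 1))
def test_raising_tolerances_grows_detection_set(seed, tol):
    """Detected positions are monotone in the missing-data tolerances."""
    aln = random_alignment(seed, 6, 30, alphabet="ACDE", missing_rate=0.15)
    names = sorted(aln.sequences)
    tight = DiscoveryGroups(
        fg=frozenset(names[:3]), bg=frozenset(names[3:6]),
        max_fg_missing=tol, max_bg_missing=tol, max_fg_gaps=tol, max_bg_gaps=tol,
    )
    loose = DiscoveryGroups(
        fg=tight.fg, bg=tight.bg,
        max_fg_missing=tol + 1, max_bg_missing=tol + 1,
        max_fg_gaps=tol + 1, max_bg_gaps=tol + 1,
    )
    pos_tight = {r.position for r in discover(aln, tight, pvalue_mode="off")}
    pos_loose = {r.position for r in discover(aln, loose, pvalue_mode="off")}
    assert pos_tight <= pos_loose


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_vectorized_classification_matches_scalar(seed):
    """The bitmask matrix classifier agrees with classify_chars everywhere."""
    aln = random_alignment(seed, 7, 40, alphabet="ACDEFG", missing_rate=0.1)
    names = sorted(aln.sequences)
    fg, bg = names[:3], names[3:6]
    codes = encode_alignment(aln, names)
    classes = classify_matrix(
        codes, fg_rows=[0, 1, 2], bg_rows=[3, 4, 5],
        max_fg_missing=1, max_bg_missing=1, max_fg_gaps=1, max_bg_gaps=1,
    )
    for col in range(aln.length):
        expected = classify_chars(
            [aln.sequences[sp][col] for sp in fg],
            [aln.sequences[sp][col] for sp in bg],
            max_fg_missing=1, max_bg_missing=1, max_fg_gaps=1, max_bg_gaps=1,
        )
        assert classes[col] == (0 if expected is None else int(expected.value[1]))
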