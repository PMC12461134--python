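import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermadapt.caas import (
    CAASRecord,
    CAASScan,
    detect_caas,
    scan_collection,
    trim_alignment,
    variability_filter,
)
from thermadapt.io import AlignedOrthogroup, RunConfig
from thermadapt.simulate import OrthogroupSimSpec, simulate_orthogroups

from conftest import FOUR_TAXA_ROLES, make_alignment


def brute_force_caas(aln, roles, scenario, max_missing):
    """Independent per-column reference: re-derives the convergence rule
    from first principles (explicit loops, no shared code with the
    implementation)."""
    fg_taxa = [t for t, r in roles.items() if r == "foreground"]
    bg_taxa = [t for t, r in roles.items() if r == "background"]
    hits = []
    for col in range(aln.length):
        fg_letters, bg_letters, missing = [], [], 0
        for t in fg_taxa:
            ch = aln.sequences[t][col]
            if ch in ("-", "X"):
                missing += 1
            else:
                fg_letters.append(ch)
        for t in bg_taxa:
            ch = aln.sequences[t][col]
            if ch in ("-", "X"):
                missing += 1
            else:
                bg_letters.append(ch)
        if not fg_letters or not bg_letters or missing > max_missing:
            continue
        fset, bset = set(fg_letters), set(bg_letters)
        if any(ch in bset for ch in fset):
            continue
        if scenario == 1 and not (len(fset) == 1 and len(bset) == 1):
            continue
        if scenario == 2 and not (len(fset) == 1 or len(bset) == 1):
            continue
        hits.append((col + 1, frozenset(fset), frozenset(bset)))
    return hits


class TestTrimAlignment:
    def test_column_above_threshold_removed(self, make_aln):
        # 4 taxa, middle column has 2 gaps: fraction 0.5 > 0.4
        aln = make_aln(["AAAA", "A-A-", "CCCC"])
        trim = trim_alignment(aln, max_gap_fraction=0.4)
        assert trim.alignment.length == 2
        assert trim.column_map == [0, 2]

    def test_threshold_one_is_identity(self, make_aln):
        aln = make_aln(["A-A-", "--C-"])
        trim = trim_alignment(aln, max_gap_fraction=1.0)
        assert trim.column_map == [0, 1]
        assert trim.alignment.sequences == aln.sequences

    def test_threshold_zero_on_gapfree_is_identity(self, make_aln):
        aln = make_aln(["AAAA", "CCCC", "DDDD"])
        trim = trim_alignment(aln, max_gap_fraction=0.0)
        assert trim.column_map == [0, 1, 2]

    def test_all_gap_alignment_yields_empty_trim(self):
        aln = AlignedOrthogroup("og", {"a": "--", "b": "--"})
        trim = trim_alignment(aln, max_gap_fraction=0.0)
        assert trim.column_map == []

    def test_column_map_strictly_increasing(self, make_aln):
        aln = make_aln(["AAAA", "A---", "CCCC", "G---", "TTTT"])
        trim = trim_alignment(aln, max_gap_fraction=0.5)
        assert all(b > a for a, b in
                   zip(trim.column_map, trim.column_map[1:]))


class TestVariabilityFilter:
    def test_invariant_alignment_unmasked(self, make_aln):
        aln = make_aln(["AAAA"] * 10)
        assert variability_filter(aln, window=5, max_distinct=3) == set()

    def test_window_one_masks_exactly_polymorphic_columns(self, make_aln):
        aln = make_aln(["AAAA", "ACAA", "GGGG", "WYAC"])
        masked = variability_filter(aln, window=1, max_distinct=1)
        assert masked == {1, 3}

    def test_hypervariable_stretch_fully_masked(self, make_aln):
        # 5 conserved columns, then 5 columns with 4 distinct residues each
        conserved = ["AAAA"] * 5
        variable = ["ACDE", "FGHI", "KLMN", "PQRS", "TVWY"]
        aln = make_aln(conserved + variable)
        masked = variability_filter(aln, window=5, max_distinct=3)
        assert set(range(5, 10)) <= masked
        assert 0 not in masked

    def test_gaps_not_counted_as_residues(self, make_aln):
        aln = make_aln(["A-A-", "A--C"])
        assert variability_filter(aln, window=1, max_distinct=1) == {1}


class TestDetectCaas:
    def test_strict_convergent_column_called(self, make_aln):
        aln = make_aln(["TTSS"])
        recs = detect_caas(aln, FOUR_TAXA_ROLES, scenario=1)
        assert len(recs) == 1
        assert recs[0].fg_residues == frozenset("T")
        assert recs[0].bg_residues == frozenset("S")
        assert recs[0].column_trimmed == 1

    def test_intersecting_sets_never_called(self, make_aln):
        aln = make_aln(["TSSS"])
        for scenario in (1, 2, 3):
            assert detect_caas(aln, FOUR_TAXA_ROLES, scenario=scenario) == []

    @pytest.mark.parametrize("column,scenario,expected", [
        ("TTSS", 1, 1),   # singleton vs singleton
        ("TASS", 1, 0),   # fg segregates: fails scenario 1
        ("TASS", 2, 1),   # ... but passes scenario 2 (bg fixed)
        ("TASE", 2, 0),   # both segregate: fails scenario 2
        ("TASE", 3, 1),   # ... passes scenario 3 (disjoint)
    ])
    def test_scenario_constraints(self, make_aln, column, scenario, expected):
        aln = make_aln([column])
        recs = detect_caas(aln, FOUR_TAXA_ROLES, scenario=scenario)
        assert len(recs) == expected

    def test_missing_data_respects_max_missing(self, make_aln):
        aln = make_aln(["T-SS", "TXSS"])
        assert detect_caas(aln, FOUR_TAXA_ROLES, scenario=3, max_missing=0) == []
        recs = detect_caas(aln, FOUR_TAXA_ROLES, scenario=3, max_missing=1)
        assert [r.column_trimmed for r in recs] == [1, 2]
        assert all(r.n_missing == 1 for r in recs)

    def test_group_empty_after_missing_removal_skipped(self, make_aln):
        aln = make_aln(["--SS"])
        # no error, just no record
        assert detect_caas(aln, FOUR_TAXA_ROLES, scenario=3, max_missing=2) == []

    def test_masked_columns_excluded(self, make_aln):
        aln = make_aln(["TTSS", "QQNN"])
        recs = detect_caas(aln, FOUR_TAXA_ROLES, scenario=1, masked={0})
        assert [r.column_trimmed for r in recs] == [2]

    def test_column_map_translates_to_original_coordinates(self, make_aln):
        aln = make_aln(["TTSS"])
        recs = detect_caas(aln, FOUR_TAXA_ROLES, scenario=1, column_map=[41])
        assert recs[0].column_original == 42

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            CAASRecord("og", 1, 1, frozenset("T"), frozenset("TS"), 3, 0)
        with pytest.raises(ValueError, match="non-empty"):
            CAASRecord("og", 1, 1, frozenset(), frozenset("S"), 3, 0)


# -- property tests against the brute-force oracle ------------------------

residue = st.sampled_from("ACDEFGHIKLX-")  # subalphabet incl. missing codes
small_alignment = st.lists(
    st.text(alphabet=residue, min_size=4, max_size=4),
    min_size=1, max_size=6,
).map(lambda cols: make_alignment(cols))


@settings(max_examples=300, derandomize=True)
@given(aln=small_alignment, scenario=st.sampled_from([1, 2, 3]),
       max_missing=st.integers(min_value=0, max_value=2))
def test_detector_matches_brute_force_oracle(aln, scenario, max_missing):
    recs = detect_caas(aln, FOUR_TAXA_ROLES, scenario=scenario,
                       max_missing=max_missing)
    got = [(r.column_trimmed, r.fg_residues, r.bg_residues) for r in recs]
    assert got == brute_force_caas(aln, FOUR_TAXA_ROLES, scenario, max_missing)


@settings(max_examples=200, derandomize=True)
@given(aln=small_alignment, max_missing=st.integers(min_value=0, max_value=2))
def test_scenario_monotonicity(aln, max_missing):
    """Stricter scenarios call a subset of looser ones' columns."""
    cols = {
        s: {r.column_trimmed for r in
            detect_caas(aln, FOUR_TAXA_ROLES, scenario=s,
                        max_missing=max_missing)}
        for s in (1, 2, 3)
    }
    assert cols[1] <= cols[2] <= cols[3]


@settings(max_examples=200, derandomize=True)
@given(aln=small_alignment, scenario=st.sampled_from([1, 2, 3]))
def test_group_swap_symmetry(aln, scenario):
    """Swapping roles yields the same columns with residue sets exchanged."""
    swapped = {t: {"foreground": "background",
                   "background": "foreground"}[r]
               for t, r in FOUR_TAXA_ROLES.items()}
    fwd = detect_caas(aln, FOUR_TAXA_ROLES, scenario=scenario)
    rev = detect_caas(aln, swapped, scenario=scenario)
    assert [(r.column_trimmed, r.fg_residues, r.bg_residues) for r in fwd] == \
           [(r.column_trimmed, r.bg_residues, r.fg_residues) for r in rev]


@settings(max_examples=100, derandomize=True)
@given(aln=small_alignment, scenario=st.sampled_from([1, 2, 3]),
       perm=st.permutations(["fg1", "fg2", "bg1", "bg2"]))
def test_permutation_invariance(aln, scenario, perm):
    """Reordering sequences within groups never changes the record set."""
    renamed = AlignedOrthogroup(
        aln.orthogroup_id,
        {perm[i]: aln.sequences[t]
         for i, t in enumerate(["fg1", "fg2", "bg1", "bg2"])},
    )
    # keep role multiset fixed: perm maps old slots to new names, but roles
    # come from FOUR_TAXA_ROLES, so this permutes membership within and
    # across groups only when roles agree; restrict to within-group swaps
    if {perm[0], perm[1]} != {"fg1", "fg2"}:
        return
    a = detect_caas(aln, FOUR_TAXA_ROLES, scenario=scenario)
    b = detect_caas(renamed, FOUR_TAXA_ROLES, scenario=scenario)
    assert [(r.column_trimmed, r.fg_residues, r.bg_residues) for r in a] == \
           [(r.column_trimmed, r.fg_residues, r.bg_residues) for r in b]


class TestScanCollection:
    def test_empty_collection(self, four_taxa_roles):
        table = scan_collection([], four_taxa_roles)
        assert len(table) == 0
        assert "orthogroup_id" in table.columns

    def test_invariant_orthogroups_yield_empty_table(self, four_taxa_roles):
        ogs = [make_alignment(["AAAA"] * 10, og_id=f"OG{i}") for i in range(3)]
        assert len(scan_collection(ogs, four_taxa_roles)) == 0

    def test_planted_truth_recovered_noise_free(self):
        spec = OrthogroupSimSpec(n_orthogroups=20, alignment_length=100,
                                 n_planted_caas=10, background_rate=0.0,
                                 gap_rate=0.0, seed=7)
        ogs, truth = simulate_orthogroups(spec)
        roles = {t.taxon_id: t.role for t in spec.taxa}
        cfg = RunConfig(scenario=1, max_missing=0)
        table = scan_collection(ogs, roles, cfg)
        found = set(zip(table.orthogroup_id, table.column_original))
        assert found == truth.positions
        assert len(table) == 10

    def test_output_sorted_by_orthogroup_then_column(self, four_taxa_roles):
        ogs = [make_alignment(["QQNN", "AAAA", "TTSS"], og_id="OGB"),
               make_alignment(["WWYY"], og_id="OGA")]
        table = scan_collection(ogs, four_taxa_roles)
        keys = list(zip(table.orthogroup_id, table.column_trimmed))
        assert keys == sorted(keys)

    def test_scan_wrapper_summary(self, four_taxa_roles):
        ogs = [make_alignment(["TTSS", "AAAA"], og_id="OG1")]
        results = CAASScan(ogs, four_taxa_roles).run()
        assert results.n_caas == 1
        assert "1 convergent column" in results.summary()
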