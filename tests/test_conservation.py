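"""Quality filtering, bait-anchored merging, and presence/absence mapping."""

import numpy as np
import pytest

from mtoc_atlas.conservation import (anchor_orthogroups, binarize, filter_by_busco,
                                     merge_all, merge_and_filter, render_matrix,
                                     rollup_clades)
from mtoc_atlas.orthogroups import BaitCluster, OrthogroupTable
from mtoc_atlas.simulate import gen_proteome_set, truth_presence_matrix

from conftest import CLADE_ORDER, OUTGROUPS, ROSTER


# -- BUSCO filter ------------------------------------------------------------

def test_busco_removal_is_strictly_less_than():
    assert filter_by_busco({"A": 95, "B": 79.9, "C": 80}, 80) == {"A", "C"}


def test_busco_threshold_zero_keeps_everyone():
    scores = {"A": 0.0, "B": 50.0}
    assert filter_by_busco(scores, 0) == {"A", "B"}


def test_busco_all_removed_warns():
    with pytest.warns(UserWarning, match="retained no species"):
        assert filter_by_busco({"A": 99.0, "B": 42.0}, 100) == set()


def test_busco_missing_score_is_an_error():
    with pytest.raises(ValueError, match="missing a BUSCO score.*'C'"):
        filter_by_busco({"A": 90.0}, 80, species=["A", "C"])


# -- anchoring and merging ---------------------------------------------------

@pytest.fixture()
def tiny_table():
    return OrthogroupTable(
        species=["Hs", "Sc", "Rg"],
        groups={"OG1": {"Hs": ["P1"], "Rg": ["R1"]},
                "OG3": {"Hs": ["P9"], "Sc": ["P2"], "Rg": ["R2"]},
                "OG7": {"Sc": ["S7"], "Rg": ["R7", "R8"]}},
        protein_lengths={"P1": 200, "R1": 300, "P9": 400, "P2": 300,
                         "R2": 149, "S7": 260, "R7": 150, "R8": 90})


def test_anchor_finds_every_orthogroup_with_a_bait_member(tiny_table):
    bait = BaitCluster("f", "distal appendages", [("Hs", "P1", 200), ("Sc", "S7", 260)])
    assert anchor_orthogroups(bait, tiny_table) == {"OG1", "OG7"}


def test_anchor_unplaced_bait_yields_empty_set(tiny_table):
    bait = BaitCluster("f", "distal appendages", [("Hs", "NOPE", 100)])
    assert anchor_orthogroups(bait, tiny_table) == set()


def test_anchor_two_baits_in_one_orthogroup(tiny_table):
    bait = BaitCluster("f", "distal appendages", [("Hs", "P9", 400), ("Sc", "P2", 300)])
    assert anchor_orthogroups(bait, tiny_table) == {"OG3"}


def test_merge_filter_threshold_is_strict(tiny_table):
    # bait lengths {200, 300, 400} -> mean 300, threshold 150
    bait = BaitCluster("f", "distal appendages",
                       [("Hs", "P1", 200), ("Sc", "P2", 300), ("Hs", "P9", 400)])
    merged = merge_and_filter(bait, {"OG3", "OG7"}, tiny_table)
    assert merged.length_threshold == 150
    kept = {p for prots in merged.members.values() for p in prots}
    dropped = {p for prots in merged.filtered_out.values() for p in prots}
    assert "R2" in dropped and "R8" in dropped      # 149 and 90 are < 150
    assert "R7" in kept                              # exactly 150 is retained
    assert kept | dropped == {"P9", "P2", "R2", "S7", "R7", "R8"}


def test_merge_union_and_count_conservation(tiny_table):
    bait = BaitCluster("f", "distal appendages", [("Hs", "P1", 200), ("Sc", "S7", 260)])
    anchored = anchor_orthogroups(bait, tiny_table)
    merged = merge_and_filter(bait, anchored, tiny_table)
    union = sum(len(ps) for og in anchored for ps in tiny_table.groups[og].values())
    assert union == merged.n_members + merged.n_filtered


def test_merge_empty_anchored_gives_empty_members(tiny_table):
    bait = BaitCluster("f", "distal appendages", [("Hs", "NOPE", 100)])
    merged = merge_and_filter(bait, set(), tiny_table)
    assert merged.members == {} and merged.n_filtered == 0


def test_merging_is_idempotent(tiny_table):
    """Re-anchoring on a merged orthogroup's own members reproduces membership."""
    bait = BaitCluster("f", "distal appendages", [("Hs", "P1", 200), ("Sc", "S7", 260)])
    merged = merge_and_filter(bait, anchor_orthogroups(bait, tiny_table), tiny_table)
    rebait = BaitCluster("f", "distal appendages",
                         [(sp, p, tiny_table.length_of(p))
                          for sp in merged.members for p in sorted(merged.members[sp])])
    # the second pass uses the merged members' own mean length, so re-filtering
    # with the same fraction must not remove anything already above threshold
    again = merge_and_filter(rebait, anchor_orthogroups(rebait, tiny_table), tiny_table,
                             fraction=merged.length_threshold / rebait.mean_length)
    assert again.members == merged.members


# -- binarize / rollup -------------------------------------------------------

def test_binarize_marks_only_species_with_members(tiny_table):
    bait = BaitCluster("f", "distal appendages", [("Hs", "P1", 200)])
    merged = merge_and_filter(bait, {"OG1"}, tiny_table)
    m = binarize([merged], tiny_table.species)
    assert m.data.loc["f"].tolist() == [True, False, True]   # Hs, Sc, Rg


def test_binarize_empty_row_is_all_false(tiny_table):
    bait = BaitCluster("f", "distal appendages", [("Hs", "NOPE", 100)])
    merged = merge_and_filter(bait, set(), tiny_table)
    m = binarize([merged], tiny_table.species)
    assert not m.data.loc["f"].any()


def test_binarize_unknown_member_species_is_error(tiny_table):
    bait = BaitCluster("f", "distal appendages", [("Hs", "P1", 200)])
    merged = merge_and_filter(bait, {"OG1"}, tiny_table)
    with pytest.raises(ValueError, match="not in.*species list"):
        binarize([merged], ["Hs", "Sc"])


def test_rollup_or_semantics_and_idempotence(tiny_table):
    bait = BaitCluster("f", "distal appendages", [("Hs", "P1", 200)])
    merged = merge_and_filter(bait, {"OG1"}, tiny_table)
    m = binarize([merged], tiny_table.species)
    clades = rollup_clades(m, {"Sc": "yeasts", "Rg": "chytrids"},
                           ["yeasts", "chytrids"], outgroups=["Hs"])
    assert clades.data.loc["f"].tolist() == [True, False, True]
    # identity rollup is a no-op
    ident = rollup_clades(m, {sp: sp for sp in m.data.columns}, list(m.data.columns))
    assert (ident.data.values == m.data.values).all()


def test_rollup_empty_clade_is_error(tiny_table):
    bait = BaitCluster("f", "distal appendages", [("Hs", "P1", 200)])
    m = binarize([merge_and_filter(bait, {"OG1"}, tiny_table)], tiny_table.species)
    with pytest.raises(ValueError, match="zero species"):
        rollup_clades(m, {"Sc": "yeasts", "Rg": "yeasts"},
                      ["yeasts", "ghosts"], outgroups=["Hs"])


# -- planted-truth recovery and monotonicity --------------------------------

def run_conservation(sim, busco_threshold=80.0, fraction=0.5):
    retained = filter_by_busco(sim.busco_scores, busco_threshold,
                               species=sim.table.species)
    table = sim.table.restrict_species(sorted(retained))
    merged = merge_all(sim.baits, table, fraction=fraction)
    m = binarize(merged, table.species)
    clades = rollup_clades(
        m, {sp: cl for sp, cl in sim.roster.items() if cl != "outgroup"},
        CLADE_ORDER, outgroups=[s for s in OUTGROUPS if s in retained])
    return retained, merged, clades


def test_planted_truth_recovered_exactly_with_splits_and_fragments(messy_sim):
    retained, merged, clades = run_conservation(messy_sim)
    expected = truth_presence_matrix(messy_sim.truths, messy_sim.roster, CLADE_ORDER,
                                     outgroups=OUTGROUPS, retained_species=retained)
    assert clades.data.astype(bool).equals(expected.astype(bool))


def test_fragments_alone_never_create_presence(messy_sim):
    _, merged, _ = run_conservation(messy_sim)
    frag_proteins = {p for t in messy_sim.truths for p in t.fragment_members}
    for m in merged:
        for sp, prots in m.members.items():
            assert not prots & frag_proteins, "a fragment survived the length filter"


def test_monotonicity_of_thresholds_over_random_instances():
    """Loosening either threshold never removes proteins or species."""
    rng = np.random.default_rng(42)
    for trial in range(25):
        sim = gen_proteome_set(ROSTER, n_families=6,
                               split_prob=float(rng.uniform(0, 0.6)),
                               fragment_prob=float(rng.uniform(0, 0.6)),
                               seed=int(rng.integers(2**31)),
                               bait_species=list(OUTGROUPS),
                               busco_fail={"Neo3": float(rng.uniform(40, 79))})
        strict_sp = filter_by_busco(sim.busco_scores, 80.0)
        loose_sp = filter_by_busco(sim.busco_scores, 50.0)
        assert strict_sp <= loose_sp
        table = sim.table.restrict_species(sorted(strict_sp))
        for bait in sim.baits:
            anchored = anchor_orthogroups(bait, table)
            strict = merge_and_filter(bait, anchored, table, fraction=0.5)
            loose = merge_and_filter(bait, anchored, table, fraction=0.25)
            for sp, prots in strict.members.items():
                assert prots <= loose.members.get(sp, set())


def test_disjoint_baits_disjoint_rows(clean_sim):
    merged = merge_all(clean_sim.baits, clean_sim.table)
    seen: set[str] = set()
    for m in merged:
        mine = {p for prots in m.members.values() for p in prots}
        assert not (mine & seen)
        seen |= mine


def test_overlapping_baits_warn():
    table = OrthogroupTable(species=["A"], groups={"OG1": {"A": ["p1", "p2"]}},
                            protein_lengths={"p1": 100, "p2": 100})
    b1 = BaitCluster("f1", "distal appendages", [("A", "p1", 100)])
    b2 = BaitCluster("f2", "distal appendages", [("A", "p2", 100)])
    with pytest.warns(UserWarning, match="anchored by both"):
        merge_all([b1, b2], table)


def test_render_matrix_is_deterministic(tmp_path, clean_sim):
    _, _, clades = run_conservation(clean_sim)
    p1 = render_matrix(clades, tmp_path / "a.svg")
    p2 = render_matrix(clades, tmp_path / "b.svg")
    assert p1.read_bytes() == p2.read_bytes()


def test_render_matrix_unknown_category_is_error(tmp_path, clean_sim):
    _, _, clades = run_conservation(clean_sim)
    clades.categories[next(iter(clades.categories))] = "mystery"
    with pytest.raises(ValueError, match="unknown category"):
        render_matrix(clades, tmp_path / "x.svg")
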