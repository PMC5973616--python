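"""Hierarchy rollup, spectrum-score formula and recommendation ranking."""

import random

import pytest

from spicemine.candidates import CandidateInstance
from spicemine.ontology import DiseaseOntology
from spicemine.relation import NEGATIVE, NO_ASSOCIATION, POSITIVE
from spicemine.scoring import (
    AssociationTable,
    SpectrumReport,
    aggregate,
    category_spectrum,
    recommend,
    relative_benevolence,
    rollup,
    spectrum_score,
)


def _ontology(spec: dict[str, list[list[int]]] | None = None, n_categories=4,
              subcats=2, diseases=2) -> DiseaseOntology:
    """Uniform ontology unless an explicit per-category disease layout
    (category -> list of per-subcategory disease counts) is given."""
    onto = DiseaseOntology()
    layout = spec or {
        f"C{i:02d}": [diseases] * subcats for i in range(1, n_categories + 1)
    }
    counter = 0
    for cat, subcat_sizes in layout.items():
        counter += 1
        onto.add(f"N{counter}", f"cat {cat}", [cat])
        for j, n_dis in enumerate(subcat_sizes, 1):
            counter += 1
            sub = f"{cat}.{j:03d}"
            onto.add(f"N{counter}", f"sub {sub}", [sub])
            for k in range(1, n_dis + 1):
                counter += 1
                onto.add(f"D{cat}.{j}.{k}", f"dis {sub}.{k}", [f"{sub}.{k:03d}"])
    return onto


def _full_table(onto: DiseaseOntology, spice="S0", polarity=POSITIVE):
    table = AssociationTable()
    for node_id in onto.nodes:
        if node_id.startswith("D"):
            table.add(spice, node_id, polarity, f"ev-{node_id}")
    return table


# ---------------------------------------------------------------------------
# rollup
# ---------------------------------------------------------------------------


def test_rollup_three_level_number():
    onto = DiseaseOntology()
    onto.add("M1", "Diabetes Mellitus, Type 2", ["C19.246.300"])
    cats, subs, level3 = rollup("M1", onto)
    assert cats == {"C19"}
    assert subs == {"C19.246"}
    assert level3 == {"C19.246.300"}


def test_rollup_category_only_number():
    onto = DiseaseOntology()
    onto.add("M1", "Endocrine System Diseases", ["C19"])
    cats, subs, level3 = rollup("M1", onto)
    assert cats == {"C19"}
    assert subs == set() and level3 == set()


def test_rollup_union_over_multiple_tree_numbers():
    onto = DiseaseOntology()
    onto.add("M1", "crossover disease", ["C01.100.200", "C05.300.400"])
    cats, subs, _ = rollup("M1", onto)
    assert cats == {"C01", "C05"}
    assert subs == {"C01.100", "C05.300"}


def test_rollup_truncates_deep_numbers():
    onto = DiseaseOntology()
    onto.add("M1", "deep disease", ["C01.100.200.300.400"])
    cats, subs, level3 = rollup("M1", onto)
    assert (cats, subs, level3) == ({"C01"}, {"C01.100"}, {"C01.100.200"})


def test_rollup_unknown_id_raises():
    with pytest.raises(KeyError):
        rollup("nope", DiseaseOntology())


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _classified(spice, disease, label, n=1):
    return [
        (
            CandidateInstance(
                f"{spice}:{disease}:{i}", "d", i, spice, disease,
                ["SPICE", "DISEASE"],
            ),
            label,
        )
        for i in range(n)
    ]


def test_aggregate_groups_evidence():
    table = aggregate(_classified("S0", "M1", POSITIVE, n=3))
    assert len(table) == 1
    assert len(table.rows[("S0", "M1", POSITIVE)]) == 3


def test_aggregate_discards_no_association():
    assert len(aggregate(_classified("S0", "M1", NO_ASSOCIATION, n=5))) == 0


def test_aggregate_override_drops_row():
    classified = _classified("S0", "M1", NEGATIVE) + _classified(
        "S0", "M2", POSITIVE
    )
    table = aggregate(classified, overrides=[("S0", "M1", NEGATIVE, "drop")])
    assert set(table.rows) == {("S0", "M2", POSITIVE)}


def test_aggregate_override_flips_polarity():
    table = aggregate(
        _classified("S0", "M1", NEGATIVE),
        overrides=[("S0", "M1", NEGATIVE, "flip")],
    )
    assert set(table.rows) == {("S0", "M1", POSITIVE)}


# ---------------------------------------------------------------------------
# spectrum score
# ---------------------------------------------------------------------------


def test_spice_without_associations_scores_zero():
    onto = _ontology()
    assert spectrum_score(AssociationTable(), onto, "S0", POSITIVE) == 0.0


def test_full_presence_27_categories_reaches_729():
    onto = _ontology(n_categories=27, subcats=3, diseases=1)
    table = _full_table(onto)
    assert spectrum_score(table, onto, "S0", POSITIVE) == pytest.approx(729.0)


def test_breadth_beats_depth():
    """Half the subcategories of every category outscores all
    subcategories of half the categories."""
    onto = _ontology(n_categories=4, subcats=2, diseases=1)
    # all subcats of 2 categories
    deep = AssociationTable()
    for cat in ("C01", "C02"):
        for j in (1, 2):
            deep.add("S0", f"D{cat}.{j}.1", POSITIVE, "e")
    # one of two subcats of all 4 categories
    broad = AssociationTable()
    for cat in ("C01", "C02", "C03", "C04"):
        broad.add("S0", f"D{cat}.1.1", POSITIVE, "e")
    deep_score = spectrum_score(deep, onto, "S0", POSITIVE)
    broad_score = spectrum_score(broad, onto, "S0", POSITIVE)
    assert deep_score == pytest.approx(4.0)  # 2 * (1 + 1)
    assert broad_score == pytest.approx(8.0)  # 4 * (4 * 1/2)
    assert broad_score > deep_score


def test_relative_benevolence_is_exact_difference():
    assert relative_benevolence(10.0, 4.0) == 6.0
    assert relative_benevolence(3.5, 3.5) == 0.0


def test_polarities_scored_independently():
    onto = _ontology(n_categories=2, subcats=2, diseases=1)
    table = AssociationTable()
    table.add("S0", "DC01.1.1", POSITIVE, "e1")
    table.add("S0", "DC01.1.1", NEGATIVE, "e2")  # same pair, both polarities
    pos = spectrum_score(table, onto, "S0", POSITIVE)
    neg = spectrum_score(table, onto, "S0", NEGATIVE)
    assert pos == neg == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# category spectrum / tradeoff
# ---------------------------------------------------------------------------


def test_category_spectrum_no_associations_is_zero():
    onto = _ontology()
    assert category_spectrum(AssociationTable(), onto, "S0", "C01", POSITIVE) == 0.0


def test_category_spectrum_hand_computed():
    # subcat sizes (2, 4, 5); spice hits 1 of 2 in subcat 1, 5 of 5 in subcat 3
    onto = _ontology(spec={"C01": [2, 4, 5]})
    table = AssociationTable()
    table.add("S0", "DC01.1.1", POSITIVE, "e")
    for k in range(1, 6):
        table.add("S0", f"DC01.3.{k}", POSITIVE, "e")
    omega = category_spectrum(table, onto, "S0", "C01", POSITIVE)
    assert omega == pytest.approx(2 * (0.5 + 1.0))


def test_category_full_coverage_reaches_squared_bound():
    onto = _ontology(spec={"C01": [3, 2, 4]})
    table = _full_table(onto)
    omega = category_spectrum(table, onto, "S0", "C01", POSITIVE)
    assert omega == pytest.approx(9.0)  # (d_i)^2 with d_i = 3


def test_category_spectrum_unknown_category():
    with pytest.raises(KeyError):
        category_spectrum(AssociationTable(), _ontology(), "S0", "C99", POSITIVE)


# ---------------------------------------------------------------------------
# invariants (randomized)
# ---------------------------------------------------------------------------


def _random_table(rng, onto, spices=("S0", "S1")):
    table = AssociationTable()
    leaves = [n for n in onto.nodes if n.startswith("D")]
    for _ in range(rng.randint(0, 40)):
        table.add(
            rng.choice(spices),
            rng.choice(leaves),
            rng.choice([POSITIVE, NEGATIVE]),
            f"e{rng.randint(0, 9)}",
        )
    return table


def test_bounds_and_monotonicity_random_tables():
    rng = random.Random(17)
    onto = _ontology(n_categories=5, subcats=3, diseases=2)
    leaves = [n for n in onto.nodes if n.startswith("D")]
    d_sq = onto.n_categories**2
    for _ in range(40):
        table = _random_table(rng, onto)
        before = spectrum_score(table, onto, "S0", POSITIVE)
        assert 0.0 <= before <= d_sq + 1e-9
        # monotone under row insertion
        table.add("S0", rng.choice(leaves), POSITIVE, "new")
        after = spectrum_score(table, onto, "S0", POSITIVE)
        assert after >= before - 1e-12


def test_score_maximal_iff_full_presence():
    onto = _ontology(n_categories=5, subcats=3, diseases=2)
    table = _full_table(onto)
    assert spectrum_score(table, onto, "S0", POSITIVE) == pytest.approx(25.0)


def test_score_invariant_to_duplicate_evidence():
    rng = random.Random(23)
    onto = _ontology(n_categories=4, subcats=2, diseases=2)
    table = _random_table(rng, onto)
    if not table.rows:
        table.add("S0", "DC01.1.1", POSITIVE, "e")
    before = spectrum_score(table, onto, "S0", POSITIVE)
    (spice, disease, pol) = next(iter(table.rows))
    for i in range(5):
        table.add(spice, disease, pol, f"dup{i}")
    assert spectrum_score(table, onto, "S0", POSITIVE) == before


def test_depth_truncation_equivalence():
    """Scores from a depth-5 ontology equal those from its depth-3
    truncation."""
    deep = DiseaseOntology()
    deep.add("NC", "cat", ["C01"])
    deep.add("NS", "sub", ["C01.100"])
    deep.add("D1", "disease one", ["C01.100.200.300.400"])
    deep.add("D2", "disease two", ["C01.100.500"])
    shallow = DiseaseOntology()
    shallow.add("NC", "cat", ["C01"])
    shallow.add("NS", "sub", ["C01.100"])
    shallow.add("D1", "disease one", ["C01.100.200"])
    shallow.add("D2", "disease two", ["C01.100.500"])
    table = AssociationTable()
    table.add("S0", "D1", POSITIVE, "e1")
    table.add("S0", "D2", POSITIVE, "e2")
    assert spectrum_score(table, deep, "S0", POSITIVE) == spectrum_score(
        table, shallow, "S0", POSITIVE
    )
    assert category_spectrum(table, deep, "S0", "C01", POSITIVE) == category_spectrum(
        table, shallow, "S0", "C01", POSITIVE
    )


# ---------------------------------------------------------------------------
# recommendations
# ---------------------------------------------------------------------------


def test_recommend_orders_by_tradeoff():
    onto = _ontology(n_categories=2, subcats=2, diseases=2)
    table = AssociationTable()
    # S0 covers both subcats of C01 positively; S1 covers one, plus a negative
    for j in (1, 2):
        for k in (1, 2):
            table.add("S0", f"DC01.{j}.{k}", POSITIVE, "e")
    table.add("S1", "DC01.1.1", POSITIVE, "e")
    table.add("S1", "DC01.2.1", NEGATIVE, "e")
    report = SpectrumReport.compute(table, onto)
    ranked = recommend(report, "C01")
    assert [r[0] for r in ranked] == ["S0", "S1"]
    assert ranked[0][1] > ranked[1][1]
    assert not ranked[0][2]


def test_recommend_flags_net_negative_spice():
    onto = _ontology(n_categories=1, subcats=2, diseases=2)
    table = AssociationTable()
    table.add("S0", "DC01.1.1", NEGATIVE, "e")
    report = SpectrumReport.compute(table, onto)
    (entry,) = recommend(report, "C01")
    assert entry[0] == "S0" and entry[2] is True


def test_recommend_unknown_category():
    onto = _ontology(n_categories=1)
    table = AssociationTable()
    table.add("S0", "DC01.1.1", POSITIVE, "e")
    report = SpectrumReport.compute(table, onto)
    with pytest.raises(KeyError):
        recommend(report, "C99")


def test_single_spice_ranks_first():
    onto = _ontology(n_categories=1)
    table = AssociationTable()
    table.add("S0", "DC01.1.1", POSITIVE, "e")
    report = SpectrumReport.compute(table, onto)
    assert recommend(report, "C01")[0][0] == "S0"
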