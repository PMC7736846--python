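import pytest

from slitrobo import docking
from slitrobo.fixtures import load_docking_fixture, load_table4_frame
from slitrobo.records import (
    CountClass,
    DockComparison,
    EnergyClass,
    Grade,
    RmsdClass,
    ScoredComplex,
    VariantRecord,
)


@pytest.mark.parametrize("param,wt,mut,expected", [
    ("free_energy", -12.3, -10.1, EnergyClass.WEAKENING),
    ("free_energy", -10.1, -12.3, EnergyClass.STRENGTHENING),
    ("free_energy", -12.0, -12.0, EnergyClass.NEUTRAL),
    ("binding_affinity", -8.0, -9.5, EnergyClass.STRENGTHENING),
    ("solvation", -6.0, -4.0, EnergyClass.WEAKENING),
    ("hbond", 7, 9, CountClass.INCREASED),
    ("hbond", 9, 7, CountClass.DECREASED),
    ("vdw", 150, 150, CountClass.NEUTRAL),
    ("saltbridge", 3, 0, CountClass.DECREASED),
])
def test_delta_classification_orientation(param, wt, mut, expected):
    assert docking.classify_delta(param, wt, mut) is expected


def test_unknown_parameter_is_an_error():
    with pytest.raises(ValueError, match="unknown"):
        docking.classify_delta("torsion", 0.0, 1.0)


@pytest.mark.parametrize("rmsd,mean,expected", [
    (2.5, 2.0, RmsdClass.ABOVE_MEAN),
    (2.0, 2.0, RmsdClass.EQUAL_MEAN),
    (1.0, 2.0, RmsdClass.BELOW_MEAN),
])
def test_rmsd_classification(rmsd, mean, expected):
    assert docking.rmsd_class(rmsd, mean) is expected


def test_negative_rmsd_is_an_error():
    with pytest.raises(ValueError):
        docking.rmsd_class(-0.1, 2.0)


def _complex(total_pattern, category="CAT", variant="A10V", gene="G",
             partner="P", rmsd=None):
    energies = {0: "neutral", 1: "strengthening", 2: "weakening"}
    counts = {0: "neutral", 1: "increased", 2: "decreased"}
    rmsds = {0: "equal_mean", 1: "below_mean", 2: "above_mean"}
    comparison = DockComparison(
        free_energy_class=energies[total_pattern[0]],
        binding_affinity_class=energies[total_pattern[1]],
        solvation_class=energies[total_pattern[2]],
        hbond_class=counts[total_pattern[3]],
        vdw_class=counts[total_pattern[4]],
        saltbridge_class=counts[total_pattern[5]],
        rmsd_class=rmsds[total_pattern[6]],
        rmsd=rmsd)
    return docking.score_docked_complex(
        VariantRecord.from_protein_change(gene, variant), comparison, category,
        wild_type_partner=partner)


def test_all_neutral_complex_scores_zero():
    assert _complex((0, 0, 0, 0, 0, 0, 0)).total_score == 0


def test_worst_case_complex_scores_fourteen():
    assert _complex((2, 2, 2, 2, 2, 2, 2)).total_score == 14


def test_published_worked_examples():
    y323h = _complex((2, 2, 2, 2, 1, 2, 2))
    assert y323h.total_score == 13
    s352l = _complex((2, 2, 2, 2, 2, 2, 2))
    assert s352l.total_score == 14


def test_category_mean_and_grading():
    members = [_complex((2, 2, 2, 2, 1, 2, 2), variant=f"A{10 + i}V")
               for i in range(2)]           # totals 13
    members += [_complex((0, 0, 0, 1, 0, 0, 0), variant=f"A{20 + i}V")
                for i in range(2)]          # totals 1
    summaries = docking.grade_all(members)
    summary = summaries["CAT"]
    assert summary.mean_total_score == pytest.approx(7.0)
    assert [c.grade for c in members] == [
        Grade.MORE_DISRUPTING, Grade.MORE_DISRUPTING,
        Grade.LESS_DISRUPTING, Grade.LESS_DISRUPTING]
    assert summary.n_more == 2 and summary.n_less == 2


def test_tie_at_the_mean_is_less_disrupting_with_flag():
    members = [_complex((1, 0, 0, 0, 0, 0, 0), variant=f"A{10 + i}V")
               for i in range(3)]  # all totals 1 -> mean 1
    docking.grade_all(members)
    assert all(c.grade is Grade.LESS_DISRUPTING and c.tie_flag for c in members)


def test_single_complex_mean_is_its_total():
    summary = docking.summarize_category([_complex((2, 2, 0, 1, 1, 1, 1))], "CAT")
    assert summary.mean_total_score == pytest.approx(8.0)


def test_grade_partition_is_exhaustive_and_consistent_on_fixture():
    complexes = load_docking_fixture()
    summaries = docking.grade_all(complexes)
    for category, summary in summaries.items():
        members = [c for c in complexes if c.category == category]
        assert summary.n_more + summary.n_less == summary.n_complexes == len(members)
        for c in members:
            if c.total_score > summary.mean_total_score:
                assert c.grade is Grade.MORE_DISRUPTING
            elif c.total_score < summary.mean_total_score:
                assert c.grade is Grade.LESS_DISRUPTING


def test_grade_partition_is_shift_invariant():
    """Adding a constant to every total leaves the partition unchanged."""
    base = [(2, 2, 2, 2, 1, 2, 2), (2, 2, 2, 0, 1, 1, 1),
            (0, 0, 0, 1, 0, 0, 0), (1, 1, 1, 0, 0, 0, 0)]
    shifted = [(2, 2, 2, 2, 1, 2, 2), (2, 2, 2, 1, 1, 1, 1),
               (0, 0, 1, 1, 0, 0, 0), (1, 1, 1, 1, 0, 0, 0)]  # +1 on each
    graded_base = [_complex(p, variant=f"A{10 + i}V") for i, p in enumerate(base)]
    graded_shift = [_complex(p, variant=f"A{10 + i}V") for i, p in enumerate(shifted)]
    docking.grade_all(graded_base)
    docking.grade_all(graded_shift)
    assert [c.grade for c in graded_base] == [c.grade for c in graded_shift]


def test_category_mismatch_is_an_error():
    from slitrobo.records import CategorySummary
    c = _complex((0, 0, 0, 0, 0, 0, 0))
    other = CategorySummary(category="OTHER", n_complexes=1,
                            mean_total_score=1.0, n_more=0, n_less=1)
    with pytest.raises(ValueError):
        docking.grade_complex(c, other)


def test_fixture_grades_match_printed_outcomes():
    complexes = load_docking_fixture()
    docking.grade_all(complexes)
    printed = load_table4_frame()["printed_outcome"]
    for c, outcome in zip(complexes, printed):
        expected = (Grade.MORE_DISRUPTING if outcome == "More disrupting"
                    else Grade.LESS_DISRUPTING)
        assert c.grade is expected, c.variant


def test_disruptor_counts_merge_aliases_and_filter_partners():
    complexes = load_docking_fixture()
    docking.grade_all(complexes)
    assert docking.count_high_disruptors(complexes, "ROBO1", "SLIT2") == 6
    assert docking.count_high_disruptors(complexes, "ROBO4", "SLIT2") == 5
    assert docking.count_high_disruptors(complexes, "SLIT2", "ROBO1") == 17
    assert docking.count_high_disruptors(complexes, "SLIT2", "ROBO4") == 13
    assert docking.count_high_disruptors([], "ROBO1", "SLIT2") == 0
    # the alias W397C resolves to the canonical W367C name
    assert docking.canonical_variant_name("ROBO4", "W397C") == "W367C"
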