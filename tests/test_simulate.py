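import numpy as np
import pandas as pd
import pytest

from slitrobo import docking, sequence, structure, tables
from slitrobo.geometry import compare_wt_mut
from slitrobo.records import Grade
from slitrobo.simulate import (
    SimulationConfig,
    build_helix,
    generate_annotation_table,
    generate_dock_table,
    generate_toy_complex,
    write_tsv,
)


def test_generators_are_deterministic_for_a_fixed_seed(tmp_path):
    config = SimulationConfig(seed=42)
    for generator in (generate_annotation_table, generate_dock_table):
        first, _ = generator(config)
        second, _ = generator(config)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_tsv(first, a)
        write_tsv(second, b)
        assert a.read_bytes() == b.read_bytes()
    wt1, mut1, _ = generate_toy_complex(config, "bury_site")
    wt2, mut2, _ = generate_toy_complex(config, "bury_site")
    assert np.array_equal(wt1.coords, wt2.coords)
    assert np.array_equal(mut1.coords, mut2.coords)


def test_different_seeds_change_the_tables():
    first, _ = generate_annotation_table(SimulationConfig(seed=1))
    second, _ = generate_annotation_table(SimulationConfig(seed=2))
    assert not first.equals(second)


def test_zero_variants_is_an_empty_table():
    frame, truth = generate_annotation_table(
        SimulationConfig(n_variants=0, n_planted=0))
    assert len(frame) == 0 and len(truth) == 0


def test_invalid_probability_is_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(p_sift_damaging=1.5)


def test_planted_variants_pass_both_prioritisation_stages(tmp_path):
    """10 planted all-damaging variants among 90 all-benign: the two-stage
    selection recovers exactly the planted set."""
    config = SimulationConfig(
        seed=3, n_variants=100, n_planted=10,
        p_provean_deleterious=0, p_sift_damaging=0, p_polyphen2_possibly=0,
        p_polyphen2_probably=0, p_snps_go_disease=0, p_imutant_decrease=0,
        p_fathmm_cancer=0, p_hbond_change=0, p_clash_change=0, p_asa_shift=0)
    frame, truth = generate_annotation_table(config)
    path = tmp_path / "annotations.tsv"
    write_tsv(frame, path)
    records = tables.read_annotation_table(path)
    scored = [(v, sequence.score_sequence_outcomes(o)) for v, o, _ in records]
    selected, _ = sequence.select_by_median(scored)
    selected_keys = {(v.gene, v.protein_change) for v, _ in selected}
    combined = [
        (v, structure.score_structure_outcomes(
            s, sequence.score_sequence_outcomes(o)).combined_total)
        for v, o, s in records if (v.gene, v.protein_change) in selected_keys]
    kept = structure.select_top_two(combined)
    kept_keys = {(v.gene, v.protein_change) for v, _ in kept}
    planted_keys = {(r.gene, r.protein_change)
                    for r in truth.itertuples() if r.planted}
    assert kept_keys == planted_keys
    assert len(kept_keys) == 10


@pytest.mark.parametrize("planted,field,expected", [
    ("none", None, None),
    ("remove_hbond", "hbond_changed", True),
    ("add_clash", "clash_changed", True),
    ("bury_site", "asa_shift", "inter_orbit"),
    ("expose_site", "asa_shift", "inter_orbit"),
])
def test_toy_complex_planted_perturbations_are_recovered(planted, field, expected):
    wt, mut, truth = generate_toy_complex(SimulationConfig(seed=5), planted)
    outcome = compare_wt_mut(wt, mut, truth["site"], n_points=320)
    if planted == "none":
        assert not outcome.hbond_changed and not outcome.clash_changed
        assert outcome.asa_shift.value == "none"
    elif field == "asa_shift":
        assert outcome.asa_shift.value == expected
    else:
        assert getattr(outcome, field) is expected
    # construction-guaranteed side conditions
    for key in ("hbond_changed", "clash_changed"):
        if truth[key] is not None:
            assert getattr(outcome, key) is truth[key]


def test_remove_hbond_changes_only_the_bond_pattern():
    wt, mut, truth = generate_toy_complex(SimulationConfig(seed=5), "remove_hbond")
    outcome = compare_wt_mut(wt, mut, truth["site"], n_points=320)
    assert outcome.hbond_changed
    assert not outcome.clash_changed
    assert outcome.asa_shift.value == "none"


def test_unknown_planted_label_is_an_error():
    with pytest.raises(ValueError, match="planted"):
        generate_toy_complex(SimulationConfig(), "melt_everything")


def test_toy_complexes_stay_small():
    wt, mut, _ = generate_toy_complex(SimulationConfig(), "bury_site")
    assert len(wt) <= 200 and len(mut) <= 200


def test_helix_is_a_single_connected_chain():
    model_atoms = build_helix(8)
    assert len({a.res_seq for a in model_atoms}) == 8
    assert all(a.chain_id == "A" for a in model_atoms)


def test_dock_generator_recovers_planted_disruptors(tmp_path):
    config = SimulationConfig(seed=9)
    frame, truth = generate_dock_table(config)
    path = tmp_path / "dock.tsv"
    write_tsv(frame, path)
    complexes = tables.read_dock_table(path)
    docking.grade_all(complexes)
    graded = {(c.category, c.variant.protein_change): c.grade for c in complexes}
    for row in truth.itertuples():
        expected = (Grade.MORE_DISRUPTING if row.planted_disruptor
                    else Grade.LESS_DISRUPTING)
        assert graded[(row.category, row.variant)] is expected


def test_identical_complexes_all_tie_at_the_mean(tmp_path):
    config = SimulationConfig(seed=1, n_planted_disruptors=0,
                              energy_noise=0.0, rmsd_noise=0.0,
                              category_sizes={"A:B": 6})
    frame, _ = generate_dock_table(config)
    path = tmp_path / "dock.tsv"
    write_tsv(frame, path)
    complexes = tables.read_dock_table(path)
    docking.grade_all(complexes)
    assert all(c.tie_flag for c in complexes)


def test_small_category_is_rejected():
    with pytest.raises(ValueError, match="category"):
        generate_dock_table(SimulationConfig(category_sizes={"A:B": 1}))


def test_recall_degrades_with_noise():
    """At default noise recovery is perfect; at very high noise it is not."""
    def recall(noise):
        hits = total = 0
        for seed in range(8):
            config = SimulationConfig(
                seed=seed, energy_noise=noise, rmsd_noise=noise,
                count_jitter=int(noise))
            frame, truth = generate_dock_table(config)
            complexes = _grade_frame(frame)
            graded = {(c.category, c.variant.protein_change): c.grade
                      for c in complexes}
            for row in truth.itertuples():
                if row.planted_disruptor:
                    total += 1
                    hits += graded[(row.category, row.variant)] is Grade.MORE_DISRUPTING
        return hits / total

    assert recall(0.05) == 1.0
    assert recall(8.0) < 1.0


def _grade_frame(frame):
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as tmp:
        path = Path(tmp) / "dock.tsv"
        write_tsv(frame, path)
        complexes = tables.read_dock_table(path)
    docking.grade_all(complexes)
    return complexes
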