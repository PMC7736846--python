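import pytest

from slitrobo import docking
from slitrobo.fixtures import (
    CATEGORY_SIZES,
    export_fixtures,
    fixture_path,
    load_docking_fixture,
    load_prioritisation_fixture,
    load_table4_frame,
)
from slitrobo.records import CountClass, EnergyClass, Grade
from slitrobo.tables import (
    ConsistencyError,
    TableFormatError,
    TableValueError,
    read_annotation_table,
    read_dock_table,
    read_report,
    write_report,
)

ANNOTATION_HEADER = ("gene\tprotein_change\tdataset\tregion\tprovean\tsift\t"
                     "polyphen2\tsnps_go\timutant\tfathmm\t"
                     "hbond_changed\tclash_changed\tasa_shift\n")


def test_prioritisation_fixture_row_counts():
    records = load_prioritisation_fixture()
    assert len(records) == 45
    genes = [v.gene for v, _, _ in records]
    assert genes.count("ROBO1") == 14
    assert genes.count("SLIT2") == 23
    assert genes.count("ROBO4") == 8


def test_docking_fixture_row_counts():
    by_cat = {}
    for c in load_docking_fixture():
        by_cat[c.category] = by_cat.get(c.category, 0) + 1
    assert by_cat == CATEGORY_SIZES


def test_docking_fixture_totals_match_component_sums():
    frame = load_table4_frame()
    complexes = load_docking_fixture()
    for c, printed in zip(complexes, frame["printed_total"].astype(int)):
        assert c.total_score == sum(c.component_scores) == printed


def test_empty_annotation_table_gives_empty_list(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text(ANNOTATION_HEADER)
    assert read_annotation_table(path) == []


def test_unknown_label_rejected_with_row_number(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(ANNOTATION_HEADER +
                    "ROBO1\tR119Q\tlung\twithin_docking_domain\tDeleterious\t"
                    "Damaging\tProbbly damaging\tDisease\tDecrease_stability\t"
                    "Passenger\ttrue\tfalse\tnone\n")
    with pytest.raises(TableValueError, match="row 2.*polyphen2"):
        read_annotation_table(path)


def test_missing_mandatory_column_named(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("gene\tprotein_change\tdataset\n")
    with pytest.raises(TableFormatError, match="region"):
        read_annotation_table(path)


def test_missing_cells_become_missing_markers(tmp_path):
    path = tmp_path / "missing.tsv"
    path.write_text(ANNOTATION_HEADER +
                    "ROBO1\tR119Q\tlung\twithin_docking_domain\tDeleterious\t\t"
                    "Benign\tNA\tDecrease_stability\tPassenger\tfalse\tfalse\tnone\n")
    [(_, outcomes, _)] = read_annotation_table(path)
    assert outcomes.sift is None and outcomes.snps_go is None
    assert outcomes.provean is not None


DOCK_HEADER = ("category\tvariant\tmutant_gene\tmutated_partner\t"
               "wild_type_partner\t")


def _dock_table(tmp_path, param_cells: str, header_extra: str):
    path = tmp_path / "dock.tsv"
    path.write_text(DOCK_HEADER + header_extra + "\n" +
                    "A:B\tR10Q\tGENEA\tA\tB\t" + param_cells + "\n" +
                    "A:B\tK11N\tGENEA\tA\tB\t" + param_cells + "\n")
    return path


def test_raw_pairs_classified_on_load(tmp_path):
    header = ("free_energy_wt\tfree_energy_mut\tbinding_affinity_wt\t"
              "binding_affinity_mut\tsolvation_wt\tsolvation_mut\t"
              "hbond_wt\thbond_mut\tvdw_wt\tvdw_mut\t"
              "saltbridge_wt\tsaltbridge_mut\trmsd")
    cells = "-12.0\t-10.1\t-8.0\t-8.0\t-6.0\t-6.5\t7\t9\t150\t120\t3\t3\t2.5"
    [c1, c2] = read_dock_table(_dock_table(tmp_path, cells, header))
    assert c1.comparison.free_energy_class is EnergyClass.WEAKENING
    assert c1.comparison.binding_affinity_class is EnergyClass.NEUTRAL
    assert c1.comparison.solvation_class is EnergyClass.STRENGTHENING
    assert c1.comparison.hbond_class is CountClass.INCREASED
    assert c1.comparison.vdw_class is CountClass.DECREASED
    assert c1.comparison.saltbridge_class is CountClass.NEUTRAL
    # identical RMSDs tie the category mean -> equal_mean
    assert c1.comparison.rmsd_class.value == "equal_mean"


def test_contradictory_class_vs_raw_pair_rejected(tmp_path):
    header = "free_energy_class\tfree_energy_wt\tfree_energy_mut\t" + "\t".join(
        f"{p}_class" for p in ("binding_affinity", "solvation", "hbond",
                               "vdw", "saltbridge", "rmsd"))
    cells = ("strengthening\t-12.0\t-10.1\tneutral\tneutral\tneutral\t"
             "neutral\tneutral\tequal_mean")
    with pytest.raises(ConsistencyError, match="free_energy"):
        read_dock_table(_dock_table(tmp_path, cells, header))


def test_parameter_without_class_or_raw_pair_rejected(tmp_path):
    header = "\t".join(f"{p}_class" for p in (
        "free_energy", "binding_affinity", "solvation", "hbond", "vdw", "rmsd"))
    cells = "neutral\tneutral\tneutral\tneutral\tneutral\tequal_mean"
    with pytest.raises(TableFormatError, match="saltbridge"):
        read_dock_table(_dock_table(tmp_path, cells, header))


def test_report_round_trip_is_identity(tmp_path):
    complexes = load_docking_fixture()
    docking.grade_all(complexes)
    path = tmp_path / "report.tsv"
    write_report(complexes, path, format="tsv")
    recovered = read_report(path)
    assert len(recovered) == len(complexes)
    for a, b in zip(complexes, recovered):
        assert a.total_score == b.total_score
        assert a.component_scores == tuple(b.component_scores)
        assert a.grade == b.grade
        assert a.tie_flag == b.tie_flag
        assert a.category == b.category
        assert a.variant == b.variant


def test_empty_report_writes_header_only(tmp_path):
    path = tmp_path / "empty.tsv"
    write_report([], path)
    lines = path.read_text().splitlines()
    assert len(lines) == 1 and lines[0].startswith("category\t")
    assert read_report(path) == []


def test_export_fixtures_is_byte_identical(tmp_path):
    written = export_fixtures(tmp_path)
    assert [p.name for p in written] == [
        "table3_prioritisation.tsv", "table4_docking.tsv"]
    for target in written:
        assert target.read_bytes() == fixture_path(target.name).read_bytes()
    again = export_fixtures(tmp_path / "again")
    assert [p.read_bytes() for p in written] == [p.read_bytes() for p in again]
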