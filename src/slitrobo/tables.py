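"""Readers and writers for annotation tables, docking tables and reports.

Formats are plain TSV/CSV with lower_snake_case canonical headers (a small
alias map accepts common spellings).  Validation is strict and front-loaded:
unknown categorical labels or missing mandatory columns are rejected at
parse time with the offending column/row named, so downstream scoring can
assume well-formed inputs.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import docking
from .records import (
    AsaShift,
    CountClass,
    DockComparison,
    EnergyClass,
    Fathmm,
    Grade,
    Imutant,
    Polyphen2,
    Provean,
    RmsdClass,
    ScoredComplex,
    SequenceToolOutcomes,
    Sift,
    SnpsGo,
    StructureChangeOutcomes,
    VariantRecord,
    COUNT_PARAMETERS,
    DOCK_PARAMETERS,
    ENERGY_PARAMETERS,
)


class TableFormatError(ValueError):
    """A table is structurally malformed (e.g. a mandatory column is absent)."""


class TableValueError(ValueError):
    """A table cell holds a label outside its enumerated vocabulary."""


class ConsistencyError(ValueError):
    """A stored class contradicts re-classification of its raw value pair."""


ANNOTATION_COLUMNS = (
    "gene", "protein_change", "dataset", "region",
    "provean", "sift", "polyphen2", "snps_go", "imutant", "fathmm",
    "hbond_changed", "clash_changed", "asa_shift",
)

COLUMN_ALIASES = {
    "aa_change": "protein_change",
    "snpsgo": "snps_go",
    "snps&go": "snps_go",
    "imutant2": "imutant",
    "polyphen": "polyphen2",
}

_MISSING = {"", "na", "n/a", "nan", "none", "missing", "."}

_LABEL_ALIASES = {
    "provean": {"deleterious": Provean.DELETERIOUS, "neutral": Provean.NEUTRAL},
    "sift": {"damaging": Sift.DAMAGING, "tolerated": Sift.TOLERATED},
    "polyphen2": {
        "benign": Polyphen2.BENIGN,
        "possibly_damaging": Polyphen2.POSSIBLY_DAMAGING,
        "possibly damaging": Polyphen2.POSSIBLY_DAMAGING,
        "probably_damaging": Polyphen2.PROBABLY_DAMAGING,
        "probably damaging": Polyphen2.PROBABLY_DAMAGING,
    },
    "snps_go": {"disease": SnpsGo.DISEASE, "disease-related": SnpsGo.DISEASE,
                "neutral": SnpsGo.NEUTRAL},
    "imutant": {
        "increase_stability": Imutant.INCREASE_STABILITY,
        "increase stability": Imutant.INCREASE_STABILITY,
        "decrease_stability": Imutant.DECREASE_STABILITY,
        "decrease stability": Imutant.DECREASE_STABILITY,
    },
    "fathmm": {"passenger": Fathmm.PASSENGER,
               "cancer_associated": Fathmm.CANCER_ASSOCIATED,
               "cancer-associated": Fathmm.CANCER_ASSOCIATED},
}

_BOOL = {"true": True, "1": True, "yes": True,
         "false": False, "0": False, "no": False}

_ASA = {"none": AsaShift.NONE, "intra_orbit": AsaShift.INTRA_ORBIT,
        "inter_orbit": AsaShift.INTER_ORBIT, "intra-orbit": AsaShift.INTRA_ORBIT,
        "inter-orbit": AsaShift.INTER_ORBIT}


def _read_table(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower())
                  for c in df.columns]
    return df


def _parse_label(column: str, cell: str, row: int):
    value = cell.strip()
    if value.lower() in _MISSING:
        return None
    label = _LABEL_ALIASES[column].get(value.lower())
    if label is None:
        raise TableValueError(
            f"row {row}: unknown {column} label {value!r}")
    return label


def _parse_bool(column: str, cell: str, row: int) -> bool:
    value = cell.strip().lower()
    if value not in _BOOL:
        raise TableValueError(f"row {row}: {column} must be boolean, got {cell!r}")
    return _BOOL[value]


def read_annotation_table(
    path: str | Path, dialect: str | None = None
) -> list[tuple[VariantRecord, SequenceToolOutcomes, StructureChangeOutcomes]]:
    """Read a variant annotation table (predictor outcomes + structure flags).

    Missing predictor cells become ``None`` markers (scored 0 later and
    flagged); unknown labels raise :class:`TableValueError` naming the row.
    """
    df = _read_table(path, dialect)
    required = ("gene", "protein_change", "dataset", "region",
                "provean", "sift", "polyphen2", "snps_go", "imutant", "fathmm")
    for column in required:
        if column not in df.columns:
            raise TableFormatError(f"missing mandatory column {column!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            variant = VariantRecord.from_protein_change(
                gene=row["gene"].strip(),
                change=row["protein_change"],
                dataset=row["dataset"].strip().lower(),
                region=row["region"].strip().lower(),
            )
        except ValueError as exc:
            raise TableValueError(f"row {i}: {exc}") from exc
        outcomes = SequenceToolOutcomes(**{
            tool: _parse_label(tool, row.get(tool, ""), i)
            for tool in _LABEL_ALIASES
        })
        asa_cell = row.get("asa_shift", "none").strip().lower()
        if asa_cell in _MISSING:
            asa = AsaShift.NONE
        elif asa_cell in _ASA:
            asa = _ASA[asa_cell]
        else:
            raise TableValueError(f"row {i}: unknown asa_shift label {asa_cell!r}")
        structure = StructureChangeOutcomes(
            hbond_changed=_parse_bool("hbond_changed", row.get("hbond_changed", "false"), i),
            clash_changed=_parse_bool("clash_changed", row.get("clash_changed", "false"), i),
            asa_shift=asa,
        )
        records.append((variant, outcomes, structure))
    return records


# --- docking tables --------------------------------------------------------

_CLASS_ENUMS = {
    **{p: EnergyClass for p in ENERGY_PARAMETERS},
    **{p: CountClass for p in COUNT_PARAMETERS},
    "rmsd": RmsdClass,
}


def _parse_class(param: str, cell: str, row: int):
    value = cell.strip().lower().replace(" ", "_")
    if value in _MISSING:
        return None
    try:
        return _CLASS_ENUMS[param](value)
    except ValueError:
        raise TableValueError(
            f"row {row}: unknown {param} class {cell!r}") from None


def read_dock_table(
    path: str | Path, dialect: str | None = None
) -> list[ScoredComplex]:
    """Read a docking-parameter table into scored (ungraded) complexes.

    Each of the seven parameters is given either as a class label column
    (``<param>_class``) or as a raw value pair (``<param>_wt``/``<param>_mut``;
    ``rmsd`` as a single mutant-complex value).  Raw pairs are classified on
    load; when both forms are present they must agree
    (:class:`ConsistencyError` otherwise).  The RMSD class of raw values is
    assigned in a second pass against the per-category mean RMSD of the
    mutant complexes.
    """
    df = _read_table(path, dialect)
    for column in ("category", "variant", "mutant_gene", "wild_type_partner"):
        if column not in df.columns:
            raise TableFormatError(f"missing mandatory column {column!r}")

    rows = []
    for i, raw_row in enumerate(df.itertuples(index=False), start=2):
        row = raw_row._asdict()
        classes: dict[str, object] = {}
        raw: dict[str, tuple[float, float]] = {}
        for param in DOCK_PARAMETERS[:6]:
            cls = _parse_class(param, row.get(f"{param}_class", ""), i)
            wt_cell = row.get(f"{param}_wt", "").strip()
            mut_cell = row.get(f"{param}_mut", "").strip()
            if wt_cell and mut_cell:
                wt_v, mut_v = float(wt_cell), float(mut_cell)
                raw[param] = (wt_v, mut_v)
                derived = docking.classify_delta(param, wt_v, mut_v)
                if cls is not None and cls != derived:
                    raise ConsistencyError(
                        f"row {i}: stored {param} class {cls.value!r} contradicts "
                        f"raw pair ({wt_v}, {mut_v}) -> {derived.value!r}")
                cls = derived
            if cls is None:
                raise TableFormatError(
                    f"row {i}: parameter {param!r} has neither a class nor a raw pair")
            classes[param] = cls
        rmsd_cell = row.get("rmsd", "").strip()
        rmsd_value = float(rmsd_cell) if rmsd_cell else None
        rmsd_cls = _parse_class("rmsd", row.get("rmsd_class", ""), i)
        if rmsd_cls is None and rmsd_value is None:
            raise TableFormatError(
                f"row {i}: parameter 'rmsd' has neither a class nor a raw value")
        rows.append((i, row, classes, raw, rmsd_value, rmsd_cls))

    # second pass: classify raw RMSDs against the category mean
    by_cat: dict[str, list[float]] = {}
    for _, row, _, _, rmsd_value, _ in rows:
        if rmsd_value is not None:
            by_cat.setdefault(row["category"], []).append(rmsd_value)
    mean_rmsd = {cat: sum(v) / len(v) for cat, v in by_cat.items()}

    complexes = []
    for i, row, classes, raw, rmsd_value, rmsd_cls in rows:
        if rmsd_value is not None:
            derived = docking.rmsd_class(rmsd_value, mean_rmsd[row["category"]])
            if rmsd_cls is not None and rmsd_cls != derived:
                raise ConsistencyError(
                    f"row {i}: stored rmsd class {rmsd_cls.value!r} contradicts raw "
                    f"value {rmsd_value} vs category mean "
                    f"{mean_rmsd[row['category']]:.3f} -> {derived.value!r}")
            rmsd_cls = derived
        comparison = DockComparison(
            free_energy_class=classes["free_energy"],
            binding_affinity_class=classes["binding_affinity"],
            solvation_class=classes["solvation"],
            hbond_class=classes["hbond"],
            vdw_class=classes["vdw"],
            saltbridge_class=classes["saltbridge"],
            rmsd_class=rmsd_cls,
            raw=raw,
            rmsd=rmsd_value,
        )
        try:
            variant = VariantRecord.from_protein_change(
                gene=row["mutant_gene"].strip(),
                change=row["variant"],
                dataset=row.get("dataset", "non_lung").strip().lower() or "non_lung",
                region=row.get("region", "within_docking_domain").strip().lower()
                or "within_docking_domain",
            )
        except ValueError as exc:
            raise TableValueError(f"row {i}: {exc}") from exc
        complexes.append(ScoredComplex(
            variant=variant,
            mutated_partner=row.get("mutated_partner", "").strip() or variant.gene,
            wild_type_partner=row["wild_type_partner"].strip(),
            category=row["category"].strip(),
            comparison=comparison,
        ))
    return complexes


# --- report writing --------------------------------------------------------

REPORT_COLUMNS = (
    "category", "variant", "mutant_gene", "mutated_partner", "wild_type_partner",
    "free_energy_class", "binding_affinity_class", "solvation_class",
    "hbond_class", "vdw_class", "saltbridge_class", "rmsd_class",
    "total_score", "grade", "tie_flag",
)


def complexes_to_frame(results: Sequence[ScoredComplex]) -> pd.DataFrame:
    rows = []
    for c in results:
        comp = c.comparison
        rows.append({
            "category": c.category,
            "variant": c.variant.protein_change,
            "mutant_gene": c.variant.gene,
            "mutated_partner": c.mutated_partner,
            "wild_type_partner": c.wild_type_partner,
            "free_energy_class": comp.free_energy_class.value,
            "binding_affinity_class": comp.binding_affinity_class.value,
            "solvation_class": comp.solvation_class.value,
            "hbond_class": comp.hbond_class.value,
            "vdw_class": comp.vdw_class.value,
            "saltbridge_class": comp.saltbridge_class.value,
            "rmsd_class": comp.rmsd_class.value,
            "total_score": c.total_score,
            "grade": c.grade.value if c.grade else "",
            "tie_flag": "true" if c.tie_flag else "false",
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(
    results: Sequence[ScoredComplex], path: str | Path, format: str = "tsv"
) -> None:
    """Write scored/graded complexes; TSV round-trips bit-exactly via
    :func:`read_report`."""
    if results is None:
        raise ValueError("results must not be None")
    frame = complexes_to_frame(results)
    path = Path(path)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> list[ScoredComplex]:
    """Read back a TSV report written by :func:`write_report`."""
    df = _read_table(path, "tsv")
    out = []
    for i, raw_row in enumerate(df.itertuples(index=False), start=2):
        row = raw_row._asdict()
        comparison = DockComparison(
            free_energy_class=row["free_energy_class"],
            binding_affinity_class=row["binding_affinity_class"],
            solvation_class=row["solvation_class"],
            hbond_class=row["hbond_class"],
            vdw_class=row["vdw_class"],
            saltbridge_class=row["saltbridge_class"],
            rmsd_class=row["rmsd_class"],
        )
        variant = VariantRecord.from_protein_change(
            gene=row["mutant_gene"], change=row["variant"])
        grade = Grade(row["grade"]) if row["grade"].strip() else None
        c = ScoredComplex(
            variant=variant,
            mutated_partner=row["mutated_partner"],
            wild_type_partner=row["wild_type_partner"],
            category=row["category"],
            comparison=comparison,
            total_score=int(row["total_score"]),
            grade=grade,
            tie_flag=_parse_bool("tie_flag", row["tie_flag"], i),
        )
        out.append(c)
    return out
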