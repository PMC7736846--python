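"""Packaged transcriptions of the published prioritisation and docking tables.

``table3_prioritisation.tsv`` holds the 45 prioritised variants (14 ROBO1,
23 SLIT2, 8 ROBO4) with their per-tool outcomes, structure-change flags and
printed totals.  ``table4_docking.tsv`` holds the 68 mutant docked
complexes of the four docking categories with their printed per-parameter
classes, totals and More/Less-disrupting outcomes.  Both are plain TSV and
can be exported for use outside the package.
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path

import pandas as pd

from .tables import read_annotation_table, read_dock_table

TABLE3 = "table3_prioritisation.tsv"
TABLE4 = "table4_docking.tsv"

#: The four docking categories, in publication order, with their sizes.
CATEGORY_SIZES = {
    "ROBO1.IG1:SLIT2.D2": 26,
    "ROBO4.IG1-2:SLIT2.D2": 22,
    "ROBO1:SLIT2": 11,
    "ROBO4:SLIT2": 9,
}

#: Whole-protein (as opposed to docking-domain) categories.
WHOLE_PROTEIN_CATEGORIES = ("ROBO1:SLIT2", "ROBO4:SLIT2")


def fixture_path(name: str) -> Path:
    return Path(str(resources.files("slitrobo").joinpath("data", name)))


def load_table3_frame() -> pd.DataFrame:
    return pd.read_csv(fixture_path(TABLE3), sep="\t", dtype=str)


def load_table4_frame() -> pd.DataFrame:
    return pd.read_csv(fixture_path(TABLE4), sep="\t", dtype=str)


def load_prioritisation_fixture():
    """The prioritised-variant fixture as parsed records."""
    return read_annotation_table(fixture_path(TABLE3), dialect="tsv")


def load_docking_fixture():
    """The docked-complex fixture as (ungraded) scored complexes."""
    return read_dock_table(fixture_path(TABLE4), dialect="tsv")


def export_fixtures(out_dir: str | Path) -> list[Path]:
    """Copy the packaged fixture TSVs into ``out_dir`` byte-identically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in (TABLE3, TABLE4):
        target = out_dir / name
        shutil.copyfile(fixture_path(name), target)
        written.append(target)
    return written
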