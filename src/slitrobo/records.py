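"""Domain types shared by all pipeline stages.

The pipeline works at protein level only: a variant is a single amino-acid
substitution on one of the interacting partners (e.g. ROBO1 p.R119Q), and
every downstream object refers back to such a variant.  Categorical
predictor outcomes and docked-complex comparisons are represented with
explicit enumerations so that malformed labels are rejected at parse time
rather than silently scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

AMINO_ACIDS_1 = set("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def normalize_aa(aa: str) -> str:
    """Normalise a one- or three-letter amino-acid code to one-letter."""
    aa = aa.strip()
    if len(aa) == 3 and aa.upper() in THREE_TO_ONE:
        return THREE_TO_ONE[aa.upper()]
    one = aa.upper()
    if one in AMINO_ACIDS_1:
        return one
    raise ValueError(f"unknown amino-acid code: {aa!r}")


class Dataset(str, Enum):
    LUNG = "lung"
    NON_LUNG = "non_lung"


class Region(str, Enum):
    WITHIN = "within_docking_domain"
    OUTSIDE = "outside_docking_domain"


# --- categorical predictor outcomes (sequence stage) -----------------------

class Provean(str, Enum):
    NEUTRAL = "Neutral"
    DELETERIOUS = "Deleterious"


class Sift(str, Enum):
    TOLERATED = "Tolerated"
    DAMAGING = "Damaging"


class Polyphen2(str, Enum):
    BENIGN = "Benign"
    POSSIBLY_DAMAGING = "Possibly_damaging"
    PROBABLY_DAMAGING = "Probably_damaging"


class SnpsGo(str, Enum):
    NEUTRAL = "Neutral"
    DISEASE = "Disease"


class Imutant(str, Enum):
    INCREASE_STABILITY = "Increase_stability"
    DECREASE_STABILITY = "Decrease_stability"


class Fathmm(str, Enum):
    PASSENGER = "Passenger"
    CANCER_ASSOCIATED = "Cancer_associated"


class AsaShift(str, Enum):
    NONE = "none"
    INTRA_ORBIT = "intra_orbit"
    INTER_ORBIT = "inter_orbit"


# --- docked-complex comparison classes -------------------------------------

class EnergyClass(str, Enum):
    """Direction of an energy-like parameter relative to the wild-type complex.

    ``STRENGTHENING`` means more negative (tighter association),
    ``WEAKENING`` less negative.
    """

    NEUTRAL = "neutral"
    STRENGTHENING = "strengthening"
    WEAKENING = "weakening"


class CountClass(str, Enum):
    """Direction of an interaction-count parameter (H-bonds, vdW, bridges)."""

    NEUTRAL = "neutral"
    INCREASED = "increased"
    DECREASED = "decreased"


class RmsdClass(str, Enum):
    EQUAL_MEAN = "equal_mean"
    BELOW_MEAN = "below_mean"
    ABOVE_MEAN = "above_mean"


class Grade(str, Enum):
    MORE_DISRUPTING = "more_disrupting"
    LESS_DISRUPTING = "less_disrupting"
    WILD_TYPE_REFERENCE = "wild_type_reference"


# Weight maps: weakening-type changes score 2, strengthening-type 1, no
# change 0 -- for RMSD, above the category mean scores 2, below it 1.
ENERGY_WEIGHTS = {
    EnergyClass.NEUTRAL: 0,
    EnergyClass.STRENGTHENING: 1,
    EnergyClass.WEAKENING: 2,
}
COUNT_WEIGHTS = {
    CountClass.NEUTRAL: 0,
    CountClass.INCREASED: 1,
    CountClass.DECREASED: 2,
}
RMSD_WEIGHTS = {
    RmsdClass.EQUAL_MEAN: 0,
    RmsdClass.BELOW_MEAN: 1,
    RmsdClass.ABOVE_MEAN: 2,
}

#: Ordered names of the seven post-docking parameters.
DOCK_PARAMETERS = (
    "free_energy",
    "binding_affinity",
    "solvation",
    "hbond",
    "vdw",
    "saltbridge",
    "rmsd",
)

ENERGY_PARAMETERS = ("free_energy", "binding_affinity", "solvation")
COUNT_PARAMETERS = ("hbond", "vdw", "saltbridge")


@dataclass(frozen=True)
class VariantRecord:
    """A missense variant at protein level, e.g. ROBO1 p.R119Q."""

    gene: str
    ref_aa: str
    position: int
    alt_aa: str
    dataset: Dataset = Dataset.NON_LUNG
    region: Region = Region.WITHIN

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene must be non-empty")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        object.__setattr__(self, "ref_aa", normalize_aa(self.ref_aa))
        object.__setattr__(self, "alt_aa", normalize_aa(self.alt_aa))
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"ref and alt amino acid are identical: {self.ref_aa}")
        object.__setattr__(self, "dataset", Dataset(self.dataset))
        object.__setattr__(self, "region", Region(self.region))

    @property
    def protein_change(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @classmethod
    def from_protein_change(
        cls,
        gene: str,
        change: str,
        dataset: Dataset | str = Dataset.NON_LUNG,
        region: Region | str = Region.WITHIN,
    ) -> "VariantRecord":
        """Parse a ``R119Q`` / ``p.R119Q`` / ``Arg119Gln`` style change string."""
        s = change.strip()
        if s.startswith(("p.", "P.")):
            s = s[2:]
        i, j = 0, len(s)
        while i < j and s[i].isalpha():
            i += 1
        k = i
        while k < j and s[k].isdigit():
            k += 1
        ref, pos, alt = s[:i], s[i:k], s[k:]
        if not ref or not pos or not alt:
            raise ValueError(f"cannot parse protein change {change!r}")
        return cls(gene=gene, ref_aa=ref, position=int(pos), alt_aa=alt,
                   dataset=dataset, region=region)


@dataclass(frozen=True)
class SequenceToolOutcomes:
    """Categorical results of the six sequence predictors; ``None`` = missing."""

    provean: Provean | None = None
    sift: Sift | None = None
    polyphen2: Polyphen2 | None = None
    snps_go: SnpsGo | None = None
    imutant: Imutant | None = None
    fathmm: Fathmm | None = None

    def __post_init__(self) -> None:
        for name, enum in (("provean", Provean), ("sift", Sift),
                           ("polyphen2", Polyphen2), ("snps_go", SnpsGo),
                           ("imutant", Imutant), ("fathmm", Fathmm)):
            value = getattr(self, name)
            if value is not None:
                object.__setattr__(self, name, enum(value))


@dataclass(frozen=True)
class StructureChangeOutcomes:
    """Structure-change flags of the mutant model relative to wild type."""

    hbond_changed: bool = False
    clash_changed: bool = False
    asa_shift: AsaShift = AsaShift.NONE

    def __post_init__(self) -> None:
        object.__setattr__(self, "asa_shift", AsaShift(self.asa_shift))


@dataclass(frozen=True)
class SequenceScoreVector:
    """Per-tool weighted scores of the sequence stage and their sum."""

    provean: int
    sift: int
    polyphen2: int
    snps_go: int
    imutant: int
    fathmm: int
    cumulative: int
    missing_tools: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        total = (self.provean + self.sift + self.polyphen2 + self.snps_go
                 + self.imutant + self.fathmm)
        if total != self.cumulative:
            raise ValueError(
                f"cumulative {self.cumulative} != sum of tool scores {total}")
        if not 0 <= self.cumulative <= 7:
            raise ValueError(f"cumulative score out of range: {self.cumulative}")


@dataclass(frozen=True)
class StructureScoreVector:
    """Structure-stage scores and the combined (sequence + structure) total."""

    hbond_score: int
    clash_score: int
    asa_score: int
    cumulative_structure: int
    combined_total: int

    def __post_init__(self) -> None:
        if self.hbond_score + self.clash_score + self.asa_score != self.cumulative_structure:
            raise ValueError("cumulative_structure is not the sum of its parts")
        if not 0 <= self.cumulative_structure <= 3:
            raise ValueError("cumulative_structure out of [0, 3]")
        if not 0 <= self.combined_total <= 10:
            raise ValueError("combined_total out of [0, 10]")


@dataclass(frozen=True)
class DockComparison:
    """The seven post-docking comparison classes for one mutant complex.

    Raw (wild type, mutant) value pairs are optional; when present the
    stored classes must agree with re-classification of the raw pair
    (checked by the table reader, not here, because the RMSD class depends
    on the category mean which is only known at cohort level).
    """

    free_energy_class: EnergyClass
    binding_affinity_class: EnergyClass
    solvation_class: EnergyClass
    hbond_class: CountClass
    vdw_class: CountClass
    saltbridge_class: CountClass
    rmsd_class: RmsdClass
    raw: dict[str, tuple[float, float]] = field(default_factory=dict)
    rmsd: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "free_energy_class", EnergyClass(self.free_energy_class))
        object.__setattr__(self, "binding_affinity_class", EnergyClass(self.binding_affinity_class))
        object.__setattr__(self, "solvation_class", EnergyClass(self.solvation_class))
        object.__setattr__(self, "hbond_class", CountClass(self.hbond_class))
        object.__setattr__(self, "vdw_class", CountClass(self.vdw_class))
        object.__setattr__(self, "saltbridge_class", CountClass(self.saltbridge_class))
        object.__setattr__(self, "rmsd_class", RmsdClass(self.rmsd_class))

    def component_scores(self) -> tuple[int, int, int, int, int, int, int]:
        return (
            ENERGY_WEIGHTS[self.free_energy_class],
            ENERGY_WEIGHTS[self.binding_affinity_class],
            ENERGY_WEIGHTS[self.solvation_class],
            COUNT_WEIGHTS[self.hbond_class],
            COUNT_WEIGHTS[self.vdw_class],
            COUNT_WEIGHTS[self.saltbridge_class],
            RMSD_WEIGHTS[self.rmsd_class],
        )


@dataclass
class ScoredComplex:
    """A mutant-vs-wild-type docked complex with its weighted score and grade."""

    variant: VariantRecord
    mutated_partner: str
    wild_type_partner: str
    category: str
    comparison: DockComparison
    component_scores: tuple[int, ...] = ()
    total_score: int = 0
    grade: Grade | None = None
    tie_flag: bool = False

    def __post_init__(self) -> None:
        if not self.component_scores:
            self.component_scores = self.comparison.component_scores()
        if self.total_score == 0 and sum(self.component_scores):
            self.total_score = sum(self.component_scores)
        if self.total_score != sum(self.component_scores):
            raise ValueError(
                f"total_score {self.total_score} != sum of component scores "
                f"{sum(self.component_scores)}")
        if not 0 <= self.total_score <= 14:
            raise ValueError(f"total_score out of [0, 14]: {self.total_score}")


@dataclass(frozen=True)
class CategorySummary:
    """Per docking-category summary: mean total score, counts, grade split."""

    category: str
    n_complexes: int
    mean_total_score: float
    mean_rmsd: float | None = None
    n_more: int = 0
    n_less: int = 0
    n_tied: int = 0

    def __post_init__(self) -> None:
        if self.n_more + self.n_less != self.n_complexes:
            # tied complexes are graded less_disrupting with tie_flag, so the
            # partition over grades must still cover every complex
            raise ValueError("grade partition does not cover the category")


@dataclass(frozen=True)
class PocketAnnotation:
    """DoGSiteScorer-style druggability annotation (informational only)."""

    mean_drug_score_wt: float
    mean_drug_score_mut: float
    n_pockets_wt: int
    n_pockets_mut: int
    drug_score_label: str = ""
    pocket_label: str = ""
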