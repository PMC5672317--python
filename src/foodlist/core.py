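"""Domain types and run configuration shared by every pipeline stage.

Tables (food register, composition, consumption events, participants) are
carried as pandas DataFrames with fixed column contracts; the small
structured objects below hold everything that is not naturally tabular:
the run configuration, the dietary-reference-value (DRV) table and the
basal-metabolic-rate (BMR) coefficient model.

Column contracts
----------------
register      : code_id, description, food_group, food_type, brand,
                is_supplement (bool), exception_class
composition   : code_id + one column per nutrient (amount per 100 g)
events        : participant_id, day, occasion_id, code_id, amount_g
participants  : participant_id, sex, age_y, weight_kg
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

EXCEPTION_CLASSES = ("none", "recipe_ingredient", "rare_unusual", "unique_unmergeable")
SEXES = ("male", "female")

REGISTER_COLUMNS = [
    "code_id", "description", "food_group", "food_type", "brand",
    "is_supplement", "exception_class",
]
EVENT_COLUMNS = ["participant_id", "day", "occasion_id", "code_id", "amount_g"]
PARTICIPANT_COLUMNS = ["participant_id", "sex", "age_y", "weight_kg"]

#: Default nutrient panel: energy plus 34 macro- and micronutrients, the
#: size of panel a national adult nutrition survey reports on.
#: Units: energy kJ; macronutrients g; vitamins/minerals mg or µg as suffixed.
DEFAULT_NUTRIENT_PANEL = [
    "energy_kj",
    # macronutrients, g/100 g
    "protein", "carbohydrate", "starch", "total_sugars", "non_milk_sugars",
    "fibre", "total_fat", "saturated_fat", "monounsaturated_fat",
    "polyunsaturated_fat", "alcohol",
    # vitamins
    "retinol_ug", "carotene_ug", "vitamin_a_ug", "vitamin_d_ug",
    "vitamin_e_mg", "thiamin_mg", "riboflavin_mg", "niacin_mg",
    "vitamin_b6_mg", "vitamin_b12_ug", "folate_ug", "folic_acid_ug",
    "biotin_ug", "pantothenate_mg", "vitamin_c_mg",
    # minerals
    "calcium_mg", "magnesium_mg", "phosphorus_mg", "iron_mg", "zinc_mg",
    "copper_mg", "sodium_mg", "potassium_mg",
]

MACRONUTRIENTS = [
    "protein", "carbohydrate", "starch", "total_sugars", "non_milk_sugars",
    "fibre", "total_fat", "saturated_fat", "monounsaturated_fat",
    "polyunsaturated_fat", "alcohol",
]
MICRONUTRIENTS = [n for n in DEFAULT_NUTRIENT_PANEL
                  if n != "energy_kj" and n not in MACRONUTRIENTS]

#: kJ per gram, UK food-table convention (Atwater-style metabolisable energy).
DEFAULT_ENERGY_CONVERSION = {
    "protein": 17.0,
    "carbohydrate": 16.0,
    "total_fat": 37.0,
    "saturated_fat": 37.0,
    "monounsaturated_fat": 37.0,
    "polyunsaturated_fat": 37.0,
    "alcohol": 29.0,
}

MACRO_RULE_KINDS = (
    "percent_energy_max", "percent_energy_range",
    "absolute_min_per_day", "per_kg_bw_min",
)


@dataclass(frozen=True)
class RunConfig:
    """Analysis-wide knobs.

    alpha : significance level shared by the normality screen and the paired
        tests (lowered to guard against multiplicity).
    under_reporter_cutoff : EI:BMR ratio below which (strictly) a participant
        is flagged as an energy under-reporter.
    n_classes : number of distribution classes for cross-classification
        (3 = tertiles).
    energy_conversion : nutrient -> kJ per g, used for percent-energy rules.
    energy_nutrient : composition column holding energy in kJ.
    recorded_days : length of the food-record window the intakes are
        averaged over.
    """

    alpha: float = 0.01
    under_reporter_cutoff: float = 1.1
    n_classes: int = 3
    energy_conversion: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENERGY_CONVERSION))
    energy_nutrient: str = "energy_kj"
    recorded_days: int = 4
    rng_seed: int = 0
    ear_strict_below: bool = True
    ul_strict_above: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.under_reporter_cutoff <= 0:
            raise ValueError("under_reporter_cutoff must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        if self.recorded_days < 1:
            raise ValueError("recorded_days must be at least 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class DRVTable:
    """Dietary reference values.

    micronutrients : one row per (nutrient, sex, age band) with columns
        nutrient, sex, age_lo, age_hi, ear, ul. Age bands are half-open
        [age_lo, age_hi); ``ul`` may be NaN (no upper level set).
    macro_rules : one row per macronutrient rule with columns
        nutrient, kind, lo, hi. ``kind`` is one of MACRO_RULE_KINDS; ``hi``
        is only used by percent_energy_range.
    """

    micronutrients: pd.DataFrame
    macro_rules: pd.DataFrame

    def validate(self, nutrient_panel: list[str] | None = None) -> None:
        m = self.micronutrients
        both = m.dropna(subset=["ul"])
        bad = both[both["ear"] >= both["ul"]]
        if len(bad):
            raise ValueError(
                "EAR must be below UL; violated for: "
                + ", ".join(sorted(bad["nutrient"].unique())))
        unknown = set(self.macro_rules["kind"]) - set(MACRO_RULE_KINDS)
        if unknown:
            raise ValueError(f"unknown macro rule kinds: {sorted(unknown)}")
        if nutrient_panel is not None:
            named = set(m["nutrient"]) | set(self.macro_rules["nutrient"])
            missing = named - set(nutrient_panel)
            if missing:
                raise ValueError(
                    f"DRV names nutrients outside the panel: {sorted(missing)}")

    def strata(self) -> pd.DataFrame:
        """Distinct (sex, age_lo, age_hi) strata of the micronutrient rows."""
        return (self.micronutrients[["sex", "age_lo", "age_hi"]]
                .drop_duplicates().reset_index(drop=True))


@dataclass
class BMRModel:
    """Piecewise-linear BMR prediction: bmr_MJ_d = slope*weight_kg + intercept.

    ``coefficients`` has columns sex, age_lo, age_hi, slope, intercept with
    half-open age bands [age_lo, age_hi) partitioning adulthood per sex.
    """

    coefficients: pd.DataFrame

    def validate(self) -> None:
        for sex, grp in self.coefficients.groupby("sex"):
            g = grp.sort_values("age_lo")
            los, his = g["age_lo"].to_numpy(), g["age_hi"].to_numpy()
            if np.any(los[1:] < his[:-1]):
                raise ValueError(f"overlapping BMR age bands for sex={sex}")

    @classmethod
    def schofield(cls) -> "BMRModel":
        """The standard adult Schofield coefficient set shipped as data."""
        with resources.files("foodlist.data").joinpath("schofield.tsv").open() as fh:
            coef = pd.read_csv(fh, sep="\t")
        model = cls(coef)
        model.validate()
        return model


def default_macro_rules() -> pd.DataFrame:
    """EFSA / UK Department of Health macronutrient reference values.

    protein PRI 0.83 g/kg body weight per day; carbohydrate 45-60 %E;
    total fat 20-35 %E; saturated fat at most 10 %E; dietary fibre adequate
    intake 25 g/d.
    """
    return pd.DataFrame(
        [
            ("protein", "per_kg_bw_min", 0.83, np.nan),
            ("carbohydrate", "percent_energy_range", 45.0, 60.0),
            ("total_fat", "percent_energy_range", 20.0, 35.0),
            ("saturated_fat", "percent_energy_max", 10.0, np.nan),
            ("fibre", "absolute_min_per_day", 25.0, np.nan),
        ],
        columns=["nutrient", "kind", "lo", "hi"],
    )
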