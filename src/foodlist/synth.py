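"""Seeded generator of survey-like bundles for end-to-end testing.

Emulates the structure of a brand-level national food-consumption survey:
brand codes nested in food types nested in food groups, skewed brand
popularity, multi-day records, a ~35-nutrient composition panel and
separately coded nutritional supplements. The single dial that controls how
much the concise list can disagree with the extensive list is
``heterogeneity_sigma``: the SD of per-brand log-multiplicative composition
noise around each food type's latent base profile. At sigma = 0 every brand
in a type has an identical composition, so list compression is lossless by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_NUTRIENT_PANEL,
    DRVTable,
    MACRONUTRIENTS,
    MICRONUTRIENTS,
    RunConfig,
)
from .io import Bundle

#: Typical per-100 g medians used for latent food-type profiles (log scale
#: centres). Macros in g; micros in the panel's suffixed unit.
_MICRO_SCALES = {
    "retinol_ug": 40.0, "carotene_ug": 150.0, "vitamin_a_ug": 60.0,
    "vitamin_d_ug": 0.6, "vitamin_e_mg": 1.0, "thiamin_mg": 0.12,
    "riboflavin_mg": 0.15, "niacin_mg": 2.0, "vitamin_b6_mg": 0.15,
    "vitamin_b12_ug": 0.6, "folate_ug": 25.0, "folic_acid_ug": 8.0,
    "biotin_ug": 3.0, "pantothenate_mg": 0.4, "vitamin_c_mg": 5.0,
    "calcium_mg": 60.0, "magnesium_mg": 20.0, "phosphorus_mg": 100.0,
    "iron_mg": 1.2, "zinc_mg": 1.0, "copper_mg": 0.12,
    "sodium_mg": 250.0, "potassium_mg": 200.0,
}


@dataclass(frozen=True)
class SimulationDesign:
    """Reduced-scale survey design.

    Defaults give 300 participants and a 20 groups x 2 types x 8 brands
    register (320 food codes plus supplements), a 4-day record with a mean
    of six eating occasions per day, and moderate (15 % CV) within-type
    brand composition heterogeneity.
    """

    n_participants: int = 300
    n_groups: int = 20
    types_per_group: int = 2
    brands_per_type: int = 8
    heterogeneity_sigma: float = 0.15
    zipf_s: float = 1.0
    events_per_day_mean: float = 5.0
    amount_lognormal: tuple[float, float] = (5.2, 0.6)
    supplement_fraction: float = 0.25
    exception_fraction: float = 0.05
    n_supplement_codes: int = 10
    recorded_days: int = 4
    alcohol_type_fraction: float = 0.08
    rng_seed: int = 0
    nutrient_panel: tuple[str, ...] = field(
        default_factory=lambda: tuple(DEFAULT_NUTRIENT_PANEL))

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_groups", "types_per_group",
                     "brands_per_type", "recorded_days"):
            if getattr(self, name) < 1 and name != "n_participants":
                raise ValueError(f"{name} must be >= 1")
        if self.heterogeneity_sigma < 0:
            raise ValueError("heterogeneity_sigma must be >= 0")
        if self.zipf_s < 0:
            raise ValueError("zipf_s must be >= 0")
        if self.events_per_day_mean <= 0:
            raise ValueError("events_per_day_mean must be > 0")


def _base_profile(rng: np.random.Generator, alcoholic: bool) -> dict[str, float]:
    """Latent per-100 g nutrient profile of one food type."""
    p: dict[str, float] = {}
    p["protein"] = rng.lognormal(np.log(8.0), 0.8)
    p["total_fat"] = rng.lognormal(np.log(9.0), 0.9)
    p["carbohydrate"] = rng.lognormal(np.log(18.0), 0.8)
    p["alcohol"] = rng.lognormal(np.log(4.0), 0.5) if alcoholic else 0.0
    # fat sub-fractions sum to < total fat
    f = rng.dirichlet([4.0, 4.0, 2.0]) * 0.95
    p["saturated_fat"] = p["total_fat"] * f[0]
    p["monounsaturated_fat"] = p["total_fat"] * f[1]
    p["polyunsaturated_fat"] = p["total_fat"] * f[2]
    # carbohydrate split
    starch_share = rng.beta(2.0, 2.0)
    p["starch"] = p["carbohydrate"] * starch_share
    p["total_sugars"] = p["carbohydrate"] * (1.0 - starch_share)
    p["non_milk_sugars"] = p["total_sugars"] * rng.beta(3.0, 1.5)
    p["fibre"] = rng.lognormal(np.log(2.0), 0.8)
    for nutrient, scale in _MICRO_SCALES.items():
        p[nutrient] = rng.lognormal(np.log(scale), 1.0)
    # energy consistent with the UK conversion factors at the base profile
    p["energy_kj"] = (17.0 * p["protein"] + 16.0 * p["carbohydrate"]
                      + 37.0 * p["total_fat"] + 29.0 * p["alcohol"])
    return p


def gen_food_db(design: SimulationDesign,
                rng: np.random.Generator | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the food register and per-100 g composition table.

    Each food type carries one latent base profile; each brand's composition
    is the base multiplied by exp(eps), eps ~ N(0, sigma^2) independently per
    nutrient. A fraction of non-supplement codes is flagged with exception
    classes (recipe ingredients, rare/unusual items, unique items) in the
    proportions such exclusions occur in brand-level surveys; supplements are
    separate single-code food types with micronutrients only.
    """
    rng = np.random.default_rng(design.rng_seed) if rng is None else rng
    panel = list(design.nutrient_panel)
    rows, comp_rows = [], []
    sigma = design.heterogeneity_sigma
    for g in range(design.n_groups):
        group = f"group_{g:02d}"
        for t in range(design.types_per_group):
            ftype = f"type_{g:02d}_{t}"
            alcoholic = rng.random() < design.alcohol_type_fraction
            base = _base_profile(rng, alcoholic)
            base_vec = np.array([base[n] for n in panel])
            for b in range(design.brands_per_type):
                code = f"F{g:02d}{t}{b:02d}"
                if sigma > 0:
                    comp = base_vec * np.exp(
                        rng.normal(0.0, sigma, size=len(panel)))
                else:
                    comp = base_vec.copy()
                rows.append((code, f"{ftype} brand {b}", group, ftype,
                             f"brand_{b}", False, "none"))
                comp_rows.append([code, *comp])
    for s in range(design.n_supplement_codes):
        code = f"S{s:03d}"
        comp = {n: 0.0 for n in panel}
        for nutrient, scale in _MICRO_SCALES.items():
            if nutrient in comp:
                comp[nutrient] = rng.lognormal(np.log(scale * 20.0), 0.8)
        rows.append((code, f"supplement {s}", "nutritional supplements",
                     f"supplement_{s}", "generic", True, "none"))
        comp_rows.append([code, *[comp[n] for n in panel]])
    register = pd.DataFrame(
        rows, columns=["code_id", "description", "food_group", "food_type",
                       "brand", "is_supplement", "exception_class"])
    composition = pd.DataFrame(comp_rows, columns=["code_id", *panel])
    # exception flags on non-supplement codes, class mix ~ 48:62:3
    food_idx = register.index[~register["is_supplement"]].to_numpy()
    n_exc = int(round(design.exception_fraction * len(food_idx)))
    if n_exc:
        chosen = rng.choice(food_idx, size=n_exc, replace=False)
        classes = rng.choice(
            ["recipe_ingredient", "rare_unusual", "unique_unmergeable"],
            size=n_exc, p=np.array([48, 62, 3]) / 113.0)
        register.loc[chosen, "exception_class"] = classes
    return register, composition


def gen_population(design: SimulationDesign,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Adults aged 18-90; weight normal by sex, truncated positive."""
    rng = np.random.default_rng(design.rng_seed) if rng is None else rng
    n = design.n_participants
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    age = rng.uniform(18.0, 90.0, size=n)
    mean = np.where(sex == "male", 84.0, 69.0)
    sd = np.where(sex == "male", 13.0, 12.0)
    weight = rng.normal(mean, sd)
    while (weight <= 30.0).any():  # truncate implausible draws
        bad = weight <= 30.0
        weight[bad] = rng.normal(mean[bad], sd[bad])
    return pd.DataFrame({
        "participant_id": [f"P{i:04d}" for i in range(n)],
        "sex": sex, "age_y": age, "weight_kg": weight,
    })


def _zipf_probs(n: int, s: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-s)
    return w / w.sum()


def gen_consumption(design: SimulationDesign, register: pd.DataFrame,
                    participants: pd.DataFrame,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate eating occasions.

    Per participant-day the occasion count is Poisson(lambda)+1; each
    occasion picks a food type uniformly and a brand within the type by a
    Zipf(s) law over a fixed per-type popularity ranking, with a lognormal
    amount in grams. Supplement users additionally log one supplement
    occasion per day.
    """
    rng = np.random.default_rng(design.rng_seed) if rng is None else rng
    foods = register[~register["is_supplement"]]
    types = foods["food_type"].unique()
    # fixed per-type popularity ranking: permutation of the type's codes
    rank_map = {}
    for ftype, grp in foods.groupby("food_type"):
        codes = np.sort(grp["code_id"].to_numpy())
        rank_map[ftype] = rng.permutation(codes)
    max_brands = max(len(v) for v in rank_map.values())
    uniform_probs = _zipf_probs(max_brands, design.zipf_s)

    mu, sd = design.amount_lognormal
    pids = participants["participant_id"].to_numpy()
    supp_codes = register.loc[register["is_supplement"], "code_id"].to_numpy()
    uses_supp = rng.random(len(pids)) < design.supplement_fraction

    recs: list[tuple] = []
    for i, pid in enumerate(pids):
        supp_code = rng.choice(supp_codes) if (uses_supp[i] and len(supp_codes)) else None
        for day in range(1, design.recorded_days + 1):
            n_occ = rng.poisson(design.events_per_day_mean) + 1
            t_idx = rng.integers(0, len(types), size=n_occ)
            occ = 1
            for ti in t_idx:
                ranking = rank_map[types[ti]]
                if len(ranking) == max_brands:
                    probs = uniform_probs
                else:
                    probs = _zipf_probs(len(ranking), design.zipf_s)
                code = ranking[rng.choice(len(ranking), p=probs)]
                amount = rng.lognormal(mu, sd)
                recs.append((pid, day, occ, code, amount))
                occ += 1
            if supp_code is not None:
                amount = rng.lognormal(np.log(5.0), 0.3)
                recs.append((pid, day, occ, supp_code, amount))
    return pd.DataFrame(
        recs, columns=["participant_id", "day", "occasion_id", "code_id",
                       "amount_g"])


#: DRV strata used by the generator: two age bands per sex.
_DRV_AGE_BANDS = [(18.0, 65.0), (65.0, 200.0)]


def gen_drv(bundle: Bundle, config: RunConfig | None = None,
            ear_quantile: float = 0.25, ul_quantile: float = 0.9,
            nutrients: list[str] | None = None) -> DRVTable:
    """Derive a DRV table from the simulated intake distribution itself.

    EAR and UL for each micronutrient are placed at stated quantiles of the
    all-sources intake distribution within each sex x age-band stratum, so
    below-EAR and above-UL proportions are non-degenerate by construction.
    Macronutrient rules are likewise calibrated from the simulated
    percent-energy and absolute intake distributions.
    """
    from .intakes import compute_daily_intakes, percent_energy

    config = config or RunConfig()
    if nutrients is None:
        nutrients = [n for n in MICRONUTRIENTS if n in bundle.nutrients]
    intakes = compute_daily_intakes(
        bundle.events, bundle.composition, bundle.participants,
        register=bundle.register, scope="all_sources",
        recorded_days=config.recorded_days)
    values = intakes.values.join(
        bundle.participants.set_index("participant_id")[["sex", "age_y"]])
    micro_rows = []
    for sex in ("male", "female"):
        for lo, hi in _DRV_AGE_BANDS:
            stratum = values[(values["sex"] == sex)
                             & (values["age_y"] >= lo) & (values["age_y"] < hi)]
            for nutrient in nutrients:
                x = stratum[nutrient]
                if len(x) == 0:
                    continue
                ear = float(x.quantile(ear_quantile))
                ul = float(x.quantile(ul_quantile))
                if not ear < ul:
                    ul = np.nan
                micro_rows.append((nutrient, sex, lo, hi, ear, ul))
    micro = pd.DataFrame(
        micro_rows, columns=["nutrient", "sex", "age_lo", "age_hi", "ear", "ul"])

    weights = bundle.participants.set_index("participant_id")["weight_kg"]
    macro_rows = []
    if "saturated_fat" in bundle.nutrients:
        pe = percent_energy(intakes, "saturated_fat", config)
        macro_rows.append(("saturated_fat", "percent_energy_max",
                           float(pe.quantile(0.6)), np.nan))
    if "carbohydrate" in bundle.nutrients:
        pe = percent_energy(intakes, "carbohydrate", config)
        macro_rows.append(("carbohydrate", "percent_energy_range",
                           float(pe.quantile(0.25)), float(pe.quantile(0.75))))
    if "total_fat" in bundle.nutrients:
        pe = percent_energy(intakes, "total_fat", config)
        macro_rows.append(("total_fat", "percent_energy_range",
                           float(pe.quantile(0.25)), float(pe.quantile(0.75))))
    if "fibre" in bundle.nutrients:
        macro_rows.append(("fibre", "absolute_min_per_day",
                           float(intakes.values["fibre"].median()), np.nan))
    if "protein" in bundle.nutrients:
        per_kg = intakes.values["protein"] / weights
        macro_rows.append(("protein", "per_kg_bw_min",
                           float(per_kg.quantile(0.3)), np.nan))
    macro = pd.DataFrame(macro_rows, columns=["nutrient", "kind", "lo", "hi"])
    drv = DRVTable(micronutrients=micro, macro_rules=macro)
    drv.validate()
    return drv


def gen_bundle(design: SimulationDesign | None = None,
               with_drv: bool = True,
               config: RunConfig | None = None) -> Bundle:
    """Generate a full validated bundle from one seed."""
    from .io import validate_bundle

    design = design or SimulationDesign()
    rng = np.random.default_rng(design.rng_seed)
    register, composition = gen_food_db(design, rng)
    participants = gen_population(design, rng)
    events = gen_consumption(design, register, participants, rng)
    bundle = Bundle(register, composition, events, participants)
    if with_drv:
        cfg = config or RunConfig(recorded_days=design.recorded_days)
        bundle.drv = gen_drv(bundle, cfg)
    validate_bundle(bundle)
    return bundle
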