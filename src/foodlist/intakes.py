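"""Per-participant mean daily nutrient intakes, BMR and under-reporting.

Mean daily intake of nutrient n for participant p is

    intake(p, n) = sum_over_events(p) amount_g / 100 * composition(code, n)
                   / recorded_days

i.e. the record-window total divided by the number of recorded days whether
or not the participant consumed on every day. The ``food_only`` scope drops
supplement-coded events before summation; ``all_sources`` keeps them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compress import CodeMap
from .core import BMRModel, RunConfig

log = logging.getLogger(__name__)

SCOPES = ("food_only", "all_sources")


@dataclass
class IntakeMatrix:
    """participant x nutrient mean daily intakes.

    values : DataFrame indexed by participant_id, one column per nutrient,
        in the nutrient's composition unit per day.
    """

    values: pd.DataFrame
    scope: str
    list_id: str
    recorded_days: int

    @property
    def nutrients(self) -> list[str]:
        return list(self.values.columns)


def apply_codemap(events: pd.DataFrame, codemap: CodeMap) -> pd.DataFrame:
    """Rewrite event code_ids through the extensive->concise mapping.

    Row count, participants, days and amounts are untouched.
    """
    out = events.copy()
    mapped = out["code_id"].map(codemap.mapping)
    if mapped.isna().any():
        unknown = sorted(out.loc[mapped.isna(), "code_id"].unique())
        raise KeyError(f"event code(s) not in codemap: {unknown}")
    out["code_id"] = mapped.to_numpy()
    return out


def compute_daily_intakes(events: pd.DataFrame, composition: pd.DataFrame,
                          participants: pd.DataFrame, *,
                          register: pd.DataFrame, scope: str = "food_only",
                          recorded_days: int = 4,
                          list_id: str = "extensive") -> IntakeMatrix:
    """Accumulate events into a participant x nutrient intake matrix.

    Every participant in ``participants`` gets a row; participants with no
    (in-scope) events get zeros. ``register`` supplies the supplement flags
    used by the food_only scope and must describe the same list as
    ``composition``.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    nutrients = [c for c in composition.columns if c != "code_id"]
    ev = events
    if scope == "food_only" and len(ev):
        supp = set(register.loc[register["is_supplement"], "code_id"])
        ev = ev[~ev["code_id"].isin(supp)]
    pid_index = pd.Index(participants["participant_id"], name="participant_id")
    if not len(ev):
        values = pd.DataFrame(0.0, index=pid_index, columns=nutrients)
        return IntakeMatrix(values, scope, list_id, recorded_days)
    missing = set(ev["code_id"]) - set(composition["code_id"])
    if missing:
        raise KeyError(f"no composition record for code(s): {sorted(missing)}")
    comp = composition.set_index("code_id")[nutrients]
    contrib = comp.reindex(ev["code_id"]).to_numpy() * (
        ev["amount_g"].to_numpy()[:, None] / 100.0)
    totals = (pd.DataFrame(contrib, columns=nutrients,
                           index=ev["participant_id"].to_numpy())
              .groupby(level=0).sum())
    values = (totals.reindex(pid_index, fill_value=0.0) / recorded_days)
    return IntakeMatrix(values, scope, list_id, recorded_days)


def percent_energy(intakes: IntakeMatrix, nutrient: str,
                   config: RunConfig) -> pd.Series:
    """Percent of total energy contributed by one macronutrient.

    %E = 100 * intake_g * kJ_per_g / energy_kJ. Participants with zero
    energy intake get NaN (excluded from classification) and are logged.
    """
    if nutrient not in config.energy_conversion:
        raise KeyError(f"no energy conversion factor for {nutrient!r}")
    energy = intakes.values[config.energy_nutrient]
    zero = energy <= 0
    if zero.any():
        log.warning("%d participant(s) with zero energy excluded from %%E",
                    int(zero.sum()))
    factor = config.energy_conversion[nutrient]
    pe = 100.0 * intakes.values[nutrient] * factor / energy.where(~zero)
    return pe.rename(f"pctE_{nutrient}")


def estimate_bmr(participants: pd.DataFrame,
                 bmr_model: BMRModel | None = None) -> pd.Series:
    """Basal metabolic rate in MJ/d from sex, age and body weight.

    Bands are half-open [age_lo, age_hi); an age outside every band is an
    error.
    """
    model = bmr_model or BMRModel.schofield()
    coef = model.coefficients
    bmr = np.full(len(participants), np.nan)
    for _, band in coef.iterrows():
        m = ((participants["sex"] == band["sex"])
             & (participants["age_y"] >= band["age_lo"])
             & (participants["age_y"] < band["age_hi"]))
        bmr[m.to_numpy()] = (band["slope"] * participants.loc[m, "weight_kg"]
                             + band["intercept"])
    if np.isnan(bmr).any():
        bad = participants.loc[np.isnan(bmr), "participant_id"].tolist()
        raise ValueError(f"age outside all BMR bands for: {bad}")
    return pd.Series(bmr, index=participants["participant_id"].to_numpy(),
                     name="bmr_mj_d")


def flag_under_reporters(intakes: IntakeMatrix, participants: pd.DataFrame,
                         config: RunConfig,
                         bmr_model: BMRModel | None = None) -> pd.DataFrame:
    """Goldberg-style energy under-reporting screen.

    A participant is flagged when reported energy intake divided by
    estimated BMR is strictly below the cutoff (default 1.1). Energy is
    taken from the all-sources intake matrix in kJ/d and converted to MJ/d.
    """
    energy_mj = intakes.values[config.energy_nutrient] / 1000.0
    bmr = estimate_bmr(participants, bmr_model)
    ratio = energy_mj / bmr
    out = pd.DataFrame({
        "energy_intake_mj_d": energy_mj,
        "bmr_mj_d": bmr,
        "ratio": ratio,
        "flagged": ratio < config.under_reporter_cutoff,
    })
    out.index.name = "participant_id"
    log.info("under-reporters: %d of %d (%.1f%%)", int(out["flagged"].sum()),
             len(out), 100.0 * out["flagged"].mean())
    return out
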