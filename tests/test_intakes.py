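import numpy as np
import pandas as pd
import pytest

from foodlist import (
    RunConfig,
    apply_codemap,
    compute_daily_intakes,
    estimate_bmr,
    flag_under_reporters,
    percent_energy,
)
from conftest import intake_oracle


def tiny_tables():
    composition = pd.DataFrame({"code_id": ["A", "B"],
                                "protein": [10.0, 2.0],
                                "energy_kj": [500.0, 100.0]})
    participants = pd.DataFrame({
        "participant_id": ["p1", "p2"],
        "sex": ["male", "female"], "age_y": [25.0, 40.0],
        "weight_kg": [70.0, 60.0]})
    events = pd.DataFrame({
        "participant_id": ["p1"], "day": [1], "occasion_id": [1],
        "code_id": ["A"], "amount_g": [100.0]})
    register = pd.DataFrame({
        "code_id": ["A", "B"], "description": ["a", "b"],
        "food_group": ["g", "g"], "food_type": ["ta", "tb"],
        "brand": ["x", "y"], "is_supplement": [False, False],
        "exception_class": ["none", "none"]})
    return events, composition, participants, register


def test_single_event_arithmetic():
    """100 g of a 10 g-protein/100 g food over a 4-day record is 2.5 g/d."""
    events, composition, participants, register = tiny_tables()
    m = compute_daily_intakes(events, composition, participants,
                              register=register, recorded_days=4)
    assert m.values.loc["p1", "protein"] == 2.5
    assert (m.values.loc["p2"] == 0).all()  # no events -> all-zero row


def test_matrix_equals_loop_oracle(small_bundle):
    m = compute_daily_intakes(
        small_bundle.events, small_bundle.composition,
        small_bundle.participants, register=small_bundle.register,
        scope="all_sources", recorded_days=4)
    oracle = intake_oracle(small_bundle.events, small_bundle.composition,
                           small_bundle.participants, 4)
    assert np.allclose(m.values.to_numpy(), oracle.to_numpy(), rtol=1e-12)


def test_additive_over_event_partitions(small_bundle):
    ev = small_bundle.events
    half = len(ev) // 2
    kw = dict(register=small_bundle.register, scope="all_sources",
              recorded_days=4)
    full = compute_daily_intakes(ev, small_bundle.composition,
                                 small_bundle.participants, **kw)
    a = compute_daily_intakes(ev.iloc[:half], small_bundle.composition,
                              small_bundle.participants, **kw)
    b = compute_daily_intakes(ev.iloc[half:], small_bundle.composition,
                              small_bundle.participants, **kw)
    assert np.allclose((a.values + b.values).to_numpy(),
                       full.values.to_numpy(), rtol=1e-12)


def test_scope_monotone(small_bundle):
    kw = dict(register=small_bundle.register, recorded_days=4)
    food = compute_daily_intakes(small_bundle.events, small_bundle.composition,
                                 small_bundle.participants, scope="food_only",
                                 **kw)
    allsrc = compute_daily_intakes(small_bundle.events,
                                   small_bundle.composition,
                                   small_bundle.participants,
                                   scope="all_sources", **kw)
    assert (allsrc.values.to_numpy() >= food.values.to_numpy() - 1e-12).all()


def test_apply_codemap_preserves_amounts(small_bundle, small_codemap):
    mapped = apply_codemap(small_bundle.events, small_codemap)
    assert len(mapped) == len(small_bundle.events)
    pd.testing.assert_series_equal(mapped["amount_g"],
                                   small_bundle.events["amount_g"])
    # events on mergeable codes collapse onto one concise code per type
    reg = small_bundle.register.set_index("code_id")
    orig = small_bundle.events["code_id"]
    mergeable = (~reg.loc[orig, "is_supplement"].to_numpy()) & (
        reg.loc[orig, "exception_class"].to_numpy() == "none")
    ftypes = reg.loc[orig, "food_type"].to_numpy()
    merged = mapped[mergeable]
    for ftype, grp in merged.groupby(ftypes[mergeable]):
        assert grp["code_id"].nunique() == 1


def test_apply_codemap_unmapped_code_raises(small_bundle, small_codemap):
    ev = small_bundle.events.copy()
    ev.loc[ev.index[0], "code_id"] = "NOPE"
    with pytest.raises(KeyError, match="NOPE"):
        apply_codemap(ev, small_codemap)


def test_missing_composition_is_named(small_bundle):
    comp = small_bundle.composition.iloc[1:]
    dropped = small_bundle.composition["code_id"].iloc[0]
    if dropped not in set(small_bundle.events["code_id"]):
        pytest.skip("dropped code never consumed in fixture")
    with pytest.raises(KeyError, match=str(dropped)):
        compute_daily_intakes(small_bundle.events, comp,
                              small_bundle.participants,
                              register=small_bundle.register, recorded_days=4)


def test_percent_energy_consistent_on_sigma0(sigma0_bundle):
    """%E over protein+carbohydrate+fat+alcohol sums to 100 when the energy
    column is built from the same conversion factors."""
    config = RunConfig()
    m = compute_daily_intakes(
        sigma0_bundle.events, sigma0_bundle.composition,
        sigma0_bundle.participants, register=sigma0_bundle.register,
        scope="food_only", recorded_days=4)
    total = sum(percent_energy(m, n, config) for n in
                ["protein", "carbohydrate", "total_fat", "alcohol"])
    assert np.allclose(total.dropna(), 100.0, atol=1e-9)


def test_percent_energy_zero_energy_excluded():
    events, composition, participants, register = tiny_tables()
    m = compute_daily_intakes(events, composition, participants,
                              register=register, recorded_days=4)
    pe = percent_energy(m, "protein", RunConfig())
    assert np.isnan(pe.loc["p2"])  # zero energy -> excluded
    # p1: 25 g/d protein * 17 kJ/g over 125 kJ/d energy
    assert pe.loc["p1"] == pytest.approx(100.0 * 2.5 * 17.0 / 12.5 / 10)


def test_schofield_point_value():
    """Male, 25 y, 70 kg: 0.063*70 + 2.896 MJ/d from the 18-30 band."""
    participants = pd.DataFrame({
        "participant_id": ["p"], "sex": ["male"], "age_y": [25.0],
        "weight_kg": [70.0]})
    bmr = estimate_bmr(participants)
    assert bmr.loc["p"] == pytest.approx(0.063 * 70 + 2.896)


def test_bmr_age_outside_bands_raises():
    participants = pd.DataFrame({
        "participant_id": ["p"], "sex": ["male"], "age_y": [10.0],
        "weight_kg": [40.0]})
    with pytest.raises(ValueError, match="p"):
        estimate_bmr(participants)


def test_under_reporter_cutoff_is_strict():
    """EI:BMR exactly at the cutoff is not flagged; just below is."""
    participants = pd.DataFrame({
        "participant_id": ["p1", "p2"], "sex": ["male", "male"],
        "age_y": [25.0, 25.0], "weight_kg": [70.0, 70.0]})
    bmr = 0.063 * 70 + 2.896
    config = RunConfig()

    class FakeMatrix:
        pass

    m = FakeMatrix()
    m.values = pd.DataFrame(
        {"energy_kj": [1.1 * bmr * 1000.0, 0.959 * bmr * 1000.0]},
        index=pd.Index(["p1", "p2"], name="participant_id"))
    flags = flag_under_reporters(m, participants, config)
    assert not flags.loc["p1", "flagged"]  # ratio == 1.1 exactly
    assert flags.loc["p2", "flagged"]


def test_flagged_fraction_matches_count_oracle(small_bundle):
    config = RunConfig()
    m = compute_daily_intakes(
        small_bundle.events, small_bundle.composition,
        small_bundle.participants, register=small_bundle.register,
        scope="all_sources", recorded_days=4)
    flags = flag_under_reporters(m, small_bundle.participants, config)
    bmr = estimate_bmr(small_bundle.participants)
    expected = sum(
        1 for pid in flags.index
        if m.values.loc[pid, "energy_kj"] / 1000.0 / bmr.loc[pid] < 1.1)
    assert int(flags["flagged"].sum()) == expected
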