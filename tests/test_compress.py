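import numpy as np
import pandas as pd
import pytest

from foodlist import (
    derive_concise_list,
    summarize_reduction,
    tally_occasions,
)
from foodlist.compress import compress_bundle, load_codemap, save_codemap
from foodlist.synth import SimulationDesign, gen_food_db


def make_register(rows):
    return pd.DataFrame(rows, columns=[
        "code_id", "description", "food_group", "food_type", "brand",
        "is_supplement", "exception_class"])


def flat_composition(codes, value=10.0):
    return pd.DataFrame({"code_id": list(codes),
                         "protein": [value] * len(codes)})


def make_events(code_counts):
    rows = []
    for code, n in code_counts.items():
        for i in range(n):
            rows.append((f"P{i:03d}", 1, i + 1, code, 100.0))
    return pd.DataFrame(rows, columns=[
        "participant_id", "day", "occasion_id", "code_id", "amount_g"])


def test_tally_counts_and_zero_fill():
    reg = make_register([
        (f"Y{i}", f"yoghurt {i}", "dairy", "yoghurt", f"b{i}", False, "none")
        for i in range(10)])
    counts = {f"Y{i}": c for i, c in
              enumerate([1, 5, 12, 3, 396, 40, 7, 2, 9, 0])}
    events = make_events(counts)
    occ = tally_occasions(events, reg)
    assert occ.sum() == len(events)  # conservation
    assert occ.loc["Y9"] == 0  # never consumed
    assert occ.idxmax() == "Y4" and occ.max() == 396


def test_most_frequent_brand_becomes_representative():
    """Ten yoghurt brands, 1..396 occasions: the 396-count brand's
    composition is carried by the generic code."""
    reg = make_register([
        (f"Y{i}", f"yoghurt {i}", "dairy", "yoghurt", f"b{i}", False, "none")
        for i in range(10)])
    comp = pd.DataFrame({"code_id": [f"Y{i}" for i in range(10)],
                         "protein": np.arange(10, dtype=float)})
    counts = dict(zip((f"Y{i}" for i in range(10)),
                      [1, 5, 12, 3, 396, 40, 7, 2, 9, 11]))
    occ = tally_occasions(make_events(counts), reg)
    cm = derive_concise_list(reg, comp, occ)
    assert cm.n_concise == 1
    generic = cm.mapping.iloc[0]
    assert (cm.mapping == generic).all()
    prov = cm.provenance.set_index("concise_code_id")
    assert prov.loc[generic, "representative_code_id"] == "Y4"
    assert prov.loc[generic, "occasions"] == 396
    assert cm.concise_composition.set_index("code_id").loc[generic, "protein"] == 4.0


def test_tie_breaks_to_smallest_code_id():
    reg = make_register([
        ("B010", "x", "g", "t", "b", False, "none"),
        ("B002", "y", "g", "t", "b", False, "none"),
        ("B005", "z", "g", "t", "b", False, "none")])
    comp = flat_composition(["B010", "B002", "B005"])
    occ = pd.Series([5, 5, 1], index=["B010", "B002", "B005"])
    cm = derive_concise_list(reg, comp, occ)
    rep = cm.provenance["representative_code_id"].iloc[0]
    # brute-force oracle: max count, then lexicographically smallest id
    best = min([c for c in occ.index if occ[c] == occ.max()])
    assert rep == best == "B002"


def test_singleton_type_maps_to_itself():
    reg = make_register([("A1", "only", "g", "t1", "b", False, "none")])
    cm = derive_concise_list(reg, flat_composition(["A1"]),
                             pd.Series([3], index=["A1"]))
    assert cm.mapping.loc["A1"] == "A1"
    pd.testing.assert_frame_equal(cm.concise_composition,
                                  flat_composition(["A1"]))


def test_supplements_and_exceptions_self_map(small_bundle, small_codemap):
    reg = small_bundle.register
    keep = reg[(reg["is_supplement"]) | (reg["exception_class"] != "none")]
    for code in keep["code_id"]:
        assert small_codemap.mapping.loc[code] == code


def test_idempotent_on_concise_register(small_bundle, small_codemap):
    """Re-deriving on the concise list returns the identity mapping."""
    occ2 = tally_occasions(small_bundle.events.assign(
        code_id=small_bundle.events["code_id"].map(small_codemap.mapping)),
        small_codemap.concise_register)
    cm2 = derive_concise_list(small_codemap.concise_register,
                              small_codemap.concise_composition, occ2)
    assert (cm2.mapping.index == cm2.mapping.to_numpy()).all()


def test_concise_compositions_are_copies(small_bundle, small_codemap):
    """Every concise record is bitwise equal to some extensive record."""
    ext = small_bundle.composition.set_index("code_id")
    con = small_codemap.concise_composition.set_index("code_id")
    prov = small_codemap.provenance.set_index("concise_code_id")
    for code in con.index:
        rep = prov.loc[code, "representative_code_id"]
        assert (con.loc[code].to_numpy() == ext.loc[rep].to_numpy()).all()


def test_image_size_formula(small_bundle, small_codemap):
    reg = small_bundle.register
    mergeable = (~reg["is_supplement"]) & (reg["exception_class"] == "none")
    n_types = reg.loc[mergeable, "food_type"].nunique()
    n_kept = int((~mergeable).sum())
    assert small_codemap.n_concise == n_types + n_kept


def test_reduction_summary_counts():
    """Synthetic 20x2x8 design, no exceptions: concise = 40 types + supplements."""
    d = SimulationDesign(n_groups=20, types_per_group=2, brands_per_type=8,
                         exception_fraction=0.0, n_supplement_codes=10,
                         rng_seed=1)
    register, composition = gen_food_db(d)
    occ = pd.Series(1, index=register["code_id"])
    cm = derive_concise_list(register, composition, occ)
    assert cm.n_extensive == 20 * 2 * 8 + 10
    assert cm.n_concise == 40 + 10
    summary = summarize_reduction(register, cm)
    total = summary[summary["food_group"] == "total"].iloc[0]
    assert total["n_extensive"] == 330 and total["n_concise"] == 50
    expected_pct = round(100 * (330 - 50) / 330)
    assert total["percent_reduction"] == expected_pct
    # per-group totals add up
    groups = summary[summary["food_group"] != "total"]
    assert groups["n_extensive"].sum() == total["n_extensive"]
    assert groups["n_concise"].sum() == total["n_concise"]


def test_no_merge_possible_zero_reduction():
    reg = make_register([
        ("A1", "a", "g1", "t1", "b", False, "none"),
        ("A2", "b", "g1", "t2", "b", False, "none")])
    cm = derive_concise_list(reg, flat_composition(["A1", "A2"]),
                             pd.Series([1, 1], index=["A1", "A2"]))
    summary = summarize_reduction(reg, cm)
    assert (summary["percent_reduction"] == 0).all()


def test_codemap_roundtrip(small_codemap, tmp_path):
    save_codemap(small_codemap, tmp_path)
    back = load_codemap(tmp_path)
    pd.testing.assert_series_equal(back.mapping, small_codemap.mapping)
    pd.testing.assert_frame_equal(
        back.concise_composition.reset_index(drop=True),
        small_codemap.concise_composition.reset_index(drop=True))
    pd.testing.assert_frame_equal(
        back.concise_register.reset_index(drop=True),
        small_codemap.concise_register.reset_index(drop=True))
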