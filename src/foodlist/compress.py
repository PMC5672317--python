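"""Derive a concise food list from an extensive brand-level list.

Within each food type, all ordinary brand codes are recoded to one generic
code that carries the nutritional composition of the type's most frequently
consumed code (ties broken by smallest code_id). Nutritional supplements and
flagged exception codes (recipe ingredients, rare/unusual items, items
unique to one participant) keep their original code and composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import Bundle

log = logging.getLogger(__name__)

GENERIC_PREFIX = "g_"


@dataclass
class CodeMap:
    """Extensive -> concise mapping plus the concise-list tables.

    mapping : pd.Series indexed by extensive code_id, values concise code_id.
    concise_register : register rows for the image codes.
    concise_composition : composition rows for the image codes; every row is
        bitwise equal to some extensive row (the representative's).
    provenance : per concise code, the representative extensive code and its
        eating-occasion count.
    """

    mapping: pd.Series
    concise_register: pd.DataFrame
    concise_composition: pd.DataFrame
    provenance: pd.DataFrame

    @property
    def n_extensive(self) -> int:
        return len(self.mapping)

    @property
    def n_concise(self) -> int:
        return self.mapping.nunique()

    @classmethod
    def identity(cls, register: pd.DataFrame,
                 composition: pd.DataFrame) -> "CodeMap":
        codes = register["code_id"]
        return cls(
            mapping=pd.Series(codes.to_numpy(), index=codes.to_numpy(),
                              name="concise_code_id"),
            concise_register=register.copy(),
            concise_composition=composition.copy(),
            provenance=pd.DataFrame({
                "concise_code_id": codes.to_numpy(),
                "representative_code_id": codes.to_numpy(),
                "occasions": 0}),
        )


def tally_occasions(events: pd.DataFrame,
                    register: pd.DataFrame) -> pd.Series:
    """Eating occasions per food code (one event row = one occasion).

    Codes never consumed get a count of 0.
    """
    counts = events.groupby("code_id").size() if len(events) else pd.Series(dtype=int)
    return (counts.reindex(register["code_id"], fill_value=0)
            .astype(int).rename("occasions"))


def derive_concise_list(register: pd.DataFrame, composition: pd.DataFrame,
                        occasions: pd.Series) -> CodeMap:
    """Build the concise list by the most-frequent-representative rule.

    Mergeable codes (not supplements, exception_class == "none") collapse,
    per food type, onto one code whose composition is the representative's:
    the member with the most eating occasions, ties broken by smallest
    code_id. A type with a single mergeable code keeps its own code id, so
    applying the derivation to an already-concise register is the identity.
    """
    comp = composition.set_index("code_id")
    mergeable = (~register["is_supplement"]) & (register["exception_class"] == "none")
    mapping: dict[str, str] = {}
    reg_rows, prov_rows = [], []
    image_codes: list[str] = []

    for ftype, grp in register[mergeable].groupby("food_type", sort=True):
        codes = grp["code_id"].sort_values().to_numpy()
        counts = occasions.reindex(codes, fill_value=0)
        if counts.sum() == 0:
            log.warning("food_type %r has zero occasions; representative "
                        "chosen by code order", ftype)
        # argmax with lexicographic tie-break: codes are pre-sorted, idxmax
        # returns the first (smallest) index at the maximum
        rep = counts.idxmax()
        generic = rep if len(codes) == 1 else f"{GENERIC_PREFIX}{ftype}"
        for c in codes:
            mapping[c] = generic
        rep_row = grp[grp["code_id"] == rep].iloc[0]
        reg_rows.append({
            "code_id": generic,
            "description": (rep_row["description"] if len(codes) == 1
                            else f"generic {ftype}"),
            "food_group": rep_row["food_group"], "food_type": ftype,
            "brand": "generic", "is_supplement": False,
            "exception_class": "none"})
        prov_rows.append((generic, rep, int(counts.loc[rep])))
        image_codes.append(generic)

    retained = register[~mergeable]
    for _, row in retained.iterrows():
        c = row["code_id"]
        mapping[c] = c
        reg_rows.append(row.to_dict())
        prov_rows.append((c, c, int(occasions.get(c, 0))))
        image_codes.append(c)

    if len(set(image_codes)) != len(image_codes):
        raise ValueError("generic code id collides with an existing code id")

    concise_register = (pd.DataFrame(reg_rows)
                        .sort_values("code_id").reset_index(drop=True))
    provenance = (pd.DataFrame(prov_rows, columns=[
        "concise_code_id", "representative_code_id", "occasions"])
        .sort_values("concise_code_id").reset_index(drop=True))
    # concise composition = representative's record, bitwise
    concise_composition = comp.loc[provenance["representative_code_id"]].copy()
    concise_composition.index = provenance["concise_code_id"].to_numpy()
    concise_composition = (concise_composition.rename_axis("code_id")
                           .reset_index())
    ext_codes = register["code_id"]
    mapping_s = pd.Series([mapping[c] for c in ext_codes],
                          index=ext_codes.to_numpy(), name="concise_code_id")
    return CodeMap(mapping_s, concise_register, concise_composition, provenance)


def compress_bundle(bundle: Bundle) -> CodeMap:
    occ = tally_occasions(bundle.events, bundle.register)
    return derive_concise_list(bundle.register, bundle.composition, occ)


def summarize_reduction(register: pd.DataFrame, codemap: CodeMap) -> pd.DataFrame:
    """Per-food-group extensive/concise counts with a total row.

    percent_reduction = 100 * (n_extensive - n_concise) / n_extensive,
    rounded to the nearest integer percent.
    """
    reg = register.merge(codemap.mapping.rename("concise_code_id"),
                         left_on="code_id", right_index=True)
    rows = []
    for group, grp in reg.groupby("food_group", sort=True):
        n_ext = len(grp)
        n_con = grp["concise_code_id"].nunique()
        rows.append((group, n_ext, n_con))
    rows.append(("total", len(reg), int(reg["concise_code_id"].nunique())))
    out = pd.DataFrame(rows, columns=["food_group", "n_extensive", "n_concise"])
    out["percent_reduction"] = (
        100.0 * (out["n_extensive"] - out["n_concise"]) / out["n_extensive"]
    ).round(0).astype(int)
    return out


def codemap_to_frame(codemap: CodeMap) -> pd.DataFrame:
    """Flat TSV-ready view of the mapping with provenance."""
    df = codemap.mapping.rename_axis("extensive_code_id").reset_index()
    return df.merge(codemap.provenance, on="concise_code_id", how="left")


CODEMAP_FILES = {
    "mapping": "codemap.tsv",
    "register": "concise_foods.tsv",
    "composition": "concise_composition.tsv",
}


def save_codemap(codemap: CodeMap, out_dir) -> None:
    from pathlib import Path

    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    codemap_to_frame(codemap).to_csv(d / CODEMAP_FILES["mapping"], sep="\t",
                                     index=False)
    codemap.concise_register.to_csv(d / CODEMAP_FILES["register"], sep="\t",
                                    index=False)
    codemap.concise_composition.to_csv(
        d / CODEMAP_FILES["composition"], sep="\t", index=False,
        float_format="%.17g")


def load_codemap(in_dir) -> CodeMap:
    from pathlib import Path

    d = Path(in_dir)
    flat = pd.read_csv(d / CODEMAP_FILES["mapping"], sep="\t",
                       dtype={"extensive_code_id": str, "concise_code_id": str,
                              "representative_code_id": str})
    register = pd.read_csv(d / CODEMAP_FILES["register"], sep="\t",
                           dtype={"code_id": str})
    register["is_supplement"] = register["is_supplement"].astype(bool)
    composition = pd.read_csv(d / CODEMAP_FILES["composition"], sep="\t",
                              dtype={"code_id": str})
    nutrient_cols = [c for c in composition.columns if c != "code_id"]
    composition[nutrient_cols] = composition[nutrient_cols].astype(float)
    mapping = pd.Series(flat["concise_code_id"].to_numpy(),
                        index=flat["extensive_code_id"].to_numpy(),
                        name="concise_code_id")
    provenance = (flat[["concise_code_id", "representative_code_id",
                        "occasions"]].drop_duplicates()
                  .reset_index(drop=True))
    return CodeMap(mapping, register, composition, provenance)
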