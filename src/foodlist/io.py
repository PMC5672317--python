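"""Validated TSV readers/writers for survey bundles and report tables.

All files are UTF-8 TSV with a header row. A *bundle* is the set of tables a
survey analysis needs: food register, composition, consumption events,
participants and (optionally) a DRV table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    DRVTable,
    EVENT_COLUMNS,
    EXCEPTION_CLASSES,
    PARTICIPANT_COLUMNS,
    REGISTER_COLUMNS,
    RunConfig,
    SEXES,
)

log = logging.getLogger(__name__)

BUNDLE_FILES = {
    "register": "foods.tsv",
    "composition": "composition.tsv",
    "events": "events.tsv",
    "participants": "participants.tsv",
    "drv": "drv.tsv",
}


class SchemaError(ValueError):
    """A table is missing required columns or has ill-typed values."""


class IntegrityError(ValueError):
    """Cross-table referential integrity is violated."""


@dataclass
class Bundle:
    register: pd.DataFrame
    composition: pd.DataFrame
    events: pd.DataFrame
    participants: pd.DataFrame
    drv: DRVTable | None = None

    @property
    def nutrients(self) -> list[str]:
        return [c for c in self.composition.columns if c != "code_id"]


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def validate_bundle(bundle: Bundle) -> None:
    """Schema + referential integrity checks; raises listing every offender."""
    _require_columns(bundle.register, REGISTER_COLUMNS, "register")
    _require_columns(bundle.events, EVENT_COLUMNS, "events")
    _require_columns(bundle.participants, PARTICIPANT_COLUMNS, "participants")
    _require_columns(bundle.composition, ["code_id"], "composition")

    reg = bundle.register
    dup = reg["code_id"][reg["code_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicate code_id in register: {sorted(set(dup))}")
    bad_exc = set(reg["exception_class"]) - set(EXCEPTION_CLASSES)
    if bad_exc:
        raise SchemaError(f"register: unknown exception_class {sorted(bad_exc)}")
    # food_type must determine a single food_group
    n_groups = reg.groupby("food_type")["food_group"].nunique()
    split = n_groups[n_groups > 1]
    if len(split):
        raise IntegrityError(
            f"food_type(s) span multiple food_groups: {sorted(split.index)}")

    bad_sex = set(bundle.participants["sex"]) - set(SEXES)
    if bad_sex:
        raise SchemaError(f"participants: unknown sex value(s) {sorted(bad_sex)}")

    ev = bundle.events
    if len(ev) and (ev["amount_g"] <= 0).any():
        n = int((ev["amount_g"] <= 0).sum())
        raise SchemaError(f"events: {n} row(s) with non-positive amount_g")
    violations = integrity_violations(bundle)
    for kind, codes in violations.items():
        if codes:
            raise IntegrityError(f"{kind}: {codes}")
    comp_vals = bundle.composition.drop(columns="code_id")
    if len(comp_vals) and (comp_vals.to_numpy(dtype=float) < 0).any():
        raise SchemaError("composition: negative nutrient amounts")
    if bundle.drv is not None:
        bundle.drv.validate()
    log.info("bundle validated: %d codes, %d events, %d participants",
             len(reg), len(ev), len(bundle.participants))


def integrity_violations(bundle: Bundle) -> dict[str, list[str]]:
    """Referential-integrity check: every violating id, by kind.

    Complete by construction: injecting k orphan codes yields exactly k
    entries under "events reference unknown food code(s)".
    """
    ev = bundle.events
    if not len(ev):
        return {}
    reg_codes = set(bundle.register["code_id"])
    comp_codes = set(bundle.composition["code_id"])
    pids = set(bundle.participants["participant_id"])
    return {
        "events reference unknown food code(s)":
            sorted(set(ev["code_id"]) - reg_codes),
        "events reference code(s) without composition":
            sorted((set(ev["code_id"]) & reg_codes) - comp_codes),
        "events reference unknown participant(s)":
            sorted(set(ev["participant_id"]) - pids),
    }


def read_drv(path: Path) -> DRVTable:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["nutrient", "kind"], "drv")
    micro = (df[df["kind"] == "micronutrient"]
             [["nutrient", "sex", "age_lo", "age_hi", "ear", "ul"]]
             .reset_index(drop=True))
    macro = (df[df["kind"] != "micronutrient"]
             [["nutrient", "kind", "lo", "hi"]].reset_index(drop=True))
    return DRVTable(micronutrients=micro, macro_rules=macro)


def write_drv(drv: DRVTable, path: Path) -> None:
    micro = drv.micronutrients.copy()
    micro.insert(1, "kind", "micronutrient")
    macro = drv.macro_rules.copy()
    out = pd.concat([micro, macro], ignore_index=True)
    cols = ["nutrient", "kind", "sex", "age_lo", "age_hi", "ear", "ul", "lo", "hi"]
    for c in cols:
        if c not in out.columns:
            out[c] = np.nan
    out[cols].to_csv(path, sep="\t", index=False)


def read_tables(bundle_dir: str | Path, require_drv: bool = False) -> Bundle:
    """Read and validate a full survey bundle from a directory of TSVs."""
    d = Path(bundle_dir)
    for key in ("register", "composition", "events", "participants"):
        if not (d / BUNDLE_FILES[key]).exists():
            raise FileNotFoundError(d / BUNDLE_FILES[key])
    register = pd.read_csv(d / BUNDLE_FILES["register"], sep="\t",
                           dtype={"code_id": str})
    register["is_supplement"] = register["is_supplement"].astype(bool)
    composition = pd.read_csv(d / BUNDLE_FILES["composition"], sep="\t",
                              dtype={"code_id": str})
    nutrient_cols = [c for c in composition.columns if c != "code_id"]
    composition[nutrient_cols] = composition[nutrient_cols].astype(float)
    events = pd.read_csv(d / BUNDLE_FILES["events"], sep="\t",
                         dtype={"code_id": str, "participant_id": str})
    events["amount_g"] = events["amount_g"].astype(float)
    participants = pd.read_csv(d / BUNDLE_FILES["participants"], sep="\t",
                               dtype={"participant_id": str})
    drv = None
    drv_path = d / BUNDLE_FILES["drv"]
    if drv_path.exists():
        drv = read_drv(drv_path)
    elif require_drv:
        raise FileNotFoundError(drv_path)
    bundle = Bundle(register, composition, events, participants, drv)
    validate_bundle(bundle)
    return bundle


# Composition values are written in full repr precision so that a write→read
# round trip is exact; report tables are the human-facing, rounded surface.
_FLOAT_FMT = "%.17g"


def write_tables(bundle: Bundle, out_dir: str | Path) -> None:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    bundle.register.to_csv(d / BUNDLE_FILES["register"], sep="\t", index=False)
    bundle.composition.to_csv(d / BUNDLE_FILES["composition"], sep="\t",
                              index=False, float_format=_FLOAT_FMT)
    bundle.events.to_csv(d / BUNDLE_FILES["events"], sep="\t", index=False,
                         float_format=_FLOAT_FMT)
    bundle.participants.to_csv(d / BUNDLE_FILES["participants"], sep="\t",
                               index=False, float_format=_FLOAT_FMT)
    if bundle.drv is not None:
        write_drv(bundle.drv, d / BUNDLE_FILES["drv"])


# ---------------------------------------------------------------------------
# report tables

REPORT_FILES = {
    "reduction": "reduction.tsv",
    "nutrient_stats": "nutrient_stats.tsv",
    "tertile_agreement": "tertile_agreement.tsv",
    "drv_macros": "drv_macros.tsv",
    "ear": "ear.tsv",
    "ul": "ul.tsv",
}

#: column-name fragment -> decimals for report rounding
_ROUND_RULES = (("kappa", 3), ("cohens_d", 3), ("d_z", 3), ("rho", 3),
                ("p_value", 4), ("pct", 1), ("percent", 1), ("mean", 3),
                ("sd", 3), ("prop", 3))


def _round_for_report(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        for frag, nd in _ROUND_RULES:
            if frag in col:
                out[col] = out[col].round(nd)
                break
        else:
            out[col] = out[col].round(3)
    return out


def write_report_tables(tables: dict[str, pd.DataFrame],
                        out_dir: str | Path) -> dict[str, Path]:
    """Write report tables as rounded TSVs with deterministic layout.

    Percentages get 1 decimal, κ/d/ρ 3 decimals; column order is taken from
    the DataFrames, which the concordance stage emits deterministically.
    """
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for key, df in tables.items():
        fname = REPORT_FILES.get(key, f"{key}.tsv")
        path = d / fname
        _round_for_report(df).to_csv(path, sep="\t", index=False)
        written[key] = path
    return written


# ---------------------------------------------------------------------------
# run manifest

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Deterministic record of one pipeline run.

    Holds the config snapshot, seeds, input/output file hashes and the
    package version. Wall-clock timings are deliberately excluded (they go
    to the log) so identical inputs yield a byte-identical manifest.
    """

    config: dict
    seed: int
    version: str
    input_hashes: dict[str, str] = field(default_factory=dict)
    output_hashes: dict[str, str] = field(default_factory=dict)

    @classmethod
    def collect(cls, config: RunConfig, seed: int,
                input_paths: dict[str, Path] | None = None,
                output_paths: dict[str, Path] | None = None) -> "RunManifest":
        from . import __version__
        return cls(
            config=config.to_dict(),
            seed=seed,
            version=__version__,
            input_hashes={k: _sha256(Path(p)) for k, p in
                          sorted((input_paths or {}).items())},
            output_hashes={k: _sha256(Path(p)) for k, p in
                           sorted((output_paths or {}).items())},
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
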