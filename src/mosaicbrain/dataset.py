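"""Assembly of the species-level analysis table.

Individual brain records (cerebrum CX, cerebellum CB, whole brain, body) are
averaged to species means on the raw mass scale, the "rest of brain" (RoB =
brain - CX - CB, minus olfactory bulbs where measured) is derived, species
whose components sum to the whole brain (leaving no RoB) are excluded, masses
are log10-transformed, and ecological covariates are merged against the tree.

Mass and volume are treated as interchangeable, as is conventional for brain
allometry given near-unit tissue density.  Olfactory bulbs are subtracted
from RoB wherever OB measurements exist; species without OB data keep their
full RoB, and the exclusion log records which rule fired for every species
that was dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import PhyloTree

__all__ = [
    "DatasetError", "ExclusionLog",
    "species_means", "validate_components", "compute_rob",
    "build_brain_table", "merge_traits",
    "read_individuals", "read_eco_table", "read_table", "write_table",
]

ECO_COLUMNS = ["group_size", "social_repertoire", "diet_breadth",
               "latitude_range", "max_dive_time", "tonal_range",
               "tonal_complexity"]


class DatasetError(ValueError):
    """Raised for invalid or inconsistent trait tables."""


@dataclass
class ExclusionLog:
    """Per-species record of why rows were dropped during assembly."""

    entries: list = field(default_factory=list)

    def add(self, species: str, stage: str, reason: str):
        self.entries.append({"species": species, "stage": stage, "reason": reason})

    def species(self) -> list:
        return sorted({e["species"] for e in self.entries})

    def to_json(self, path=None) -> str:
        text = json.dumps(self.entries, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def species_means(records: pd.DataFrame,
                  mass_columns=("cx_mass", "cb_mass", "brain_mass", "body_mass"),
                  ) -> pd.DataFrame:
    """Arithmetic per-species means of raw masses (log transform comes later).

    ``records`` needs a ``species`` column; mass columns absent from the frame
    are ignored, NaNs are ignored per column.  Adds ``n_individuals``.
    """
    if "species" not in records.columns:
        raise DatasetError("records need a 'species' column")
    cols = [c for c in mass_columns if c in records.columns]
    g = records.groupby("species", sort=True)
    out = g[cols].mean()
    out["n_individuals"] = g.size()
    return out.reset_index()


def validate_components(brain, cx, cb, tol: float = 1e-3):
    """Keep/exclude decision for one species: exclude when CX + CB leaves a
    relative RoB of at most ``tol`` (components swallow the whole brain,
    implying one of them includes extra structures).

    Returns ``(keep: bool, reason: str | None)``.
    """
    if brain <= 0:
        raise DatasetError("brain mass must be positive")
    frac = (brain - cx - cb) / brain
    if frac <= tol:
        return False, (f"CX + CB account for the whole brain "
                       f"(relative RoB {frac:.2e} <= tol {tol:g})")
    return True, None


def compute_rob(brain, cx, cb, olfactory_bulb=None):
    """RoB = brain - CX - CB - OB (OB subtracted only when measured)."""
    ob = 0.0 if olfactory_bulb is None or (isinstance(olfactory_bulb, float)
                                           and np.isnan(olfactory_bulb)) else olfactory_bulb
    rob = brain - cx - cb - ob
    if np.ndim(rob) == 0:
        if rob <= 0:
            raise DatasetError("non-positive RoB; species should have been "
                               "excluded by validate_components")
    return rob


def build_brain_table(means: pd.DataFrame, group_map: pd.DataFrame | dict = None,
                      tol: float = 1e-3, log=None) -> pd.DataFrame:
    """Species-mean masses -> log10 analysis table with group flags.

    ``means`` holds per-species raw masses (columns cx_mass, cb_mass,
    brain_mass, optional body_mass, optional ob_mass).  Applies the
    component-validity exclusion, derives RoB, takes log10, and attaches any
    boolean group flags from ``group_map`` (dict or frame indexed by species,
    e.g. is_cetacean / is_mysticete / is_primate / is_placental).
    """
    log = log if log is not None else ExclusionLog()
    rows = []
    for _, r in means.iterrows():
        sp = r["species"]
        brain, cx, cb = r["brain_mass"], r["cx_mass"], r["cb_mass"]
        if any(pd.isna(v) for v in (brain, cx, cb)):
            log.add(sp, "components", "missing CX, CB or brain mass")
            continue
        if min(brain, cx, cb) < 0 or brain <= 0:
            log.add(sp, "components", "non-positive mass")
            continue
        keep, reason = validate_components(brain, cx, cb, tol=tol)
        if not keep:
            log.add(sp, "components", reason)
            continue
        ob = r.get("ob_mass", np.nan)
        rob = compute_rob(brain, cx, cb, None if pd.isna(ob) else ob)
        row = {
            "species": sp,
            "log_cx": np.log10(cx), "log_cb": np.log10(cb),
            "log_brain": np.log10(brain), "log_rob": np.log10(rob),
            "ob_subtracted": not pd.isna(ob),
            "n_individuals": int(r.get("n_individuals", 1)),
        }
        body = r.get("body_mass", np.nan)
        row["log_body"] = np.log10(body) if not pd.isna(body) and body > 0 else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    if group_map is not None and len(table):
        gm = pd.DataFrame(group_map)
        if "species" in gm.columns:
            gm = gm.set_index("species")
        for col in gm.columns:
            table[col] = table["species"].map(gm[col]).fillna(False).astype(bool)
    return table


def merge_traits(brain: pd.DataFrame, eco: pd.DataFrame | None,
                 tree: PhyloTree, log=None) -> pd.DataFrame:
    """Inner-join brain and ecological tables on species present in the tree.

    Species lost at each stage are written to the exclusion log; an empty
    intersection is an error.
    """
    log = log if log is not None else ExclusionLog()
    tips = set(tree.tip_labels)
    keep = brain[brain["species"].isin(tips)].copy()
    for sp in sorted(set(brain["species"]) - tips):
        log.add(sp, "tree", "species not a tip of the tree")
    if eco is not None:
        eco_sp = set(eco["species"])
        for sp in sorted(set(keep["species"]) - eco_sp):
            log.add(sp, "eco", "no ecological covariates")
        keep = keep.merge(eco, on="species", how="inner")
    if keep.empty:
        raise DatasetError("no species shared between tree and trait tables")
    return keep.reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O helpers (TSV/CSV with a mandatory case-sensitive `species` column)


def read_table(path) -> pd.DataFrame:
    """Read a TSV/CSV trait table (correctly-rounded float parsing, so a
    write/read cycle through :func:`write_table` is bit-identical)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "species" not in df.columns:
        raise DatasetError(f"{path}: missing mandatory 'species' column")
    return df


_read_table = read_table  # backward-compatible internal alias


def read_individuals(path) -> pd.DataFrame:
    """Individual-level records: raw masses (cx_mass, cb_mass, brain_mass)
    or already-logged components (log_cx, log_cb, ...)."""
    df = _read_table(path)
    raw = {"cx_mass", "cb_mass", "brain_mass"} <= set(df.columns)
    logged = {"log_cx", "log_cb"} <= set(df.columns)
    if not (raw or logged):
        raise DatasetError(f"{path}: need cx_mass/cb_mass/brain_mass "
                           f"or log_cx/log_cb columns")
    return df


def read_eco_table(path) -> pd.DataFrame:
    """Ecological covariates; validates diet_breadth codes when present."""
    df = _read_table(path)
    if "diet_breadth" in df.columns:
        vals = df["diet_breadth"].dropna()
        if not vals.isin([1, 2, 3, 4]).all():
            raise DatasetError("diet_breadth must be coded 1-4")
    return df


def write_table(df: pd.DataFrame, path):
    """TSV/CSV writer at full float precision (%.17g), so numeric columns
    survive a write/read round trip bit-identically."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
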