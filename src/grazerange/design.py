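"""Fixed-effect design matrices for the use and RSF models.

The vocabulary is deliberately closed: continuous terms are the scaled tree
cover, NDVI and distance-to-site (plus their squares, taken on the scaled
variable), categorical terms are the grazing treatment (reference *before*)
and time of day (reference *day*), and the calving/rut flags are 0/1.
Interactions are written ``a:b[:c]`` and expand to elementwise products of
the component columns.  Column construction is deterministic: canonical
level order, components in the order written.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# continuous basis: term name -> (source column, power)
CONT_BASIS = {
    "cover": ("cover_s", 1),
    "cover2": ("cover_s", 2),
    "ndvi": ("ndvi_s", 1),
    "ndvi2": ("ndvi_s", 2),
    "dist": ("dist_site_s", 1),
    "dist2": ("dist_site_s", 2),
}

# factors: name -> (reference level, canonical non-reference levels)
FACTORS = {
    "treatment": ("before", ("early", "ongoing", "after")),
    "tod": ("day", ("night", "twilight")),
}

BINARY = ("calving", "rut")

INTERCEPT = "(Intercept)"


@dataclass
class ModelSpec:
    """Fixed-effect term list plus response and grouping columns."""

    terms: list
    response: str = "response"
    group: str = "animal_id"

    def __post_init__(self) -> None:
        for term in self.terms:
            for comp in term.split(":"):
                if comp not in CONT_BASIS and comp not in FACTORS and comp not in BINARY:
                    raise ValueError(f"unknown design term component {comp!r}")


def _component_columns(df: pd.DataFrame, comp: str, levels: dict):
    """Expand one term component into [(name_part, value_vector), ...]."""
    n = len(df)
    if comp in CONT_BASIS:
        col, power = CONT_BASIS[comp]
        if col not in df:
            raise ValueError(f"column {col!r} required by term component {comp!r}")
        v = np.asarray(df[col], dtype=float) ** power
        return [(comp, v)]
    if comp in BINARY:
        if comp not in df:
            raise ValueError(f"column {comp!r} missing from data")
        return [(comp, np.asarray(df[comp], dtype=float))]
    # factor
    if comp not in df:
        raise ValueError(f"column {comp!r} missing from data")
    vals = np.asarray(df[comp].astype(str))
    out = []
    for level in levels[comp]:
        out.append((f"{comp}[{level}]", (vals == level).astype(float)))
    return out


def _present_levels(df: pd.DataFrame, spec: ModelSpec, warn: bool = True) -> dict:
    """Non-reference factor levels retained, dropping those absent from data."""
    levels = {}
    for factor, (_ref, canon) in FACTORS.items():
        if factor in df.columns:
            present = set(df[factor].astype(str).unique())
            kept = tuple(lv for lv in canon if lv in present)
            dropped = [lv for lv in canon if lv not in present]
            if warn and dropped and any(factor in t.split(":") for t in spec.terms):
                logger.warning(
                    "factor %s: level(s) %s absent from data; columns dropped",
                    factor, dropped,
                )
            levels[factor] = kept
        else:
            levels[factor] = FACTORS[factor][1]
    return levels


def build_design(df: pd.DataFrame, spec: ModelSpec, columns=None):
    """Build (X, y, groups) for a mixed logistic fit.

    Returns
    -------
    X : pandas.DataFrame
        Design matrix with an intercept column first; dummy coding against
        the stated reference levels; interaction columns are elementwise
        products.  Column order is deterministic.
    y : ndarray or None
        Response vector (None when ``spec.response`` is absent, e.g. for
        scenario rows).
    groups : ndarray or None
        Grouping factor values (None when absent).
    columns : list, optional
        Reindex the result to exactly these columns (missing dummy columns
        filled with 0) -- used to align scenario rows with a fitted design.
    """
    # when reindexing to known columns (scenario rows), absent levels are
    # expected and not worth a warning
    levels = _present_levels(df, spec, warn=columns is None)
    data = {INTERCEPT: np.ones(len(df))}
    term_map: dict[str, list[str]] = {}
    for term in spec.terms:
        comps = term.split(":")
        expanded = [_component_columns(df, c, levels) for c in comps]
        names = []
        for combo in itertools.product(*expanded):
            name = ":".join(part for part, _ in combo)
            vec = np.ones(len(df))
            for _, v in combo:
                vec = vec * v
            data[name] = vec
            names.append(name)
        term_map[term] = names
    X = pd.DataFrame(data, index=df.index)
    if columns is not None:
        missing_cont = [
            c for c in columns
            if c not in X.columns and not any(tok in c for tok in ("[", "]"))
        ]
        if missing_cont:
            raise ValueError(f"scenario/design missing required columns: {missing_cont}")
        X = X.reindex(columns=list(columns), fill_value=0.0)
    X.attrs["term_map"] = term_map
    y = np.asarray(df[spec.response], dtype=float) if spec.response in df else None
    groups = np.asarray(df[spec.group]) if spec.group in df else None
    return X, y, groups


def scenario_frame(scenario: dict) -> pd.DataFrame:
    """One-row data frame from a scenario description.

    ``scenario`` may set factor levels (``treatment``, ``tod``), the binary
    flags and scaled continuous columns (``cover_s``, ``ndvi_s``,
    ``dist_site_s``).  Unset entries fall back to reference levels / zeros
    (zero on the scaled scale is the dataset mean).
    """
    row = {
        "treatment": FACTORS["treatment"][0],
        "tod": FACTORS["tod"][0],
        "calving": 0.0,
        "rut": 0.0,
        "cover_s": 0.0,
        "ndvi_s": 0.0,
        "dist_site_s": 0.0,
    }
    row.update(scenario)
    return pd.DataFrame([row])
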