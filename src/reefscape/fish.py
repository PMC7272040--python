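"""Standardisation of roving-herbivore timed-swim censuses.

Surveys record parrotfishes, surgeonfishes and rabbitfishes in total-length
size classes on belt transects of two widths: a 5 m belt for fishes > 10 cm
TL and a 1 m belt for fishes < 10 cm TL. Counts are converted to densities
per 250 m^2 (the conventional reporting unit), the two belts standardized
separately and summed, replicate census days averaged, and biomass derived
from allometric length-weight parameters W = a * L^b evaluated at size-class
midpoints.

Survey tables use the columns
``site, habitat, replicate, species, tl_lower_cm, tl_upper_cm, count,
transect_length_m, transect_width_m``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataGapError

TARGET_AREA_M2 = 250.0
SMALL_LARGE_CUTOFF_CM = 10.0

SURVEY_COLUMNS = [
    "site",
    "habitat",
    "replicate",
    "species",
    "tl_lower_cm",
    "tl_upper_cm",
    "count",
    "transect_length_m",
    "transect_width_m",
]


@dataclass(frozen=True)
class LengthWeightParams:
    """Allometric length-weight coefficients for one species: W(g) = a * L(cm)^b."""

    species: str
    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("coefficient a must be positive")
        if not 2.0 < self.b < 4.0:
            raise ValueError("allometric exponent b outside the plausible (2, 4) range")


def weight_from_length(params: LengthWeightParams, length_cm: float) -> float:
    """Weight in grams from total length via W = a * L^b."""
    if length_cm <= 0:
        raise ValueError("length must be positive")
    return params.a * length_cm ** params.b


def class_midpoint(size_class: tuple) -> float:
    """Midpoint of a (lower, upper) total-length class in cm."""
    lo, up = size_class
    if not lo < up:
        raise ValueError("size class lower bound must be below the upper bound")
    return 0.5 * (lo + up)


def _lw_table(lw_params) -> dict:
    if isinstance(lw_params, pd.DataFrame):
        return {
            r.species: LengthWeightParams(r.species, float(r.a), float(r.b))
            for r in lw_params.itertuples()
        }
    return {p.species: p for p in lw_params}


def standardize_density(
    records: pd.DataFrame,
    lw_params=None,
    target_area: float = TARGET_AREA_M2,
) -> pd.DataFrame:
    """Per site x habitat abundance and biomass standardized to ``target_area``.

    Each record contributes ``count / (length * width) * target_area``
    individuals; the 1 m (small fish) and 5 m (large fish) belts are
    standardized separately and summed within each replicate day, and the
    replicate days are then averaged per unit. Biomass (kg per unit area)
    uses size-class midpoints and the length-weight table when provided.

    Returns one row per ``site x habitat x species x size_group`` with columns
    ``abund_250m2`` and (if ``lw_params`` given) ``biomass_kg_250m2``, plus the
    per-m^2 equivalents.
    """
    df = records.copy()
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey table missing columns: {missing}")
    area = df["transect_length_m"].to_numpy(float) * df["transect_width_m"].to_numpy(float)
    if np.any(area <= 0):
        raise ValueError("transect area must be positive")
    if np.any(df["count"].to_numpy(float) < 0):
        raise ValueError("counts must be non-negative")
    df["abund"] = df["count"].to_numpy(float) / area * target_area
    df["size_group"] = np.where(
        df["tl_upper_cm"].to_numpy(float) <= SMALL_LARGE_CUTOFF_CM, "small", "large"
    )
    if lw_params is not None:
        table = _lw_table(lw_params)
        unknown = set(df["species"]) - set(table)
        if unknown:
            raise DataGapError(f"no length-weight parameters for species: {sorted(unknown)}")
        mids = 0.5 * (df["tl_lower_cm"].to_numpy(float) + df["tl_upper_cm"].to_numpy(float))
        per_fish_g = np.array(
            [weight_from_length(table[s], m) for s, m in zip(df["species"], mids)]
        )
        df["biomass_kg"] = df["abund"] * per_fish_g / 1000.0

    keys = ["site", "habitat", "species", "size_group"]
    value_cols = ["abund"] + (["biomass_kg"] if lw_params is not None else [])
    # sum within a replicate day (belts and split records), then average days
    per_rep = df.groupby(keys + ["replicate"], as_index=False)[value_cols].sum()
    n_reps = records.groupby(["site", "habitat"])["replicate"].nunique()
    out = per_rep.groupby(keys, as_index=False)[value_cols].sum()
    out = out.merge(n_reps.rename("n_reps").reset_index(), on=["site", "habitat"])
    for c in value_cols:
        out[c] = out[c] / out["n_reps"]
    out = out.drop(columns="n_reps")
    out = out.rename(columns={"abund": "abund_250m2", "biomass_kg": "biomass_kg_250m2"})
    out["abund_m2"] = out["abund_250m2"] / target_area
    if "biomass_kg_250m2" in out:
        out["biomass_kg_m2"] = out["biomass_kg_250m2"] / target_area
    return out


def build_assemblage(
    records: pd.DataFrame,
    lw_params=None,
    covariates: pd.DataFrame | None = None,
    expected_units: list | None = None,
    target_area: float = TARGET_AREA_M2,
) -> dict:
    """Site x habitat assemblage matrices with attached covariates.

    Returns a dict with:

    * ``abundance``: unit x species matrix with species split into
      ``<species>_small`` / ``<species>_large`` columns (ind per 250 m^2),
    * ``biomass``: unit x species matrix pooled across sizes (kg per 250 m^2,
      present when ``lw_params`` given),
    * ``units``: DataFrame of unit identifiers, totals and any covariates.

    ``covariates`` (indexed or keyed by site, habitat) are joined onto the
    unit table. A missing expected unit raises :class:`DataGapError`.
    """
    dens = standardize_density(records, lw_params=lw_params, target_area=target_area)
    units = dens[["site", "habitat"]].drop_duplicates().sort_values(["site", "habitat"])
    if expected_units is not None:
        have = set(map(tuple, units.to_numpy()))
        missing = [u for u in expected_units if tuple(u) not in have]
        if missing:
            raise DataGapError(f"no survey records for unit(s): {missing}")
    idx = pd.MultiIndex.from_frame(units)

    dens["sp_size"] = dens["species"] + "_" + dens["size_group"]
    abund = (
        dens.pivot_table(
            index=["site", "habitat"], columns="sp_size", values="abund_250m2", aggfunc="sum"
        )
        .reindex(idx)
        .fillna(0.0)
    )
    out = {"abundance": abund}
    if lw_params is not None:
        biom = (
            dens.pivot_table(
                index=["site", "habitat"], columns="species", values="biomass_kg_250m2", aggfunc="sum"
            )
            .reindex(idx)
            .fillna(0.0)
        )
        out["biomass"] = biom

    unit_tbl = units.reset_index(drop=True)
    unit_tbl["total_abund_250m2"] = abund.sum(axis=1).to_numpy()
    if lw_params is not None:
        unit_tbl["total_biomass_kg_250m2"] = out["biomass"].sum(axis=1).to_numpy()
    if covariates is not None:
        unit_tbl = unit_tbl.merge(covariates, on=["site", "habitat"], how="left")
    out["units"] = unit_tbl
    return out
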