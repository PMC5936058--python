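"""Population-level carbon/nitrogen pools and phytodetritus-processing fractions.

Per-individual quantities measured in the size-fraction feeding experiment are
projected onto size-structured abundance counts from stained sediment cores:
pool(fraction) = mean quantity per individual * living density. Volumetric
pools (ug cm-3 of the counted sediment layer) convert to areal pools
(mg m-2) via the layer thickness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError

QUANTITIES = ("TOC", "TN", "pC", "pN")

_AGG_COL = {
    "TOC": "mean_TOC_per_individual_ug",
    "TN": "mean_TN_per_individual_ug",
    "pC": "mean_pC_per_individual_ug",
    "pN": "mean_pN_per_individual_ug",
}

ABUNDANCE_COLUMNS = ["station", "size_fraction", "density_ind_per_cm3", "layer_cm"]


def to_areal(volumetric_ug_cm3: float | np.ndarray, layer_thickness_cm: float = 1.0) -> float | np.ndarray:
    """Convert a volumetric pool (ug cm-3) to an areal pool (mg m-2).

    ug cm-3 * cm = ug cm-2; x1e4 cm2 m-2, /1e3 ug mg-1 => factor 10 per cm.
    """
    v = np.asarray(volumetric_ug_cm3, dtype=float)
    if np.any(v < 0) or layer_thickness_cm <= 0:
        raise InvalidInputError("volumetric pool must be >= 0 and layer > 0")
    out = v * layer_thickness_cm * 10.0
    return out if out.ndim else float(out)


@dataclass
class PopulationBudget:
    """Volumetric and areal element pools of a foraminiferal population.

    Attributes
    ----------
    per_fraction : DataFrame
        One row per station x size_fraction with density and the four pools
        (columns ``TOC_pool``, ... in ug cm-3).
    totals : DataFrame
        One row per station, pools summed over fractions.
    layer_thickness_cm : float
    """

    per_fraction: pd.DataFrame
    totals: pd.DataFrame
    layer_thickness_cm: float = 1.0

    def areal(self) -> pd.DataFrame:
        """Station totals as areal pools, mg m-2 over the counted layer."""
        out = self.totals[["station"]].copy()
        for q in QUANTITIES:
            out[f"{q}_areal_mg_m2"] = to_areal(
                self.totals[f"{q}_pool"].to_numpy(), self.layer_thickness_cm)
        return out

    def shares(self) -> pd.DataFrame:
        """Percent contribution of each size fraction to each station pool."""
        merged = self.per_fraction.merge(
            self.totals, on="station", suffixes=("", "_total"))
        out = merged[["station", "size_fraction"]].copy()
        for q in QUANTITIES:
            total = merged[f"{q}_pool_total"].replace(0.0, np.nan)
            out[f"{q}_share_pct"] = (100.0 * merged[f"{q}_pool"] / total).fillna(0.0)
        return out

    def to_dict(self) -> dict:
        return {
            "layer_thickness_cm": self.layer_thickness_cm,
            "per_fraction": self.per_fraction.to_dict(orient="records"),
            "totals": self.totals.to_dict(orient="records"),
            "areal_mg_m2": self.areal().to_dict(orient="records"),
            "shares_pct": self.shares().to_dict(orient="records"),
        }


def extrapolate_pools(
    aggregates: pd.DataFrame,
    abundances: pd.DataFrame,
    *,
    stations: Sequence[str] | None = None,
    exclude_stations: Sequence[str] = (),
) -> PopulationBudget:
    """Project per-individual quantities onto living abundance densities.

    Parameters
    ----------
    aggregates : DataFrame
        Output of :func:`foramtracer.prep.aggregate_by_group`, reduced to one
        row per size_fraction (average over days/treatments beforehand if
        several are present; a duplicated fraction raises).
    abundances : DataFrame
        Columns station, size_fraction, density_ind_per_cm3 and optionally
        layer_cm (default 1; must be uniform).
    stations, exclude_stations :
        Optional include/exclude filters (e.g. drop a station with too few
        individuals for reliable fraction ratios).
    """
    ab = abundances.copy()
    if "layer_cm" not in ab.columns:
        ab["layer_cm"] = 1.0
    layers = ab["layer_cm"].unique()
    if len(layers) != 1:
        raise ConfigurationError("layer_cm must be uniform across abundance rows")
    if (ab["density_ind_per_cm3"] < 0).any():
        raise InvalidInputError("densities must be >= 0")
    if stations is not None:
        ab = ab[ab["station"].isin(stations)]
    if len(exclude_stations):
        ab = ab[~ab["station"].isin(list(exclude_stations))]
    if len(ab) == 0:
        raise ConfigurationError("no abundance rows left after station filtering")

    if aggregates["size_fraction"].duplicated().any():
        raise ConfigurationError(
            "aggregates must contain one row per size_fraction; "
            "average over days/treatments first")
    agg = aggregates.set_index("size_fraction")
    missing = sorted(set(ab["size_fraction"]) - set(agg.index))
    if missing:
        raise ConfigurationError(f"no aggregate for size fraction(s): {missing}")

    per = ab[["station", "size_fraction", "density_ind_per_cm3"]].copy()
    for q in QUANTITIES:
        per_ind = agg.loc[per["size_fraction"], _AGG_COL[q]].to_numpy()
        per[f"{q}_pool"] = per_ind * per["density_ind_per_cm3"].to_numpy()
    totals = (per.groupby("station", sort=True)[[f"{q}_pool" for q in QUANTITIES]]
              .sum().reset_index())
    return PopulationBudget(per_fraction=per.reset_index(drop=True), totals=totals,
                            layer_thickness_cm=float(layers[0]))


@dataclass(frozen=True)
class ProcessingEstimate:
    """Fraction of the regional phytodetritus flux a population can process."""

    station: str
    element: str
    day_basis: str
    intake_rate_mg_m2_day: float
    production_mg_m2_day: float
    processing_fraction_pct: float
    is_max: bool = False


def processing_fraction(
    areal_pool_mg_m2: float,
    incubation_days: float,
    production_mg_m2_day: float,
) -> float:
    """Percent of a daily phytodetritus flux matched by the population intake rate.

    Intake rate = areal pool accrued over the incubation / incubation days.
    """
    if incubation_days <= 0:
        raise InvalidInputError("incubation_days must be > 0")
    if production_mg_m2_day <= 0:
        raise InvalidInputError("production must be > 0")
    if areal_pool_mg_m2 < 0:
        raise InvalidInputError("areal pool must be >= 0")
    return 100.0 * (areal_pool_mg_m2 / incubation_days) / production_mg_m2_day


def processing_matrix(
    budgets_by_day: Mapping[int, PopulationBudget],
    *,
    production_range: tuple[float, float] = (500.0, 2000.0),
    food_cn_mass_ratio: float | None = None,
    combined_label: str = "combined",
) -> pd.DataFrame:
    """Full parameter matrix of processing-fraction estimates.

    The single configuration behind a printed "maximum processing" number is
    rarely recoverable, so every defensible choice is reported: each station
    plus the station sum; the intake rate from each sampling day's pools
    (pool/day) and from the mean of the per-day rates; and both ends of the
    regional production range. The row with the highest carbon fraction is
    flagged ``is_max``.

    Parameters
    ----------
    budgets_by_day : mapping day -> PopulationBudget
        Budgets extrapolated from each sampling day's aggregates.
    production_range : (low, high)
        Daily gross particulate C production, mg C m-2 day-1.
    food_cn_mass_ratio : float, optional
        If given, nitrogen fractions are computed against an N flux of
        production / C:N (mass).
    """
    low, high = production_range
    if low <= 0 or high < low:
        raise InvalidInputError("production range must satisfy 0 < low <= high")

    # station -> day -> element -> intake rate (mg m-2 day-1)
    rates: dict[str, dict[str, dict[str, float]]] = {}
    days = sorted(budgets_by_day)
    for day in days:
        budget = budgets_by_day[day]
        if day <= 0:
            raise InvalidInputError("incubation days must be > 0")
        areal = budget.areal().set_index("station")
        for station in list(areal.index) + [combined_label]:
            st = rates.setdefault(station, {})
            basis = st.setdefault(f"day{day}", {})
            for el, col in (("C", "pC_areal_mg_m2"), ("N", "pN_areal_mg_m2")):
                pool = (areal[col].sum() if station == combined_label
                        else float(areal.loc[station, col]))
                basis[el] = pool / day
    for station, bases in rates.items():
        per_day = [bases[f"day{d}"] for d in days if f"day{d}" in bases]
        bases["mean"] = {el: float(np.mean([b[el] for b in per_day])) for el in ("C", "N")}

    rows = []
    for station, bases in rates.items():
        for basis, by_el in bases.items():
            for production in (low, high):
                rows.append({
                    "station": station, "day_basis": basis, "element": "C",
                    "intake_rate_mg_m2_day": by_el["C"],
                    "production_mg_m2_day": production,
                    "processing_fraction_pct": 100.0 * by_el["C"] / production,
                })
                if food_cn_mass_ratio is not None:
                    n_flux = production / food_cn_mass_ratio
                    rows.append({
                        "station": station, "day_basis": basis, "element": "N",
                        "intake_rate_mg_m2_day": by_el["N"],
                        "production_mg_m2_day": n_flux,
                        "processing_fraction_pct": 100.0 * by_el["N"] / n_flux,
                    })
    out = pd.DataFrame(rows)
    out["is_max"] = False
    c_rows = out[out["element"] == "C"]
    out.loc[c_rows["processing_fraction_pct"].idxmax(), "is_max"] = True
    return out.sort_values(["element", "station", "day_basis", "production_mg_m2_day"]
                           ).reset_index(drop=True)
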