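"""Isotope-tracer arithmetic: from isotope ratios to phytodetrital C/N incorporation.

The tracer signal in a dual-label (13C/15N) feeding experiment is the excess
atom percent of the heavy isotope above the natural-abundance background.
Multiplying the excess fraction by the sample's total elemental content gives
the mass of incorporated heavy isotope (I_iso); dividing by the label fraction
of the food source converts that to the mass of food-derived element in the
cytoplasm (I_phyto, written pC for carbon and pN for nitrogen).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateLabelError, InvalidInputError, SchemaError

Element = Literal["C", "N"]


@dataclass(frozen=True)
class IsotopeStandard:
    """An international isotope-ratio reference scale.

    Parameters
    ----------
    element : {"C", "N"}
    name : str
        Conventional name of the standard.
    R : float
        Heavy/light isotope abundance ratio of the standard, 0 < R < 1.
    """

    element: Element
    name: str
    R: float

    def __post_init__(self) -> None:
        if not 0 < self.R < 1:
            raise InvalidInputError(f"standard ratio must be in (0, 1), got {self.R}")

    @property
    def atom_percent(self) -> float:
        """Natural-abundance atom% implied by the standard ratio."""
        return ratio_to_atom_percent(self.R)


#: Vienna Pee Dee Belemnite, the 13C/12C reference scale.
VPDB = IsotopeStandard("C", "VPDB", 0.0112372)
#: Atmospheric N2, the 15N/14N reference scale.
AIR_N2 = IsotopeStandard("N", "air-N2", 0.0036765)

STANDARDS: Mapping[Element, IsotopeStandard] = {"C": VPDB, "N": AIR_N2}


def ratio_to_atom_percent(r_sample: float | np.ndarray) -> float | np.ndarray:
    """Convert an isotope ratio (heavy/light) to atom percent of the heavy isotope.

    atom% = 100 * R / (1 + R); strictly increasing in R, bounded in (0, 100).
    """
    r = np.asarray(r_sample, dtype=float)
    if np.any(r <= 0):
        raise InvalidInputError("isotope ratio must be > 0")
    out = 100.0 * r / (1.0 + r)
    return out if out.ndim else float(out)


def atom_percent_to_ratio(atom_pct: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`ratio_to_atom_percent`: R = A / (100 - A)."""
    a = np.asarray(atom_pct, dtype=float)
    if np.any((a <= 0) | (a >= 100)):
        raise InvalidInputError("atom percent must be in (0, 100)")
    out = a / (100.0 - a)
    return out if out.ndim else float(out)


def delta_to_ratio(delta: float | np.ndarray, standard: IsotopeStandard) -> float | np.ndarray:
    """Convert delta notation (per mil vs. a standard) to an isotope ratio.

    R = R_standard * (delta/1000 + 1). Values at or below -1000 permil would
    imply a non-positive ratio and are rejected.
    """
    d = np.asarray(delta, dtype=float)
    if np.any(d <= -1000):
        raise InvalidInputError("delta must be > -1000 permil")
    out = standard.R * (d / 1000.0 + 1.0)
    return out if out.ndim else float(out)


def ratio_to_delta(r_sample: float | np.ndarray, standard: IsotopeStandard) -> float | np.ndarray:
    """Inverse of :func:`delta_to_ratio`."""
    r = np.asarray(r_sample, dtype=float)
    if np.any(r <= 0):
        raise InvalidInputError("isotope ratio must be > 0")
    out = 1000.0 * (r / standard.R - 1.0)
    return out if out.ndim else float(out)


def natural_background(element: Element) -> float:
    """Natural-abundance atom% of 13C or 15N from the reference standards."""
    return STANDARDS[element].atom_percent


def excess(atom_pct_sample: float | np.ndarray, atom_pct_background: float | np.ndarray) -> float | np.ndarray:
    """Excess (E) atom% above background. May be negative for unlabelled noise;
    the caller decides whether to clamp (budgets do, raw records do not)."""
    s = np.asarray(atom_pct_sample, dtype=float)
    b = np.asarray(atom_pct_background, dtype=float)
    if np.any((s <= 0) | (s >= 100)) or np.any((b <= 0) | (b >= 100)):
        raise InvalidInputError("atom percent values must be in (0, 100)")
    out = s - b
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FoodSource:
    """Characterisation of the labelled phytodetritus food source.

    Defaults describe freeze-dried *Dunaliella tertiolecta* grown on 98 atom%
    13C bicarbonate and 98 atom% 15N nitrate; elemental fractions are typical
    for chlorophyte detritus.
    """

    atom13C_pct: float = 98.0
    atom15N_pct: float = 98.0
    C_per_dryweight: float = 0.45  # ug C per ug detritus
    N_per_dryweight: float = 0.08  # ug N per ug detritus
    dose_areal_mgC_m2: float = 560.0
    schedule_days: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        for a in (self.atom13C_pct, self.atom15N_pct):
            if not 0 < a <= 100:
                raise InvalidInputError(f"food atom% must be in (0, 100], got {a}")
        for f in (self.C_per_dryweight, self.N_per_dryweight):
            if not 0 < f < 1:
                raise InvalidInputError(f"elemental mass fraction must be in (0, 1), got {f}")

    def atom_percent(self, element: Element) -> float:
        return self.atom13C_pct if element == "C" else self.atom15N_pct

    @property
    def cn_mass_ratio(self) -> float:
        """C:N mass ratio of the detritus."""
        return self.C_per_dryweight / self.N_per_dryweight


@dataclass
class TracerIncorporationResult:
    """Per-sample, per-element tracer bookkeeping (pC or pN and intermediates).

    ``excess_raw`` keeps the signed measurement; ``excess_clamped`` (>= 0) is
    what the downstream mass budget uses, so control-sample noise cannot
    produce negative carbon.
    """

    sample_id: str
    element: Element
    atom_pct_sample: float
    atom_pct_background: float
    excess_raw: float
    excess_clamped: float
    i_iso_ug: float
    i_phyto_ug: float
    per_individual_ug: float
    per_dryweight: float
    fraction_of_total_pct: float


# Canonical column order for incorporation tables.
INCORPORATION_COLUMNS = [
    "sample_id", "element", "atom_pct_sample", "atom_pct_background",
    "excess_raw", "excess_clamped", "i_iso_ug", "i_phyto_ug",
    "per_individual_ug", "per_dryweight", "fraction_of_total_pct",
]


def incorporation(
    *,
    sample_id: str,
    element: Element,
    atom_pct_sample: float,
    total_element_ug: float,
    n_individuals: int,
    dry_weight_ug: float,
    background_atom_pct: float,
    food_atom_pct: float,
) -> TracerIncorporationResult:
    """Compute phytodetrital element incorporation for one sample and element.

    I_iso = (E/100) * total element mass;
    I_phyto = I_iso / ((food atom% - background atom%)/100).
    Negative excess is preserved in ``excess_raw`` and clamped to zero before
    the mass calculations.
    """
    if total_element_ug <= 0:
        raise InvalidInputError(f"{sample_id}: total {element} must be > 0")
    if n_individuals < 1:
        raise InvalidInputError(f"{sample_id}: n_individuals must be >= 1")
    if dry_weight_ug <= 0:
        raise InvalidInputError(f"{sample_id}: dry weight must be > 0")
    if food_atom_pct <= background_atom_pct:
        raise DegenerateLabelError(
            f"{sample_id}: food atom% ({food_atom_pct}) must exceed background "
            f"({background_atom_pct})"
        )
    e_raw = excess(atom_pct_sample, background_atom_pct)
    e = max(e_raw, 0.0)
    i_iso = e / 100.0 * total_element_ug
    food_excess_fraction = (food_atom_pct - background_atom_pct) / 100.0
    i_phyto = i_iso / food_excess_fraction
    return TracerIncorporationResult(
        sample_id=sample_id,
        element=element,
        atom_pct_sample=float(atom_pct_sample),
        atom_pct_background=float(background_atom_pct),
        excess_raw=float(e_raw),
        excess_clamped=float(e),
        i_iso_ug=float(i_iso),
        i_phyto_ug=float(i_phyto),
        per_individual_ug=float(i_phyto / n_individuals),
        per_dryweight=float(i_phyto / dry_weight_ug),
        fraction_of_total_pct=float(100.0 * i_phyto / total_element_ug),
    )


def batch_incorporation(
    samples: pd.DataFrame,
    backgrounds: Mapping[Element, float],
    food: FoodSource,
) -> pd.DataFrame:
    """Apply :func:`incorporation` to every sample row for both elements.

    Parameters
    ----------
    samples : DataFrame
        Validated sample table (see :mod:`foramtracer.io`): columns
        sample_id, n_individuals, dry_weight_ug, TOC_ug, TN_ug,
        atom13C_pct, atom15N_pct (plus metadata carried through).
    backgrounds : mapping
        Background atom% per element, e.g. ``{"C": 1.111, "N": 0.366}``.
    food : FoodSource

    Returns
    -------
    DataFrame
        One row per sample x element, order preserved (C then N per sample),
        with treatment metadata joined back on.
    """
    if len(samples) == 0:
        raise InvalidInputError("sample table is empty")
    records = []
    for row in samples.itertuples(index=False):
        for element, total_col, atom_col in (
            ("C", "TOC_ug", "atom13C_pct"),
            ("N", "TN_ug", "atom15N_pct"),
        ):
            try:
                rec = incorporation(
                    sample_id=str(row.sample_id),
                    element=element,
                    atom_pct_sample=getattr(row, atom_col),
                    total_element_ug=getattr(row, total_col),
                    n_individuals=int(row.n_individuals),
                    dry_weight_ug=row.dry_weight_ug,
                    background_atom_pct=backgrounds[element],
                    food_atom_pct=food.atom_percent(element),
                )
            except InvalidInputError as err:
                raise type(err)(f"sample {row.sample_id!r}: {err}") from err
            records.append(rec.__dict__)
    out = pd.DataFrame.from_records(records)[INCORPORATION_COLUMNS]
    meta_cols = [c for c in ("treatment", "day", "size_fraction", "n_individuals",
                             "dry_weight_ug", "TOC_ug", "TN_ug") if c in samples.columns]
    if meta_cols:
        out = out.merge(samples[["sample_id", *meta_cols]], on="sample_id", how="left")
    return out


class TracerIncorporation:
    """scikit-learn style transformer: sample table -> incorporation table.

    ``fit`` learns the per-element background atom% — either the
    natural-abundance values implied by the reference standards
    (``background="natural"``) or the mean atom% of control rows present in
    the table (``background="controls"``, preferred when controls were
    measured). ``transform`` applies the mixing model to every row for both
    elements.

    Parameters
    ----------
    food : FoodSource, optional
    background : {"natural", "controls"} or mapping, default "natural"
        Explicit per-element atom% values may be given as a mapping.

    Attributes
    ----------
    background_atom_pct_ : dict
        Fitted background atom% per element.
    n_controls_ : int
        Number of control rows used (0 for "natural" or explicit backgrounds).
    """

    def __init__(self, food: FoodSource | None = None,
                 background: str | Mapping[Element, float] = "natural"):
        self.food = food
        self.background = background

    def get_params(self, deep: bool = True) -> dict:
        return {"food": self.food, "background": self.background}

    def set_params(self, **params) -> "TracerIncorporation":
        for key, value in params.items():
            if key not in ("food", "background"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "TracerIncorporation":
        self.n_controls_ = 0
        if isinstance(self.background, Mapping):
            self.background_atom_pct_ = {"C": float(self.background["C"]),
                                         "N": float(self.background["N"])}
        elif self.background == "natural":
            self.background_atom_pct_ = {"C": natural_background("C"),
                                         "N": natural_background("N")}
        elif self.background == "controls":
            if "treatment" not in X.columns:
                raise SchemaError("background='controls' needs a treatment column")
            controls = X[X["treatment"] == "control"]
            if len(controls) == 0:
                raise InvalidInputError("background='controls' but no control rows present")
            self.background_atom_pct_ = {
                "C": float(controls["atom13C_pct"].mean()),
                "N": float(controls["atom15N_pct"].mean()),
            }
            self.n_controls_ = int(len(controls))
        else:
            raise ValueError(f"unknown background mode {self.background!r}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "background_atom_pct_"):
            raise RuntimeError("TracerIncorporation must be fitted before transform")
        return batch_incorporation(X, self.background_atom_pct_,
                                   self.food if self.food is not None else FoodSource())

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
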