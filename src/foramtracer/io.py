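"""Readers, writers, validation and the end-to-end pipeline.

CSV dialect: UTF-8, comma separated, '.' decimal, header row required,
missing values as empty cells. All randomness in a pipeline run flows from a
single seed in the configuration; a run writes every intermediate artifact
plus a manifest (input hashes, seed, package version) so results are
reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .allometry import classify_scaling, standard_fits
from .budget import extrapolate_pools, processing_matrix
from .errors import ConfigurationError, SchemaError
from .prep import aggregate_by_group, correct_dry_weight, per_individual_table
from .simulate import SIZE_FRACTIONS
from .tracer import (AIR_N2, VPDB, FoodSource, TracerIncorporation,
                     delta_to_ratio, ratio_to_atom_percent)

logger = logging.getLogger("foramtracer")

TREATMENTS = {"constant_feed_1", "constant_feed_2", "single_pulse",
              "size_experiment", "control"}
FRACTION_VALUES = set(SIZE_FRACTIONS) | {"mixed"}

_BASE_COLUMNS = ["sample_id", "treatment", "day", "size_fraction",
                 "n_individuals", "dry_weight_ug", "TOC_ug", "TN_ug"]
_ATOM_COLUMNS = ["atom13C_pct", "atom15N_pct"]
_DELTA_COLUMNS = ["d13C_permil", "d15N_permil"]


def _schema_fail(path, row, message) -> SchemaError:
    loc = f"{path}, row {row}" if row is not None else str(path)
    return SchemaError(f"{loc}: {message}")


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read and validate an IRMS sample table.

    Isotope composition may be given as atom% (``atom13C_pct``/``atom15N_pct``)
    or delta notation (``d13C_permil``/``d15N_permil``); the two forms are
    auto-detected and mutually exclusive, and deltas are converted to atom%
    on the VPDB / atmospheric-N2 scales. If a ``carbonate_ug`` column is
    present, ``dry_weight_ug`` is taken as the raw post-decalcification
    residue and corrected for the CaCl2 mass. Rows whose live count is zero
    (``n_individuals`` <= 0, e.g. all specimens dead) are dropped with a
    logged warning; an ``n_dead`` column is bookkeeping only.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"sample file not found: {path}")
    df = pd.read_csv(path)

    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise _schema_fail(path, None, f"missing column(s): {missing}")
    has_atom = all(c in df.columns for c in _ATOM_COLUMNS)
    has_delta = all(c in df.columns for c in _DELTA_COLUMNS)
    if has_atom and has_delta:
        raise _schema_fail(path, None, "atom% and delta columns are mutually exclusive")
    if not (has_atom or has_delta):
        raise _schema_fail(path, None,
                           f"need either {_ATOM_COLUMNS} or {_DELTA_COLUMNS}")

    numeric = ["day", "n_individuals", "dry_weight_ug", "TOC_ug", "TN_ug"]
    numeric += _ATOM_COLUMNS if has_atom else _DELTA_COLUMNS
    if "carbonate_ug" in df.columns:
        numeric.append("carbonate_ug")
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            raise _schema_fail(path, int(bad[0]) + 2, f"non-numeric value in {col!r}")
        if parsed.isna().any() and col != "carbonate_ug":
            raise _schema_fail(path, int(parsed.index[parsed.isna()][0]) + 2,
                               f"missing value in required column {col!r}")
        df[col] = parsed

    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise _schema_fail(path, None, f"duplicate sample_id {dup!r}")
    bad_treat = ~df["treatment"].isin(TREATMENTS)
    if bad_treat.any():
        raise _schema_fail(path, int(df.index[bad_treat][0]) + 2,
                           f"unknown treatment {df.loc[bad_treat, 'treatment'].iloc[0]!r}")
    bad_frac = ~df["size_fraction"].isin(FRACTION_VALUES)
    if bad_frac.any():
        raise _schema_fail(path, int(df.index[bad_frac][0]) + 2,
                           f"unknown size_fraction {df.loc[bad_frac, 'size_fraction'].iloc[0]!r}")

    dead_only = df["n_individuals"] <= 0
    if dead_only.any():
        logger.warning("dropping %d sample(s) with no live individuals: %s",
                       int(dead_only.sum()),
                       ", ".join(df.loc[dead_only, "sample_id"]))
        df = df[~dead_only].reset_index(drop=True)

    if has_delta:
        df["atom13C_pct"] = ratio_to_atom_percent(
            delta_to_ratio(df.pop("d13C_permil").to_numpy(), VPDB))
        df["atom15N_pct"] = ratio_to_atom_percent(
            delta_to_ratio(df.pop("d15N_permil").to_numpy(), AIR_N2))

    if "carbonate_ug" in df.columns:
        carb = df["carbonate_ug"].fillna(0.0)
        df["dry_weight_ug"] = [
            correct_dry_weight(m, c) for m, c in zip(df["dry_weight_ug"], carb)]

    for idx, row in df.iterrows():
        rowno = idx + 2
        if row["TOC_ug"] <= 0 or row["TN_ug"] <= 0:
            raise _schema_fail(path, rowno, "TOC and TN must be > 0")
        if row["TOC_ug"] < row["TN_ug"]:
            raise _schema_fail(path, rowno, "TOC must be >= TN")
        if row["dry_weight_ug"] < row["TOC_ug"]:
            raise _schema_fail(path, rowno, "dry weight must be >= TOC")
        for col in _ATOM_COLUMNS:
            if not 0 < row[col] < 100:
                raise _schema_fail(path, rowno, f"{col} out of (0, 100): {row[col]}")
    return df


def read_abundances(path: str | Path) -> pd.DataFrame:
    """Read and validate a station x size-fraction living-abundance table."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"abundance file not found: {path}")
    df = pd.read_csv(path)
    required = ["station", "size_fraction", "density_ind_per_cm3"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise _schema_fail(path, None, f"missing column(s): {missing}")
    if "layer_cm" not in df.columns:
        df["layer_cm"] = 1.0
    for col in ("density_ind_per_cm3", "layer_cm"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            raise _schema_fail(path, int(parsed.index[parsed.isna()][0]) + 2,
                               f"non-numeric or missing value in {col!r}")
        df[col] = parsed
    if (df["density_ind_per_cm3"] < 0).any():
        raise _schema_fail(path, None, "densities must be >= 0")
    bad_frac = ~df["size_fraction"].isin(FRACTION_VALUES)
    if bad_frac.any():
        raise _schema_fail(path, None,
                           f"unknown size_fraction {df.loc[bad_frac, 'size_fraction'].iloc[0]!r}")
    return df


def read_food(path: str | Path) -> FoodSource:
    """Load a food-source characterisation from YAML."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"atom13C_pct", "atom15N_pct", "C_per_dryweight", "N_per_dryweight",
             "dose_areal_mgC_m2", "schedule_days"}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown food keys {sorted(unknown)}")
    if "schedule_days" in raw:
        raw["schedule_days"] = tuple(raw["schedule_days"])
    return FoodSource(**raw)


def write_food(food: FoodSource, path: str | Path) -> None:
    import yaml

    data = asdict(food)
    data["schedule_days"] = list(data["schedule_days"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    samples_path: str | Path
    abundances_path: str | Path
    out_dir: str | Path
    food: FoodSource = field(default_factory=FoodSource)
    background: str | Mapping[str, float] = "natural"
    exclude_stations: Sequence[str] = ("Station 3",)
    production_range: tuple[float, float] = (500.0, 2000.0)
    fit_treatments: Sequence[str] | None = None  # None => all non-control rows
    seed: int = 0
    log_level: str = "INFO"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute compute-intake -> aggregate -> fit-scaling -> budget.

    Writes intake.csv, aggregates.csv, fits.json, budget.json and
    manifest.json into ``config.out_dir`` and returns the manifest dict.
    Deterministic for fixed inputs; any stage failure propagates with the
    stage name attached.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    def stage(name):
        stages.append(name)
        logger.info("stage %s", name)

    try:
        stage("compute-intake")
        samples = read_samples(config.samples_path)
        transformer = TracerIncorporation(food=config.food, background=config.background)
        intake = transformer.fit_transform(samples)
        _write_csv(intake, out_dir / "intake.csv")

        stage("aggregate")
        experimental = intake[intake["treatment"] != "control"]
        aggregates = aggregate_by_group(experimental)
        _write_csv(aggregates, out_dir / "aggregates.csv")

        stage("fit-scaling")
        per_ind = per_individual_table(experimental)
        if config.fit_treatments is not None:
            per_ind = per_ind[per_ind["treatment"].isin(config.fit_treatments)]
        fits = standard_fits(per_ind)
        fits_out = {key: {**fit.to_dict(), "regime": classify_scaling(fit)}
                    for key, fit in fits.items()}
        _write_json(fits_out, out_dir / "fits.json")

        stage("budget")
        abundances = read_abundances(config.abundances_path)
        budgets_by_day = {}
        for day, group in aggregates.groupby("day"):
            if group["size_fraction"].duplicated().any():
                raise ConfigurationError(
                    f"day {day}: multiple treatments per size fraction; "
                    "restrict fit_treatments or pre-filter the samples")
            budgets_by_day[int(day)] = extrapolate_pools(
                group, abundances, exclude_stations=config.exclude_stations)
        mean_agg = (aggregates.groupby("size_fraction", as_index=False)
                    [["mean_dry_weight_per_individual_ug",
                      "mean_TOC_per_individual_ug", "mean_TN_per_individual_ug",
                      "mean_pC_per_individual_ug", "mean_pN_per_individual_ug"]]
                    .mean())
        mean_budget = extrapolate_pools(mean_agg, abundances,
                                        exclude_stations=config.exclude_stations)
        matrix = processing_matrix(budgets_by_day,
                                   production_range=config.production_range,
                                   food_cn_mass_ratio=config.food.cn_mass_ratio)
        budget_out = {
            "day_mean": mean_budget.to_dict(),
            "by_day": {str(d): b.to_dict() for d, b in budgets_by_day.items()},
            "processing_matrix": matrix.to_dict(orient="records"),
        }
        _write_json(budget_out, out_dir / "budget.json")
    except Exception as err:
        raise type(err)(f"[stage {stages[-1]}] {err}") from err

    manifest = {
        "package": "foramtracer",
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            "samples": {"path": str(config.samples_path),
                        "sha256": _sha256(Path(config.samples_path))},
            "abundances": {"path": str(config.abundances_path),
                           "sha256": _sha256(Path(config.abundances_path))},
        },
        "stages": stages,
        "outputs": ["intake.csv", "aggregates.csv", "fits.json", "budget.json"],
    }
    _write_json(manifest, out_dir / "manifest.json")
    return manifest
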