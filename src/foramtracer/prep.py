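"""Specimen preparation corrections and replicate aggregation.

Decalcifying a foraminiferal test with HCl converts CaCO3 to CaCl2
(CaCO3 + 2 HCl -> CaCl2 + H2O + CO2, 1:1 molar); the CaCl2 stays in the dried
capsule and inflates the weighed residue, so the cytoplasm dry mass is the
measured residue minus carbonate_mass * M(CaCl2)/M(CaCO3).
"""

from __future__ import annotations

import pandas as pd

from .errors import InconsistentMassError, InvalidInputError

M_CACL2 = 110.98  # g/mol
M_CACO3 = 100.09  # g/mol
#: Mass of CaCl2 residue produced per unit mass of dissolved CaCO3.
CACL2_PER_CACO3 = M_CACL2 / M_CACO3


def correct_dry_weight(measured_ug: float, carbonate_ug: float = 0.0) -> float:
    """Cytoplasm dry mass after removing the CaCl2 decalcification residue.

    Parameters
    ----------
    measured_ug : float
        Post-acid, dried residue mass (cytoplasm + CaCl2), ug.
    carbonate_ug : float
        Mass of CaCO3 dissolved by the acid, ug.

    Returns
    -------
    float
        measured - carbonate * 110.98/100.09, ug; must remain positive.
    """
    if measured_ug <= 0:
        raise InvalidInputError("measured dry weight must be > 0")
    if carbonate_ug < 0:
        raise InvalidInputError("carbonate mass must be >= 0")
    residue = carbonate_ug * CACL2_PER_CACO3
    corrected = measured_ug - residue
    if corrected <= 0:
        raise InconsistentMassError(
            f"CaCl2 residue ({residue:.2f} ug) consumes the measured mass "
            f"({measured_ug:.2f} ug)"
        )
    return corrected


#: Grouping keys for replicate aggregation.
GROUP_KEYS = ["treatment", "day", "size_fraction"]

AGGREGATE_COLUMNS = GROUP_KEYS + [
    "n_samples",
    "mean_dry_weight_per_individual_ug",
    "mean_TOC_per_individual_ug",
    "mean_TN_per_individual_ug",
    "mean_pC_per_individual_ug",
    "mean_pN_per_individual_ug",
]


def per_individual_table(incorporation: pd.DataFrame) -> pd.DataFrame:
    """One row per capsule with per-individual dry weight, TOC, TN, pC and pN.

    The input is the long (sample x element) incorporation table with joined
    sample metadata; the output is the wide per-sample view the scaling fits
    and the replicate aggregation both work from.
    """
    missing = [c for c in GROUP_KEYS + ["sample_id", "element"] if c not in incorporation.columns]
    if missing:
        raise InvalidInputError(f"incorporation table lacks columns: {missing}")
    base = incorporation.drop_duplicates("sample_id").set_index("sample_id")
    wide = pd.DataFrame({
        "dw_per_ind": base["dry_weight_ug"] / base["n_individuals"],
        "toc_per_ind": base["TOC_ug"] / base["n_individuals"],
        "tn_per_ind": base["TN_ug"] / base["n_individuals"],
    })
    for element, col in (("C", "pc_per_ind"), ("N", "pn_per_ind")):
        sub = incorporation[incorporation["element"] == element]
        wide[col] = sub.set_index("sample_id")["per_individual_ug"]
    for key in GROUP_KEYS:
        wide[key] = base[key]
    return wide.reset_index()


def aggregate_by_group(incorporation: pd.DataFrame) -> pd.DataFrame:
    """Average per-individual quantities across replicate samples.

    Parameters
    ----------
    incorporation : DataFrame
        Long incorporation table from :func:`foramtracer.tracer.batch_incorporation`
        (one row per sample x element) with the joined sample metadata
        (treatment, day, size_fraction, n_individuals, dry_weight_ug, TOC_ug,
        TN_ug).

    Returns
    -------
    DataFrame
        One row per treatment x day x size_fraction with replicate count and
        mean per-individual dry weight, TOC, TN, pC and pN. Groups without
        samples are simply absent. Sample-level per-individual values are
        averaged with equal weight per IRMS capsule (a pooled capsule is one
        physical measurement regardless of how many specimens went in).
    """
    wide = per_individual_table(incorporation)
    grouped = wide.groupby(GROUP_KEYS, sort=True, observed=True)
    out = grouped.agg(
        n_samples=("toc_per_ind", "size"),
        mean_dry_weight_per_individual_ug=("dw_per_ind", "mean"),
        mean_TOC_per_individual_ug=("toc_per_ind", "mean"),
        mean_TN_per_individual_ug=("tn_per_ind", "mean"),
        mean_pC_per_individual_ug=("pc_per_ind", "mean"),
        mean_pN_per_individual_ug=("pn_per_ind", "mean"),
    ).reset_index()
    return out[AGGREGATE_COLUMNS]
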