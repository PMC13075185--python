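"""Derived traits, ion concentrations and per-trait Stress Tolerance Indices.

The Stress Tolerance Index (STI) is the dimensionless ratio of a genotype's
mean trait value under salinity stress to its mean under control, so STI > 1
means stressed performance above the non-stressed mean and higher STI means
stronger tolerance. The inverse orientation (control/stress) is available
via the ``orientation`` argument. The visual injury score SES, recorded only
under stress on the 1 (symptom-free) .. 9 (severe) scale, has no control
denominator: its index is defined as SESSTI = 1/SES, which equals 1 exactly
for symptom-free genotypes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import PHENOTYPE_COLUMNS

log = logging.getLogger(__name__)

ORIENTATIONS = ("stress_over_control", "control_over_stress")

#: (new trait, factor traits): vigour indices derived at the germination
#: stage from germination percentage, total seedling length and dry weight.
VIGOUR_INDICES = {"SVI": ("GP", "TSL"), "SVII": ("GP", "DW")}


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(PHENOTYPE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns {sorted(missing)}")
    if (table["value"] < 0).any():
        raise ValueError("phenotype values must be non-negative")
    ses = table[table["trait"] == "SES"]
    if len(ses):
        if (ses["condition"] != "stress").any():
            raise ValueError("SES must be recorded under stress only")
        v = ses["value"].to_numpy()
        if not np.all((v == np.rint(v)) & (v >= 1) & (v <= 9)):
            raise ValueError("SES values must be integers in [1, 9]")
    return table


def derive_vigour_indices(table: pd.DataFrame,
                          stage: str = "germination") -> pd.DataFrame:
    """Append SVI = GP x TSL and SVII = GP x DW, computed replicate-wise.

    Original records are left untouched; the products are taken within each
    (genotype, condition, replicate) cell of the given stage.
    """
    sub = table[table["stage"] == stage]
    wide = sub.pivot_table(index=["genotype_id", "condition", "replicate"],
                           columns="trait", values="value")
    new = []
    for name, (a, b) in VIGOUR_INDICES.items():
        for t in (a, b):
            if t not in wide.columns:
                raise ValueError(
                    f"trait {t!r} required for {name} absent at stage {stage!r}")
        prod = wide[a] * wide[b]
        df = prod.rename("value").reset_index()
        df["stage"] = stage
        df["trait"] = name
        new.append(df[PHENOTYPE_COLUMNS])
    return pd.concat([table] + new, ignore_index=True)


def ion_concentration(reading_mg_per_L: float, digest_volume_L: float,
                      dry_weight_g: float, molar_mass_g_per_mol: float) -> float:
    """Flame-photometer reading (mg/L) to tissue concentration (mmol/g DW):
    reading x digest volume / (dry weight x molar mass)."""
    if dry_weight_g <= 0:
        raise ValueError("dry weight must be positive")
    if molar_mass_g_per_mol <= 0:
        raise ValueError("molar mass must be positive")
    return reading_mg_per_L * digest_volume_L / (dry_weight_g * molar_mass_g_per_mol)


def compute_sti(table: pd.DataFrame,
                orientation: str = "stress_over_control") -> pd.DataFrame:
    """Per-(genotype, stage, trait) STI from per-condition replicate means.

    Returns a DataFrame with columns genotype_id, stage, trait, sti. Records
    whose denominator mean is zero are flagged (NaN sti) and logged; SES is
    converted as 1/SES regardless of orientation.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    validate_phenotypes(table)
    means = (table.groupby(["genotype_id", "stage", "trait", "condition"],
                           sort=False)["value"].mean().unstack("condition"))
    out = means.reset_index()

    is_ses = out["trait"] == "SES"
    stress = out.get("stress")
    control = out.get("control")
    if control is None:
        control = pd.Series(np.nan, index=out.index)
    if stress is None:
        raise ValueError("no stress records in phenotype table")

    if orientation == "stress_over_control":
        num, den = stress, control
    else:
        num, den = control, stress
    with np.errstate(divide="ignore", invalid="ignore"):
        sti = num / den
    # SES: best score / observed score
    sti = sti.where(~is_ses, 1.0 / stress)

    bad = (~is_ses) & ((den == 0) | den.isna() | num.isna())
    if bad.any():
        for _, r in out.loc[bad].iterrows():
            log.warning("STI undefined for %s/%s/%s (zero or missing "
                        "denominator); record flagged", r["genotype_id"],
                        r["stage"], r["trait"])
    sti = sti.where(~bad)
    res = out[["genotype_id", "stage", "trait"]].copy()
    res["sti"] = sti.to_numpy()
    return res


def replicate_sti(table: pd.DataFrame,
                  orientation: str = "stress_over_control") -> pd.DataFrame:
    """Per-replicate STI: replicate stress value over the genotype's control
    mean (used for check comparisons, which need within-genotype spread)."""
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    non_ses = table[table["trait"] != "SES"]
    ctrl = (non_ses[non_ses["condition"] == "control"]
            .groupby(["genotype_id", "stage", "trait"])["value"].mean()
            .rename("control_mean"))
    strs = non_ses[non_ses["condition"] == "stress"].merge(
        ctrl, on=["genotype_id", "stage", "trait"])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = strs["value"] / strs["control_mean"]
        if orientation == "control_over_stress":
            ratio = 1.0 / ratio
    strs = strs.assign(sti=ratio.replace([np.inf, -np.inf], np.nan))
    cols = ["genotype_id", "stage", "trait", "replicate", "sti"]
    parts = [strs[cols]]
    ses = table[table["trait"] == "SES"].copy()
    if len(ses):
        ses["sti"] = 1.0 / ses["value"]
        parts.append(ses[cols])
    return pd.concat(parts, ignore_index=True)


def compare_to_checks(sti_reps: np.ndarray, check_reps: np.ndarray,
                      direction: str = "higher",
                      alpha: float = 0.05) -> dict:
    """One-sided Welch two-sample t-test of genotype replicate STIs against a
    check's replicate STIs.

    Returns a dict with the t statistic, one-sided p-value and a
    ``significant`` flag; fewer than 2 replicates in either group makes the
    comparison untestable (flagged, never significant).
    """
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    a = np.asarray(sti_reps, float)
    b = np.asarray(check_reps, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return {"t": np.nan, "p": np.nan, "significant": False,
                "testable": False}
    alt = "greater" if direction == "higher" else "less"
    t, p = stats.ttest_ind(a, b, equal_var=False, alternative=alt)
    return {"t": float(t), "p": float(p),
            "significant": bool(np.isfinite(p) and p < alpha),
            "testable": True}


def check_comparison_summary(rep_sti: pd.DataFrame, tolerant_check: str,
                             susceptible_check: str, stage: str,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Per-genotype counts of traits with STI significantly above the
    tolerant check and significantly below the susceptible check."""
    sub = rep_sti[rep_sti["stage"] == stage]
    traits = sub["trait"].unique()
    gts = [g for g in sub["genotype_id"].unique()
           if g not in (tolerant_check, susceptible_check)]
    grouped = {k: v["sti"].to_numpy()
               for k, v in sub.groupby(["genotype_id", "trait"])}
    rows = []
    for g in gts:
        above = below = 0
        for t in traits:
            reps = grouped.get((g, t))
            if reps is None:
                continue
            tol = grouped.get((tolerant_check, t))
            sus = grouped.get((susceptible_check, t))
            if tol is not None and compare_to_checks(
                    reps, tol, "higher", alpha)["significant"]:
                above += 1
            if sus is not None and compare_to_checks(
                    reps, sus, "lower", alpha)["significant"]:
                below += 1
        rows.append((g, above, below))
    return pd.DataFrame(rows, columns=["genotype_id",
                                       "n_above_tolerant_check",
                                       "n_below_susceptible_check"])


# ----------------------------------------------------------------------
# I/O

def read_phenotypes(path: str) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path))


def write_phenotypes(table: pd.DataFrame, path: str) -> None:
    table[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def write_sti(sti: pd.DataFrame, path: str) -> None:
    sti.to_csv(path, sep="\t", index=False)
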