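"""Single-marker association scan with Bonferroni control.

The scan is a per-marker additive ordinary-least-squares model of the trait
on alt-allele dosage (0/1/2) over non-missing samples — a deliberately
simple, documented stand-in for multi-locus mixed-model scanners. On top of
it sit the computations this package cares about: the Bonferroni threshold
alpha/m, phenotypic variance explained (PVE = 100 x marker R2), and peak-SNP
naming in the qTRAIT<chrom>.<index> convention (markers ordered by position
within a trait/chromosome and numbered from 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_qc import GenotypeMatrix

SCAN_METHOD = "single-marker additive OLS (stand-in scan)"


@dataclass
class MTARecord:
    """A significant marker-trait association."""

    name: str
    trait: str
    marker_id: str
    chrom: str
    pos: int
    p_value: float
    effect: float
    pve: float


def scan(matrix: GenotypeMatrix, trait_values,
         covariates=None) -> pd.DataFrame:
    """Per-marker additive OLS of the trait on alt-allele dosage.

    Returns a DataFrame (marker id, chrom, pos, n, effect, se, t, p_value,
    pve). Monomorphic or nearly-all-missing markers (fewer than 3 informative
    samples) get NaN statistics and are excluded from significance calls
    downstream. ``covariates`` (n_samples x c), if given, are regressed out
    of the trait first.
    """
    y = np.asarray(trait_values, dtype=float)
    if len(y) != matrix.n_samples:
        raise ValueError("trait vector length != number of samples")
    if covariates is not None:
        C = np.column_stack([np.ones(len(y)), np.asarray(covariates, float)])
        y = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]

    d = matrix.dosage()  # NaN where missing
    valid = np.isfinite(d) & np.isfinite(y)[None, :]
    n = valid.sum(axis=1).astype(float)

    dv = np.where(valid, d, 0.0)
    yv = np.where(valid, y[None, :], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = dv.sum(axis=1) / n
        my = yv.sum(axis=1) / n
        sxx = (dv**2).sum(axis=1) / n - mx**2
        syy = (yv**2).sum(axis=1) / n - my**2
        sxy = (dv * yv).sum(axis=1) / n - mx * my
        slope = sxy / sxx
        r2 = sxy**2 / (sxx * syy)
        r2 = np.clip(r2, 0.0, 1.0)
        df = n - 2
        tstat = np.sign(slope) * np.sqrt(np.where(r2 < 1, r2 * df / (1 - r2),
                                                  np.inf))
        se = np.where(tstat != 0, slope / tstat, np.nan)
        p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(df, 1))
        p = np.where(np.isinf(tstat), 0.0, p)

    bad = (n < 3) | (sxx <= 0) | (syy <= 0)
    for arr in (slope, se, tstat, p, r2):
        arr[bad] = np.nan

    return pd.DataFrame({
        "id": matrix.markers["id"].to_numpy(),
        "chrom": matrix.markers["chrom"].astype(str).to_numpy(),
        "pos": matrix.markers["pos"].to_numpy(),
        "n": n.astype(int),
        "effect": slope,
        "se": se,
        "t": tstat,
        "p_value": p,
        "pve": 100.0 * r2,
    })


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def significant_hits(scan_result: pd.DataFrame, alpha: float = 0.05,
                     m: int | None = None) -> pd.DataFrame:
    """Markers below the Bonferroni threshold; m defaults to the number of
    markers with defined statistics."""
    defined = scan_result.dropna(subset=["p_value"])
    if m is None:
        m = len(defined)
    if m == 0:
        return defined
    thr = bonferroni_threshold(alpha, m)
    return defined[defined["p_value"] < thr].copy()


def name_mtas(hits: pd.DataFrame, trait: str) -> list[MTARecord]:
    """Name significant markers qTRAIT<chrom>.<i>, ordering by position
    within each chromosome and numbering from 1."""
    records = []
    for chrom, grp in hits.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        for i, (_, row) in enumerate(grp.iterrows(), start=1):
            records.append(MTARecord(
                name=f"q{trait}{chrom}.{i}", trait=trait,
                marker_id=row["id"], chrom=str(chrom), pos=int(row["pos"]),
                p_value=float(row["p_value"]), effect=float(row["effect"]),
                pve=float(row["pve"])))
    return records


def scan_traits(matrix: GenotypeMatrix, trait_table: pd.DataFrame,
                alpha: float = 0.05) -> tuple[pd.DataFrame, list[MTARecord]]:
    """Scan every column of a samples-x-traits table and collect named
    significant MTAs. Rows of ``trait_table`` must align with
    ``matrix.samples`` (reindexed by sample id)."""
    trait_table = trait_table.reindex(matrix.samples)
    all_scans, mtas = [], []
    for trait in trait_table.columns:
        res = scan(matrix, trait_table[trait].to_numpy())
        res.insert(0, "trait", trait)
        all_scans.append(res)
        mtas.extend(name_mtas(significant_hits(res, alpha=alpha), trait))
    return pd.concat(all_scans, ignore_index=True), mtas


def manhattan_table(scan_result: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (chrom, pos, -log10 p) table."""
    out = scan_result[["chrom", "pos", "p_value"]].dropna().copy()
    out["neg_log10_p"] = -np.log10(np.maximum(out.pop("p_value"), 1e-300))
    return out
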