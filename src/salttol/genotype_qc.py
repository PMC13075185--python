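"""Biallelic SNP matrices: containers, VCF/HapMap I/O, per-marker statistics
and the quality-control filters applied ahead of association mapping.

Call encoding follows the alt-allele dosage convention: 0 = homozygous
reference, 1 = heterozygous, 2 = homozygous alternate, -1 = missing. QC
removes, in order: samples with high missingness, then markers by
missingness, minor allele frequency and heterozygosity (marker statistics
recomputed after sample removal). Thresholds quoted with ">"/"<" are
honoured strictly: a marker exactly at a removal threshold is retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

#: IUPAC single-letter heterozygote codes used by some HapMap dialects.
_IUPAC_HET = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
_IUPAC_DECODE = {v: k for k, v in _IUPAC_HET.items()}


class GenotypeMatrix:
    """Biallelic SNP calls for a panel of samples.

    Parameters
    ----------
    samples : list of sample identifiers.
    markers : DataFrame with columns ``id, chrom, pos, ref, alt`` (1-based
        positions, single-nucleotide alleles); extra columns (e.g. a causal
        flag from the simulator) are carried along.
    calls : int8 array of shape (n_markers, n_samples) in {0, 1, 2, -1}.
    """

    REQUIRED_COLS = ("id", "chrom", "pos", "ref", "alt")

    def __init__(self, samples: list[str], markers: pd.DataFrame,
                 calls: np.ndarray):
        markers = markers.reset_index(drop=True)
        calls = np.asarray(calls, dtype=np.int8)
        for col in self.REQUIRED_COLS:
            if col not in markers.columns:
                raise ValueError(f"markers missing column {col!r}")
        if calls.shape != (len(markers), len(samples)):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(markers)}, {len(samples)})"
            )
        if (markers["pos"] <= 0).any():
            raise ValueError("marker positions must be strictly positive")
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, -1}")
        self.samples = list(samples)
        self.markers = markers
        self.calls = calls

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def dosage(self, impute_mean: bool = False) -> np.ndarray:
        """Alt-allele dosage as float, NaN (or marker mean) where missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        if impute_mean:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mu = np.nanmean(d, axis=1)
            mu = np.where(np.isfinite(mu), mu, 0.0)
            idx = np.where(np.isnan(d))
            d[idx] = mu[idx[0]]
        return d

    def subset(self, marker_idx=None, sample_idx=None) -> "GenotypeMatrix":
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        return GenotypeMatrix(
            [self.samples[i] for i in si],
            self.markers.iloc[mi],
            self.calls[np.ix_(mi, si)],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.markers[list(self.REQUIRED_COLS)].equals(
                other.markers[list(self.REQUIRED_COLS)])
            and np.array_equal(self.calls, other.calls)
        )


# ----------------------------------------------------------------------
# statistics and filters


def marker_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker missing fraction, minor allele frequency and het fraction.

    MAF uses allele counts over non-missing calls: p = (2*homAlt + het) /
    (2*n_called), MAF = min(p, 1-p). Markers with zero non-missing calls get
    NaN MAF/het (they fall to the missingness filter).
    """
    if matrix.n_markers == 0:
        raise ValueError("empty matrix")
    calls = matrix.calls
    miss = calls == MISSING
    n = matrix.n_samples
    n_called = (~miss).sum(axis=1)
    n_het = (calls == 1).sum(axis=1)
    n_alt_hom = (calls == 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0,
                     (2.0 * n_alt_hom + n_het) / (2.0 * n_called), np.nan)
        het = np.where(n_called > 0, n_het / n_called, np.nan)
    return pd.DataFrame({
        "id": matrix.markers["id"].to_numpy(),
        "missing_frac": miss.sum(axis=1) / n,
        "maf": np.minimum(p, 1.0 - p),
        "het_frac": het,
    })


def sample_missingness(matrix: GenotypeMatrix) -> np.ndarray:
    return (matrix.calls == MISSING).sum(axis=0) / max(matrix.n_markers, 1)


@dataclass
class QCReport:
    """Removal counts per filter, in application order."""

    thresholds: dict = field(default_factory=dict)
    n_samples_in: int = 0
    n_markers_in: int = 0
    samples_removed_missing: int = 0
    markers_removed_missing: int = 0
    markers_removed_maf: int = 0
    markers_removed_het: int = 0
    n_samples_out: int = 0
    n_markers_out: int = 0

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "samples": {"in": self.n_samples_in,
                        "removed_missing": self.samples_removed_missing,
                        "out": self.n_samples_out},
            "markers": {"in": self.n_markers_in,
                        "removed_missing": self.markers_removed_missing,
                        "removed_maf": self.markers_removed_maf,
                        "removed_het": self.markers_removed_het,
                        "out": self.n_markers_out},
        }


class QCError(ValueError):
    def __init__(self, msg: str, report: QCReport):
        super().__init__(msg)
        self.report = report


def apply_qc(matrix: GenotypeMatrix,
             max_sample_missing: float = 0.2,
             max_marker_missing: float = 0.1,
             min_maf: float = 0.05,
             max_het: float = 0.5) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the standard panel filters and return the retained matrix.

    Order: samples with missingness > ``max_sample_missing`` first, then
    markers with missingness > ``max_marker_missing``, MAF < ``min_maf``, or
    heterozygosity > ``max_het`` (statistics recomputed on retained samples).
    Boundary values are retained (strict inequalities). Because removing
    markers changes per-sample missingness, the filter sequence is repeated
    until no further record is removed; this fixed-point pass makes the
    operation idempotent, and the report accumulates removals per filter
    across passes.
    """
    for v in (max_sample_missing, max_marker_missing, min_maf, max_het):
        if not (0.0 <= v <= 1.0):
            raise ValueError("QC thresholds must be in [0, 1]")
    report = QCReport(
        thresholds={"max_sample_missing": max_sample_missing,
                    "max_marker_missing": max_marker_missing,
                    "min_maf": min_maf, "max_het": max_het},
        n_samples_in=matrix.n_samples, n_markers_in=matrix.n_markers,
    )

    m = matrix
    while True:
        smiss = sample_missingness(m)
        keep_s = np.where(smiss <= max_sample_missing)[0]
        report.samples_removed_missing += m.n_samples - len(keep_s)
        if len(keep_s) == 0:
            raise QCError("all samples removed by missingness filter", report)
        removed = len(keep_s) < m.n_samples
        m = m.subset(sample_idx=keep_s)

        stats = marker_stats(m)
        miss_ok = stats["missing_frac"].to_numpy() <= max_marker_missing
        # undefined MAF/het only occur when all calls are missing, i.e.
        # already removed by the missingness filter
        maf_ok = stats["maf"].to_numpy() >= min_maf
        het_ok = stats["het_frac"].to_numpy() <= max_het
        report.markers_removed_missing += int((~miss_ok).sum())
        report.markers_removed_maf += int((miss_ok & ~maf_ok).sum())
        report.markers_removed_het += int((miss_ok & maf_ok & ~het_ok).sum())
        keep_m = np.where(miss_ok & maf_ok & het_ok)[0]
        if len(keep_m) == 0:
            raise QCError("all markers removed by QC filters", report)
        removed |= len(keep_m) < m.n_markers
        m = m.subset(marker_idx=keep_m)
        if not removed:
            break

    report.n_samples_out = m.n_samples
    report.n_markers_out = m.n_markers
    return m, report


# ----------------------------------------------------------------------
# I/O


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a minimal GT-only VCFv4.2 text file."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(matrix.markers["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        mk = matrix.markers
        for i in range(matrix.n_markers):
            row = mk.iloc[i]
            gts = "\t".join(gt_map[int(c)] for c in matrix.calls[i])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t"
                     f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF; multi-allelic records are
    skipped with a logged count."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        ids.append(var.ID if var.ID not in (None, ".") else
                   f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        # gts012: 0/1/2 dosage, 3 = missing
        g = var.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        rows.append(g)
    vcf.close()
    if n_skipped:
        log.warning("skipped %d non-biallelic-SNP records", n_skipped)
    markers = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    calls = np.vstack(rows) if rows else np.empty((0, len(samples)), np.int8)
    return GenotypeMatrix(samples, markers, calls)


_HAPMAP_HEADER = ["rs#", "alleles", "chrom", "pos", "strand", "assembly#",
                  "center", "protLSID", "assayLSID", "panelLSID", "QCcode"]


def write_hapmap(matrix: GenotypeMatrix, path: str) -> None:
    """Write a HapMap TSV with two-letter diploid genotype codes."""
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_HEADER + matrix.samples) + "\n")
        mk = matrix.markers
        for i in range(matrix.n_markers):
            row = mk.iloc[i]
            ref, alt = row["ref"], row["alt"]
            code = {0: ref + ref, 1: ref + alt, 2: alt + alt, MISSING: "NN"}
            gts = "\t".join(code[int(c)] for c in matrix.calls[i])
            fh.write(f"{row['id']}\t{ref}/{alt}\t{row['chrom']}\t{row['pos']}"
                     f"\t+\tNA\tNA\tNA\tNA\tNA\tNA\t{gts}\n")


def read_hapmap(path: str) -> GenotypeMatrix:
    """Read a HapMap TSV; accepts two-letter diploid codes ("AT") and
    single-letter IUPAC heterozygote codes ("W")."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    samples = list(df.columns[11:])
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for _, rec in df.iterrows():
        ref, alt = rec.iloc[1].split("/")
        calls = np.empty(len(samples), dtype=np.int8)
        for j, s in enumerate(samples):
            g = str(rec[s]).upper()
            if g in ("NN", "N", "NA", "--", "NAN"):
                calls[j] = MISSING
            elif len(g) == 1:
                if g == ref:
                    calls[j] = 0
                elif g == alt:
                    calls[j] = 2
                elif g in _IUPAC_DECODE and _IUPAC_DECODE[g] == frozenset(
                        (ref, alt)):
                    calls[j] = 1
                else:
                    calls[j] = MISSING
            else:
                n_alt = sum(1 for ch in g if ch == alt)
                n_ref = sum(1 for ch in g if ch == ref)
                calls[j] = n_alt if n_alt + n_ref == 2 else MISSING
        ids.append(rec.iloc[0])
        chroms.append(rec.iloc[2])
        poss.append(int(rec.iloc[3]))
        refs.append(ref)
        alts.append(alt)
        rows.append(calls)
    markers = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    calls = np.vstack(rows) if rows else np.empty((0, len(samples)), np.int8)
    return GenotypeMatrix(samples, markers, calls)
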