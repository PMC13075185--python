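"""Favourable-allele mining, multilocus combinations, candidate-gene windows.

For each significant marker the favourable allele (FA) is the one whose
homozygous carriers show the better mean trait value (heterozygotes are
excluded from the means); the allelic advantage is the relative mean
difference in percent, 100 x (FA - AA) / AA under higher-is-better. Traits
with several peak SNPs are examined as homozygous multilocus combinations
(one allele letter per locus), and genotypes carrying each trait's
top-ranked combination are intersected into an UpSet-ready membership
matrix. Candidate genes are collected from a GFF3 annotation within a
+/- 150 kb window around each significant SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .association import MTARecord
from .genotype_qc import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class AlleleEffect:
    mta_name: str
    marker_id: str
    favourable_allele: str
    alternate_allele: str
    favourable_mean: float
    alternate_mean: float
    advantage_percent: float
    n_favourable: int
    n_alternate: int
    tie: bool = False


def favourable_allele(calls, trait_values, ref: str, alt: str,
                      direction: str = "higher_is_better",
                      mta_name: str = "", marker_id: str = "") -> AlleleEffect:
    """Identify the favourable allele at one marker.

    ``calls`` are 0/1/2/-1 dosage codes; means are over homozygous carriers
    only. A tie is broken alphabetically with a logged warning; an empty
    homozygous class raises.
    """
    if direction not in ("higher_is_better", "lower_is_better"):
        raise ValueError("bad direction")
    calls = np.asarray(calls)
    y = np.asarray(trait_values, float)
    ref_mask = (calls == 0) & np.isfinite(y)
    alt_mask = (calls == 2) & np.isfinite(y)
    if ref_mask.sum() == 0 or alt_mask.sum() == 0:
        raise ValueError(
            f"marker {marker_id or '?'}: a homozygous class has no carriers")
    means = {ref: float(y[ref_mask].mean()), alt: float(y[alt_mask].mean())}
    counts = {ref: int(ref_mask.sum()), alt: int(alt_mask.sum())}

    tie = means[ref] == means[alt]
    if tie:
        fa = min(ref, alt)
        log.warning("marker %s: allele means tie; favourable allele "
                    "assigned alphabetically (%s)", marker_id or "?", fa)
    elif direction == "higher_is_better":
        fa = ref if means[ref] > means[alt] else alt
    else:
        fa = ref if means[ref] < means[alt] else alt
    aa = alt if fa == ref else ref

    if means[aa] != 0:
        if direction == "higher_is_better":
            adv = 100.0 * (means[fa] - means[aa]) / means[aa]
        else:
            adv = 100.0 * (means[aa] - means[fa]) / means[aa]
    else:
        adv = float("nan")
    return AlleleEffect(mta_name=mta_name, marker_id=marker_id,
                        favourable_allele=fa, alternate_allele=aa,
                        favourable_mean=means[fa], alternate_mean=means[aa],
                        advantage_percent=adv, n_favourable=counts[fa],
                        n_alternate=counts[aa], tie=tie)


def mine_favourable_alleles(matrix: GenotypeMatrix, trait_values,
                            mtas: list[MTARecord],
                            direction: str = "higher_is_better"
                            ) -> list[AlleleEffect]:
    """Favourable allele for every MTA of one trait (skipping markers whose
    homozygous classes are not both populated, with a warning)."""
    idx = {mid: i for i, mid in enumerate(matrix.markers["id"])}
    out = []
    for mta in mtas:
        i = idx[mta.marker_id]
        row = matrix.markers.iloc[i]
        try:
            out.append(favourable_allele(
                matrix.calls[i], trait_values, row["ref"], row["alt"],
                direction=direction, mta_name=mta.name,
                marker_id=mta.marker_id))
        except ValueError as exc:
            log.warning("favourable allele undefined: %s", exc)
    return out


# ----------------------------------------------------------------------
# multilocus combinations

@dataclass
class CombinationResult:
    trait: str
    loci: list[str]
    combination: str
    n: int
    mean: float


def combination_analysis(matrix: GenotypeMatrix, trait_values,
                         mta_loci: list[str],
                         trait: str = "") -> list[CombinationResult]:
    """Group genotypes homozygous at every listed locus by their allele
    string and rank the groups by mean trait value (descending).

    Heterozygous or missing calls at any listed locus exclude the genotype
    from every group. Returns an empty list with a warning if no genotype is
    fully homozygous.
    """
    if len(mta_loci) < 2:
        raise ValueError("combination analysis needs >= 2 loci")
    idx = {mid: i for i, mid in enumerate(matrix.markers["id"])}
    missing_loci = [m for m in mta_loci if m not in idx]
    if missing_loci:
        raise ValueError(f"loci absent from matrix: {missing_loci}")
    rows = [idx[m] for m in mta_loci]
    calls = matrix.calls[rows]  # (loci, samples)
    y = np.asarray(trait_values, float)

    hom = np.all((calls == 0) | (calls == 2), axis=0) & np.isfinite(y)
    if not hom.any():
        log.warning("no genotype homozygous at all loci %s", mta_loci)
        return []
    letters = np.empty(calls.shape, dtype=object)
    for k, r in enumerate(rows):
        rec = matrix.markers.iloc[r]
        letters[k] = np.where(calls[k] == 2, rec["alt"], rec["ref"])

    groups: dict[str, list[int]] = {}
    for j in np.where(hom)[0]:
        combo = "".join(letters[:, j])
        groups.setdefault(combo, []).append(j)
    results = [
        CombinationResult(trait=trait, loci=list(mta_loci), combination=c,
                          n=len(js), mean=float(y[js].mean()))
        for c, js in groups.items()
    ]
    results.sort(key=lambda r: (-r.mean, r.combination))
    return results


def superior_genotypes(combinations_per_trait: dict[str, list[CombinationResult]],
                       matrix: GenotypeMatrix) -> pd.DataFrame:
    """UpSet-ready membership matrix of genotypes carrying each trait's
    best (highest-mean) homozygous combination.

    Only genotypes carrying at least one best combination are emitted; a
    ``n_traits`` column counts memberships.
    """
    samples = np.array(matrix.samples)
    idx = {mid: i for i, mid in enumerate(matrix.markers["id"])}
    membership: dict[str, np.ndarray] = {}
    for trait, combos in combinations_per_trait.items():
        if not combos:
            continue
        best = combos[0]  # ranked descending by mean
        rows = [idx[m] for m in best.loci]
        calls = matrix.calls[rows]
        letters = np.empty(calls.shape, dtype=object)
        ok = np.all((calls == 0) | (calls == 2), axis=0)
        for k, r in enumerate(rows):
            rec = matrix.markers.iloc[r]
            letters[k] = np.where(calls[k] == 2, rec["alt"], rec["ref"])
        carries = ok.copy()
        for j in np.where(ok)[0]:
            carries[j] = "".join(letters[:, j]) == best.combination
        membership[trait] = carries
    if not membership:
        return pd.DataFrame(index=pd.Index([], name="genotype_id"))
    df = pd.DataFrame(membership, index=pd.Index(samples, name="genotype_id"))
    df["n_traits"] = df.sum(axis=1).astype(int)
    return df[df["n_traits"] >= 1].sort_values("n_traits", ascending=False)


# ----------------------------------------------------------------------
# candidate-gene windows

@dataclass
class GeneHit:
    mta_name: str
    gene_id: str
    chrom: str
    start: int
    end: int
    distance_kb: float
    within_gene: bool
    nearest: bool = False
    #: from a user-supplied variant-effect annotation; never computed here
    non_synonymous: bool | None = None


def read_gff3_genes(path: str, feature_type: str = "gene",
                    chrom_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Gene intervals (1-based inclusive) from a GFF3 file.

    Returns columns gene_id, chrom, start, end. ``chrom_map`` renames
    annotation chromosome names onto the SNP naming scheme.
    """
    cols = ["seqid", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols,
                     dtype={"seqid": str})
    df = df[df["type"] == feature_type].copy()

    def gene_id(attrs: str) -> str:
        for field in attrs.split(";"):
            k, _, v = field.strip().partition("=")
            if k == "ID":
                return v
        return attrs

    chrom = df["seqid"]
    if chrom_map:
        chrom = chrom.map(lambda c: chrom_map.get(c, c))
    return pd.DataFrame({
        "gene_id": df["attributes"].map(gene_id).to_numpy(),
        "chrom": chrom.to_numpy(),
        "start": df["start"].astype(int).to_numpy(),
        "end": df["end"].astype(int).to_numpy(),
    })


def candidate_gene_scan(mtas: list[MTARecord], genes: pd.DataFrame,
                        window_kb: float = 150.0,
                        non_synonymous: set[str] | None = None
                        ) -> list[GeneHit]:
    """All genes whose interval intersects [pos - W, pos + W] for each MTA.

    Distance is 0 when the SNP lies inside the gene, else the gap to the
    nearest gene boundary in kb; the closest gene per MTA is flagged.
    Chromosome names must match between SNPs and annotation.
    ``non_synonymous`` optionally names MTAs whose SNP a variant-effect
    annotation calls non-synonymous; the flag is carried through, never
    computed.
    """
    if len(genes) == 0:
        return []
    snp_chroms = {str(m.chrom) for m in mtas}
    gene_chroms = set(genes["chrom"].astype(str))
    unmatched = sorted(snp_chroms - gene_chroms)
    if unmatched:
        raise ValueError(
            f"SNP chromosomes absent from annotation: {unmatched}")

    w = int(round(window_kb * 1000))
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in genes.groupby(genes["chrom"].astype(str)):
        t = IntervalTree()
        for gid, s, e in zip(grp["gene_id"], grp["start"], grp["end"]):
            t.addi(int(s), int(e) + 1, gid)  # half-open over 1-based inclusive
        trees[chrom] = t

    hits: list[GeneHit] = []
    for mta in mtas:
        tree = trees[str(mta.chrom)]
        found = []
        for iv in sorted(tree.overlap(mta.pos - w, mta.pos + w + 1)):
            start, end = iv.begin, iv.end - 1
            if start <= mta.pos <= end:
                dist = 0.0
                inside = True
            else:
                dist = min(abs(mta.pos - start), abs(mta.pos - end)) / 1000.0
                inside = False
            found.append(GeneHit(
                mta_name=mta.name, gene_id=iv.data, chrom=str(mta.chrom),
                start=start, end=end, distance_kb=dist, within_gene=inside,
                non_synonymous=(mta.name in non_synonymous
                                if non_synonymous is not None else None)))
        if found:
            nearest = min(found, key=lambda h: (h.distance_kb, h.gene_id))
            nearest.nearest = True
        hits.extend(found)
    return hits
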