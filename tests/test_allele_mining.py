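"""Favourable alleles, multilocus combinations, gene windows, intersections."""

import numpy as np
import pandas as pd
import pytest

from salttol import allele_mining as am
from salttol.association import MTARecord
from conftest import toy_matrix


def mta(name="qGP12.1", marker="m0", chrom="12", pos=21124440):
    return MTARecord(name=name, trait="GP", marker_id=marker, chrom=chrom,
                     pos=pos, p_value=1e-9, effect=0.5, pve=20.0)


class TestFavourableAllele:
    def test_higher_mean_wins(self):
        # T-homozygotes mean 83.63, A-homozygotes mean 67.17
        calls = [2, 2, 0, 0]
        y = [83.63, 83.63, 67.17, 67.17]
        eff = am.favourable_allele(calls, y, ref="A", alt="T")
        assert eff.favourable_allele == "T"
        assert eff.alternate_allele == "A"
        assert eff.favourable_mean == pytest.approx(83.63)
        # implemented formula: 100 x (FA - AA) / AA
        assert eff.advantage_percent == pytest.approx(24.51, abs=0.01)

    def test_hets_excluded_from_means(self):
        calls = [2, 1, 0, 1]
        y = [10.0, 99.0, 4.0, 99.0]
        eff = am.favourable_allele(calls, y, ref="A", alt="T")
        assert eff.favourable_mean == 10.0 and eff.alternate_mean == 4.0

    def test_tie_alphabetical(self, caplog):
        with caplog.at_level("WARNING"):
            eff = am.favourable_allele([0, 2], [5.0, 5.0], ref="G", alt="C")
        assert eff.favourable_allele == "C" and eff.tie
        assert "tie" in caplog.text

    def test_lower_is_better(self):
        # e.g. sodium accumulation: lower mean is favourable
        eff = am.favourable_allele([0, 2], [2.0, 8.0], ref="A", alt="T",
                                   direction="lower_is_better")
        assert eff.favourable_allele == "A"
        assert eff.advantage_percent == pytest.approx(75.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="no carriers"):
            am.favourable_allele([0, 0, 1], [1.0, 2, 3], ref="A", alt="T")

    def test_advantage_antisymmetry(self):
        # advantage(b->a) = -100*adv / (100+adv) when roles are exchanged
        a_mean, b_mean = 83.63, 67.17
        adv = 100 * (a_mean - b_mean) / b_mean
        rev = 100 * (b_mean - a_mean) / a_mean
        assert rev == pytest.approx(-100 * adv / (100 + adv))

    def test_planted_alt_allele_recovered(self):
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            calls = r.choice([0, 1, 2], size=200, p=[0.36, 0.48, 0.16])
            y = 0.8 * calls + r.normal(size=200)  # alt allele favourable
            eff = am.favourable_allele(calls, y, ref="A", alt="T")
            hits += eff.favourable_allele == "T"
        assert hits >= 19


class TestCombinationAnalysis:
    def test_toy_hand_table(self):
        # 6 genotypes, 2 loci; genotype s4 het at locus 1 -> excluded
        calls = np.array([
            [2, 2, 0, 0, 2, 0],
            [2, 0, 2, 0, 1, 0],
        ])
        y = [1.2, 1.0, 0.8, 0.4, 9.9, 0.6]
        m = toy_matrix(calls, ref="C", alt="T")
        res = am.combination_analysis(m, y, ["m0", "m1"], trait="SVII")
        table = {r.combination: (r.n, r.mean) for r in res}
        assert table == {"TT": (1, 1.2), "TC": (1, 1.0), "CT": (1, 0.8),
                         "CC": (2, pytest.approx(0.5))}
        assert res[0].combination == "TT"  # ranked by mean, best first
        assert sum(r.n for r in res) == 5  # fully homozygous genotypes only

    def test_no_homozygous_genotype(self, caplog):
        m = toy_matrix([[1, 1], [0, 0]])
        with caplog.at_level("WARNING"):
            res = am.combination_analysis(m, [1.0, 2.0], ["m0", "m1"])
        assert res == []

    def test_needs_two_loci(self):
        m = toy_matrix([[0, 2]])
        with pytest.raises(ValueError, match=">= 2"):
            am.combination_analysis(m, [1.0, 2.0], ["m0"])

    def test_unknown_locus(self):
        m = toy_matrix([[0, 2], [0, 2]])
        with pytest.raises(ValueError, match="absent"):
            am.combination_analysis(m, [1.0, 2.0], ["m0", "nope"])


class TestSuperiorGenotypes:
    def test_membership_matrix(self):
        # 4 genotypes x 2 loci; best combination per trait planted by hand
        calls = np.array([
            [2, 2, 0, 0],
            [2, 0, 0, 2],
        ])
        m = toy_matrix(calls, ref="A", alt="G")
        y1 = [5.0, 1.0, 0.5, 0.2]   # best combo GG: only s0
        y2 = [0.1, 0.2, 9.0, 0.3]   # best combo AA: only s2
        combos = {
            "t1": am.combination_analysis(m, y1, ["m0", "m1"], trait="t1"),
            "t2": am.combination_analysis(m, y2, ["m0", "m1"], trait="t2"),
        }
        out = am.superior_genotypes(combos, m)
        assert set(out.index) == {"s0", "s2"}
        assert bool(out.loc["s0", "t1"]) and bool(out.loc["s2", "t2"])
        assert out.loc["s0", "n_traits"] == 1

    def test_multi_trait_carrier_counted(self):
        calls = np.array([[2, 0], [2, 0]])
        m = toy_matrix(calls, ref="A", alt="G")
        combos = {t: am.combination_analysis(m, [3.0, 1.0], ["m0", "m1"],
                                             trait=t)
                  for t in ("a", "b", "c")}
        out = am.superior_genotypes(combos, m)
        assert out.loc["s0", "n_traits"] == 3
        assert "s1" not in out.index  # carries no best combination


def gff3(tmp_path, genes):
    lines = ["##gff-version 3"]
    for gid, chrom, start, end in genes:
        lines.append(f"{chrom}\tsrc\tgene\t{start}\t{end}\t.\t+\t."
                     f"\tID={gid};Name={gid}")
        lines.append(f"{chrom}\tsrc\tmRNA\t{start}\t{end}\t.\t+\t."
                     f"\tID={gid}.1;Parent={gid}")
    p = tmp_path / "ann.gff3"
    p.write_text("\n".join(lines) + "\n")
    return str(p)


class TestCandidateGeneScan:
    def test_snp_inside_gene(self, tmp_path):
        genes = am.read_gff3_genes(gff3(tmp_path,
                                        [("g1", "12", 21124000, 21125000)]))
        hits = am.candidate_gene_scan([mta()], genes)
        assert hits[0].within_gene and hits[0].distance_kb == 0.0
        assert hits[0].nearest

    def test_gene_outside_window(self, tmp_path):
        genes = am.read_gff3_genes(gff3(tmp_path,
                                        [("g1", "12", 21284441, 21290000)]))
        # boundary 160 kb away: no hit at the default 150 kb window
        assert am.candidate_gene_scan([mta()], genes) == []

    def test_boundary_distances_and_nearest(self, tmp_path):
        pos = 1_000_000
        genes = am.read_gff3_genes(gff3(tmp_path, [
            ("near", "12", pos + 353, pos + 2000),
            ("mid", "12", pos - 6000, pos - 5000),
            ("far", "12", pos + 149_000, pos + 200_000),
        ]))
        hits = am.candidate_gene_scan([mta(pos=pos)], genes)
        by_id = {h.gene_id: h for h in hits}
        assert set(by_id) == {"near", "mid", "far"}
        assert by_id["near"].distance_kb == pytest.approx(0.353)
        assert by_id["mid"].distance_kb == pytest.approx(5.0)
        assert by_id["far"].distance_kb == pytest.approx(149.0)
        assert by_id["near"].nearest and not by_id["far"].nearest

    def test_mrna_features_ignored(self, tmp_path):
        genes = am.read_gff3_genes(gff3(tmp_path,
                                        [("g1", "12", 100, 200)]))
        assert len(genes) == 1 and genes["gene_id"].iloc[0] == "g1"

    def test_chromosome_mismatch(self, tmp_path):
        genes = am.read_gff3_genes(gff3(tmp_path, [("g1", "7", 100, 200)]))
        with pytest.raises(ValueError, match="12"):
            am.candidate_gene_scan([mta()], genes)

    def test_brute_force_equivalence(self, tmp_path):
        rng = np.random.default_rng(3)
        n_genes = 500
        starts = rng.integers(1, 5_000_000, size=n_genes)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "chrom": rng.choice(["1", "2"], size=n_genes),
            "start": starts,
            "end": starts + rng.integers(200, 20_000, size=n_genes),
        })
        mtas = [mta(name=f"qX{c}.{i}", chrom=c,
                    pos=int(rng.integers(1, 5_000_000)))
                for i, c in enumerate(["1", "1", "2", "2", "1"])]
        hits = am.candidate_gene_scan(mtas, genes, window_kb=150)
        got = {(h.mta_name, h.gene_id, round(h.distance_kb, 6))
               for h in hits}
        expected = set()
        w = 150_000
        for m in mtas:
            for _, g in genes.iterrows():
                if g["chrom"] != m.chrom:
                    continue
                if g["end"] >= m.pos - w and g["start"] <= m.pos + w:
                    if g["start"] <= m.pos <= g["end"]:
                        d = 0.0
                    else:
                        d = min(abs(m.pos - g["start"]),
                                abs(m.pos - g["end"])) / 1000
                    expected.add((m.name, g["gene_id"], round(d, 6)))
        assert got == expected
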