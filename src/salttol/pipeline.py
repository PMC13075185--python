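"""End-to-end orchestration of the stage-wise salinity-tolerance analysis.

Each stage reads its inputs from, and writes its outputs to, the run
directory, so any stage can be rerun in isolation from the serialized
intermediates without numeric drift; ``run_pipeline`` chains them all. A
single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))``, keeping every
source of randomness reproducible and independent between stages. All
tabular outputs are TSV/CSV with full-precision numbers; a manifest JSON
records the config, seeds, package versions and per-stage record counts.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from . import allele_mining as mining
from . import association as assoc
from . import genotype_qc as gq
from . import phenotype_traits as pt
from . import predictive_model as pm
from . import tolerance_scoring as ts
from . import synthetic_data as sd

log = logging.getLogger(__name__)

#: stage index used in the seed fan-out, fixed for reproducibility
_STAGE_STREAMS = {"simulate": 0, "split": 1, "cv": 2}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed, below 2**31."""
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGE_STREAMS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def _path(cfg: RunConfig, name: str) -> str:
    return os.path.join(cfg.out_dir, name)


def _write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# ----------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig) -> None:
    sim = cfg.simulate
    if sim is None:
        raise ValueError("no simulate block in config")
    sim = type(sim)(**{**sim.to_dict(), "stages": sim.stages,
                       "seed": stage_seed(cfg.seed, "simulate")})
    genotypes = sd.generate_genotypes(sim)
    phenos, latent = sd.generate_phenotypes(sim, genotypes)
    pt.write_phenotypes(phenos, _path(cfg, "phenotypes.csv"))
    gq.write_vcf(genotypes, _path(cfg, "genotypes.vcf"))
    gq.write_hapmap(genotypes, _path(cfg, "genotypes.hmp.txt"))
    sd.write_truth_table(genotypes, latent, _path(cfg, "truth.tsv"))


def _load_phenotypes(cfg: RunConfig) -> pd.DataFrame:
    path = (_path(cfg, "phenotypes.csv") if cfg.simulate is not None
            else cfg.phenotype_csv)
    return pt.read_phenotypes(path)


def _load_genotypes(cfg: RunConfig, qc: bool = False) -> gq.GenotypeMatrix:
    if qc:
        return gq.read_vcf(_path(cfg, "genotypes_qc.vcf"))
    path = (_path(cfg, "genotypes.vcf") if cfg.simulate is not None
            else cfg.genotype_vcf)
    return gq.read_vcf(path)


def _phenos_with_derived(cfg: RunConfig) -> pd.DataFrame:
    phenos = _load_phenotypes(cfg)
    germ = phenos[phenos["stage"] == "germination"]
    if len(germ) and {"GP", "TSL", "DW"} <= set(germ["trait"].unique()):
        phenos = pt.derive_vigour_indices(phenos, stage="germination")
    return phenos


def stage_sti(cfg: RunConfig) -> pd.DataFrame:
    phenos = _phenos_with_derived(cfg)
    sti = pt.compute_sti(phenos, orientation=cfg.sti_orientation)
    pt.write_sti(sti, _path(cfg, "sti.tsv"))
    return sti


def stage_score(cfg: RunConfig) -> pd.DataFrame:
    sti = pd.read_csv(_path(cfg, "sti.tsv"), sep="\t")
    mfv = ts.compute_mfv(sti)
    amfv = ts.compute_amfv(mfv)
    scores, thresholds = ts.classify_stage(amfv)
    mfv.to_csv(_path(cfg, "mfv.tsv"), sep="\t", index=False)
    scores.to_csv(_path(cfg, "amfv_class.tsv"), sep="\t", index=False)
    _write_json({k: v.to_dict() for k, v in thresholds.items()},
                _path(cfg, "classification_thresholds.json"))
    return scores


def stage_crossstage(cfg: RunConfig) -> dict:
    scores = pd.read_csv(_path(cfg, "amfv_class.tsv"), sep="\t")
    stages = list(dict.fromkeys(scores["stage"]))
    if len(stages) < 2:
        log.info("single stage; cross-stage dynamics skipped")
        return {}
    s1 = scores[scores["stage"] == stages[0]]
    s2 = scores[scores["stage"] == stages[1]]
    table, summary = ts.cross_stage(s1, s2)
    table.to_csv(_path(cfg, "transitions.tsv"), sep="\t", index=False)
    _write_json(summary, _path(cfg, "transition_summary.json"))
    return summary


def _sti_wide(sti: pd.DataFrame, stage: str) -> pd.DataFrame:
    sub = sti[sti["stage"] == stage].dropna(subset=["sti"])
    wide = sub.pivot(index="genotype_id", columns="trait", values="sti")
    wide.columns = [f"{t}STI" for t in wide.columns]
    return wide.dropna(axis=0)


def stage_predict(cfg: RunConfig) -> dict:
    sti = pd.read_csv(_path(cfg, "sti.tsv"), sep="\t")
    scores = pd.read_csv(_path(cfg, "amfv_class.tsv"), sep="\t")
    split_seed = stage_seed(cfg.seed, "split")
    cv_seed = stage_seed(cfg.seed, "cv")
    results = {}
    for stage in dict.fromkeys(scores["stage"]):
        wide = _sti_wide(sti, stage)
        sc = scores[scores["stage"] == stage].set_index("genotype_id")
        sc = sc.loc[wide.index]
        y = sc["amfv"].to_numpy()
        labels = sc["tolerance_class"].to_numpy()

        tr, te = pm.stratified_split(labels, cfg.train_fraction, split_seed)
        X = wide.to_numpy()
        names = list(wide.columns)

        vifs = pm.vif(X[tr], names)
        model = pm.fit_cv_model(X[tr], y[tr], names=names,
                                alpha_grid=cfg.alpha_grid, k=cfg.cv_folds,
                                seed=cv_seed)
        coefs = np.array([model.coefficients[n] for n in names])
        pred_te = X[te] @ coefs + model.intercept
        test_metrics = pm.fit_metrics(y[te], pred_te,
                                      p=len(model.active_set))
        r2_rank = pm.rank_single_trait_r2(y[tr], wide.iloc[tr])

        pred_tbl = pd.DataFrame({
            "genotype_id": wide.index[te],
            "observed_amfv": y[te],
            "predicted_y": pred_te,
            "abs_diff": np.abs(y[te] - pred_te),
        })
        tag = stage.replace(" ", "_")
        pred_tbl.to_csv(_path(cfg, f"predictions_{tag}.tsv"), sep="\t",
                        index=False)
        vifs.to_csv(_path(cfg, f"vif_{tag}.tsv"), sep="\t")
        r2_rank.to_csv(_path(cfg, f"single_trait_r2_{tag}.tsv"), sep="\t")
        export = model.to_dict()
        export["test_metrics"] = test_metrics
        export["train_n"] = int(len(tr))
        export["test_n"] = int(len(te))
        _write_json(export, _path(cfg, f"model_{tag}.json"))
        results[stage] = export
    return results


def stage_qc(cfg: RunConfig) -> gq.QCReport:
    matrix = _load_genotypes(cfg)
    filtered, report = gq.apply_qc(
        matrix, max_sample_missing=cfg.qc_sample_missing,
        max_marker_missing=cfg.qc_marker_missing,
        min_maf=cfg.qc_maf, max_het=cfg.qc_het)
    gq.write_vcf(filtered, _path(cfg, "genotypes_qc.vcf"))
    _write_json(report.to_dict(), _path(cfg, "qc_report.json"))
    return report


def stress_trait_means(phenos: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype mean of every trait under stress; traits duplicated
    across stages get an ``s`` suffix for later stages (the association
    scan's trait ids must be unique)."""
    stages = list(dict.fromkeys(phenos["stage"]))
    seen: set[str] = set()
    frames = []
    for si, stage in enumerate(stages):
        sub = phenos[(phenos["stage"] == stage)
                     & (phenos["condition"] == "stress")]
        means = (sub.groupby(["genotype_id", "trait"])["value"].mean()
                 .unstack("trait"))
        rename = {}
        for t in means.columns:
            name = t if t not in seen else t + "s" * si
            rename[t] = name
            seen.add(name)
        frames.append(means.rename(columns=rename))
    return pd.concat(frames, axis=1)


def stage_scan(cfg: RunConfig) -> list[assoc.MTARecord]:
    matrix = _load_genotypes(cfg, qc=True)
    traits = stress_trait_means(_phenos_with_derived(cfg))
    scans, mtas = assoc.scan_traits(matrix, traits,
                                    alpha=cfg.association_alpha)
    scans.to_csv(_path(cfg, "scan.tsv"), sep="\t", index=False)
    assoc.manhattan_table(scans).to_csv(_path(cfg, "manhattan.tsv"),
                                        sep="\t", index=False)
    mta_cols = ["name", "trait", "marker_id", "chrom", "pos", "p_value",
                "effect", "pve"]
    pd.DataFrame([asdict(m) for m in mtas], columns=mta_cols).to_csv(
        _path(cfg, "mtas.tsv"), sep="\t", index=False)
    m = int(scans.dropna(subset=["p_value"])
            .groupby("trait").size().max()) if len(scans) else 0
    _write_json({
        "method": assoc.SCAN_METHOD,
        "alpha": cfg.association_alpha,
        "markers_tested_per_trait": m,
        "bonferroni_threshold": (assoc.bonferroni_threshold(
            cfg.association_alpha, m) if m else None),
        "n_significant": len(mtas),
    }, _path(cfg, "scan_metadata.json"))
    return mtas


def stage_mine(cfg: RunConfig) -> dict:
    matrix = _load_genotypes(cfg, qc=True)
    traits = stress_trait_means(_phenos_with_derived(cfg)).reindex(
        matrix.samples)
    try:
        mta_df = pd.read_csv(_path(cfg, "mtas.tsv"), sep="\t")
    except pd.errors.EmptyDataError:
        mta_df = None
    out = {"n_allele_effects": 0, "n_combination_traits": 0}
    if mta_df is None or len(mta_df) == 0:
        _write_json(out, _path(cfg, "mining_summary.json"))
        return out

    effects_rows = []
    combos_per_trait: dict[str, list[mining.CombinationResult]] = {}
    combo_rows = []
    for trait, grp in mta_df.groupby("trait", sort=False):
        y = traits[trait].to_numpy()
        mtas = [assoc.MTARecord(**{k: row[k] for k in (
            "name", "trait", "marker_id", "chrom", "pos", "p_value",
            "effect", "pve")}) for _, row in grp.iterrows()]
        for eff in mining.mine_favourable_alleles(matrix, y, mtas):
            effects_rows.append(asdict(eff))
        if len(mtas) >= 2:
            loci = [m.marker_id for m in
                    sorted(mtas, key=lambda r: (int(r.chrom)
                                                if str(r.chrom).isdigit()
                                                else r.chrom, r.pos))]
            combos = mining.combination_analysis(matrix, y, loci, trait=trait)
            combos_per_trait[trait] = combos
            for c in combos:
                combo_rows.append({"trait": c.trait,
                                   "loci": ",".join(c.loci),
                                   "combination": c.combination,
                                   "n": c.n, "mean": c.mean})
    pd.DataFrame(effects_rows).to_csv(_path(cfg, "allele_effects.tsv"),
                                      sep="\t", index=False)
    pd.DataFrame(combo_rows).to_csv(_path(cfg, "combinations.tsv"),
                                    sep="\t", index=False)
    members = mining.superior_genotypes(combos_per_trait, matrix)
    members.to_csv(_path(cfg, "superior_genotypes.tsv"), sep="\t")

    if cfg.gff3:
        genes = mining.read_gff3_genes(cfg.gff3)
        mtas_all = [assoc.MTARecord(**{k: row[k] for k in (
            "name", "trait", "marker_id", "chrom", "pos", "p_value",
            "effect", "pve")}) for _, row in mta_df.iterrows()]
        hits = mining.candidate_gene_scan(mtas_all, genes,
                                          window_kb=cfg.window_kb)
        pd.DataFrame([asdict(h) for h in hits]).to_csv(
            _path(cfg, "gene_hits.tsv"), sep="\t", index=False)
        out["n_gene_hits"] = len(hits)

    out["n_allele_effects"] = len(effects_rows)
    out["n_combination_traits"] = len(combos_per_trait)
    out["n_superior_genotypes"] = int(len(members))
    _write_json(out, _path(cfg, "mining_summary.json"))
    return out


# ----------------------------------------------------------------------

_STAGES = ["simulate", "sti", "score", "crossstage", "predict", "qc",
           "scan", "mine"]


def run_pipeline(cfg: RunConfig) -> str:
    """Run every stage in order and write a reproducibility manifest.

    Returns the run directory. Rerunning with the same config and seed
    reproduces all outputs bit-identically.
    """
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    counts: dict[str, dict] = {}
    for stage in _STAGES:
        if stage == "simulate" and cfg.simulate is None:
            continue
        fn = globals()[f"stage_{stage}"]
        log.info("running stage %s", stage)
        try:
            fn(cfg)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        counts[stage] = _stage_counts(cfg, stage)
    manifest = {
        "package": "salttol",
        "version": __version__,
        "versions": _lib_versions(),
        "seed": cfg.seed,
        "stage_seeds": {k: stage_seed(cfg.seed, k) for k in _STAGE_STREAMS},
        "config": _config_echo(cfg),
        "record_counts": counts,
    }
    _write_json(manifest, _path(cfg, "manifest.json"))
    return cfg.out_dir


def _lib_versions() -> dict:
    import scipy
    import sklearn
    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__, "scikit-learn": sklearn.__version__}


def _config_echo(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d.pop("out_dir", None)  # implied by the manifest's own location
    return d


def _stage_counts(cfg: RunConfig, stage: str) -> dict:
    try:
        if stage in ("simulate", "sti"):
            ph = _load_phenotypes(cfg)
            return {"phenotype_records": int(len(ph)),
                    "genotypes": int(ph["genotype_id"].nunique())}
        if stage == "score":
            sc = pd.read_csv(_path(cfg, "amfv_class.tsv"), sep="\t")
            return {"classified": int(len(sc)),
                    "genotypes": int(sc["genotype_id"].nunique())}
        if stage == "crossstage":
            p = _path(cfg, "transitions.tsv")
            return {"transitions": int(len(pd.read_csv(p, sep="\t")))
                    if os.path.exists(p) else 0}
        if stage == "qc":
            with open(_path(cfg, "qc_report.json")) as fh:
                return json.load(fh)["markers"]
        if stage == "scan":
            with open(_path(cfg, "scan_metadata.json")) as fh:
                return {"n_significant": json.load(fh)["n_significant"]}
        if stage == "mine":
            with open(_path(cfg, "mining_summary.json")) as fh:
                return json.load(fh)
    except OSError:  # pragma: no cover
        pass
    return {}
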