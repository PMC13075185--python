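"""Synthetic phenotype and genotype generator.

Emulates a two-stage salinity screen of a diploid panel: each genotype
carries a latent tolerance score per stage built from planted additive
causal SNPs plus a Gaussian residual, correlated across stages. Control
replicate values are a trait baseline times lognormal noise; stress values
shrink the baseline by ``stress_severity`` modulated through a sigmoid of
the latent score, so more tolerant genotypes lose less under stress. The
visual injury score SES is emitted only under stress, as an integer 1..9
decreasing in tolerance.

All randomness flows from ``SimulationConfig.seed`` through a
``numpy.random.SeedSequence`` fan-out, so an identical config reproduces
bit-identical outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DEFAULT_BASELINES, SimulationConfig
from .genotype_qc import MISSING, GenotypeMatrix

NUCLEOTIDES = np.array(list("ACGT"))

PHENOTYPE_COLUMNS = ["genotype_id", "stage", "trait", "condition",
                     "replicate", "value"]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence(config.seed, spawn_key=(stream,)))
    )


def genotype_ids(n: int) -> list[str]:
    return [f"G{i + 1}" for i in range(n)]


def generate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate a biallelic SNP matrix with planted causal loci.

    Allele frequencies are Beta(a, b) truncated to [maf_min, 1 - maf_min];
    calls are Hardy-Weinberg draws. Missingness is injected completely at
    random at ``missing_marker_rate`` per call, plus extra dropout for a
    ``missing_genotype_rate`` fraction of samples; a ``het_excess_rate``
    fraction of markers have calls resampled to heterozygous to exercise the
    heterozygosity filter. Causal loci are flagged in the marker metadata.
    """
    config.validate()
    rng = _rng(config, 0)
    n, m = config.n_genotypes, config.n_snps

    # allele frequencies: truncated Beta via rejection
    freqs = np.empty(m)
    filled = 0
    while filled < m:
        draw = rng.beta(config.maf_beta_a, config.maf_beta_b, size=m)
        ok = draw[(draw >= config.maf_min) & (draw <= 1.0 - config.maf_min)]
        take = min(len(ok), m - filled)
        freqs[filled:filled + take] = ok[:take]
        filled += take

    # map: markers spread over chromosomes, positions strictly increasing
    chroms = np.sort(rng.integers(1, config.n_chromosomes + 1, size=m))
    positions = np.empty(m, dtype=np.int64)
    for c in np.unique(chroms):
        idx = np.where(chroms == c)[0]
        # strictly increasing positions via cumulative random gaps
        gaps = rng.integers(1, 60_000, size=len(idx))
        positions[idx] = np.cumsum(gaps)

    ref_idx = rng.integers(0, 4, size=m)
    alt_shift = rng.integers(1, 4, size=m)
    refs = NUCLEOTIDES[ref_idx]
    alts = NUCLEOTIDES[(ref_idx + alt_shift) % 4]

    calls = rng.binomial(2, freqs[:, None], size=(m, n)).astype(np.int8)

    # heterozygote excess: selected markers resampled toward het
    n_het_markers = int(round(config.het_excess_rate * m))
    het_markers = rng.choice(m, size=n_het_markers, replace=False)
    for i in het_markers:
        mask = rng.random(n) < 0.7
        calls[i, mask] = 1

    # MCAR per-call missingness + high-dropout samples
    miss = rng.random((m, n)) < config.missing_marker_rate
    bad_samples = rng.random(n) < config.missing_genotype_rate
    extra = rng.random((m, n)) < 0.3
    miss |= extra & bad_samples[None, :]
    calls[miss] = MISSING

    causal = np.zeros(m, dtype=bool)
    eligible = np.setdiff1d(np.arange(m), het_markers)
    causal_idx = rng.choice(eligible if len(eligible) >= config.n_causal
                            else np.arange(m),
                            size=config.n_causal, replace=False)
    causal[causal_idx] = True
    effects = np.zeros(m)
    effects[np.sort(causal_idx)] = config.effects()

    markers = pd.DataFrame({
        "id": [f"S{c}_{p}" for c, p in zip(chroms, positions)],
        "chrom": [str(c) for c in chroms],
        "pos": positions,
        "ref": refs,
        "alt": alts,
        "is_causal": causal,
        "effect": effects,
        "freq": freqs,
    })
    return GenotypeMatrix(genotype_ids(n), markers, calls)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def latent_tolerance(config: SimulationConfig,
                     genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-genotype latent tolerance scores, one standardized column per
    stage, correlated across stages at ``cross_stage_correlation``."""
    config.validate()
    rng = _rng(config, 1)
    n = config.n_genotypes
    rho = config.cross_stage_correlation

    dos = genotypes.dosage(impute_mean=True)
    g = genotypes.markers["effect"].to_numpy() @ dos  # genetic score
    vg = float(np.var(g))
    sigma = config.latent_residual_sd
    h2 = vg / (vg + sigma**2) if vg + sigma**2 > 0 else 0.0
    gs = (g - g.mean()) / np.sqrt(vg) if vg > 0 else np.zeros(n)

    if h2 >= 1.0:
        r = 1.0 if rho == 1.0 else 0.0
    else:
        r = (rho - h2) / (1.0 - h2)
    if not (-1.0 <= r <= 1.0 + 1e-12):
        raise ValueError(
            f"cross_stage_correlation={rho} unreachable with genetic share "
            f"h2={h2:.3f} (residual correlation {r:.3f} out of [-1, 1])")
    r = min(r, 1.0)

    stage_names = [st.name for st in config.stages]
    e1 = rng.standard_normal(n)
    resid = {stage_names[0]: e1}
    for name in stage_names[1:]:
        resid[name] = r * e1 + np.sqrt(max(0.0, 1.0 - r**2)) * rng.standard_normal(n)

    out = {"genotype_id": genotype_ids(n)}
    for name in stage_names:
        out[name] = np.sqrt(h2) * gs + np.sqrt(1.0 - h2) * resid[name]
    return pd.DataFrame(out)


def generate_phenotypes(
    config: SimulationConfig, genotypes: GenotypeMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate replicate-level phenotypes for every stage.

    Returns (phenotype table, latent tolerance table). The phenotype table
    is long-format with columns genotype_id, stage, trait, condition,
    replicate, value.
    """
    config.validate()
    latent = latent_tolerance(config, genotypes)
    rng = _rng(config, 2)
    n, nrep = config.n_genotypes, config.n_replicates
    ids = genotype_ids(n)

    cv = config.noise_cv
    s = np.sqrt(np.log1p(cv**2))  # lognormal sigma for unit-mean noise

    def noise(size):
        if cv == 0:
            return np.ones(size)
        return np.exp(rng.normal(-0.5 * s**2, s, size=size))

    records = []
    for st in config.stages:
        lat = latent[st.name].to_numpy()
        reduction = 1.0 - config.stress_severity * (1.0 - _sigmoid(lat))
        for trait in st.traits:
            if trait == "SES":
                # visual injury score: stress only, integer 1..9, worse
                # (higher) for less tolerant genotypes
                base = 1.0 + 8.0 * (1.0 - _sigmoid(lat))
                for rep in range(1, nrep + 1):
                    vals = np.clip(np.rint(base + rng.normal(0, 0.5, n)),
                                   1, 9).astype(int)
                    for gid, v in zip(ids, vals):
                        records.append((gid, st.name, trait, "stress", rep,
                                        float(v)))
                continue
            baseline = DEFAULT_BASELINES.get(trait, 1.0)
            for rep in range(1, nrep + 1):
                ctrl = baseline * noise(n)
                strs = baseline * reduction * noise(n)
                for gid, v in zip(ids, ctrl):
                    records.append((gid, st.name, trait, "control", rep, v))
                for gid, v in zip(ids, strs):
                    records.append((gid, st.name, trait, "stress", rep, v))

    table = pd.DataFrame(records, columns=PHENOTYPE_COLUMNS)
    return table, latent


def write_truth_table(genotypes: GenotypeMatrix, latent: pd.DataFrame,
                      path: str) -> None:
    """TSV of planted causal loci (id, chrom, pos, effect) followed by the
    per-genotype latent scores."""
    causal = genotypes.markers[genotypes.markers["is_causal"]]
    with open(path, "w") as fh:
        fh.write("# causal loci\n")
        causal[["id", "chrom", "pos", "effect"]].to_csv(fh, sep="\t",
                                                        index=False)
        fh.write("# latent tolerance\n")
        latent.to_csv(fh, sep="\t", index=False)
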