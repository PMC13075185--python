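"""Configuration objects for the simulator and the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

GERMINATION_TRAITS = ["GP", "RL", "SL", "TSL", "FW", "DW"]
SEEDLING_TRAITS = [
    "SES", "RL", "SL", "TSL", "RFW", "SFW", "TFW", "RDW", "SDW", "TDW",
    "RNa", "RK", "RNaK", "SNa", "SK", "SNaK",
]

#: Arbitrary positive per-trait baselines (trait units); indices downstream
#: are ratios, so the scale carries no biological calibration.
DEFAULT_BASELINES: dict[str, float] = {
    "GP": 90.0, "RL": 8.0, "SL": 12.0, "TSL": 20.0, "FW": 0.8, "DW": 0.08,
    "RFW": 0.5, "SFW": 1.2, "TFW": 1.7, "RDW": 0.05, "SDW": 0.12,
    "TDW": 0.17, "RNa": 5.0, "RK": 1.5, "RNaK": 3.3, "SNa": 4.0,
    "SK": 2.0, "SNaK": 2.0,
}


@dataclass
class StageSpec:
    """A developmental stage and the traits measured at it."""

    name: str
    traits: list[str]


def default_stages() -> list[StageSpec]:
    return [
        StageSpec("germination", list(GERMINATION_TRAITS)),
        StageSpec("early_seedling", list(SEEDLING_TRAITS)),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic phenotype + genotype generator.

    The defaults emulate the design of the screening experiment the package
    targets: 201 genotypes, three replicates per genotype under control and
    120 mM NaCl stress, a germination stage (6 measured traits, two vigour
    indices derived downstream) and an early-seedling stage (16 traits
    including the visual SES injury score recorded only under stress).
    """

    n_genotypes: int = 201
    n_replicates: int = 3
    stages: list[StageSpec] = field(default_factory=default_stages)
    n_snps: int = 500
    n_chromosomes: int = 12
    n_causal: int = 5
    causal_effect_sizes: list[float] | None = None  # default 0.5 per locus
    latent_residual_sd: float = 1.0
    stress_severity: float = 0.5
    noise_cv: float = 0.1
    cross_stage_correlation: float = 0.75
    missing_genotype_rate: float = 0.02
    missing_marker_rate: float = 0.02
    het_excess_rate: float = 0.02
    maf_beta_a: float = 0.5
    maf_beta_b: float = 0.5
    maf_min: float = 0.05
    seed: int = 0

    def effects(self) -> list[float]:
        if self.causal_effect_sizes is None:
            return [0.5] * self.n_causal
        return list(self.causal_effect_sizes)

    def validate(self) -> None:
        if self.n_genotypes < 1 or self.n_replicates < 1 or self.n_snps < 1:
            raise ValueError("counts must be positive")
        if self.n_causal > self.n_snps:
            raise ValueError(
                f"n_causal ({self.n_causal}) exceeds n_snps ({self.n_snps})"
            )
        if len(self.effects()) != self.n_causal:
            raise ValueError("causal_effect_sizes length must equal n_causal")
        if not (0.0 <= self.stress_severity < 1.0):
            raise ValueError("stress_severity must be in [0, 1)")
        for name in ("missing_genotype_rate", "missing_marker_rate",
                     "het_excess_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (-1.0 <= self.cross_stage_correlation <= 1.0):
            raise ValueError("cross_stage_correlation must be in [-1, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not self.stages:
            raise ValueError("at least one stage required")
        for st in self.stages:
            if not st.traits:
                raise ValueError(f"stage {st.name!r} has an empty trait list")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "stages" in d and d["stages"] is not None:
            d["stages"] = [
                st if isinstance(st, StageSpec) else StageSpec(**st)
                for st in d["stages"]
            ]
        return cls(**d)


@dataclass
class RunConfig:
    """Top-level pipeline configuration.

    Exactly one of ``simulate`` or the input paths (``phenotype_csv`` and
    ``genotype_vcf``) must be provided. ``gff3`` is optional; without it the
    candidate-gene window scan is skipped.
    """

    simulate: SimulationConfig | None = None
    phenotype_csv: str | None = None
    genotype_vcf: str | None = None
    gff3: str | None = None
    sti_orientation: str = "stress_over_control"
    train_fraction: float = 0.8
    cv_folds: int = 10
    alpha_grid: list[float] = field(
        default_factory=lambda: [round(0.1 * i, 1) for i in range(11)]
    )
    qc_sample_missing: float = 0.2
    qc_marker_missing: float = 0.1
    qc_maf: float = 0.05
    qc_het: float = 0.5
    association_alpha: float = 0.05
    window_kb: float = 150.0
    seed: int = 0
    out_dir: str = "salttol_run"

    def validate(self) -> None:
        has_sim = self.simulate is not None
        has_paths = self.phenotype_csv is not None and self.genotype_vcf is not None
        if not has_sim and not has_paths:
            raise ValueError(
                "config needs either a simulate block or phenotype_csv + genotype_vcf"
            )
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        for name in ("qc_sample_missing", "qc_marker_missing", "qc_maf", "qc_het"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 < self.association_alpha < 1.0):
            raise ValueError("association_alpha must be in (0, 1)")
        if self.window_kb < 0:
            raise ValueError("window_kb must be non-negative")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if d.get("simulate") is not None and not isinstance(
            d["simulate"], SimulationConfig
        ):
            d["simulate"] = SimulationConfig.from_dict(d["simulate"])
        return cls(**d)
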