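"""Configuration objects: simulation, QC thresholds, and run-level settings."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields as dc_fields

import yaml

from .errors import ConfigurationError


def _check(cond: bool, name: str, message: str) -> None:
    if not cond:
        raise ConfigurationError(f"{name}: {message}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genotype/phenotype generator.

    ``causal_spec`` lists ``(handle, per_allele_odds_ratio)`` pairs where a
    handle is either a SNP id from the generated map or ``"gene:<gene id>"``
    (the SNP nearest the gene midpoint is made causal).  The phenotype is
    additive on the log-odds scale: ``logit P(case) = logit(prevalence) +
    sum(dosage * ln OR)``.
    """

    n_cases: int = 100
    n_controls: int = 100
    n_trios: int = 100
    n_chromosomes: int = 2
    genes_per_chromosome: int = 50
    gene_length_range: tuple[int, int] = (20_000, 120_000)
    intergenic_gap_range: tuple[int, int] = (20_000, 200_000)
    snp_spacing_range: tuple[int, int] = (5_000, 20_000)
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    causal_spec: list[tuple[str, float]] = field(default_factory=list)
    baseline_prevalence: float = 0.1
    missing_rate: float = 0.0
    second_transcript_fraction: float = 0.0   # extra transcript obeying merge rules
    split_transcript_fraction: float = 0.0    # extra transcript violating merge rules
    mendel_error_rate: float = 0.0            # inconsistency injection for QC tests
    trio_draw_cap: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cases", "n_controls", "n_trios", "n_chromosomes",
                     "genes_per_chromosome", "trio_draw_cap"):
            _check(getattr(self, name) >= 0, name, "must be >= 0")
        lo, hi = self.maf_range
        _check(0 < lo <= hi <= 0.5, "maf_range", "must lie within (0, 0.5]")
        _check(0 <= self.ld_rho < 1, "ld_rho", "must lie in [0, 1)")
        _check(0 <= self.baseline_prevalence < 1, "baseline_prevalence",
               "must lie in [0, 1)")
        for name in ("missing_rate", "second_transcript_fraction",
                     "split_transcript_fraction", "mendel_error_rate"):
            _check(0 <= getattr(self, name) <= 1, name, "must lie in [0, 1]")
        for name in ("gene_length_range", "intergenic_gap_range",
                     "snp_spacing_range"):
            lo, hi = getattr(self, name)
            _check(0 < lo <= hi, name, "must be a positive (low, high) interval")
        for handle, orr in self.causal_spec:
            _check(orr > 0, "causal_spec", f"odds ratio for {handle!r} must be > 0")


@dataclass
class QcThresholds:
    """SNP/sample quality-control thresholds.

    ``maf_min_cc`` applies to the whole case-control sample; ``maf_min_parents``
    to parents of trios.  ``hwe_p_min`` is evaluated in the design-specific
    stratum (controls for case-control, parents for trios).  The per-SNP
    call-rate minimum defaults symmetrically to the per-sample one.
    """

    sample_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.95
    maf_min_cc: float = 0.01
    maf_min_parents: float = 0.05
    hwe_p_min: float = 0.001
    mendel_fraction_max: float = 0.05

    def __post_init__(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            _check(0 <= v <= 1, f.name, "must lie in [0, 1]")


@dataclass
class RunConfig:
    """End-to-end run settings: schedule, margins, percentiles, seed, paths."""

    design: str = "case-control"              # or "trios"
    ped_path: str | None = None
    map_path: str | None = None
    annotation_path: str | None = None
    gene_set_path: str | None = None
    output_dir: str = "snpgsea_out"
    qc: QcThresholds = field(default_factory=QcThresholds)
    upstream_bp: int = 110_000
    downstream_bp: int = 40_000
    strand_aware: bool = True
    permutation_schedule: tuple[int, ...] = (10_000, 100_000, 1_000_000)
    escalation_thresholds: tuple[float, ...] = (0.01, 0.001)
    percentiles: tuple[int, ...] = (95, 75, 50)
    n_samplings: int = 10_000
    seed: int = 0

    def __post_init__(self):
        _check(self.design in ("case-control", "trios"), "design",
               "must be 'case-control' or 'trios'")
        sched = tuple(self.permutation_schedule)
        _check(all(b > a for a, b in zip(sched, sched[1:])),
               "permutation_schedule", "stages must be strictly increasing")
        _check(len(self.escalation_thresholds) == len(sched) - 1,
               "escalation_thresholds",
               "needs one threshold per schedule escalation")
        _check(all(0 < p < 100 for p in self.percentiles), "percentiles",
               "must lie in (0, 100)")
        _check(self.n_samplings >= 1, "n_samplings", "must be >= 1")


def _from_mapping(cls, data: dict):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_simulation_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "causal_spec" in data:
        data["causal_spec"] = [tuple(x) for x in data["causal_spec"]]
    for key in ("gene_length_range", "intergenic_gap_range", "snp_spacing_range",
                "maf_range"):
        if key in data:
            data[key] = tuple(data[key])
    return _from_mapping(SimulationConfig, data)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "qc" in data:
        data["qc"] = _from_mapping(QcThresholds, data["qc"] or {})
    for key in ("permutation_schedule", "escalation_thresholds", "percentiles"):
        if key in data:
            data[key] = tuple(data[key])
    return _from_mapping(RunConfig, data)


def dump_config(cfg, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
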