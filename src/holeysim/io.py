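"""Configuration files, result tables, FASTA export, run manifests."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from .evolution import EquilibriumCriterion
from .experiments import ExperimentConfig

__all__ = [
    "load_config",
    "dump_config",
    "write_results",
    "read_results",
    "export_fasta",
    "RunManifest",
]

_EQ_KEYS = {"window", "slope_tol", "min_generations", "measure_every", "sample_size"}
_CONFIG_KEYS = {
    "model",
    "L",
    "p",
    "sigma",
    "alpha",
    "N_values",
    "regimes",
    "U",
    "U_policy",
    "NU",
    "replicates",
    "target_D",
    "cadence",
    "snapshots",
    "measure_RI",
    "master_seed",
    "max_generations",
    "equilibrium",
}

RESULT_COLUMNS = [
    "cell",
    "N",
    "regime",
    "replicate",
    "generation",
    "D",
    "II_12",
    "II_21",
    "II_within_1",
    "II_within_2",
    "nu_1",
    "nu_2",
    "pi_1",
    "pi_2",
    "RI",
    "extinct",
    "equilibrated",
]


def _config_from_mapping(data: dict) -> ExperimentConfig:
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    data = dict(data)
    if "p" in data and not 0.0 < float(data["p"]) < 1.0:
        raise ValueError(f"configuration key 'p' must lie in (0, 1), got {data['p']}")
    eq = data.pop("equilibrium", None)
    if eq is not None:
        bad = set(eq) - _EQ_KEYS
        if bad:
            raise ValueError(f"unknown equilibrium key(s): {sorted(bad)}")
        data["equilibrium"] = EquilibriumCriterion(**eq)
    return ExperimentConfig(**data)


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration.

    Every unset field takes its documented default; unknown keys are
    rejected with an error naming the offending key.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration in {path} is not a mapping")
    try:
        return _config_from_mapping(data)
    except TypeError as exc:
        raise ValueError(f"invalid configuration in {path}: {exc}") from exc


def dump_config(config: ExperimentConfig) -> str:
    """Canonical YAML form of a configuration (regimes as string labels)."""
    data = asdict(config)
    data["regimes"] = [r.label() for r in config.regimes]
    data["N_values"] = list(config.N_values)
    return yaml.safe_dump(data, sort_keys=True)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a tidy results table as CSV at full numeric precision."""
    cols = [c for c in RESULT_COLUMNS if c in table.columns] + [
        c for c in table.columns if c not in RESULT_COLUMNS
    ]
    table[cols].to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


def export_fasta(pop, path, pop_id: int = 0) -> None:
    """Write an RNA population as FASTA; ids encode population, member, generation."""
    if pop.alphabet != "rna":
        raise ValueError("FASTA export is defined for RNA populations only")
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(g.sequence),
            id=f"pop{pop_id}|ind{i}|gen{pop.generation}",
            description="",
        )
        for i, g in enumerate(pop.members)
    ]
    seqio_write(records, str(path), "fasta")


@dataclass
class RunManifest:
    """Everything needed to re-run any grid cell bit-identically."""

    config: dict
    master_seed: int
    version: str
    replicate_seeds: dict[str, list[list[int]]] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_config(cls, config: ExperimentConfig) -> "RunManifest":
        from . import __version__

        seeds = {}
        for ci, (N, regime) in enumerate(config.cells()):
            cell_id = f"N{N}_{regime.label()}"
            seeds[cell_id] = [
                [config.master_seed, ci, rep] for rep in range(config.replicates)
            ]
        return cls(
            config=yaml.safe_load(dump_config(config)),
            master_seed=config.master_seed,
            version=__version__,
            replicate_seeds=seeds,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**yaml.safe_load(Path(path).read_text()))
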