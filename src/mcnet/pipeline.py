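"""One-command orchestration: align, transfer, correlate, threshold, extract.

A :class:`PipelineConfig` describes a full analysis — where the landmarks
(or a precomputed Rv matrix) come from, the threshold, the annealing
plan, and which robustness analyses to run.  :func:`run` executes the
stages in order, returns the in-memory artifacts, and (when an output
directory is given) writes aligned coordinates, the Rv matrix, networks,
frequency tables, reproducibility scores, sweep/leave-one-out reports and
a manifest sufficient to reproduce the run.  Starting from an Rv matrix
skips superimposition and transfer.

Defaults mirror the study design the package targets: primary threshold
0.2, sweep over {none, 0.2, 0.4}, 10,000 annealing trials, gamma 1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from . import io as mio
from .community import (
    AnnealConfig,
    Partition,
    SolutionFrequencyTable,
    frequency_solutions,
    module_reproducibility,
    null_model,
)
from .data import Dataset
from .errors import McnetError, StructureError
from .procrustes import AlignedDataset, gpa, procrustes_anova, transfer
from .rv import CorrelationNetwork, RvMatrix, rv_matrix, threshold_network
from .sensitivity import StabilityReport, SweepReport, leave_one_out, threshold_sweep


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of one full analysis run."""

    landmarks_path: Optional[str] = None
    landmarks_format: Optional[str] = None
    roles: Optional[tuple[str, ...]] = None  # TPS side-channel role map
    labels: Optional[tuple[str, ...]] = None
    rv_path: Optional[str] = None  # start-from-Rv-matrix mode
    species_label: str = ""
    tau: Optional[float] = 0.2
    sweep_taus: tuple[Optional[float], ...] = (None, 0.2, 0.4)
    trials: int = 10_000
    gamma: float = 1.0
    use: str = "specimen_means"
    seed: int = 0
    run_sweep: bool = False
    run_loo: bool = False
    loo_trials: int = 1_000
    initial_temperature: Optional[float] = None
    cooling_factor: float = 0.99
    sweeps_per_temperature: int = 50
    min_temperature: float = 1e-3
    patience: int = 200
    outdir: Optional[str] = None

    def anneal_config(self, trials: Optional[int] = None) -> AnnealConfig:
        return AnnealConfig(
            trials=self.trials if trials is None else trials,
            initial_temperature=self.initial_temperature,
            cooling_factor=self.cooling_factor,
            sweeps_per_temperature=self.sweeps_per_temperature,
            min_temperature=self.min_temperature,
            patience=self.patience,
            gamma=self.gamma,
            master_seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roles"] = list(self.roles) if self.roles else None
        d["labels"] = list(self.labels) if self.labels else None
        d["sweep_taus"] = list(self.sweep_taus)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("roles", "labels", "sweep_taus"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class PipelineResult:
    """All artifacts of one run (entries are None for skipped stages)."""

    config: PipelineConfig
    dataset: Optional[Dataset]
    aligned: Optional[AlignedDataset]
    anova: Optional[object]
    rv: RvMatrix
    network: CorrelationNetwork
    table: SolutionFrequencyTable
    reproducibility: dict[str, float]  # per top-solution module, keyed by members
    sweep: Optional[SweepReport]
    loo: Optional[StabilityReport]

    @property
    def top_partition(self) -> Partition:
        return self.table.top.partition


def _load_inputs(config: PipelineConfig) -> tuple[Optional[Dataset], Optional[RvMatrix]]:
    if config.rv_path is not None:
        return None, mio.read_rv_matrix(config.rv_path)
    if config.landmarks_path is None:
        raise StructureError("config must name landmarks_path or rv_path")
    dataset = mio.read_landmarks(
        config.landmarks_path,
        config.landmarks_format,
        roles=config.roles,
        labels=config.labels,
        species_label=config.species_label,
    )
    return dataset, None


def run(
    config: PipelineConfig,
    dataset: Optional[Dataset] = None,
    rv: Optional[RvMatrix] = None,
) -> PipelineResult:
    """Execute the pipeline; ``dataset``/``rv`` override file inputs."""
    if dataset is None and rv is None:
        dataset, rv = _load_inputs(config)

    aligned = None
    anova = None
    if rv is None:
        try:
            fit = gpa(dataset)
            aligned = transfer(fit, dataset)
        except McnetError as exc:
            raise type(exc)(f"superimposition stage failed: {exc}") from exc
        counts = set(dataset.replicate_counts().values())
        if counts == {next(iter(counts))} and next(iter(counts)) >= 2:
            anova = procrustes_anova(aligned)
        try:
            rv = rv_matrix(aligned, use=config.use)
        except McnetError as exc:
            raise type(exc)(f"correlation stage failed: {exc}") from exc

    net = threshold_network(rv, config.tau)
    null = null_model(net)
    table = frequency_solutions(net, null, config.anneal_config())
    reproducibility = {
        ",".join(mod): module_reproducibility(table, mod)
        for mod in table.top.partition.modules
    }

    sweep = None
    if config.run_sweep:
        sweep = threshold_sweep(rv, config.sweep_taus, config.anneal_config())
    loo = None
    if config.run_loo:
        if dataset is None:
            raise StructureError("leave-one-out requires landmark input")
        loo = leave_one_out(
            dataset, config.tau, config.anneal_config(config.loo_trials), config.use
        )

    result = PipelineResult(
        config=config,
        dataset=dataset,
        aligned=aligned,
        anova=anova,
        rv=rv,
        network=net,
        table=table,
        reproducibility=reproducibility,
        sweep=sweep,
        loo=loo,
    )
    if config.outdir is not None:
        write_bundle(result, config.outdir)
    return result


def _tau_tag(tau: Optional[float]) -> str:
    return "none" if tau is None else f"{tau:g}"


def sweep_to_dict(sweep: SweepReport) -> dict:
    return {
        "taus": [_tau_tag(t) for t in sweep.taus],
        "tables": [mio.frequency_table_to_dict(t) for t in sweep.tables],
        "agreement": sweep.agreement.tolist(),
        "rand_index": sweep.rand_index.tolist(),
        "all_agree": sweep.all_agree,
    }


def loo_to_dict(loo: StabilityReport) -> dict:
    return {
        "specimen_ids": list(loo.specimen_ids),
        "full_top": mio.partition_to_dict(loo.full_top),
        "full_top_frequency": loo.full_top_frequency,
        "loo_tops": [mio.partition_to_dict(p) for p in loo.loo_tops],
        "loo_top_frequencies": list(loo.loo_top_frequencies),
        "agreement": list(loo.agreement),
        "rand_index": list(loo.rand_index),
        "agreement_fraction": loo.agreement_fraction,
        "stable": loo.stable,
    }


def write_bundle(result: PipelineResult, outdir) -> None:
    """Write every artifact plus a reproduction manifest to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config_dict = result.config.to_dict()
    config_dict.pop("outdir")  # a location, not an analysis parameter
    manifest = {
        "mcnet_version": __version__,
        "config": config_dict,
    }
    mio.write_json_report(manifest, out / "manifest.json")
    if result.aligned is not None:
        result.aligned.to_dataframe().to_csv(out / "aligned.csv", index=False)
    if result.anova is not None:
        mio.write_json_report(
            {
                "SS_individual": result.anova.ss_individual,
                "SS_error": result.anova.ss_error,
                "df_individual": result.anova.df_individual,
                "df_error": result.anova.df_error,
                "MS_individual": result.anova.ms_individual,
                "MS_error": result.anova.ms_error if not result.anova.zero_error else 0.0,
                "F": "inf" if result.anova.zero_error else result.anova.f_ratio,
                "p": result.anova.p_value,
                "shape_dim": result.anova.shape_dim,
            },
            out / "anova.json",
        )
    mio.write_rv_matrix(result.rv, out / "rv_matrix.csv")
    mio.write_network(result.network, out / "network.graphml")
    mio.write_network(result.network, out / "network.edgelist")
    mio.write_frequency_table(result.table, out / "solutions.json")
    mio.write_json_report(
        {
            "top_partition": mio.partition_to_dict(result.top_partition),
            "module_reproducibility": result.reproducibility,
        },
        out / "reproducibility.json",
    )
    if result.sweep is not None:
        mio.write_json_report(sweep_to_dict(result.sweep), out / "sweep.json")
    if result.loo is not None:
        mio.write_json_report(loo_to_dict(result.loo), out / "loo.json")
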