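"""Robustness analyses: threshold sweep and leave-one-out sample sufficiency.

The module architecture extracted from a thresholded correlation network
can in principle depend on the threshold choice and on the particular
specimens sampled.  Two checks address this:

* a *threshold sweep* re-runs module extraction at several threshold
  levels (including none, i.e. the complete weighted graph) and compares
  the most frequent solutions across levels;
* a *leave-one-out* analysis re-runs the full pipeline (superimposition,
  transfer, Rv matrix, thresholding, module extraction) on every n-1
  subset and compares each top solution with the full-sample one.

Architecture comparison uses exact canonical-partition equality; an
adjusted Rand index is additionally reported as a graded diagnostic,
never as the pass criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .community import (
    AnnealConfig,
    Partition,
    SolutionFrequencyTable,
    frequency_solutions,
    null_model,
)
from .data import Dataset
from .errors import StructureError
from .procrustes import AlignedDataset, ProcrustesFit, gpa, transfer
from .rv import CorrelationNetwork, RvMatrix, rv_matrix, threshold_network


@dataclass(frozen=True)
class AnalysisResult:
    """Artifacts of one full pipeline run on one dataset."""

    fit: ProcrustesFit
    aligned: AlignedDataset
    rv: RvMatrix
    network: CorrelationNetwork
    table: SolutionFrequencyTable

    @property
    def top_partition(self) -> Partition:
        return self.table.top.partition


def analyze(
    dataset: Dataset,
    tau: Optional[float],
    config: AnnealConfig,
    use: str = "specimen_means",
) -> AnalysisResult:
    """Superimpose, transfer, correlate, threshold and extract modules."""
    fit = gpa(dataset)
    aligned = transfer(fit, dataset)
    rv = rv_matrix(aligned, use=use)
    net = threshold_network(rv, tau)
    table = frequency_solutions(net, null_model(net), config)
    return AnalysisResult(fit, aligned, rv, net, table)


def _rand(a: Partition, b: Partition) -> float:
    return float(adjusted_rand_score(a.membership(), b.membership()))


@dataclass(frozen=True)
class SweepReport:
    """Per-threshold solutions and pairwise agreement of the top architectures."""

    taus: tuple[Optional[float], ...]
    tables: tuple[SolutionFrequencyTable, ...]
    agreement: np.ndarray  # (L, L) bool, exact top-partition equality
    rand_index: np.ndarray  # (L, L) adjusted Rand of the top partitions

    @property
    def top_partitions(self) -> tuple[Partition, ...]:
        return tuple(t.top.partition for t in self.tables)

    @property
    def all_agree(self) -> bool:
        return bool(np.all(self.agreement))


def threshold_sweep(
    rv: RvMatrix,
    taus: Sequence[Optional[float]],
    config: AnnealConfig,
) -> SweepReport:
    """Extract modules at each threshold level and compare top solutions.

    Every level reuses the same annealing configuration (and master seed),
    so a single-level sweep reproduces a direct ``frequency_solutions``
    run exactly.
    """
    taus = tuple(taus)
    if not taus:
        raise StructureError("threshold sweep needs at least one level")
    tables = []
    for tau in taus:
        net = threshold_network(rv, tau)
        tables.append(frequency_solutions(net, null_model(net), config))
    tops = [t.top.partition for t in tables]
    n = len(taus)
    agree = np.ones((n, n), dtype=bool)
    rand = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            agree[i, j] = agree[j, i] = tops[i] == tops[j]
            rand[i, j] = rand[j, i] = _rand(tops[i], tops[j])
    return SweepReport(taus, tuple(tables), agree, rand)


@dataclass(frozen=True)
class StabilityReport:
    """Leave-one-out stability of the top modular architecture.

    ``agreement_fraction`` is the share of n-1 subsets whose most frequent
    partition equals the full-sample one; ``stable`` flags whether that
    share reaches 0.9 (a diagnostic convention, documented, not a test of
    significance).
    """

    specimen_ids: tuple[str, ...]
    full_top: Partition
    full_top_frequency: float
    loo_tops: tuple[Partition, ...]
    loo_top_frequencies: tuple[float, ...]
    agreement: tuple[bool, ...]
    rand_index: tuple[float, ...]

    @property
    def agreement_fraction(self) -> float:
        return sum(self.agreement) / len(self.agreement)

    @property
    def stable(self) -> bool:
        return self.agreement_fraction >= 0.9


def leave_one_out(
    dataset: Dataset,
    tau: Optional[float],
    config: AnnealConfig,
    use: str = "specimen_means",
) -> StabilityReport:
    """Re-run the full pipeline on every n-1 subset and compare top partitions.

    All subsets (every specimen omitted once, not just a few) reuse the
    same master seed, so each run is reproducible in isolation.
    """
    specs = dataset.specimen_ids
    if len(specs) < 4:
        raise StructureError("leave-one-out needs at least 4 specimens")
    full = analyze(dataset, tau, config, use)
    tops = []
    freqs = []
    agree = []
    rand = []
    for s in specs:
        sub = analyze(dataset.without_specimen(s), tau, config, use)
        top = sub.top_partition
        tops.append(top)
        freqs.append(sub.table.top.frequency)
        agree.append(top == full.top_partition)
        rand.append(_rand(top, full.top_partition))
    return StabilityReport(
        specimen_ids=specs,
        full_top=full.top_partition,
        full_top_frequency=full.table.top.frequency,
        loo_tops=tuple(tops),
        loo_top_frequencies=tuple(freqs),
        agreement=tuple(agree),
        rand_index=tuple(rand),
    )
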