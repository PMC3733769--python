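"""Spin-glass module extraction on weighted correlation networks.

Modules are found by minimizing the Potts spin-glass energy

    H({sigma}) = - sum_{i<j} (W_ij - gamma * p) delta(sigma_i, sigma_j)

where W is the (thresholded) weighted adjacency matrix, p the expected
pair weight under a weighted Erdos-Renyi null model that preserves the
network's total edge weight, and sigma_i in {1..q} the module index of
node i, with q equal to the node count so the number of modules is free.
The sum runs over unordered pairs; a sum over ordered pairs differs only
by a global factor of two and has the same minimizers.

Because the energy landscape of a spin glass typically has several states
near the minimum, simulated annealing is run many times from random
initial spin assignments; the distinct partitions found are tallied with
their occurrence frequencies, which quantify the ambiguity of the modular
architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._anneal import _anneal_kernel
from .errors import McnetError, StructureError
from .rv import CorrelationNetwork

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class Partition:
    """A module assignment in canonical form.

    The canonical form lists modules as tuples of node labels: members are
    ordered by their position in the network's node order, and modules are
    ordered by their smallest member's position.  Two assignments that
    differ only by a permutation of module indices share one canonical
    form.
    """

    modules: tuple[tuple[str, ...], ...]
    node_order: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "modules", tuple(tuple(m) for m in self.modules)
        )
        object.__setattr__(self, "node_order", tuple(self.node_order))
        seen = [l for m in self.modules for l in m]
        if sorted(seen) != sorted(self.node_order):
            raise StructureError(
                "partition must cover every node exactly once"
            )

    @classmethod
    def from_assignment(
        cls, assignment: Mapping[str, int], node_order: Sequence[str]
    ) -> "Partition":
        node_order = tuple(node_order)
        missing = [l for l in node_order if l not in assignment]
        if missing:
            raise StructureError(f"nodes missing from partition: {missing}")
        pos = {l: i for i, l in enumerate(node_order)}
        groups: dict[int, list[str]] = {}
        for label in node_order:
            groups.setdefault(assignment[label], []).append(label)
        modules = sorted(
            (tuple(sorted(g, key=pos.__getitem__)) for g in groups.values()),
            key=lambda m: pos[m[0]],
        )
        return cls(tuple(modules), node_order)

    @classmethod
    def from_labels(
        cls, spins: Sequence[int], node_order: Sequence[str]
    ) -> "Partition":
        return cls.from_assignment(
            dict(zip(node_order, spins)), node_order
        )

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def assignment(self) -> dict[str, int]:
        return {l: i for i, mod in enumerate(self.modules) for l in mod}

    def membership(self) -> np.ndarray:
        """Module index per node, in node order (for Rand-index comparisons)."""
        a = self.assignment()
        return np.array([a[l] for l in self.node_order])

    def contains_module(self, nodeset: Iterable[str]) -> bool:
        target = frozenset(nodeset)
        return any(frozenset(m) == target for m in self.modules)

    def as_lists(self) -> list[list[str]]:
        return [list(m) for m in self.modules]


@dataclass(frozen=True)
class NullModel:
    """Weighted Erdos-Renyi null: every pair carries the same expected weight p.

    p is the observed total edge weight divided by the number of node
    pairs, so the null preserves the network's total weight — the natural
    weighted extension of a random graph "with the same number of edges".
    """

    p: float
    kind: str = "erdos_renyi_weighted"

    def __post_init__(self) -> None:
        if self.p < 0.0:
            raise ValueError("null expected weight p must be >= 0")


def null_model(net: CorrelationNetwork) -> NullModel:
    """Fit the weighted ER null to a network."""
    k = net.k
    if k < 2:
        raise StructureError("null model needs at least 2 nodes")
    n_pairs = k * (k - 1) / 2
    return NullModel(p=net.total_weight / n_pairs)


def _coupling_matrix(
    net: CorrelationNetwork, null: NullModel, gamma: float
) -> np.ndarray:
    b = net.weights - gamma * null.p
    np.fill_diagonal(b, 0.0)
    return np.ascontiguousarray(b)


def rb_energy(
    part: Partition,
    net: CorrelationNetwork,
    null: NullModel,
    gamma: float = 1.0,
) -> float:
    """Spin-glass energy of a partition: -sum over same-module pairs of (W_ij - gamma p)."""
    if sorted(part.node_order) != sorted(net.labels) or sorted(
        l for m in part.modules for l in m
    ) != sorted(net.labels):
        raise StructureError("partition does not cover the network's nodes")
    b = _coupling_matrix(net, null, gamma)
    idx = {l: i for i, l in enumerate(net.labels)}
    energy = 0.0
    for mod in part.modules:
        ids = [idx[l] for l in mod]
        for a in range(len(ids)):
            for c in range(a + 1, len(ids)):
                energy -= b[ids[a], ids[c]]
    return float(energy)


def _partitions_rgs(k: int):
    """Yield all set partitions of range(k) as restricted-growth strings."""
    a = [0] * k
    b = [1] * k  # b[i] = 1 + max(a[:i])
    while True:
        yield a
        j = k - 1
        while j > 0 and a[j] == b[j]:
            j -= 1
        if j == 0:
            return
        a[j] += 1
        m = b[j] + (1 if a[j] == b[j] else 0)
        for i in range(j + 1, k):
            a[i] = 0
            b[i] = m


def brute_force_min(
    net: CorrelationNetwork,
    null: NullModel,
    gamma: float = 1.0,
    *,
    max_nodes: int = 12,
    tie_tol: float = 1e-12,
) -> tuple[list[Partition], float]:
    """Exhaustively enumerate all set partitions; return the minimizers and energy.

    Intended as an independent oracle on small networks; refuses more than
    ``max_nodes`` nodes (the Bell number explodes).  All partitions within
    ``tie_tol`` of the minimum energy are returned.
    """
    k = net.k
    if k > max_nodes:
        raise StructureError(
            f"exhaustive enumeration limited to {max_nodes} nodes, got {k}"
        )
    b = _coupling_matrix(net, null, gamma)
    pairs = [(i, j, b[i, j]) for i in range(k) for j in range(i + 1, k)]
    best_energy = np.inf
    best: list[tuple[int, ...]] = []
    for rgs in _partitions_rgs(k) if k > 0 else iter(()):
        e = 0.0
        for i, j, w in pairs:
            if rgs[i] == rgs[j]:
                e -= w
        if e < best_energy - tie_tol:
            best_energy = e
            best = [tuple(rgs)]
        elif e <= best_energy + tie_tol:
            best.append(tuple(rgs))
    parts = [Partition.from_labels(rgs, net.labels) for rgs in best]
    return parts, float(best_energy)


@dataclass(frozen=True)
class AnnealConfig:
    """Simulated-annealing schedule and trial plan.

    ``initial_temperature=None`` auto-calibrates T0 per trial so uphill
    moves from the random start are accepted with probability ~0.9;
    cooling is geometric; each temperature stage performs
    ``sweeps_per_temperature`` sweeps of k single-spin Metropolis updates;
    annealing stops at ``min_temperature`` or after ``patience``
    consecutive stages without improving the best energy seen.  The best
    state visited (not the final one) is returned.
    """

    trials: int = 100
    initial_temperature: Optional[float] = None
    cooling_factor: float = 0.99
    sweeps_per_temperature: int = 50
    min_temperature: float = 1e-3
    patience: int = 200
    gamma: float = 1.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling_factor must lie in (0, 1)")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.gamma <= 0.0:
            raise ValueError("gamma must be > 0")
        if self.sweeps_per_temperature < 1:
            raise ValueError("sweeps_per_temperature must be >= 1")
        if self.min_temperature <= 0.0:
            raise ValueError("min_temperature must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    def trial_seeds(self) -> np.ndarray:
        """Per-trial seeds spawned deterministically from the master seed."""
        ss = np.random.SeedSequence(self.master_seed)
        return ss.generate_state(self.trials, dtype=np.uint32)


@dataclass(frozen=True)
class AnnealResult:
    partition: Partition
    energy: float
    initial_energy: float
    degenerate: bool  # all couplings ~0: every partition has the same energy


def anneal(
    net: CorrelationNetwork,
    null: NullModel,
    config: AnnealConfig,
    trial_seed: int,
) -> AnnealResult:
    """One annealing trial from a seed-determined random spin assignment.

    q equals the node count, so up to k modules are allowed; empty spin
    states are dropped on canonicalization.  Deterministic given
    ``(config, trial_seed)``.
    """
    k = net.k
    if k < 2:
        raise StructureError("annealing needs at least 2 nodes")
    b = _coupling_matrix(net, null, config.gamma)
    degenerate = bool(np.max(np.abs(b)) < _DEGENERATE_TOL)
    if degenerate:
        # every partition has the same energy; resolve to the canonical
        # all-singleton representative (isolated nodes stay singletons)
        part = Partition.from_labels(list(range(k)), net.labels)
        return AnnealResult(part, 0.0, 0.0, True)
    t0 = config.initial_temperature
    sigma, energy, e0, _ = _anneal_kernel(
        b,
        int(trial_seed) & 0xFFFFFFFF,
        -1.0 if t0 is None else float(t0),
        config.cooling_factor,
        config.sweeps_per_temperature,
        config.min_temperature,
        config.patience,
    )
    part = Partition.from_labels([int(s) for s in sigma], net.labels)
    return AnnealResult(
        partition=part,
        energy=float(energy),
        initial_energy=float(e0),
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class SolutionEntry:
    partition: Partition
    count: int
    frequency: float
    mean_energy: float


@dataclass(frozen=True)
class SolutionFrequencyTable:
    """Canonical partitions found over repeated annealing trials.

    Entries are sorted by descending frequency (canonical form as a
    deterministic tie-break); counts sum to the number of trials.
    Multiplicity of solutions is the landscape's own signal of ambiguity
    in the modular architecture.
    """

    entries: tuple[SolutionEntry, ...]
    trials: int

    def __post_init__(self) -> None:
        if sum(e.count for e in self.entries) != self.trials:
            raise StructureError("entry counts must sum to the trial count")

    @property
    def top(self) -> SolutionEntry:
        return self.entries[0]

    def module_reproducibility(self, nodeset: Iterable[str]) -> float:
        return module_reproducibility(self, nodeset)


def frequency_solutions(
    net: CorrelationNetwork,
    null: NullModel,
    config: AnnealConfig,
) -> SolutionFrequencyTable:
    """Run ``config.trials`` independent annealing trials and tally partitions."""
    seeds = config.trial_seeds()
    counts: dict[Partition, int] = {}
    energy_sums: dict[Partition, float] = {}
    for s in seeds:
        res = anneal(net, null, config, int(s))
        counts[res.partition] = counts.get(res.partition, 0) + 1
        energy_sums[res.partition] = energy_sums.get(res.partition, 0.0) + res.energy
    entries = [
        SolutionEntry(
            partition=p,
            count=c,
            frequency=c / config.trials,
            mean_energy=energy_sums[p] / c,
        )
        for p, c in counts.items()
    ]
    entries.sort(key=lambda e: (-e.count, e.partition.modules))
    return SolutionFrequencyTable(tuple(entries), config.trials)


def module_reproducibility(
    table: SolutionFrequencyTable, nodeset: Iterable[str]
) -> float:
    """Fraction of trials whose partition contains ``nodeset`` exactly as a module."""
    nodes = frozenset(nodeset)
    if not nodes:
        raise StructureError("nodeset must be non-empty")
    known = set(table.entries[0].partition.node_order) if table.entries else set()
    unknown = nodes - known
    if unknown:
        raise StructureError(f"unknown node label(s): {sorted(unknown)}")
    hits = sum(e.count for e in table.entries if e.partition.contains_module(nodes))
    return hits / table.trials
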