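"""Core containers for digitized landmark data.

A specimen is digitized as a *configuration*: an ordered list of 2-D
landmarks, each tagged either as a ``reference`` landmark (stable anatomy,
e.g. a wing-vein junction, used to estimate the superimposition) or as a
``measurement`` point (a pattern/vein intersection whose variation is the
object of study).  A :class:`Dataset` collects the configurations of one
species, possibly with several digitization replicates per specimen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import StructureError

ROLE_REFERENCE = "reference"
ROLE_MEASUREMENT = "measurement"
VALID_ROLES = frozenset({ROLE_REFERENCE, ROLE_MEASUREMENT})


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One digitization of one specimen: labeled, role-tagged 2-D landmarks.

    Parameters
    ----------
    specimen_id
        Identifier of the biological individual.
    replicate_id
        Digitization replicate number, ``>= 1``.
    coords
        ``(k, 2)`` array of pixel coordinates, in landmark order.
    roles
        Per-landmark tag, ``"reference"`` or ``"measurement"``.
    labels
        Per-landmark name (e.g. ``"MP1"``); unique within a configuration.
    """

    specimen_id: str
    replicate_id: int
    coords: np.ndarray
    roles: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise StructureError(
                f"coords must be (k, 2), got {coords.shape} "
                f"for specimen {self.specimen_id!r}"
            )
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "roles", tuple(self.roles))
        object.__setattr__(self, "labels", tuple(self.labels))
        k = coords.shape[0]
        if len(self.roles) != k or len(self.labels) != k:
            raise StructureError(
                f"coords ({k}), roles ({len(self.roles)}) and labels "
                f"({len(self.labels)}) must have equal length"
            )
        if not np.all(np.isfinite(coords)):
            raise StructureError(
                f"non-finite coordinate in specimen {self.specimen_id!r}"
            )
        bad = set(self.roles) - VALID_ROLES
        if bad:
            raise StructureError(f"unknown landmark role(s): {sorted(bad)}")
        if len(set(self.labels)) != k:
            raise StructureError(
                f"duplicate landmark labels in specimen {self.specimen_id!r}"
            )
        if int(self.replicate_id) < 1:
            raise StructureError("replicate_id must be >= 1")
        object.__setattr__(self, "replicate_id", int(self.replicate_id))
        if sum(r == ROLE_REFERENCE for r in self.roles) < 3:
            raise StructureError(
                "at least 3 reference landmarks are required for a rigid fit"
            )

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def reference_mask(self) -> np.ndarray:
        return np.array([r == ROLE_REFERENCE for r in self.roles])

    @property
    def reference_coords(self) -> np.ndarray:
        return self.coords[self.reference_mask]

    @property
    def measurement_coords(self) -> np.ndarray:
        return self.coords[~self.reference_mask]

    @property
    def reference_labels(self) -> tuple[str, ...]:
        return tuple(l for l, r in zip(self.labels, self.roles) if r == ROLE_REFERENCE)

    @property
    def measurement_labels(self) -> tuple[str, ...]:
        return tuple(l for l, r in zip(self.labels, self.roles) if r == ROLE_MEASUREMENT)


@dataclass(frozen=True)
class Dataset:
    """All configurations of one species, with a shared landmark scheme."""

    configurations: tuple[LandmarkConfiguration, ...]
    species_label: str = ""

    def __post_init__(self) -> None:
        configs = tuple(self.configurations)
        object.__setattr__(self, "configurations", configs)
        if not configs:
            raise StructureError("dataset must contain at least one configuration")
        ref = configs[0]
        seen: set[tuple[str, int]] = set()
        for cfg in configs:
            if cfg.labels != ref.labels or cfg.roles != ref.roles:
                raise StructureError(
                    f"configuration {cfg.specimen_id!r}/{cfg.replicate_id} has a "
                    "different label/role sequence than the first configuration"
                )
            key = (cfg.specimen_id, cfg.replicate_id)
            if key in seen:
                raise StructureError(f"duplicate (specimen, replicate) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.configurations[0].labels

    @property
    def roles(self) -> tuple[str, ...]:
        return self.configurations[0].roles

    @property
    def measurement_labels(self) -> tuple[str, ...]:
        return self.configurations[0].measurement_labels

    @property
    def reference_labels(self) -> tuple[str, ...]:
        return self.configurations[0].reference_labels

    @property
    def specimen_ids(self) -> tuple[str, ...]:
        """Unique specimen ids in first-appearance order."""
        out: list[str] = []
        for cfg in self.configurations:
            if cfg.specimen_id not in out:
                out.append(cfg.specimen_id)
        return tuple(out)

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    def replicate_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cfg in self.configurations:
            counts[cfg.specimen_id] = counts.get(cfg.specimen_id, 0) + 1
        return counts

    def without_specimen(self, specimen_id: str) -> "Dataset":
        """Dataset with every configuration of ``specimen_id`` removed."""
        if specimen_id not in self.specimen_ids:
            raise StructureError(f"unknown specimen {specimen_id!r}")
        kept = tuple(c for c in self.configurations if c.specimen_id != specimen_id)
        return Dataset(kept, self.species_label)

    def with_configurations(
        self, extra: Sequence[LandmarkConfiguration]
    ) -> "Dataset":
        return Dataset(tuple(self.configurations) + tuple(extra), self.species_label)
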