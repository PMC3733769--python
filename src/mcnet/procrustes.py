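"""Generalized Procrustes superimposition with reference-landmark transfer.

The superimposition is estimated on the *reference* landmarks only
(stable anatomy), in three steps per configuration — scaling to unit
centroid size, translation of the centroid to the origin, and least-squares
rotation to the running consensus — iterated with consensus re-estimation
until convergence.  The fitted per-configuration similarity transform is
then *transferred* to the measurement points, which take no part in
estimating the fit.  This two-step procedure avoids the spurious covariance
that a joint fit would induce among the measurement points.

Digitization precision is certified with a Procrustes ANOVA: the summed
squared deviations of the aligned measurement coordinates are decomposed
into a between-specimen (individual) and a within-specimen between-replicate
(error) component, compared with an F ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset, ROLE_REFERENCE
from .errors import (
    ConvergenceError,
    DegenerateConfigurationError,
    DesignError,
    MismatchError,
    StructureError,
)

_DEGENERACY_TOL = 1e-12


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared distances of landmarks to their centroid.

    This is the scale measure removed by the superimposition; it scales
    linearly under uniform scaling of the configuration.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise StructureError("centroid size needs a (k>=2, d) coordinate array")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs < _DEGENERACY_TOL:
        raise DegenerateConfigurationError(
            "all landmarks coincident; centroid size is zero"
        )
    return cs


def _principal_axis_gauge(shape: np.ndarray) -> np.ndarray:
    """Rotation (det +1) aligning a centered shape's principal axes with x/y.

    The remaining 180-degree ambiguity is resolved by requiring the first
    landmark with a non-negligible first-axis coordinate to lie on the
    positive side.
    """
    cov = shape.T @ shape
    _, vecs = np.linalg.eigh(cov)
    r = vecs[:, ::-1]  # major axis first
    if np.linalg.det(r) < 0:
        r[:, 1] *= -1.0
    proj = shape @ r
    for x, _ in proj:
        if abs(x) > 1e-8:
            if x < 0:
                r = -r  # 180-degree turn keeps det +1 in 2-D
            break
    return r


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, no reflection) minimizing ||x @ R - target||_F."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


@dataclass(frozen=True)
class ProcrustesFit:
    """Similarity transforms fitted on reference landmarks.

    ``aligned_reference[i] = (X_i - centroid_i) / centroid_size_i @ rotation_i``
    where ``X_i`` are the raw reference coordinates of configuration *i*.
    """

    aligned_reference: np.ndarray  # (m, k_ref, 2)
    consensus: np.ndarray  # (k_ref, 2), unit centroid size
    centroids: np.ndarray  # (m, 2)
    centroid_sizes: np.ndarray  # (m,)
    rotations: np.ndarray  # (m, 2, 2), det +1
    specimen_ids: tuple[str, ...]
    replicate_ids: tuple[int, ...]
    reference_labels: tuple[str, ...]
    n_iterations: int
    residual_history: tuple[float, ...]  # summed squared distances to consensus

    def transform_index(self) -> dict[tuple[str, int], int]:
        return {
            key: i
            for i, key in enumerate(zip(self.specimen_ids, self.replicate_ids))
        }


@dataclass(frozen=True)
class AlignedDataset:
    """Measurement-point coordinates in Procrustes units, one row per digitization."""

    coords: np.ndarray  # (m, k, 2)
    labels: tuple[str, ...]
    specimen_ids: tuple[str, ...]
    replicate_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "specimen_ids", tuple(self.specimen_ids))
        object.__setattr__(self, "replicate_ids", tuple(int(r) for r in self.replicate_ids))
        m = coords.shape[0]
        if coords.ndim != 3 or coords.shape[2] != 2:
            raise StructureError("aligned coords must be (m, k, 2)")
        if coords.shape[1] != len(self.labels):
            raise StructureError("label count does not match coordinate columns")
        if len(self.specimen_ids) != m or len(self.replicate_ids) != m:
            raise StructureError("id lists must match the number of rows")
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite aligned coordinate")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def unique_specimens(self) -> tuple[str, ...]:
        out: list[str] = []
        for s in self.specimen_ids:
            if s not in out:
                out.append(s)
        return tuple(out)

    def specimen_means(self) -> "AlignedDataset":
        """Average replicates within each specimen (replicate id set to 1)."""
        specs = self.unique_specimens()
        sid = np.asarray(self.specimen_ids)
        mean_coords = np.stack(
            [self.coords[sid == s].mean(axis=0) for s in specs]
        )
        return AlignedDataset(mean_coords, self.labels, specs, (1,) * len(specs))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, (s, r) in enumerate(zip(self.specimen_ids, self.replicate_ids)):
            for j, lab in enumerate(self.labels):
                rows.append(
                    {
                        "specimen": s,
                        "replicate": r,
                        "label": lab,
                        "x": self.coords[i, j, 0],
                        "y": self.coords[i, j, 1],
                    }
                )
        return pd.DataFrame(rows)


def gpa(
    dataset: Dataset,
    role: str = ROLE_REFERENCE,
    *,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> ProcrustesFit:
    """Iterative least-squares generalized Procrustes fit on the tagged landmarks.

    Each configuration is scaled to unit centroid size, centered at the
    origin, and rotated (rotations only, det +1 — specimens are same-side
    structures, so reflections are anatomically meaningless) to minimize the
    summed squared distance to the consensus; the consensus is re-estimated
    and rescaled to unit centroid size each iteration, until the change in
    the summed squared Procrustes distance falls below ``tol``.
    """
    if role != ROLE_REFERENCE:
        raise StructureError("gpa fits on reference landmarks only")
    configs = dataset.configurations
    if len(configs) < 2:
        raise StructureError("gpa needs at least 2 configurations")

    raw = np.stack([c.reference_coords for c in configs])  # (m, k, 2)
    centroids = raw.mean(axis=1)
    centered = raw - centroids[:, None, :]
    sizes = np.sqrt(np.sum(centered**2, axis=(1, 2)))
    if np.any(sizes < _DEGENERACY_TOL):
        raise DegenerateConfigurationError("degenerate reference configuration")
    scaled = centered / sizes[:, None, None]

    m = scaled.shape[0]
    rotations = np.tile(np.eye(2), (m, 1, 1))
    consensus = scaled[0].copy()
    consensus /= np.sqrt(np.sum(consensus**2))

    history: list[float] = []
    prev = np.inf
    for it in range(1, max_iter + 1):
        aligned = np.empty_like(scaled)
        for i in range(m):
            rotations[i] = _optimal_rotation(scaled[i], consensus)
            aligned[i] = scaled[i] @ rotations[i]
        resid = float(np.sum((aligned - consensus[None]) ** 2))
        history.append(resid)
        consensus = aligned.mean(axis=0)
        consensus -= consensus.mean(axis=0)
        cs = np.sqrt(np.sum(consensus**2))
        if cs < _DEGENERACY_TOL:
            raise DegenerateConfigurationError("consensus collapsed to a point")
        consensus /= cs
        if abs(prev - resid) < tol:
            break
        prev = resid
    else:
        raise ConvergenceError(
            f"generalized Procrustes fit did not converge in {max_iter} "
            f"iterations (residual {resid:.3e})"
        )

    # Gauge fix: the converged consensus is defined only up to a global
    # rotation (seeded by the first configuration's pose).  Rotating the
    # consensus onto its principal axes makes the output invariant to
    # per-configuration similarity pre-transforms and to specimen order.
    consensus = consensus @ _principal_axis_gauge(consensus)
    aligned = np.empty_like(scaled)
    for i in range(m):
        rotations[i] = _optimal_rotation(scaled[i], consensus)
        aligned[i] = scaled[i] @ rotations[i]

    return ProcrustesFit(
        aligned_reference=aligned,
        consensus=consensus,
        centroids=centroids,
        centroid_sizes=sizes,
        rotations=rotations,
        specimen_ids=tuple(c.specimen_id for c in configs),
        replicate_ids=tuple(c.replicate_id for c in configs),
        reference_labels=configs[0].reference_labels,
        n_iterations=it,
        residual_history=tuple(history),
    )


def transfer(fit: ProcrustesFit, dataset: Dataset) -> AlignedDataset:
    """Apply each configuration's reference-fit transform to its measurement points.

    The measurement points are scaled, translated and rotated with exactly
    the parameters estimated from the reference landmarks; they are never
    refit.
    """
    index = fit.transform_index()
    coords = []
    spec_ids = []
    rep_ids = []
    for cfg in dataset.configurations:
        key = (cfg.specimen_id, cfg.replicate_id)
        if key not in index:
            raise MismatchError(f"configuration {key} absent from the Procrustes fit")
        i = index[key]
        mp = cfg.measurement_coords
        coords.append(
            (mp - fit.centroids[i]) / fit.centroid_sizes[i] @ fit.rotations[i]
        )
        spec_ids.append(cfg.specimen_id)
        rep_ids.append(cfg.replicate_id)
    return AlignedDataset(
        np.stack(coords),
        dataset.measurement_labels,
        tuple(spec_ids),
        tuple(rep_ids),
    )


@dataclass(frozen=True)
class ProcrustesAnovaTable:
    """Individual-vs-digitization-error decomposition of aligned shape variation.

    Degrees of freedom use the similarity shape-space dimensionality
    ``d = 2k - 4`` for ``k`` 2-D landmarks; ``d`` is recorded so alternative
    conventions remain auditable.
    """

    ss_individual: float
    ss_error: float
    df_individual: int
    df_error: int
    n_specimens: int
    n_replicates: int
    shape_dim: int  # d = 2k - 4

    @property
    def ss_total(self) -> float:
        return self.ss_individual + self.ss_error

    @property
    def ms_individual(self) -> float:
        return self.ss_individual / self.df_individual

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error

    @property
    def f_ratio(self) -> float:
        if self.ms_error == 0.0:
            return float("inf")
        return self.ms_individual / self.ms_error

    @property
    def zero_error(self) -> bool:
        """True when replicates are identical (SS_error exactly 0)."""
        return self.ms_error == 0.0

    @property
    def p_value(self) -> float:
        if self.zero_error:
            return 0.0
        return float(stats.f.sf(self.f_ratio, self.df_individual, self.df_error))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": "individual",
                    "SS": self.ss_individual,
                    "df": self.df_individual,
                    "MS": self.ms_individual,
                    "F": self.f_ratio,
                    "p": self.p_value,
                },
                {
                    "effect": "error",
                    "SS": self.ss_error,
                    "df": self.df_error,
                    "MS": self.ms_error,
                    "F": np.nan,
                    "p": np.nan,
                },
            ]
        )


def procrustes_anova(aligned: AlignedDataset) -> ProcrustesAnovaTable:
    """Decompose aligned coordinates into individual and digitization-error terms.

    Requires a balanced design: every specimen digitized the same number
    ``r >= 2`` of times, with ``n >= 2`` specimens.  Sums of squares are
    summed over all landmarks and both coordinates; by construction
    ``SS_total = SS_individual + SS_error``.
    """
    specs = aligned.unique_specimens()
    n = len(specs)
    sid = np.asarray(aligned.specimen_ids)
    counts = {s: int(np.sum(sid == s)) for s in specs}
    r = counts[specs[0]]
    if any(c != r for c in counts.values()):
        raise DesignError(f"unbalanced replicate design: {counts}")
    if r < 2:
        raise DesignError("Procrustes ANOVA needs >= 2 replicates per specimen")
    if n < 2:
        raise DesignError("Procrustes ANOVA needs >= 2 specimens")

    grand = aligned.coords.mean(axis=0)
    means = np.stack([aligned.coords[sid == s].mean(axis=0) for s in specs])
    ss_ind = float(r * np.sum((means - grand[None]) ** 2))
    ss_err = 0.0
    for i, s in enumerate(specs):
        ss_err += float(np.sum((aligned.coords[sid == s] - means[i][None]) ** 2))

    k = aligned.n_landmarks
    d = 2 * k - 4
    if d <= 0:
        raise DesignError("too few landmarks for the similarity shape space")
    return ProcrustesAnovaTable(
        ss_individual=ss_ind,
        ss_error=ss_err,
        df_individual=(n - 1) * d,
        df_error=n * (r - 1) * d,
        n_specimens=n,
        n_replicates=r,
        shape_dim=d,
    )
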