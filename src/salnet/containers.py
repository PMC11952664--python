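"""Shared in-memory containers for surface BOLD data, atlases, and network maps.

Vertex indexing is 0-based everywhere in memory; on-disk tables are written
1-based with hemisphere labels (see :mod:`salnet.io`). Network labels are
1-based (1..K) to match the convention of surface parcellation atlases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtlasSpec",
    "BoldRun",
    "EngagementMap",
    "PriorMaps",
    "PosteriorMap",
    "MembershipMask",
    "NetworkMetrics",
]


@dataclass(frozen=True)
class AtlasSpec:
    """A K-network hard parcellation of a V-vertex cortical surface.

    Parameters
    ----------
    labels
        Integer array of shape (V,) with entries in 1..K assigning every
        vertex to exactly one network.
    salience_index
        Which network (1-based) plays the role of the salience /
        ventral-attention network whose expansion and connectivity the
        pipeline summarizes. In the 17-network ordering this is network 8
        (Salience/Ventral Attention B).
    """

    labels: np.ndarray
    K: int
    salience_index: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D vertex vector")
        if self.K < 1:
            raise ValueError("K must be positive")
        if labels.min(initial=1) < 1 or labels.max(initial=1) > self.K:
            raise ValueError("labels must lie in 1..K")
        if not (1 <= self.salience_index <= self.K):
            raise ValueError(
                f"salience_index {self.salience_index} outside 1..{self.K}"
            )

    @property
    def V(self) -> int:
        return self.labels.shape[0]

    def vertices_in(self, network: int) -> np.ndarray:
        """0-based vertex indices belonging to ``network`` (1-based)."""
        return np.flatnonzero(self.labels == network)


@dataclass
class BoldRun:
    """A vertices x timepoints BOLD matrix with its repetition time.

    ``data`` has shape (V, T); ``tr`` is in seconds.
    """

    data: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("BOLD data must be a 2-D (V, T) matrix")
        if self.data.shape[1] < 2:
            raise ValueError("BOLD run needs at least 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data must be finite")
        if self.tr <= 0:
            raise ValueError("TR must be positive (seconds)")

    @property
    def V(self) -> int:
        return self.data.shape[0]

    @property
    def T(self) -> int:
        return self.data.shape[1]


@dataclass
class EngagementMap:
    """Per-vertex, per-network continuous engagement estimates.

    ``values`` and ``sampling_var`` are (V, K); ``sampling_var`` holds the
    vertex-wise OLS sampling variance of each estimate (``inf`` where a
    network was dropped from the regression).
    """

    values: np.ndarray
    sampling_var: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.sampling_var = np.asarray(self.sampling_var, dtype=np.float64)
        if self.values.shape != self.sampling_var.shape:
            raise ValueError("values and sampling_var shapes differ")
        if self.values.ndim != 2:
            raise ValueError("engagement maps are 2-D (V, K)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("engagement values must be finite")
        if np.any(self.sampling_var < 0):
            raise ValueError("sampling variances must be nonnegative")


@dataclass
class PriorMaps:
    """Population prior: mean and between-subject variance per (vertex, network)."""

    mean: np.ndarray
    between_var: np.ndarray
    n_sessions_used: int
    floor_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.between_var = np.asarray(self.between_var, dtype=np.float64)
        if self.mean.shape != self.between_var.shape:
            raise ValueError("mean and between_var shapes differ")
        if np.any(self.between_var < 0):
            raise ValueError("between_var must be nonnegative (floored)")


@dataclass
class PosteriorMap:
    """Posterior engagement mean and standard error after empirical-Bayes shrinkage."""

    mean: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.se = np.asarray(self.se, dtype=np.float64)
        if self.mean.shape != self.se.shape:
            raise ValueError("mean and se shapes differ")
        if np.any(self.se[np.isfinite(self.se)] <= 0):
            raise ValueError("posterior se must be positive where finite")


@dataclass
class MembershipMask:
    """Boolean salience-membership vector from the vertex-wise hypothesis test."""

    mask: np.ndarray
    alpha: float
    n_tests: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_members(self) -> int:
        return int(self.mask.sum())


@dataclass
class NetworkMetrics:
    """Per-subject salience-network summary metrics.

    ``expansion`` is the fraction of all vertices classified as significant
    members (in [0, 1]); ``connectivity`` is the mean pairwise Pearson
    correlation among member vertices (in [-1, 1], NaN when undefined);
    ``valid`` is False for subjects excluded by the low-variance guard.
    """

    expansion: float
    connectivity: float = field(default=np.nan)
    valid: bool = True
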