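"""Core in-memory containers for paired hemisphere maps and derived maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class HemiPair:
    """Paired left/right vertex-wise signal maps for one subject and epoch.

    Parameters
    ----------
    left, right
        Vertex vectors of first-level contrast estimates (arbitrary signal
        units), one value per vertex on the symmetric mesh.  Vertex ``v`` of
        ``left`` and vertex ``v`` of ``right`` are mirrored anatomical
        homologues.
    coords_left, coords_right
        Optional per-vertex 3-D Cartesian coordinates, shape ``(n, 3)``.
        Used only by the interhemispheric correspondence check.
    subject_id, epoch
        Provenance metadata carried through to derived maps.
    """

    left: np.ndarray
    right: np.ndarray
    coords_left: np.ndarray | None = None
    coords_right: np.ndarray | None = None
    subject_id: str | None = None
    epoch: str | None = None

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.ndim != 1 or self.right.ndim != 1:
            raise ValueError("hemisphere maps must be 1-D vertex vectors")
        if self.left.shape != self.right.shape:
            raise ValueError(
                f"hemisphere vertex counts differ: left has {self.left.size}, "
                f"right has {self.right.size}"
            )
        for name in ("coords_left", "coords_right"):
            c = getattr(self, name)
            if c is not None:
                c = np.asarray(c, dtype=float)
                if c.shape != (self.left.size, 3):
                    raise ValueError(
                        f"{name} must have shape ({self.left.size}, 3), got {c.shape}"
                    )
                setattr(self, name, c)

    @property
    def n_vertices(self) -> int:
        return self.left.size


@dataclass
class VertexMap:
    """A single vertex vector with subject/epoch provenance."""

    values: np.ndarray
    subject_id: str | None = None
    epoch: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_vertices(self) -> int:
        return self.values.size


@dataclass
class AsymmetryMap(VertexMap):
    """Vertex-wise laterality index Δ = (L − R)/(|L| + |R|), in [−1, 1].

    Positive values indicate leftward lateralization.  ``n_degenerate``
    counts vertices where the bilateral amplitude fell below the epsilon
    threshold and Δ was defined as 0.
    """

    n_degenerate: int = 0


@dataclass
class AmplitudeMap(VertexMap):
    """Vertex-wise mean bilateral amplitude A = (|L| + |R|)/2, ≥ 0."""


@dataclass
class CorrespondenceReport:
    """Per-axis coordinate correlations of mirrored hemisphere vertices."""

    r_x: float
    r_y: float
    r_z: float
    threshold: float = 0.995

    @property
    def correlations(self) -> tuple[float, float, float]:
        return (self.r_x, self.r_y, self.r_z)

    @property
    def passed(self) -> bool:
        return all(r > self.threshold for r in self.correlations)
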