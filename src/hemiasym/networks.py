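"""Network-level aggregation of vertex maps and network/epoch ranking.

Vertex maps are averaged within a network partition per subject × epoch,
yielding a subjects × (network, epoch) matrix.  Networks are ranked by
the root-mean-square of their cohort-mean values across epochs; epochs by
the signed mean of cohort-mean values across networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import VertexMap


@dataclass
class NetworkEpochMatrix:
    """Subjects × (network, epoch) matrix of one measure.

    ``values`` is a DataFrame indexed by subject_id whose columns are a
    MultiIndex of (network, epoch).  ``measure`` names what the cells are:
    ``"amplitude"`` (signal units) or ``"asymmetry"`` (dimensionless).
    """

    values: pd.DataFrame
    measure: str = "amplitude"

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex):
            raise ValueError("values must have a (network, epoch) MultiIndex column axis")
        self.values.columns = self.values.columns.set_names(["network", "epoch"])

    @property
    def networks(self) -> list[str]:
        return list(self.values.columns.get_level_values("network").unique())

    @property
    def epochs(self) -> list[str]:
        return list(self.values.columns.get_level_values("epoch").unique())

    @property
    def subjects(self) -> list:
        return list(self.values.index)

    def cell(self, network: str, epoch: str) -> np.ndarray:
        """The per-subject vector of one (network, epoch) cell."""
        return self.values[(network, epoch)].to_numpy()

    def cohort_mean(self) -> pd.DataFrame:
        """Network × epoch table of cohort-mean values."""
        m = self.values.mean(axis=0)
        return m.unstack("epoch").reindex(index=self.networks, columns=self.epochs)

    def subset(self, subject_ids: Iterable) -> "NetworkEpochMatrix":
        return NetworkEpochMatrix(self.values.loc[list(subject_ids)], self.measure)

    def to_tidy(self) -> pd.DataFrame:
        """Tidy long-format view (subject, network, epoch, measure, value)."""
        long = self.values.stack(["network", "epoch"], future_stack=True).rename("value")
        out = long.reset_index()
        out.columns = ["subject", "network", "epoch", "value"]
        out.insert(3, "measure", self.measure)
        return out

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame) -> "NetworkEpochMatrix":
        measure = tidy["measure"].iloc[0]
        wide = tidy.pivot(index="subject", columns=["network", "epoch"], values="value")
        return cls(wide, measure)


def aggregate_by_network(
    maps: Sequence[VertexMap], partition: np.ndarray, measure: str = "amplitude"
) -> NetworkEpochMatrix:
    """Average each vertex map within the partition's network labels.

    ``maps`` is a collection of per-subject × epoch maps (each carrying
    ``subject_id`` and ``epoch`` metadata); every vertex must be labeled.
    """
    partition = np.asarray(partition, dtype=object)
    networks = sorted(set(partition))
    masks = {k: partition == k for k in networks}
    for k, m in masks.items():
        if not m.any():
            raise ValueError(f"network {k!r} has no vertices under this partition")
    records: dict[tuple, dict] = {}
    epochs_seen: list[str] = []
    for vmap in maps:
        if vmap.n_vertices != partition.size:
            raise ValueError(
                f"map has {vmap.n_vertices} vertices but partition labels {partition.size}"
            )
        if vmap.epoch not in epochs_seen:
            epochs_seen.append(vmap.epoch)
        row = records.setdefault(vmap.subject_id, {})
        for k in networks:
            row[(k, vmap.epoch)] = vmap.values[masks[k]].mean()
    frame = pd.DataFrame.from_dict(records, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["network", "epoch"])
    frame = frame.reindex(
        columns=pd.MultiIndex.from_product([networks, epochs_seen], names=["network", "epoch"])
    )
    frame.index.name = "subject"
    return NetworkEpochMatrix(frame, measure)


def aggregate_cohort_arrays(
    values: np.ndarray,
    partition: np.ndarray,
    subject_ids: Sequence,
    epochs: Sequence[str],
    measure: str = "amplitude",
    networks: Sequence[str] | None = None,
) -> NetworkEpochMatrix:
    """Vectorized aggregation of an (S, E, V) array within network labels.

    Equivalent to :func:`aggregate_by_network` over per-map objects, but
    operating directly on a cohort's stacked map arrays.
    """
    partition = np.asarray(partition, dtype=object)
    if networks is None:
        networks = sorted(set(partition))
    cols = {}
    for k in networks:
        mask = partition == k
        if not mask.any():
            raise ValueError(f"network {k!r} has no vertices under this partition")
        means = values[:, :, mask].mean(axis=2)  # (S, E)
        for j, e in enumerate(epochs):
            cols[(k, e)] = means[:, j]
    frame = pd.DataFrame(cols, index=pd.Index(subject_ids, name="subject"))
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["network", "epoch"])
    return NetworkEpochMatrix(frame, measure)


def motor_vs_average(
    matrix: NetworkEpochMatrix, motor_epochs: Sequence[str] = ("lh", "rh", "lf", "rf", "tongue")
) -> NetworkEpochMatrix:
    """Contrast each motor epoch against the average of all five.

    Per subject × network, the returned cell for a motor epoch is its
    value minus the mean over the five motor epochs; the five contrasts
    therefore sum to zero within each subject × network.
    """
    missing = [e for e in motor_epochs if e not in matrix.epochs]
    if missing:
        raise ValueError(f"missing motor epoch(s): {missing}")
    networks = matrix.networks
    sub = matrix.values.loc[
        :, [(k, e) for k in networks for e in motor_epochs]
    ]
    out = sub.copy()
    for k in networks:
        block = sub[k]
        out[k] = block.sub(block.mean(axis=1), axis=0).to_numpy()
    return NetworkEpochMatrix(out, matrix.measure + "_motor_contrast")


def rank_networks(
    matrix: NetworkEpochMatrix, subject_level: bool = False
) -> pd.Series:
    """Rank networks by RMS of their values across epochs (descending).

    By default the cohort-mean network × epoch table is computed first and
    the RMS is taken across its epochs; ``subject_level=True`` instead
    takes the RMS across subjects × epochs before averaging is ever done.
    Ties break by alphabetical label order.
    """
    if matrix.values.empty:
        raise ValueError("cannot rank an empty matrix")
    if subject_level:
        scores = {
            k: float(np.sqrt(np.mean(np.square(matrix.values[k].to_numpy()))))
            for k in matrix.networks
        }
        scores = pd.Series(scores)
    else:
        cm = matrix.cohort_mean()
        scores = np.sqrt((cm**2).mean(axis=1))
    return scores.sort_index().sort_values(ascending=False, kind="stable")


def rank_epochs(matrix: NetworkEpochMatrix) -> pd.Series:
    """Rank epochs by signed mean of cohort-mean values across networks."""
    if matrix.values.empty:
        raise ValueError("cannot rank an empty matrix")
    cm = matrix.cohort_mean()
    scores = cm.mean(axis=0)
    return scores.sort_index().sort_values(ascending=False, kind="stable")
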