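"""File formats: CIFTI-2 dscalar surface maps, a plain-text toy map
layout, subject tables, network-epoch matrices and YAML configs.

Full-scale hemisphere pairs travel as CIFTI-2 dscalar files with separate
left/right cortical surface models (via nibabel).  The toy layout is a
self-describing CSV — columns ``vertex, left, right`` with ``# key: value``
header comments — that round-trips losslessly and needs no binary tooling.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from nibabel.cifti2 import cifti2_axes

from .networks import NetworkEpochMatrix
from .types import HemiPair

_FLOAT_FMT = "%.17g"  # lossless float round-trip


# ---------------------------------------------------------------- toy layout

def write_toy_pair(pair: HemiPair, path: str) -> None:
    """Write one hemisphere pair in the plain-text toy layout."""
    with open(path, "w") as fh:
        fh.write("# format: hemiasym-toy-pair v1\n")
        if pair.subject_id is not None:
            fh.write(f"# subject_id: {pair.subject_id}\n")
        if pair.epoch is not None:
            fh.write(f"# epoch: {pair.epoch}\n")
        cols = {"vertex": np.arange(pair.n_vertices), "left": pair.left, "right": pair.right}
        if pair.coords_left is not None and pair.coords_right is not None:
            for i, ax in enumerate("xyz"):
                cols[f"lcoord_{ax}"] = pair.coords_left[:, i]
            for i, ax in enumerate("xyz"):
                cols[f"rcoord_{ax}"] = pair.coords_right[:, i]
        pd.DataFrame(cols).to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_toy_pair(path: str) -> HemiPair:
    """Read one hemisphere pair from the toy layout."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), float_precision="round_trip")
    for col in ("left", "right"):
        if col not in df.columns:
            raise ValueError(f"toy layout is missing the {col!r} hemisphere column")
    coords_l = coords_r = None
    if {"lcoord_x", "rcoord_x"} <= set(df.columns):
        coords_l = df[["lcoord_x", "lcoord_y", "lcoord_z"]].to_numpy(float)
        coords_r = df[["rcoord_x", "rcoord_y", "rcoord_z"]].to_numpy(float)
    return HemiPair(
        left=df["left"].to_numpy(float),
        right=df["right"].to_numpy(float),
        coords_left=coords_l,
        coords_right=coords_r,
        subject_id=meta.get("subject_id"),
        epoch=meta.get("epoch"),
    )


# ------------------------------------------------------------- CIFTI dscalar

def write_pair_dscalar(pair: HemiPair, path: str, map_name: str = "map") -> None:
    """Write a hemisphere pair as a CIFTI-2 dscalar with L/R cortex models."""
    n = pair.n_vertices
    bm_left = cifti2_axes.BrainModelAxis.from_surface(
        np.arange(n), n, name="CIFTI_STRUCTURE_CORTEX_LEFT"
    )
    bm_right = cifti2_axes.BrainModelAxis.from_surface(
        np.arange(n), n, name="CIFTI_STRUCTURE_CORTEX_RIGHT"
    )
    bm = bm_left + bm_right
    scalar = cifti2_axes.ScalarAxis([map_name])
    data = np.concatenate([pair.left, pair.right])[None, :]
    img = nib.Cifti2Image(data, header=(scalar, bm))
    img.to_filename(path)


def read_pair_dscalar(path: str) -> HemiPair:
    """Read left/right cortical vertex vectors from a CIFTI-2 dscalar."""
    img = nib.load(path)
    bm = img.header.get_axis(1)
    data = np.asarray(img.get_fdata())
    found: dict[str, np.ndarray] = {}
    for name, sl, sub_axis in bm.iter_structures():
        if name == "CIFTI_STRUCTURE_CORTEX_LEFT":
            found["left"] = data[0, sl]
        elif name == "CIFTI_STRUCTURE_CORTEX_RIGHT":
            found["right"] = data[0, sl]
    for side in ("left", "right"):
        if side not in found:
            raise ValueError(
                f"dscalar file lacks the CIFTI_STRUCTURE_CORTEX_{side.upper()} model"
            )
    if found["left"].size != found["right"].size:
        raise ValueError("left and right cortical models differ in vertex count")
    return HemiPair(left=found["left"], right=found["right"])


def read_surface_maps(paths) -> list[HemiPair]:
    """Read a collection of hemisphere pairs (dscalar or toy layout)."""
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    out = []
    for p in paths:
        p = str(p)
        if p.endswith(".nii"):
            out.append(read_pair_dscalar(p))
        else:
            out.append(read_toy_pair(p))
    return out


def write_stat_map(stat_map, path: str) -> None:
    """Write a vertex-wise statistical map (t, p, q, d) as CSV."""
    pd.DataFrame(
        {"vertex": np.arange(stat_map.t.size), "t": stat_map.t,
         "p": stat_map.p, "q": stat_map.q, "d": stat_map.d}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ------------------------------------------------------------------- tables

def write_subject_table(subjects: pd.DataFrame, path: str) -> None:
    subjects.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_subject_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_matrix(matrix: NetworkEpochMatrix, path: str) -> None:
    """Write a NetworkEpochMatrix as tidy CSV."""
    matrix.to_tidy().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_matrix(path: str) -> NetworkEpochMatrix:
    return NetworkEpochMatrix.from_tidy(pd.read_csv(path, float_precision="round_trip"))


def write_split(split, path: str) -> None:
    rows = [{"subject_id": s, "half": "discovery"} for s in split.discovery_ids]
    rows += [{"subject_id": s, "half": "replication"} for s in split.replication_ids]
    pd.DataFrame(rows).to_csv(path, index=False)


# -------------------------------------------------------------------- config

def write_yaml(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
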