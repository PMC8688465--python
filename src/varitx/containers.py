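"""Shared data containers.

The canonical in-memory objects the pipeline passes around: the stack of
seed-voxel FC profiles, the synthetic cohort bundle, and gene-set
collections.  Expression matrices travel as plain pandas DataFrames
(index = voxel id, columns = gene symbols).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class FCProfileStack:
    """Seed-voxel FC profiles: values[v, s, t, :] is the Pearson-r profile
    of seed voxel ``v`` for subject ``s`` in session ``t`` to all other
    mask voxels (self-correlation excluded, so the last axis has length
    ``n_voxels - 1``)."""

    values: np.ndarray                      # (V, S, T, V-1)
    coords: np.ndarray | None = None        # (V, 3) in mm

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 4:
            raise ValueError("values must be a 4-d (seed, subject, session, "
                             "target) array")
        if v.shape[3] != v.shape[0] - 1:
            raise ValueError("target axis must have length n_voxels - 1 "
                             "(self-correlation excluded)")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1.0 or finite.max() > 1.0):
            raise ValueError("FC values must lie in [-1, 1]")
        self.values = v
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (v.shape[0], 3):
                raise ValueError("coords must have shape (n_voxels, 3)")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    @property
    def n_sessions(self) -> int:
        return self.values.shape[2]


@dataclass
class Cohort:
    """A simulated study: either FC profiles (``stack``) or raw runs
    (``runs``: (subject, session) -> list of voxel-by-time arrays), plus
    the planted per-voxel inter-subject field as ground truth."""

    stack: FCProfileStack | None
    runs: dict | None
    truth: np.ndarray
    gradient: np.ndarray
    coords: np.ndarray
    network_labels: np.ndarray
    config: object


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe.

    Sets are intersected with the background at construction; sets that
    become empty are dropped with a warning.  The background must not
    contain duplicate symbols.
    """

    sets: dict
    background: list

    def __post_init__(self) -> None:
        bg = list(self.background)
        if len(bg) != len(set(bg)):
            raise ValueError("background contains duplicate gene symbols")
        self.background = bg
        bgset = set(bg)
        cleaned = {}
        for name, members in self.sets.items():
            inter = set(members) & bgset
            if not inter:
                warnings.warn(f"gene set {name!r} is empty after "
                              "intersection with the background; dropped")
                continue
            cleaned[name] = inter
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)
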