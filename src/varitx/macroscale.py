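"""Macroscale map coupling and behavioral decoding.

Intersubject variability of auxiliary imaging indices (CBF, WM volume,
FA, T1w/T2w) is the voxelwise SD across subjects.  Coupling with the
functional-variability map is a Spearman correlation over the common
non-zero voxels, with significance from spatially constrained (MSR)
surrogates of the first map and BH correction across the comparison
family (whole mask plus the 12 networks).  Behavioral decoding
correlates the variability map with meta-analytic term maps over their
non-zero overlap and keeps terms whose Fisher z exceeds a threshold
(default 2.1, i.e. Pearson P < 0.05).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .spatial import (WeightMatrix, build_weight_matrix, empirical_p,
                      fdr_bh, moran_eigenbasis, msr_surrogates)

__all__ = ["index_variability", "map_correlation", "behavior_decode"]


def index_variability(stack: np.ndarray) -> np.ndarray:
    """Voxelwise intersubject variability of an index map: SD across
    subjects (sample SD, ddof=1).  ``stack`` is subjects x voxels."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 2 or stack.shape[0] < 2:
        raise ValueError("need a subjects x voxels stack with >= 2 subjects")
    return stack.std(axis=0, ddof=1)


def _overlap_mask(map1: np.ndarray, map2: np.ndarray) -> np.ndarray:
    return (np.isfinite(map1) & np.isfinite(map2)
            & (map1 != 0) & (map2 != 0))


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def map_correlation(map1: np.ndarray, map2: np.ndarray,
                    coords: np.ndarray | None = None,
                    weights: WeightMatrix | None = None,
                    n_surr: int = 1000, seed: int | None = None,
                    method: str = "spearman",
                    labels: np.ndarray | None = None,
                    n_networks: int = 12) -> pd.DataFrame:
    """Spatially corrected correlation between two voxel maps.

    The correlation is computed over the common finite non-zero voxels;
    the p-value compares it with correlations of MSR surrogates of
    ``map1`` against ``map2``.  With ``labels``, network-restricted
    correlations are added and the whole family is BH-corrected.
    """
    map1 = np.asarray(map1, dtype=float)
    map2 = np.asarray(map2, dtype=float)
    if map1.shape != map2.shape:
        raise ValueError("maps must share the voxel set")
    if weights is None:
        if coords is None:
            raise ValueError("provide coords or a prebuilt weight matrix")
        coords = np.asarray(coords, dtype=float)

    def one(sel: np.ndarray, name: str) -> dict | None:
        m = _overlap_mask(map1, map2) & sel
        n = int(m.sum())
        if n < 10:
            warnings.warn(f"{name}: overlap {n} < 10 voxels; skipped")
            return None
        a, b = map1[m], map2[m]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError(f"{name}: constant map on the overlap")
        rho = _corr(a, b, method)
        if weights is not None and bool(m.all()):
            w = weights
        else:
            if coords is None:
                raise ValueError("coords required to restrict the weight "
                                 "matrix to the overlap voxels")
            w = build_weight_matrix(coords[m], k=min(8, n - 1))
        basis = moran_eigenbasis(w)
        ens = msr_surrogates(a, basis, n_surr, seed=seed)
        null = np.array([_corr(s, b, method) for s in ens.maps])
        return {"region": name, "n_voxels": n, "rho": rho,
                "p_moran": empirical_p(rho, null)}

    rows = [one(np.ones(map1.size, dtype=bool), "whole")]
    if labels is not None:
        labels = np.asarray(labels)
        for k in range(1, n_networks + 1):
            if np.any(labels == k):
                rows.append(one(labels == k, f"network{k:02d}"))
    rows = [r for r in rows if r is not None]
    out = pd.DataFrame(rows)
    out["q"] = fdr_bh(out["p_moran"].to_numpy())
    return out


def behavior_decode(variability_map: np.ndarray, term_maps: pd.DataFrame,
                    z_thresh: float = 2.1,
                    return_all: bool = False) -> pd.DataFrame:
    """Meta-analytic term decoding of the variability map.

    Per term: Pearson r over the non-zero overlap with the variability
    map and Fisher z = atanh(r) * sqrt(n - 3).  Terms with |z| above the
    threshold are returned sorted by r (descending); terms with fewer
    than 4 overlap voxels are skipped with a warning (Fisher z needs
    n > 3).
    """
    vmap = np.asarray(variability_map, dtype=float)
    rows = []
    for term in term_maps.columns:
        tmap = term_maps[term].to_numpy(dtype=float)
        if tmap.shape != vmap.shape:
            raise ValueError(f"term {term!r} not aligned with the map")
        m = _overlap_mask(vmap, tmap)
        n = int(m.sum())
        if n < 4:
            warnings.warn(f"term {term!r}: overlap {n} < 4 voxels; skipped")
            continue
        r = float(stats.pearsonr(vmap[m], tmap[m]).statistic)
        z = float(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
                  * np.sqrt(n - 3))
        rows.append({"term": term, "r": r, "z": z, "n_voxels": n,
                     "selected": abs(z) > z_thresh})
    out = pd.DataFrame(rows,
                       columns=["term", "r", "z", "n_voxels", "selected"])
    out = out.sort_values("r", ascending=False, ignore_index=True)
    if return_all:
        return out
    return out[out["selected"]].reset_index(drop=True)
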