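"""Synthetic cohorts, expression matrices, gene sets and auxiliary maps.

Everything downstream of the scanner is emulated here with known ground
truth: multi-subject, multi-session seed-based FC profiles with separable
inter-subject / intra-subject / measurement-noise variance components, an
expression matrix in which a chosen fraction of genes tracks a spatial
gradient, gene sets with planted overlaps, and smooth term/index maps.

The cohort generator works directly in FC space by default (cheap and
deterministic); a latent-time-course mode emits raw BOLD-like runs so the
full profile-and-tSNR path can be exercised end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import Cohort, FCProfileStack, GeneSetCollection

__all__ = [
    "CohortConfig",
    "ExpressionConfig",
    "simulate_cohort",
    "simulate_expression",
    "simulate_gene_sets",
    "simulate_term_maps",
    "simulate_index_stack",
]


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("cannot min-max scale a constant field")
    return (x - lo) / (hi - lo)


@dataclass
class CohortConfig:
    """Parameters of the synthetic multi-session FC cohort.

    The defaults describe a desk-scale test-retest study: 20 subjects
    scanned in 4 sessions of 2 runs each over a 300-voxel white-matter
    mask.  ``inter_sd_field`` / ``intra_sd_field`` are per-voxel scales
    (unitless, FC units) of the subject- and session-specific profile
    deviations; ``noise_sd`` is the per-entry measurement noise in FC
    space (per-timepoint noise in time-series mode).  When a field is
    left ``None`` it is derived deterministically from ``seed``:
    coordinates uniform in a 60 mm box, gradient = min-max scaled first
    coordinate, inter-subject field ``0.1 + 0.3 * gradient``, and an
    intra-subject field ``0.05 + 0.2 * minmax(y)`` driven by the second
    coordinate — intra-subject variability has its own spatial
    organization, independent of the planted inter-subject field, so the
    confound-removal GLM has a genuine (not collinear) regressor.
    """

    n_subjects: int = 20
    n_sessions: int = 4
    n_runs_per_session: int = 2
    n_voxels: int = 300
    n_timepoints: int = 150
    inter_sd_field: np.ndarray | None = None
    intra_sd_field: np.ndarray | None = None
    noise_sd: float = 0.05
    gradient: np.ndarray | None = None
    coords: np.ndarray | None = None
    seed: int = 0

    def resolve(self) -> "CohortConfig":
        """Return a copy with all optional fields filled in and validated."""
        for name in ("n_subjects", "n_sessions", "n_runs_per_session",
                     "n_voxels", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3 for pairwise similarity")
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("noise_sd must be finite and >= 0")

        rng = np.random.default_rng(self.seed)
        coords = self.coords
        if coords is None:
            coords = rng.uniform(0.0, 60.0, size=(self.n_voxels, 3))
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_voxels, 3):
            raise ValueError("coords must have shape (n_voxels, 3)")

        gradient = self.gradient
        if gradient is None:
            gradient = _minmax(coords[:, 0])
        gradient = np.asarray(gradient, dtype=float)
        if gradient.shape != (self.n_voxels,):
            raise ValueError("gradient length must equal n_voxels")

        inter = self.inter_sd_field
        if inter is None:
            inter = 0.1 + 0.3 * gradient
        inter = np.asarray(inter, dtype=float)
        intra = self.intra_sd_field
        if intra is None:
            intra = 0.05 + 0.2 * _minmax(coords[:, 1])
        intra = np.asarray(intra, dtype=float)
        for name, f in (("inter_sd_field", inter), ("intra_sd_field", intra)):
            if f.shape != (self.n_voxels,):
                raise ValueError(f"{name} length must equal n_voxels")
            if not np.all(np.isfinite(f)) or np.any(f < 0):
                raise ValueError(f"{name} must be finite and >= 0")

        return CohortConfig(
            n_subjects=self.n_subjects,
            n_sessions=self.n_sessions,
            n_runs_per_session=self.n_runs_per_session,
            n_voxels=self.n_voxels,
            n_timepoints=self.n_timepoints,
            inter_sd_field=inter,
            intra_sd_field=intra,
            noise_sd=self.noise_sd,
            gradient=gradient,
            coords=coords,
            seed=self.seed,
        )


@dataclass
class ExpressionConfig:
    """Parameters of the synthetic voxels-by-genes expression matrix.

    ``effect`` is the target absolute Pearson correlation between each
    signal gene and the spatial gradient; ``noise_sd`` sets the overall
    expression scale (correlations are scale invariant).
    """

    n_genes: int = 1000
    n_signal_genes: int = 20
    effect: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_signal_genes < 0:
            raise ValueError("gene counts must be positive")
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes cannot exceed n_genes")
        if not (0.0 <= self.effect < 1.0):
            raise ValueError("effect must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _base_profile_matrix(coords: np.ndarray, gradient: np.ndarray) -> np.ndarray:
    """Smooth seed-by-target baseline FC: distance decay plus a gradient term.

    FC between nearby voxels is high and decays with Euclidean distance;
    the additive gradient term gives every profile a shared smooth spatial
    structure so surrogate tests see realistic autocorrelation.  Profiles
    are row-standardized to a common mean (0.25) and SD (0.25) so every
    seed has the same baseline profile variance and differences in the
    similarity maps reflect the planted variance components, not seed
    position in the bounding box.
    """
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    raw = np.exp(-d / 25.0) + 0.6 * gradient[None, :]
    z = (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1,
                                                          keepdims=True)
    return 0.25 + 0.25 * z


def _network_labels(gradient: np.ndarray, n_networks: int = 12) -> np.ndarray:
    lab = 1 + np.minimum(n_networks - 1, (gradient * n_networks).astype(int))
    return lab.astype(int)


def simulate_cohort(config: CohortConfig, mode: str = "profiles") -> Cohort:
    """Simulate a multi-subject, multi-session FC cohort with known truth.

    In ``profiles`` mode the profile of seed voxel ``v`` for subject ``s``
    in session ``t`` is

        f_v(s, t) = base_v + inter_sd[v] * u_{v,s} + intra_sd[v] * e_{v,s,t}
                    + noise_sd * eps,

    with ``u`` shared across sessions of a subject and ``e`` drawn fresh
    per session; values are clipped to the valid correlation range.  The
    planted ``inter_sd_field`` is returned as ground truth.

    In ``timeseries`` mode raw runs of latent-time-course mixtures are
    emitted instead (``Cohort.runs``), from which FC profiles and tSNR
    can be computed end to end.
    """
    cfg = config.resolve()
    rng = np.random.default_rng(cfg.seed)
    V, S, T = cfg.n_voxels, cfg.n_subjects, cfg.n_sessions
    labels = _network_labels(cfg.gradient)

    if mode == "timeseries":
        runs = _simulate_runs(cfg, rng)
        return Cohort(stack=None, runs=runs, truth=cfg.inter_sd_field,
                      gradient=cfg.gradient, coords=cfg.coords,
                      network_labels=labels, config=cfg)
    if mode != "profiles":
        raise ValueError(f"unknown mode {mode!r}")

    base = _base_profile_matrix(cfg.coords, cfg.gradient)
    # per-seed target set excludes the seed itself
    tgt = np.array([[w for w in range(V) if w != v] for v in range(V)])
    base_t = np.take_along_axis(base, tgt, axis=1)           # (V, V-1)

    u = rng.standard_normal((V, S, V - 1))
    e = rng.standard_normal((V, S, T, V - 1))
    eps = rng.standard_normal((V, S, T, V - 1))
    values = (base_t[:, None, None, :]
              + cfg.inter_sd_field[:, None, None, None] * u[:, :, None, :]
              + cfg.intra_sd_field[:, None, None, None] * e
              + cfg.noise_sd * eps)
    np.clip(values, -0.999, 0.999, out=values)

    stack = FCProfileStack(values=values, coords=cfg.coords)
    return Cohort(stack=stack, runs=None, truth=cfg.inter_sd_field,
                  gradient=cfg.gradient, coords=cfg.coords,
                  network_labels=labels, config=cfg)


def _simulate_runs(cfg: CohortConfig, rng: np.random.Generator) -> dict:
    """Latent-time-course BOLD-like runs: (subject, session) -> list of V x T."""
    V, S, T, K = cfg.n_voxels, cfg.n_subjects, cfg.n_sessions, 5
    centers = rng.uniform(0.0, 60.0, size=(K, 3))
    d = np.linalg.norm(cfg.coords[:, None, :] - centers[None, :, :], axis=-1)
    loadings = 0.6 * np.exp(-d / 20.0)                        # (V, K)
    u = rng.standard_normal((S, V, K))
    e = rng.standard_normal((S, T, V, K))
    noise_sd = max(cfg.noise_sd, 1e-3)                        # keep tSNR finite
    runs: dict[tuple[int, int], list[np.ndarray]] = {}
    for s in range(S):
        for t in range(T):
            A = (loadings
                 + cfg.inter_sd_field[:, None] * u[s]
                 + cfg.intra_sd_field[:, None] * e[s, t])
            runs[(s, t)] = []
            for _ in range(cfg.n_runs_per_session):
                L = rng.standard_normal((K, cfg.n_timepoints))
                ts = A @ L + 100.0 + noise_sd * rng.standard_normal(
                    (V, cfg.n_timepoints))
                runs[(s, t)].append(ts)
    return runs


def simulate_expression(
    gradient: np.ndarray, config: ExpressionConfig
) -> tuple[pd.DataFrame, np.ndarray]:
    """Voxels-by-genes expression with a planted gradient-tracking subset.

    Each signal gene is ``effect * z(gradient) * sign + sqrt(1 - effect^2)
    * noise`` (sign random, so both PLS1+ and PLS1- genes exist); null
    genes are pure noise.  Returns the matrix (index = voxel id, columns
    = unique gene symbols) and the boolean signal mask over columns.
    """
    config.validate()
    gradient = np.asarray(gradient, dtype=float)
    if not np.all(np.isfinite(gradient)):
        raise ValueError("gradient must be finite")
    if np.ptp(gradient) == 0:
        raise ValueError("gradient must be non-constant")
    rng = np.random.default_rng(config.seed)
    V, G = gradient.size, config.n_genes
    g = (gradient - gradient.mean()) / gradient.std()

    X = rng.standard_normal((V, G))
    signal_idx = rng.choice(G, size=config.n_signal_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_signal_genes)
    X[:, signal_idx] = (config.effect * g[:, None] * signs[None, :]
                        + np.sqrt(1.0 - config.effect ** 2)
                        * X[:, signal_idx])
    X *= config.noise_sd

    symbols = [f"G{i:05d}" for i in range(G)]
    mask = np.zeros(G, dtype=bool)
    mask[signal_idx] = True
    df = pd.DataFrame(X, columns=symbols)
    df.index.name = "voxel_id"
    return df, mask


def simulate_gene_sets(
    signal_genes: Sequence[str],
    all_genes: Sequence[str],
    n_sets: int,
    overlap_fracs: Sequence[float],
    seed: int = 0,
    set_sizes: int | Sequence[int] = 40,
) -> GeneSetCollection:
    """Gene sets drawing a stated fraction of members from the signal genes.

    Set ``i`` contains ``round(overlap_fracs[i] * size)`` signal genes and
    fills the remainder with null genes; names carry the planted fraction.
    """
    fracs = np.asarray(overlap_fracs, dtype=float)
    if fracs.size != n_sets:
        raise ValueError("overlap_fracs must have length n_sets")
    if np.any(fracs < 0) or np.any(fracs > 1):
        raise ValueError("overlap_fracs must lie in [0, 1]")
    sizes = np.broadcast_to(np.asarray(set_sizes, dtype=int), (n_sets,))
    signal = list(dict.fromkeys(signal_genes))
    universe = list(dict.fromkeys(all_genes))
    null = [g for g in universe if g not in set(signal)]
    rng = np.random.default_rng(seed)

    sets: dict[str, set] = {}
    for i, (frac, size) in enumerate(zip(fracs, sizes)):
        k = int(round(frac * size))
        if k > len(signal) or size - k > len(null):
            raise ValueError(
                f"set {i}: requested size {size} with overlap {k} exceeds "
                f"the available universe")
        members = (list(rng.choice(signal, size=k, replace=False))
                   + list(rng.choice(null, size=size - k, replace=False)))
        sets[f"set{i:02d}_overlap{frac:.2f}"] = set(members)
    return GeneSetCollection(sets=sets, background=universe)


def simulate_term_maps(
    base_map: np.ndarray,
    n_terms: int,
    target_corrs: Sequence[float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Strictly positive meta-analytic-style term maps with known coupling.

    Term ``i`` mixes the standardized base map with independent noise to
    hit a target correlation, then is shifted to be positive (activation
    probabilities are non-negative).
    """
    base = np.asarray(base_map, dtype=float)
    if np.ptp(base) == 0:
        raise ValueError("base map must be non-constant")
    rng = np.random.default_rng(seed)
    if target_corrs is None:
        target_corrs = rng.uniform(-0.6, 0.9, size=n_terms)
    target_corrs = np.asarray(target_corrs, dtype=float)
    if target_corrs.size != n_terms:
        raise ValueError("target_corrs must have length n_terms")
    z = (base - base.mean()) / base.std()
    cols = {}
    for i, rho in enumerate(target_corrs):
        noise = rng.standard_normal(base.size)
        m = rho * z + np.sqrt(max(0.0, 1.0 - rho ** 2)) * noise
        cols[f"term{i:02d}"] = m - m.min() + 0.1
    df = pd.DataFrame(cols)
    df.index.name = "voxel_id"
    return df


def simulate_index_stack(
    mean_map: np.ndarray,
    sd_field: np.ndarray,
    n_subjects: int,
    seed: int = 0,
) -> np.ndarray:
    """Subjects-by-voxels stack of an anatomical/functional index.

    Each subject's map is the group mean plus voxelwise Gaussian deviation
    scaled by ``sd_field``, so the SD-across-subjects map recovers
    ``sd_field``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    mean_map = np.asarray(mean_map, dtype=float)
    sd_field = np.asarray(sd_field, dtype=float)
    if sd_field.shape != mean_map.shape:
        raise ValueError("mean_map and sd_field must share shape")
    if np.any(sd_field < 0):
        raise ValueError("sd_field must be >= 0")
    rng = np.random.default_rng(seed)
    dev = rng.standard_normal((n_subjects, mean_map.size))
    return mean_map[None, :] + sd_field[None, :] * dev
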