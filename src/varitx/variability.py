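"""Intersubject variability of seed-based functional connectivity.

For every seed voxel the FC profile (Pearson r to all other mask voxels)
is computed per subject and session.  The per-session intersubject
similarity map R_v(t) averages the correlation between every pair of
subjects' profiles; its complement R'_v(t) = 1 - R_v(t) is the
unadjusted variability.  Intra-subject variability N_v averages
1 - corr over session pairs within each subject, and technical noise is
the inverse temporal SNR.  A per-session GLM removes both confounds:

    V_v(t) = R'_v(t) - b1 * N_v - b2 * noise_v - c

and the session-averaged residual map V_mean is the final adjusted
intersubject-variability map.  Correlations are averaged raw by default;
Fisher-z averaging is available behind a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import FCProfileStack

__all__ = [
    "compute_fc_profile",
    "stack_from_runs",
    "technical_noise",
    "noise_map_from_runs",
    "intersubject_similarity",
    "intrasubject_variability",
    "adjust_variability",
    "network_aggregate",
    "GLMFit",
    "VariabilityModel",
    "VariabilityResults",
]


# ---------------------------------------------------------------------------
# profile construction

def compute_fc_profile(run: np.ndarray, seed_voxel: int) -> np.ndarray:
    """Pearson correlation of one seed voxel's time series with every other
    voxel's series.

    ``run`` is voxels x time (multiple runs of a session are concatenated
    in time before calling).  Zero-variance target series yield NaN with a
    warning; a zero-variance seed is an error.
    """
    run = np.asarray(run, dtype=float)
    if run.ndim != 2:
        raise ValueError("run must be a voxels x time matrix")
    V, T = run.shape
    if T < 3:
        raise ValueError("need at least 3 timepoints")
    if not 0 <= seed_voxel < V:
        raise IndexError("seed_voxel out of range")
    centered = run - run.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    if norms[seed_voxel] == 0:
        raise ValueError("seed voxel time series is constant")
    if np.all(norms == 0):
        raise ValueError("all time series are constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = centered @ centered[seed_voxel] / (norms * norms[seed_voxel])
    bad = norms == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} constant target series set to NaN")
        r[bad] = np.nan
    return np.delete(r, seed_voxel)


def stack_from_runs(runs: dict, coords: np.ndarray | None = None
                    ) -> FCProfileStack:
    """Build the full profile stack from raw runs.

    ``runs`` maps ``(subject, session)`` to a list of voxel-by-time run
    arrays; runs of a session are concatenated in time and the complete
    seed-by-seed correlation matrix is computed once per session.
    """
    subjects = sorted({s for s, _ in runs})
    sessions = sorted({t for _, t in runs})
    sample = np.concatenate(runs[(subjects[0], sessions[0])], axis=1)
    V = sample.shape[0]
    values = np.full((V, len(subjects), len(sessions), V - 1), np.nan)
    off = ~np.eye(V, dtype=bool)
    for si, s in enumerate(subjects):
        for ti, t in enumerate(sessions):
            data = np.concatenate(runs[(s, t)], axis=1)
            cm = np.corrcoef(data)
            values[:, si, ti, :] = cm[off].reshape(V, V - 1)
    return FCProfileStack(values=values, coords=coords)


# ---------------------------------------------------------------------------
# similarity / variability maps

def _mean_offdiag_corr(profiles: np.ndarray, fisher: bool) -> tuple[float, int]:
    """Mean pairwise Pearson r between rows; rows with zero variance are
    excluded with a warning.  Returns (mean r, number of pairs used)."""
    sd = profiles.std(axis=1)
    usable = sd > 0
    if not usable.all():
        warnings.warn(f"{int((~usable).sum())} constant profiles excluded "
                      "from the pairwise similarity")
    profiles = profiles[usable]
    k = profiles.shape[0]
    if k < 2:
        raise ValueError("fewer than 2 usable profiles")
    cm = np.corrcoef(profiles)
    iu = np.triu_indices(k, 1)
    vals = cm[iu]
    if fisher:
        vals = np.clip(vals, -1 + 1e-12, 1 - 1e-12)
        return float(np.tanh(np.mean(np.arctanh(vals)))), vals.size
    return float(vals.mean()), vals.size


def intersubject_similarity(stack: FCProfileStack, session: int,
                            fisher: bool = False
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel intersubject similarity map R_v(t) for one session.

    R_v(t) is the mean Pearson correlation over all C(S, 2) unordered
    subject pairs of their seed-``v`` FC profiles.  Returns the R map and
    the per-voxel count of pairs actually averaged.
    """
    if stack.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    V = stack.n_voxels
    R = np.empty(V)
    n_pairs = np.empty(V, dtype=int)
    for v in range(V):
        R[v], n_pairs[v] = _mean_offdiag_corr(
            stack.values[v, :, session, :], fisher)
    return R, n_pairs


def intrasubject_variability(stack: FCProfileStack, fisher: bool = False
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intra-subject variability from repeated sessions.

    N_v(s) = 1 - mean correlation over all C(T, 2) session pairs of
    subject ``s``'s seed-``v`` profiles; N_v averages N_v(s) over
    subjects.  Subjects with fewer than two usable sessions are excluded
    from the average with a warning.  Returns (N_subject (S, V), N (V,),
    per-voxel pair counts of the first usable subject).
    """
    if stack.n_sessions < 2:
        raise ValueError("need at least 2 sessions per subject")
    V, S = stack.n_voxels, stack.n_subjects
    N_subject = np.full((S, V), np.nan)
    n_pairs = np.zeros(V, dtype=int)
    for s in range(S):
        for v in range(V):
            try:
                r, k = _mean_offdiag_corr(stack.values[v, s, :, :], fisher)
            except ValueError:
                warnings.warn(f"subject {s} has fewer than 2 usable sessions "
                              f"at voxel {v}; excluded")
                continue
            N_subject[s, v] = 1.0 - r
            n_pairs[v] = max(n_pairs[v], k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        N = np.nanmean(N_subject, axis=0)
    return N_subject, N, n_pairs


def technical_noise(run: np.ndarray) -> np.ndarray:
    """Per-voxel technical noise 1/tSNR of one run.

    tSNR_v is the temporal mean divided by the temporal SD (sample SD,
    ddof=1).  Voxels with zero temporal SD or zero mean are flagged NaN
    with a warning.
    """
    run = np.asarray(run, dtype=float)
    if run.ndim != 2 or run.shape[1] < 2:
        raise ValueError("run must be voxels x time with >= 2 timepoints")
    mean = run.mean(axis=1)
    sd = run.std(axis=1, ddof=1)
    noise = np.full(run.shape[0], np.nan)
    bad = (sd == 0) | (mean == 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} voxels with zero temporal SD or "
                      "zero mean flagged NaN in the noise map")
    ok = ~bad
    noise[ok] = sd[ok] / mean[ok]
    return noise


def noise_map_from_runs(runs: dict) -> np.ndarray:
    """One technical-noise regressor map: 1/tSNR per run, averaged over
    all runs, sessions and subjects."""
    maps = [technical_noise(r) for run_list in runs.values()
            for r in run_list]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.stack(maps), axis=0)


# ---------------------------------------------------------------------------
# GLM adjustment

@dataclass
class GLMFit:
    """Coefficients of the confound-removal GLM for one session."""

    beta1: float                 # weight on intra-subject variability
    beta2: float | None          # weight on technical noise (None if absent)
    c: float                     # intercept
    residual_variance: float


def adjust_variability(r_adj: np.ndarray, N: np.ndarray,
                       noise: np.ndarray | None = None
                       ) -> tuple[np.ndarray, GLMFit]:
    """Regress intra-subject variability (and technical noise, when
    available) out of one session's unadjusted map.

    Ordinary least squares of R'_v on [N_v, noise_v, 1]; the residual is
    the adjusted variability V_v for that session.
    """
    r_adj = np.asarray(r_adj, dtype=float)
    N = np.asarray(N, dtype=float)
    cols = [N]
    if noise is not None:
        noise = np.asarray(noise, dtype=float)
        cols.append(noise)
    if r_adj.size < 4:
        raise ValueError("need at least 4 voxels for the GLM")
    X = sm.add_constant(np.column_stack(cols))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear regressors in the adjustment GLM")
    fit = sm.OLS(r_adj, X).fit()
    resid = np.asarray(fit.resid)
    glm = GLMFit(
        beta1=float(fit.params[1]),
        beta2=float(fit.params[2]) if noise is not None else None,
        c=float(fit.params[0]),
        residual_variance=float(resid.var(ddof=X.shape[1])),
    )
    return resid, glm


def network_aggregate(values: np.ndarray, labels: np.ndarray,
                      n_networks: int = 12) -> pd.Series:
    """Mean of a voxel map within each functional network label 1..12.

    Label 0 (unassigned) is excluded; empty networks are reported as
    missing (NaN) with a warning, never as 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("map and labels must share shape")
    if labels.min() < 0 or labels.max() > n_networks:
        raise ValueError(f"labels must lie in 0..{n_networks}")
    out = pd.Series(np.nan, index=pd.RangeIndex(1, n_networks + 1,
                                                name="network"))
    for k in range(1, n_networks + 1):
        sel = labels == k
        if sel.any():
            out.loc[k] = values[sel].mean()
        else:
            warnings.warn(f"network {k} has no voxels; reported as missing")
    return out


# ---------------------------------------------------------------------------
# model / results

class VariabilityModel:
    """Adjusted intersubject-variability model over an FC profile stack.

    Parameters
    ----------
    stack : FCProfileStack
        Seed-voxel FC profiles, voxels x subjects x sessions x targets.
    noise : ndarray, optional
        Per-voxel technical-noise regressor (1/tSNR averaged over runs).
        When omitted the GLM adjusts for intra-subject variability only.
    fisher : bool
        Average correlations through Fisher's z instead of raw r.
    """

    def __init__(self, stack: FCProfileStack,
                 noise: np.ndarray | None = None,
                 fisher: bool = False) -> None:
        self.stack = stack
        self.noise = None if noise is None else np.asarray(noise, dtype=float)
        if self.noise is not None and self.noise.shape != (stack.n_voxels,):
            raise ValueError("noise map length must equal n_voxels")
        self.fisher = fisher

    @classmethod
    def from_runs(cls, runs: dict, coords: np.ndarray | None = None,
                  fisher: bool = False) -> "VariabilityModel":
        """Build the model from raw runs: profiles from concatenated runs
        per session, noise from the pooled 1/tSNR maps."""
        stack = stack_from_runs(runs, coords=coords)
        noise = noise_map_from_runs(runs)
        return cls(stack, noise=noise, fisher=fisher)

    def fit(self) -> "VariabilityResults":
        stack = self.stack
        T, V = stack.n_sessions, stack.n_voxels
        R = np.empty((T, V))
        pair_counts = np.empty((T, V), dtype=int)
        for t in range(T):
            R[t], pair_counts[t] = intersubject_similarity(
                stack, t, fisher=self.fisher)
        R_adj = 1.0 - R
        N_subject, N, session_pairs = intrasubject_variability(
            stack, fisher=self.fisher)

        keep = np.isfinite(N) & np.all(np.isfinite(R_adj), axis=0)
        if self.noise is not None:
            keep &= np.isfinite(self.noise)
        if not keep.all():
            warnings.warn(f"{int((~keep).sum())} flagged voxels dropped "
                          "before the adjustment GLM")

        N_keep = N[keep]
        noise_keep = None if self.noise is None else self.noise[keep]
        use_N = np.ptp(N_keep) > 1e-12
        use_noise = noise_keep is not None and np.ptp(noise_keep) > 1e-12
        if not use_N:
            warnings.warn("intra-subject variability map is constant; "
                          "dropped from the adjustment GLM")
        if noise_keep is not None and not use_noise:
            warnings.warn("technical-noise map is constant; dropped from "
                          "the adjustment GLM")

        V_map = np.full((T, V), np.nan)
        glms = []
        for t in range(T):
            r = R_adj[t, keep]
            if use_N:
                resid, glm = adjust_variability(
                    r, N_keep, noise_keep if use_noise else None)
            elif use_noise:
                resid, fit = adjust_variability(r, noise_keep)
                glm = GLMFit(beta1=0.0, beta2=fit.beta1, c=fit.c,
                             residual_variance=fit.residual_variance)
            else:
                resid = r - r.mean()
                glm = GLMFit(beta1=0.0, beta2=None, c=float(r.mean()),
                             residual_variance=float(resid.var(ddof=1)))
            V_map[t, keep] = resid
            glms.append(glm)
        V_mean = V_map.mean(axis=0)

        return VariabilityResults(
            model=self, R=R, R_adj=R_adj, N_subject=N_subject, N=N,
            noise=self.noise, V=V_map, V_mean=V_mean, glm_fits=glms,
            subject_pair_count=pair_counts, session_pair_count=session_pairs,
            voxel_keep=keep)


@dataclass
class VariabilityResults:
    """Fitted variability maps and the per-session adjustment GLMs."""

    model: VariabilityModel
    R: np.ndarray                # (T, V) intersubject similarity
    R_adj: np.ndarray            # (T, V) unadjusted variability 1 - R
    N_subject: np.ndarray        # (S, V) per-subject intra-subject variability
    N: np.ndarray                # (V,) subject-averaged
    noise: np.ndarray | None     # (V,) 1/tSNR regressor
    V: np.ndarray                # (T, V) adjusted variability per session
    V_mean: np.ndarray           # (V,) final adjusted map
    glm_fits: list
    subject_pair_count: np.ndarray
    session_pair_count: np.ndarray
    voxel_keep: np.ndarray

    def network_table(self, labels: np.ndarray) -> pd.DataFrame:
        """Network-averaged unadjusted and adjusted variability."""
        return pd.DataFrame({
            "unadjusted": network_aggregate(self.R_adj.mean(axis=0), labels),
            "adjusted": network_aggregate(self.V_mean, labels),
        })

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "R_mean": self.R.mean(axis=0),
            "R_adj_mean": self.R_adj.mean(axis=0),
            "N": self.N,
            "V_mean": self.V_mean,
        })
        if self.noise is not None:
            df["noise"] = self.noise
        df.index.name = "voxel_id"
        return df

    def summary(self) -> str:
        stack = self.model.stack
        lines = [
            "Adjusted intersubject variability of seed-based FC",
            "=" * 52,
            f"voxels:   {stack.n_voxels}",
            f"subjects: {stack.n_subjects} "
            f"({math.comb(stack.n_subjects, 2)} pairs/voxel/session)",
            f"sessions: {stack.n_sessions} "
            f"({math.comb(stack.n_sessions, 2)} pairs/voxel/subject)",
            f"fisher-z averaging: {self.model.fisher}",
            f"noise regressor: "
            f"{'1/tSNR map' if self.noise is not None else 'absent'}",
            "",
            "per-session adjustment GLM  V = R' - b1*N - b2*noise - c",
        ]
        for t, g in enumerate(self.glm_fits):
            b2 = "   --  " if g.beta2 is None else f"{g.beta2:7.4f}"
            lines.append(f"  session {t}: b1={g.beta1:7.4f}  b2={b2}  "
                         f"c={g.c:7.4f}  resid var={g.residual_variance:.3e}")
        vm = self.V_mean[np.isfinite(self.V_mean)]
        lines += ["", f"V_mean: mean={vm.mean():.4f}  sd={vm.std(ddof=1):.4f}"
                      f"  range=[{vm.min():.4f}, {vm.max():.4f}]"]
        return "\n".join(lines)

    def plot_map(self, ax=None):
        """Histogram of the final adjusted variability map."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.V_mean[np.isfinite(self.V_mean)], bins=40)
        ax.set_xlabel("adjusted intersubject variability")
        ax.set_ylabel("voxels")
        return ax
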