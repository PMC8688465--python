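"""PLS1 transcriptomic decoding of a voxelwise brain map.

With a z-scored voxels-by-genes expression matrix X and a z-scored
response map y, the first partial-least-squares component has weight
vector w proportional to X'y (for a univariate response the leading left
singular vector of the cross-covariance); voxel scores are X w, oriented
so corr(scores, y) >= 0.  Gene significance comes from a voxel bootstrap:
each resampled weight vector is sign-aligned to the full-sample weights
and the bootstrap ratio Z_g = w_g / SD_boot(w_g) ranks the genes.  The
genes with two-sided normal p below an FDR threshold form the PLS1+ and
PLS1- lists.  Leave-one-session-out validation refits the component on
the mean of the training-session maps and correlates the predicted
scores with the held-out session's map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spatial import empirical_p, fdr_bh, msr_surrogates

__all__ = [
    "PLSModel",
    "PLSResults",
    "pls1_fit",
    "bootstrap_z",
    "select_gene_lists",
    "predictive_validation",
]


def _zscore_columns(X: np.ndarray, name: str = "X") -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(np.flatnonzero(sd == 0)[:10])
        raise ValueError(f"constant columns in {name}: {bad}")
    return (X - X.mean(axis=0)) / sd


def _pls1_weights(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unit-norm PLS1 weight vector of z-scored X against z-scored y."""
    w = X.T @ y
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("X'y vanishes; no PLS1 direction")
    return w / nrm


@dataclass
class PLSResults:
    """PLS1 scores, gene weights, bootstrap ratios and FDR gene lists."""

    scores: np.ndarray                  # per-voxel PLS1 score
    weights: np.ndarray                 # per-gene unit-norm PLS1 weight
    gene_symbols: list
    r_scores_y: float                   # corr(scores, y), >= 0 by orientation
    explained_covariance: float         # squared corr(scores, y)
    z: np.ndarray | None = None         # bootstrap ratio per gene
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    plus_list: list = field(default_factory=list)
    minus_list: list = field(default_factory=list)
    n_boot: int | None = None
    seed: int | None = None

    def gene_table(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene": self.gene_symbols,
                           "weight": self.weights})
        if self.z is not None:
            df["z"] = self.z
            df["p"] = self.p
            df["q"] = self.q
            df["list"] = ""
            df.loc[df["gene"].isin(self.plus_list), "list"] = "PLS1+"
            df.loc[df["gene"].isin(self.minus_list), "list"] = "PLS1-"
            df = df.reindex(df["z"].abs().sort_values(ascending=False).index)
        return df.reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "PLS1 transcriptomic decoding",
            "=" * 40,
            f"voxels: {self.scores.size}   genes: {len(self.gene_symbols)}",
            f"corr(PLS1 scores, map): {self.r_scores_y:.4f}",
            f"variance of map explained: {self.explained_covariance:.4f}",
        ]
        if self.z is not None:
            lines += [
                f"bootstrap resamples: {self.n_boot} (seed={self.seed})",
                f"PLS1+ genes (q < 0.05): {len(self.plus_list)}",
                f"PLS1- genes (q < 0.05): {len(self.minus_list)}",
            ]
            top = self.gene_table().head(5)
            lines.append("top |Z| genes: "
                         + ", ".join(f"{r.gene} (Z={r.z:.2f})"
                                     for r in top.itertuples()))
        return "\n".join(lines)

    def plot_scores(self, y: np.ndarray, ax=None):
        """Scatter of PLS1 voxel scores against the decoded map."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.scores, y, s=8, alpha=0.6)
        ax.set_xlabel("PLS1 score")
        ax.set_ylabel("intersubject variability")
        ax.set_title(f"r = {self.r_scores_y:.2f}")
        return ax


def pls1_fit(X, y, gene_symbols=None) -> PLSResults:
    """First PLS component of the gene expression matrix against a map.

    Columns of X and y are z-scored; weights are X'y normalized to unit
    length; scores are X w, sign-oriented so corr(scores, y) >= 0.
    ``X`` may be a DataFrame (columns are gene symbols) or an array.
    """
    if isinstance(X, pd.DataFrame):
        gene_symbols = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be voxels x genes aligned with y")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 voxels")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 genes")
    if y.std() == 0:
        raise ValueError("response map is constant")
    if gene_symbols is None:
        gene_symbols = [f"g{i}" for i in range(X.shape[1])]

    Xz = _zscore_columns(X)
    yz = (y - y.mean()) / y.std(ddof=1)
    w = _pls1_weights(Xz, yz)
    scores = Xz @ w
    r = float(np.corrcoef(scores, y)[0, 1])
    if r < 0:
        w, scores, r = -w, -scores, -r
    return PLSResults(scores=scores, weights=w,
                      gene_symbols=list(gene_symbols),
                      r_scores_y=r, explained_covariance=r ** 2)


def bootstrap_z(X, y, n_boot: int = 1000, seed: int | None = None
                ) -> np.ndarray:
    """Bootstrap ratio of each PLS1 gene weight.

    Voxels are resampled with replacement; each resampled weight vector
    is sign-aligned to the full-sample weights (flipped when the dot
    product is negative); Z_g is the full-sample weight divided by the
    bootstrap SD.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    V = X.shape[0]
    if V < 10:
        raise ValueError("need at least 10 voxels")
    full = pls1_fit(X, y)
    rng = np.random.default_rng(seed)
    W = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, V, size=V)
        Xb, yb = X[idx], y[idx]
        sd = Xb.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf                      # degenerate resample column
        Xb = (Xb - Xb.mean(axis=0)) / sd
        ysd = yb.std(ddof=1)
        if ysd == 0:
            W[b] = 0.0
            continue
        wb = _pls1_weights(Xb, (yb - yb.mean()) / ysd)
        if wb @ full.weights < 0:
            wb = -wb
        W[b] = wb
    se = W.std(axis=0, ddof=1)
    se[se == 0] = np.finfo(float).tiny
    return full.weights / se


def select_gene_lists(z: np.ndarray, gene_symbols, alpha: float = 0.05
                      ) -> tuple[list, list]:
    """FDR-selected PLS1+ / PLS1- gene lists from bootstrap ratios.

    Two-sided normal p per gene, BH-adjusted; genes with q < alpha are
    split by the sign of Z and returned in descending |Z| order.
    """
    z = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z)):
        raise ValueError("bootstrap ratios must be finite")
    symbols = np.asarray(list(gene_symbols))
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = fdr_bh(p)
    order = np.argsort(np.abs(z))[::-1]
    sig = q < alpha
    plus = [str(symbols[i]) for i in order if sig[i] and z[i] > 0]
    minus = [str(symbols[i]) for i in order if sig[i] and z[i] < 0]
    return plus, minus


class PLSModel:
    """PLS1 decoding model of a brain map against gene expression.

    Parameters
    ----------
    X : DataFrame or ndarray
        Voxels-by-genes expression; DataFrame columns are gene symbols.
    y : ndarray
        Voxelwise response map aligned with the rows of X.
    """

    def __init__(self, X, y, gene_symbols=None) -> None:
        if isinstance(X, pd.DataFrame):
            gene_symbols = list(X.columns)
            X = X.to_numpy(dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        self.gene_symbols = (list(gene_symbols) if gene_symbols is not None
                             else [f"g{i}" for i in range(self.X.shape[1])])

    @classmethod
    def from_dataframe(cls, expression: pd.DataFrame, y) -> "PLSModel":
        return cls(expression, y)

    def fit(self, n_boot: int = 1000, seed: int | None = None,
            alpha: float = 0.05) -> PLSResults:
        res = pls1_fit(self.X, self.y, gene_symbols=self.gene_symbols)
        res.z = bootstrap_z(self.X, self.y, n_boot=n_boot, seed=seed)
        res.p = 2.0 * stats.norm.sf(np.abs(res.z))
        res.q = fdr_bh(res.p)
        res.plus_list, res.minus_list = select_gene_lists(
            res.z, self.gene_symbols, alpha=alpha)
        res.n_boot, res.seed = n_boot, seed
        return res


def predictive_validation(session_maps: np.ndarray, X,
                          basis=None, n_surr: int = 1000,
                          seed: int | None = None) -> pd.DataFrame:
    """Leave-one-session-out predictive validation of the PLS1 model.

    For each held-out session the component is fit on the mean of the
    remaining sessions' adjusted maps and the predicted voxel scores are
    correlated with the held-out map.  Every session is rotated through
    as the test set (the last row is the train-on-first-sessions /
    test-on-last split).  When a Moran basis is supplied, each fold's r
    gets a surrogate p-value.
    """
    maps = np.asarray(session_maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("need at least 2 session maps (sessions x voxels)")
    T = maps.shape[0]
    rows = []
    for t in range(T):
        train = np.delete(np.arange(T), t)
        y_train = maps[train].mean(axis=0)
        res = pls1_fit(X, y_train)
        r = float(np.corrcoef(res.scores, maps[t])[0, 1])
        row = {"held_out_session": t, "n_train_sessions": T - 1, "r": r}
        if basis is not None:
            ens = msr_surrogates(maps[t], basis, n_surr, seed=seed)
            null_r = np.array([np.corrcoef(res.scores, s)[0, 1]
                               for s in ens.maps])
            row["p_moran"] = empirical_p(r, null_r)
        rows.append(row)
    return pd.DataFrame(rows)
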