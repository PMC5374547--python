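"""Plaid-model biclustering of the regulatory score matrix.

The plaid model represents a matrix as a sum of overlapping layers,

    Y_ij ~= theta0_ij + sum_k (mu_k + alpha_ik + beta_jk) * rho_ik * kappa_jk,

where ``rho`` and ``kappa`` are binary row/column memberships and each
layer's effects (mu, alpha, beta) follow a two-way ANOVA decomposition.
Layers are fitted greedily on the residuals of the previous ones:

1. memberships are initialised from sign splits of the leading singular
   vectors of the residual,
2. effects and memberships alternate — effects by least squares given the
   memberships, memberships by *binary least squares* given the effects
   (a row/column joins iff joining reduces the layer's residual sum of
   squares; an exactly-zero contribution resolves to non-membership),
3. rows/columns whose variation the layer explains poorly are released,
4. the layer is kept only if its explained sum of squares beats every one
   of ``shuffles`` refits on row-wise permuted copies of the residual
   (structure destroyed, marginals preserved).

The background layer theta0 is fitted by Tukey median polish (a minority
block cannot drag robust row/column effects, so no compensating stripes
leak into the residual), and after each accepted layer one backfitting
cycle re-estimates the background and all layer effects jointly.
Fitting stops at the first rejected layer.  Degenerate layers (fewer than
two rows or columns) are rejected regardless of significance — a sponge
module needs at least two mRNAs.

Rows are mRNAs and columns are miRNAs throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, BiclusterMixin
from sklearn.utils import check_array, check_random_state

_EPS = 1e-12


def _two_way(sub: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares two-way decomposition mu + alpha_i + beta_j of a submatrix."""
    mu = float(sub.mean())
    alpha = sub.mean(axis=1) - mu
    beta = sub.mean(axis=0) - mu
    return mu, alpha, beta


def _median_polish(z: np.ndarray, n_iter: int = 10) -> tuple[float, np.ndarray, np.ndarray]:
    """Tukey median polish: robust two-way fit for the background layer.

    A mean-based background fit lets an implanted block drag the row and
    column effects, leaving compensating stripes in the residual that later
    masquerade as layers; medians ignore a minority block.
    """
    r = z.copy()
    mu = 0.0
    alpha = np.zeros(z.shape[0])
    beta = np.zeros(z.shape[1])
    for _ in range(n_iter):
        rm = np.median(r, axis=1)
        alpha += rm
        r -= rm[:, None]
        cm = np.median(r, axis=0)
        beta += cm
        r -= cm[None, :]
    a_med = float(np.median(alpha))
    mu += a_med
    alpha -= a_med
    b_med = float(np.median(beta))
    mu += b_med
    beta -= b_med
    return mu, alpha, beta


@dataclass
class _Layer:
    rows: np.ndarray  # bool mask over all rows
    cols: np.ndarray  # bool mask over all cols
    mu: float
    alpha: np.ndarray  # effects for selected rows, in np.where(rows)[0] order
    beta: np.ndarray

    def theta(self) -> np.ndarray:
        return self.mu + self.alpha[:, None] + self.beta[None, :]

    @property
    def ss(self) -> float:
        return float((self.theta() ** 2).sum())

    def refit(self, resid: np.ndarray) -> None:
        sub = resid[np.ix_(self.rows, self.cols)]
        self.mu, self.alpha, self.beta = _two_way(sub)


class PlaidBiclustering(BiclusterMixin, BaseEstimator):
    """Greedy plaid-model biclustering with permutation-based layer selection.

    Parameters
    ----------
    max_layers : int, default=20
        Maximum number of layers fitted beyond the background.
    background : bool, default=True
        Fit and subtract a global two-way layer (mu0 + alpha_i0 + beta_j0)
        before searching for biclusters.
    row_release, col_release : float in [0, 1], default=0.7
        A member row (column) is released from a layer when the fraction of
        its within-layer sum of squares explained by the layer effects
        falls below this value.
    shuffles : int, default=3
        Number of row-wise permuted copies of the residual the layer must
        beat in explained sum of squares; 0 disables the test.
    iterations : int, default=10
        Alternating effect/membership update cycles per layer.
    random_state : int, RandomState or None
        Seeds the permutations; the fit is bit-reproducible given a seed.

    Attributes
    ----------
    rows_, columns_ : bool arrays of shape (n_layers, n_rows) / (n_layers, n_cols)
    layers_ : list of fitted layer objects (memberships and effects)
    background_ : (mu, alpha, beta) of the background layer, or None
    n_layers_ : int
    layer_ss_ : list of float, explained sum of squares per accepted layer
    residual_ss_ : list of float, residual sum of squares after the
        background and after each accepted layer (non-increasing)
    """

    def __init__(
        self,
        max_layers: int = 20,
        background: bool = True,
        row_release: float = 0.7,
        col_release: float = 0.7,
        shuffles: int = 3,
        iterations: int = 10,
        random_state=None,
    ):
        self.max_layers = max_layers
        self.background = background
        self.row_release = row_release
        self.col_release = col_release
        self.shuffles = shuffles
        self.iterations = iterations
        self.random_state = random_state

    # -- single-layer machinery -------------------------------------------

    def _grow_layer(self, z: np.ndarray, rho: np.ndarray, kappa: np.ndarray) -> _Layer | None:
        """Alternate binary-least-squares updates from an initial membership."""
        for _ in range(self.iterations):
            prev = (rho.copy(), kappa.copy())
            # effects given memberships
            sub = z[np.ix_(rho, kappa)]
            mu, _, beta = _two_way(sub)
            # rows: alpha estimated for every row, join iff it lowers layer SS
            zk = z[:, kappa]
            alpha_all = (zk - mu - beta[None, :]).mean(axis=1)
            theta = mu + alpha_all[:, None] + beta[None, :]
            gain = (2.0 * zk * theta - theta ** 2).sum(axis=1)
            rho = gain > 0.0
            if rho.sum() < 2:
                return None
            # columns: symmetric update given the new rows
            sub = z[np.ix_(rho, kappa)]
            mu, alpha, _ = _two_way(sub)
            zr = z[rho, :]
            beta_all = (zr - mu - alpha[:, None]).mean(axis=0)
            theta = mu + alpha[:, None] + beta_all[None, :]
            gain = (2.0 * zr * theta - theta ** 2).sum(axis=0)
            kappa = gain > 0.0
            if kappa.sum() < 2:
                return None
            if np.array_equal(rho, prev[0]) and np.array_equal(kappa, prev[1]):
                break

        # release pruning: drop rows/cols the layer explains poorly
        sub = z[np.ix_(rho, kappa)]
        mu, alpha, beta = _two_way(sub)
        resid = sub - (mu + alpha[:, None] + beta[None, :])
        tot = (sub ** 2).sum(axis=1)
        frac = np.where(tot > _EPS, 1.0 - (resid ** 2).sum(axis=1) / np.maximum(tot, _EPS), 1.0)
        keep_rows = frac >= self.row_release
        if keep_rows.sum() < 2:
            return None
        rho = rho.copy()
        rho[np.where(rho)[0][~keep_rows]] = False

        sub = z[np.ix_(rho, kappa)]
        mu, alpha, beta = _two_way(sub)
        resid = sub - (mu + alpha[:, None] + beta[None, :])
        tot = (sub ** 2).sum(axis=0)
        frac = np.where(tot > _EPS, 1.0 - (resid ** 2).sum(axis=0) / np.maximum(tot, _EPS), 1.0)
        keep_cols = frac >= self.col_release
        if keep_cols.sum() < 2:
            return None
        kappa = kappa.copy()
        kappa[np.where(kappa)[0][~keep_cols]] = False

        sub = z[np.ix_(rho, kappa)]
        mu, alpha, beta = _two_way(sub)
        return _Layer(rows=rho, cols=kappa, mu=mu, alpha=alpha, beta=beta)

    def _fit_layer(self, z: np.ndarray) -> _Layer | None:
        """Best layer over sign-split initialisations of the top singular vectors.

        Two singular pairs are tried because equally deep disjoint blocks
        make the leading pair rotationally degenerate: a single-vector
        start then merges the blocks into a union layer that release
        pruning destroys, while the second vector's sign split separates
        them.
        """
        if float((z ** 2).sum()) < _EPS:
            return None
        n_comp = min(2, min(z.shape))
        u, _, vt = np.linalg.svd(z, full_matrices=False)
        best: _Layer | None = None
        for k in range(n_comp):
            for rsel in (u[:, k] > 0.0, u[:, k] < 0.0):
                if rsel.sum() < 2:
                    continue
                for csel in (vt[k] > 0.0, vt[k] < 0.0):
                    if csel.sum() < 2:
                        continue
                    layer = self._grow_layer(z, rsel.copy(), csel.copy())
                    if layer is not None and (best is None or layer.ss > best.ss):
                        best = layer
        return best

    @staticmethod
    def _permute_rows(z: np.ndarray, rng) -> np.ndarray:
        out = np.empty_like(z)
        n = z.shape[1]
        for i in range(z.shape[0]):
            out[i] = z[i, rng.permutation(n)]
        return out

    def _backfit(self, x: np.ndarray, bg, layers: list[_Layer]):
        """One cycle of joint re-estimation of background and layer effects."""
        def embed(layer: _Layer) -> np.ndarray:
            full = np.zeros_like(x)
            full[np.ix_(layer.rows, layer.cols)] = layer.theta()
            return full

        layer_sum = sum((embed(l) for l in layers), np.zeros_like(x))
        if bg is not None:
            mu0, a0, b0 = _median_polish(x - layer_sum)
            bg = (mu0, a0, b0)
            bg_full = mu0 + a0[:, None] + b0[None, :]
        else:
            bg_full = np.zeros_like(x)
        for layer in layers:
            others = layer_sum - embed(layer)
            layer.refit(x - bg_full - others)
            layer_sum = others + embed(layer)
        z = x - bg_full - layer_sum
        return bg, z

    # -- public API --------------------------------------------------------

    def fit(self, X, y=None):
        x = check_array(
            X, dtype=float, ensure_min_samples=2, ensure_min_features=2,
            ensure_all_finite=False,
        )
        if not np.isfinite(x).all():
            raise ValueError("input matrix contains missing entries; impute first")
        rng = check_random_state(self.random_state)
        if self.max_layers < 1:
            raise ValueError("max_layers must be >= 1")

        if self.background:
            mu0, a0, b0 = _median_polish(x)
            bg = (mu0, a0, b0)
            z = x - (mu0 + a0[:, None] + b0[None, :])
        else:
            bg = None
            z = x.copy()

        layers: list[_Layer] = []
        layer_ss: list[float] = []
        residual_ss = [float((z ** 2).sum())]
        for _ in range(self.max_layers):
            layer = self._fit_layer(z)
            if layer is None:
                break
            if self.shuffles > 0:
                null_ss = []
                for _ in range(self.shuffles):
                    zp = self._permute_rows(z, rng)
                    lp = self._fit_layer(zp)
                    null_ss.append(0.0 if lp is None else lp.ss)
                if layer.ss <= max(null_ss):
                    break
            layers.append(layer)
            layer_ss.append(layer.ss)
            z[np.ix_(layer.rows, layer.cols)] -= layer.theta()
            bg, z = self._backfit(x, bg, layers)
            residual_ss.append(float((z ** 2).sum()))

        m, n = x.shape
        self.layers_ = layers
        self.background_ = bg
        self.n_layers_ = len(layers)
        self.layer_ss_ = layer_ss
        self.residual_ss_ = residual_ss
        if layers:
            self.rows_ = np.vstack([l.rows for l in layers])
            self.columns_ = np.vstack([l.cols for l in layers])
        else:
            self.rows_ = np.zeros((0, m), dtype=bool)
            self.columns_ = np.zeros((0, n), dtype=bool)
        return self


# ---------------------------------------------------------------------------
# id-aware wrappers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bicluster:
    """A fitted layer mapped back to mRNA/miRNA identifiers."""

    mrna_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    mu: float = 0.0
    alpha: tuple[float, ...] = field(default_factory=tuple)
    beta: tuple[float, ...] = field(default_factory=tuple)
    layer_index: int = 1

    def __post_init__(self) -> None:
        if not self.mrna_ids or not self.mirna_ids:
            raise ValueError("a bicluster needs non-empty row and column sets")


def fit_plaid(scores: pd.DataFrame, **config) -> list[Bicluster]:
    """Fit :class:`PlaidBiclustering` to a score DataFrame and return labelled layers.

    ``config`` forwards to the estimator (max_layers, background,
    row_release, col_release, shuffles, iterations, random_state).
    """
    model = PlaidBiclustering(**config).fit(scores.to_numpy(dtype=float))
    out = []
    for k, layer in enumerate(model.layers_, start=1):
        out.append(
            Bicluster(
                mrna_ids=tuple(str(i) for i in scores.index[layer.rows]),
                mirna_ids=tuple(str(c) for c in scores.columns[layer.cols]),
                mu=layer.mu,
                alpha=tuple(layer.alpha),
                beta=tuple(layer.beta),
                layer_index=k,
            )
        )
    return out


def bicluster_summary(biclusters: Sequence[Bicluster]) -> pd.DataFrame:
    """Per-layer sizes and effect magnitudes."""
    rows = []
    for b in biclusters:
        theta = b.mu + np.add.outer(np.asarray(b.alpha), np.asarray(b.beta))
        rows.append(
            {
                "layer": b.layer_index,
                "n_mrnas": len(b.mrna_ids),
                "n_mirnas": len(b.mirna_ids),
                "mu": b.mu,
                "mean_abs_effect": float(np.abs(theta).mean()) if theta.size else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["layer", "n_mrnas", "n_mirnas", "mu", "mean_abs_effect"])


def write_biclusters(biclusters: Sequence[Bicluster], path: str | Path) -> None:
    """Two-line block per layer: mRNA ids, then miRNA ids (tab-separated)."""
    with open(path, "w") as fh:
        for b in biclusters:
            fh.write(f"# layer {b.layer_index} mu={b.mu:.6g}\n")
            fh.write("\t".join(b.mrna_ids) + "\n")
            fh.write("\t".join(b.mirna_ids) + "\n")


def read_biclusters(path: str | Path) -> list[Bicluster]:
    """Read the two-block format back (effects are not round-tripped)."""
    out: list[Bicluster] = []
    lines = [l.rstrip("\n") for l in open(path) if l.strip()]
    block: list[str] = []
    for line in lines:
        if line.startswith("#"):
            continue
        block.append(line)
        if len(block) == 2:
            out.append(
                Bicluster(
                    mrna_ids=tuple(block[0].split("\t")),
                    mirna_ids=tuple(block[1].split("\t")),
                    layer_index=len(out) + 1,
                )
            )
            block = []
    if block:
        raise ValueError(f"{path}: trailing incomplete bicluster block")
    return out
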