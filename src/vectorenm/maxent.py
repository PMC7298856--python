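"""Presence-background maximum-entropy niche model.

The model estimates a Gibbs distribution over background (accessible
area) cells,

    P(x) = exp(lambda . f(x)) / Z,   Z = sum_background exp(lambda . f(x)),

whose feature expectations match those of the presence sample, subject
to per-feature L1 penalties.  The fitted weights maximize the penalized
log-likelihood

    sum_presences log P(x_i)  -  sum_j beta_j |lambda_j| ,

where beta_j = RM * beta_class(n) * sd_j(presences) / sqrt(n) follows
the published Maxent default regularization scheme and RM is the
user-facing regularization multiplier.  Optimization is by monotone
proximal-gradient descent (ISTA with backtracking line search), which
reaches the same optimum family as the classic sequential-update
algorithm; bit-compatibility with the Maxent java release is a
non-goal.

Feature classes follow the standard l/q/p/t/h expansion: linear,
quadratic, pairwise products, step ("threshold") indicators, and
forward/reverse hinges, with knots at training-background deciles by
default.  All features are affinely rescaled to [0, 1] on the training
background.

Usage mirrors statsmodels: build a :class:`MaxentNiche` from presence
and background environment tables, call :meth:`~MaxentNiche.fit`, and
work with the returned :class:`MaxentResults` (weights, entropy,
``predict``, ``summary``).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .grids import LayerStack

__all__ = ["FeatureExpansion", "MaxentNiche", "MaxentResults", "build_features"]

VALID_CLASSES = set("lqpth")

# Published Maxent default base penalties, interpolated in the presence
# sample size n (clamped at the table ends).
_BETA_TABLES = {
    "lq": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "lqp": ([0, 10, 17, 30, 100, 200], [2.6, 1.6, 0.9, 0.55, 0.25, 0.05]),
    "t": ([0, 100], [2.0, 1.0]),
    "h": ([0, 1], [0.5, 0.5]),
}


def _beta_class(table: str, n: int) -> float:
    xs, ys = _BETA_TABLES[table]
    return float(np.interp(n, xs, ys))


@dataclasses.dataclass(frozen=True)
class _FeatureDef:
    kind: str               # 'l', 'q', 'p', 't', 'h+', 'h-'
    variables: tuple[str, ...]
    knot: float | None = None

    @property
    def name(self) -> str:
        if self.kind == "l":
            return self.variables[0]
        if self.kind == "q":
            return f"{self.variables[0]}^2"
        if self.kind == "p":
            return f"{self.variables[0]}*{self.variables[1]}"
        if self.kind == "t":
            return f"({self.variables[0]}>{self.knot:.6g})"
        side = "fwd" if self.kind == "h+" else "rev"
        return f"hinge_{side}({self.variables[0]}@{self.knot:.6g})"


class FeatureExpansion:
    """Deterministic l/q/p/t/h feature expansion with training-set scaling.

    Built from the training background; raw features are rescaled to
    [0, 1] using background min/max, and each source variable's training
    range is recorded so predictions can clamp transfer environments.
    """

    def __init__(
        self,
        background: np.ndarray,
        var_names: Sequence[str],
        classes: str = "lq",
        knots: int = 9,
    ) -> None:
        classes = "".join(sorted(set(classes)))
        if not classes or not set(classes) <= VALID_CLASSES:
            raise ValueError(f"classes must be a non-empty subset of 'lqpth', got {classes!r}")
        background = np.asarray(background, float)
        if background.ndim != 2 or background.shape[1] != len(var_names):
            raise ValueError("background must be (n_cells, n_vars)")
        if not np.all(np.isfinite(background)):
            raise ValueError("non-finite values in background environment")
        v = len(var_names)
        if "p" in classes and v < 2 and classes == "p":
            raise ValueError("product features require at least 2 variables")
        if knots < 1:
            raise ValueError("knots must be >= 1")
        self.var_names = list(var_names)
        self.classes = classes
        self.knots = knots
        self.var_min = background.min(axis=0)
        self.var_max = background.max(axis=0)
        self.defs: list[_FeatureDef] = []
        qs = np.linspace(0, 1, knots + 2)[1:-1]  # interior deciles for knots=9
        for j, name in enumerate(self.var_names):
            if "l" in classes:
                self.defs.append(_FeatureDef("l", (name,)))
        for j, name in enumerate(self.var_names):
            if "q" in classes:
                self.defs.append(_FeatureDef("q", (name,)))
        if "p" in classes:
            for a in range(v):
                for b in range(a + 1, v):
                    self.defs.append(
                        _FeatureDef("p", (self.var_names[a], self.var_names[b]))
                    )
        if "t" in classes:
            for j, name in enumerate(self.var_names):
                for k in np.quantile(background[:, j], qs):
                    self.defs.append(_FeatureDef("t", (name,), float(k)))
        if "h" in classes:
            for j, name in enumerate(self.var_names):
                for k in np.quantile(background[:, j], qs):
                    self.defs.append(_FeatureDef("h+", (name,), float(k)))
                    self.defs.append(_FeatureDef("h-", (name,), float(k)))
        raw = self._raw(background)
        self.f_min = raw.min(axis=0)
        self.f_max = raw.max(axis=0)
        span = self.f_max - self.f_min
        self._span = np.where(span > 0, span, 1.0)
        self._degenerate = span <= 0

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.defs]

    def __len__(self) -> int:
        return len(self.defs)

    def _raw(self, X: np.ndarray) -> np.ndarray:
        cols = {n: X[:, j] for j, n in enumerate(self.var_names)}
        out = np.empty((X.shape[0], len(self.defs)))
        for i, d in enumerate(self.defs):
            if d.kind == "l":
                out[:, i] = cols[d.variables[0]]
            elif d.kind == "q":
                out[:, i] = cols[d.variables[0]] ** 2
            elif d.kind == "p":
                out[:, i] = cols[d.variables[0]] * cols[d.variables[1]]
            elif d.kind == "t":
                out[:, i] = (cols[d.variables[0]] > d.knot).astype(float)
            elif d.kind == "h+":
                out[:, i] = np.maximum(cols[d.variables[0]] - d.knot, 0.0)
            else:  # 'h-'
                out[:, i] = np.maximum(d.knot - cols[d.variables[0]], 0.0)
        return out

    def transform(self, X: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Feature matrix scaled to the training-background [0, 1] range."""
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.var_names):
            raise ValueError("wrong number of variables")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in environment table")
        if clamp:
            X = np.clip(X, self.var_min, self.var_max)
        raw = self._raw(X)
        F = (raw - self.f_min) / self._span
        F[:, self._degenerate] = 0.0
        return F

    def beta_base(self, n_presence: int) -> np.ndarray:
        """Per-feature base penalty (before the RM multiplier and sd scaling)."""
        out = np.empty(len(self.defs))
        lq_table = "lqp" if "p" in self.classes else "lq"
        for i, d in enumerate(self.defs):
            if d.kind in ("l", "q", "p"):
                out[i] = _beta_class(lq_table, n_presence)
            elif d.kind == "t":
                out[i] = _beta_class("t", n_presence)
            else:
                out[i] = _beta_class("h", n_presence)
        return out


def build_features(
    background: np.ndarray,
    var_names: Sequence[str],
    classes: str = "lq",
    knots: int = 9,
) -> FeatureExpansion:
    """Convenience constructor for :class:`FeatureExpansion`."""
    return FeatureExpansion(background, var_names, classes, knots)


class MaxentNiche:
    """Presence-background maximum-entropy model (statsmodels-style).

    Parameters
    ----------
    presence : (n, v) array
        Environmental values at presence cells.
    background : (m, v) array
        Environmental values at background (accessible-area) cells.
    var_names : sequence of str
    classes : str
        Feature classes, subset of ``"lqpth"``.
    knots : int
        Knots per variable for threshold/hinge features (default 9,
        the training-background deciles).
    """

    def __init__(
        self,
        presence: np.ndarray,
        background: np.ndarray,
        var_names: Sequence[str],
        classes: str = "lq",
        knots: int = 9,
    ) -> None:
        presence = np.asarray(presence, float)
        background = np.asarray(background, float)
        if presence.ndim != 2 or presence.shape[0] < 2:
            raise ValueError("need at least 2 presence records")
        if not np.all(np.isfinite(presence)):
            raise ValueError("non-finite values in presence environment")
        self.presence = presence
        self.background = background
        self.var_names = list(var_names)
        self.features = FeatureExpansion(background, var_names, classes, knots)
        self._F_bg = self.features.transform(background)
        self._F_pres = self.features.transform(presence, clamp=True)

    @classmethod
    def from_stack(
        cls,
        stack: LayerStack,
        presence_lonlat: np.ndarray,
        classes: str = "lq",
        knots: int = 9,
        max_background: int = 10_000,
        seed: int = 0,
    ) -> "MaxentNiche":
        """Build from a (cropped) layer stack and presence coordinates.

        Background is every valid cell of the stack, subsampled uniformly
        to ``max_background`` cells when larger (seeded).
        """
        rows, cols = np.where(stack.mask)
        if len(rows) > max_background:
            rng = np.random.default_rng(seed)
            pick = rng.choice(len(rows), size=max_background, replace=False)
            rows, cols = rows[pick], cols[pick]
        bg = stack.values_at(rows, cols)
        pr, pc = zip(
            *(stack.grid.cell_of(lon, lat) for lon, lat in np.asarray(presence_lonlat))
        )
        pres = stack.values_at(np.array(pr), np.array(pc))
        return cls(pres, bg, stack.names, classes, knots)

    def fit(
        self,
        rm: float = 1.0,
        max_iter: int = 500,
        tol: float = 1e-6,
    ) -> "MaxentResults":
        """Fit by monotone proximal-gradient (ISTA with backtracking).

        The penalized objective is non-increasing across iterations by
        construction of the line search; non-convergence within
        ``max_iter`` produces a warning and a flagged result, never a
        silent success.
        """
        if rm <= 0:
            raise ValueError("regularization multiplier must be positive")
        Fb, Fp = self._F_bg, self._F_pres
        n = Fp.shape[0]
        pres_mean = Fp.mean(axis=0)
        sd = np.maximum(Fp.std(axis=0), 1e-3)
        beta = rm * self.features.beta_base(n) * sd / np.sqrt(n)

        lam = np.zeros(Fb.shape[1])

        def smooth(l: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
            eta = Fb @ l
            logz = logsumexp(eta)
            p = np.exp(eta - logz)
            g = Fb.T @ p - pres_mean
            return logz - l @ pres_mean, g, p

        f_val, grad, _ = smooth(lam)
        obj = f_val + beta @ np.abs(lam)
        history = [obj]
        step = 1.0
        converged = False
        for _ in range(max_iter):
            while True:
                z = lam - step * grad
                new = np.sign(z) * np.maximum(np.abs(z) - step * beta, 0.0)
                d = new - lam
                f_new, g_new, _ = smooth(new)
                # sufficient-decrease (majorization) condition
                if f_new <= f_val + grad @ d + (d @ d) / (2 * step) + 1e-12:
                    break
                step *= 0.5
                if step < 1e-12:
                    new, f_new, g_new = lam, f_val, grad
                    break
            obj_new = f_new + beta @ np.abs(new)
            history.append(min(obj_new, history[-1]))
            delta = history[-2] - obj_new
            lam, f_val, grad = new, f_new, g_new
            step = min(step * 2.0, 1e6)
            if 0 <= delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"maxent solver did not converge in {max_iter} iterations "
                f"(last objective change {delta:.3g})"
            )
        eta_bg = Fb @ lam
        logz = float(logsumexp(eta_bg))
        p_bg = np.exp(eta_bg - logz)
        entropy = float(-(p_bg * np.log(np.maximum(p_bg, 1e-300))).sum())
        return MaxentResults(
            model=self,
            params=lam,
            rm=rm,
            beta=beta,
            log_partition=logz,
            entropy=entropy,
            converged=converged,
            objective_history=np.array(history),
        )


@dataclasses.dataclass
class MaxentResults:
    """Fitted maximum-entropy niche model.

    Attributes
    ----------
    params : array
        L1-penalized feature weights (lambdas).
    log_partition : float
        log Z over the training background; raw predictions are
        ``exp(lambda . f(x) - log_partition)`` and sum to one over the
        training background.
    entropy : float
        Shannon entropy H of the fitted background distribution; the
        cloglog output is ``1 - exp(-exp(H) * raw)``.
    """

    model: MaxentNiche
    params: np.ndarray
    rm: float
    beta: np.ndarray
    log_partition: float
    entropy: float
    converged: bool
    objective_history: np.ndarray

    @property
    def feature_names(self) -> list[str]:
        return self.model.features.names

    @property
    def n_presence(self) -> int:
        return self.model.presence.shape[0]

    @property
    def n_background(self) -> int:
        return self.model.background.shape[0]

    def count_parameters(self, atol: float = 1e-8) -> int:
        """Number of features with non-zero weight (the k of AICc)."""
        return int((np.abs(self.params) > atol).sum())

    # ------------------------------------------------------------ prediction

    def predict(
        self,
        X: np.ndarray | LayerStack,
        scale: str = "cloglog",
        clamp: bool = True,
    ) -> np.ndarray:
        """Predict suitability for an environment table or a layer stack.

        ``scale='raw'`` gives the Gibbs probability normalized over the
        *training* background; ``'cloglog'`` maps it to [0, 1].  For a
        LayerStack input the result is a raster (NaN outside the mask);
        the stack must contain every model variable.  ``clamp`` limits
        each variable to its training-background range before feature
        expansion (the standard transfer convention).
        """
        if scale not in ("raw", "cloglog"):
            raise ValueError("scale must be 'raw' or 'cloglog'")
        if isinstance(X, LayerStack):
            missing = [v for v in self.model.var_names if v not in X]
            if missing:
                raise KeyError(f"stack is missing model variable(s): {missing}")
            rows, cols = np.where(X.mask)
            tbl = np.column_stack([X[v][rows, cols] for v in self.model.var_names])
            vals = self.predict(tbl, scale=scale, clamp=clamp)
            out = np.full(X.grid.shape, np.nan)
            out[rows, cols] = vals
            return out
        F = self.model.features.transform(np.asarray(X, float), clamp=clamp)
        raw = np.exp(F @ self.params - self.log_partition)
        if scale == "raw":
            return raw
        return 1.0 - np.exp(-np.exp(self.entropy) * raw)

    def training_gain(self) -> float:
        """Unpenalized mean log-likelihood improvement over the uniform model."""
        Fp = self.model._F_pres
        ll = (Fp @ self.params).mean() - self.log_partition
        return float(ll + np.log(self.n_background))

    # ------------------------------------------------------------- reporting

    def summary(self) -> str:
        lines = [
            "Maximum-entropy niche model",
            "=" * 44,
            f"presences:        {self.n_presence}",
            f"background cells: {self.n_background}",
            f"feature classes:  {self.model.features.classes}",
            f"features:         {len(self.params)}",
            f"nonzero weights:  {self.count_parameters()}",
            f"regularization multiplier: {self.rm}",
            f"log partition:    {self.log_partition:.6f}",
            f"entropy H:        {self.entropy:.6f}",
            f"training gain:    {self.training_gain():.6f}",
            f"converged:        {self.converged}",
            "-" * 44,
            f"{'feature':<28} {'weight':>12}",
        ]
        for name, w in zip(self.feature_names, self.params):
            if abs(w) > 1e-8:
                lines.append(f"{name:<28} {w:>12.6f}")
        return "\n".join(lines)

    def plot_response(self, variable: str, ax=None, n_points: int = 200):
        """Marginal response curve: cloglog suitability along one variable
        with the others held at their background means. Requires matplotlib."""
        import matplotlib.pyplot as plt

        if variable not in self.model.var_names:
            raise KeyError(f"unknown variable {variable!r}")
        j = self.model.var_names.index(variable)
        bg = self.model.background
        X = np.tile(bg.mean(axis=0), (n_points, 1))
        X[:, j] = np.linspace(bg[:, j].min(), bg[:, j].max(), n_points)
        y = self.predict(X, scale="cloglog")
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(X[:, j], y)
        ax.set_xlabel(variable)
        ax.set_ylabel("suitability (cloglog)")
        return ax

    # ---------------------------------------------------------- persistence

    def to_json(self, path: str | Path | None = None) -> str:
        feats = self.model.features
        payload = {
            "var_names": self.model.var_names,
            "classes": feats.classes,
            "knots": feats.knots,
            "rm": self.rm,
            "log_partition": self.log_partition,
            "entropy": self.entropy,
            "converged": self.converged,
            "features": [
                {
                    "name": d.name,
                    "kind": d.kind,
                    "variables": list(d.variables),
                    "knot": d.knot,
                    "weight": float(w),
                    "scale_min": float(lo),
                    "scale_max": float(hi),
                }
                for d, w, lo, hi in zip(feats.defs, self.params, feats.f_min, feats.f_max)
            ],
            "var_min": feats.var_min.tolist(),
            "var_max": feats.var_max.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text
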