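"""Presence-background maximum-entropy species distribution model.

The model estimates the Gibbs distribution of maximum entropy over the
background landscape subject to soft constraints that tie model feature
expectations to their presence-sample means.  With features f(x) and
coefficients lambda, the penalised log likelihood over m presences and a
background sample B is

    L(lambda) = mean_presence[lambda . f(x)] - log Z - sum_j beta_j |lambda_j|
    Z         = sum_{x in B} exp(lambda . f(x))

which is concave; the L1 penalties beta_j follow the classic MaxEnt defaults
(class- and sample-size-dependent base values scaled by the presence SD of
each feature and 1/sqrt(m)), times a user regularisation multiplier.

Features are the standard linear / quadratic / hinge basis, all mapped to
[0, 1] using covariate bounds recorded at training time; prediction clamps
covariates to those bounds, leaving extrapolation to the transfer
diagnostics instead of the exponential model.

Outputs: ``raw`` (the Gibbs density over the background, summing to one),
``cloglog`` 1 - exp(-e^H r(x)) and ``logistic`` e^H r/(1 + e^H r), where H is
the entropy of the fitted background distribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .geodata import GeodataError, Layer, OccurrenceSet, Stack, occurrence_cells

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("L", "Q", "H")
#: candidate feature-class combinations explored during model selection
CLASS_COMBOS = ("L", "Q", "H", "LQ", "LH", "QH", "LQH")


class MaxentError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """Optimiser failed to reach the projected-gradient tolerance."""

    def __init__(self, grad_norm: float, tol: float, n_iter: int):
        self.grad_norm = grad_norm
        super().__init__(
            f"MaxEnt fit did not converge: projected gradient {grad_norm:.3e} "
            f"> tol {tol:.1e} after {n_iter} iterations"
        )


# ---------------------------------------------------------------------------
# features


@dataclass
class FeatureSet:
    """Feature construction recipe frozen at training time.

    ``classes`` is a subset of "LQH".  Bounds come from the union of presence
    and background training rows; hinge knots are equally spaced strictly
    inside the bounds, ``k_h`` per direction per covariate.
    """

    classes: str
    covariate_names: list[str]
    bounds: dict[str, tuple[float, float]]
    hinge_knots: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [c for c in self.classes if c not in FEATURE_CLASSES]
        if bad or not self.classes:
            raise MaxentError(f"feature classes must be a non-empty subset of L/Q/H, got {self.classes!r}")
        for name in self.covariate_names:
            lo, hi = self.bounds[name]
            if not lo < hi:
                raise MaxentError(f"covariate {name!r} has degenerate bounds [{lo}, {hi}]")

    @classmethod
    def build(
        cls,
        X: np.ndarray,
        covariate_names: Sequence[str],
        classes: str = "LQH",
        k_h: int = 20,
    ) -> "FeatureSet":
        """Derive bounds and knots from training covariate rows (n x p)."""
        X = np.asarray(X, dtype=float)
        names, bounds, knots = [], {}, {}
        for j, name in enumerate(covariate_names):
            lo, hi = float(np.min(X[:, j])), float(np.max(X[:, j]))
            if lo == hi:
                logger.warning("covariate %r is constant over training rows; dropped", name)
                continue
            names.append(name)
            bounds[name] = (lo, hi)
            if "H" in classes:
                knots[name] = lo + (np.arange(1, k_h + 1) / (k_h + 1)) * (hi - lo)
        if not names:
            raise MaxentError("all covariates are constant")
        return cls(classes, names, bounds, knots)

    def feature_names(self) -> list[str]:
        out: list[str] = []
        for name in self.covariate_names:
            if "L" in self.classes:
                out.append(f"L:{name}")
            if "Q" in self.classes:
                out.append(f"Q:{name}")
            if "H" in self.classes:
                out.extend(f"HF:{name}:{t:g}" for t in self.hinge_knots[name])
                out.extend(f"HR:{name}:{t:g}" for t in self.hinge_knots[name])
        return out

    def feature_types(self) -> list[str]:
        """Per-feature class tag ('L', 'Q' or 'H'), aligned with feature_names."""
        out: list[str] = []
        for name in self.covariate_names:
            if "L" in self.classes:
                out.append("L")
            if "Q" in self.classes:
                out.append("Q")
            if "H" in self.classes:
                out.extend(["H"] * (2 * len(self.hinge_knots[name])))
        return out

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map covariate rows (n x p, in covariate_names order) to features in [0, 1].

        Covariates are clamped to the training bounds first.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.covariate_names):
            raise MaxentError(
                f"expected {len(self.covariate_names)} covariate columns, got {X.shape}"
            )
        cols: list[np.ndarray] = []
        for j, name in enumerate(self.covariate_names):
            lo, hi = self.bounds[name]
            x = np.clip(X[:, j], lo, hi)
            lin = (x - lo) / (hi - lo)
            if "L" in self.classes:
                cols.append(lin)
            if "Q" in self.classes:
                cols.append(lin**2)
            if "H" in self.classes:
                for t in self.hinge_knots[name]:
                    cols.append(np.maximum(0.0, (x - t) / (hi - t)))
                for t in self.hinge_knots[name]:
                    cols.append(np.maximum(0.0, (t - x) / (t - lo)))
        return np.column_stack(cols)


# Classic MaxEnt default regularisation tables: (sample size, base beta)
# interpolated linearly in m and clamped at the ends.
_BETA_TABLES = {
    "L": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "LQ": ([10, 17, 30, 100], [1.3, 0.8, 0.5, 0.05]),
    "H": ([0, 1], [0.5, 0.5]),
}


def _base_beta(feature_type: str, classes: str, m: int) -> float:
    if feature_type == "H":
        table = _BETA_TABLES["H"]
    elif "Q" in classes:
        table = _BETA_TABLES["LQ"]
    else:
        table = _BETA_TABLES["L"]
    return float(np.interp(m, table[0], table[1]))


def default_penalties(
    presence_features: np.ndarray, feature_types: Sequence[str], classes: str, rm: float
) -> np.ndarray:
    """Per-feature L1 penalties: rm * base(class, m) * s_j / sqrt(m).

    s_j is the presence-sample SD of feature j, floored at 1e-4 so that
    near-constant features still carry a nonzero penalty.
    """
    if rm <= 0:
        raise MaxentError("regularisation multiplier must be positive")
    m = presence_features.shape[0]
    s = presence_features.std(axis=0, ddof=1) if m > 1 else np.zeros(presence_features.shape[1])
    s = np.maximum(s, 1e-4)
    base = np.array([_base_beta(t, classes, m) for t in feature_types])
    return rm * base * s / np.sqrt(m)


# ---------------------------------------------------------------------------
# model


@dataclass
class MaxentModel:
    features: FeatureSet
    coefficients: np.ndarray
    reg_multiplier: float
    penalties: np.ndarray
    log_partition: float  # log Z over the training background
    entropy: float  # entropy H of the fitted background distribution
    output: str = "cloglog"
    n_background: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.penalties = np.asarray(self.penalties, dtype=float)
        if self.output not in ("raw", "cloglog", "logistic"):
            raise MaxentError(f"unknown output transform {self.output!r}")

    # -- prediction ---------------------------------------------------------

    def raw_from_features(self, F: np.ndarray) -> np.ndarray:
        return np.exp(F @ self.coefficients - self.log_partition)

    def predict_matrix(self, X: np.ndarray, output: str | None = None) -> np.ndarray:
        """Predict from covariate rows (clamped to training bounds)."""
        raw = self.raw_from_features(self.features.transform(X))
        return self._transform(raw, output or self.output)

    def _transform(self, raw: np.ndarray, output: str) -> np.ndarray:
        if output == "raw":
            return raw
        scaled = np.exp(self.entropy) * raw
        if output == "cloglog":
            return 1.0 - np.exp(-scaled)
        if output == "logistic":
            return scaled / (1.0 + scaled)
        raise MaxentError(f"unknown output transform {output!r}")

    # -- serialisation ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "classes": self.features.classes,
            "covariate_names": self.features.covariate_names,
            "bounds": {k: list(v) for k, v in self.features.bounds.items()},
            "hinge_knots": {k: v.tolist() for k, v in self.features.hinge_knots.items()},
            "coefficients": self.coefficients.tolist(),
            "reg_multiplier": self.reg_multiplier,
            "penalties": self.penalties.tolist(),
            "log_partition": self.log_partition,
            "entropy": self.entropy,
            "output": self.output,
            "n_background": self.n_background,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MaxentModel":
        doc = json.loads(Path(path).read_text())
        fs = FeatureSet(
            classes=doc["classes"],
            covariate_names=list(doc["covariate_names"]),
            bounds={k: tuple(v) for k, v in doc["bounds"].items()},
            hinge_knots={k: np.array(v) for k, v in doc["hinge_knots"].items()},
        )
        return cls(
            features=fs,
            coefficients=np.array(doc["coefficients"]),
            reg_multiplier=float(doc["reg_multiplier"]),
            penalties=np.array(doc["penalties"]),
            log_partition=float(doc["log_partition"]),
            entropy=float(doc["entropy"]),
            output=doc["output"],
            n_background=int(doc["n_background"]),
        )


# ---------------------------------------------------------------------------
# fitting


def penalized_objective(
    lam: np.ndarray, F_pres: np.ndarray, F_bg: np.ndarray, betas: np.ndarray
) -> float:
    """The concave penalised log likelihood L(lambda) (to be maximised)."""
    return float(
        np.mean(F_pres @ lam) - logsumexp(F_bg @ lam) - np.sum(betas * np.abs(lam))
    )


def _smooth_neg(lam, F_pres, F_bg, pres_mean):
    """-(smooth part) and its gradient: logsumexp over background minus presence mean."""
    scores = F_bg @ lam
    lz = logsumexp(scores)
    q = np.exp(scores - lz)
    value = lz - pres_mean @ lam
    grad = F_bg.T @ q - pres_mean
    return value, grad, lz, q


def fit_maxent(
    F_pres: np.ndarray,
    F_bg: np.ndarray,
    betas: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 5000,
) -> tuple[np.ndarray, float, float]:
    """Maximise the L1-penalised Gibbs likelihood.

    Solved as a box-constrained smooth problem via the positive/negative
    split lambda = u - v (u, v >= 0), which is exactly equivalent to the
    penalised problem and lets L-BFGS-B drive the projected gradient to
    tolerance.  Returns (coefficients, log_partition, entropy).

    Raises :class:`ConvergenceError` if the projected gradient of the
    original L1 problem still exceeds ``tol`` at the returned point.
    """
    if F_pres.ndim != 2 or F_bg.ndim != 2 or F_pres.shape[1] != F_bg.shape[1]:
        raise MaxentError("presence/background feature matrices are incompatible")
    if F_pres.shape[0] < 1 or F_bg.shape[0] < 2:
        raise MaxentError("need >= 1 presence and >= 2 background rows")
    k = F_pres.shape[1]
    betas = np.asarray(betas, dtype=float)
    pres_mean = F_pres.mean(axis=0)

    def fun(z):
        u, v = z[:k], z[k:]
        val, grad, _, _ = _smooth_neg(u - v, F_pres, F_bg, pres_mean)
        val += betas @ (u + v)
        return val, np.concatenate([grad + betas, -grad + betas])

    def l1_residual(lam: np.ndarray):
        """Projected gradient of the original L1 problem (optimality residual)."""
        _, grad, lz, q = _smooth_neg(lam, F_pres, F_bg, pres_mean)
        pg = np.where(
            lam != 0,
            grad + betas * np.sign(lam),
            np.sign(grad) * np.maximum(np.abs(grad) - betas, 0.0),
        )
        return (float(np.max(np.abs(pg))) if k else 0.0), lz, q

    z0 = np.zeros(2 * k)
    n_iter = 0
    # restarts clear the quasi-Newton memory, which recovers from line-search
    # stalls on kinked coordinates (L-BFGS-B can report an ftol stop while the
    # L1 optimality residual is still large)
    for _ in range(8):
        res = minimize(
            fun,
            z0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0, None)] * (2 * k),
            options={"maxiter": max_iter, "maxfun": 10 * max_iter, "ftol": 1e-14,
                     "gtol": tol, "maxcor": 30},
        )
        n_iter += res.nit
        # collapse the split: keep only the net coefficient before restarting,
        # which zeroes any jointly inflated (u, v) pairs
        lam = res.x[:k] - res.x[k:]
        lam[np.abs(lam) < 1e-12] = 0.0
        z0 = np.concatenate([np.maximum(lam, 0.0), np.maximum(-lam, 0.0)])
        pg_norm, lz, q = l1_residual(lam)
        if pg_norm <= tol or n_iter >= max_iter:
            break
    if pg_norm > tol:
        raise ConvergenceError(pg_norm, tol, n_iter)
    entropy = float(-(q * np.log(np.clip(q, 1e-300, None))).sum())
    return lam, float(lz), entropy


def train_maxent(
    X_pres: np.ndarray,
    X_bg: np.ndarray,
    covariate_names: Sequence[str],
    classes: str = "LQH",
    rm: float = 1.0,
    k_h: int = 20,
    output: str = "cloglog",
    tol: float = 1e-4,
    max_iter: int = 5000,
) -> MaxentModel:
    """Build features from training rows, derive penalties, and fit.

    ``X_pres`` / ``X_bg`` are covariate matrices (rows = sites) sharing
    ``covariate_names`` order; bounds come from their union.
    """
    X_pres = np.asarray(X_pres, dtype=float)
    X_bg = np.asarray(X_bg, dtype=float)
    if np.isnan(X_pres).any() or np.isnan(X_bg).any():
        raise MaxentError("sample matrices must not contain missing values")
    fs = FeatureSet.build(np.vstack([X_pres, X_bg]), covariate_names, classes, k_h)
    kept = [list(covariate_names).index(n) for n in fs.covariate_names]
    F_pres = fs.transform(X_pres[:, kept])
    F_bg = fs.transform(X_bg[:, kept])
    betas = default_penalties(F_pres, fs.feature_types(), classes, rm)
    lam, lz, entropy = fit_maxent(F_pres, F_bg, betas, tol=tol, max_iter=max_iter)
    return MaxentModel(
        features=fs,
        coefficients=lam,
        reg_multiplier=rm,
        penalties=betas,
        log_partition=lz,
        entropy=entropy,
        output=output,
        n_background=X_bg.shape[0],
    )


# ---------------------------------------------------------------------------
# stack-level helpers


def sample_background(
    stack: Stack, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample up to ``n`` valid cells uniformly without replacement.

    Returns (covariate matrix, flat cell indices into the grid).
    """
    mask = stack.joint_mask()
    flat = np.flatnonzero(mask.ravel())
    if len(flat) == 0:
        raise MaxentError("stack has no jointly valid cells")
    if len(flat) > n:
        flat = np.sort(rng.choice(flat, size=n, replace=False))
    sel = np.zeros(mask.size, dtype=bool)
    sel[flat] = True
    sel = sel.reshape(mask.shape)
    X = np.column_stack([stack[name].values[sel] for name in stack.names])
    return X, flat


def covariates_at(occ: OccurrenceSet, stack: Stack) -> np.ndarray:
    """Covariate rows at occurrence cells; records on invalid cells are dropped."""
    mask = stack.joint_mask()
    cells = occurrence_cells(occ, stack.spec)
    ok = mask[cells[:, 0], cells[:, 1]]
    if not ok.all():
        logger.warning("%s: %d records on nodata cells dropped", occ.species, int((~ok).sum()))
    cells = cells[ok]
    return np.column_stack([stack[name].values[cells[:, 0], cells[:, 1]] for name in stack.names])


def predict(model: MaxentModel, stack: Stack, output: str | None = None) -> Layer:
    """Predict suitability over all jointly valid cells of a stack."""
    missing = [n for n in model.features.covariate_names if n not in stack.layers]
    if missing:
        raise GeodataError(f"stack is missing covariates {missing}")
    sub = stack.subset(model.features.covariate_names)
    mask = sub.joint_mask()
    X = sub.to_matrix(mask)
    pred = model.predict_matrix(X, output=output)
    values = np.full(stack.spec.shape, np.nan)
    values[mask] = pred
    return Layer(stack.spec, values, mask.copy())


def permutation_importance(
    model: MaxentModel,
    stack: Stack,
    occ: OccurrenceSet,
    n_perm: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance as AUC drop, normalised to percentages.

    Each covariate is shuffled across the jointly valid cells (seeded), the
    presence-vs-background AUC recomputed, and the drop relative to the
    unshuffled AUC floored at zero; drops are averaged over ``n_perm``
    shuffles and scaled to sum to 100.
    """
    from .evaluation import auc  # late import: evaluation has no maxent dependency

    if n_perm < 1:
        raise MaxentError("n_perm must be >= 1")
    if len(occ) == 0:
        raise MaxentError("permutation importance needs presence records")
    sub = stack.subset(model.features.covariate_names)
    mask = sub.joint_mask()
    X_bg = sub.to_matrix(mask)
    cells = occurrence_cells(occ, stack.spec)
    ok = mask[cells[:, 0], cells[:, 1]]
    cells = cells[ok]
    if len(cells) == 0:
        raise MaxentError("no presence records on valid cells")
    names = model.features.covariate_names
    X_pres = np.column_stack([stack[n].values[cells[:, 0], cells[:, 1]] for n in names])
    rng = np.random.default_rng(seed)
    base = auc(model.predict_matrix(X_pres), model.predict_matrix(X_bg))
    # presences are landscape cells too: shuffle the landscape column, and read
    # presence values at their (row-order) positions within the valid cells
    flat_valid = np.flatnonzero(mask.ravel())
    pres_flat = cells[:, 0] * stack.spec.n_cols + cells[:, 1]
    pres_pos = np.searchsorted(flat_valid, pres_flat)
    drops = np.zeros(len(names))
    for j in range(len(names)):
        for _ in range(n_perm):
            perm = rng.permutation(X_bg.shape[0])
            Xb = X_bg.copy()
            Xb[:, j] = X_bg[perm, j]
            Xp = X_pres.copy()
            Xp[:, j] = Xb[pres_pos, j]
            a = auc(model.predict_matrix(Xp), model.predict_matrix(Xb))
            drops[j] += max(0.0, base - a)
    drops /= n_perm
    total = drops.sum()
    if total <= 0:
        # no covariate matters (e.g. all-zero coefficients): report zeros
        return {n: 0.0 for n in names}
    return {n: 100.0 * d / total for n, d in zip(names, drops)}
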