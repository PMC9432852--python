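"""Correlation-matrix PCA for collinear environmental stacks.

Environmental variables mix units (temperature, precipitation, soil
percentages, terrain indices), so components are extracted from the
correlation matrix: each layer is standardised by its mean and SD over the
jointly valid cells of the *current* scenario, and those normalisers together
with the loadings are frozen and applied unchanged to every future scenario.
Freezing keeps PC axes comparable across scenarios, which is what makes
habitat projections and extrapolation diagnostics meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geodata import GeodataError, Layer, Stack


class PcaError(ValueError):
    pass


@dataclass
class PcaTransform:
    """Frozen standardisation + rotation fitted on the current scenario.

    ``loadings`` has shape (n_layers, n_components) with orthonormal columns,
    ordered by decreasing explained variance.  ``n_kept`` is the smallest
    component count whose cumulative explained fraction reaches the variance
    target used at fit time.
    """

    layer_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray
    explained_fraction: np.ndarray
    n_kept: int

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.explained_fraction = np.asarray(self.explained_fraction, dtype=float)
        p = len(self.layer_names)
        if self.loadings.shape[0] != p or len(self.means) != p or len(self.sds) != p:
            raise PcaError("inconsistent transform dimensions")
        if np.any(self.sds <= 0):
            raise PcaError("standard deviations must be positive")

    @property
    def component_names(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.n_kept)]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "layer_names": self.layer_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_fraction": self.explained_fraction.tolist(),
            "n_kept": self.n_kept,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PcaTransform":
        doc = json.loads(Path(path).read_text())
        return cls(
            layer_names=list(doc["layer_names"]),
            means=np.array(doc["means"]),
            sds=np.array(doc["sds"]),
            loadings=np.array(doc["loadings"]),
            explained_fraction=np.array(doc["explained_fraction"]),
            n_kept=int(doc["n_kept"]),
        )


def fit_pca(stack: Stack, variance_target: float = 0.95) -> PcaTransform:
    """PCA of the correlation matrix over jointly valid cells.

    Keeps the smallest number of components whose cumulative explained
    fraction reaches ``variance_target``.  Sign convention: within each
    component the loading of largest absolute value is made positive, so the
    rotation is deterministic.
    """
    if not (0 < variance_target <= 1):
        raise PcaError("variance_target must be in (0, 1]")
    if len(stack) < 2:
        raise PcaError("PCA needs at least two layers")
    mask = stack.joint_mask()
    X = stack.to_matrix(mask)
    n, p = X.shape
    if n < p:
        raise PcaError(f"only {n} valid cells for {p} layers")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for name, sd in zip(stack.names, sds):
        if sd <= 0 or not np.isfinite(sd):
            raise PcaError(f"layer {name!r} is constant over valid cells")
    Z = (X - means) / sds
    corr = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    anchor = np.argmax(np.abs(eigvecs), axis=0)
    signs = np.sign(eigvecs[anchor, np.arange(p)])
    signs[signs == 0] = 1.0
    eigvecs = eigvecs * signs
    explained = eigvals / eigvals.sum()
    cumulative = np.cumsum(explained)
    n_kept = int(np.searchsorted(cumulative, variance_target - 1e-12) + 1)
    n_kept = min(n_kept, p)
    return PcaTransform(
        layer_names=list(stack.names),
        means=means,
        sds=sds,
        loadings=eigvecs,
        explained_fraction=explained,
        n_kept=n_kept,
    )


def project(stack: Stack, t: PcaTransform) -> Stack:
    """Project a stack into kept-PC space with frozen normalisers.

    Output layers are named PC1..PCk; the mask is the intersection of the
    input layer masks.
    """
    missing = [n for n in t.layer_names if n not in stack.layers]
    if missing:
        raise GeodataError(f"stack is missing layers {missing}")
    sub = stack.subset(t.layer_names)
    mask = sub.joint_mask()
    X = sub.to_matrix(mask)
    Z = (X - t.means) / t.sds
    scores = Z @ t.loadings[:, : t.n_kept]
    out = Stack(stack.spec)
    for i, name in enumerate(t.component_names):
        values = np.full(stack.spec.shape, np.nan)
        values[mask] = scores[:, i]
        out.add(name, Layer(stack.spec, values, mask.copy()))
    return out
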