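"""Extrapolation and niche-similarity diagnostics for model transfer.

A model trained on a reference region/period and projected elsewhere can be
asked to predict in environments it never saw.  ExDet quantifies this per
projection cell: NT1 (<= 0) sums the negative univariate exceedances of the
reference ranges, and where every covariate is in range, NT2 (>= 0) scales
the Mahalanobis distance to the reference cloud by the largest distance of
any reference point, so NT2 > 1 flags novel covariate *combinations*.  Cells
are classed univariate (NT1 < 0), combinatorial (NT1 = 0, NT2 > 1) or
analogue, with the most influential covariate (MIC) attributed per cell.
The percentage of data nearby (%N) counts reference samples inside an
axis-aligned SD box around each projection point.  Niche similarity between
two suitability surfaces uses Schoener's D and Warren's I on the surfaces
normalised to probability distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geodata import GeodataError, Layer, Stack

logger = logging.getLogger(__name__)

NOVELTY_UNIVARIATE = 1
NOVELTY_COMBINATORIAL = 2
NOVELTY_ANALOGUE = 3

_CLASS_NAMES = {
    NOVELTY_UNIVARIATE: "univariate",
    NOVELTY_COMBINATORIAL: "combinatorial",
    NOVELTY_ANALOGUE: "analogue",
}


class DiagnosticsError(ValueError):
    pass


@dataclass
class ExDetResult:
    covariate_names: list[str]
    nt1: Layer
    nt2: Layer  # defined (non-NaN) only where nt1 == 0
    exdet: Layer  # nt1 where nt1 < 0, else nt2
    novelty_class: Layer  # integer codes, see NOVELTY_*
    mic: np.ndarray  # per-cell covariate index, -1 where analogue/invalid
    # internals reused by MIC attribution
    _ud: np.ndarray  # (cells x covariates) negative exceedances at valid cells
    _mask: np.ndarray


def _reference_stats(reference: np.ndarray, ridge: float = 1e-8):
    mu = reference.mean(axis=0)
    centered = reference - mu
    cov = centered.T @ centered / (reference.shape[0] - 1)
    # ridge-regularise when near-singular so the Mahalanobis form stays defined
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        logger.warning("singular reference covariance; applying ridge regularisation")
        cov = cov + ridge * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
    return mu, cov


def _mahalanobis_sq(X: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    sol = np.linalg.solve(cov, (X - mu).T)
    return np.einsum("ij,ji->i", X - mu, sol)


def exdet(reference: np.ndarray, projection: Stack, covariate_names: list[str] | None = None) -> ExDetResult:
    """ExDet novelty surfaces for a projection stack against reference rows.

    ``reference`` is a (rows x covariates) sample matrix (typically the
    model's training presences plus background); ``projection`` must carry
    one layer per reference covariate, in order.
    """
    reference = np.asarray(reference, dtype=float)
    if covariate_names is None:
        covariate_names = projection.names
    if reference.ndim != 2 or reference.shape[1] != len(covariate_names):
        raise DiagnosticsError("reference matrix does not match the covariate list")
    if reference.shape[0] < reference.shape[1] + 1:
        raise DiagnosticsError("reference needs at least n_covariates + 1 rows")
    sub = projection.subset(covariate_names)
    mask = sub.joint_mask()
    X = sub.to_matrix(mask)

    mins = reference.min(axis=0)
    maxs = reference.max(axis=0)
    rng = maxs - mins
    if np.any(rng <= 0):
        flat = [covariate_names[j] for j in np.flatnonzero(rng <= 0)]
        raise DiagnosticsError(f"reference covariates with zero range: {flat}")

    below = np.minimum(X - mins, 0.0) / rng  # <= 0 where x < min
    above = np.minimum(maxs - X, 0.0) / rng  # <= 0 where x > max
    ud = below + above  # per-covariate negative exceedance
    nt1 = ud.sum(axis=1)

    mu, cov = _reference_stats(reference)
    d2_ref_max = float(np.max(_mahalanobis_sq(reference, mu, cov)))
    nt2 = np.full(len(X), np.nan)
    in_range = nt1 == 0
    if in_range.any():
        nt2[in_range] = _mahalanobis_sq(X[in_range], mu, cov) / d2_ref_max

    classes = np.full(len(X), NOVELTY_ANALOGUE, dtype=float)
    classes[nt1 < 0] = NOVELTY_UNIVARIATE
    classes[in_range & (nt2 > 1)] = NOVELTY_COMBINATORIAL

    combined = np.where(nt1 < 0, nt1, nt2)

    spec = projection.spec

    def as_layer(vec: np.ndarray, layer_mask: np.ndarray | None = None) -> Layer:
        values = np.full(spec.shape, np.nan)
        values[mask] = vec
        m = mask.copy()
        if layer_mask is not None:
            m[mask] = layer_mask
            values[~m] = np.nan
        return Layer(spec, values, m)

    result = ExDetResult(
        covariate_names=list(covariate_names),
        nt1=as_layer(nt1),
        nt2=as_layer(nt2, in_range),
        exdet=as_layer(combined),
        novelty_class=as_layer(classes),
        mic=np.full(len(X), -1, dtype=int),
        _ud=ud,
        _mask=mask,
    )
    result.mic = _attribute_mic(result, reference, X)
    return result


def _attribute_mic(result: ExDetResult, reference: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Most influential covariate per novel cell.

    Univariate cells: the covariate with the most negative exceedance (ties
    to the first covariate in order).  Combinatorial cells: the covariate
    whose omission most reduces NT2, each leave-one-out NT2 renormalised by
    its own reference maximum distance.
    """
    n, p = X.shape
    mic = np.full(n, -1, dtype=int)
    classes = result.novelty_class.values[result._mask]

    uni = classes == NOVELTY_UNIVARIATE
    if uni.any():
        mic[uni] = np.argmin(result._ud[uni], axis=1)  # argmin = most negative, first on ties

    comb = classes == NOVELTY_COMBINATORIAL
    if comb.any():
        nt2_full = result.nt2.values[result._mask][comb]
        Xc = X[comb]
        reductions = np.empty((Xc.shape[0], p))
        for j in range(p):
            keep = [k for k in range(p) if k != j]
            mu_j, cov_j = _reference_stats(reference[:, keep])
            d2_ref = float(np.max(_mahalanobis_sq(reference[:, keep], mu_j, cov_j)))
            nt2_wo = _mahalanobis_sq(Xc[:, keep], mu_j, cov_j) / d2_ref
            reductions[:, j] = 100.0 * (nt2_full - nt2_wo) / nt2_full
        mic[comb] = np.argmax(reductions, axis=1)
    return mic


def summarize_exdet(result: ExDetResult) -> dict:
    """Class and MIC counts with percentages formatted to 2 decimals (half-up)."""
    mask = result._mask
    classes = result.novelty_class.values[mask]
    total = int(mask.sum())
    class_counts = {
        name: int(np.sum(classes == code)) for code, name in _CLASS_NAMES.items()
    }
    summary = {
        "total": total,
        "classes": {
            name: {"count": c, "percentage": format_percentage(c, total)}
            for name, c in class_counts.items()
        },
        "subtotal_novel": {
            "count": class_counts["univariate"] + class_counts["combinatorial"],
            "percentage": format_percentage(
                class_counts["univariate"] + class_counts["combinatorial"], total
            ),
        },
        "mic": {},
    }
    for code, name in ((NOVELTY_UNIVARIATE, "univariate"), (NOVELTY_COMBINATORIAL, "combinatorial")):
        sel = classes == code
        counts = {
            cov: int(np.sum(result.mic[sel] == j))
            for j, cov in enumerate(result.covariate_names)
        }
        summary["mic"][name] = {
            cov: {"count": c, "percentage": format_percentage(c, total)}
            for cov, c in sorted(counts.items(), key=lambda kv: -kv[1])
        }
    return summary


def format_percentage(count: int, total: int, decimals: int = 2) -> float:
    """100*count/total rounded half-up to ``decimals`` places."""
    if total <= 0:
        raise DiagnosticsError("total must be positive")
    value = 100.0 * count / total
    scale = 10**decimals
    return float(np.floor(value * scale + 0.5) / scale)


def percent_nearby(reference: np.ndarray, projection: Stack, radius_sd: float = 1.0,
                   covariate_names: list[str] | None = None) -> Layer:
    """%N: share of reference rows inside an axis-aligned SD box per cell.

    A reference row counts as nearby if |x_j - r_j| <= radius_sd * sigma_j for
    every covariate j, with sigma_j the reference SD (floored at 1e-12).
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape[0] == 0:
        raise DiagnosticsError("reference must be non-empty")
    if radius_sd <= 0:
        raise DiagnosticsError("radius_sd must be positive")
    if covariate_names is None:
        covariate_names = projection.names
    sub = projection.subset(covariate_names)
    mask = sub.joint_mask()
    X = sub.to_matrix(mask)
    sigma = reference.std(axis=0, ddof=1) if len(reference) > 1 else np.zeros(reference.shape[1])
    if np.any(sigma <= 0):
        logger.warning("zero-variance reference covariate; SD floored at 1e-12")
    sigma = np.maximum(sigma, 1e-12)
    half = radius_sd * sigma
    # chunked pairwise box test to bound the temporary to ~tens of MB
    pct = np.empty(len(X))
    step = max(1, int(4e6 // max(1, reference.shape[0] * reference.shape[1])))
    for start in range(0, len(X), step):
        block = X[start:start + step]
        inside = np.all(
            np.abs(block[:, None, :] - reference[None, :, :]) <= half[None, None, :], axis=2
        )
        pct[start:start + step] = 100.0 * inside.mean(axis=1)
    values = np.full(projection.spec.shape, np.nan)
    values[mask] = pct
    return Layer(projection.spec, values, mask.copy())


@dataclass
class OverlapScore:
    d: float  # Schoener's D
    i: float  # Warren's I


def niche_overlap(s1: Layer, s2: Layer) -> OverlapScore:
    """Schoener's D and Warren's I between two suitability surfaces.

    Both layers are normalised to sum to one over the joint valid mask;
    D = 1 - 0.5*sum|p - q| and I = 1 - 0.5*sum(sqrt(p) - sqrt(q))^2.  Both
    equal 1 exactly when the normalised surfaces coincide.
    """
    if s1.spec != s2.spec:
        raise GeodataError("overlap needs layers on the same grid")
    mask = s1.valid_mask & s2.valid_mask
    if not mask.any():
        raise DiagnosticsError("layers share no valid cells")
    p = s1.values[mask]
    q = s2.values[mask]
    if np.any(p < 0) or np.any(q < 0):
        raise DiagnosticsError("suitability layers must be non-negative")
    ps, qs = p.sum(), q.sum()
    if ps <= 0 or qs <= 0:
        raise DiagnosticsError("suitability layers must have positive totals")
    p = p / ps
    q = q / qs
    d = 1.0 - 0.5 * np.abs(p - q).sum()
    i = 1.0 - 0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum()
    return OverlapScore(d=float(d), i=float(i))
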