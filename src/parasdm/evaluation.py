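"""Spatially blocked evaluation for presence-background models.

Presence-only models are tuned here with a hierarchical checkerboard: two
nested checkerboard grids (aggregation factors a1 and a1*a2 native cells)
whose parities combine into four spatial folds, so train and test presences
are separated in space rather than at random.  Per-fold discrimination is
scored with the rank AUC, calibration with the Continuous Boyce Index (CBI,
the Spearman correlation between the predicted-to-expected presence ratio
and suitability across sliding windows), and conservatism with the omission
rate at a training-percentile threshold.  Candidate settings are ranked by
mean CBI, the criterion best suited to presence-only calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata, spearmanr

from .geodata import GridSpec, Layer

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# hierarchical checkerboard partition


@dataclass
class CvPartition:
    """Fold labels in {1,2,3,4} for presences and background rows."""

    presence_folds: np.ndarray
    background_folds: np.ndarray
    aggregation_factors: tuple[int, int]


def checkerboard_folds(rows: np.ndarray, cols: np.ndarray, a1: int, a2: int) -> np.ndarray:
    """Fold of each (row, col) cell under the nested checkerboard.

    g1 = (floor(cx/a1) + floor(cy/a1)) mod 2 at the fine scale and
    g2 = (floor(cx/(a1*a2)) + floor(cy/(a1*a2))) mod 2 at the coarse scale
    combine as fold = 1 + g1 + 2*g2; the fold is a pure function of the cell.
    """
    if a1 < 1 or a2 < 2:
        raise EvaluationError("aggregation factors need a1 >= 1 and a2 >= 2")
    cx = np.asarray(cols, dtype=int)
    cy = np.asarray(rows, dtype=int)
    g1 = (cx // a1 + cy // a1) % 2
    g2 = (cx // (a1 * a2) + cy // (a1 * a2)) % 2
    return 1 + g1 + 2 * g2


def checkerboard_partition(
    presence_cells: np.ndarray,
    background_cells: np.ndarray,
    spec: GridSpec,
    a1: int = 2,
    a2: int = 2,
) -> CvPartition:
    """Partition presence and background cells identically into 4 spatial folds."""
    pres = checkerboard_folds(presence_cells[:, 0], presence_cells[:, 1], a1, a2)
    bg = checkerboard_folds(background_cells[:, 0], background_cells[:, 1], a1, a2)
    for fold in range(1, 5):
        if not np.any(pres == fold):
            logger.warning("checkerboard fold %d holds no presences; it will be skipped", fold)
    return CvPartition(pres, bg, (a1, a2))


# ---------------------------------------------------------------------------
# metrics


def auc(pred_presence: np.ndarray, pred_background: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC of presences vs background, ties counted 1/2."""
    p = np.asarray(pred_presence, dtype=float)
    b = np.asarray(pred_background, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise EvaluationError("AUC needs non-empty presence and background predictions")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2
    return float(u / (len(p) * len(b)))


@dataclass
class BoyceCurve:
    """Predicted-to-expected ratio curve underlying the CBI."""

    window_midpoints: np.ndarray
    P: np.ndarray  # fraction of evaluation presences per window
    E: np.ndarray  # fraction of landscape cells per window
    F: np.ndarray  # P/E over retained (E > 0) windows
    retained: np.ndarray  # boolean, which windows enter F
    cbi: float


def cbi(
    pred_presence_test: np.ndarray,
    pred_landscape: Layer | np.ndarray,
    n_windows: int = 101,
    window_frac: float = 0.1,
) -> BoyceCurve:
    """Continuous Boyce Index.

    Windows of width ``window_frac`` times the landscape prediction range
    slide from the minimum to the maximum; in each, P is the share of test
    presences and E the share of landscape cells, and the CBI is the Spearman
    rank correlation (average ranks on ties) between F = P/E and the window
    midpoint over windows with E > 0.
    """
    pres = np.asarray(pred_presence_test, dtype=float)
    land = pred_landscape.valid_values() if isinstance(pred_landscape, Layer) else np.asarray(pred_landscape, dtype=float)
    if len(pres) == 0:
        raise EvaluationError("CBI needs test presences")
    lo, hi = float(np.min(land)), float(np.max(land))
    if not hi > lo:
        raise EvaluationError("landscape predictions need >= 2 distinct values")
    width = window_frac * (hi - lo)
    starts = np.linspace(lo, hi - width, n_windows)
    mids = starts + width / 2
    P = np.empty(n_windows)
    E = np.empty(n_windows)
    for k, s in enumerate(starts):
        in_p = (pres >= s) & (pres <= s + width)
        in_l = (land >= s) & (land <= s + width)
        P[k] = in_p.mean()
        E[k] = in_l.mean()
    retained = E > 0
    if retained.sum() < 3:
        raise EvaluationError("fewer than 3 windows contain landscape cells; CBI undefined")
    F = P[retained] / E[retained]
    rho = spearmanr(F, mids[retained]).statistic
    if np.isnan(rho):  # constant F: no calibration signal either way
        rho = 0.0
    return BoyceCurve(mids, P, E, F, retained, float(rho))


def omission_rate(
    pred_presence_train: np.ndarray,
    pred_presence_test: np.ndarray,
    percentile: float = 10.0,
) -> float:
    """Share of test presences strictly below a training-percentile threshold.

    The threshold is the linear-interpolation ("type 7") percentile of the
    training presence predictions.
    """
    train = np.asarray(pred_presence_train, dtype=float)
    test = np.asarray(pred_presence_test, dtype=float)
    if len(train) == 0 or len(test) == 0:
        raise EvaluationError("omission rate needs non-empty train and test predictions")
    if not 0 < percentile < 100:
        raise EvaluationError("percentile must be in (0, 100)")
    threshold = float(np.percentile(train, percentile))  # linear interpolation
    return float(np.mean(test < threshold))


# ---------------------------------------------------------------------------
# aggregation and selection


@dataclass
class EvalMetrics:
    """Per-fold AUC / CBI / omission rate with their means and SDs."""

    fold_ids: list[int]
    auc_folds: list[float]
    cbi_folds: list[float]
    or_folds: list[float]
    auc_mean: float = field(init=False)
    auc_sd: float = field(init=False)
    cbi_mean: float = field(init=False)
    cbi_sd: float = field(init=False)
    or_mean: float = field(init=False)
    or_sd: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.fold_ids:
            raise EvaluationError("metrics need at least one evaluated fold")
        self.auc_mean, self.auc_sd = _mean_sd(self.auc_folds)
        self.cbi_mean, self.cbi_sd = _mean_sd(self.cbi_folds)
        self.or_mean, self.or_sd = _mean_sd(self.or_folds)

    def to_rows(self, species: str, settings: str) -> list[dict]:
        rows = [
            {
                "species": species, "settings": settings, "fold": f,
                "auc": a, "cbi": c, "or": o,
            }
            for f, a, c, o in zip(self.fold_ids, self.auc_folds, self.cbi_folds, self.or_folds)
        ]
        rows.append({
            "species": species, "settings": settings, "fold": "mean",
            "auc": self.auc_mean, "cbi": self.cbi_mean, "or": self.or_mean,
        })
        rows.append({
            "species": species, "settings": settings, "fold": "sd",
            "auc": self.auc_sd, "cbi": self.cbi_sd, "or": self.or_sd,
        })
        return rows


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0


def select_model(candidates: Sequence[tuple[object, EvalMetrics]]) -> object:
    """Pick the settings with maximum mean CBI.

    Ties break by lower mean omission rate, then higher mean AUC, then first
    in candidate order.
    """
    valid = [
        (i, s, m) for i, (s, m) in enumerate(candidates)
        if m is not None and np.isfinite(m.cbi_mean)
    ]
    if not valid:
        raise EvaluationError("no candidate with a valid mean CBI")
    best = min(valid, key=lambda t: (-t[2].cbi_mean, t[2].or_mean, -t[2].auc_mean, t[0]))
    return best[1]
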