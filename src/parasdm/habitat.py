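"""Habitat classing, scenario change trends, and reserve delineation.

Suitability surfaces are cut into four habitat levels (ISH/LSH/MSH/HSH:
inappropriate, low, medium, highly suitable) with Jenks natural breaks fitted
on the *current* surface only; the same thresholds are applied to every
future surface so that per-class areas stay comparable across scenarios.
Class-area change ratios r = (A_future - A_current)/A_current summarise the
trend per species, scenario and class, with the maximum growth ratio (MGR)
and maximum reduction ratio (MRR) as extremes.  Hosts whose habitat shrinks
under most futures, intersected with the parasite's medium/high habitat,
delineate the core reserve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodata import GeodataError, GridSpec, Layer, row_areas_km2

logger = logging.getLogger(__name__)

CLASS_CODES = {"ISH": 1, "LSH": 2, "MSH": 3, "HSH": 4}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}


class HabitatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Jenks natural breaks (Fisher's exact dynamic programme)


def jenks_breaks(values: np.ndarray, k: int = 4, max_exact: int = 100_000,
                 subsample: int = 10_000, seed: int = 0) -> np.ndarray:
    """Optimal 1-D classification minimising within-class squared deviation.

    Returns the k-1 upper class boundaries (data values, excluding the global
    maximum).  The dynamic programme is exact and O(k n^2); inputs larger
    than ``max_exact`` are first reduced to a seeded uniform subsample of
    ``subsample`` values.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if k < 2:
        raise HabitatError("need at least 2 classes")
    if len(np.unique(x)) < k:
        raise HabitatError(f"need at least {k} distinct values for {k} classes")
    if len(x) > max_exact:
        rng = np.random.default_rng(seed)
        x = np.sort(rng.choice(x, size=subsample, replace=False))
        if len(np.unique(x)) < k:
            raise HabitatError("subsample has too few distinct values")
    n = len(x)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: np.ndarray, j: int) -> np.ndarray:
        """Within-class SSD of x[i..j] inclusive, vectorised over i."""
        cnt = j - i + 1
        tot = s1[j + 1] - s1[i]
        return (s2[j + 1] - s2[i]) - tot * tot / cnt

    # cost[c][j] = minimal SSD splitting x[0..j] into c+1 classes
    cost = np.empty((k, n))
    cut = np.zeros((k, n), dtype=int)
    ones = np.arange(1, n + 1, dtype=float)
    cost[0] = s2[1:] - s1[1:] ** 2 / ones
    for c in range(1, k):
        for j in range(n):
            if j < c:
                cost[c, j] = 0.0
                cut[c, j] = j
                continue
            starts = np.arange(c, j + 1)
            cand = cost[c - 1, starts - 1] + ssd(starts, j)
            best = int(np.argmin(cand))
            cost[c, j] = cand[best]
            cut[c, j] = starts[best]
    # backtrack class boundaries
    breaks = []
    j = n - 1
    for c in range(k - 1, 0, -1):
        i = cut[c, j]
        breaks.append(x[i - 1])  # upper boundary of the class below
        j = i - 1
    return np.array(breaks[::-1])


def within_class_ssd(values: np.ndarray, breaks: np.ndarray) -> float:
    """Total within-class SSD induced by right-closed breaks (oracle support)."""
    x = np.asarray(values, dtype=float)
    labels = np.digitize(x, np.asarray(breaks), right=True)
    total = 0.0
    for lab in np.unique(labels):
        grp = x[labels == lab]
        total += float(((grp - grp.mean()) ** 2).sum())
    return total


# ---------------------------------------------------------------------------
# classification and areas


@dataclass
class HabitatClassification:
    breaks: np.ndarray  # 3 ascending thresholds
    class_layer: Layer  # integer codes 1..4
    class_areas_km2: dict[str, float]

    @property
    def spec(self) -> GridSpec:
        return self.class_layer.spec

    def class_mask(self, *names: str) -> np.ndarray:
        codes = [CLASS_CODES[n] for n in names]
        return self.class_layer.valid_mask & np.isin(self.class_layer.values, codes)


def classify(suitability: Layer, breaks: np.ndarray) -> HabitatClassification:
    """Assign habitat levels by right-closed intervals (value == break -> lower class).

    Future surfaces must be classified with the breaks fitted on the current
    surface, keeping class definitions fixed across scenarios.
    """
    breaks = np.asarray(breaks, dtype=float)
    if len(breaks) != 3 or np.any(np.diff(breaks) <= 0):
        raise HabitatError("need 3 strictly ascending breaks")
    mask = suitability.valid_mask
    codes = np.full(suitability.spec.shape, np.nan)
    codes[mask] = np.digitize(suitability.values[mask], breaks, right=True) + 1
    layer = Layer(suitability.spec, codes, mask.copy())
    row_a = row_areas_km2(suitability.spec)
    areas = {}
    for name, code in CLASS_CODES.items():
        class_mask = mask & (codes == code)
        areas[name] = float(np.sum(row_a * class_mask.sum(axis=1)))
    return HabitatClassification(breaks, layer, areas)


def classify_current_and_futures(
    current: Layer, futures: dict[str, Layer], k: int = 4, seed: int = 0
) -> tuple[HabitatClassification, dict[str, HabitatClassification]]:
    """Fit Jenks breaks on the current surface and apply them everywhere."""
    breaks = jenks_breaks(current.valid_values(), k=k, seed=seed)
    cur = classify(current, breaks)
    futs = {key: classify(layer, breaks) for key, layer in futures.items()}
    return cur, futs


# ---------------------------------------------------------------------------
# change trends


def change_ratio(current: HabitatClassification, future: HabitatClassification) -> dict[str, float]:
    """Per-class relative area change (A_future - A_current) / A_current."""
    if current.spec != future.spec:
        raise GeodataError("classifications are on different grids")
    if not np.array_equal(current.breaks, future.breaks):
        raise HabitatError("future must be classified with the current breaks")
    out: dict[str, float] = {}
    for name in CLASS_CODES:
        a_cur = current.class_areas_km2[name]
        a_fut = future.class_areas_km2[name]
        if a_cur == 0:
            logger.warning("class %s has zero current area; ratio undefined", name)
            out[name] = float("nan")
        else:
            out[name] = (a_fut - a_cur) / a_cur
    return out


def change_category(current: HabitatClassification, future: HabitatClassification) -> Layer:
    """Per-cell trend: 0 constant, -1 class decreased, +1 class increased."""
    if current.spec != future.spec:
        raise GeodataError("classifications are on different grids")
    if not np.array_equal(current.breaks, future.breaks):
        raise HabitatError("future must be classified with the current breaks")
    mask = current.class_layer.valid_mask & future.class_layer.valid_mask
    diff = future.class_layer.values - current.class_layer.values
    values = np.where(mask, np.sign(diff), np.nan)
    return Layer(current.spec, values, mask)


def trend_table(
    entries: list[tuple[str, str, dict[str, float]]]
) -> pd.DataFrame:
    """Tidy change-ratio table: one row per (species, scenario key, class)."""
    rows = []
    for species, key, ratios in entries:
        for cls, r in ratios.items():
            rows.append({"species": species, "scenario": key, "class": cls, "ratio": r})
    return pd.DataFrame(rows)


def trend_extremes(trend: pd.DataFrame) -> pd.DataFrame:
    """MGR (max ratio) and MRR (min ratio) per species x class with their keys."""
    required = {"species", "scenario", "class", "ratio"}
    if not required.issubset(trend.columns):
        raise HabitatError(f"trend table needs columns {sorted(required)}")
    if trend.empty:
        raise HabitatError("trend table is empty")
    rows = []
    for (species, cls), grp in trend.groupby(["species", "class"], sort=False):
        grp = grp.dropna(subset=["ratio"])
        if grp.empty:
            continue
        imax = grp["ratio"].idxmax()
        imin = grp["ratio"].idxmin()
        rows.append({
            "species": species,
            "class": cls,
            "mgr": float(grp.loc[imax, "ratio"]),
            "mgr_scenario": grp.loc[imax, "scenario"],
            "mrr": float(grp.loc[imin, "ratio"]),
            "mrr_scenario": grp.loc[imin, "scenario"],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# host screening and reserve delineation


def select_influential_hosts(
    i_values: pd.DataFrame,
    mic_shares: dict[str, float] | None = None,
    i_threshold: float = 0.9,
) -> list[str]:
    """Hosts whose mean niche similarity (Warren's I) clears the threshold.

    ``i_values`` has columns species, scenario, i.  Selected hosts rank by
    their univariate-MIC share (descending) when given, then by mean I.
    """
    required = {"species", "i"}
    if not required.issubset(i_values.columns):
        raise HabitatError("i_values needs columns 'species' and 'i'")
    means = i_values.groupby("species")["i"].mean()
    selected = means[means >= i_threshold]
    if selected.empty:
        logger.warning("no host clears the niche-similarity threshold %.2f", i_threshold)
        return []
    mic_shares = mic_shares or {}
    return sorted(
        selected.index,
        key=lambda h: (-mic_shares.get(h, 0.0), -selected[h]),
    )


def shrinking_classes(
    trend: pd.DataFrame,
    neg_fraction: float = 0.5,
) -> set[tuple[str, str]]:
    """(species, class) pairs whose habitat shrinks across futures.

    A pair qualifies when its ratio is negative in at least ``neg_fraction``
    of the scenario x period keys AND its mean ratio is negative.
    """
    out: set[tuple[str, str]] = set()
    for (species, cls), grp in trend.groupby(["species", "class"], sort=False):
        r = grp["ratio"].dropna().to_numpy()
        if len(r) == 0:
            continue
        if np.mean(r < 0) >= neg_fraction and r.mean() < 0:
            out.add((species, cls))
    return out


@dataclass
class ReserveMap:
    core_layer: Layer  # boolean-valued
    area_km2: float
    rule_trace: dict[str, int]


def delineate_reserve(
    parasite: HabitatClassification,
    host_classifications: dict[str, HabitatClassification],
    shrink_set: set[tuple[str, str]],
    rule: str = "intersection",
) -> ReserveMap:
    """Core conservation zone from parasite habitat and shrinking host habitat.

    intersection (default): cells in the parasite's MSH/HSH that also carry a
    shrinking host's current habitat class.  union: parasite MSH/HSH cells
    plus all shrinking-host cells.  All classifications must come from the
    current scenario on a shared grid.
    """
    if rule not in ("intersection", "union"):
        raise HabitatError(f"unknown reserve rule {rule!r}")
    spec = parasite.spec
    for host, hc in host_classifications.items():
        if hc.spec != spec:
            raise GeodataError(f"host {host!r} classification is on a different grid")
    parasite_mask = parasite.class_mask("MSH", "HSH")
    trace = {"parasite_MSH_HSH": int(parasite_mask.sum())}
    host_mask = np.zeros(spec.shape, dtype=bool)
    effective = [
        (h, c) for (h, c) in sorted(shrink_set) if h in host_classifications
    ]
    for host, cls in effective:
        m = host_classifications[host].class_mask(cls)
        trace[f"{host}_{cls}"] = int(m.sum())
        host_mask |= m
    if not effective:
        logger.warning("empty shrink set: core falls back to parasite MSH/HSH alone")
        core = parasite_mask
    elif rule == "intersection":
        core = parasite_mask & host_mask
    else:
        core = parasite_mask | host_mask
    trace["core"] = int(core.sum())
    row_a = row_areas_km2(spec)
    area = float(np.sum(row_a * core.sum(axis=1)))
    layer = Layer(spec, core.astype(float), np.ones(spec.shape, dtype=bool))
    return ReserveMap(core_layer=layer, area_km2=area, rule_trace=trace)
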