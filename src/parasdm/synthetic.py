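"""Synthetic study system with known ground truth.

Generates everything the pipeline consumes — collinear environmental rasters
for a current scenario and SSP x period futures (with several GCM variants
each), host-plant suitability surfaces that are known functions of the
latent environment, a parasite suitability surface that is a known function
of the *host* suitabilities, and presence records sampled proportionally to
truth.  The construction mirrors the structure of real inputs: ~30 observed
covariates mixing ~8 independent spatially autocorrelated latent fields, so
a correlation-matrix PCA recovers the latent dimensionality; futures are the
current latents plus a smooth scenario-strength trend field plus per-GCM
noise.

Every output is a deterministic function of the :class:`WorldConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .geodata import (
    PERIODS,
    GridSpec,
    Layer,
    OccurrenceSet,
    ScenarioKey,
    Stack,
    future_keys,
)


class SyntheticError(ValueError):
    pass


def _default_host_coefficients() -> dict[str, np.ndarray]:
    # five hosts, each anchored on its own pair of latent fields so host
    # suitabilities are informative but not collinear
    return {
        "host_A": np.array([1.6, 1.0, 0, 0, 0, 0, 0, 0.0]),
        "host_B": np.array([0, 0, 1.6, 1.0, 0, 0, 0, 0.0]),
        "host_C": np.array([0, 0, 0, 0, 1.6, 1.0, 0, 0.0]),
        "host_D": np.array([0, 0.6, 0, 0, 0, 0, 1.4, 0.0]),
        "host_E": np.array([0.6, 0, 0, 0, 0, 0.6, 0, 1.4]),
    }


@dataclass
class WorldConfig:
    """Full recipe for one synthetic world (identical config => identical world)."""

    seed: int = 42
    n_rows: int = 120
    n_cols: int = 100
    n_latent: int = 8
    n_covariates: int = 30
    smoothing_length: float = 6.0  # cells, Gaussian kernel SD
    covariate_noise_sd: float = 0.15
    cross_mixing: float = 0.1
    scenarios: list[ScenarioKey] = field(default_factory=lambda: [ScenarioKey("current")] + future_keys())
    n_gcm: int = 2
    gcm_noise_sd: float = 0.05
    trend_magnitude: dict[str, float] = field(
        default_factory=lambda: {"SSP126": 0.15, "SSP245": 0.3, "SSP370": 0.5, "SSP585": 0.7}
    )
    host_coefficients: dict[str, np.ndarray] = field(default_factory=_default_host_coefficients)
    host_intercepts: dict[str, float] | None = None
    parasite_weights: np.ndarray = field(default_factory=lambda: np.array([3.0, 3.0, 1.0, 0.0, 0.0]))
    parasite_intercept: float = -3.5
    n_presence: int = 200

    def __post_init__(self) -> None:
        if self.n_covariates < self.n_latent:
            raise SyntheticError("need at least as many covariates as latent fields")
        if len(self.parasite_weights) != len(self.host_coefficients):
            raise SyntheticError("one parasite weight per host is required")
        for name, w in self.host_coefficients.items():
            if len(w) != self.n_latent:
                raise SyntheticError(f"host {name!r} coefficient length != n_latent")

    @property
    def hosts(self) -> list[str]:
        return list(self.host_coefficients)

    def grid(self) -> GridSpec:
        # an arid-belt window; extent is arbitrary but fixed by the config
        cell = 0.05
        return GridSpec(
            origin_lon=80.0,
            origin_lat=46.0,
            cell_size=cell,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
        )


@dataclass
class World:
    """Materialised synthetic study system."""

    config: WorldConfig
    spec: GridSpec
    latents: dict[str, np.ndarray]  # per scenario key: (n_latent, rows, cols), GCM-mean
    stacks: dict[str, list[Stack]]  # per scenario key: one Stack per GCM variant
    host_truth: dict[str, dict[str, Layer]]  # scenario -> host -> truth
    parasite_truth: dict[str, Layer]  # scenario -> truth
    occurrences: dict[str, OccurrenceSet]  # species -> presences (current scenario)

    @property
    def covariate_names(self) -> list[str]:
        return [f"env{j + 1:02d}" for j in range(self.config.n_covariates)]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], length: float) -> np.ndarray:
    """Standardised spatially autocorrelated Gaussian field."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=length, mode="wrap")
    return (raw - raw.mean()) / raw.std()


def _mixing_matrix(cfg: WorldConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_covariates x n_latent) weights: round-robin anchor + weak cross-mixing.

    Each covariate loads mainly on one latent so all latent fields carry
    comparable shares of the total variance and the latent rank is
    recoverable from the correlation spectrum.
    """
    W = cfg.cross_mixing * rng.standard_normal((cfg.n_covariates, cfg.n_latent))
    for j in range(cfg.n_covariates):
        W[j, j % cfg.n_latent] += 1.0
    return W


def make_world(cfg: WorldConfig) -> World:
    """Generate the full synthetic system from its config."""
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.grid()
    shape = spec.shape

    base_latents = np.stack([_smooth_field(rng, shape, cfg.smoothing_length) for _ in range(cfg.n_latent)])
    trend_field = _smooth_field(rng, shape, cfg.smoothing_length)
    mixing = _mixing_matrix(cfg, rng)
    names = [f"env{j + 1:02d}" for j in range(cfg.n_covariates)]

    full_mask = np.ones(shape, dtype=bool)

    def covariate_stack(latents: np.ndarray, noise_rng: np.random.Generator) -> Stack:
        stack = Stack(spec)
        fields = np.einsum("jl,lrc->jrc", mixing, latents)
        for j, name in enumerate(names):
            vals = fields[j] + cfg.covariate_noise_sd * noise_rng.standard_normal(shape)
            stack.add(name, Layer(spec, vals, full_mask.copy()))
        return stack

    latents_by_key: dict[str, np.ndarray] = {}
    stacks: dict[str, list[Stack]] = {}
    for key in cfg.scenarios:
        kname = str(key)
        if key.scenario == "current":
            shifted = base_latents
            variants = 1
        else:
            step = PERIODS.index(key.period) + 1
            shift = cfg.trend_magnitude[key.scenario] * step * trend_field
            shifted = base_latents + shift[None, :, :]
            variants = cfg.n_gcm
        gcm_latents = []
        gcm_stacks = []
        for g in range(variants):
            if key.scenario == "current":
                lat_g = shifted
            else:
                noise = cfg.gcm_noise_sd * rng.standard_normal(shifted.shape)
                lat_g = shifted + noise
            gcm_latents.append(lat_g)
            gcm_stacks.append(covariate_stack(lat_g, rng))
        latents_by_key[kname] = np.mean(gcm_latents, axis=0)
        stacks[kname] = gcm_stacks

    host_truth: dict[str, dict[str, Layer]] = {}
    parasite_truth: dict[str, Layer] = {}
    for kname, lat in latents_by_key.items():
        hosts, para = make_truth(cfg, lat, spec)
        host_truth[kname] = hosts
        parasite_truth[kname] = para

    occurrences: dict[str, OccurrenceSet] = {}
    sample_seeds = rng.integers(0, 2**31 - 1, size=len(cfg.hosts) + 1)
    for i, host in enumerate(cfg.hosts):
        occurrences[host] = sample_occurrences(
            host_truth["current"][host], cfg.n_presence, int(sample_seeds[i]), species=host
        )
    occurrences["parasite"] = sample_occurrences(
        parasite_truth["current"], cfg.n_presence, int(sample_seeds[-1]), species="parasite"
    )

    return World(
        config=cfg,
        spec=spec,
        latents=latents_by_key,
        stacks=stacks,
        host_truth=host_truth,
        parasite_truth=parasite_truth,
        occurrences=occurrences,
    )


def make_truth(
    cfg: WorldConfig, latents: np.ndarray, spec: GridSpec
) -> tuple[dict[str, Layer], Layer]:
    """Two-level logistic ground truth: hosts from latents, parasite from hosts."""
    full_mask = np.ones(spec.shape, dtype=bool)
    intercepts = cfg.host_intercepts or {}
    hosts: dict[str, Layer] = {}
    host_fields = []
    for name, w in cfg.host_coefficients.items():
        alpha = intercepts.get(name, -1.0)
        truth = expit(alpha + np.einsum("l,lrc->rc", w, latents))
        hosts[name] = Layer(spec, truth, full_mask.copy())
        host_fields.append(truth)
    para = expit(
        cfg.parasite_intercept
        + np.einsum("h,hrc->rc", np.asarray(cfg.parasite_weights, dtype=float), np.stack(host_fields))
    )
    return hosts, Layer(spec, para, full_mask.copy())


def sample_occurrences(truth: Layer, n: int, seed: int, species: str = "species") -> OccurrenceSet:
    """Draw n cells without replacement, probability proportional to truth.

    Records are cell centres jittered uniformly within the cell so that
    spatial thinning has real work to do on the way back in.
    """
    rng = np.random.default_rng(seed)
    mask = truth.valid_mask
    weights = truth.values[mask]
    if np.any(weights < 0) or np.any(weights > 1):
        raise SyntheticError("truth must lie in [0, 1]")
    total = weights.sum()
    if total <= 0:
        raise SyntheticError("truth is zero everywhere; nothing to sample")
    if n > mask.sum():
        raise SyntheticError("cannot sample more presences than valid cells")
    flat = np.flatnonzero(mask.ravel())
    p = weights / total
    chosen = rng.choice(flat, size=n, replace=False, p=p)
    rows, cols = np.divmod(chosen, truth.spec.n_cols)
    lon_c, lat_c = truth.spec.cell_center(rows, cols)
    half = truth.spec.cell_size / 2
    lon = lon_c + rng.uniform(-half, half, size=n) * 0.999
    lat = lat_c + rng.uniform(-half, half, size=n) * 0.999
    return OccurrenceSet(species, np.column_stack([lon, lat]))
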