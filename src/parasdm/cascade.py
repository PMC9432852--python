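"""Two-stage host -> parasite modelling pipeline.

The parasite is a holoparasite: where it can live is governed by where its
host plants can live.  The pipeline therefore runs MaxEnt twice.  Stage one
fits one model per host plant on the reduced environmental components (PCs)
and predicts a host suitability layer each; stage two fits the parasite
model using those host suitability layers as its covariates.  Candidate
settings (feature-class combination x regularisation multiplier) are scored
by hierarchical-checkerboard cross-validation and the maximum mean CBI wins;
the winner is refit on all presences before prediction.

Models are selected and fitted on the current scenario only and transferred
frozen to every future scenario: future occurrences do not exist, so there
is nothing to refit on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import evaluation as ev
from . import maxent as mx
from .geodata import (
    GeodataError,
    Layer,
    OccurrenceSet,
    ScenarioKey,
    Stack,
    average_gcms,
    occurrence_cells,
    thin_to_cells,
)
from .pca import PcaTransform, project

logger = logging.getLogger(__name__)


class CascadeError(ValueError):
    pass


@dataclass
class CascadeConfig:
    """Candidate grid and evaluation settings shared by both stages."""

    classes: tuple[str, ...] = mx.CLASS_COMBOS
    rms: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    background_n: int = 10_000
    k_h: int = 20
    a1: int = 2
    a2: int = 2
    cbi_windows: int = 101
    cbi_window_frac: float = 0.1
    or_percentile: float = 10.0
    min_presences: int = 10
    output: str = "cloglog"
    tol: float = 1e-4
    max_iter: int = 5000


@dataclass
class SpeciesFit:
    """Selected model for one species plus its cross-validation record."""

    species: str
    settings: tuple[str, float]  # (feature classes, regularisation multiplier)
    model: mx.MaxentModel
    metrics: ev.EvalMetrics
    suitability: Layer
    all_metrics: list[tuple[tuple[str, float], ev.EvalMetrics | None]]
    n_presences: int
    seed: int


@dataclass
class CascadeRun:
    """One scenario's worth of pipeline output."""

    scenario: ScenarioKey
    host_fits: dict[str, SpeciesFit] | None
    host_suitability: Stack
    parasite_fit: SpeciesFit | None
    parasite_suitability: Layer
    seeds: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# candidate evaluation


def evaluate_candidates(
    occ: OccurrenceSet,
    stack: Stack,
    config: CascadeConfig,
    seed: int,
) -> SpeciesFit:
    """Thin, partition, score the candidate grid, select by max CBI, refit.

    The returned fit carries the final model (refit on all thinned
    presences), its fold metrics under the selected settings, and the full
    candidate record.
    """
    thinned = thin_to_cells(occ, stack.spec)
    if len(thinned) < config.min_presences:
        raise CascadeError(
            f"{occ.species}: only {len(thinned)} thinned presences "
            f"(< {config.min_presences})"
        )
    rng = np.random.default_rng(seed)
    X_bg, bg_flat = mx.sample_background(stack, config.background_n, rng)
    bg_cells = np.column_stack(np.divmod(bg_flat, stack.spec.n_cols))
    X_pres = mx.covariates_at(thinned, stack)
    pres_cells = occurrence_cells(thinned, stack.spec)
    mask = stack.joint_mask()
    ok = mask[pres_cells[:, 0], pres_cells[:, 1]]
    pres_cells = pres_cells[ok]

    part = ev.checkerboard_partition(pres_cells, bg_cells, stack.spec, config.a1, config.a2)
    names = stack.names

    candidates: list[tuple[tuple[str, float], ev.EvalMetrics | None]] = []
    for classes in config.classes:
        for rm in config.rms:
            metrics = _cross_validate(
                X_pres, X_bg, part, names, classes, rm, config
            )
            candidates.append(((classes, rm), metrics))

    scored = [(s, m) for s, m in candidates if m is not None]
    if not scored:
        raise CascadeError(f"{occ.species}: no candidate could be evaluated")
    settings = ev.select_model(scored)
    classes, rm = settings
    final = mx.train_maxent(
        X_pres, X_bg, names, classes=classes, rm=rm, k_h=config.k_h,
        output=config.output, tol=config.tol, max_iter=config.max_iter,
    )
    suitability = mx.predict(final, stack)
    metrics = dict(scored)[settings]
    logger.info(
        "%s: selected classes=%s rm=%g (CBI %.3f, AUC %.3f, OR %.3f) from %d candidates",
        occ.species, classes, rm, metrics.cbi_mean, metrics.auc_mean, metrics.or_mean,
        len(candidates),
    )
    return SpeciesFit(
        species=occ.species,
        settings=settings,
        model=final,
        metrics=metrics,
        suitability=suitability,
        all_metrics=candidates,
        n_presences=len(thinned),
        seed=seed,
    )


def _cross_validate(
    X_pres: np.ndarray,
    X_bg: np.ndarray,
    part: ev.CvPartition,
    names: list[str],
    classes: str,
    rm: float,
    config: CascadeConfig,
) -> ev.EvalMetrics | None:
    fold_ids, aucs, cbis, ors = [], [], [], []
    for fold in range(1, 5):
        test_p = part.presence_folds == fold
        test_b = part.background_folds == fold
        if not test_p.any() or test_p.all() or not test_b.any() or test_b.all():
            continue
        try:
            model = mx.train_maxent(
                X_pres[~test_p], X_bg[~test_b], names, classes=classes, rm=rm,
                k_h=config.k_h, output=config.output, tol=config.tol,
                max_iter=config.max_iter,
            )
            pred_test_p = model.predict_matrix(X_pres[test_p])
            pred_train_p = model.predict_matrix(X_pres[~test_p])
            pred_landscape = model.predict_matrix(X_bg)
            aucs.append(ev.auc(pred_test_p, model.predict_matrix(X_bg[test_b])))
            cbis.append(
                ev.cbi(pred_test_p, pred_landscape,
                       n_windows=config.cbi_windows,
                       window_frac=config.cbi_window_frac).cbi
            )
            ors.append(ev.omission_rate(pred_train_p, pred_test_p, config.or_percentile))
            fold_ids.append(fold)
        except (mx.ConvergenceError, ev.EvaluationError, mx.MaxentError) as exc:
            logger.warning("fold %d (classes=%s rm=%g) skipped: %s", fold, classes, rm, exc)
    if not fold_ids:
        return None
    return ev.EvalMetrics(fold_ids, aucs, cbis, ors)


# ---------------------------------------------------------------------------
# pipeline stages


def fit_hosts(
    host_occs: list[OccurrenceSet],
    pc_stack: Stack,
    config: CascadeConfig,
    seed: int = 0,
) -> tuple[dict[str, SpeciesFit], Stack]:
    """Fit and select one model per host; returns fits plus the host suitability stack."""
    if not host_occs:
        raise CascadeError("need at least one host occurrence set")
    seeds = np.random.SeedSequence(seed).generate_state(len(host_occs)) % (2**31 - 1)
    fits: dict[str, SpeciesFit] = {}
    suit = Stack(pc_stack.spec)
    for occ, s in zip(host_occs, seeds):
        try:
            fit = evaluate_candidates(occ, pc_stack, config, int(s))
        except CascadeError as exc:
            logger.warning("host skipped: %s", exc)
            continue
        fits[occ.species] = fit
        suit.add(occ.species, fit.suitability)
    if not fits:
        raise CascadeError("every host was skipped; cannot continue")
    return fits, suit


def fit_parasite(
    parasite_occ: OccurrenceSet,
    host_suitability: Stack,
    config: CascadeConfig,
    seed: int = 1,
) -> SpeciesFit:
    """Fit and select the parasite model on host suitability covariates."""
    if len(host_suitability) == 0:
        raise CascadeError("host suitability stack is empty")
    return evaluate_candidates(parasite_occ, host_suitability, config, seed)


def run_current(
    host_occs: list[OccurrenceSet],
    env_stack: Stack,
    transform: PcaTransform,
    parasite_occ: OccurrenceSet,
    config: CascadeConfig,
    seed: int = 0,
) -> CascadeRun:
    """Full current-scenario pipeline: PCs -> host fits -> parasite fit."""
    pc_stack = project(env_stack, transform)
    host_seed, parasite_seed = (
        int(s) for s in np.random.SeedSequence(seed).generate_state(2) % (2**31 - 1)
    )
    host_fits, host_suit = fit_hosts(host_occs, pc_stack, config, host_seed)
    parasite_fit = fit_parasite(parasite_occ, host_suit, config, parasite_seed)
    return CascadeRun(
        scenario=ScenarioKey("current"),
        host_fits=host_fits,
        host_suitability=host_suit,
        parasite_fit=parasite_fit,
        parasite_suitability=parasite_fit.suitability,
        seeds={"master": seed, "hosts": host_seed, "parasite": parasite_seed},
    )


def project_scenario(
    run_cur: CascadeRun,
    future_env: list[Stack],
    transform: PcaTransform,
    key: ScenarioKey,
) -> CascadeRun:
    """Transfer the frozen current-scenario models to one future scenario.

    GCM variants are ensembled by cellwise mean, projected into the frozen PC
    space, host predictions made with the frozen host models, and the
    parasite predicted from those host layers.  Nothing is refit.
    """
    if run_cur.host_fits is None or run_cur.parasite_fit is None:
        raise CascadeError("current run must carry fitted models")
    if not future_env:
        raise CascadeError("no future environmental stacks supplied")
    env = future_env[0] if len(future_env) == 1 else average_gcms(future_env)
    if env.spec != run_cur.host_suitability.spec:
        raise GeodataError("future stacks are on a different grid")
    pc_stack = project(env, transform)
    host_suit = Stack(pc_stack.spec)
    for host, fit in run_cur.host_fits.items():
        host_suit.add(host, mx.predict(fit.model, pc_stack))
    parasite_layer = mx.predict(run_cur.parasite_fit.model, host_suit)
    return CascadeRun(
        scenario=key,
        host_fits=None,
        host_suitability=host_suit,
        parasite_fit=None,
        parasite_suitability=parasite_layer,
        seeds=dict(run_cur.seeds),
    )
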