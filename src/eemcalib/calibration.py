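"""Model selection, figures of merit, and the end-to-end UPCA-ANN pipeline.

The pipeline: unfold the cube, fit PCA, screen the PC1-PC2 score plot for
outliers, split the scores calibration/validation/test by Kennard-Stone,
pick the number of components by leave-one-out cross-validation, optionally
scan hyperparameter response surfaces, train the final network with early
stopping, and report RMSE, REP%, R^2, and LOD/LOQ.

Two REP% conventions coexist in this field and both are provided:
``rep_per_sample`` is the signed per-sample relative error
100*(predicted - nominal)/nominal, while ``rep_aggregate`` is
100*RMSE/mean(true) — the scalar usually quoted next to RMSEP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .bpnn import NetworkState, ScalingParams, TrainConfig, TrainResult, init_network, mse_loss, predict, train
from .eem_data import EEMCube
from .kennard_stone import SplitAssignment, three_way_split
from .upca import PCAModel, UnfoldedMatrix, fit_pca, flag_outliers, project, unfold

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Figures of merit

def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean square error, sqrt(sum((yhat - y)^2)/n)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y_true.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def rep_per_sample(nominal: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Signed per-sample relative error of prediction, 100*(yhat - y)/y."""
    nominal = np.atleast_1d(np.asarray(nominal, dtype=float))
    predicted = np.atleast_1d(np.asarray(predicted, dtype=float))
    if np.any(nominal <= 0):
        raise ValueError("per-sample REP%% needs nominal concentrations > 0")
    return 100.0 * (predicted - nominal) / nominal


def rep_aggregate(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Aggregate relative error of prediction, 100*RMSE/mean(y_true)."""
    mean_true = float(np.mean(y_true))
    if mean_true <= 0:
        raise ValueError("aggregate REP%% needs a positive mean true concentration")
    return 100.0 * rmse(y_true, y_pred) / mean_true


def r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant y_true")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


def lod_loq(blank_predictions: np.ndarray) -> tuple[float, float]:
    """Univariate detection/quantification limits from blank predictions.

    S_b is the sample standard deviation (ddof=1) of the concentrations the
    model predicts for blank solutions; LOD = 3*S_b, LOQ = 10*S_b.
    """
    blanks = np.asarray(blank_predictions, dtype=float)
    if blanks.size < 2:
        raise ValueError("need at least 2 blank predictions")
    s_b = float(np.std(blanks, ddof=1))
    return 3.0 * s_b, 10.0 * s_b


@dataclass
class FigureOfMeritReport:
    rmse_calibration: float
    rmse_validation: float
    rmse_prediction: float
    r2_calibration: float
    r2_validation: float
    r2_prediction: float
    rep_pct_aggregate: float
    rep_pct_per_sample: np.ndarray
    rmse_cv: float | None = None
    r2_cv: float | None = None
    lod: float | None = None
    loq: float | None = None
    dynamic_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.lod is not None and self.loq is not None and self.lod > self.loq:
            raise ValueError("LOD cannot exceed LOQ")


# ---------------------------------------------------------------------------
# Model selection

def _train_once(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    n_hidden: int,
) -> tuple[TrainResult, ScalingParams]:
    scaling = ScalingParams.fit(X_cal, y_cal)
    state = init_network(X_cal.shape[1], n_hidden, seed=config.seed)
    result = train(
        state,
        scaling.scale_x(X_cal),
        scaling.scale_y(y_cal),
        scaling.scale_x(X_val),
        scaling.scale_y(y_val),
        config,
    )
    return result, scaling


def select_n_pcs(
    scores: np.ndarray,
    y: np.ndarray,
    candidates: list[int],
    config: TrainConfig,
    n_hidden: int = 5,
) -> tuple[int, dict[int, float]]:
    """Choose the number of leading PCs by leave-one-out cross-validation.

    For each candidate n, every calibration sample is left out in turn, a
    network is trained on the rest for the configured epoch budget (early
    stopping monitors the training fold itself, so the left-out sample never
    influences the fit), and its concentration predicted; the candidate
    minimizing RMSEcv wins, ties to the smaller n.  Returns the winner and
    the full RMSEcv curve.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(candidates) == 0:
        raise ValueError("empty candidate range")
    if scores.shape[0] < 3:
        raise ValueError("LOO selection needs at least 3 calibration samples")
    m = scores.shape[0]
    curve: dict[int, float] = {}
    for n in sorted(candidates):
        preds = np.empty(m)
        for i in range(m):
            mask = np.ones(m, dtype=bool)
            mask[i] = False
            X_tr, y_tr = scores[mask, :n], y[mask]
            X_out = scores[~mask, :n]
            cfg = replace(config, seed=config.seed + 1000 * n + i)
            result, scaling = _train_once(X_tr, y_tr, X_tr, y_tr, cfg, n_hidden)
            preds[i] = predict(result.state, scaling, X_out)[0]
        curve[n] = rmse(y, preds)
    best = min(curve, key=lambda n: (curve[n], n))
    return best, curve


@dataclass
class SelectionSurface:
    """Grid of test-set MSE over two hyperparameter axes."""

    axis1_name: str
    axis1_values: list
    axis2_name: str
    axis2_values: list
    mse: np.ndarray  # (len(axis1), len(axis2))
    argmin: tuple[int, int]

    @property
    def best_values(self) -> tuple:
        return (self.axis1_values[self.argmin[0]], self.axis2_values[self.argmin[1]])


_SCANNABLE = {"n_hidden", "max_epochs", "learning_rate", "momentum"}


def surface_scan(
    axis1: tuple[str, list],
    axis2: tuple[str, list],
    data: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    base_config: TrainConfig,
    n_hidden: int = 5,
) -> SelectionSurface:
    """Response-surface scan: train one model per grid cell, record test MSE.

    ``data`` is (X_cal, y_cal, X_val, y_val, X_test, y_test).  Each cell
    gets a deterministic seed derived from the base seed and cell index.
    The argmin is the minimal finite cell; exact ties resolve to the
    earlier cell in row-major order, so with axes listed small-to-large the
    smallest model wins.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    if name1 not in _SCANNABLE or name2 not in _SCANNABLE:
        raise ValueError(f"scannable axes are {_SCANNABLE}")
    if len(vals1) == 0 or len(vals2) == 0:
        raise ValueError("empty scan axis")
    X_cal, y_cal, X_val, y_val, X_test, y_test = data
    mse = np.full((len(vals1), len(vals2)), np.inf)
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            params = {name1: v1, name2: v2}
            nh = int(params.pop("n_hidden", n_hidden))
            cfg = replace(
                base_config,
                seed=base_config.seed + i * len(vals2) + j,
                **params,
            )
            result, scaling = _train_once(X_cal, y_cal, X_val, y_val, cfg, nh)
            mse[i, j] = mse_loss(result.state, scaling.scale_x(X_test), scaling.scale_y(y_test))
    flat = int(np.argmin(mse))  # first minimum in row-major order
    argmin = (flat // len(vals2), flat % len(vals2))
    return SelectionSurface(name1, list(vals1), name2, list(vals2), mse, argmin)


# ---------------------------------------------------------------------------
# End-to-end pipeline

@dataclass
class PipelineConfig:
    """Everything the end-to-end run depends on, for exact reproducibility."""

    n_pc_max: int = 10
    pc_candidates: list[int] | None = None  # None -> fixed n_pcs, no LOO scan
    n_pcs: int = 6
    n_hidden: int = 5
    train: TrainConfig = field(default_factory=TrainConfig)
    split_fractions: tuple[float, float, float] = (0.65, 0.15, 0.20)
    outlier_threshold: float = 3.0
    scan_hidden_epochs: tuple[list, list] | None = None
    scan_rate_momentum: tuple[list, list] | None = None
    leak_free_split: bool = False
    compute_lod: bool = True
    loo_config: TrainConfig | None = None  # lighter settings for the LOO scan


@dataclass
class PipelineResult:
    report: FigureOfMeritReport
    split: SplitAssignment
    pca: PCAModel
    n_pcs: int
    train_result: TrainResult
    scaling: ScalingParams
    outlier_indices: list[int]
    rmse_cv_curve: dict[int, float] | None = None
    surfaces: list[SelectionSurface] = field(default_factory=list)
    predictions: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def run_pipeline(cube: EEMCube, config: PipelineConfig | None = None) -> PipelineResult:
    """Unfold -> PCA -> Kennard-Stone split -> (optional) factor selection and
    response-surface scans -> final early-stopped training -> figures of merit.

    Blank samples (role ``blank``) are kept out of the split and used only
    to estimate LOD/LOQ.  By default PCA is fitted on all non-blank samples
    before splitting, mirroring standard practice for this workflow; set
    ``leak_free_split`` to fit PCA on the calibration set alone (the rest
    projected), at the cost of comparability.
    """
    if config is None:
        config = PipelineConfig()

    non_blank = [s for s in cube.samples if s.role != "blank"]
    blanks = [s.sample_id for s in cube.samples if s.role == "blank"]
    ids = [s.sample_id for s in non_blank]
    conc = {s.sample_id: s.concentration for s in non_blank}
    if any(conc[i] is None for i in ids):
        raise ValueError("pipeline stage 'setup': every non-blank sample needs a concentration")

    logger.info("stage unfold: cube %s", cube.shape)
    unfolded = unfold(cube)
    row_of = {sid: i for i, sid in enumerate(unfolded.sample_ids)}
    nb_rows = [row_of[i] for i in ids]

    nb_matrix = UnfoldedMatrix(
        values=unfolded.values[nb_rows],
        column_map=unfolded.column_map,
        sample_ids=ids,
    )

    k = min(config.n_pc_max, len(ids) - 1, nb_matrix.n_variables)
    logger.info("stage pca: k=%d", k)
    if config.leak_free_split:
        logger.warning("leak_free_split: PCA fitted on calibration rows only; "
                       "scores are not comparable with the default mode")
        # provisional PCA on everything just to order samples for the split
        provisional = fit_pca(nb_matrix, k)
        split = three_way_split(provisional.scores, ids, config.split_fractions)
        cal_rows = [ids.index(i) for i in split.calibration_ids]
        cal_matrix = UnfoldedMatrix(
            values=nb_matrix.values[cal_rows],
            column_map=nb_matrix.column_map,
            sample_ids=list(split.calibration_ids),
        )
        pca = fit_pca(cal_matrix, min(k, len(cal_rows) - 1))
    else:
        pca = fit_pca(nb_matrix, k)
        split = three_way_split(pca.scores, ids, config.split_fractions)

    outliers = flag_outliers(pca, config.outlier_threshold) if pca.k >= 2 else []
    if outliers:
        flagged = outliers if config.leak_free_split else [ids[i] for i in outliers]
        logger.info("score-plot screening flags samples %s (reported, not removed)", flagged)

    scores_all = project(pca, nb_matrix, pca.k)
    score_of = {sid: scores_all[i] for i, sid in enumerate(ids)}
    y_of = {sid: conc[sid] for sid in ids}

    def xy(id_list):
        X = np.array([score_of[i] for i in id_list])
        y = np.array([y_of[i] for i in id_list])
        return X, y

    X_cal_full, y_cal = xy(split.calibration_ids)
    X_val_full, y_val = xy(split.validation_ids)
    X_test_full, y_test = xy(split.test_ids)

    rmse_cv_curve = None
    rmse_cv = r2_cv = None
    n_pcs = config.n_pcs
    if config.pc_candidates:
        loo_cfg = config.loo_config or config.train
        logger.info("stage select_n_pcs: candidates %s", config.pc_candidates)
        n_pcs, rmse_cv_curve = select_n_pcs(
            X_cal_full, y_cal, config.pc_candidates, loo_cfg, config.n_hidden
        )
    n_pcs = min(n_pcs, pca.k)

    X_cal, X_val, X_test = (X[:, :n_pcs] for X in (X_cal_full, X_val_full, X_test_full))

    surfaces = []
    cfg = config.train
    n_hidden = config.n_hidden
    if config.scan_hidden_epochs:
        vals_h, vals_e = config.scan_hidden_epochs
        surf = surface_scan(("n_hidden", vals_h), ("max_epochs", vals_e),
                            (X_cal, y_cal, X_val, y_val, X_test, y_test), cfg)
        surfaces.append(surf)
        n_hidden = int(surf.best_values[0])
        cfg = replace(cfg, max_epochs=int(surf.best_values[1]))
        logger.info("stage scan hidden x epochs: best %s", surf.best_values)
    if config.scan_rate_momentum:
        vals_lr, vals_mo = config.scan_rate_momentum
        surf = surface_scan(("learning_rate", vals_lr), ("momentum", vals_mo),
                            (X_cal, y_cal, X_val, y_val, X_test, y_test), cfg, n_hidden)
        surfaces.append(surf)
        cfg = replace(cfg, learning_rate=float(surf.best_values[0]),
                      momentum=float(surf.best_values[1]))
        logger.info("stage scan rate x momentum: best %s", surf.best_values)

    logger.info("stage final train: %d-%d-1, lr=%.2f, momentum=%.2f, epochs=%d",
                n_pcs, n_hidden, cfg.learning_rate, cfg.momentum, cfg.max_epochs)
    result, scaling = _train_once(X_cal, y_cal, X_val, y_val, cfg, n_hidden)

    pred_cal = predict(result.state, scaling, X_cal)
    pred_val = predict(result.state, scaling, X_val)
    pred_test = predict(result.state, scaling, X_test)

    # LOO-CV statistics of the final factor count (fast: reuse the LOO curve
    # when the scan already ran with this n)
    if config.pc_candidates and n_pcs in (rmse_cv_curve or {}):
        rmse_cv = rmse_cv_curve[n_pcs]

    lod = loq = None
    if config.compute_lod and blanks:
        if len(blanks) < 2:
            raise ValueError("pipeline stage 'lod': need >= 2 blank samples")
        blank_rows = [row_of[b] for b in blanks]
        blank_matrix = UnfoldedMatrix(
            values=unfolded.values[blank_rows],
            column_map=unfolded.column_map,
            sample_ids=blanks,
        )
        blank_scores = project(pca, blank_matrix, pca.k)[:, :n_pcs]
        blank_pred = predict(result.state, scaling, blank_scores)
        lod, loq = lod_loq(blank_pred)
        logger.info("stage lod: S_b-based LOD %.3e M", lod)

    report = FigureOfMeritReport(
        rmse_calibration=rmse(y_cal, pred_cal),
        rmse_validation=rmse(y_val, pred_val),
        rmse_prediction=rmse(y_test, pred_test),
        r2_calibration=r2(y_cal, pred_cal),
        r2_validation=r2(y_val, pred_val),
        r2_prediction=r2(y_test, pred_test),
        rep_pct_aggregate=rep_aggregate(y_test, pred_test),
        rep_pct_per_sample=rep_per_sample(y_test, pred_test),
        rmse_cv=rmse_cv,
        r2_cv=r2_cv,
        lod=lod,
        loq=loq,
        dynamic_range=(float(np.min(y_cal)), float(np.max(y_cal))),
    )
    return PipelineResult(
        report=report,
        split=split,
        pca=pca,
        n_pcs=n_pcs,
        train_result=result,
        scaling=scaling,
        outlier_indices=outliers,
        rmse_cv_curve=rmse_cv_curve,
        surfaces=surfaces,
        predictions={
            "calibration": (y_cal, pred_cal),
            "validation": (y_val, pred_val),
            "test": (y_test, pred_test),
        },
    )
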