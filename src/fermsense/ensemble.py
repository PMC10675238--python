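"""Weighted-ensemble soft sensor: model and results objects.

The estimator follows a local-modelling recipe for multi-stage batch
processes:

1. select auxiliary variables whose grey-relational degree with the
   target exceeds a threshold (default 0.7);
2. partition the training rows into local sample subsets with adaptive
   density-peak clustering on the z-scored selected features;
3. fit one GP regression per subset, its kernel hyperparameters tuned
   by the improved seagull optimizer;
4. summarise each subset by its entropy-weighted grey centroid
   Z_m = w * Z*.

At prediction time a test sample is compared with every weighted
centroid by grey-relational degree; sub-models with degree >= omega*
(default 0.7) are retained (falling back to the single best when none
pass) and their predictive means fused with weights proportional to the
degrees, so the ensemble output is a convex combination of the selected
sub-model outputs.

Usage::

    model = WeightedEnsembleSoftSensor(train, target="P")
    res = model.fit(seed=1)
    print(res.summary())
    yhat = res.predict(test)
    report = res.evaluate(test)

``GlobalGPRSoftSensor`` is the matching single-global baseline: the
same preprocessing and tuning on the undivided training set.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import adpc
from .datamodel import BatchDataset, Scaler, max_abs_error, rmse
from .gpr import GPRModel, Hyperparams, gpr_fit, gpr_predict, tune_with_isoa
from .grey import GreyConfig, WeightedCentroid, gate_degrees, select_aux_variables, weighted_centroid
from .isoa import SwarmConfig

__all__ = [
    "PipelineConfig",
    "SubModel",
    "Prediction",
    "WeightedEnsembleSoftSensor",
    "GlobalGPRSoftSensor",
    "SoftSensorResults",
    "EvaluationReport",
    "compare_to_global",
]


@dataclass
class PipelineConfig:
    """Everything tunable about the fit, in one place.

    aux_threshold : grey-degree cut for auxiliary-variable selection.
    omega_star : gating threshold on the test-sample/centroid degree.
    include_time : append the time index as an auxiliary feature.
    dist_c_percentile, k_max, min_cluster_size : clustering controls;
        clusters smaller than ``min_cluster_size`` are merged into the
        nearest one before sub-models are fitted.
    swarm : ISOA budget for hyperparameter tuning.
    tune_criterion : "nlml" or "cv_rmse".
    log_hyper_bounds : box for the log hyperparameters.
    """

    aux_threshold: float = 0.7
    omega_star: float = 0.7
    grey: GreyConfig = field(default_factory=GreyConfig)
    include_time: bool = True
    dist_c_percentile: float = 2.0
    # batch fermentations traverse 2-4 macroscopic phases; capping the
    # cluster search there avoids shattering one phase across sub-models
    k_max: int | None = 4
    min_cluster_size: int = 5
    include_drop_point: bool = False
    swarm: SwarmConfig = field(default_factory=lambda: SwarmConfig(population=12, max_iter=30))
    tune_criterion: str = "nlml"
    log_hyper_bounds: tuple[float, float] = (-5.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.omega_star <= 1.0:
            raise ValueError("omega_star must lie in (0, 1]")


@dataclass
class SubModel:
    """One local sample subset: rows, tuned GP, grey centroid."""

    row_indices: np.ndarray
    gpr: GPRModel
    centroid: WeightedCentroid
    tune_info: dict


@dataclass
class Prediction:
    """Fused prediction of one sample with its gating diagnostics."""

    y_hat: float
    omegas: np.ndarray                # (m,)
    selected: np.ndarray              # indices into sub-models
    normalized_weights: np.ndarray    # over selected, sums to 1
    sub_means: np.ndarray             # (m,) all sub-model means


@dataclass
class EvaluationReport:
    target: str
    rmse: float
    max_abs_error: float
    frame: pd.DataFrame               # actual, predicted, abs_error per row

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


class _BaseSoftSensor:
    """Shared preprocessing: time feature, grey variable selection, scaling."""

    def __init__(self, train: BatchDataset, target: str, config: PipelineConfig | None = None):
        if train.n_batches < 2:
            raise ValueError("need at least 2 training batches")
        if target not in train.target_names:
            raise ValueError(f"unknown target {target!r}")
        self.train = train
        self.target = target
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        target: str,
        aux: tuple[str, ...],
        targets: tuple[str, ...] | None = None,
        batch_col: str = "batch_id",
        time_col: str = "time_index",
        config: PipelineConfig | None = None,
    ):
        from .datamodel import ColumnSchema

        schema = ColumnSchema(batch=batch_col, time=time_col, aux=tuple(aux),
                              targets=tuple(targets or (target,)))
        return cls(BatchDataset.from_frame(df, schema), target, config)

    def _prepare(self):
        """Variable selection and scaling.

        The GPR sub-models see the z-scored *selected* variables; the
        grey centroids and the gate work on the min-max scaled *full*
        auxiliary set, whose channel pattern identifies the process
        regime regardless of which channels predict this target.
        """
        cfg = self.config
        ds = self.train.with_time_feature() if cfg.include_time else self.train
        selected, degrees = select_aux_variables(ds, self.target, cfg.aux_threshold, cfg.grey)
        X_sel = ds.aux_matrix(selected)
        X_full = ds.aux
        zscaler = Scaler("zscore").fit(X_sel)
        mscaler = Scaler("minmax").fit(X_full)
        y = ds.target_vector(self.target)
        return ds, selected, degrees, X_sel, X_full, zscaler, mscaler, y


class WeightedEnsembleSoftSensor(_BaseSoftSensor):
    """Density-peak partitioned, ISOA-tuned GPR ensemble with grey gating."""

    def fit(self, seed: int | None = None) -> "SoftSensorResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        t0 = time.perf_counter()
        ds, selected, degrees, X_sel, X_full, zscaler, mscaler, y = self._prepare()
        Xz = zscaler.transform(X_sel)
        Xm = mscaler.transform(X_full)

        part, profile = adpc.cluster(
            Xz,
            dist_c_percentile=cfg.dist_c_percentile,
            k_max=cfg.k_max,
            include_drop_point=cfg.include_drop_point,
        )
        part = adpc.merge_small_clusters(Xz, part, cfg.min_cluster_size)

        submodels: list[SubModel] = []
        for j, label in enumerate(range(1, part.k + 1)):
            rows = part.members(label)
            swarm = replace(cfg.swarm, seed=(seed + 1000 * (j + 1)) % 2**31)
            model, info = tune_with_isoa(
                Xz[rows], y[rows], swarm,
                criterion=cfg.tune_criterion, log_bounds=cfg.log_hyper_bounds,
            )
            cen = weighted_centroid(Xm[rows], cfg.grey)
            submodels.append(SubModel(row_indices=rows, gpr=model, centroid=cen, tune_info=info))

        return SoftSensorResults(
            kind="ensemble",
            target=self.target,
            config=cfg,
            selected_aux=tuple(selected),
            gate_aux=ds.aux_names,
            aux_degrees=degrees,
            zscaler=zscaler,
            mscaler=mscaler,
            partition=part,
            profile=profile,
            submodels=submodels,
            n_train=ds.n_rows,
            seed=seed,
            fit_seconds=time.perf_counter() - t0,
        )


class GlobalGPRSoftSensor(_BaseSoftSensor):
    """Single global ISOA-tuned GPR on the full training set (baseline)."""

    def fit(self, seed: int | None = None) -> "SoftSensorResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        t0 = time.perf_counter()
        ds, selected, degrees, X_sel, X_full, zscaler, mscaler, y = self._prepare()
        Xz = zscaler.transform(X_sel)
        Xm = mscaler.transform(X_full)
        swarm = replace(cfg.swarm, seed=(seed + 1000) % 2**31)
        model, info = tune_with_isoa(
            Xz, y, swarm, criterion=cfg.tune_criterion, log_bounds=cfg.log_hyper_bounds
        )
        cen = weighted_centroid(Xm, cfg.grey)
        sub = SubModel(row_indices=np.arange(ds.n_rows), gpr=model, centroid=cen, tune_info=info)
        return SoftSensorResults(
            kind="global",
            target=self.target,
            config=cfg,
            selected_aux=tuple(selected),
            gate_aux=ds.aux_names,
            aux_degrees=degrees,
            zscaler=zscaler,
            mscaler=mscaler,
            partition=None,
            profile=None,
            submodels=[sub],
            n_train=ds.n_rows,
            seed=seed,
            fit_seconds=time.perf_counter() - t0,
        )


@dataclass
class SoftSensorResults:
    """Fitted soft sensor: sub-models, gating data and diagnostics."""

    kind: str
    target: str
    config: PipelineConfig
    selected_aux: tuple[str, ...]     # GPR inputs (z-scored)
    gate_aux: tuple[str, ...]         # gating/centroid inputs (min-max scaled)
    aux_degrees: dict[str, float]
    zscaler: Scaler
    mscaler: Scaler
    partition: adpc.Partition | None
    profile: adpc.DensityProfile | None
    submodels: list[SubModel]
    n_train: int
    seed: int
    fit_seconds: float

    @property
    def m(self) -> int:
        return len(self.submodels)

    # -- prediction ------------------------------------------------------
    def _gate_matrix(self, data) -> np.ndarray:
        """Full auxiliary matrix (gating feature space)."""
        if isinstance(data, BatchDataset):
            ds = data.with_time_feature() if self.config.include_time else data
            return ds.aux_matrix(self.gate_aux)
        X = np.atleast_2d(np.asarray(data, dtype=float))
        if X.shape[1] != len(self.gate_aux):
            raise ValueError(
                f"expected {len(self.gate_aux)} features {self.gate_aux}, got {X.shape[1]}"
            )
        return X

    def _features(self, data) -> np.ndarray:
        """Selected-variable matrix (GPR feature space)."""
        if isinstance(data, BatchDataset):
            ds = data.with_time_feature() if self.config.include_time else data
            return ds.aux_matrix(self.selected_aux)
        X = self._gate_matrix(data)
        idx = [self.gate_aux.index(name) for name in self.selected_aux]
        return X[:, idx]

    def gate_and_weigh(self, data) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
        """Grey gating of every row: omega matrix, selected sets, weights.

        omega_i is the grey degree between the (min-max scaled) sample
        and sub-model i's weighted centroid Z_m, both expressed in that
        sub-model's entropy-weighted feature space; the min/max block
        spans all m centroids of the sample.  Gating operates on the full
        auxiliary channel set, not the per-target selected variables.
        """
        Xm = self.mscaler.transform(self._gate_matrix(data))
        Z = np.vstack([s.centroid.z_weighted for s in self.submodels])
        W = np.vstack([s.centroid.weights for s in self.submodels])
        omegas = gate_degrees(Xm, W, Z, self.config.grey)       # (n, m)
        selected, weights = [], []
        for om in omegas:
            sel = np.flatnonzero(om >= self.config.omega_star)
            if sel.size == 0:
                sel = np.array([int(np.argmax(om))])
            w = om[sel] / om[sel].sum()
            selected.append(sel)
            weights.append(w)
        return omegas, selected, weights

    def _sub_means(self, data) -> np.ndarray:
        X_raw = self._features(data)
        Xz = self.zscaler.transform(X_raw)
        return np.column_stack([gpr_predict(s.gpr, Xz)[0] for s in self.submodels])

    def predict(self, data) -> np.ndarray:
        """Fused predictive means, one per row."""
        means = self._sub_means(data)                            # (n, m)
        _, selected, weights = self.gate_and_weigh(data)
        out = np.empty(means.shape[0])
        for i, (sel, w) in enumerate(zip(selected, weights)):
            out[i] = float(means[i, sel] @ w)
        return out

    def predict_one(self, x) -> Prediction:
        """Single-sample prediction with full gating diagnostics."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        means = self._sub_means(x)[0]
        omegas, selected, weights = self.gate_and_weigh(x)
        sel, w = selected[0], weights[0]
        return Prediction(
            y_hat=float(means[sel] @ w),
            omegas=omegas[0],
            selected=sel,
            normalized_weights=w,
            sub_means=means,
        )

    # -- evaluation -------------------------------------------------------
    def evaluate(self, test: BatchDataset) -> EvaluationReport:
        y = test.target_vector(self.target)
        yhat = self.predict(test)
        frame = pd.DataFrame(
            {
                "batch_id": test.batch_id,
                "time_index": test.time_index,
                "actual": y,
                "predicted": yhat,
                "abs_error": np.abs(y - yhat),
            }
        )
        return EvaluationReport(
            target=self.target, rmse=rmse(y, yhat), max_abs_error=max_abs_error(y, yhat), frame=frame
        )

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        lines = []
        title = "Weighted-ensemble GPR soft sensor" if self.kind == "ensemble" else "Global GPR soft sensor"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"target: {self.target}    train rows: {self.n_train}    seed: {self.seed}")
        lines.append(
            f"aux selection (grey degree > {cfg.aux_threshold}): "
            + ", ".join(f"{n}={self.aux_degrees[n]:.3f}" for n in self.selected_aux)
        )
        lines.append(
            f"sub-models: {self.m}    gating threshold omega* = {cfg.omega_star}"
            f"    tuned by ISOA/{cfg.tune_criterion}"
            f" (pop {cfg.swarm.population}, {cfg.swarm.max_iter} iter)"
        )
        lines.append("-" * 78)
        lines.append(f"{'sub':>4} {'rows':>6} {'lengthscale':>12} {'signal_var':>11} "
                     f"{'noise_var':>10} {'criterion':>12}")
        for j, s in enumerate(self.submodels, start=1):
            h = s.gpr.hyper
            lines.append(
                f"{j:>4} {len(s.row_indices):>6} {h.lengthscale:>12.4g} "
                f"{h.signal_var:>11.4g} {h.noise_var:>10.4g} "
                f"{s.tune_info['best_value']:>12.5g}"
            )
        lines.append("-" * 78)
        lines.append(f"fit time: {self.fit_seconds:.1f} s")
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        """Serialize to a JSON file (arrays inline; reloadable exactly)."""
        cfg = self.config
        payload = {
            "kind": self.kind,
            "target": self.target,
            "selected_aux": list(self.selected_aux),
            "gate_aux": list(self.gate_aux),
            "aux_degrees": self.aux_degrees,
            "n_train": self.n_train,
            "seed": self.seed,
            "fit_seconds": self.fit_seconds,
            "config": {
                "aux_threshold": cfg.aux_threshold,
                "omega_star": cfg.omega_star,
                "rho": cfg.grey.rho,
                "include_time": cfg.include_time,
                "dist_c_percentile": cfg.dist_c_percentile,
                "k_max": cfg.k_max,
                "min_cluster_size": cfg.min_cluster_size,
                "include_drop_point": cfg.include_drop_point,
                "tune_criterion": cfg.tune_criterion,
                "log_hyper_bounds": list(cfg.log_hyper_bounds),
                "seed": cfg.seed,
                "swarm": asdict(cfg.swarm),
            },
            "scalers": {
                "zscore": {"center": self.zscaler.center.tolist(), "scale": self.zscaler.scale.tolist()},
                "minmax": {"center": self.mscaler.center.tolist(), "scale": self.mscaler.scale.tolist()},
            },
            "submodels": [
                {
                    "row_indices": s.row_indices.tolist(),
                    "hyper": list(s.gpr.hyper.as_array()),
                    "X_train": s.gpr.X_train.tolist(),
                    "y": (s.gpr.y_train + s.gpr.y_mean).tolist(),
                    "centroid": {
                        "center_row_index": s.centroid.center_row_index,
                        "z_star": s.centroid.z_star.tolist(),
                        "weights": s.centroid.weights.tolist(),
                        "z_weighted": s.centroid.z_weighted.tolist(),
                    },
                    "tune_best_value": s.tune_info.get("best_value"),
                }
                for s in self.submodels
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "SoftSensorResults":
        payload = json.loads(Path(path).read_text())
        c = payload["config"]
        cfg = PipelineConfig(
            aux_threshold=c["aux_threshold"],
            omega_star=c["omega_star"],
            grey=GreyConfig(rho=c["rho"]),
            include_time=c["include_time"],
            dist_c_percentile=c["dist_c_percentile"],
            k_max=c["k_max"],
            min_cluster_size=c["min_cluster_size"],
            include_drop_point=c["include_drop_point"],
            swarm=SwarmConfig(**c["swarm"]),
            tune_criterion=c["tune_criterion"],
            log_hyper_bounds=tuple(c["log_hyper_bounds"]),
            seed=c["seed"],
        )
        zs = Scaler("zscore")
        zs.center = np.asarray(payload["scalers"]["zscore"]["center"])
        zs.scale = np.asarray(payload["scalers"]["zscore"]["scale"])
        ms = Scaler("minmax")
        ms.center = np.asarray(payload["scalers"]["minmax"]["center"])
        ms.scale = np.asarray(payload["scalers"]["minmax"]["scale"])
        submodels = []
        for s in payload["submodels"]:
            hyper = Hyperparams.from_array(np.asarray(s["hyper"]))
            model = gpr_fit(np.asarray(s["X_train"]), np.asarray(s["y"]), hyper)
            cen = WeightedCentroid(
                center_row_index=s["centroid"]["center_row_index"],
                z_star=np.asarray(s["centroid"]["z_star"]),
                weights=np.asarray(s["centroid"]["weights"]),
                z_weighted=np.asarray(s["centroid"]["z_weighted"]),
            )
            submodels.append(
                SubModel(
                    row_indices=np.asarray(s["row_indices"], dtype=int),
                    gpr=model,
                    centroid=cen,
                    tune_info={"best_value": s.get("tune_best_value")},
                )
            )
        return cls(
            kind=payload["kind"],
            target=payload["target"],
            config=cfg,
            selected_aux=tuple(payload["selected_aux"]),
            gate_aux=tuple(payload["gate_aux"]),
            aux_degrees=payload["aux_degrees"],
            zscaler=zs,
            mscaler=ms,
            partition=None,
            profile=None,
            submodels=submodels,
            n_train=payload["n_train"],
            seed=payload["seed"],
            fit_seconds=payload["fit_seconds"],
        )


def compare_to_global(
    train: BatchDataset,
    test: BatchDataset,
    targets: tuple[str, ...] | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit ensemble and single-global sensors per target; tabulate both
    error metrics side by side."""
    targets = tuple(targets or train.target_names)
    rows = []
    for target in targets:
        ens = WeightedEnsembleSoftSensor(train, target, config).fit(seed=seed)
        glo = GlobalGPRSoftSensor(train, target, config).fit(seed=seed)
        r_e, r_g = ens.evaluate(test), glo.evaluate(test)
        rows.append(
            {
                "target": target,
                "rmse_ensemble": r_e.rmse,
                "rmse_global": r_g.rmse,
                "mae_ensemble": r_e.max_abs_error,
                "mae_global": r_g.max_abs_error,
                "m_submodels": ens.m,
                "rmse_reduction_pct": 100.0 * (1.0 - r_e.rmse / r_g.rmse),
            }
        )
    return pd.DataFrame(rows)
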