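"""Binding free-energy models, least-squares fitting and cross-validation.

The direct-interaction approximation expresses the binding free energy of
a protein-ligand complex as a linear combination of ensemble-averaged
interaction sums and fluctuation descriptors::

    simple : dG = alpha*sum_vdw + beta*sum_ele
    DIAV   : dG = alpha*sum_vdw + alpha2*sum_fluct_vdw
                  + beta*sum_ele + beta2*sum_fluct_ele + tau*S_x
    DIAS   : as DIAV, with the dielectric-scaled electrostatic sum
             replacing sum_ele
    generalized : as DIAS, with one tau_x*S_x term per selected property

All models are linear in their parameters, so fitting is ordinary least
squares; the DIAS regularizer x enters non-linearly and is handled by an
outer grid search. Model quality is reported as the mean absolute error
and Pearson correlation of leave-one-out cross-validated predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    CollinearityError,
    ConfigurationError,
    FeatureError,
    ParameterError,
    UndefinedCorrelationError,
)

MODEL_KINDS = ("simple", "diav", "dias", "generalized")

#: Default grid for the DIAS dielectric regularizer x.
DEFAULT_X_GRID = np.round(np.arange(0.1, 2.0 + 1e-9, 0.1), 10)


@dataclass
class ComplexFeatures:
    """Scalar feature set of one complex.

    Energy sums are over protein residues (kcal/mol); ``entropy`` maps a
    property tag (ASA/DIH/VDW/ELE) to its fluctuation descriptor S_x.
    ``dg_exptl`` is the experimental binding free energy, optional for
    prediction-only use.
    """

    complex_id: str
    sum_vdw: float
    sum_ele: float
    sum_fluct_vdw: float
    sum_fluct_ele: float
    entropy: dict = field(default_factory=dict)
    sum_ele_scaled: float | None = None
    dg_exptl: float | None = None
    vdw_form: str = "12-6"
    n_frames: int | None = None

    def __post_init__(self):
        vals = [self.sum_vdw, self.sum_ele, self.sum_fluct_vdw, self.sum_fluct_ele]
        vals += [v for v in self.entropy.values()]
        if self.sum_ele_scaled is not None:
            vals.append(self.sum_ele_scaled)
        if not all(np.isfinite(v) for v in vals):
            raise ParameterError(f"non-finite feature for complex {self.complex_id}")
        if any(v < 0 for v in self.entropy.values()):
            raise ParameterError(
                f"entropy descriptors must be >= 0 (complex {self.complex_id})"
            )


@dataclass
class ModelParams:
    """Fitted coefficients of one model variant.

    ``tau`` weights the single entropy descriptor named by
    ``property_tag``; for the generalized model ``tau_by_property`` holds
    one weight per property and ``tau``/``property_tag`` are unused.
    ``x`` is the DIAS dielectric regularizer (positive for DIAS models).
    """

    alpha: float = 0.0
    alpha2: float = 0.0
    beta: float = 0.0
    beta2: float = 0.0
    tau: float = 0.0
    x: float = 0.0
    vdw_form: str = "8-4"
    property_tag: str = "ASA"
    model_kind: str = "diav"
    tau_by_property: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ConfigurationError(
                f"unknown model kind {self.model_kind!r}; one of {MODEL_KINDS}"
            )
        if self.model_kind == "simple" and not (
            self.alpha2 == self.beta2 == self.tau == 0.0
        ):
            raise ConfigurationError(
                "simple model admits only alpha and beta; "
                "alpha2, beta2 and tau must be zero"
            )
        if self.model_kind in ("dias", "generalized") and not self.x > 0:
            raise ConfigurationError("DIAS models require a positive regularizer x")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "alpha2": self.alpha2,
            "beta": self.beta,
            "beta2": self.beta2,
            "tau": self.tau,
            "x": self.x,
            "vdw_form": self.vdw_form,
            "property_tag": self.property_tag,
            "model_kind": self.model_kind,
            "tau_by_property": dict(self.tau_by_property),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass
class CVResult:
    """Leave-one-out cross-validation summary.

    ``predictions`` are the held-out predictions, aligned with
    ``complex_ids``; ``params`` is the full-data fit (one parameter set,
    as reported alongside CV statistics).
    """

    complex_ids: list
    predictions: np.ndarray
    dg_exptl: np.ndarray
    mae: float
    pearson_r: float
    params: ModelParams

    def __post_init__(self):
        if self.mae < 0 or not (-1.0 <= self.pearson_r <= 1.0):
            raise ParameterError("invalid CV metrics")
        if len(self.predictions) != len(self.complex_ids):
            raise ParameterError("prediction list length must equal dataset size")


def _ele_sum(f: ComplexFeatures, model_kind: str) -> float:
    if model_kind in ("dias", "generalized"):
        if f.sum_ele_scaled is None:
            raise FeatureError(
                f"complex {f.complex_id} lacks sum_ele_scaled required by "
                f"the {model_kind} model"
            )
        return f.sum_ele_scaled
    return f.sum_ele


def _entropy_value(f: ComplexFeatures, tag: str) -> float:
    try:
        return f.entropy[tag]
    except KeyError:
        raise FeatureError(
            f"complex {f.complex_id} lacks entropy descriptor S_{tag}"
        ) from None


def predict_dg(f: ComplexFeatures, p: ModelParams) -> float:
    """Predicted binding free energy of one complex, kcal/mol."""
    if p.model_kind == "simple":
        return p.alpha * f.sum_vdw + p.beta * _ele_sum(f, "simple")
    dg = (
        p.alpha * f.sum_vdw
        + p.alpha2 * f.sum_fluct_vdw
        + p.beta * _ele_sum(f, p.model_kind)
        + p.beta2 * f.sum_fluct_ele
    )
    if p.model_kind == "generalized":
        for tag, tau in p.tau_by_property.items():
            dg += tau * _entropy_value(f, tag)
    else:
        dg += p.tau * _entropy_value(f, p.property_tag)
    return float(dg)


def _design_columns(model_kind: str, property_tag: str, properties) -> list[str]:
    if model_kind == "simple":
        return ["sum_vdw", "sum_ele"]
    ele = "sum_ele_scaled" if model_kind in ("dias", "generalized") else "sum_ele"
    cols = ["sum_vdw", "sum_fluct_vdw", ele, "sum_fluct_ele"]
    if model_kind == "generalized":
        cols += [f"S_{tag}" for tag in properties]
    else:
        cols.append(f"S_{property_tag}")
    return cols


def _design_matrix(dataset, model_kind, property_tag, properties):
    cols = _design_columns(model_kind, property_tag, properties)
    rows = []
    for f in dataset:
        row = []
        for c in cols:
            if c == "sum_vdw":
                row.append(f.sum_vdw)
            elif c == "sum_ele":
                row.append(f.sum_ele)
            elif c == "sum_ele_scaled":
                row.append(_ele_sum(f, model_kind))
            elif c == "sum_fluct_vdw":
                row.append(f.sum_fluct_vdw)
            elif c == "sum_fluct_ele":
                row.append(f.sum_fluct_ele)
            else:  # S_<tag>
                row.append(_entropy_value(f, c[2:]))
        rows.append(row)
    return np.asarray(rows, dtype=float), cols


def _ols(X: np.ndarray, y: np.ndarray, cols: list[str]) -> np.ndarray:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns that QR flags as (near-)dependent
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [cols[j] for j in np.flatnonzero(diag <= tol)] or cols
        raise CollinearityError(bad)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def _params_from_coef(coef, model_kind, vdw_form, property_tag, properties, x):
    if model_kind == "simple":
        return ModelParams(
            alpha=float(coef[0]),
            beta=float(coef[1]),
            vdw_form=vdw_form,
            property_tag=property_tag,
            model_kind="simple",
        )
    base = dict(
        alpha=float(coef[0]),
        alpha2=float(coef[1]),
        beta=float(coef[2]),
        beta2=float(coef[3]),
        vdw_form=vdw_form,
        property_tag=property_tag,
        model_kind=model_kind,
        x=x,
    )
    if model_kind == "generalized":
        base["tau_by_property"] = {
            tag: float(c) for tag, c in zip(properties, coef[4:])
        }
        return ModelParams(**base)
    base["tau"] = float(coef[4])
    return ModelParams(**base)


def fit_params(
    dataset,
    model_kind: str = "diav",
    vdw_form: str = "8-4",
    property_tag: str = "ASA",
    x_grid=None,
    dataset_for_x=None,
    properties=("ASA", "DIH"),
    x: float = 0.6,
) -> ModelParams:
    """Fit model coefficients by ordinary least squares.

    For DIAS-type models the linear coefficients are fitted at a given
    dielectric regularizer ``x``. When ``dataset_for_x`` (a callable
    mapping x to a feature dataset with the electrostatics re-scaled at
    that x) is supplied, an outer grid search over ``x_grid`` picks the x
    with the smallest training residual. The fit is deterministic.

    Raises :class:`CollinearityError` naming the dependent columns on a
    rank-deficient design, and :class:`ConfigurationError` when the
    dataset is not larger than the number of free parameters.
    """
    if model_kind not in MODEL_KINDS:
        raise ConfigurationError(f"unknown model kind {model_kind!r}")
    if model_kind in ("dias", "generalized") and dataset_for_x is not None:
        grid = DEFAULT_X_GRID if x_grid is None else np.asarray(x_grid, float)
        best = None
        for xv in grid:
            ds = dataset_for_x(float(xv))
            p = fit_params(
                ds, model_kind, vdw_form, property_tag,
                properties=properties, x=float(xv),
            )
            ssr = float(
                sum((predict_dg(f, p) - f.dg_exptl) ** 2 for f in ds)
            )
            if best is None or ssr < best[0] - 1e-12:
                best = (ssr, p)
        return best[1]

    dataset = list(dataset)
    if any(f.dg_exptl is None for f in dataset):
        raise FeatureError("every complex needs dg_exptl for fitting")
    X, cols = _design_matrix(dataset, model_kind, property_tag, properties)
    if len(dataset) <= X.shape[1]:
        raise ConfigurationError(
            f"dataset of {len(dataset)} complexes cannot determine "
            f"{X.shape[1]} free parameters"
        )
    y = np.array([f.dg_exptl for f in dataset], dtype=float)
    coef = _ols(X, y, cols)
    return _params_from_coef(coef, model_kind, vdw_form, property_tag, properties, x)


def metrics(pred, expt) -> tuple[float, float]:
    """Mean absolute error and Pearson correlation of predictions."""
    pred = np.asarray(pred, dtype=float)
    expt = np.asarray(expt, dtype=float)
    if pred.shape != expt.shape or pred.size < 2:
        raise ParameterError("pred and expt must have equal length >= 2")
    if np.std(pred) == 0.0 or np.std(expt) == 0.0:
        raise UndefinedCorrelationError(
            "Pearson correlation undefined for zero-variance input"
        )
    mae = float(np.mean(np.abs(pred - expt)))
    r = float(stats.pearsonr(pred, expt).statistic)
    return mae, r


def loo_cv(
    dataset,
    model_kind: str = "diav",
    vdw_form: str = "8-4",
    property_tag: str = "ASA",
    x_grid=None,
    dataset_for_x=None,
    properties=("ASA", "DIH"),
    x: float = 0.6,
    per_fold_x: bool = False,
) -> CVResult:
    """Leave-one-out cross-validation.

    Each complex is predicted by a model refitted on the remaining n-1;
    MAE and Pearson r are computed over the held-out predictions, and the
    full-data fit is reported alongside. For DIAS models the regularizer
    x is by default fitted once on the full data and held fixed across
    folds (``per_fold_x=True`` refits it in every fold).
    """
    dataset = list(dataset)
    if len(dataset) < 3:
        raise ConfigurationError("leave-one-out needs at least 3 complexes")

    full = fit_params(
        dataset, model_kind, vdw_form, property_tag,
        x_grid=x_grid, dataset_for_x=dataset_for_x, properties=properties, x=x,
    )
    if model_kind in ("dias", "generalized") and dataset_for_x is not None:
        # freeze the full-data x; folds refit only the linear coefficients
        if not per_fold_x:
            dataset = list(dataset_for_x(full.x))
            dataset_for_x = None
            x = full.x

    preds = np.empty(len(dataset))
    for i in range(len(dataset)):
        rest = dataset[:i] + dataset[i + 1 :]
        try:
            p = fit_params(
                rest, model_kind, vdw_form, property_tag,
                x_grid=x_grid, dataset_for_x=dataset_for_x,
                properties=properties, x=x,
            )
        except Exception as err:
            raise type(err)(
                f"fold holding out {dataset[i].complex_id!r}: {err}"
            ) from err
        preds[i] = predict_dg(dataset[i], p)

    expt = np.array([f.dg_exptl for f in dataset], dtype=float)
    mae, r = metrics(preds, expt)
    return CVResult(
        complex_ids=[f.complex_id for f in dataset],
        predictions=preds,
        dg_exptl=expt,
        mae=mae,
        pearson_r=r,
        params=full,
    )


def rank_poses(pose_features, p: ModelParams) -> list[int]:
    """Indices of candidate poses sorted by predicted dG, best (lowest) first.

    The sort is stable: ties keep input order.
    """
    pose_features = list(pose_features)
    if not pose_features:
        raise ConfigurationError("need at least one pose")
    preds = np.array([predict_dg(f, p) for f in pose_features])
    return [int(i) for i in np.argsort(preds, kind="stable")]


def success_rates(best_pose_rmsd, thresholds) -> np.ndarray:
    """Fraction of complexes whose best pose lies under each RMSD threshold.

    A pose counts as a success at threshold t when RMSD < t (strict), the
    convention under which 2 A defines a "correct" pose.
    """
    rmsd = np.asarray(best_pose_rmsd, dtype=float)
    if rmsd.size == 0:
        raise ConfigurationError("empty RMSD list")
    if np.any(rmsd < 0):
        raise ParameterError("RMSD values must be >= 0")
    thresholds = np.asarray(thresholds, dtype=float)
    return np.array([(rmsd < t).mean() for t in thresholds])
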