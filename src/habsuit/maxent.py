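"""From-scratch maximum-entropy presence-background suitability model.

The model is a Gibbs distribution over background locations,
``raw(x) = exp(lambda . f(x)) / Z``, fitted by maximizing the L1-penalized
presence log-likelihood

    l(lambda) = mean_presence lambda.f(x)
                - log( mean_background exp(lambda.f(x)) )
                - sum_j beta_j |lambda_j|

Features are min-max scaled linear and quadratic transforms of the
continuous variables plus one indicator per categorical class. The logistic
output is ``e^H r / (1 + e^H r)`` where ``r`` is the raw value under the
training normalizer and ``H`` the entropy of the fitted raw distribution
over the training background, so an uninformative model scores 0.5
everywhere. Hinge, product and threshold features are deliberately not
implemented and are rejected by name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from habsuit.grid import (
    CategoricalGridLayer,
    GridError,
    GridLayer,
    LayerStack,
    OccurrenceSet,
    extract_values,
    haversine_km,
)

logger = logging.getLogger(__name__)

SUPPORTED_FEATURE_CLASSES = ("linear", "quadratic", "categorical")
_REJECTED_FEATURE_CLASSES = ("hinge", "product", "threshold")

DEFAULT_BACKGROUND_N = 10000
DEFAULT_BIAS_BUFFER_KM = 20.0
DEFAULT_BETA = 1.0

#: floor on the per-feature presence standard deviation entering beta_j,
#: so constant features are still (strongly) regularized
_BETA_STD_FLOOR = 1e-2


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# background sampling
# ---------------------------------------------------------------------------

@dataclass
class BackgroundSample:
    lons: np.ndarray
    lats: np.ndarray
    mode: str
    buffer_km: float | None
    seed: int

    def __len__(self) -> int:
        return len(self.lons)

    def to_occurrences(self) -> OccurrenceSet:
        ids = [f"bg_{i}" for i in range(len(self.lons))]
        return OccurrenceSet(self.lons, self.lats, ids)


def sample_background(
    stack: LayerStack,
    occ: OccurrenceSet | None = None,
    n: int = DEFAULT_BACKGROUND_N,
    mode: str = "global",
    buffer_km: float = DEFAULT_BIAS_BUFFER_KM,
    seed: int = 0,
) -> BackgroundSample:
    """Uniform sample (with replacement) of eligible sea-cell centres.

    ``mode="global"`` draws from all valid cells; ``mode="bias"`` restricts
    eligibility to cells within ``buffer_km`` of at least one occurrence.
    """
    if mode not in ("global", "bias"):
        raise ValueError(f"mode must be 'global' or 'bias', got {mode!r}")
    ref = stack.reference
    eligible = stack.valid_mask()
    if mode == "bias":
        if occ is None or len(occ) == 0:
            raise ValueError("bias mode requires occurrences")
        rows, cols = np.nonzero(eligible)
        lon_c = ref.lon_centres()[cols]
        lat_c = ref.lat_centres()[rows]
        mind = np.full(lon_c.shape, np.inf)
        for plon, plat in zip(occ.lons, occ.lats):
            mind = np.minimum(mind, haversine_km(plon, plat, lon_c, lat_c))
        keep = mind <= buffer_km
        if not np.any(keep):
            raise GridError(f"no sea cells within {buffer_km} km of any occurrence")
        flat = np.ravel_multi_index((rows[keep], cols[keep]), ref.shape)
    else:
        flat = np.flatnonzero(eligible.ravel())
        if flat.size == 0:
            raise GridError("no eligible sea cells to sample background from")
    rng = np.random.default_rng(seed)
    pick = flat[rng.integers(0, flat.size, size=n)]
    prows, pcols = np.unravel_index(pick, ref.shape)
    return BackgroundSample(
        lons=ref.lon_centres()[pcols],
        lats=ref.lat_centres()[prows],
        mode=mode,
        buffer_km=buffer_km if mode == "bias" else None,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

@dataclass
class FeatureMapper:
    """Min-max scaling constants fitted on the background sample.

    Continuous variables contribute a linear and a quadratic feature, each
    scaled to [0, 1] over the background; categorical variables contribute
    one indicator per class observed in the background. Transforms clamp to
    the training range, so projected values never leave [0, 1].
    """

    continuous: list[str]
    categorical: dict[str, list[int]]
    mins: np.ndarray = field(default=None)
    maxs: np.ndarray = field(default=None)
    feature_names: list[str] = field(default_factory=list)

    @classmethod
    def fit(
        cls,
        background: pd.DataFrame,
        continuous: list[str],
        categorical: dict[str, list[int]] | None = None,
        feature_classes: tuple[str, ...] = ("linear", "quadratic", "categorical"),
    ) -> "FeatureMapper":
        for fc in feature_classes:
            if fc in _REJECTED_FEATURE_CLASSES:
                raise NotImplementedError(
                    f"feature class {fc!r} is recognized but not implemented; "
                    f"supported classes: {SUPPORTED_FEATURE_CLASSES}"
                )
            if fc not in SUPPORTED_FEATURE_CLASSES:
                raise ValueError(f"unknown feature class {fc!r}")
        categorical = categorical or {}
        mapper = cls(continuous=list(continuous), categorical={k: list(v) for k, v in categorical.items()})
        raw = mapper._raw_features(background, feature_classes)
        mapper._classes = tuple(feature_classes)
        mins = raw.min(axis=0)
        maxs = raw.max(axis=0)
        span = maxs - mins
        span[span == 0] = 1.0
        mapper.mins = mins
        mapper.maxs = mins + span
        return mapper

    def _raw_features(self, df: pd.DataFrame, classes: tuple[str, ...] | None = None) -> np.ndarray:
        classes = classes or getattr(self, "_classes", ("linear", "quadratic", "categorical"))
        cols = []
        names = []
        for var in self.continuous:
            x = df[var].to_numpy(dtype=float)
            if "linear" in classes:
                cols.append(x)
                names.append(f"{var}")
            if "quadratic" in classes:
                cols.append(x**2)
                names.append(f"{var}^2")
        if "categorical" in classes:
            for var, codes in self.categorical.items():
                x = df[var].to_numpy()
                for code in codes:
                    cols.append((x == code).astype(float))
                    names.append(f"{var}=={code}")
        self.feature_names = names
        return np.column_stack(cols) if cols else np.empty((len(df), 0))

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        raw = self._raw_features(df)
        scaled = (raw - self.mins) / (self.maxs - self.mins)
        return np.clip(scaled, 0.0, 1.0)

    @property
    def n_features(self) -> int:
        return len(self.mins)

    def to_dict(self) -> dict:
        return {
            "continuous": self.continuous,
            "categorical": self.categorical,
            "feature_classes": list(getattr(self, "_classes", ("linear", "quadratic", "categorical"))),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "feature_names": self.feature_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureMapper":
        m = cls(
            continuous=list(d["continuous"]),
            categorical={k: [int(c) for c in v] for k, v in d["categorical"].items()},
        )
        m._classes = tuple(d.get("feature_classes", ("linear", "quadratic", "categorical")))
        m.mins = np.asarray(d["mins"], dtype=float)
        m.maxs = np.asarray(d["maxs"], dtype=float)
        m.feature_names = list(d["feature_names"])
        return m


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class MaxentModel:
    mapper: FeatureMapper
    lambdas: np.ndarray
    betas: np.ndarray
    log_z: float  # log sum over training background of exp(lambda.f)
    n_background: int
    entropy: float  # H of the fitted raw distribution over training background
    metadata: dict = field(default_factory=dict)
    objective_trace: list[float] = field(default_factory=list, repr=False)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        return self.mapper.transform(df) @ self.lambdas

    def raw_training(self, df: pd.DataFrame) -> np.ndarray:
        """Raw values under the training normalizer (sum to 1 over the
        training background)."""
        return np.exp(self.linear_predictor(df) - self.log_z)

    def logistic(self, df: pd.DataFrame) -> np.ndarray:
        r = np.exp(self.linear_predictor(df) - self.log_z + self.entropy)
        return r / (1.0 + r)

    def to_dict(self) -> dict:
        return {
            "mapper": self.mapper.to_dict(),
            "lambdas": self.lambdas.tolist(),
            "betas": self.betas.tolist(),
            "log_z": self.log_z,
            "n_background": self.n_background,
            "entropy": self.entropy,
            "metadata": self.metadata,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "MaxentModel":
        return cls(
            mapper=FeatureMapper.from_dict(d["mapper"]),
            lambdas=np.asarray(d["lambdas"], dtype=float),
            betas=np.asarray(d["betas"], dtype=float),
            log_z=float(d["log_z"]),
            n_background=int(d["n_background"]),
            entropy=float(d["entropy"]),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "MaxentModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _penalized_objective(lam, f_pres_mean, F_bg, betas):
    """Negative penalized log-likelihood and its gradient wrt lambda
    (L1 term handled by the caller's split parametrization)."""
    scores = F_bg @ lam
    lse = logsumexp(scores)
    log_mean = lse - np.log(F_bg.shape[0])
    nll = -(f_pres_mean @ lam) + log_mean
    w = np.exp(scores - lse)
    model_mean = w @ F_bg
    grad = -f_pres_mean + model_mean
    return nll, grad


def fit(
    presence: pd.DataFrame | np.ndarray,
    background: pd.DataFrame | np.ndarray,
    beta: float = DEFAULT_BETA,
    mapper: FeatureMapper | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    metadata: dict | None = None,
) -> MaxentModel:
    """Fit weights by L1-penalized maximum likelihood.

    ``presence`` and ``background`` are either variable DataFrames (a
    ``mapper`` is then fitted on the background, or the supplied one used) or
    pre-built feature matrices in [0, 1] (``mapper`` required only for
    prediction). At the optimum the KKT box condition
    ``|presence mean f_j - model mean f_j| <= beta_j`` holds for every j.
    """
    if isinstance(presence, pd.DataFrame):
        if mapper is None:
            continuous = [c for c in background.columns if background[c].dtype.kind == "f"]
            categorical = {
                c: sorted(int(v) for v in background[c].unique())
                for c in background.columns
                if background[c].dtype.kind in "iu"
            }
            mapper = FeatureMapper.fit(background, continuous, categorical)
        F_p = mapper.transform(presence)
        F_b = mapper.transform(background)
    else:
        F_p = np.asarray(presence, dtype=float)
        F_b = np.asarray(background, dtype=float)
    m, n_bg = F_p.shape[0], F_b.shape[0]
    if m < 2 or n_bg < 2:
        raise ValueError(f"need >= 2 presence and >= 2 background rows, got {m}/{n_bg}")
    if not (np.all(np.isfinite(F_p)) and np.all(np.isfinite(F_b))):
        raise ValueError("features must be finite")

    betas = beta * np.maximum(F_p.std(axis=0), _BETA_STD_FLOOR) / np.sqrt(m)
    f_pres_mean = F_p.mean(axis=0)
    J = F_p.shape[1]

    def objective(theta):
        lam = theta[:J] - theta[J:]
        nll, grad = _penalized_objective(lam, f_pres_mean, F_b, betas)
        if not np.isfinite(nll):
            raise FloatingPointError(f"non-finite objective at |lambda|={np.abs(lam).max():.3g}")
        pen = betas @ (theta[:J] + theta[J:])
        g = np.concatenate([grad + betas, -grad + betas])
        return nll + pen, g

    theta0 = np.zeros(2 * J)
    trace: list[float] = [objective(theta0)[0]]

    def record(theta):
        # per accepted iterate, so the trace is monotone under line search
        trace.append(objective(theta)[0])

    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * J),
        callback=record,
        options={"maxiter": max_iter, "ftol": tol * 1e-2, "gtol": 1e-9},
    )
    if not res.success and res.nit >= max_iter:
        raise ConvergenceError(
            f"optimizer hit the iteration cap ({max_iter}); last projected "
            f"gradient norm {np.linalg.norm(res.jac):.3g}"
        )
    lam = res.x[:J] - res.x[J:]
    scores_bg = F_b @ lam
    log_z = float(logsumexp(scores_bg))
    p_bg = np.exp(scores_bg - log_z)
    entropy = float(-(p_bg * np.log(np.clip(p_bg, 1e-300, None))).sum())
    return MaxentModel(
        mapper=mapper,
        lambdas=lam,
        betas=betas,
        log_z=log_z,
        n_background=n_bg,
        entropy=entropy,
        metadata=dict(metadata or {}, beta=beta, n_presence=m),
        objective_trace=trace,
    )


def training_gain(model: MaxentModel, F_p: np.ndarray, F_b: np.ndarray) -> float:
    """Unpenalized log-likelihood gain over the uniform background model."""
    lam = model.lambdas
    log_mean = logsumexp(F_b @ lam) - np.log(F_b.shape[0])
    return float((F_p @ lam).mean() - log_mean)


# ---------------------------------------------------------------------------
# prediction over stacks
# ---------------------------------------------------------------------------

def _stack_frame(model: MaxentModel, stack: LayerStack) -> tuple[pd.DataFrame, np.ndarray]:
    """Variable table over valid cells plus the validity mask."""
    needed = list(model.mapper.continuous) + list(model.mapper.categorical)
    missing = [v for v in needed if v not in stack]
    if missing:
        raise GridError(f"stack is missing model variable(s): {missing}")
    valid = stack.valid_mask()
    rows, cols = np.nonzero(valid)
    data = {}
    for var in model.mapper.continuous:
        data[var] = stack[var].values[rows, cols].astype(float)
    for var in model.mapper.categorical:
        data[var] = stack[var].values[rows, cols].astype(int)
    return pd.DataFrame(data), valid


def _as_layer(stack: LayerStack, valid: np.ndarray, cell_values: np.ndarray, name: str) -> GridLayer:
    ref = stack.reference
    out = np.full(ref.shape, np.nan)
    out[valid] = cell_values
    return GridLayer(
        name=name,
        values=out,
        nodata_mask=~valid,
        origin_lon=ref.origin_lon,
        origin_lat=ref.origin_lat,
        cell_size=ref.cell_size,
        units="probability",
    )


def predict_raw(model: MaxentModel, stack: LayerStack) -> GridLayer:
    """Gibbs probabilities normalized to sum to 1 over valid evaluation cells."""
    df, valid = _stack_frame(model, stack)
    scores = model.mapper.transform(df) @ model.lambdas
    p = np.exp(scores - logsumexp(scores))
    return _as_layer(stack, valid, p, "raw")


def predict_logistic(model: MaxentModel, stack: LayerStack) -> GridLayer:
    """Logistic suitability in (0, 1); 0.5 for an uninformative model."""
    df, valid = _stack_frame(model, stack)
    return _as_layer(stack, valid, model.logistic(df), "suitability")


def project(model: MaxentModel, scenario_stack: LayerStack) -> GridLayer:
    """Apply the trained model to a scenario stack (features clamp to the
    training range; the logistic entropy stays that of the training fit)."""
    return predict_logistic(model, scenario_stack)


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------

def jackknife(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    variables: list[str] | None = None,
    beta: float = DEFAULT_BETA,
) -> pd.DataFrame:
    """Per-variable with-only / without training gains plus AUC without.

    Returns a DataFrame indexed by variable with columns ``gain_with_only``,
    ``gain_without`` and ``auc_without``; the full-model gain is stored under
    ``df.attrs["full_gain"]``.
    """
    from habsuit.validation import auc as _auc

    variables = list(variables or background.columns)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")

    def fit_on(cols: list[str]) -> tuple[MaxentModel, np.ndarray, np.ndarray]:
        bg = background[cols]
        pr = presence[cols]
        continuous = [c for c in cols if background[c].dtype.kind == "f"]
        categorical = {
            c: sorted(int(v) for v in background[c].unique())
            for c in cols
            if background[c].dtype.kind in "iu"
        }
        mapper = FeatureMapper.fit(bg, continuous, categorical)
        F_p, F_b = mapper.transform(pr), mapper.transform(bg)
        model = fit(F_p, F_b, beta=beta, mapper=mapper)
        return model, F_p, F_b

    full_model, F_p, F_b = fit_on(variables)
    full_gain = training_gain(full_model, F_p, F_b)
    rows = []
    for var in variables:
        only_model, op, ob = fit_on([var])
        rest = [v for v in variables if v != var]
        wo_model, wp, wb = fit_on(rest)
        rows.append(
            {
                "variable": var,
                "gain_with_only": training_gain(only_model, op, ob),
                "gain_without": training_gain(wo_model, wp, wb),
                "auc_without": _auc(wp @ wo_model.lambdas, wb @ wo_model.lambdas),
            }
        )
    out = pd.DataFrame(rows).set_index("variable")
    out.attrs["full_gain"] = full_gain
    return out


def features_at(
    stack: LayerStack, points: OccurrenceSet | BackgroundSample
) -> pd.DataFrame:
    """Variable table at point locations (continuous floats, categorical ints)."""
    occ = points.to_occurrences() if isinstance(points, BackgroundSample) else points
    df = extract_values(stack, occ)
    for name in stack.categorical_names():
        df[name] = df[name].astype(int)
    return df
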