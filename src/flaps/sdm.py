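"""Distribution model: logistic regression of farm occurrence with AIC
multi-model averaging.

The workflow follows standard information-theoretic practice for
presence/absence species-distribution modelling: screen covariate pairs with
Spearman |r| ≥ 0.7 and keep one of each pair, pick the linear or squared form
of each covariate by single-covariate AIC, fit all subsets of the resulting
global logistic model, and average coefficients over the models within two
AIC units of the best using Akaike weights (full-model averaging — a
coefficient contributes zero from models that omit it).  The published
national swine equation ships as a built-in so a probability surface can be
produced without refitting.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .raster import GeoTransform, ProbabilitySurface

__all__ = [
    "CandidateModel",
    "AveragedModel",
    "screen_collinearity",
    "choose_form",
    "all_subsets",
    "model_average",
    "builtin_swine_model",
    "fit_distribution_model",
    "predict_surface",
    "auc_score",
    "kfold_auc",
    "variable_importance",
]

log = logging.getLogger(__name__)

LINEAR = "linear"
QUADRATIC = "quadratic"


def _design_column(x: np.ndarray, form: str) -> np.ndarray:
    return x * x if form == QUADRATIC else x


@dataclass(frozen=True)
class CandidateModel:
    """One fitted subset of the global logistic model."""

    terms: tuple[tuple[str, str], ...]  # (covariate, form) pairs
    coefficients: dict[str, float]  # keyed by covariate name; plus "intercept"
    stderr: dict[str, float]
    loglik: float
    aic: float
    delta: float = 0.0

    @property
    def k(self) -> int:
        """Number of estimated parameters (terms + intercept)."""
        return len(self.terms) + 1


@dataclass(frozen=True)
class AveragedModel:
    """Model-averaged logistic equation over the supported candidate set."""

    beta: dict[str, float]  # covariate -> averaged coefficient; plus "intercept"
    term_forms: dict[str, str]  # covariate -> linear|quadratic

    def logit(self, cov: Mapping[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        eta = np.asarray(self.beta.get("intercept", 0.0), dtype=float)
        for name, form in self.term_forms.items():
            x = np.asarray(cov[name], dtype=float)
            eta = eta + self.beta.get(name, 0.0) * _design_column(x, form)
        return eta

    def predict(self, cov: Mapping[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        """Occurrence probability via the inverse logit."""
        with np.errstate(over="ignore"):  # extreme logits saturate cleanly
            return 1.0 / (1.0 + np.exp(-self.logit(cov)))


# ---------------------------------------------------------------------------
# covariate screening and form choice


def screen_collinearity(
    sample: pd.DataFrame,
    threshold: float = 0.7,
    prefer: Optional[Sequence[str]] = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop one covariate from every pair with Spearman |r| ≥ ``threshold``.

    ``prefer`` orders covariates by priority (earlier = kept); without it the
    sample's column order decides.  Returns (retained, dropped) where each
    dropped entry is (dropped, kept, r).
    """
    covs = [c for c in sample.columns if c not in ("y", "county")]
    if len(covs) < 2:
        raise ValueError("need at least two covariates to screen")
    for c in covs:
        if sample[c].nunique() <= 1:
            raise ValueError("covariate %s is constant; correlation undefined" % c)
    rank = {c: (prefer.index(c) if prefer and c in prefer else len(prefer or []) + covs.index(c)) for c in covs}
    corr = sample[covs].corr(method="spearman")
    retained = list(covs)
    dropped: list[tuple[str, str, float]] = []
    for a, b in itertools.combinations(covs, 2):
        if a not in retained or b not in retained:
            continue
        r = float(corr.loc[a, b])
        if abs(r) >= threshold:
            keep, drop = (a, b) if rank[a] <= rank[b] else (b, a)
            retained.remove(drop)
            dropped.append((drop, keep, r))
    return retained, dropped


def _fit_logit(y: np.ndarray, X: np.ndarray):
    # Newton first; BFGS as a fallback for (quasi-)separated designs, where
    # the Hessian goes singular but a usable direction still exists
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            return model.fit(disp=0, maxiter=200)
        except Exception:
            return model.fit(disp=0, maxiter=500, method="bfgs")


def choose_form(sample: pd.DataFrame, cov: str) -> str:
    """Linear vs squared form of ``cov`` by single-covariate logistic AIC.

    Ties go to the linear form.  Complete separation is reported as a warning
    but a form is still returned.
    """
    y = sample["y"].to_numpy(dtype=float)
    x = sample[cov].to_numpy(dtype=float)
    aics = {}
    for form in (LINEAR, QUADRATIC):
        X = np.column_stack([np.ones_like(x), _design_column(x, form)])
        try:
            res = _fit_logit(y, X)
            if not res.mle_retvals.get("converged", True):
                warnings.warn("possible separation fitting %s (%s form)" % (cov, form))
            aics[form] = res.aic
        except Exception as e:  # pragma: no cover - statsmodels edge cases
            warnings.warn("fit failed for %s (%s): %s" % (cov, form, e))
            aics[form] = np.inf
    return QUADRATIC if aics[QUADRATIC] < aics[LINEAR] else LINEAR


# ---------------------------------------------------------------------------
# all-subsets selection and averaging


def all_subsets(
    sample: pd.DataFrame,
    covariates: Sequence[str],
    forms: Optional[Mapping[str, str]] = None,
) -> list[CandidateModel]:
    """Fit every subset of the global model (plus intercept-only), ranked by AIC.

    ``forms`` fixes each covariate's functional form; unspecified covariates
    are resolved with :func:`choose_form`.  Non-convergent subsets are skipped
    with a log entry.  Capped at 15 covariates (2^15 fits).
    """
    covariates = list(covariates)
    if len(covariates) > 15:
        raise ValueError("all-subsets enumeration capped at 15 covariates")
    forms = dict(forms or {})
    for c in covariates:
        forms.setdefault(c, choose_form(sample, c))
    y = sample["y"].to_numpy(dtype=float)
    cols = {c: _design_column(sample[c].to_numpy(dtype=float), forms[c]) for c in covariates}
    out: list[CandidateModel] = []
    for r in range(len(covariates) + 1):
        for subset in itertools.combinations(covariates, r):
            X = np.column_stack(
                [np.ones_like(y)] + [cols[c] for c in subset]
            )
            try:
                res = _fit_logit(y, X)
            except Exception as e:
                log.warning("subset %s skipped: %s", subset, e)
                continue
            if np.any(~np.isfinite(res.params)):
                log.warning("subset %s skipped: non-finite coefficients", subset)
                continue
            names = ["intercept"] + list(subset)
            out.append(
                CandidateModel(
                    terms=tuple((c, forms[c]) for c in subset),
                    coefficients=dict(zip(names, map(float, res.params))),
                    stderr=dict(zip(names, map(float, res.bse))),
                    loglik=float(res.llf),
                    aic=float(res.aic),
                )
            )
    if not out:
        raise RuntimeError("no candidate model converged")
    best = min(m.aic for m in out)
    out = [
        CandidateModel(m.terms, m.coefficients, m.stderr, m.loglik, m.aic,
                       delta=m.aic - best)
        for m in out
    ]
    out.sort(key=lambda m: m.aic)
    return out


def model_average(
    models: Sequence[CandidateModel], window: float = 2.0
) -> AveragedModel:
    """Akaike-weighted full-model averaging over candidates with ΔAIC ≤ window.

    Each coefficient is averaged across the whole window set, entering as zero
    for models that omit its term; the intercept is averaged the same way.
    """
    window_set = [m for m in models if m.delta <= window]
    if not window_set:
        raise ValueError("no model inside the AIC window")
    w = np.exp(-0.5 * np.array([m.delta for m in window_set]))
    w /= w.sum()
    names: list[str] = []
    forms: dict[str, str] = {}
    for m in window_set:
        for c, f in m.terms:
            if c not in forms:
                forms[c] = f
                names.append(c)
            elif forms[c] != f:
                raise ValueError("conflicting forms for %s across candidates" % c)
    beta = {
        "intercept": float(
            sum(wi * m.coefficients["intercept"] for wi, m in zip(w, window_set))
        )
    }
    for c in names:
        beta[c] = float(
            sum(wi * m.coefficients.get(c, 0.0) for wi, m in zip(w, window_set))
        )
    return AveragedModel(beta=beta, term_forms=forms)


def fit_distribution_model(
    sample: pd.DataFrame,
    covariates: Optional[Sequence[str]] = None,
    prefer: Optional[Sequence[str]] = None,
    threshold: float = 0.7,
    window: float = 2.0,
    forms: Optional[Mapping[str, str]] = None,
) -> tuple[AveragedModel, list[CandidateModel]]:
    """Full selection pipeline: screen → form choice → all subsets → average."""
    if covariates is None:
        covariates = [c for c in sample.columns if c not in ("y", "county")]
    if len(covariates) >= 2:
        sub = sample[["y", *covariates]]
        retained, _ = screen_collinearity(sub, threshold=threshold, prefer=prefer)
    else:
        retained = list(covariates)
    models = all_subsets(sample, retained, forms=forms)
    return model_average(models, window=window), models


# ---------------------------------------------------------------------------
# built-in national swine model

#: model-averaged coefficients of the published national swine equation
_SWINE_BETA = {
    "intercept": -5.63e-2,
    "dOpen": -5.66e-3,
    "dCrop": -4.12e-4,
    "Temp": -8.51e-3,
    "dRoads": -1.48e-3,
    "Slope": -2.62e-2,
    "Precip": 3.29e-7,
    "dForest": -4.84e-9,
    "dUrban": -2.95e-10,
    "dWetland": -1.28e-9,
    "dBarren": -2.58e-10,
}

_SWINE_FORMS = {
    "dOpen": LINEAR,
    "dCrop": LINEAR,
    "Temp": LINEAR,
    "dRoads": LINEAR,
    "Slope": QUADRATIC,
    "Precip": QUADRATIC,
    "dForest": QUADRATIC,
    "dUrban": QUADRATIC,
    "dWetland": QUADRATIC,
    "dBarren": QUADRATIC,
}


def builtin_swine_model() -> AveragedModel:
    """The national model-averaged swine-farm occurrence equation.

    Ten terms — distances to open areas, cropland, roads and mean annual
    temperature enter linearly; slope, precipitation and distances to forest,
    high-intensity urban areas, wetlands and barren land enter as squares —
    plus the intercept.  Distances are in meters, temperature in °C,
    precipitation in mm, slope in degrees.
    """
    return AveragedModel(beta=dict(_SWINE_BETA), term_forms=dict(_SWINE_FORMS))


# ---------------------------------------------------------------------------
# rasterization


def predict_surface(
    model: AveragedModel,
    stack: Mapping[str, np.ndarray],
    mask: Optional[np.ndarray] = None,
    transform: Optional[GeoTransform] = None,
    county_index: Optional[np.ndarray] = None,
    county_fips: Optional[list[str]] = None,
) -> ProbabilitySurface:
    """Map the averaged equation over co-registered covariate rasters.

    ``mask`` is True where farms are prohibited (urban, water, public land);
    those pixels are flagged unavailable but keep their probability value.
    """
    shapes = {name: np.asarray(r).shape for name, r in stack.items()}
    missing = [c for c in model.term_forms if c not in stack]
    if missing:
        raise ValueError("missing covariate layers: %s" % ", ".join(missing))
    if len(set(shapes.values())) != 1:
        raise ValueError("covariate rasters are not co-registered: %s" % shapes)
    shape = next(iter(shapes.values()))
    if mask is None:
        mask = np.zeros(shape, dtype=bool)
    if np.asarray(mask).shape != shape:
        raise ValueError("mask shape differs from covariate rasters")
    prob = model.predict({k: np.asarray(v, dtype=float) for k, v in stack.items()})
    return ProbabilitySurface(
        grid=prob,
        available=~np.asarray(mask, dtype=bool),
        transform=transform or GeoTransform(0.0, 0.0, 1.0, 1.0),
        county_index=county_index,
        county_fips=county_fips or [],
    )


# ---------------------------------------------------------------------------
# evaluation


def auc_score(y: np.ndarray, score: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) statistic, ties averaged."""
    y = np.asarray(y, dtype=bool)
    score = np.broadcast_to(np.asarray(score, dtype=float), y.shape)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(score)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::folds] for i in range(folds)]


def kfold_auc(
    sample: pd.DataFrame,
    folds: int = 5,
    seed: int = 0,
    covariates: Optional[Sequence[str]] = None,
    forms: Optional[Mapping[str, str]] = None,
    max_refolds: int = 10,
) -> tuple[float, list[float]]:
    """K-fold cross-validated AUC of the selection + averaging pipeline.

    Each fold trains the full pipeline on the other 1 − 1/k of the data and
    scores the holdout.  Folds are a seeded uniform shuffle; a draw that
    leaves a fold single-class is redrawn with a fresh seed (logged).
    """
    y = sample["y"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    for attempt in range(max_refolds):
        idx = _fold_indices(len(sample), folds, rng)
        if all(0 < y[f].sum() < len(f) for f in idx):
            break
        log.warning("single-class fold on attempt %d; reshuffling", attempt + 1)
    else:
        raise ValueError("could not build folds with both classes present")
    aucs = []
    for f in idx:
        train = sample.drop(sample.index[f])
        test = sample.iloc[f]
        model, _ = fit_distribution_model(train, covariates=covariates, forms=forms)
        aucs.append(auc_score(test["y"].to_numpy(), model.predict(test)))
    return float(np.mean(aucs)), aucs


def variable_importance(
    sample: pd.DataFrame,
    folds: int = 5,
    seed: int = 0,
    covariates: Optional[Sequence[str]] = None,
    forms: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Permutation importance per covariate per cross-validation fold.

    Importance is the holdout AUC drop when one covariate's values are
    permuted; rows are covariates, columns the per-fold runs plus their mean
    and standard error.
    """
    y = sample["y"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    idx = _fold_indices(len(sample), folds, rng)
    if covariates is None:
        covariates = [c for c in sample.columns if c not in ("y", "county")]
    rows: dict[str, list[float]] = {c: [] for c in covariates}
    for f in idx:
        train = sample.drop(sample.index[f])
        test = sample.iloc[f].reset_index(drop=True)
        model, _ = fit_distribution_model(train, covariates=covariates, forms=forms)
        base = auc_score(test["y"].to_numpy(), model.predict(test))
        for c in covariates:
            perm = test.copy()
            perm[c] = rng.permutation(perm[c].to_numpy())
            rows[c].append(base - auc_score(perm["y"].to_numpy(), model.predict(perm)))
    df = pd.DataFrame(rows).T
    df.columns = ["run%d" % (i + 1) for i in range(folds)]
    df["mean"] = df.mean(axis=1)
    df["se"] = df[[c for c in df.columns if c.startswith("run")]].std(axis=1, ddof=1) / np.sqrt(folds)
    return df.sort_values("mean", ascending=False)
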