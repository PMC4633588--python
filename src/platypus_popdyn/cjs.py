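"""Cormack–Jolly–Seber survival and detection inference.

Open-population mark-recapture: conditioning on each animal's first capture,
apparent survival Φ (per annual interval) and detection p (per occasion) are
modelled on the logit scale as linear functions of individual covariates
(sex, time-varying age class, per-stage body weight in raw grams) and
occasion covariates (netting effort, cumulative river flow over 1/6/12/24
month look-backs, maximum monthly flows). Candidate models are ranked by
AICc (effective sample size = number of release events) and averaged over
the top set holding 99% cumulative Akaike weight.

The likelihood for a history seen last at occasion l is the product of
interval survival and detection terms up to l times the "never seen again"
probability χ_l, computed by the usual backward recursion

    χ_t = (1 − Φ_t) + Φ_t (1 − p_{t+1}) χ_{t+1},   χ_T = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .io_data_model import CaptureRecord, Occasion, assign_occasion
from .synthetic_data import age_to_class, STAGE_OF_CLASS

AGE_CODE = {"juvenile": 0, "subadult": 1, "adult": 2}
#: minimum age implied by the class at first capture
MIN_AGE_AT_FIRST = {
    ("female", "juvenile"): 0,
    ("female", "adult"): 1,
    ("male", "juvenile"): 0,
    ("male", "subadult"): 1,
    ("male", "adult"): 3,
}

OCCASION_TERMS = (
    "flow_1m",
    "flow_6m",
    "flow_12m",
    "flow_24m",
    "flow_max_jan_dec",
    "flow_max_jan_apr",
    "effort",
)
INDIVIDUAL_TERMS = ("sex", "weight", "age")


class FitError(RuntimeError):
    """Optimization failed to converge; carries the best point found."""

    def __init__(self, message: str, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass
class CaptureHistoryMatrix:
    """Encounter histories plus the covariates the CJS designs may reference."""

    encounter: np.ndarray  # (n, T) 0/1
    first: np.ndarray  # (n,) first-capture occasion index
    last: np.ndarray  # (n,) last-capture occasion index
    animal_ids: list
    sex_male: np.ndarray  # (n,) 0/1
    age_code: np.ndarray  # (n, T) 0 juv / 1 subadult / 2 adult, forward-propagated
    weight: np.ndarray  # (n, T) grams, per-stage mean
    occasion_covariates: dict  # name -> (T,) array

    @property
    def n_individuals(self) -> int:
        return self.encounter.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.encounter.shape[1]

    @property
    def n_releases(self) -> int:
        """Release events: captures not on the final occasion (AICc sample size)."""
        return int(self.encounter[:, :-1].sum())


def build_capture_histories(
    records: Sequence[CaptureRecord], occasions: Sequence[Occasion]
) -> CaptureHistoryMatrix:
    """Collapse capture records to an annual encounter matrix with covariates.

    Multiple captures of one animal within an occasion collapse to a single 1.
    Per-stage mean weights follow the one-average-per-stage rule; age class is
    propagated forward from the minimum age implied at first capture.
    """
    T = len(occasions)
    order: dict[str, int] = {}
    for r in records:
        if r.animal_id not in order:
            order[r.animal_id] = len(order)
    n = len(order)
    encounter = np.zeros((n, T), dtype=int)
    sex_male = np.zeros(n, dtype=int)
    first_rec: dict[str, tuple[int, CaptureRecord]] = {}
    stage_weights: dict[str, dict[str, list[float]]] = {a: {} for a in order}

    for r in records:
        occ = assign_occasion(r, occasions)
        i = order[r.animal_id]
        encounter[i, occ] = 1
        sex_male[i] = 1 if r.sex == "male" else 0
        prev = first_rec.get(r.animal_id)
        if prev is None or (occ, r.date) < (prev[0], prev[1].date):
            first_rec[r.animal_id] = (occ, r)
        if r.weight_g is not None:
            stage_weights[r.animal_id].setdefault(r.age_class, []).append(r.weight_g)

    first = encounter.argmax(axis=1)
    last = T - 1 - encounter[:, ::-1].argmax(axis=1)

    age_code = np.zeros((n, T), dtype=int)
    weight = np.full((n, T), np.nan)
    class_mean_weight: dict[int, list[float]] = {}
    for aid, i in order.items():
        f_occ, f = first_rec[aid]
        age0 = MIN_AGE_AT_FIRST[(f.sex, f.age_class)]
        for t in range(T):
            age_t = max(age0 + (t - f_occ), 0)
            cls = age_to_class(f.sex, age_t)
            age_code[i, t] = AGE_CODE[STAGE_OF_CLASS[cls]]
        means = {s: float(np.mean(v)) for s, v in stage_weights[aid].items()}
        for t in range(T):
            stage = ("juvenile", "subadult", "adult")[age_code[i, t]]
            if stage in means:
                weight[i, t] = means[stage]
            elif means:  # nearest observed stage for this animal
                weight[i, t] = means[max(means, key=lambda s: AGE_CODE[s])]
        for t in range(T):
            class_mean_weight.setdefault(
                sex_male[i] * 10 + age_code[i, t], []
            ).append(weight[i, t])

    # fall back to the dataset mean for the same sex-age cell
    cell_mean = {
        k: float(np.nanmean(v)) if np.isfinite(v).any() else 1000.0
        for k, v in ((k, np.array(v)) for k, v in class_mean_weight.items())
    }
    for i in range(n):
        for t in range(T):
            if not np.isfinite(weight[i, t]):
                weight[i, t] = cell_mean.get(sex_male[i] * 10 + age_code[i, t], 1000.0)

    occ_cov = {
        "effort": np.array([o.effort_hours for o in occasions], float),
        "flow_1m": np.array([o.flow_1m for o in occasions], float),
        "flow_6m": np.array([o.flow_6m for o in occasions], float),
        "flow_12m": np.array([o.flow_12m for o in occasions], float),
        "flow_24m": np.array([o.flow_24m for o in occasions], float),
        "flow_max_jan_dec": np.array([o.flow_max_jan_dec for o in occasions], float),
        "flow_max_jan_apr": np.array([o.flow_max_jan_apr for o in occasions], float),
    }
    return CaptureHistoryMatrix(
        encounter=encounter,
        first=first,
        last=last,
        animal_ids=list(order),
        sex_male=sex_male,
        age_code=age_code,
        weight=weight,
        occasion_covariates=occ_cov,
    )


@dataclass(frozen=True)
class CJSDesign:
    """Named covariate terms for Φ and p; ``name^2`` adds a raw quadratic."""

    phi_terms: tuple = ()
    p_terms: tuple = ()

    def __post_init__(self) -> None:
        for terms in (self.phi_terms, self.p_terms):
            for t in terms:
                base = t[:-2] if t.endswith("^2") else t
                if base not in OCCASION_TERMS + INDIVIDUAL_TERMS:
                    raise ValueError(f"unknown covariate {t!r}")
                if t.endswith("^2") and base not in terms:
                    raise ValueError(f"quadratic {t!r} requires the linear term")

    def column_names(self, which: str) -> list[str]:
        terms = self.phi_terms if which == "phi" else self.p_terms
        cols = [f"{which}:intercept"]
        for t in terms:
            if t == "age":
                cols += [f"{which}:age[subadult]", f"{which}:age[adult]"]
            else:
                cols.append(f"{which}:{t}")
        return cols

    @property
    def n_params(self) -> int:
        return len(self.column_names("phi")) + len(self.column_names("p"))

    @property
    def name(self) -> str:
        def fmt(terms):
            out, seen_sq = [], set()
            for t in terms:
                if t.endswith("^2"):
                    continue
                out.append(t)
            return " + ".join(out) if out else "."

        return f"Phi({fmt(self.phi_terms)}) p({fmt(self.p_terms)})"


def _term_matrix(chm: CaptureHistoryMatrix, term: str) -> tuple[np.ndarray, bool]:
    """Per-occasion value matrix for a term; flag: occasion-level covariate."""
    base = term[:-2] if term.endswith("^2") else term
    n, T = chm.encounter.shape
    if base == "sex":
        V = np.repeat(chm.sex_male[:, None], T, axis=1).astype(float)
        occ = False
    elif base == "weight":
        V = chm.weight.copy()
        occ = False
    elif base in OCCASION_TERMS:
        V = np.repeat(chm.occasion_covariates[base][None, :], n, axis=0)
        occ = True
    else:
        raise ValueError(f"unknown covariate {term!r}")
    if term.endswith("^2"):
        V = V**2
    return V, occ


def _design_tensor(chm: CaptureHistoryMatrix, terms: tuple, for_phi: bool) -> np.ndarray:
    """(n, T-1, k) design including intercept.

    Interval t runs occasion t → t+1. Individual covariates (sex, weight, age)
    are taken at occasion t for Φ; occasion covariates (flows, effort) at
    occasion t+1 — the conditions accumulated over the interval, and the
    occasion at which detection happens.
    """
    n, T = chm.encounter.shape
    cols = [np.ones((n, T - 1))]
    for term in terms:
        if term == "age":
            sub = (chm.age_code == 1).astype(float)
            ad = (chm.age_code == 2).astype(float)
            sl = slice(0, T - 1) if for_phi else slice(1, T)
            cols += [sub[:, sl], ad[:, sl]]
            continue
        V, occ_level = _term_matrix(chm, term)
        if for_phi and not occ_level:
            cols.append(V[:, : T - 1])
        else:
            cols.append(V[:, 1:])
    return np.stack(cols, axis=2)


_PCLIP = 1e-12


def _real_parameters(chm, design: CJSDesign, params: np.ndarray):
    params = np.asarray(params, float)
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite parameters")
    k_phi = len(design.column_names("phi"))
    if len(params) != design.n_params:
        raise ValueError(
            f"expected {design.n_params} parameters, got {len(params)}"
        )
    X_phi = _design_tensor(chm, design.phi_terms, for_phi=True)
    X_p = _design_tensor(chm, design.p_terms, for_phi=False)
    phi = expit(X_phi @ params[:k_phi])
    p = expit(X_p @ params[k_phi:])
    return np.clip(phi, _PCLIP, 1 - _PCLIP), np.clip(p, _PCLIP, 1 - _PCLIP)


def cjs_loglik_per_individual(chm, phi: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Log-likelihood per history given (n, T-1) interval Φ and detection p.

    ``p[:, t]`` is the detection probability at occasion t+1.
    """
    y = chm.encounter
    n, T = y.shape
    chi = np.ones((n, T))
    for t in range(T - 2, -1, -1):
        chi[:, t] = (1 - phi[:, t]) + phi[:, t] * (1 - p[:, t]) * chi[:, t + 1]
    t_idx = np.arange(T - 1)
    mask = (chm.first[:, None] <= t_idx) & (t_idx < chm.last[:, None])
    det = np.where(y[:, 1:] == 1, np.log(p), np.log1p(-p))
    ll = (mask * (np.log(phi) + det)).sum(axis=1)
    return ll + np.log(chi[np.arange(n), chm.last])


def cjs_negloglik(chm: CaptureHistoryMatrix, design: CJSDesign, params) -> float:
    """−Σ ln P(history | first capture) under the design at ``params``."""
    phi, p = _real_parameters(chm, design, params)
    return float(-cjs_loglik_per_individual(chm, phi, p).sum())


@dataclass
class CJSFit:
    design: CJSDesign
    coefficients: pd.DataFrame  # term, estimate, se, lcl, ucl
    beta: np.ndarray
    cov: Optional[np.ndarray]
    loglik: float
    n_par: int
    ess: int
    aicc: float
    deviance: float
    converged: bool
    se_available: bool

    @property
    def name(self) -> str:
        return self.design.name


def aicc(loglik: float, k: int, ess: int) -> float:
    """Small-sample corrected AIC: −2ℓ + 2k + 2k(k+1)/(ess − k − 1)."""
    if ess <= k + 1:
        raise ValueError(f"effective sample size {ess} must exceed k+1 = {k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (ess - k - 1)


def fit_cjs(
    chm: CaptureHistoryMatrix,
    design: CJSDesign,
    n_starts: int = 5,
    seed: int = 0,
    gtol: float = 1e-8,
) -> CJSFit:
    """Maximum-likelihood fit by quasi-Newton from jittered starts.

    Covariate columns are standardized internally for conditioning; reported
    coefficients and their covariance are on the raw covariate scale. Standard
    errors come from the numerically differentiated Hessian.
    """
    if chm.n_occasions < 2:
        raise ValueError("CJS needs at least two occasions")
    k_phi = len(design.column_names("phi"))
    X_phi = _design_tensor(chm, design.phi_terms, for_phi=True)
    X_p = _design_tensor(chm, design.p_terms, for_phi=False)
    scale = np.ones(design.n_params)
    for j in range(1, k_phi):
        s = np.std(X_phi[:, :, j])
        scale[j] = s if s > 0 else 1.0
    for j in range(1, X_p.shape[2]):
        s = np.std(X_p[:, :, j])
        scale[k_phi + j] = s if s > 0 else 1.0

    def nll_scaled(z: np.ndarray) -> float:
        try:
            return cjs_negloglik(chm, design, z / scale)
        except (ValueError, FloatingPointError):
            return np.inf

    rng = np.random.default_rng(seed)
    best = None
    converged = False
    for s_idx in range(max(n_starts, 1)):
        x0 = np.zeros(design.n_params) if s_idx == 0 else rng.normal(0, 0.5, design.n_params)
        res = minimize(nll_scaled, x0, method="BFGS", options={"gtol": gtol, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        # finite-difference gradients stall below ~1e-4; a tiny scaled gradient
        # at the best point is convergence even when BFGS reports precision loss
        if res.success or (np.isfinite(res.fun) and np.max(np.abs(res.jac)) < 1e-2):
            converged = True

    beta = best.x / scale
    loglik = -best.fun
    hess = _numerical_hessian(nll_scaled, best.x)
    cov = None
    se_available = False
    try:
        cov_scaled = np.linalg.inv(hess)
        if np.all(np.diag(cov_scaled) > 0):
            cov = cov_scaled / np.outer(scale, scale)
            se_available = True
    except np.linalg.LinAlgError:
        pass

    names = design.column_names("phi") + design.column_names("p")
    se = np.sqrt(np.diag(cov)) if se_available else np.full(len(beta), np.nan)
    coef = pd.DataFrame(
        {
            "term": names,
            "estimate": beta,
            "se": se,
            "lcl": beta - 1.96 * se,
            "ucl": beta + 1.96 * se,
        }
    )
    ess = chm.n_releases
    fit = CJSFit(
        design=design,
        coefficients=coef,
        beta=beta,
        cov=cov,
        loglik=loglik,
        n_par=design.n_params,
        ess=ess,
        aicc=aicc(loglik, design.n_params, ess),
        deviance=-2.0 * loglik,
        converged=converged,
        se_available=se_available,
    )
    if not converged:
        raise FitError("no start converged", best_fit=fit)
    return fit


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return H


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalized model plausibilities exp(−Δ/2)/Σ; shift-invariant."""
    a = np.asarray(aicc_values, float)
    if a.size == 0:
        raise ValueError("no models")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelTable:
    """Ranked fits with Akaike weights and the retained model-averaging set."""

    table: pd.DataFrame
    fits: list
    retained: list  # indices into ``fits`` holding the cumulative-weight set
    retained_weights: np.ndarray  # renormalized over the retained set

    def predict(self, covariates: Mapping) -> dict:
        """Model-averaged real-scale Φ and p at the given covariates."""
        out = {"phi": 0.0, "p": 0.0}
        for w, idx in zip(self.retained_weights, self.retained):
            pred = predict_real(self.fits[idx], covariates)
            out["phi"] += w * pred["phi"][0]
            out["p"] += w * pred["p"][0]
        return out


def rank_and_average(fits: Sequence[CJSFit], cumulative: float = 0.99) -> ModelTable:
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("no converged fits to rank")
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aicc, fits[i].n_par))
    fits = [fits[i] for i in order]
    a = np.array([f.aicc for f in fits])
    w = akaike_weights(a)
    cum = np.cumsum(w)
    n_keep = int(np.searchsorted(cum, cumulative) + 1)
    n_keep = min(n_keep, len(fits))
    retained = list(range(n_keep))
    rw = w[:n_keep] / w[:n_keep].sum()
    table = pd.DataFrame(
        {
            "model": [f.name for f in fits],
            "n_par": [f.n_par for f in fits],
            "AICc": a,
            "delta_AICc": a - a.min(),
            "weight": w,
            "deviance": [f.deviance for f in fits],
            "retained": [i < n_keep for i in range(len(fits))],
        }
    )
    return ModelTable(table=table, fits=fits, retained=retained, retained_weights=rw)


def _covariate_row(design: CJSDesign, which: str, covariates: Mapping) -> np.ndarray:
    terms = design.phi_terms if which == "phi" else design.p_terms
    row = [1.0]
    for t in terms:
        if t == "age":
            age = covariates.get("age_class")
            if age is None:
                raise KeyError("missing covariate 'age_class'")
            row += [1.0 if age == "subadult" else 0.0, 1.0 if age == "adult" else 0.0]
            continue
        base = t[:-2] if t.endswith("^2") else t
        if base == "sex":
            sex = covariates.get("sex")
            if sex is None:
                raise KeyError("missing covariate 'sex'")
            val = 1.0 if sex == "male" else 0.0
        else:
            if base not in covariates:
                raise KeyError(f"missing covariate {base!r}")
            val = float(covariates[base])
        row.append(val**2 if t.endswith("^2") else val)
    return np.array(row)


def predict_real(fit: CJSFit, covariates: Mapping) -> dict:
    """Real-scale Φ and p with delta-method 95% intervals on the logit scale."""
    k_phi = len(fit.design.column_names("phi"))
    out = {}
    for which, sl in (("phi", slice(0, k_phi)), ("p", slice(k_phi, None))):
        x = _covariate_row(fit.design, which, covariates)
        beta = fit.beta[sl]
        eta = float(x @ beta)
        if fit.cov is not None:
            var = float(x @ fit.cov[sl, sl] @ x)
            half = 1.96 * math.sqrt(max(var, 0.0))
            out[which] = (float(expit(eta)), float(expit(eta - half)), float(expit(eta + half)))
        else:
            out[which] = (float(expit(eta)), float("nan"), float("nan"))
    return out


def predict_from_coefficients(
    coefficients: Mapping[str, float], covariates: Mapping[str, float]
) -> float:
    """Inverse-logit prediction from a plain coefficient table.

    ``coefficients`` maps term names (including "intercept") to values;
    ``covariates`` supplies each non-intercept term's value (indicator terms
    such as an age-class offset are passed as 0/1). Terms absent from
    ``covariates`` raise, so a forgotten offset cannot silently default.
    """
    eta = 0.0
    for name, b in coefficients.items():
        if name == "intercept":
            eta += b
            continue
        if name not in covariates:
            raise KeyError(f"missing covariate {name!r}")
        eta += b * float(covariates[name])
    return float(expit(eta))


@dataclass
class AbundanceTrend:
    adjusted: np.ndarray
    slope: float
    intercept: float


def estimate_abundance_trend(annual_counts, p_hat) -> AbundanceTrend:
    """Horvitz–Thompson style count adjustment plus an OLS annual slope."""
    counts = np.asarray(annual_counts, float)
    p = np.asarray(p_hat, float)
    if counts.shape != p.shape:
        raise ValueError("counts and detection probabilities must align")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("detection probabilities must lie in (0, 1]")
    adjusted = counts / p
    years = np.arange(len(counts), dtype=float)
    slope, intercept = np.polyfit(years, adjusted, 1)
    return AbundanceTrend(adjusted=adjusted, slope=float(slope), intercept=float(intercept))


def default_model_set() -> list[CJSDesign]:
    """The default candidate set: thirteen structures combining sex, weight,
    age and lagged-flow effects on Φ with effort/flow/age/sex effects on p,
    plus the longer-lag and seasonal-maximum flow alternatives. Flow and
    weight enter Φ with raw quadratic terms."""

    def phi(flow):
        return (flow, f"{flow}^2", "sex", "weight", "weight^2", "age")

    def phi_noage(flow):
        return (flow, f"{flow}^2", "sex", "weight", "weight^2")

    p_base = ("flow_1m", "effort")
    p_age = p_base + ("age",)
    p_sex = p_base + ("sex",)
    p_sexage = p_base + ("sex", "age")
    designs = [
        CJSDesign(phi("flow_6m"), p_age),
        CJSDesign(phi("flow_1m"), p_age),
        CJSDesign(phi("flow_6m"), p_sexage),
        CJSDesign(phi("flow_1m"), p_sexage),
        CJSDesign(phi("flow_6m"), p_base),
        CJSDesign(phi("flow_6m"), p_sex),
        CJSDesign(phi("flow_12m"), p_age),
        CJSDesign(phi("flow_12m"), p_base),
        CJSDesign(phi_noage("flow_6m"), p_base),
        CJSDesign(phi("flow_1m"), p_sex),
        CJSDesign(phi_noage("flow_6m"), p_age),
        CJSDesign(phi("flow_12m"), p_sexage),
        CJSDesign(phi_noage("flow_6m"), p_sex),
        CJSDesign(phi("flow_24m"), p_age),
        CJSDesign(phi("flow_max_jan_dec"), p_age),
        CJSDesign(phi("flow_max_jan_apr"), p_age),
    ]
    return designs
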