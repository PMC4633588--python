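"""Bayesian building blocks for the descriptive life-history analyses.

Three small models recur throughout: an exact Binomial–Beta(1,1) test of
proportion (residency rates, sex ratios, lactation proportions), a
semi-conjugate Gibbs-sampled Gaussian linear model (weight and length
contrasts between sex–age classes), and a Poisson regression with a log
exposure offset sampled by random-walk Metropolis (annual lactating counts
against river flow). Plus the plain breeding/lactation summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .io_data_model import CaptureRecord

DECADES = ((1973, 1983), (1984, 1993), (1994, 2003), (2004, 2014))


@dataclass(frozen=True)
class ProportionPosterior:
    """Beta(1+x, 1+n−x) posterior for a binomial proportion under a flat prior."""

    x: int
    n: int
    credible_level: float
    mean: float
    interval: tuple

    @property
    def alpha(self) -> float:
        return 1.0 + self.x

    @property
    def beta(self) -> float:
        return 1.0 + self.n - self.x

    def quantile(self, q) -> float:
        return float(stats.beta.ppf(q, self.alpha, self.beta))


def beta_binomial_test(x: int, n: int, credible_level: float = 0.95) -> ProportionPosterior:
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    a, b = 1.0 + x, 1.0 + n - x
    lo = (1.0 - credible_level) / 2.0
    return ProportionPosterior(
        x=x,
        n=n,
        credible_level=credible_level,
        mean=a / (a + b),
        interval=(float(stats.beta.ppf(lo, a, b)), float(stats.beta.ppf(1 - lo, a, b))),
    )


def beta_binomial_difference(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    credible_level: float = 0.95,
    draws: int = 100_000,
    seed: int = 0,
) -> dict:
    """θ1 − θ2 summarized from paired Monte-Carlo posterior draws."""
    rng = np.random.default_rng(seed)
    d = rng.beta(1 + x1, 1 + n1 - x1, draws) - rng.beta(1 + x2, 1 + n2 - x2, draws)
    lo = (1.0 - credible_level) / 2.0
    return {
        "mean": float(d.mean()),
        "sd": float(d.std(ddof=1)),
        "interval": (float(np.quantile(d, lo)), float(np.quantile(d, 1 - lo))),
        "prob_positive": float((d > 0).mean()),
    }


@dataclass
class GibbsConfig:
    draws: int = 10_000
    burn_in: int = 1_000
    thin: int = 5
    c0: float = 0.001  # inverse-Gamma shape hyperparameter (c0/2 convention)
    d0: float = 0.001  # inverse-Gamma scale hyperparameter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.draws <= 0 or self.thin < 1:
            raise ValueError("draws must be positive and thin >= 1")


@dataclass
class GibbsResult:
    summary: pd.DataFrame  # per coefficient + sigma2: mean, sd, 2.5%, 97.5%
    beta_draws: np.ndarray  # (n_retained, p)
    sigma2_draws: np.ndarray
    diagnostics: dict


def gibbs_linear_model(y, X, config: Optional[GibbsConfig] = None, names=None) -> GibbsResult:
    """Gaussian linear model with flat slope prior and IG(c0/2, d0/2) variance prior.

    Alternates the exact full conditionals: β | σ² ~ N(β̂_OLS, σ² (XᵀX)⁻¹)
    (the flat-prior limit of the Gaussian conditional) and
    σ² | β ~ IG((c0+n)/2, (d0+RSS)/2).
    """
    config = config or GibbsConfig()
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be (n, p) aligned with y")
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")

    rng = np.random.default_rng(config.seed)
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ X.T @ y
    chol = np.linalg.cholesky(XtX_inv)

    sigma2 = float(np.var(y - X @ beta_hat, ddof=p)) or 1.0
    total = config.burn_in + config.draws
    kept_beta, kept_s2 = [], []
    for it in range(total):
        beta = beta_hat + np.sqrt(sigma2) * (chol @ rng.standard_normal(p))
        rss = float(np.sum((y - X @ beta) ** 2))
        sigma2 = 1.0 / rng.gamma((config.c0 + n) / 2.0, 2.0 / (config.d0 + rss))
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            kept_beta.append(beta)
            kept_s2.append(sigma2)

    B = np.array(kept_beta)
    S = np.array(kept_s2)
    names = list(names) if names is not None else [f"b{j}" for j in range(p)]
    rows = []
    for j, name in enumerate(names):
        rows.append(_summary_row(name, B[:, j]))
    rows.append(_summary_row("sigma2", S))
    diag = {
        "n_retained": len(S),
        "split_half_shift": {
            names[j]: float(abs(B[: len(B) // 2, j].mean() - B[len(B) // 2 :, j].mean()))
            for j in range(p)
        },
        "lag1_autocorr": {
            names[j]: float(np.corrcoef(B[:-1, j], B[1:, j])[0, 1]) for j in range(p)
        },
    }
    return GibbsResult(
        summary=pd.DataFrame(rows), beta_draws=B, sigma2_draws=S, diagnostics=diag
    )


def _summary_row(name: str, draws: np.ndarray) -> dict:
    return {
        "term": name,
        "mean": float(draws.mean()),
        "sd": float(draws.std(ddof=1)),
        "q2.5": float(np.quantile(draws, 0.025)),
        "q97.5": float(np.quantile(draws, 0.975)),
    }


def bayes_poisson_regression(
    y,
    exposure,
    x,
    draws: int = 10_000,
    burn_in: int = 1_000,
    seed: int = 0,
    prior_sd: float = 25.0,
) -> dict:
    """Poisson regression y_t ~ Poisson(n_t · exp(a + b·x_t)).

    Coefficients get independent N(0, prior_sd²) priors — effectively flat for
    any plausible effect size but proper, so degenerate designs (e.g. a
    constant predictor) still yield a well-defined posterior. Sampled by
    random-walk Metropolis with the proposal covariance set from the curvature
    at the posterior mode (so acceptance stays in a sensible range without
    hand tuning). Returns posterior summaries for intercept and slope.
    """
    y = np.asarray(y, float)
    n_t = np.asarray(exposure, float)
    x = np.asarray(x, float)
    if len(y) < 3:
        raise ValueError("need at least three observations")
    if np.any(y > n_t):
        raise ValueError("counts cannot exceed exposure")
    if np.all(n_t == 0):
        raise ValueError("all-zero exposure")
    keep = n_t > 0
    y, n_t, x = y[keep], n_t[keep], x[keep]

    def neg_log_post(theta):
        eta = theta[0] + theta[1] * x
        lam = n_t * np.exp(np.clip(eta, -50, 50))
        penalty = 0.5 * float(np.sum(theta**2)) / prior_sd**2
        return float(np.sum(lam) - np.sum(y * (np.log(n_t) + eta))) + penalty

    res = minimize(neg_log_post, np.array([np.log(max(y.sum() / n_t.sum(), 1e-8)), 0.0]))
    mode = res.x
    H = _hessian_2d(neg_log_post, mode)
    try:
        prop_cov = np.linalg.inv(H) * (2.4**2 / 2)
        chol = np.linalg.cholesky(prop_cov)
    except np.linalg.LinAlgError:
        chol = np.eye(2) * 0.1

    rng = np.random.default_rng(seed)
    theta = mode.copy()
    lp = -neg_log_post(theta)
    kept = []
    accepted = 0
    for it in range(burn_in + draws):
        cand = theta + chol @ rng.standard_normal(2)
        lp_cand = -neg_log_post(cand)
        if np.log(rng.random()) < lp_cand - lp:
            theta, lp = cand, lp_cand
            accepted += 1
        if it >= burn_in:
            kept.append(theta.copy())
    K = np.array(kept)
    return {
        "intercept": _summary_row("intercept", K[:, 0]),
        "slope": _summary_row("slope", K[:, 1]),
        "acceptance_rate": accepted / (burn_in + draws),
        "draws": K,
    }


def _hessian_2d(f, x, h: float = 1e-4) -> np.ndarray:
    H = np.zeros((2, 2))
    f0 = f(x)
    e = np.eye(2) * h
    for i in range(2):
        H[i, i] = (f(x + e[i]) - 2 * f0 + f(x - e[i])) / h**2
    H[0, 1] = H[1, 0] = (
        f(x + e[0] + e[1]) - f(x + e[0] - e[1]) - f(x - e[0] + e[1]) + f(x - e[0] - e[1])
    ) / (4 * h**2)
    return H


def _decade_of(year: int) -> Optional[tuple]:
    for lo, hi in DECADES:
        if lo <= year <= hi:
            return (lo, hi)
    return None


def breeding_stats(records: Sequence[CaptureRecord]) -> dict:
    """Lactation index, decadal proportions, consecutive-year breeding table,
    and decadal sex / juvenile:adult ratios.

    The annual lactation index is the ratio of lactating to tested females
    captured during December–January; each female counts once per year (and so
    can count multiple times within a decade).
    """
    rows = []
    for r in records:
        rows.append(
            {
                "animal_id": r.animal_id,
                "year": r.date.year,
                "month": r.date.month,
                "sex": r.sex,
                "age_class": r.age_class,
                "lactating": r.lactating,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return {"annual_lactation_index": {}, "decade_lactation": {}, "consecutive": None}

    # December belongs with the following January (one breeding season)
    df["season_year"] = np.where(df["month"] == 12, df["year"] + 1, df["year"])

    fem = df[(df.sex == "female") & (df.lactating != "untested") & df.month.isin((12, 1))]
    per_fy = fem.groupby(["season_year", "animal_id"])["lactating"].agg(
        lambda s: "yes" if (s == "yes").any() else "no"
    )
    annual_index = {}
    for year, grp in per_fy.groupby(level=0):
        annual_index[int(year)] = float((grp == "yes").mean())

    decade_lact = {}
    fem = fem.copy()
    fem["decade"] = fem["year"].map(_decade_of)
    for dec, grp in fem.dropna(subset=["decade"]).groupby("decade"):
        once = grp.groupby(["season_year", "animal_id"])["lactating"].agg(
            lambda s: "yes" if (s == "yes").any() else "no"
        )
        post = beta_binomial_test(int((once == "yes").sum()), int(len(once)))
        decade_lact[f"{dec[0]}-{dec[1]}"] = {
            "mean": post.mean,
            "interval": post.interval,
            "n": post.n,
        }

    # consecutive-year breeding over females tested in both years of a pair
    both = first_only = second_only = neither = 0
    tested = per_fy.reset_index()
    tested.columns = ["season_year", "animal_id", "lactating"]
    by_animal = tested.groupby("animal_id")
    for _aid, grp in by_animal:
        grp = grp.sort_values("season_year")
        yrs = grp["season_year"].to_numpy()
        lac = (grp["lactating"] == "yes").to_numpy()
        for i in range(len(yrs) - 1):
            if yrs[i + 1] == yrs[i] + 1:
                if lac[i] and lac[i + 1]:
                    both += 1
                elif lac[i]:
                    first_only += 1
                elif lac[i + 1]:
                    second_only += 1
                else:
                    neither += 1
    n_pairs = both + first_only + second_only + neither
    consecutive = None
    if n_pairs:
        consecutive = {
            "n_pairs": n_pairs,
            "both": both / n_pairs,
            "first_only": first_only / n_pairs,
            "second_only": second_only / n_pairs,
            "neither": neither / n_pairs,
        }

    df["decade"] = df["year"].map(_decade_of)
    sex_ratio, juv_ratio = {}, {}
    for dec, grp in df.dropna(subset=["decade"]).groupby("decade"):
        once = grp.drop_duplicates(["year", "animal_id"])
        key = f"{dec[0]}-{dec[1]}"
        post = beta_binomial_test(int((once.sex == "female").sum()), int(len(once)))
        sex_ratio[key] = {"mean": post.mean, "interval": post.interval, "n": post.n}
        post = beta_binomial_test(int((once.age_class == "juvenile").sum()), int(len(once)))
        juv_ratio[key] = {"mean": post.mean, "interval": post.interval, "n": post.n}

    return {
        "annual_lactation_index": annual_index,
        "mean_annual_lactation_index": float(np.mean(list(annual_index.values())))
        if annual_index
        else float("nan"),
        "decade_lactation": decade_lact,
        "consecutive": consecutive,
        "decade_sex_ratio": sex_ratio,
        "decade_juvenile_ratio": juv_ratio,
    }
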