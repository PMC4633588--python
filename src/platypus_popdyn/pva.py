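"""Two-sex, age-classed stochastic population viability analysis.

The simulator projects a single platypus population year by year with the
event order breed → die → disperse → age → truncate-to-K (a post-breeding
annual census). Females first breed at age 2; each breeding female enters
the breeding pool independently every year (62% by default), breeding
happens only if at least one adult male is in the male pool (each adult male
enters with probability 38%), litters are 1 or 2 young with mean 1.5, births
are 50:50. Mortality is class-specific over five sex–age classes (juvenile
female, adult female, juvenile male, sub-adult male, adult male). Dispersal
is temporary emigration: a surviving disperser dies in transit with
probability 1 − s_disp and otherwise remains in the (single) population.
Animals exceeding age 21 die.

Because individuals within a sex–age class are exchangeable, the simulator
tracks exact integer counts per (sex, age) cell and draws binomials — the
same stochastic process as simulating each animal, vectorised across Monte
Carlo iterations. Truncation to carrying capacity removes individuals
uniformly at random (multivariate hypergeometric across cells).

Apparent survival Φ from mark-recapture confounds death with emigration;
given pool residency r, the adjusted (true) survival is S = Φ / r.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_data_model import FIVE_CLASSES

#: Table of dispersal fractions by class used by the adjusted preset.
ADJUSTED_DISPERSAL = {
    "female_juvenile": 0.154,
    "female_adult": 0.145,
    "male_juvenile": 0.55,
    "male_subadult": 0.38,
    "male_adult": 0.26,
}
APPARENT_MORTALITY = {
    "female_juvenile": 0.73,
    "female_adult": 0.24,
    "male_juvenile": 0.87,
    "male_subadult": 0.62,
    "male_adult": 0.43,
}
ADJUSTED_MORTALITY = {
    "female_juvenile": 0.71,
    "female_adult": 0.11,
    "male_juvenile": 0.77,
    "male_subadult": 0.43,
    "male_adult": 0.23,
}


@dataclass(frozen=True)
class VitalRates:
    """Per-class annual survival and dispersal, with provenance."""

    survival: dict  # class -> annual survival probability S_y
    dispersal: dict  # class -> dispersal probability d_y (= 1 - r_y)
    s_disp: float = 1.0  # disperser transit survival, shared across classes
    phi: Optional[dict] = None  # apparent survival, if rates were derived
    residency: Optional[dict] = None

    def __post_init__(self) -> None:
        for cls in FIVE_CLASSES:
            if not 0.0 <= self.survival[cls] <= 1.0:
                raise ValueError(f"survival[{cls}] outside [0,1]")
            if not 0.0 <= self.dispersal[cls] <= 1.0:
                raise ValueError(f"dispersal[{cls}] outside [0,1]")
        if not 0.0 <= self.s_disp <= 1.0:
            raise ValueError("s_disp outside [0,1]")

    @property
    def mortality(self) -> dict:
        return {c: 1.0 - s for c, s in self.survival.items()}

    def effective_survival(self) -> dict:
        """Survival including transit mortality of dispersers."""
        return {
            c: self.survival[c] * (1.0 - self.dispersal[c] * (1.0 - self.s_disp))
            for c in FIVE_CLASSES
        }


def derive_vital_rates(phi: dict, residency: dict, s_disp: float = 1.0) -> VitalRates:
    """Adjust apparent survival for emigration: S_y = Φ_y / r_y, capped at 1.

    Residency r is the probability consecutive recaptures fall in the same
    pool, a proxy for site fidelity; dispersal d_y = 1 − r_y.
    """
    survival, dispersal = {}, {}
    for cls in FIVE_CLASSES:
        p, r = phi[cls], residency[cls]
        if not 0.0 < p <= 1.0:
            raise ValueError(f"phi[{cls}] must lie in (0,1]")
        if not 0.0 < r <= 1.0:
            raise ValueError(f"residency[{cls}] must lie in (0,1]")
        s = p / r
        if s > 1.0:
            warnings.warn(f"adjusted survival for {cls} capped at 1 (phi/r = {s:.3f})")
            s = 1.0
        survival[cls] = s
        dispersal[cls] = 1.0 - r
    return VitalRates(
        survival=survival, dispersal=dispersal, s_disp=s_disp, phi=dict(phi), residency=dict(residency)
    )


def vital_rates_from_mortality(
    mortality: dict, dispersal: Optional[dict] = None, s_disp: float = 1.0
) -> VitalRates:
    return VitalRates(
        survival={c: 1.0 - mortality[c] for c in FIVE_CLASSES},
        dispersal=dict(dispersal) if dispersal else {c: 0.0 for c in FIVE_CLASSES},
        s_disp=s_disp,
    )


@dataclass(frozen=True)
class PVAConfig:
    vital_rates: VitalRates
    breeding_pool_female: float = 0.62
    breeding_pool_male: float = 0.38
    first_breeding_age: int = 2
    max_age: int = 21
    max_litter: int = 2
    mean_litter: float = 1.5
    male_birth_fraction: float = 0.5
    initial_size: int = 50
    carrying_capacity: Optional[int] = 200  # None = unbounded
    years: int = 100
    iterations: int = 1000
    seed: int = 0
    # optional explicit initial age structure: {"female": counts, "male": counts},
    # each indexed by age 0..max_age (age 0 entries are ignored: census ages are >= 1)
    initial_counts: Optional[dict] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.breeding_pool_female <= 1.0:
            raise ValueError("breeding fraction outside [0,1]")
        if not 0.0 <= self.breeding_pool_male <= 1.0:
            raise ValueError("breeding fraction outside [0,1]")
        if self.years < 1 or self.iterations < 1:
            raise ValueError("years and iterations must be >= 1")
        if not 1.0 <= self.mean_litter <= self.max_litter:
            raise ValueError("mean litter must lie in [1, max_litter]")
        if self.max_litter != 2:
            raise ValueError("litter distribution is defined on {1, 2}")


def apparent_scenario(**overrides) -> PVAConfig:
    """Preset: unadjusted apparent-survival mortalities, dispersal disabled."""
    return PVAConfig(vital_rates=vital_rates_from_mortality(APPARENT_MORTALITY), **overrides)


def adjusted_scenario(s_disp: float = 1.0, **overrides) -> PVAConfig:
    """Preset: residency-adjusted mortalities with class dispersal fractions."""
    return PVAConfig(
        vital_rates=vital_rates_from_mortality(ADJUSTED_MORTALITY, ADJUSTED_DISPERSAL, s_disp),
        **overrides,
    )


def _female_leslie(config: PVAConfig) -> np.ndarray:
    """Female-only projection over census ages 1..max_age (post-breeding census).

    Fecundity = breeding-pool fraction × mean litter × daughter fraction,
    times first-year (juvenile) survival so newborns are counted at census age
    1; survival entries include transit mortality of dispersers.
    """
    s = config.vital_rates.effective_survival()
    A = config.max_age
    m = (
        config.breeding_pool_female
        * config.mean_litter
        * (1.0 - config.male_birth_fraction)
        * s["female_juvenile"]
    )
    L = np.zeros((A, A))  # index a-1 <-> age a
    for a in range(config.first_breeding_age, A + 1):
        L[0, a - 1] = m
    for a in range(1, A):
        L[a, a - 1] = s["female_adult"]
    return L


def leslie_lambda(config: PVAConfig) -> tuple[float, float]:
    """Dominant eigenvalue λ (and ln λ) of the female projection, by power iteration."""
    L = _female_leslie(config)
    v = np.ones(L.shape[0])
    lam = 1.0
    for _ in range(100_000):
        w = L @ v
        new = float(np.linalg.norm(w))
        if new == 0.0:
            return 0.0, -math.inf
        w /= new
        if abs(new - lam) < 1e-12 and np.linalg.norm(w - v) < 1e-10:
            lam = new
            break
        lam, v = new, w
    return lam, math.log(lam) if lam > 0 else -math.inf


def _male_survival_by_age(config: PVAConfig) -> np.ndarray:
    s = config.vital_rates.effective_survival()
    A = config.max_age
    out = np.empty(A + 1)
    out[0] = s["male_juvenile"]
    out[1] = s["male_subadult"]
    out[2:] = s["male_adult"]
    return out


def stable_stage(config: PVAConfig) -> dict:
    """Initial (sex, age) counts at the stable stage, integerized to initial_size.

    Right eigenvector of the two-sex projection at the dominant λ, scaled to the
    configured initial size with largest-remainder rounding.
    """
    s = config.vital_rates.effective_survival()
    A = config.max_age
    F = _female_leslie(config)
    M = np.zeros((A, A))
    m_male = (
        config.breeding_pool_female
        * config.mean_litter
        * config.male_birth_fraction
        * s["male_juvenile"]
    )
    male_s = _male_survival_by_age(config)
    for a in range(1, A):
        M[a, a - 1] = male_s[a]
    P = np.zeros((2 * A, 2 * A))
    P[:A, :A] = F
    P[A, config.first_breeding_age - 1 : A] = m_male  # male recruits from adult females
    P[A:, A:] = M
    vals, vecs = np.linalg.eig(P)
    lead = int(np.argmax(vals.real))
    v = np.abs(vecs[:, lead].real)
    if v.sum() == 0:
        v = np.ones(2 * A)
    shares = v / v.sum() * config.initial_size
    counts = np.floor(shares).astype(int)
    remainder = config.initial_size - counts.sum()
    order = np.argsort(-(shares - counts))
    counts[order[:remainder]] += 1
    female = np.zeros(A + 1, dtype=int)
    male = np.zeros(A + 1, dtype=int)
    female[1:] = counts[:A]
    male[1:] = counts[A:]
    return {"female": female, "male": male}


@dataclass
class PVAResult:
    trajectories: np.ndarray  # (iterations, years+1) population sizes
    extinction_time: np.ndarray  # (iterations,) first year with N=0, nan if never
    r_mean: float  # mean of ln(N_{t+1}/N_t) over iterations x years with N>0
    r_sd: float
    config: PVAConfig
    seed: int


def run_pva(config: PVAConfig) -> PVAResult:
    """Project the population ``iterations`` times for ``years`` years."""
    rng = np.random.default_rng(config.seed)
    A = config.max_age
    I = config.iterations
    s = config.vital_rates.survival
    d = config.vital_rates.dispersal
    q_transit = {c: d[c] * (1.0 - config.vital_rates.s_disp) for c in FIVE_CLASSES}

    if config.initial_counts is not None:
        f0 = np.asarray(config.initial_counts["female"], dtype=np.int64)
        m0 = np.asarray(config.initial_counts["male"], dtype=np.int64)
        if len(f0) != A + 1 or len(m0) != A + 1:
            raise ValueError("initial_counts arrays must have length max_age + 1")
    else:
        ss = stable_stage(config)
        f0, m0 = ss["female"], ss["male"]

    F = np.tile(f0, (I, 1)).astype(np.int64)
    M = np.tile(m0, (I, 1)).astype(np.int64)
    F[:, 0] = 0
    M[:, 0] = 0
    K = config.carrying_capacity
    fb = config.first_breeding_age
    p_two = config.mean_litter - 1.0

    traj = np.zeros((I, config.years + 1), dtype=np.int64)
    traj[:, 0] = F.sum(axis=1) + M.sum(axis=1)

    for t in range(config.years):
        # 1. breeding (year-start census state)
        n_af = F[:, fb:].sum(axis=1)
        n_am = M[:, fb:].sum(axis=1)
        males_in_pool = rng.binomial(n_am, config.breeding_pool_male)
        can_breed = males_in_pool >= 1
        breeders = rng.binomial(n_af, config.breeding_pool_female) * can_breed
        offspring = breeders + rng.binomial(breeders, p_two)
        born_m = rng.binomial(offspring, config.male_birth_fraction)
        born_f = offspring - born_m

        # 2. mortality (newborns face juvenile mortality in their first year)
        nf = rng.binomial(born_f, s["female_juvenile"])
        nm = rng.binomial(born_m, s["male_juvenile"])
        F[:, 1:] = rng.binomial(F[:, 1:], s["female_adult"])
        M[:, 1] = rng.binomial(M[:, 1], s["male_subadult"])
        M[:, 2:] = rng.binomial(M[:, 2:], s["male_adult"])

        # 3. dispersal: survivors die in transit with probability d_y (1 - s_disp)
        if config.vital_rates.s_disp < 1.0:
            nf = rng.binomial(nf, 1.0 - q_transit["female_juvenile"])
            nm = rng.binomial(nm, 1.0 - q_transit["male_juvenile"])
            F[:, 1:] = rng.binomial(F[:, 1:], 1.0 - q_transit["female_adult"])
            M[:, 1] = rng.binomial(M[:, 1], 1.0 - q_transit["male_subadult"])
            M[:, 2:] = rng.binomial(M[:, 2:], 1.0 - q_transit["male_adult"])

        # 4. aging; age-max_age animals leave the table (exceed maximum age)
        F[:, 2:] = F[:, 1:A]
        M[:, 2:] = M[:, 1:A]
        F[:, 1] = nf
        M[:, 1] = nm

        # 5. truncation to K by uniform random removal
        if K is not None:
            N = F.sum(axis=1) + M.sum(axis=1)
            for i in np.flatnonzero(N > K):
                cells = np.concatenate([F[i, 1:], M[i, 1:]])
                kept = rng.multivariate_hypergeometric(cells, K)
                F[i, 1:] = kept[:A]
                M[i, 1:] = kept[A:]

        traj[:, t + 1] = F.sum(axis=1) + M.sum(axis=1)

    ext = np.full(I, np.nan)
    zero = traj == 0
    any_ext = zero.any(axis=1)
    ext[any_ext] = zero[any_ext].argmax(axis=1)

    prev, nxt = traj[:, :-1].astype(float), traj[:, 1:].astype(float)
    ok = (prev > 0) & (nxt > 0)
    ratios = np.log(nxt[ok] / prev[ok])
    r_mean = float(ratios.mean()) if ratios.size else float("nan")
    r_sd = float(ratios.std(ddof=1)) if ratios.size > 1 else float("nan")
    return PVAResult(
        trajectories=traj,
        extinction_time=ext,
        r_mean=r_mean,
        r_sd=r_sd,
        config=config,
        seed=config.seed,
    )


def summarize_pva(result: PVAResult, horizons: Sequence[int]) -> dict:
    """Extinction probabilities by horizon and median time to extinction."""
    years = result.trajectories.shape[1] - 1
    for h in horizons:
        if not 0 <= h <= years:
            raise ValueError(f"horizon {h} outside simulated span 0..{years}")
    ext = result.extinction_time
    extinct = ext[~np.isnan(ext)]
    return {
        "extinction_probability": {
            int(h): float(np.mean(np.nan_to_num(ext, nan=np.inf) <= h)) for h in horizons
        },
        "median_time_to_extinction": float(np.median(extinct)) if extinct.size else None,
        "censored": extinct.size < len(ext),
        "fraction_extinct": float(extinct.size / len(ext)),
        "r_mean": result.r_mean,
        "r_sd": result.r_sd,
    }
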