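"""Shared fixtures: a small ground-truthed dataset and hand-rolled oracles."""

from __future__ import annotations

import numpy as np
import pytest

from platypus_popdyn import TruthConfig, build_occasions, generate_dataset
from platypus_popdyn.cjs import CaptureHistoryMatrix, build_capture_histories


@pytest.fixture(scope="session")
def small_dataset():
    """A 12-year synthetic study small enough for every stage to run fast."""
    cfg = TruthConfig(years=12, initial_n=50, seed=5)
    truth, records, book = generate_dataset(cfg)
    occasions = build_occasions(records, truth.flows, cfg.season_start_month)
    return {
        "config": cfg,
        "truth": truth,
        "records": records,
        "book": book,
        "occasions": occasions,
    }


@pytest.fixture(scope="session")
def small_chm(small_dataset):
    return build_capture_histories(small_dataset["records"], small_dataset["occasions"])


def enumerate_history_probability(history, first, phi, p) -> float:
    """Brute-force CJS history probability by summing over death times.

    ``phi[t]`` is survival over interval t→t+1 and ``p[t]`` detection at
    occasion t+1. Conditions on first capture at ``first``.
    """
    history = list(history)
    T = len(history)
    last = max(i for i, v in enumerate(history) if v)
    total = 0.0
    for a in range(max(first, last), T):  # a = last occasion alive
        prob = 1.0
        for t in range(first, a):
            prob *= phi[t]
            prob *= p[t] if history[t + 1] else (1.0 - p[t])
        if a < T - 1:
            prob *= 1.0 - phi[a]
        total += prob
    return total


def all_histories(T: int, first: int = 0):
    """Every post-release encounter history with a 1 at the release occasion."""
    out = []
    for bits in range(2 ** (T - first - 1)):
        h = [0] * T
        h[first] = 1
        for j in range(T - first - 1):
            h[first + 1 + j] = (bits >> j) & 1
        out.append(h)
    return out


def make_history_matrix(encounter: np.ndarray) -> CaptureHistoryMatrix:
    """Wrap a raw encounter matrix with neutral covariates."""
    enc = np.asarray(encounter, dtype=int)
    n, T = enc.shape
    first = enc.argmax(axis=1)
    last = T - 1 - enc[:, ::-1].argmax(axis=1)
    zeros = np.zeros(T)
    return CaptureHistoryMatrix(
        encounter=enc,
        first=first,
        last=last,
        animal_ids=[f"a{i}" for i in range(n)],
        sex_male=np.zeros(n, dtype=int),
        age_code=np.full((n, T), 2, dtype=int),
        weight=np.full((n, T), 1000.0),
        occasion_covariates={
            k: zeros.copy()
            for k in (
                "effort",
                "flow_1m",
                "flow_6m",
                "flow_12m",
                "flow_24m",
                "flow_max_jan_dec",
                "flow_max_jan_apr",
            )
        },
    )


def simulate_constant_histories(
    n: int, T: int, phi: float, p: float, rng: np.random.Generator
) -> CaptureHistoryMatrix:
    """CJS data with constant survival and detection; releases spread uniformly."""
    enc = np.zeros((n, T), dtype=int)
    first = rng.integers(0, T - 1, size=n)
    for i in range(n):
        enc[i, first[i]] = 1
        for t in range(first[i], T - 1):
            if rng.random() >= phi:
                break
            if rng.random() < p:
                enc[i, t + 1] = 1
    return make_history_matrix(enc)
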