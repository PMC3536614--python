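"""Synthetic fixtures: tiny networks and reference distribution samples.

These support estimator-recovery checks (lognormal and power-law fits on
samples of known parameters), the random-walk first-passage oracle for the
-3/2 lifetime exponent, and a small deterministic network record for fast
integration tests.
"""

from __future__ import annotations

import numpy as np

from .params import NetworkParams
from .engine import SimulationRecord, RecordSpec, run

__all__ = [
    "tiny_net_record", "lognormal_sample", "powerlaw_sample",
    "random_walk_lifetimes", "make_fixture", "FIXTURE_KINDS",
]

FIXTURE_KINDS = ("tiny-net", "lognormal-sample", "powerlaw-sample",
                 "random-walk-lifetimes")


def tiny_net_record(seed: int = 1, n_steps: int = 500) -> SimulationRecord:
    """A 10E/2I network run — small enough for exhaustive checks."""
    params = NetworkParams(n_exc=10, n_inh=2, seed=seed)
    return run(params, n_steps,
               record=RecordSpec(snapshot_every=100, stdp_deltas=True))


def lognormal_sample(mu: float = -3.0, sigma: float = 1.0, n: int = 10_000,
                     seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.lognormal(mu, sigma, n)


def powerlaw_sample(alpha: float = 1.5, n: int = 10_000, xmin: int = 1,
                    seed: int = 0) -> np.ndarray:
    """Discrete power-law sample, p(k) ~ k^-alpha for k >= xmin.

    Drawn from the zeta (Zipf) distribution and, for xmin > 1, restricted
    to the tail by rejection — exact for any xmin, efficient for the small
    xmin values used here.
    """
    from scipy import stats
    rng = np.random.default_rng(seed)
    out = np.empty(0, dtype=np.int64)
    while out.size < n:
        draw = stats.zipf.rvs(alpha, size=2 * n, random_state=rng)
        out = np.concatenate([out, draw[draw >= xmin]])
    return out[:n]


def random_walk_lifetimes(n_walks: int = 100_000, horizon: int = 10_000,
                          seed: int = 0) -> np.ndarray:
    """First-passage times to zero of symmetric unit random walks.

    Walks start at +1 and take +/-1 steps; the first step t at which the
    position reaches 0 is the lifetime.  Walks still alive at the horizon
    are dropped (right censoring), matching the lifetime analysis.  The
    asymptotic density falls as t^{-3/2} — the null model for synapses
    whose weight diffuses under balanced STDP kicks.
    """
    rng = np.random.default_rng(seed)
    pos = np.ones(n_walks, dtype=np.int64)
    alive = np.arange(n_walks)
    out = []
    for t in range(1, horizon + 1):
        steps = rng.integers(0, 2, size=alive.size) * 2 - 1
        pos[alive] += steps
        dead = pos[alive] <= 0
        if dead.any():
            out.append(np.full(dead.sum(), t, dtype=np.int64))
            alive = alive[~dead]
        if alive.size == 0:
            break
    return np.concatenate(out) if out else np.empty(0, np.int64)


def make_fixture(kind: str, seed: int = 0, **kwargs):
    """Dispatch by fixture kind; returns the in-memory object."""
    if kind == "tiny-net":
        return tiny_net_record(seed=seed, **kwargs)
    if kind == "lognormal-sample":
        return lognormal_sample(seed=seed, **kwargs)
    if kind == "powerlaw-sample":
        return powerlaw_sample(seed=seed, **kwargs)
    if kind == "random-walk-lifetimes":
        return random_walk_lifetimes(seed=seed, **kwargs)
    raise ValueError(f"unknown fixture kind {kind!r}; "
                     f"choose one of {FIXTURE_KINDS}")
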