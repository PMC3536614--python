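"""The five plasticity rules as pure state-transforming operations.

1. Additive STDP on excitatory->excitatory synapses, with elimination of
   synapses driven below zero.
2. Synaptic normalization: each excitatory unit's incoming EE weights are
   rescaled to sum to one (multiplicative synaptic scaling).
3. Intrinsic plasticity: excitatory thresholds track a target firing rate.
4. Structural plasticity: random creation of new EE synapses at a small
   rate.
5. Inhibitory STDP on inhibitory->excitatory synapses, balancing
   excitatory and inhibitory drive.

All functions mutate the passed state in place and return it (plus event
information where relevant); callers who need the old state copy first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SynapticState, ThresholdState
from .params import ParameterError

__all__ = [
    "StdpDelta", "stdp_update", "synaptic_normalization",
    "intrinsic_plasticity", "structural_plasticity", "istdp_update",
]


@dataclass(frozen=True)
class StdpDelta:
    """One nonzero STDP weight change on synapse (post, pre).

    ``w_before`` is the weight prior to the change; ``eliminated`` marks
    synapses that the change drove to zero (and out of the network).
    """

    post: int
    pre: int
    delta: float
    w_before: float
    eliminated: bool


def _stdp_apply(syn: SynapticState, x_now: np.ndarray, x_prev: np.ndarray,
                eta: float):
    """Array core of the STDP rule (used directly by the engine hot loop).

    Returns ``(rows, cols, dvals, w_before, killed)`` for the synapses
    whose weight actually changed; ``killed`` is a boolean mask over those
    entries marking eliminations.
    """
    empty = (np.empty(0, np.intp), np.empty(0, np.intp),
             np.empty(0, float), np.empty(0, float), np.empty(0, bool))
    now_i = np.flatnonzero(x_now)
    prev_i = np.flatnonzero(x_prev)
    if now_i.size == 0 or prev_i.size == 0:
        return empty
    # Candidates: potentiation needs post active now & pre active at the
    # previous step; depression the reverse.  Only the small grid spanned
    # by the active units is touched, not the full matrix.
    u = np.union1d(now_i, prev_i)
    in_now = np.isin(u, now_i, assume_unique=True)
    in_prev = np.isin(u, prev_i, assume_unique=True)
    ch = eta * (np.outer(in_now, in_prev).astype(float)
                - np.outer(in_prev, in_now))
    ch *= syn.ee_mask[np.ix_(u, u)]
    r, c = np.nonzero(ch)
    if r.size == 0:
        return empty
    rows = u[r]
    cols = u[c]
    dvals = ch[r, c]
    w_before = syn.w_ee[rows, cols].copy()
    w_after = w_before + dvals
    killed = w_after <= 0   # reaching zero IS elimination
    w_after[killed] = 0.0
    syn.w_ee[rows, cols] = w_after
    if killed.any():
        syn.ee_mask[rows[killed], cols[killed]] = False
    return rows, cols, dvals, w_before, killed


def stdp_update(syn: SynapticState, x_now: np.ndarray, x_prev: np.ndarray,
                eta: float) -> tuple[SynapticState, list[StdpDelta]]:
    """Additive spike-timing-dependent plasticity on existing EE synapses.

    For each structurally existing synapse (post i, pre j):

        dw_ij = eta * ( x_i(t+1) x_j(t)  -  x_i(t) x_j(t+1) )

    i.e. pre-before-post potentiates by ``eta``, post-before-pre depresses
    by the same amount; coincident activity at both steps cancels.  A
    weight driven below zero is set to exactly zero and the synapse is
    removed (elimination).  Returns the list of nonzero changes; synapses
    with a zero net change are omitted.
    """
    if eta < 0:
        raise ParameterError("eta_stdp", f"must be >= 0, got {eta!r}")
    if eta == 0:
        return syn, []
    rows, cols, dvals, w_before, killed = _stdp_apply(syn, x_now, x_prev, eta)
    deltas = [StdpDelta(int(i), int(j), float(d), float(wb), bool(k))
              for i, j, d, wb, k in zip(rows, cols, dvals, w_before, killed)]
    return syn, deltas


def synaptic_normalization(syn: SynapticState) -> SynapticState:
    """Rescale each unit's incoming EE weights to sum to one.

    Rows with zero total (units without incoming synapses) are left
    unchanged.  Relative strengths within a row are preserved, so the rule
    induces competition without reordering synapses.
    """
    row = syn.w_ee.sum(axis=1, keepdims=True)
    np.divide(syn.w_ee, row, out=syn.w_ee, where=row > 0)
    return syn


def intrinsic_plasticity(thr: ThresholdState, x_now: np.ndarray,
                         eta_ip: float,
                         target_rate: float | np.ndarray) -> ThresholdState:
    """Homeostatic threshold adaptation toward a target firing rate.

        T_E[i] <- T_E[i] + eta_ip * ( x_i - target_rate_i )

    An active unit raises its threshold, an inactive one lowers it.
    Thresholds are not clipped: under weak drive homeostasis may push
    them negative.  Inhibitory thresholds are untouched.
    """
    if eta_ip < 0:
        raise ParameterError("eta_ip", f"must be >= 0, got {eta_ip!r}")
    thr.t_exc += eta_ip * (x_now.astype(np.float64) - target_rate)
    return thr


def structural_plasticity(syn: SynapticState, p_struct: float, w_new: float,
                          rng: np.random.Generator,
                          ) -> tuple[SynapticState, tuple[int, int] | None]:
    """One synapse-creation attempt.

    With probability ``p_struct``, one ordered non-self pair is drawn
    uniformly from the currently unconnected EE pairs and created with
    weight ``w_new``.  If every pair is connected, the attempt is a no-op.
    Returns the created (post, pre) pair, or None.

    Sampling is by rejection (uniform over unconnected pairs); at the
    sparse densities the model operates in this almost always succeeds on
    the first draw.  A dense fallback guarantees termination.
    """
    if p_struct <= 0 or rng.random() >= p_struct:
        return syn, None
    n = syn.w_ee.shape[0]
    if n < 2:
        return syn, None
    for _ in range(64):
        i = int(rng.integers(n))
        j = int(rng.integers(n))
        if i != j and not syn.ee_mask[i, j]:
            syn.ee_mask[i, j] = True
            syn.w_ee[i, j] = w_new
            return syn, (i, j)
    free = ~syn.ee_mask
    np.fill_diagonal(free, False)
    candidates = np.argwhere(free)
    if candidates.size == 0:
        return syn, None
    i, j = candidates[rng.integers(len(candidates))]
    syn.ee_mask[i, j] = True
    syn.w_ee[i, j] = w_new
    return syn, (int(i), int(j))


def istdp_update(syn: SynapticState, y_prev: np.ndarray, x_now: np.ndarray,
                 eta_pot: float, eta_dep: float,
                 w_floor: float) -> SynapticState:
    """Inhibitory STDP on existing inhibitory->excitatory synapses.

    For each existing synapse (excitatory i, inhibitory k) with
    y_k(t) = 1:

    * x_i(t+1) = 0 — the inhibitory spike "succeeded": the weight is
      reduced by ``eta_dep`` but floored at ``w_floor`` so it is never
      eliminated;
    * x_i(t+1) = 1 — the spike "failed": the weight grows by the larger
      amount ``eta_pot``.

    Synapses whose inhibitory unit was silent are unchanged.  The
    asymmetry (eta_pot > eta_dep) balances excitatory and inhibitory
    drive at the low firing rates the network operates at.
    """
    if eta_pot <= eta_dep:
        raise ParameterError(
            "eta_istdp_pot",
            f"potentiation must exceed depression ({eta_pot!r} <= {eta_dep!r})")
    if eta_dep < 0:
        raise ParameterError("eta_istdp_dep", f"must be >= 0, got {eta_dep!r}")
    active_k = np.flatnonzero(y_prev)
    if active_k.size == 0:
        return syn
    fired = x_now.astype(bool)
    sub = syn.w_ei[:, active_k]
    mask = syn.ei_mask[:, active_k]
    pot = mask & fired[:, None]
    dep = mask & ~fired[:, None]
    sub[pot] += eta_pot
    sub[dep] = np.maximum(sub[dep] - eta_dep, w_floor)
    syn.w_ei[:, active_k] = sub
    return syn
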