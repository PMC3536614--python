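"""Network state containers and the noisy binary threshold dynamics.

The model has three weight matrices, all stored incoming-major so that a
row collects the inputs of one target unit:

* ``w_ee[i, j]`` — excitatory j -> excitatory i (sparse, fully plastic);
* ``w_ei[i, k]`` — inhibitory k -> excitatory i (sparse, iSTDP-plastic);
* ``w_ie[k, j]`` — excitatory j -> inhibitory k (dense, fixed, each row
  normalized to sum to one).

Units are binary: at each discrete step a unit fires iff its summed drive,
plus white Gaussian membrane noise, strictly exceeds its threshold.
Excitatory thresholds are plastic (intrinsic plasticity); inhibitory
thresholds stay at their random initial values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import NetworkParams

__all__ = [
    "SynapticState", "ThresholdState", "ActivityState",
    "init_network", "update_state",
]


@dataclass
class SynapticState:
    """The three weight matrices plus the EE structural-connection mask.

    ``ee_mask`` is the authoritative record of which excitatory->excitatory
    synapses structurally exist; outside of a single plasticity update a
    weight is positive iff its mask entry is True.  ``ei_mask`` is fixed
    after initialization because the iSTDP floor prevents elimination.
    """

    w_ee: np.ndarray          # (n_exc, n_exc)
    ee_mask: np.ndarray       # bool (n_exc, n_exc)
    w_ei: np.ndarray          # (n_exc, n_inh)
    ei_mask: np.ndarray       # bool (n_exc, n_inh)
    w_ie: np.ndarray          # (n_inh, n_exc), fixed

    @property
    def ee_connected(self) -> set[tuple[int, int]]:
        """Structurally existing EE synapses as ordered (post, pre) pairs."""
        return set(map(tuple, np.argwhere(self.ee_mask)))

    def n_ee_connections(self) -> int:
        return int(self.ee_mask.sum())

    def connection_fraction(self) -> float:
        """Existing EE synapses over all ordered non-self pairs."""
        n = self.w_ee.shape[0]
        return self.n_ee_connections() / (n * (n - 1))

    def copy(self) -> "SynapticState":
        return SynapticState(self.w_ee.copy(), self.ee_mask.copy(),
                             self.w_ei.copy(), self.ei_mask.copy(),
                             self.w_ie.copy())


@dataclass
class ThresholdState:
    t_exc: np.ndarray   # plastic
    t_inh: np.ndarray   # fixed after initialization

    def copy(self) -> "ThresholdState":
        return ThresholdState(self.t_exc.copy(), self.t_inh.copy())


@dataclass
class ActivityState:
    """Binary firing vectors at the current and previous step."""

    x: np.ndarray
    y: np.ndarray
    x_prev: np.ndarray
    y_prev: np.ndarray

    def copy(self) -> "ActivityState":
        return ActivityState(self.x.copy(), self.y.copy(),
                             self.x_prev.copy(), self.y_prev.copy())


def init_network(params: NetworkParams, seed: int | None = None,
                 rng: np.random.Generator | None = None,
                 ) -> tuple[SynapticState, ThresholdState, ActivityState]:
    """Draw the random initial network.

    Draw order (fixed for reproducibility): EE connectivity mask, EE
    weights, EI connectivity mask, EI weights, IE weights, excitatory
    thresholds, inhibitory thresholds, initial excitatory activity,
    initial inhibitory activity.

    * EE: each ordered non-self pair connected independently with
      probability ``p_ee_init``; weights uniform on (0, 1], then each row
      with incoming synapses is normalized to sum to one.
    * EI (inhibitory->excitatory): sparse with probability ``p_ei_init``,
      weights uniform on (0, 1].
    * IE (excitatory->inhibitory): dense, uniform draws, each row
      normalized so the input to an inhibitory unit sums to one.
    * Thresholds uniform on [0, t_exc_max] resp. [0, t_inh_max].
    * Initial activity: independent Bernoulli(target_rate) per unit; the
      arbitrary start is washed out downstream.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    ne, ni = params.n_exc, params.n_inh

    ee_mask = rng.random((ne, ne)) < params.p_ee_init
    np.fill_diagonal(ee_mask, False)
    w_ee = np.where(ee_mask, 1.0 - rng.random((ne, ne)), 0.0)  # uniform (0,1]
    row = w_ee.sum(axis=1, keepdims=True)
    np.divide(w_ee, row, out=w_ee, where=row > 0)

    ei_mask = rng.random((ne, ni)) < params.p_ei_init
    w_ei = np.where(ei_mask, 1.0 - rng.random((ne, ni)), 0.0)

    w_ie = 1.0 - rng.random((ni, ne))
    w_ie /= w_ie.sum(axis=1, keepdims=True)

    thr = ThresholdState(
        t_exc=rng.uniform(0.0, params.t_exc_max, ne),
        t_inh=rng.uniform(0.0, params.t_inh_max, ni),
    )
    tr = params.target_rate_vector()
    x0 = (rng.random(ne) < tr).astype(np.uint8)
    y0 = (rng.random(ni) < float(np.mean(tr))).astype(np.uint8)
    act = ActivityState(x=x0, y=y0,
                        x_prev=np.zeros(ne, np.uint8),
                        y_prev=np.zeros(ni, np.uint8))
    syn = SynapticState(w_ee, ee_mask, w_ei, ei_mask, w_ie)
    return syn, thr, act


def update_state(act: ActivityState, syn: SynapticState, thr: ThresholdState,
                 params: NetworkParams, rng: np.random.Generator,
                 ) -> ActivityState:
    """One step of the noisy binary threshold dynamics.

    x_i(t+1) = H( sum_j W_EE[i,j] x_j(t) - sum_k W_EI[i,k] y_k(t)
                  - T_E[i] + xi_E_i )
    y_k(t+1) = H( sum_j W_IE[k,j] x_j(t) - T_I[k] + xi_I_k )

    with H the Heaviside step under strict inequality (a unit at exactly
    threshold stays silent) and xi white Gaussian noise.  Noise is drawn
    excitatory first, then inhibitory.  The previous activity is kept in
    ``x_prev`` / ``y_prev`` for the timing-dependent plasticity rules.
    """
    x = act.x.astype(np.float64)
    y = act.y.astype(np.float64)
    noise_e = rng.normal(0.0, params.sigma_noise_exc, params.n_exc) \
        if params.sigma_noise_exc > 0 else 0.0
    noise_i = rng.normal(0.0, params.sigma_noise_inh, params.n_inh) \
        if params.sigma_noise_inh > 0 else 0.0
    drive_e = syn.w_ee @ x - syn.w_ei @ y - thr.t_exc + noise_e
    drive_i = syn.w_ie @ x - thr.t_inh + noise_i
    return ActivityState(
        x=(drive_e > 0.0).astype(np.uint8),
        y=(drive_i > 0.0).astype(np.uint8),
        x_prev=act.x,
        y_prev=act.y,
    )
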