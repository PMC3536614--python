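"""Model parameters for the self-organizing recurrent network (SORN).

All constants of the model live in :class:`NetworkParams`: population sizes,
initial connection probabilities, plasticity step sizes, the homeostatic
target rate, membrane-noise scales and the structural-plasticity settings.
Every field is overridable; validation happens eagerly at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace, asdict

import numpy as np

__all__ = ["NetworkParams", "ParameterError"]


class ParameterError(ValueError):
    """A model parameter is outside its admissible range."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"parameter '{field_name}': {message}")


@dataclass(frozen=True)
class NetworkParams:
    """Constants of the SORN model.

    Attributes
    ----------
    n_exc, n_inh
        Number of excitatory / inhibitory binary threshold units.
    p_ee_init
        Probability that an ordered non-self excitatory pair is connected
        at initialization.
    p_ei_init
        Probability that an inhibitory->excitatory synapse exists at
        initialization (these are the iSTDP-plastic connections).
    eta_stdp
        Additive STDP step applied to excitatory-to-excitatory weights.
    eta_istdp_pot, eta_istdp_dep
        iSTDP potentiation / depression steps for inhibitory->excitatory
        weights; potentiation must be the larger amount.
    eta_ip
        Intrinsic-plasticity threshold step.
    target_rate
        Homeostatic target firing probability per excitatory unit.  A
        scalar applies the same target to every unit; an array gives
        per-unit targets.
    sigma_noise_exc, sigma_noise_inh
        Standard deviations of the white Gaussian membrane noise.
    p_struct
        Per-step probability of one structural-plasticity creation attempt.
    w_new
        Weight assigned to a newly created excitatory synapse.
    w_ei_floor
        Minimum retained inhibitory->excitatory weight (prevents
        elimination of inhibitory synapses).
    t_exc_max, t_inh_max
        Upper bounds of the uniform threshold-initialization intervals.
    hist_exclusion
        Weights at or below this value are dropped from weight histograms,
        mimicking the detection limit of experimental spine imaging.
    seed
        Default RNG seed used when none is passed explicitly.
    """

    n_exc: int = 200
    n_inh: int = 40
    p_ee_init: float = 0.1
    p_ei_init: float = 0.2
    eta_stdp: float = 0.004
    eta_istdp_pot: float = 0.004
    eta_istdp_dep: float = 0.001
    eta_ip: float = 0.01
    target_rate: float | np.ndarray = 0.1
    # membrane noise is specified by its variance (0.05) in this model
    # family; the fields hold the standard deviation
    sigma_noise_exc: float = 0.05 ** 0.5
    sigma_noise_inh: float = 0.05 ** 0.5
    p_struct: float = 0.1
    w_new: float = 0.001
    w_ei_floor: float = 0.001
    t_exc_max: float = 0.5
    t_inh_max: float = 1.0
    hist_exclusion: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        for name in ("n_exc", "n_inh"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ParameterError(name, f"must be an integer >= 1, got {v!r}")
        for name in ("p_ee_init", "p_ei_init", "p_struct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(name, f"must lie in [0, 1], got {v!r}")
        for name in ("eta_stdp", "eta_istdp_pot", "eta_istdp_dep", "eta_ip",
                     "sigma_noise_exc", "sigma_noise_inh", "hist_exclusion"):
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(name, f"must be >= 0, got {v!r}")
        tr = np.asarray(self.target_rate, dtype=float)
        if tr.ndim not in (0, 1):
            raise ParameterError("target_rate", "must be scalar or 1-d")
        if tr.ndim == 1 and tr.size != self.n_exc:
            raise ParameterError(
                "target_rate", f"per-unit array must have length n_exc={self.n_exc}")
        if np.any(tr <= 0.0) or np.any(tr >= 1.0):
            raise ParameterError("target_rate", "entries must lie in (0, 1)")
        if self.eta_istdp_pot <= self.eta_istdp_dep:
            raise ParameterError(
                "eta_istdp_pot",
                "iSTDP potentiation must exceed depression "
                f"({self.eta_istdp_pot!r} <= {self.eta_istdp_dep!r})")
        if self.w_new <= 0:
            raise ParameterError("w_new", f"must be > 0, got {self.w_new!r}")
        if self.w_ei_floor <= 0:
            raise ParameterError("w_ei_floor", f"must be > 0, got {self.w_ei_floor!r}")

    # -- convenience -------------------------------------------------------

    def target_rate_vector(self) -> np.ndarray:
        """Per-unit target rates as a length-``n_exc`` array."""
        tr = np.asarray(self.target_rate, dtype=float)
        if tr.ndim == 0:
            return np.full(self.n_exc, float(tr))
        return tr.copy()

    def replace(self, **changes) -> "NetworkParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = asdict(self)
        tr = d["target_rate"]
        if isinstance(tr, np.ndarray):
            d["target_rate"] = tr.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(sorted(unknown)[0], "unknown parameter")
        d = dict(d)
        if isinstance(d.get("target_rate"), list):
            d["target_rate"] = np.asarray(d["target_rate"], dtype=float)
        return cls(**d)
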