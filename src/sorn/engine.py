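"""Simulation engine: step ordering, recording, events, persistence.

A :class:`Simulation` owns the network state, a single seeded random
generator, and the recording buffers.  Each step applies, in order:

1. the threshold dynamics (noise drawn excitatory first, inhibitory
   second);
2. STDP on the (t, t+1) excitatory activity pair;
3. iSTDP on the (t, t+1) inhibitory/excitatory pair;
4. synaptic normalization — so the incoming-sum-to-one invariant holds at
   every step boundary;
5. intrinsic plasticity;
6. structural plasticity last, so a newborn synapse survives at its birth
   weight into the next step (the structural draw is the third and final
   RNG consumption of the step).

Each mechanism can be switched off independently (ablation experiments).
Records store the spike raster, the EE connection-fraction series, periodic
weight snapshots, the synapse birth/death event log and, optionally, every
nonzero STDP weight change.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .params import NetworkParams
from .network import init_network, update_state, SynapticState
from . import plasticity as pl

__all__ = [
    "Ablations", "RecordSpec", "SynapseEvent", "StdpLog",
    "SimulationRecord", "Simulation", "run",
]

INITIAL = -1      # birth_step sentinel for synapses present at t=0
ALIVE = -1        # death_step sentinel for synapses alive at the end


@dataclass(frozen=True)
class Ablations:
    """Independent switches for the five plasticity mechanisms."""

    stdp: bool = True
    normalization: bool = True
    intrinsic: bool = True
    istdp: bool = True
    structural: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Ablations":
        return cls(**d)

    @classmethod
    def none(cls) -> "Ablations":
        return cls()

    @classmethod
    def all_off(cls) -> "Ablations":
        return cls(False, False, False, False, False)


@dataclass(frozen=True)
class RecordSpec:
    """What to record during a run.

    ``snapshot_every`` sets the weight-snapshot cadence in steps (None
    disables snapshots; the final step is always snapshotted when enabled).
    ``stdp_deltas`` additionally logs every nonzero STDP change with its
    pre-update weight, which the rich-get-richer analyses need.
    ``memory_budget_bytes`` guards against accidentally huge recordings.
    """

    raster: bool = True
    connection_fraction: bool = True
    snapshot_every: int | None = 200
    events: bool = True
    stdp_deltas: bool = False
    memory_budget_bytes: int = 2 << 30


@dataclass
class SynapseEvent:
    """Birth/death interval of one EE synapse.

    ``birth_step`` is ``INITIAL`` (-1) for synapses present at t=0 and the
    creation step otherwise; ``death_step`` is ``ALIVE`` (-1) while the
    synapse exists.  ``cause`` records the provenance of the interval:
    ``"initial"``, ``"structural_birth"`` or, once dead,
    ``"stdp_elimination"``.
    """

    post: int
    pre: int
    birth_step: int
    death_step: int
    cause: str


@dataclass
class StdpLog:
    """Flat arrays of every logged nonzero STDP change."""

    step: np.ndarray
    post: np.ndarray
    pre: np.ndarray
    delta: np.ndarray
    w_before: np.ndarray

    def __len__(self):
        return len(self.step)


@dataclass
class SimulationRecord:
    """Everything recorded from one run, plus its provenance."""

    params: NetworkParams
    seed: int
    ablations: Ablations
    n_steps: int
    raster_exc: np.ndarray | None          # (n_steps+1, n_exc) incl. t=0
    raster_inh: np.ndarray | None
    connection_fraction: np.ndarray | None  # (n_steps+1,)
    snapshots: dict[int, np.ndarray]        # step -> w_ee copy
    events: list[SynapseEvent]
    stdp_log: StdpLog | None
    final_syn: SynapticState
    final_t_exc: np.ndarray
    config_hash: str = ""

    def raster_all(self) -> np.ndarray:
        """Excitatory and inhibitory rasters side by side."""
        if self.raster_exc is None:
            raise ValueError("raster was not recorded (record flag 'raster')")
        return np.concatenate([self.raster_exc, self.raster_inh], axis=1)

    def snapshot_steps(self) -> list[int]:
        return sorted(self.snapshots)

    def events_dataframe(self):
        import pandas as pd
        rows = [(e.post, e.pre,
                 "initial" if e.birth_step == INITIAL else e.birth_step,
                 "NA" if e.death_step == ALIVE else e.death_step,
                 e.cause) for e in self.events]
        return pd.DataFrame(rows, columns=["post", "pre", "birth_step",
                                           "death_step", "cause"])

    def events_to_csv(self, path) -> None:
        self.events_dataframe().to_csv(path, index=False)

    # -- persistence -------------------------------------------------------

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w", track_order=False) as f:
            f.attrs["params"] = json.dumps(self.params.to_dict())
            f.attrs["seed"] = self.seed
            f.attrs["ablations"] = json.dumps(self.ablations.to_dict())
            f.attrs["n_steps"] = self.n_steps
            f.attrs["config_hash"] = self.config_hash
            if self.raster_exc is not None:
                f.create_dataset("raster_exc", data=self.raster_exc,
                                 compression="gzip")
                f.create_dataset("raster_inh", data=self.raster_inh,
                                 compression="gzip")
            if self.connection_fraction is not None:
                f.create_dataset("connection_fraction",
                                 data=self.connection_fraction)
            g = f.create_group("snapshots")
            for step, w in self.snapshots.items():
                g.create_dataset(str(step), data=w, compression="gzip")
            ev = f.create_group("events")
            ev.create_dataset("post", data=np.array(
                [e.post for e in self.events], dtype=np.int32))
            ev.create_dataset("pre", data=np.array(
                [e.pre for e in self.events], dtype=np.int32))
            ev.create_dataset("birth_step", data=np.array(
                [e.birth_step for e in self.events], dtype=np.int64))
            ev.create_dataset("death_step", data=np.array(
                [e.death_step for e in self.events], dtype=np.int64))
            causes = sorted({e.cause for e in self.events})
            ev.attrs["cause_codes"] = json.dumps(causes)
            code = {c: k for k, c in enumerate(causes)}
            ev.create_dataset("cause", data=np.array(
                [code[e.cause] for e in self.events], dtype=np.int8))
            fs = f.create_group("final")
            fs.create_dataset("w_ee", data=self.final_syn.w_ee,
                              compression="gzip")
            fs.create_dataset("w_ei", data=self.final_syn.w_ei)
            fs.create_dataset("w_ie", data=self.final_syn.w_ie)
            fs.create_dataset("t_exc", data=self.final_t_exc)
            if self.stdp_log is not None:
                g = f.create_group("stdp_log")
                for name in ("step", "post", "pre", "delta", "w_before"):
                    g.create_dataset(name, data=getattr(self.stdp_log, name),
                                     compression="gzip")

    @classmethod
    def from_hdf5(cls, path) -> "SimulationRecord":
        import h5py
        with h5py.File(path, "r") as f:
            params = NetworkParams.from_dict(json.loads(f.attrs["params"]))
            ablations = Ablations.from_dict(json.loads(f.attrs["ablations"]))
            raster_exc = f["raster_exc"][:] if "raster_exc" in f else None
            raster_inh = f["raster_inh"][:] if "raster_inh" in f else None
            cf = (f["connection_fraction"][:]
                  if "connection_fraction" in f else None)
            snapshots = {int(k): v[:] for k, v in f["snapshots"].items()}
            ev = f["events"]
            causes = json.loads(ev.attrs["cause_codes"])
            events = [SynapseEvent(int(p), int(q), int(b), int(d),
                                   causes[int(c)])
                      for p, q, b, d, c in zip(ev["post"][:], ev["pre"][:],
                                               ev["birth_step"][:],
                                               ev["death_step"][:],
                                               ev["cause"][:])]
            fs = f["final"]
            w_ee = fs["w_ee"][:]
            syn = SynapticState(w_ee, w_ee > 0, fs["w_ei"][:],
                                fs["w_ei"][:] > 0, fs["w_ie"][:])
            stdp_log = None
            if "stdp_log" in f:
                g = f["stdp_log"]
                stdp_log = StdpLog(g["step"][:], g["post"][:], g["pre"][:],
                                   g["delta"][:], g["w_before"][:])
            return cls(params=params, seed=int(f.attrs["seed"]),
                       ablations=ablations, n_steps=int(f.attrs["n_steps"]),
                       raster_exc=raster_exc, raster_inh=raster_inh,
                       connection_fraction=cf, snapshots=snapshots,
                       events=events, stdp_log=stdp_log, final_syn=syn,
                       final_t_exc=fs["t_exc"][:],
                       config_hash=str(f.attrs.get("config_hash", "")))


class Simulation:
    """A running SORN simulation with its recording buffers.

    The object is deep-copyable: ``sim.checkpoint()`` captures network
    state, RNG stream position and all buffers, so a resumed run
    reproduces the uninterrupted one bit-exactly.
    """

    def __init__(self, params: NetworkParams, seed: int | None = None,
                 ablations: Ablations | None = None,
                 record: RecordSpec | None = None):
        self.params = params
        self.seed = params.seed if seed is None else int(seed)
        self.ablations = ablations or Ablations()
        self.record_spec = record or RecordSpec()
        self.rng = np.random.default_rng(self.seed)
        self.syn, self.thr, self.act = init_network(params, rng=self.rng)
        self.t = 0
        self._target = params.target_rate_vector()
        # recording buffers
        self._raster_x: list[np.ndarray] = []
        self._raster_y: list[np.ndarray] = []
        self._cf: list[float] = []
        self._snapshots: dict[int, np.ndarray] = {}
        self._events: list[SynapseEvent] = []
        self._open: dict[tuple[int, int], SynapseEvent] = {}
        self._log_step: list[np.ndarray] = []
        self._log_post: list[np.ndarray] = []
        self._log_pre: list[np.ndarray] = []
        self._log_delta: list[np.ndarray] = []
        self._log_wb: list[np.ndarray] = []
        if self.record_spec.events:
            for i, j in zip(*np.nonzero(self.syn.ee_mask)):
                ev = SynapseEvent(int(i), int(j), INITIAL, ALIVE, "initial")
                self._events.append(ev)
                self._open[(int(i), int(j))] = ev
        self._record_step()

    # -- recording ---------------------------------------------------------

    def _record_step(self):
        rs = self.record_spec
        if rs.raster:
            self._raster_x.append(self.act.x.copy())
            self._raster_y.append(self.act.y.copy())
        if rs.connection_fraction:
            self._cf.append(self.syn.connection_fraction())
        if rs.snapshot_every and self.t % rs.snapshot_every == 0:
            self._snapshots[self.t] = self.syn.w_ee.copy()

    def _check_budget(self, n_steps: int):
        rs = self.record_spec
        ne, ni = self.params.n_exc, self.params.n_inh
        total = 0
        if rs.raster:
            total += (n_steps + 1) * (ne + ni)
        if rs.snapshot_every:
            total += (n_steps // rs.snapshot_every + 2) * ne * ne * 8
        if total > rs.memory_budget_bytes:
            raise MemoryError(
                f"recording ~{total / 2**20:.0f} MiB exceeds the "
                f"{rs.memory_budget_bytes / 2**20:.0f} MiB budget; raise "
                "RecordSpec.memory_budget_bytes or thin the recording")

    # -- dynamics ----------------------------------------------------------

    def step(self) -> None:
        """Advance the network by one time step (dynamics + plasticity)."""
        p, ab, syn = self.params, self.ablations, self.syn
        self.act = update_state(self.act, syn, self.thr, p, self.rng)
        self.t += 1
        if ab.stdp and p.eta_stdp > 0:
            rows, cols, dvals, w_before, killed = pl._stdp_apply(
                syn, self.act.x, self.act.x_prev, p.eta_stdp)
            if self.record_spec.stdp_deltas and rows.size:
                self._log_step.append(np.full(rows.size, self.t, np.int64))
                self._log_post.append(rows.astype(np.int32))
                self._log_pre.append(cols.astype(np.int32))
                self._log_delta.append(dvals)
                self._log_wb.append(w_before)
            if self.record_spec.events and killed is not None:
                for i, j in zip(rows[killed], cols[killed]):
                    ev = self._open.pop((int(i), int(j)), None)
                    if ev is not None:
                        ev.death_step = self.t
                        ev.cause = "stdp_elimination"
        if ab.istdp:
            pl.istdp_update(syn, self.act.y_prev, self.act.x,
                            p.eta_istdp_pot, p.eta_istdp_dep, p.w_ei_floor)
        if ab.normalization:
            pl.synaptic_normalization(syn)
        if ab.intrinsic:
            pl.intrinsic_plasticity(self.thr, self.act.x, p.eta_ip,
                                    self._target)
        if ab.structural:
            _, born = pl.structural_plasticity(syn, p.p_struct, p.w_new,
                                               self.rng)
            if born is not None and self.record_spec.events:
                ev = SynapseEvent(born[0], born[1], self.t, ALIVE,
                                  "structural_birth")
                self._events.append(ev)
                self._open[born] = ev
        self._record_step()

    def run(self, n_steps: int) -> "Simulation":
        if n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        self._check_budget(self.t + n_steps)
        for _ in range(n_steps):
            self.step()
        return self

    def checkpoint(self) -> "Simulation":
        """Deep copy capturing state, RNG position and buffers."""
        return copy.deepcopy(self)

    # -- record assembly ---------------------------------------------------

    def record(self, config_hash: str = "") -> SimulationRecord:
        rs = self.record_spec
        snapshots = dict(self._snapshots)
        if rs.snapshot_every and self.t not in snapshots:
            snapshots[self.t] = self.syn.w_ee.copy()
        stdp_log = None
        if rs.stdp_deltas:
            cat = (lambda lst, dt: np.concatenate(lst) if lst
                   else np.empty(0, dt))
            stdp_log = StdpLog(cat(self._log_step, np.int64),
                               cat(self._log_post, np.int32),
                               cat(self._log_pre, np.int32),
                               cat(self._log_delta, np.float64),
                               cat(self._log_wb, np.float64))
        return SimulationRecord(
            params=self.params, seed=self.seed, ablations=self.ablations,
            n_steps=self.t,
            raster_exc=np.array(self._raster_x, np.uint8) if rs.raster else None,
            raster_inh=np.array(self._raster_y, np.uint8) if rs.raster else None,
            connection_fraction=(np.array(self._cf)
                                 if rs.connection_fraction else None),
            snapshots=snapshots,
            events=[copy.copy(e) for e in self._events],
            stdp_log=stdp_log,
            final_syn=self.syn.copy(),
            final_t_exc=self.thr.t_exc.copy(),
            config_hash=config_hash,
        )


def run(params: NetworkParams, n_steps: int, seed: int | None = None,
        ablations: Ablations | None = None,
        record: RecordSpec | None = None) -> SimulationRecord:
    """Initialize, simulate ``n_steps`` steps and return the record."""
    sim = Simulation(params, seed=seed, ablations=ablations, record=record)
    sim.run(n_steps)
    return sim.record()
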