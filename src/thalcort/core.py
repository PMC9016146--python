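"""Kinetic-synapse neural mass primitives.

A population is a point ensemble with a lumped membrane potential ``V``.
Transmitter release is a sigmoid of the presynaptic voltage; each directed
pathway carries one two-state (open/closed) ligand-gated channel variable
``r`` driven by first-order binding kinetics; synaptic and leak currents are
ohmic.  The coupled system is

    [T]_u   = T_max / (1 + exp(-(V_u - theta_u)/sigma_u))
    dr/dt   = alpha * [T]_u * (1 - r) - beta * r
    I_syn   = C * g_max * r * (V_v - E_rev)
    kappa dV_v/dt = -sum_u I_syn - I_lk,   I_lk = g_lk * (V_v - E_lk)

with currents written outward-positive and subtracted, so AMPA input
(E_rev = 0 mV) depolarizes and GABA_A input (E_rev = -85/-75 mV)
hyperpolarizes a population resting near -65 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "AMPA",
    "GABA_A",
    "PopulationSpec",
    "ReceptorParams",
    "SynapseSpec",
    "NetworkState",
    "NetworkModel",
    "transmitter_concentration",
    "channel_open_fraction_rhs",
    "synaptic_current",
    "leak_current",
    "membrane_rhs",
    "network_rhs",
]

AMPA = "AMPA"
GABA_A = "GABA_A"

#: populations with their own membrane dynamics, in state-vector order
DYNAMIC_POPULATIONS = ("TCR", "TRN", "IN", "Py4", "SS4", "Py6", "B4", "B6")
#: exogenous drive nodes whose voltage is the stimulus signal
EXOGENOUS_POPULATIONS = ("Ret", "Asy", "Sy")
ALL_POPULATIONS = DYNAMIC_POPULATIONS + EXOGENOUS_POPULATIONS

#: presynaptic populations releasing onto AMPA receptors (excitatory)
EXCITATORY = frozenset({"TCR", "Py4", "SS4", "Py6", "Ret", "Asy"})
#: presynaptic populations releasing onto GABA_A receptors (inhibitory)
INHIBITORY = frozenset({"IN", "TRN", "B4", "B6", "Sy"})


@dataclass(frozen=True)
class PopulationSpec:
    """One neural mass: membrane constants and sigmoid release parameters.

    Exogenous nodes (Ret, Asy, Sy) have no leak/membrane dynamics --- their
    voltage *is* the stimulus --- so ``g_lk``/``E_lk`` are ``None`` for them.
    """

    name: str
    kind: str  # excitatory | inhibitory | exogenous
    V_rest: float  # mV
    theta_u: float  # sigmoid half-activation voltage, mV
    sigma_u: float  # sigmoid slope, mV
    g_lk: Optional[float] = None  # leak conductance, uS/cm^2
    E_lk: Optional[float] = None  # leak reversal potential, mV
    kappa: float = 1.0  # membrane capacitance (calibrated scale)
    T_max: float = 1.0  # maximal transmitter concentration, mM

    def __post_init__(self) -> None:
        if self.kind not in ("excitatory", "inhibitory", "exogenous"):
            raise ValueError(f"unknown population kind {self.kind!r}")
        if self.sigma_u <= 0:
            raise ValueError("sigma_u must be > 0")
        if self.T_max <= 0:
            raise ValueError("T_max must be > 0")
        if self.kind == "exogenous":
            if self.g_lk is not None or self.E_lk is not None:
                raise ValueError(
                    f"exogenous population {self.name} has no leak dynamics"
                )
        else:
            if self.g_lk is None or self.g_lk <= 0:
                raise ValueError(f"dynamic population {self.name} needs g_lk > 0")
            if self.E_lk is None:
                raise ValueError(f"dynamic population {self.name} needs E_lk")

    @property
    def is_dynamic(self) -> bool:
        return self.kind != "exogenous"


@dataclass(frozen=True)
class ReceptorParams:
    """Kinetic receptor constants for one synapse (AMPA or GABA_A)."""

    psi: str  # receptor kind
    alpha: float  # forward binding rate, (mM s)^-1
    beta: float  # unbinding rate, s^-1
    g_max: float  # maximal conductance, uS/cm^2
    E_rev: float  # reversal potential, mV

    def __post_init__(self) -> None:
        if self.psi not in (AMPA, GABA_A):
            raise ValueError(f"unknown receptor kind {self.psi!r}")
        if min(self.alpha, self.beta, self.g_max) <= 0:
            raise ValueError("alpha, beta, g_max must all be > 0")


@dataclass
class SynapseSpec:
    """Directed pathway pre -> post with connectivity fraction ``C``.

    ``C`` is the afferent synaptic-count fraction (table percentage / 100);
    ``C = 0`` encodes a lesioned or absent pathway.  ``r`` is the open-channel
    fraction state variable, kept in [0, 1] by the kinetics.
    """

    pre: str
    post: str
    receptor: ReceptorParams
    C: float
    r: float = 0.0

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError("connectivity C must be >= 0")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("open-channel fraction r must be in [0, 1]")


@dataclass
class NetworkState:
    """Flat state: dynamic-population voltages, synapse open fractions, time."""

    V: np.ndarray  # mV, one per dynamic population
    r: np.ndarray  # one per synapse
    t: float = 0.0

    def validate(self, net: "NetworkModel") -> None:
        if self.V.shape != (net.n_dynamic,) or self.r.shape != (net.n_synapses,):
            raise ValueError(
                f"state dimensions {self.V.shape}/{self.r.shape} do not match "
                f"network ({net.n_dynamic} populations, {net.n_synapses} synapses)"
            )
        if not (np.all(np.isfinite(self.V)) and np.all(np.isfinite(self.r))):
            raise ValueError("non-finite state")


class NetworkModel:
    """The wired network: populations, synapses and exogenous drive nodes."""

    def __init__(self, populations, synapses):
        self.populations = {p.name: p for p in populations}
        for name in ALL_POPULATIONS:
            if name not in self.populations:
                raise ValueError(f"missing population {name}")
        self.synapses = list(synapses)
        self.dynamic = [
            n for n in DYNAMIC_POPULATIONS if self.populations[n].is_dynamic
        ]
        self._pop_index = {n: i for i, n in enumerate(ALL_POPULATIONS)}
        self._dyn_index = {n: i for i, n in enumerate(self.dynamic)}
        self._edges = {}
        for i, s in enumerate(self.synapses):
            if (s.pre, s.post) in self._edges:
                raise ValueError(f"duplicate synapse {s.pre}->{s.post}")
            self._edges[(s.pre, s.post)] = i

    # -- structure queries ---------------------------------------------------

    @property
    def n_dynamic(self) -> int:
        return len(self.dynamic)

    @property
    def n_synapses(self) -> int:
        return len(self.synapses)

    def dyn_index(self, name: str) -> int:
        return self._dyn_index[name]

    def synapse(self, pre: str, post: str) -> SynapseSpec:
        try:
            return self.synapses[self._edges[(pre, post)]]
        except KeyError:
            raise KeyError(f"no synapse {pre}->{post} in network") from None

    def has_edge(self, pre: str, post: str) -> bool:
        return (pre, post) in self._edges

    def edges(self):
        return list(self._edges)

    def afferents(self, post: str):
        return [s for s in self.synapses if s.post == post]

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            list(self.populations.values()), [replace(s) for s in self.synapses]
        )

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "populations": [
                {
                    "name": p.name, "kind": p.kind, "V_rest": p.V_rest,
                    "theta_u": p.theta_u, "sigma_u": p.sigma_u,
                    "g_lk": p.g_lk, "E_lk": p.E_lk, "kappa": p.kappa,
                    "T_max": p.T_max,
                }
                for p in self.populations.values()
            ],
            "synapses": [
                {
                    "pre": s.pre, "post": s.post, "C": s.C,
                    "psi": s.receptor.psi, "alpha": s.receptor.alpha,
                    "beta": s.receptor.beta, "g_max": s.receptor.g_max,
                    "E_rev": s.receptor.E_rev,
                }
                for s in self.synapses
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        pops = [PopulationSpec(**p) for p in d["populations"]]
        syns = [
            SynapseSpec(
                pre=s["pre"], post=s["post"], C=s["C"],
                receptor=ReceptorParams(
                    psi=s["psi"], alpha=s["alpha"], beta=s["beta"],
                    g_max=s["g_max"], E_rev=s["E_rev"],
                ),
            )
            for s in d["synapses"]
        ]
        return cls(pops, syns)

    # -- packed arrays for the compiled integrator ---------------------------

    def packed(self):
        """Arrays in state-vector order for the compiled RHS/integrator."""
        nd = self.n_dynamic
        g_lk = np.array([self.populations[n].g_lk for n in self.dynamic])
        E_lk = np.array([self.populations[n].E_lk for n in self.dynamic])
        kappa = np.array([self.populations[n].kappa for n in self.dynamic])
        theta = np.array([self.populations[n].theta_u for n in ALL_POPULATIONS])
        sigma = np.array([self.populations[n].sigma_u for n in ALL_POPULATIONS])
        T_max = np.array([self.populations[n].T_max for n in ALL_POPULATIONS])
        pre = np.array([self._pop_index[s.pre] for s in self.synapses], dtype=np.int64)
        post = np.array([self._dyn_index[s.post] for s in self.synapses], dtype=np.int64)
        Cg = np.array([s.C * s.receptor.g_max for s in self.synapses])
        E_rev = np.array([s.receptor.E_rev for s in self.synapses])
        alpha = np.array([s.receptor.alpha for s in self.synapses])
        beta = np.array([s.receptor.beta for s in self.synapses])
        return dict(
            n_dynamic=nd, g_lk=g_lk, E_lk=E_lk, kappa=kappa, theta=theta,
            sigma=sigma, T_max=T_max, pre=pre, post=post, Cg=Cg, E_rev=E_rev,
            alpha=alpha, beta=beta,
        )

    def initial_state(self) -> NetworkState:
        V0 = np.array([self.populations[n].V_rest for n in self.dynamic])
        return NetworkState(V=V0, r=np.zeros(self.n_synapses), t=0.0)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def transmitter_concentration(V_u: float, spec: PopulationSpec) -> float:
    """Sigmoid transmitter release [T]_u as a function of presynaptic voltage.

    Returns ``T_max / (1 + exp(-(V_u - theta_u)/sigma_u))`` (mM), strictly
    increasing in ``V_u`` and bounded in (0, T_max); equals ``0.5 * T_max`` at
    the half-activation voltage.
    """
    if not np.all(np.isfinite(V_u)):
        raise ValueError("non-finite presynaptic voltage")
    z = -(np.asarray(V_u, dtype=float) - spec.theta_u) / spec.sigma_u
    out = spec.T_max / (1.0 + np.exp(np.clip(z, -700, 700)))
    return float(out) if np.isscalar(V_u) or np.ndim(V_u) == 0 else out


def channel_open_fraction_rhs(r: float, T: float, rec: ReceptorParams) -> float:
    """First-order binding kinetics dr/dt = alpha*T*(1-r) - beta*r (1/s)."""
    if np.any(np.asarray(T) < 0):
        raise ValueError("transmitter concentration must be >= 0")
    return rec.alpha * T * (1.0 - r) - rec.beta * r


def synaptic_current(syn: SynapseSpec, V_v: float) -> float:
    """Ohmic postsynaptic current I = C * g_max * r * (V_v - E_rev).

    Zero exactly at the reversal potential, for a lesioned pathway (C = 0),
    or with all channels closed (r = 0).
    """
    if not np.all(np.isfinite(V_v)):
        raise ValueError("non-finite postsynaptic voltage")
    return syn.C * syn.receptor.g_max * syn.r * (V_v - syn.receptor.E_rev)


def leak_current(V_v: float, spec: PopulationSpec) -> float:
    """Ensemble leak current g_lk * (V_v - E_lk); dynamic populations only."""
    if not spec.is_dynamic:
        raise ValueError(f"exogenous population {spec.name} has no leak current")
    return spec.g_lk * (V_v - spec.E_lk)


def membrane_rhs(v: str, state: NetworkState, net: NetworkModel) -> float:
    """dV/dt of one dynamic population: (-sum of synaptic currents - leak)/kappa.

    Currents are outward-positive as written, so both terms are subtracted;
    this makes AMPA input depolarizing and GABA_A input hyperpolarizing.
    """
    if v not in net.populations:
        raise KeyError(f"unknown population {v!r}")
    spec = net.populations[v]
    if not spec.is_dynamic:
        raise ValueError(f"exogenous population {v} has no membrane dynamics")
    V_v = state.V[net.dyn_index(v)]
    I_syn = 0.0
    for s in net.afferents(v):
        i = net._edges[(s.pre, s.post)]
        I_syn += s.C * s.receptor.g_max * state.r[i] * (V_v - s.receptor.E_rev)
    return (-I_syn - leak_current(V_v, spec)) / spec.kappa


def network_rhs(state: NetworkState, net: NetworkModel, drive: dict) -> np.ndarray:
    """Full state derivative [dV..., dr...] at time ``state.t``.

    ``drive`` maps exogenous node name -> voltage (mV) at the current time;
    exogenous nodes use the drive signal as their presynaptic voltage when
    computing transmitter release.
    """
    state.validate(net)
    for name in EXOGENOUS_POPULATIONS:
        if name not in drive:
            raise KeyError(f"drive missing exogenous node {name}")
    dV = np.array([membrane_rhs(v, state, net) for v in net.dynamic])
    dr = np.empty(net.n_synapses)
    for i, s in enumerate(net.synapses):
        pre_spec = net.populations[s.pre]
        V_u = drive[s.pre] if not pre_spec.is_dynamic else state.V[net.dyn_index(s.pre)]
        T = transmitter_concentration(V_u, pre_spec)
        dr[i] = channel_open_fraction_rhs(state.r[i], T, s.receptor)
    return np.concatenate([dV, dr])
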