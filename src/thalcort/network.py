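"""Network construction, connectivity derivation, lesions and state schemes."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from . import tables
from .config import DEFAULT_CONFIG, Edge, ModelConfig
from .core import (
    AMPA,
    GABA_A,
    ALL_POPULATIONS,
    DYNAMIC_POPULATIONS,
    EXCITATORY,
    INHIBITORY,
    NetworkModel,
    PopulationSpec,
    ReceptorParams,
    SynapseSpec,
)

__all__ = [
    "SynapseCountTable",
    "ConnectivityTable",
    "LesionSet",
    "StateScheme",
    "connectivity_from_counts",
    "build_base_network",
    "apply_lesion",
    "apply_scheme",
    "make_scheme",
    "LGN_ISOLATION_LESION",
    "INTERLAYER_LESION",
    "connectivity_matrix",
]

L4_POPULATIONS = ("Py4", "SS4", "B4")
L6_POPULATIONS = ("Py6", "B6")
CORTEX_POPULATIONS = L4_POPULATIONS + L6_POPULATIONS
LGN_POPULATIONS = ("TCR", "TRN", "IN")


# ---------------------------------------------------------------------------
# synapse-count table and the connectivity formula
# ---------------------------------------------------------------------------


@dataclass
class SynapseCountTable:
    """Absolute synapse counts, rows = postsynaptic, cols = presynaptic."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("synapse counts must be non-negative")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("row/column labels must be unique")

    @classmethod
    def printed(cls) -> "SynapseCountTable":
        return cls(tables.synapse_counts())


def connectivity_from_counts(
    table: SynapseCountTable, X, Y: str
) -> float:
    """Afferent connectivity percentage of pathway(s) X -> Y.

    ``C = 100 * M / N`` where ``N`` is the total synapse count of row ``Y``
    (all afferents of Y, all layers) and ``M`` the count(s) in column(s) ``X``
    of that row.  ``X`` may be one label or a sequence (counts are summed).
    """
    df = table.counts
    if Y not in df.index:
        raise KeyError(f"unknown postsynaptic label {Y!r}")
    cols = [X] if isinstance(X, str) else list(X)
    for c in cols:
        if c not in df.columns:
            raise KeyError(f"unknown presynaptic label {c!r}")
    N = float(df.loc[Y].sum())
    if N == 0:
        raise ValueError(f"row {Y!r} has zero total synapse count")
    M = float(df.loc[Y, cols].sum())
    return 100.0 * M / N


@dataclass
class ConnectivityTable:
    """Base-state percentages with a provenance flag per entry."""

    entries: Dict[Edge, float]
    provenance: Dict[Edge, str]

    @classmethod
    def printed(cls) -> "ConnectivityTable":
        entries, prov = {}, {}
        for post, row in tables.CONNECTIVITY_PCT.items():
            for pre, pct in row.items():
                entries[(pre, post)] = pct
                prov[(pre, post)] = tables.connectivity_provenance(pre, post)
        return cls(entries, prov)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.entries.values()):
            raise ValueError("connectivity percentages must be >= 0")
        boosted = self.entries.get(("B6", "Py6"))
        if boosted is not None and self.provenance.get(("B6", "Py6")) == "boosted":
            assert boosted == 10.0 * tables.B6_PY6_PREBOOST


# ---------------------------------------------------------------------------
# building the base network
# ---------------------------------------------------------------------------


def _receptor_for(pre: str, post: str, cfg: ModelConfig) -> ReceptorParams:
    if pre in EXCITATORY:
        psi, E_rev = AMPA, tables.E_REV_AMPA
        g = cfg.g_ampa_special.get((pre, post), cfg.g_ampa)
    elif pre in INHIBITORY:
        psi = GABA_A
        E_rev = tables.E_REV_GABA_RECURRENT if pre == post else tables.E_REV_GABA_INTER
        g = cfg.g_gaba
    else:
        raise ValueError(f"unknown presynaptic population {pre!r}")
    return ReceptorParams(psi=psi, alpha=tables.ALPHA[psi], beta=tables.BETA[psi],
                          g_max=g, E_rev=E_rev)


def build_base_network(config: ModelConfig | None = None) -> NetworkModel:
    """Wire the base-state network from the printed tables.

    Eight dynamic populations, three exogenous drive nodes, and exactly the
    nonzero printed pathways (C = percentage / 100).  Receptor kind follows
    the presynaptic population; the special AMPA conductances (Ret->TCR 300,
    Ret->IN and TCR->TRN 100) override the calibrated generic value.
    """
    cfg = config if config is not None else DEFAULT_CONFIG
    for key in ("theta_u", "sigma_u", "kappa", "g_ampa"):
        if getattr(cfg, key, None) is None:
            raise ValueError(f"missing required model parameter {key!r}")
    cfg.log_time_constants()
    pops = []
    for name, (kind, V_rest, g_lk, E_lk) in tables.MEMBRANE.items():
        pops.append(
            PopulationSpec(
                name=name, kind=kind, V_rest=V_rest, g_lk=g_lk, E_lk=E_lk,
                theta_u=cfg.theta_for(name), sigma_u=cfg.sigma_for(name),
                kappa=cfg.kappa, T_max=cfg.T_max,
            )
        )
    syns = []
    for post, row in tables.CONNECTIVITY_PCT.items():
        for pre, pct in row.items():
            if pct == 0:
                continue
            syns.append(
                SynapseSpec(pre=pre, post=post, C=pct / 100.0,
                            receptor=_receptor_for(pre, post, cfg))
            )
    return NetworkModel(pops, syns)


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------


@dataclass
class LesionSet:
    """Pathways to disconnect (C -> 0)."""

    edges: List[Edge] = field(default_factory=list)

    def __add__(self, other: "LesionSet") -> "LesionSet":
        return LesionSet(list(self.edges) + list(other.edges))


#: disconnect the LGN from cortex: all feedforward TCR->cortex and all
#: feedback Py6->LGN pathways (intra-LGN and all cortical wiring kept)
LGN_ISOLATION_LESION = LesionSet(
    [("TCR", p) for p in ("Py4", "SS4", "B4", "Py6", "B6")]
    + [("Py6", p) for p in ("TCR", "IN", "TRN")]
)

#: disconnect layer 4 from layer 6 (both directions, every existing pathway)
INTERLAYER_LESION = LesionSet(
    [(pre, post) for pre in L4_POPULATIONS for post in L6_POPULATIONS]
    + [(pre, post) for pre in L6_POPULATIONS for post in L4_POPULATIONS]
)


def apply_lesion(net: NetworkModel, lesions: LesionSet) -> NetworkModel:
    """Copy of ``net`` with C = 0 on the listed edges; all else untouched."""
    out = net.copy()
    for pre, post in lesions.edges:
        if not out.has_edge(pre, post):
            raise KeyError(f"cannot lesion missing pathway {pre}->{post}")
        out.synapse(pre, post).C = 0.0
    return out


# ---------------------------------------------------------------------------
# state schemes
# ---------------------------------------------------------------------------


@dataclass
class StateScheme:
    """Declarative multiplicative edits defining an experimental condition.

    ``connectivity_edits`` maps (pre, post) -> factor on C;
    ``conductance_edits`` maps (receptor kind, scope) -> factor on g_max,
    where scope is ``"network"`` or ``"cortex"`` (postsynaptic side in L4/L6).
    """

    name: str
    connectivity_edits: Dict[Edge, float] = field(default_factory=dict)
    conductance_edits: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.connectivity_edits.values()):
            raise ValueError("scheme factors must be > 0 (lesions use LesionSet)")


def make_scheme(name: str, cfg: ModelConfig | None = None) -> StateScheme:
    """Named scheme factory: base | theta | alpha | beta | scz.

    theta: Py4->Py6 and Py6->Py6 tripled.  alpha: the inhibitory L6->L4
    pathways B6->Py4 and B6->B4 reduced by 25%.  beta: calibrated factors
    raising TCR->L4 / Py4 recurrence / Py4->Py6 and lowering L6->L4
    inhibition and Py6->LGN-interneuron feedback.  scz: the beta edits plus
    conductance reductions (cortical AMPA x0.93, GABA_A x0.90) and the
    TCR->Py4 x0.95, TCR->SS4 x0.97 feedforward reductions.
    """
    cfg = cfg if cfg is not None else DEFAULT_CONFIG
    if name == "base":
        return StateScheme("base")
    if name == "theta":
        return StateScheme(
            "theta", {("Py4", "Py6"): 3.0, ("Py6", "Py6"): 3.0}
        )
    if name == "alpha":
        return StateScheme(
            "alpha", {("B6", "Py4"): 0.75, ("B6", "B4"): 0.75}
        )
    if name == "beta":
        return StateScheme("beta", dict(cfg.beta_factors))
    if name == "scz":
        edits = dict(cfg.beta_factors)  # scz composes on top of its control
        for edge, f in cfg.scz_c_factors.items():
            edits[edge] = edits.get(edge, 1.0) * f
        gaba_scope = "cortex" if cfg.scz_gaba_cortex_only else "network"
        return StateScheme(
            "scz",
            edits,
            {(AMPA, "cortex"): cfg.scz_ampa_factor,
             (GABA_A, gaba_scope): cfg.scz_gaba_factor},
        )
    raise ValueError(f"unknown scheme {name!r}")


def apply_scheme(net: NetworkModel, scheme: StateScheme) -> NetworkModel:
    """Copy of ``net`` with the scheme's multiplicative edits applied."""
    out = net.copy()
    for (pre, post), f in scheme.connectivity_edits.items():
        if not out.has_edge(pre, post):
            raise KeyError(f"scheme edits missing pathway {pre}->{post}")
        out.synapse(pre, post).C *= f
    for (psi, scope), f in scheme.conductance_edits.items():
        for s in out.synapses:
            if s.receptor.psi != psi:
                continue
            if scope == "cortex" and s.post not in CORTEX_POPULATIONS:
                continue
            s.receptor = replace(s.receptor, g_max=s.receptor.g_max * f)
    return out


def connectivity_matrix(net: NetworkModel) -> pd.DataFrame:
    """Effective connectivity percentages (post x pre), e.g. for CSV export."""
    df = pd.DataFrame(0.0, index=list(DYNAMIC_POPULATIONS),
                      columns=list(ALL_POPULATIONS))
    for s in net.synapses:
        df.loc[s.post, s.pre] = 100.0 * s.C
    return df
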