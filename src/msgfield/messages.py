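"""Messages, force fields, and entropy production.

A *message* is any entity — a secreted chemical, light, a mechanical
stimulus, or a cell-adhesion contact — that changes the state of the
system receiving it.  The force a message exerts on a receiver decays
exponentially with the sender-receiver distance,

    G(d) = exp(-beta * d),

except for contact-borne messages (adhesion molecules, touch), whose
force is 1 at distance zero and 0 at any positive distance.  Receptor
activation requires the force to reach a per-message threshold, and a
pair contributes only if the sender expresses the message's ligand and
the receiver its receptor.

Message flow J is the amount of message passing through a unit area per
unit time, J = (1/A) dn/dt.  The entropy generated by messages flowing
down their force field is sigma = sum_i G_i * J_i, the package's measure
of how strongly a configuration drives irreversible state change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Modality",
    "MessageSpec",
    "MessageFlow",
    "ForceField",
    "EntropyReport",
    "ConfigurationError",
    "force_at_distance",
    "diffusion_flow",
    "coupling_matrix",
    "entropy_production",
    "entropy_report",
    "count_flows",
]


class ConfigurationError(ValueError):
    """A message or config block references something that does not exist."""


class Modality(str, Enum):
    CHEMICAL = "chemical"
    LIGHT = "light"
    MECHANICAL = "mechanical"
    CONTACT = "contact"


#: Modalities whose force follows the exponential distance decay.  Light and
#: mechanical messages are treated like chemical ones (the modality is kept
#: as metadata); only contact messages have the all-or-nothing distance rule.
_DIFFUSIVE = frozenset({Modality.CHEMICAL, Modality.LIGHT, Modality.MECHANICAL})


@dataclass(frozen=True)
class MessageSpec:
    """Parameters of one message species.

    Parameters
    ----------
    id : str
        Unique message identifier.
    modality : Modality or str
        chemical / light / mechanical (exponential decay) or contact
        (force 1 at distance 0, else 0).
    decay_rate : float
        beta, per unit length; spatial decay rate of the force.
    secretion_rate : float
        Amount emitted per unit time per secreting cell (used to build
        steady flows; the force law itself is amplitude-1).
    activation_threshold : float
        Minimum force required to activate the receptor; weaker forces
        contribute nothing.
    ligand, receptor : str or None
        Species the sender must express / the receiver must express.
    weight : float
        Pre-decay force amplitude, in (0, 1]; default 1.
    """

    id: str
    modality: Modality = Modality.CHEMICAL
    decay_rate: float = 0.0
    secretion_rate: float = 1.0
    activation_threshold: float = 0.0
    ligand: str | None = None
    receptor: str | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "modality", Modality(self.modality))
        for name in ("decay_rate", "secretion_rate", "activation_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError(f"weight must be in (0, 1], got {self.weight}")

    @property
    def is_contact(self) -> bool:
        return self.modality is Modality.CONTACT


@dataclass(frozen=True)
class MessageFlow:
    """One realized flow of a message from a source cell to a target cell."""

    message_id: str
    source: str
    target: str
    J: float  # amount per unit area per unit time

    def __post_init__(self) -> None:
        if self.J < 0:
            raise ValueError(f"flow J must be >= 0, got {self.J}")
        if self.source == self.target:
            raise ValueError(
                f"autocrine flow {self.source}->{self.target} must be "
                "constructed explicitly via coupling_matrix(autocrine=True)"
            )


def force_at_distance(spec: MessageSpec, d) -> float | np.ndarray:
    """Force exerted by a message at sender-receiver distance ``d``.

    Diffusive modalities return ``weight * exp(-beta d)``; the contact
    modality returns 1 at ``d == 0`` and 0 otherwise.  Scalar or array
    ``d`` accepted; negative distances are rejected.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError(f"distance must be >= 0, got {d}")
    if spec.is_contact:
        out = np.where(d_arr == 0.0, 1.0, 0.0)
    else:
        out = spec.weight * np.exp(-spec.decay_rate * d_arr)
    return float(out) if np.isscalar(d) or d_arr.ndim == 0 else out


def diffusion_flow(amounts: Sequence[float], times: Sequence[float], area: float = 1.0) -> np.ndarray:
    """Flow series J(t) = (1/A) dn/dt from a sampled amount series.

    The derivative uses the central stencil
    ``(n[i+1] - n[i-1]) / (t[i+1] - t[i-1])`` in the interior and
    one-sided differences at the two boundaries.
    """
    n = np.asarray(amounts, dtype=float)
    t = np.asarray(times, dtype=float)
    if n.shape != t.shape or n.ndim != 1:
        raise ValueError("amounts and times must be 1-D and of equal length")
    if n.size < 2:
        raise ValueError("need at least 2 time points to estimate a flow")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if area <= 0:
        raise ValueError(f"area must be > 0, got {area}")
    dn = np.empty_like(n)
    dn[0] = (n[1] - n[0]) / (t[1] - t[0])
    dn[-1] = (n[-1] - n[-2]) / (t[-1] - t[-2])
    if n.size > 2:
        dn[1:-1] = (n[2:] - n[:-2]) / (t[2:] - t[:-2])
    return dn / area


@dataclass
class ForceField:
    """Pairwise state-change forces, per message and aggregated.

    ``per_message[m][j, k]`` is the force message ``m`` exerts on receiver
    ``j`` from sender ``k``; the aggregate is the elementwise sum over
    messages.  Entries are zero wherever the receiver lacks the receptor,
    the sender lacks the ligand, or the force falls below the message's
    activation threshold.
    """

    cell_ids: tuple[str, ...]
    per_message: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        for mid, mat in self.per_message.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (n, n):
                raise ValueError(f"matrix for message {mid!r} has shape {mat.shape}, expected {(n, n)}")
            if np.any(mat < 0) or np.any(mat > 1):
                raise ValueError(f"per-message forces for {mid!r} must lie in [0, 1]")
            self.per_message[mid] = mat

    @property
    def aggregate(self) -> np.ndarray:
        n = len(self.cell_ids)
        total = np.zeros((n, n))
        for mat in self.per_message.values():
            total += mat
        return total

    def row_sums(self) -> np.ndarray:
        """Total force received by each cell (row sums of the aggregate)."""
        return self.aggregate.sum(axis=1)


def coupling_matrix(population, messages: Iterable[MessageSpec], autocrine: bool = False) -> ForceField:
    """Receptor-gated pairwise force matrices over a population's contacts.

    Entry (j, k) of each per-message matrix is ``force_at_distance`` at the
    contact-graph edge distance, kept only if sender ``k`` expresses the
    ligand, receiver ``j`` expresses the receptor, and the force reaches the
    activation threshold.  Pairs without a contact edge exert no force.
    ``autocrine=True`` additionally evaluates the diagonal at distance 0.
    """
    cells = population.cells
    ids = [c.id for c in cells]
    index = {cid: i for i, cid in enumerate(ids)}
    n = len(ids)
    known = population.species
    per_message: dict[str, np.ndarray] = {}
    for spec in messages:
        if known is not None:
            for role, sp in (("ligand", spec.ligand), ("receptor", spec.receptor)):
                if sp is not None and sp not in known:
                    raise ConfigurationError(
                        f"message {spec.id!r} references unknown {role} species {sp!r}"
                    )
        mat = np.zeros((n, n))
        has_ligand = np.array([spec.ligand is None or spec.ligand in c.ligands for c in cells])
        has_receptor = np.array([spec.receptor is None or spec.receptor in c.receptors for c in cells])
        for a, b, d in population.graph.edges_with_distance():
            for j, k in ((index[a], index[b]), (index[b], index[a])):
                if has_receptor[j] and has_ligand[k]:
                    f = force_at_distance(spec, d)
                    if f >= spec.activation_threshold and f > 0:
                        mat[j, k] = f
        if autocrine:
            f0 = force_at_distance(spec, 0.0)
            if f0 >= spec.activation_threshold:
                for j in range(n):
                    if has_receptor[j] and has_ligand[j]:
                        mat[j, j] = f0
        per_message[spec.id] = mat
    return ForceField(cell_ids=tuple(ids), per_message=per_message)


def entropy_production(forces, flows) -> float:
    """Entropy generation density sigma = sum_i G_i J_i.

    ``forces`` may be a vector of forces G_i, or a callable G(J) returning
    that vector when forces interfere through the full flow vector.
    """
    j = np.asarray(flows, dtype=float).ravel()
    if callable(forces):
        g = np.asarray(forces(j), dtype=float).ravel()
    else:
        g = np.asarray(forces, dtype=float).ravel()
    if g.shape != j.shape:
        raise ValueError(f"forces ({g.shape}) and flows ({j.shape}) must have equal length")
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(j))):
        raise ValueError("forces and flows must be finite")
    return float(g @ j)


@dataclass
class EntropyReport:
    """Entropy-generation time series, total and per message."""

    times: np.ndarray
    per_message_sigma: dict[str, np.ndarray]

    @property
    def sigma(self) -> np.ndarray:
        total = np.zeros_like(np.asarray(self.times, dtype=float))
        for series in self.per_message_sigma.values():
            total = total + np.asarray(series, dtype=float)
        return total


def entropy_report(
    times: Sequence[float],
    per_message_forces: Mapping[str, np.ndarray],
    per_message_flows: Mapping[str, np.ndarray] | Callable[[str, float], np.ndarray] | None = None,
) -> EntropyReport:
    """Entropy series for a set of message force matrices.

    ``per_message_flows`` maps message id to a flow matrix aligned with the
    force matrix (default: unit flow on every pair with nonzero force, i.e.
    a steady flow through unit area).  Forces are taken constant in time,
    so each per-message series is flat unless time-dependent flows are given
    via a callable ``flows(message_id, t) -> matrix``.
    """
    t = np.asarray(times, dtype=float)
    per_sigma: dict[str, np.ndarray] = {}
    for mid, g in per_message_forces.items():
        g = np.asarray(g, dtype=float)
        if callable(per_message_flows):
            series = np.array(
                [entropy_production(g.ravel(), np.asarray(per_message_flows(mid, tk)).ravel()) for tk in t]
            )
        else:
            if per_message_flows is None or mid not in per_message_flows:
                flow = (g > 0).astype(float)
            else:
                flow = np.asarray(per_message_flows[mid], dtype=float)
            series = np.full(t.shape, entropy_production(g.ravel(), flow.ravel()))
        per_sigma[mid] = series
    return EntropyReport(times=t, per_message_sigma=per_sigma)


def count_flows(graph, secretion: Mapping[str, Iterable[str]]) -> dict[str, int]:
    """Number of message streams each cell receives from its contacts.

    The count for cell ``c`` is the number of (neighbor, message) pairs
    where the neighbor is adjacent to ``c`` and secretes that message.
    With one message secreted by every cell this is the vertex degree.
    """
    nodes = set(graph.nodes())
    for cid in secretion:
        if cid not in nodes:
            raise ConfigurationError(f"secretion references cell {cid!r} absent from the graph")
    counts: dict[str, int] = {}
    for c in graph.nodes():
        counts[c] = sum(len(set(secretion.get(nbr, ()))) for nbr in graph.neighbors(c))
    return counts
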