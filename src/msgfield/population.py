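"""Spatial cell populations, contact graphs, proliferation, and symmetry breaking.

A population is a set of cells with positions, expression profiles
(ligands secreted, receptors displayed) and one phase oscillator per
cell.  Contacts are an undirected graph whose edges carry the
sender-receiver distance used by the message force law.  The module
implements the growth-driven route to symmetry breaking: synchronous
division doubles the population, compaction densifies contacts, the
received message force splits into a strong centre and a weaker
periphery, and the phase dynamics then settle into separate
synchronized sub-populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

from .messages import ForceField, MessageSpec
from .oscillators import TWO_PI, FrequencyModel, PhaseState, sample_frequencies

__all__ = [
    "Cell",
    "ContactGraph",
    "PopulationState",
    "make_fixture",
    "divide_all",
    "rebuild_contacts",
    "apply_compaction",
    "classify_inner_outer",
    "detect_sync_clusters",
    "register_placement_rule",
    "write_population_tsv",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("four_cell", "eight_cell", "ring", "global")


@dataclass(frozen=True)
class Cell:
    """One cell: identity, location, expression profile, state label."""

    id: str
    position: tuple[float, ...]
    ligands: frozenset[str] = frozenset()
    receptors: frozenset[str] = frozenset()
    state_label: str = "uniform"

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", tuple(float(x) for x in self.position))
        object.__setattr__(self, "ligands", frozenset(self.ligands))
        object.__setattr__(self, "receptors", frozenset(self.receptors))


class ContactGraph:
    """Undirected cell-contact graph with per-edge distances (thin networkx wrapper)."""

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple[str, str, float]] = ()):
        self._g = nx.Graph()
        self._g.add_nodes_from(nodes)
        for a, b, d in edges:
            self.add_edge(a, b, d)

    def add_edge(self, a: str, b: str, distance: float) -> None:
        if a == b:
            raise ValueError(f"self-edge on {a!r} not allowed")
        if distance < 0:
            raise ValueError(f"edge ({a!r}, {b!r}) has negative distance {distance}")
        self._g.add_edge(a, b, distance=float(distance))

    def nodes(self) -> list[str]:
        return list(self._g.nodes())

    def neighbors(self, node: str) -> list[str]:
        return list(self._g.neighbors(node))

    def degree(self, node: str) -> int:
        return self._g.degree(node)

    def edges_with_distance(self) -> Iterator[tuple[str, str, float]]:
        for a, b, data in self._g.edges(data=True):
            yield a, b, data["distance"]

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    # -- serialization: TSV edge list (source, target, distance) --------------

    def to_edgelist_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tdistance\n")
            for a, b, d in self.edges_with_distance():
                fh.write(f"{a}\t{b}\t{d:.12g}\n")

    @classmethod
    def from_edgelist_tsv(cls, path, nodes: Iterable[str] = ()) -> "ContactGraph":
        graph = cls(nodes=nodes)
        with open(path) as fh:
            header = fh.readline()
            if header.strip().split("\t") != ["source", "target", "distance"]:
                raise ValueError(f"unexpected edge-list header in {path}")
            for line in fh:
                a, b, d = line.rstrip("\n").split("\t")
                graph.add_edge(a, b, float(d))
        return graph

    def to_graphml(self, path) -> None:
        nx.write_graphml(self._g, path)


@dataclass
class PopulationState:
    """Cells + contact graph + aligned phase state (+ population-level models)."""

    cells: list[Cell]
    graph: ContactGraph
    phases: PhaseState
    freq_model: FrequencyModel = field(default_factory=FrequencyModel)
    contact_radius: float | None = None
    species: frozenset[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("cell ids must be unique")
        if set(self.graph.nodes()) != set(ids):
            raise ValueError("contact graph nodes must equal the cell id set")
        if len(self.phases) != len(self.cells):
            raise ValueError("need exactly one phase/frequency per cell")

    @property
    def cell_ids(self) -> list[str]:
        return [c.id for c in self.cells]

    def __len__(self) -> int:
        return len(self.cells)


# --- fixtures -----------------------------------------------------------------

_FIXTURE_SPECIES = frozenset({"msg", "msgR"})


def _fixture_cells(positions: Sequence[tuple[float, ...]]) -> list[Cell]:
    return [
        Cell(id=f"c{i}", position=p, ligands=frozenset({"msg"}), receptors=frozenset({"msgR"}))
        for i, p in enumerate(positions)
    ]


def make_fixture(name: str, n: int | None = None) -> PopulationState:
    """Canonical cluster geometries used throughout the package.

    four_cell
        Complete contact graph on 4 touching cells (every cell contacts
        the other three; with one shared autocrine message every cell
        receives 3 message streams).
    eight_cell
        Planar cluster of 6 outer cells on a hexagonal ring (each touching
        its 2 ring neighbours) plus 2 inner hub cells (touching each other
        and 3 outer cells each): outer degree 3, inner degree 4, so with a
        universal autocrine message the inner cells receive 4 streams and
        the outer cells 3.
    ring(n >= 3)
        n cells on a cycle.
    global(n >= 2)
        n cells, complete contact graph.

    All fixture edge distances are 0 (touching cells); positions are
    schematic metadata.  Every cell secretes ligand "msg" and displays
    receptor "msgR"; phases and frequencies start at 0.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")

    if name == "four_cell":
        positions = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)]
        cells = _fixture_cells(positions)
        edges = [(a.id, b.id, 0.0) for i, a in enumerate(cells) for b in cells[i + 1 :]]
        meta = {"fixture": name, "geometry": "2x2 touching square, complete contact graph"}
    elif name == "eight_cell":
        ring = [
            (np.cos(k * np.pi / 3.0), np.sin(k * np.pi / 3.0)) for k in range(6)
        ]  # hexagon, outer cells c0..c5
        positions = ring + [(-0.25, 0.0), (0.25, 0.0)]  # inner hubs c6, c7
        cells = _fixture_cells(positions)
        edges = [(f"c{k}", f"c{(k + 1) % 6}", 0.0) for k in range(6)]
        edges.append(("c6", "c7", 0.0))
        # each hub touches 3 outer cells on its side of the cluster
        edges += [("c6", "c2", 0.0), ("c6", "c3", 0.0), ("c6", "c4", 0.0)]
        edges += [("c7", "c5", 0.0), ("c7", "c0", 0.0), ("c7", "c1", 0.0)]
        meta = {
            "fixture": name,
            "geometry": "hexagonal ring of 6 outer cells + 2 central hubs; outer degree 3, inner degree 4",
        }
    elif name == "ring":
        if n is None or n < 3:
            raise ValueError(f"ring fixture needs n >= 3, got {n}")
        positions = [(np.cos(TWO_PI * k / n), np.sin(TWO_PI * k / n)) for k in range(n)]
        cells = _fixture_cells(positions)
        edges = [(f"c{k}", f"c{(k + 1) % n}", 0.0) for k in range(n)]
        meta = {"fixture": name, "geometry": f"cycle of {n} touching cells"}
    else:  # global
        if n is None or n < 2:
            raise ValueError(f"global fixture needs n >= 2, got {n}")
        positions = [(np.cos(TWO_PI * k / n), np.sin(TWO_PI * k / n)) for k in range(n)]
        cells = _fixture_cells(positions)
        edges = [(a.id, b.id, 0.0) for i, a in enumerate(cells) for b in cells[i + 1 :]]
        meta = {"fixture": name, "geometry": f"complete contact graph on {n} cells"}

    graph = ContactGraph(nodes=[c.id for c in cells], edges=edges)
    m = len(cells)
    return PopulationState(
        cells=cells,
        graph=graph,
        phases=PhaseState(theta=np.zeros(m), omega=np.zeros(m)),
        contact_radius=0.0,
        species=_FIXTURE_SPECIES,
        meta=meta,
    )


# --- geometry -----------------------------------------------------------------


def rebuild_contacts(cells: Sequence[Cell], contact_radius: float) -> ContactGraph:
    """Contacts from geometry: edge iff Euclidean distance <= contact_radius.

    The stored edge distance is the actual distance; coincident cells
    yield distance-0 edges (touching membranes).
    """
    if contact_radius < 0:
        raise ValueError(f"contact_radius must be >= 0, got {contact_radius}")
    graph = ContactGraph(nodes=[c.id for c in cells])
    pos = np.array([c.position for c in cells], dtype=float)
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if d <= contact_radius:
                graph.add_edge(cells[i].id, cells[j].id, d)
    return graph


# --- proliferation ------------------------------------------------------------

PlacementRule = Callable[[Cell, float, np.random.Generator], tuple[tuple[float, ...], tuple[float, ...]]]

_PLACEMENT_RULES: dict[str, PlacementRule] = {}


def register_placement_rule(name: str, rule: PlacementRule) -> None:
    _PLACEMENT_RULES[name] = rule


def _random_axis_rule(cell: Cell, delta: float, rng: np.random.Generator):
    """Daughters displaced +/- delta along a random unit vector from the parent."""
    dim = len(cell.position)
    u = rng.normal(size=dim)
    norm = np.linalg.norm(u)
    u = u / norm if norm > 0 else np.eye(dim)[0]
    p = np.asarray(cell.position)
    return tuple(p + delta * u), tuple(p - delta * u)


register_placement_rule("random_axis", _random_axis_rule)


def divide_all(
    pop: PopulationState,
    placement: str = "random_axis",
    seed: int | np.random.Generator = 0,
    phase_jitter: float = 0.0,
    freq_mode: str = "redraw",
    freq_jitter: float = 0.0,
    contact_radius: float | None = None,
) -> PopulationState:
    """Synchronous division: every cell is replaced by two daughters.

    Daughters inherit the parent's expression profile and state label,
    and its phase up to Gaussian jitter ``phase_jitter``.  Natural
    frequencies are redrawn from ``pop.freq_model`` (``freq_mode="redraw"``,
    the default: population growth re-disperses intrinsic rates) or
    inherited with Gaussian jitter ``freq_jitter``
    (``freq_mode="inherit"``).  Positions come from the registered
    placement rule and the contact graph is rebuilt from the new
    geometry.
    """
    if placement not in _PLACEMENT_RULES:
        raise ValueError(f"unknown placement rule {placement!r}")
    if freq_mode not in ("redraw", "inherit"):
        raise ValueError(f"freq_mode must be 'redraw' or 'inherit', got {freq_mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    radius = pop.contact_radius if contact_radius is None else contact_radius
    if radius is None:
        raise ValueError("no contact radius available to rebuild contacts")
    delta = radius / 2.0 if radius > 0 else 0.5
    rule = _PLACEMENT_RULES[placement]

    cells: list[Cell] = []
    theta: list[float] = []
    omega: list[float] = []
    for parent, th, om in zip(pop.cells, pop.phases.theta, pop.phases.omega):
        p0, p1 = rule(parent, delta, rng)
        for suffix, p in (("0", p0), ("1", p1)):
            cells.append(replace(parent, id=f"{parent.id}.{suffix}", position=p))
            theta.append(th + (phase_jitter * rng.normal() if phase_jitter > 0 else 0.0))
            if freq_mode == "redraw":
                omega.append(float(sample_frequencies(1, pop.freq_model, rng)[0]))
            else:
                omega.append(om + (freq_jitter * rng.normal() if freq_jitter > 0 else 0.0))

    return PopulationState(
        cells=cells,
        graph=rebuild_contacts(cells, radius),
        phases=PhaseState(theta=np.array(theta), omega=np.array(omega)),
        freq_model=pop.freq_model,
        contact_radius=radius,
        species=pop.species,
        meta=dict(pop.meta),
    )


# --- compaction and classification ---------------------------------------------


def apply_compaction(pop: PopulationState, adhesion: MessageSpec, compaction_factor: float = 1.4) -> PopulationState:
    """Compaction: adhesion tightens the cluster's contacts.

    The contact radius is scaled by ``compaction_factor``, the graph is
    rebuilt from the (unchanged) positions, and the adhesion message's
    ligand and receptor are added to every cell's expression profile, so
    the homophilic contact force appears on distance-0 edges.
    """
    if not adhesion.is_contact:
        raise ValueError(f"adhesion message {adhesion.id!r} must have contact modality")
    if pop.contact_radius is None:
        raise ValueError("population has no contact radius to compact")
    if compaction_factor < 1:
        raise ValueError(f"compaction_factor must be >= 1, got {compaction_factor}")
    new_radius = pop.contact_radius * compaction_factor
    extra = {s for s in (adhesion.ligand, adhesion.receptor) if s is not None}
    cells = [
        replace(
            c,
            ligands=c.ligands | ({adhesion.ligand} if adhesion.ligand else set()),
            receptors=c.receptors | ({adhesion.receptor} if adhesion.receptor else set()),
        )
        for c in pop.cells
    ]
    return PopulationState(
        cells=cells,
        graph=rebuild_contacts(cells, new_radius),
        phases=PhaseState(theta=pop.phases.theta.copy(), omega=pop.phases.omega.copy()),
        freq_model=pop.freq_model,
        contact_radius=new_radius,
        species=(pop.species | extra) if pop.species is not None else None,
        meta=dict(pop.meta),
    )


def classify_inner_outer(pop: PopulationState, fld: ForceField, tol: float = 1e-9) -> dict[str, str]:
    """Median split of received force: strong centre = inner, rest = outer.

    A cell is "inner" when its total received force (aggregate row sum)
    exceeds the population median by more than a relative tolerance; ties
    go to "outer", so a fully symmetric field labels every cell outer
    (no symmetry to break).
    """
    if len(pop) < 2:
        raise ValueError("classification needs at least 2 cells")
    if tuple(fld.cell_ids) != tuple(pop.cell_ids):
        raise ValueError("force field is not aligned with the population")
    rows = fld.row_sums()
    med = float(np.median(rows))
    cut = med + tol * max(1.0, abs(med))
    return {cid: ("inner" if r > cut else "outer") for cid, r in zip(pop.cell_ids, rows)}


def detect_sync_clusters(theta, coherence_threshold: float) -> tuple[np.ndarray, int]:
    """Partition oscillators into phase-coherent clusters.

    Builds a graph with an edge wherever the pairwise coherence
    cos(theta_j - theta_k) is >= ``coherence_threshold`` and returns the
    connected components, labelled 0, 1, ... in decreasing size order
    (ties broken by smallest member index).  ``theta`` may be a single
    phase vector or a (time x N) window, in which case the coherence is
    the time average of cos(theta_j - theta_k) — robust to two
    populations drifting past each other.
    """
    if not 0 < coherence_threshold <= 1:
        raise ValueError(f"coherence_threshold must be in (0, 1], got {coherence_threshold}")
    th = np.asarray(theta, dtype=float)
    if th.size == 0:
        raise ValueError("empty phase input")
    if th.ndim == 1:
        th = th[None, :]
    elif th.ndim != 2:
        raise ValueError("theta must be a vector or a (time x N) matrix")
    n = th.shape[1]
    # mean_t cos(a_j - a_k) = (C C^T + S S^T)/T with C=cos(th), S=sin(th)
    c = np.cos(th)
    s = np.sin(th)
    coh = (c.T @ c + s.T @ s) / th.shape[0]
    adj = coh >= coherence_threshold
    g = nx.from_numpy_array(adj)
    comps = sorted(nx.connected_components(g), key=lambda comp: (-len(comp), min(comp)))
    labels = np.empty(n, dtype=int)
    for label, comp in enumerate(comps):
        for idx in comp:
            labels[idx] = label
    return labels, len(comps)


# --- serialization -------------------------------------------------------------


def write_population_tsv(pop: PopulationState, prefix: str) -> tuple[str, str]:
    """Write (cells, edges) tables; returns the two file paths."""
    cells_path = f"{prefix}_cells.tsv"
    edges_path = f"{prefix}_edges.tsv"
    dim = len(pop.cells[0].position) if pop.cells else 2
    coord_cols = ["x", "y", "z"][:dim]
    with open(cells_path, "w") as fh:
        fh.write("id\t" + "\t".join(coord_cols) + "\tligands\treceptors\tstate_label\n")
        for c in pop.cells:
            coords = "\t".join(f"{x:.12g}" for x in c.position)
            fh.write(
                f"{c.id}\t{coords}\t{','.join(sorted(c.ligands))}\t"
                f"{','.join(sorted(c.receptors))}\t{c.state_label}\n"
            )
    pop.graph.to_edgelist_tsv(edges_path)
    return cells_path, edges_path
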