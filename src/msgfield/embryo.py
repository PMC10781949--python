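"""Early-embryo demonstration: symmetry generation and breaking in six stages.

The pipeline follows pre-implantation development from the fertilized
egg to the 16-cell stage as a six-stage discrete model

    S1 fertilized egg (1 cell) -> S2 (2) -> S3 (4) -> S4 (8)
    -> S5 compaction (8) -> S6 (16, trophectoderm + inner cell mass)

and couples it to the message force field.  From S1 to S4 every
blastomere secretes seven autocrine growth factors (EGF, IGF-I, GM-CSF,
BDNF, CSF-1, artemin, GDNF) and displays their six receptors, producing
a uniform field: every cell receives the same total force, cell-division
phases stay synchronized, and the population forms one coherent cluster.
Compaction (E-cadherin homophilic contact adhesion) densifies the
contact graph: the central cells gain contacts, the received force
becomes asymmetric between centre and periphery, and the median split of
received force labels the strong-field cells "inner" (prospective inner
cell mass) and the rest "outer" (prospective trophectoderm, which
carries the cdx2 transcript proxy).  The final division produces 16
cells in two lineages whose coupling is restructured (within-lineage
retained, cross-lineage attenuated); the two populations synchronize
separately, and the coherence detector reports two clusters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .messages import MessageSpec, Modality, coupling_matrix, entropy_report
from .oscillators import (
    TWO_PI,
    CouplingConfig,
    FrequencyModel,
    PhaseState,
    integrate,
    steady_state_R,
)
from .population import (
    Cell,
    ContactGraph,
    PopulationState,
    apply_compaction,
    classify_inner_outer,
    detect_sync_clusters,
    rebuild_contacts,
)
from .transitions import ModelMap, TransitionSystem, iterated_system

__all__ = [
    "Stage",
    "StageModel",
    "GrowthFactorNetwork",
    "StageRecord",
    "DemoReport",
    "EmbryoConfig",
    "EMBRYO_STAGES",
    "build_stage_model",
    "build_growth_factor_network",
    "growth_factor_messages",
    "ecadherin_message",
    "run_embryo_demo",
    "export_demo_transition_systems",
]


# --- stage model ---------------------------------------------------------------


@dataclass(frozen=True)
class Stage:
    id: str
    label: str
    cell_count: int
    event: str  # event leading out of this stage


@dataclass(frozen=True)
class StageModel:
    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        if len(self.stages) != 6:
            raise ValueError(f"the embryo model has exactly 6 stages, got {len(self.stages)}")
        counts = [s.cell_count for s in self.stages]
        if counts != [1, 2, 4, 8, 8, 16]:
            raise ValueError(f"stage cell counts must be (1, 2, 4, 8, 8, 16), got {counts}")
        allowed = {"division", "compaction", "division+differentiation", "none"}
        for s in self.stages:
            if s.event not in allowed:
                raise ValueError(f"unknown stage event {s.event!r}")


EMBRYO_STAGES = (
    Stage("S1", "fertilized egg", 1, "division"),
    Stage("S2", "2-cell", 2, "division"),
    Stage("S3", "4-cell", 4, "division"),
    Stage("S4", "8-cell", 8, "compaction"),
    Stage("S5", "compaction", 8, "division+differentiation"),
    Stage("S6", "16-cell", 16, "none"),
)


def build_stage_model() -> StageModel:
    return StageModel(stages=EMBRYO_STAGES)


# --- growth-factor network ------------------------------------------------------

_GF_PAIRING = {
    "EGF": "EGF receptor",
    "IGF-I": "IGF-I receptor",
    "GM-CSF": "GM-CSF receptor",
    "BDNF": "TrkB",
    "CSF-1": "CSF-1 receptor",
    "artemin": "GFRa3",
    "GDNF": "GFRa3",  # artemin and GDNF share the GFRa3 receptor
}


@dataclass(frozen=True)
class GrowthFactorNetwork:
    """Seven autocrine growth-factor ligands paired onto six receptors."""

    ligands: tuple[str, ...]
    receptors: tuple[str, ...]
    pairing: dict[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairing", dict(self.pairing))
        if len(self.ligands) != 7:
            raise ValueError(f"expected 7 ligands, got {len(self.ligands)}")
        if len(self.receptors) != 6:
            raise ValueError(f"expected 6 receptors, got {len(self.receptors)}")
        for lig in self.ligands:
            if lig not in self.pairing:
                raise ValueError(f"ligand {lig!r} has no receptor pairing")
            if self.pairing[lig] not in self.receptors:
                raise ValueError(f"ligand {lig!r} pairs to unknown receptor {self.pairing[lig]!r}")
        if set(self.pairing.values()) != set(self.receptors):
            raise ValueError("every receptor must receive at least one ligand")


def build_growth_factor_network() -> GrowthFactorNetwork:
    return GrowthFactorNetwork(
        ligands=tuple(_GF_PAIRING.keys()),
        receptors=tuple(dict.fromkeys(_GF_PAIRING.values())),
        pairing=dict(_GF_PAIRING),
    )


def growth_factor_messages(beta: float = 1.0, secretion_rate: float = 1.0, threshold: float = 0.0) -> list[MessageSpec]:
    """One diffusive chemical message per growth factor; shared default kinetics."""
    net = build_growth_factor_network()
    return [
        MessageSpec(
            id=lig,
            modality=Modality.CHEMICAL,
            decay_rate=beta,
            secretion_rate=secretion_rate,
            activation_threshold=threshold,
            ligand=lig,
            receptor=net.pairing[lig],
        )
        for lig in net.ligands
    ]


def ecadherin_message() -> MessageSpec:
    """Homophilic E-cadherin adhesion: a contact message, force 1 only when touching."""
    return MessageSpec(
        id="E-cadherin",
        modality=Modality.CONTACT,
        ligand="E-cadherin",
        receptor="E-cadherin",
    )


# --- configuration and report ----------------------------------------------------


@dataclass(frozen=True)
class EmbryoConfig:
    """Tunable parameters of the demonstration (defaults are the packaged run).

    omega0/gamma parameterize the blastomere frequency model; blastomeres
    are near-identical, so daughters inherit the parent frequency with
    Gaussian jitter ``freq_jitter`` per division rather than redrawing
    from the heavy-tailed Cauchy law (see docs/methods.md).  ``coupling``
    is the global binding strength of the uniform growth-factor field
    during S1-S5; at S6 cross-lineage coupling is attenuated by
    ``between_group_attenuation`` and the two lineages' centre
    frequencies split by ``lineage_frequency_split``.
    """

    omega0: float = 3.0
    gamma: float = 0.05
    coupling: float = 1.0
    between_group_attenuation: float = 0.1
    lineage_frequency_split: float = 0.6
    dt: float = 0.01
    stage_horizon: float = 100.0
    burn_in_fraction: float = 0.5
    compaction_factor: float = 1.4
    coherence_threshold: float = 0.9
    contact_radius: float = 1.05
    beta: float = 1.0
    phase_jitter: float = 0.5
    freq_jitter: float = 0.01
    sync_R_threshold: float = 0.9


@dataclass(frozen=True)
class StageRecord:
    stage_id: str
    label: str
    cell_count: int
    steady_R: float
    sigma: float
    cluster_count: int
    force_row_spread: float  # max - min of received-force row sums (0 = symmetric)


@dataclass
class DemoReport:
    """Stage-by-stage record of one demonstration run."""

    stages: list[StageRecord]
    inner_outer: dict[str, str]
    cdx2_proxy: tuple[str, ...]
    counts: dict[str, int]
    warnings: list[str]
    seed: int
    config: EmbryoConfig
    final_population: PopulationState | None = None
    final_theta_window: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.counts.get("n_stages") != len(self.stages):
            raise ValueError("n_stages must equal the number of stage records")
        outer = {cid for cid, lab in self.inner_outer.items() if lab == "outer"}
        if not set(self.cdx2_proxy) <= outer:
            raise ValueError("cdx2 proxy must be carried by outer-labelled cells only")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": [vars(s) for s in self.stages],
            "inner_outer": self.inner_outer,
            "cdx2_proxy": list(self.cdx2_proxy),
            "counts": self.counts,
            "warnings": self.warnings,
        }


# --- the pipeline ----------------------------------------------------------------


def _circle_positions(n: int, spacing: float = 1.0) -> list[tuple[float, float]]:
    """n cells equally spaced on a circle with nearest-neighbour distance ``spacing``."""
    if n == 1:
        return [(0.0, 0.0)]
    radius = spacing / (2.0 * math.sin(math.pi / n))
    return [(radius * math.cos(TWO_PI * k / n), radius * math.sin(TWO_PI * k / n)) for k in range(n)]


def _simulate_stage(
    pop: PopulationState,
    coupling,
    cfg: EmbryoConfig,
) -> tuple[PopulationState, float, np.ndarray]:
    """Run the phase dynamics for one stage; returns updated pop, steady R, phase window."""
    config = CouplingConfig(coupling=coupling, dt=cfg.dt)
    traj = integrate(pop.phases, config, cfg.stage_horizon, store_phases=True)
    start = int(len(traj.times) * cfg.burn_in_fraction)
    window = traj.theta_matrix[start:]
    new_phases = PhaseState(theta=traj.theta_matrix[-1].copy(), omega=pop.phases.omega.copy())
    pop = replace(pop, phases=new_phases)
    return pop, steady_state_R(traj, cfg.burn_in_fraction), window


def _divide(pop: PopulationState, cfg: EmbryoConfig, rng: np.random.Generator) -> PopulationState:
    """Synchronous division with inherited (jittered) phases and frequencies."""
    cells: list[Cell] = []
    theta: list[float] = []
    omega: list[float] = []
    for parent, th, om in zip(pop.cells, pop.phases.theta, pop.phases.omega):
        for suffix in ("0", "1"):
            cells.append(replace(parent, id=f"{parent.id}.{suffix}", position=parent.position))
            theta.append(th + cfg.phase_jitter * rng.normal())
            omega.append(om + cfg.freq_jitter * rng.normal())
    # re-pack the blastomeres: equal spacing on a circle, in cell order
    for i, p in enumerate(_circle_positions(len(cells))):
        cells[i] = replace(cells[i], position=p)
    return PopulationState(
        cells=cells,
        graph=rebuild_contacts(cells, pop.contact_radius),
        phases=PhaseState(theta=np.array(theta), omega=np.array(omega)),
        freq_model=pop.freq_model,
        contact_radius=pop.contact_radius,
        species=pop.species,
        meta=dict(pop.meta),
    )


def _field_stats(pop: PopulationState, messages) -> tuple[float, float]:
    """(entropy generation, row-sum spread) of the current message force field."""
    fld = coupling_matrix(pop, messages)
    rows = fld.row_sums()
    rep = entropy_report([0.0], fld.per_message)
    spread = float(rows.max() - rows.min()) if rows.size else 0.0
    return float(rep.sigma[0]), spread


def run_embryo_demo(config: EmbryoConfig | None = None, seed: int = 0) -> DemoReport:
    """Execute the six-stage demonstration; deterministic given ``seed``."""
    cfg = config or EmbryoConfig()
    rng = np.random.default_rng(seed)
    warn_list: list[str] = []
    if cfg.coupling < 2.0 * cfg.gamma:
        msg = (
            f"coupling {cfg.coupling} is below the synchronization threshold "
            f"2*gamma = {2 * cfg.gamma}: synchronized division is not expected"
        )
        warn_list.append(msg)
        warnings.warn(msg, stacklevel=2)

    net = build_growth_factor_network()
    gf_messages = growth_factor_messages(beta=cfg.beta)
    adhesion = ecadherin_message()
    species = frozenset(net.ligands) | frozenset(net.receptors)

    egg = Cell(
        id="z",
        position=(0.0, 0.0),
        ligands=frozenset(net.ligands),
        receptors=frozenset(net.receptors),
        state_label="uniform",
    )
    pop = PopulationState(
        cells=[egg],
        graph=ContactGraph(nodes=["z"]),
        phases=PhaseState(theta=np.array([rng.uniform(0, TWO_PI)]), omega=np.array([cfg.omega0])),
        freq_model=FrequencyModel(omega0=cfg.omega0, gamma=cfg.gamma),
        contact_radius=cfg.contact_radius,
        species=species,
    )

    records: list[StageRecord] = []

    def record_stage(stage: Stage, steady_r: float, window: np.ndarray, messages) -> None:
        sigma, spread = _field_stats(pop, messages)
        _, n_clusters = detect_sync_clusters(window, cfg.coherence_threshold)
        records.append(
            StageRecord(
                stage_id=stage.id,
                label=stage.label,
                cell_count=len(pop),
                steady_R=steady_r,
                sigma=sigma,
                cluster_count=n_clusters,
                force_row_spread=spread,
            )
        )

    # S1: single fertilized egg — trivially coherent
    record_stage(EMBRYO_STAGES[0], 1.0, pop.phases.theta[None, :], gf_messages)

    # S2-S4: synchronized divisions under the uniform autocrine field
    for stage in EMBRYO_STAGES[1:4]:
        pop = _divide(pop, cfg, rng)
        pop, steady_r, window = _simulate_stage(pop, cfg.coupling, cfg)
        record_stage(stage, steady_r, window, gf_messages)
        if steady_r < cfg.sync_R_threshold:
            warn_list.append(
                f"stage {stage.id}: steady R = {steady_r:.3f} below {cfg.sync_R_threshold}; "
                "division synchrony lost"
            )

    # S5: compaction — the two prospective inner cells move to the centre of
    # the mass (a distance-0, fully adherent contact), the rest to a unit
    # hexagon; adhesion densifies the contact graph and the field becomes
    # asymmetric between centre and periphery.
    inner_idx = sorted(rng.choice(len(pop), size=2, replace=False).tolist())
    hexagon = iter(_circle_positions(6, spacing=1.0))
    cells = []
    for i, c in enumerate(pop.cells):
        pos = (0.0, 0.0) if i in inner_idx else next(hexagon)
        cells.append(replace(c, position=pos))
    pop = PopulationState(
        cells=cells,
        graph=rebuild_contacts(cells, pop.contact_radius),
        phases=pop.phases,
        freq_model=pop.freq_model,
        contact_radius=pop.contact_radius,
        species=pop.species,
    )
    pop = apply_compaction(pop, adhesion, cfg.compaction_factor)
    all_messages = gf_messages + [adhesion]
    labels = classify_inner_outer(pop, coupling_matrix(pop, all_messages))
    pop = replace(pop, cells=[replace(c, state_label=labels[c.id]) for c in pop.cells])
    pop, steady_r, window = _simulate_stage(pop, cfg.coupling, cfg)
    record_stage(EMBRYO_STAGES[4], steady_r, window, all_messages)

    # S6: final division with differentiation — daughters inherit lineage
    # labels; lineage centre frequencies split; cross-lineage coupling is
    # attenuated; the cdx2 proxy marks the outer (trophectoderm) lineage.
    pop = _divide(pop, cfg, rng)
    is_inner = np.array([c.state_label == "inner" for c in pop.cells])
    omega = pop.phases.omega.copy()
    omega[is_inner] -= cfg.lineage_frequency_split / 2.0
    omega[~is_inner] += cfg.lineage_frequency_split / 2.0
    pop = replace(pop, phases=PhaseState(theta=pop.phases.theta.copy(), omega=omega))
    same = is_inner[:, None] == is_inner[None, :]
    block = np.where(same, cfg.coupling, cfg.coupling * cfg.between_group_attenuation)
    np.fill_diagonal(block, 0.0)
    pop, steady_r, window = _simulate_stage(pop, block, cfg)
    record_stage(EMBRYO_STAGES[5], steady_r, window, all_messages)

    inner_outer = {c.id: c.state_label for c in pop.cells}
    cdx2 = tuple(sorted(cid for cid, lab in inner_outer.items() if lab == "outer"))
    _, n_final = detect_sync_clusters(window, cfg.coherence_threshold)

    return DemoReport(
        stages=records,
        inner_outer=inner_outer,
        cdx2_proxy=cdx2,
        counts={
            "n_stages": len(records),
            "n_ligands": len(net.ligands),
            "n_receptors": len(net.receptors),
            "n_final_populations": n_final,
        },
        warnings=warn_list,
        seed=seed,
        config=cfg,
        final_population=pop,
        final_theta_window=window,
    )


# --- exporting the three transition systems --------------------------------------


def export_demo_transition_systems(report: DemoReport) -> dict:
    """The causal, surrogate, and message-field systems of one demo run.

    causal: stage types under the single "advance" factor (S6 absorbing).
    surrogate: feature-vector states (cell count, cluster count, inner-cell
    count per stage) under natural-number time actions 0..5 acting by
    iteration — a monoid action by construction.
    message: message-network states (contact-edge count, adhesion present)
    under the "field_change" action.
    Also returns ModelMaps from the causal system onto the other two; both
    pass check_functor.
    """
    if len(report.stages) != 6:
        raise ValueError(f"report is incomplete: {len(report.stages)} of 6 stage records")
    n_inner_final = sum(1 for lab in report.inner_outer.values() if lab == "inner")
    stage_ids = [s.stage_id for s in report.stages]

    causal_trans = {("advance", sid): stage_ids[min(i + 1, 5)] for i, sid in enumerate(stage_ids)}
    causal = TransitionSystem(
        role="causal", states=tuple(stage_ids), actions=("advance",), transition=causal_trans
    )

    inner_counts = [0, 0, 0, 0, 2 if n_inner_final else 0, n_inner_final]
    feature_states = [
        f"cells={rec.cell_count};clusters={rec.cluster_count};inner={inner_counts[i]}"
        for i, rec in enumerate(report.stages)
    ]
    if len(set(feature_states)) != 6:
        raise ValueError("stage feature vectors are not distinct; cannot build the surrogate system")
    one_step = {feature_states[i]: feature_states[min(i + 1, 5)] for i in range(6)}
    surrogate = iterated_system("surrogate", feature_states, one_step, max_t=5)

    msg_states = []
    for i, rec in enumerate(report.stages):
        adhesion = i >= 4
        msg_states.append(f"gf7;cells={rec.cell_count};adhesion={adhesion};sigma={rec.sigma:.6g}")
    if len(set(msg_states)) != 6:
        raise ValueError("stage message-network states are not distinct")
    message = TransitionSystem(
        role="message",
        states=tuple(msg_states),
        actions=("field_change",),
        transition={("field_change", s): msg_states[min(i + 1, 5)] for i, s in enumerate(msg_states)},
    )

    causal_to_surrogate = ModelMap(
        source=causal,
        target=surrogate,
        state_map=dict(zip(stage_ids, feature_states)),
        action_map={"advance": 1},
    )
    causal_to_message = ModelMap(
        source=causal,
        target=message,
        state_map=dict(zip(stage_ids, msg_states)),
        action_map={"advance": "field_change"},
    )
    return {
        "causal": causal,
        "surrogate": surrogate,
        "message": message,
        "maps": {
            "causal_to_surrogate": causal_to_surrogate,
            "causal_to_message": causal_to_message,
        },
    }
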