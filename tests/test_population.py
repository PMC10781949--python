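"""Fixtures, proliferation, contact rebuilding, compaction, classification, clustering."""

import math
from dataclasses import replace

import networkx as nx
import numpy as np
import pytest

from msgfield import (
    Cell,
    ContactGraph,
    MessageSpec,
    PhaseState,
    apply_compaction,
    classify_inner_outer,
    coupling_matrix,
    detect_sync_clusters,
    divide_all,
    make_fixture,
    rebuild_contacts,
)
from msgfield.population import PopulationState


def grid_cells(positions, ligands=("msg",), receptors=("msgR",)):
    return [
        Cell(id=f"g{i}", position=p, ligands=frozenset(ligands), receptors=frozenset(receptors))
        for i, p in enumerate(positions)
    ]


class TestFixtures:
    def test_four_cell_complete_graph(self, four_cell):
        assert len(four_cell) == 4
        assert four_cell.graph.number_of_edges() == 6
        assert all(four_cell.graph.degree(c) == 3 for c in four_cell.graph.nodes())

    def test_eight_cell_degree_pattern(self, eight_cell):
        degrees = sorted(eight_cell.graph.degree(c) for c in eight_cell.graph.nodes())
        assert degrees == [3, 3, 3, 3, 3, 3, 4, 4]
        # the two hubs touch each other
        hubs = [c for c in eight_cell.graph.nodes() if eight_cell.graph.degree(c) == 4]
        assert eight_cell.graph.has_edge(*hubs)

    def test_ring_needs_three_cells(self):
        with pytest.raises(ValueError, match="ring"):
            make_fixture("ring", n=1)
        ring = make_fixture("ring", n=5)
        assert ring.graph.number_of_edges() == 5

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            make_fixture("blob")


class TestDivideAll:
    def test_counts_double_and_expression_preserved(self, four_cell):
        children = divide_all(four_cell, seed=0)
        assert len(children) == 8
        assert all(c.ligands == {"msg"} and c.receptors == {"msgR"} for c in children.cells)
        grandchildren = divide_all(children, seed=1)
        assert len(grandchildren) == 16

    def test_zero_jitter_daughters_inherit_phase(self, four_cell):
        pop = replace(four_cell, phases=PhaseState(theta=np.array([0.1, 0.2, 0.3, 0.4]), omega=np.zeros(4)))
        children = divide_all(pop, seed=0, phase_jitter=0.0, freq_mode="inherit")
        assert np.allclose(np.sort(children.phases.theta), np.repeat([0.1, 0.2, 0.3, 0.4], 2))

    def test_seeded_division_is_deterministic(self, four_cell):
        a = divide_all(four_cell, seed=7, phase_jitter=0.1)
        b = divide_all(four_cell, seed=7, phase_jitter=0.1)
        assert [c.position for c in a.cells] == [c.position for c in b.cells]
        assert np.array_equal(a.phases.omega, b.phases.omega)

    def test_redraw_mode_uses_population_frequency_model(self, four_cell):
        from msgfield import FrequencyModel

        pop = replace(four_cell, freq_model=FrequencyModel(omega0=5.0, gamma=0.0))
        children = divide_all(pop, seed=0, freq_mode="redraw")
        assert np.all(children.phases.omega == 5.0)


class TestRebuildContacts:
    def test_distant_cells_stay_disconnected(self):
        cells = grid_cells([(0.0, 0.0), (3.0, 0.0)])
        assert rebuild_contacts(cells, 1.0).number_of_edges() == 0

    def test_unit_grid_with_generous_radius_is_complete(self):
        cells = grid_cells([(0, 0), (1, 0), (0, 1), (1, 1)])
        g = rebuild_contacts(cells, 1.5)  # diagonal sqrt(2) < 1.5
        assert g.number_of_edges() == 6

    def test_zero_radius_connects_only_coincident_cells(self):
        cells = grid_cells([(0, 0), (0, 0), (1, 0)])
        g = rebuild_contacts(cells, 0.0)
        assert g.number_of_edges() == 1
        assert g.has_edge("g0", "g1")

    def test_symmetric_and_radius_monotone(self, rng):
        cells = grid_cells([tuple(p) for p in rng.uniform(0, 3, size=(12, 2))])
        small = rebuild_contacts(cells, 0.8)
        large = rebuild_contacts(cells, 1.6)
        small_edges = {frozenset((a, b)) for a, b, _ in small.edges_with_distance()}
        large_edges = {frozenset((a, b)) for a, b, _ in large.edges_with_distance()}
        assert small_edges <= large_edges
        for a, b, d in small.edges_with_distance():
            assert small.has_edge(b, a) and d >= 0


class TestApplyCompaction:
    @pytest.fixture
    def loose_cluster(self):
        cells = grid_cells([(0, 0), (1, 0), (0, 1), (1, 1), (2, 0), (2, 1), (0, 2), (1, 2)])
        return PopulationState(
            cells=cells,
            graph=rebuild_contacts(cells, 1.0),
            phases=PhaseState(theta=np.zeros(8), omega=np.zeros(8)),
            contact_radius=1.0,
            species=frozenset({"msg", "msgR"}),
        )

    def adhesion(self):
        return MessageSpec(id="adh", modality="contact", ligand="cadherin", receptor="cadherin")

    def test_edge_count_increases(self, loose_cluster):
        before = loose_cluster.graph.number_of_edges()
        after = apply_compaction(loose_cluster, self.adhesion(), compaction_factor=1.5)
        assert after.graph.number_of_edges() > before
        assert all("cadherin" in c.ligands and "cadherin" in c.receptors for c in after.cells)

    def test_factor_one_is_identity_on_the_graph(self, loose_cluster):
        after = apply_compaction(loose_cluster, self.adhesion(), compaction_factor=1.0)
        before_edges = {frozenset((a, b)) for a, b, _ in loose_cluster.graph.edges_with_distance()}
        after_edges = {frozenset((a, b)) for a, b, _ in after.graph.edges_with_distance()}
        assert before_edges == after_edges

    def test_adhesion_force_appears_only_on_touching_pairs(self):
        cells = grid_cells([(0, 0), (0, 0), (1, 0)])  # two coincident + one at distance 1
        pop = PopulationState(
            cells=cells,
            graph=rebuild_contacts(cells, 1.0),
            phases=PhaseState(theta=np.zeros(3), omega=np.zeros(3)),
            contact_radius=1.0,
            species=frozenset({"msg", "msgR"}),
        )
        compacted = apply_compaction(pop, self.adhesion(), compaction_factor=1.0)
        fld = coupling_matrix(compacted, [self.adhesion()])
        adh = fld.per_message["adh"]
        assert adh[0, 1] == adh[1, 0] == 1.0
        assert adh[0, 2] == adh[2, 0] == adh[1, 2] == adh[2, 1] == 0.0

    def test_non_contact_adhesion_rejected(self, loose_cluster):
        chem = MessageSpec(id="adh", modality="chemical", ligand="cadherin", receptor="cadherin")
        with pytest.raises(ValueError, match="contact"):
            apply_compaction(loose_cluster, chem)


class TestClassifyInnerOuter:
    def test_eight_cell_hubs_are_inner(self, eight_cell):
        msg = MessageSpec(id="auto", modality="contact", ligand="msg", receptor="msgR")
        fld = coupling_matrix(eight_cell, [msg])
        labels = classify_inner_outer(eight_cell, fld)
        inner = {c for c, lab in labels.items() if lab == "inner"}
        assert inner == {c for c in eight_cell.graph.nodes() if eight_cell.graph.degree(c) == 4}
        assert sum(1 for lab in labels.values() if lab == "outer") == 6

    def test_symmetric_four_cell_stays_undifferentiated(self, four_cell):
        msg = MessageSpec(id="auto", modality="contact", ligand="msg", receptor="msgR")
        fld = coupling_matrix(four_cell, [msg])
        labels = classify_inner_outer(four_cell, fld)
        assert set(labels.values()) == {"outer"}

    def test_scaling_the_field_does_not_change_labels(self, eight_cell):
        from msgfield import ForceField

        msg = MessageSpec(id="auto", modality="contact", ligand="msg", receptor="msgR")
        fld = coupling_matrix(eight_cell, [msg])
        scaled = ForceField(
            cell_ids=fld.cell_ids, per_message={k: 0.25 * v for k, v in fld.per_message.items()}
        )
        assert classify_inner_outer(eight_cell, fld) == classify_inner_outer(eight_cell, scaled)

    def test_single_cell_rejected(self):
        cells = grid_cells([(0, 0)])
        pop = PopulationState(
            cells=cells,
            graph=rebuild_contacts(cells, 1.0),
            phases=PhaseState(theta=np.zeros(1), omega=np.zeros(1)),
        )
        from msgfield import ForceField

        with pytest.raises(ValueError):
            classify_inner_outer(pop, ForceField(cell_ids=("g0",), per_message={}))


class TestDetectSyncClusters:
    def test_coherent_population_is_one_cluster(self):
        labels, n = detect_sync_clusters(np.full(9, 1.1), 0.9)
        assert n == 1 and set(labels) == {0}

    def test_antipodal_split_gives_two_equal_clusters(self):
        theta = np.array([0.0] * 5 + [np.pi] * 5)
        labels, n = detect_sync_clusters(theta, 0.9)
        assert n == 2
        assert set(labels[:5]) != set(labels[5:])
        assert (labels == 0).sum() == (labels == 1).sum() == 5

    def test_matches_brute_force_component_oracle(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 100)
        labels, n = detect_sync_clusters(theta, 0.999)
        g = nx.Graph()
        g.add_nodes_from(range(100))
        for j in range(100):
            for k in range(j + 1, 100):
                if math.cos(theta[j] - theta[k]) >= 0.999:
                    g.add_edge(j, k)
        assert n == nx.number_connected_components(g)
        # same partition, up to label names
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(g)):
            for v in comp:
                comp_of[v] = ci
        for j in range(100):
            for k in range(100):
                assert (labels[j] == labels[k]) == (comp_of[j] == comp_of[k])

    def test_permutation_equivariance(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 40)
        perm = rng.permutation(40)
        labels, n = detect_sync_clusters(theta, 0.95)
        plabels, pn = detect_sync_clusters(theta[perm], 0.95)
        assert pn == n
        for a in range(40):
            for b in range(40):
                assert (labels[perm[a]] == labels[perm[b]]) == (plabels[a] == plabels[b])

    def test_windowed_coherence_separates_drifting_groups(self):
        # two internally locked groups drifting past each other: a single
        # snapshot can look merged, the time average cannot
        t = np.linspace(0, 20, 400)[:, None]
        group_a = np.mod(1.0 * t + np.zeros(5), 2 * np.pi)
        group_b = np.mod(1.6 * t + np.pi / 8, 2 * np.pi) * np.ones((1, 5))
        window = np.hstack([np.repeat(group_a, 1, axis=1) * np.ones((1, 5)), group_b])
        _, n = detect_sync_clusters(window, 0.9)
        assert n == 2

    def test_empty_and_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_sync_clusters(np.array([]), 0.9)
        with pytest.raises(ValueError):
            detect_sync_clusters(np.zeros(3), 0.0)


class TestContactGraphIO:
    def test_edgelist_roundtrip(self, tmp_path, eight_cell):
        path = tmp_path / "edges.tsv"
        eight_cell.graph.to_edgelist_tsv(path)
        back = ContactGraph.from_edgelist_tsv(path, nodes=eight_cell.graph.nodes())
        orig = {frozenset((a, b)): d for a, b, d in eight_cell.graph.edges_with_distance()}
        got = {frozenset((a, b)): d for a, b, d in back.edges_with_distance()}
        assert orig == got

    def test_self_edges_rejected(self):
        g = ContactGraph(nodes=["a"])
        with pytest.raises(ValueError, match="self-edge"):
            g.add_edge("a", "a", 0.0)
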