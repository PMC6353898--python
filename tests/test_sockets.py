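"""Clique enumeration, socket classification and interface restriction."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ksdesign import (atomic_contacts, build_toy_complex, classify_socket,
                      enumerate_packing_cliques, identify_knob_sockets,
                      interface_filter, residue_contact_graph, topology_map)
from ksdesign.contacts import ContactGraph, ResidueRef
from ksdesign.structure import Structure


def _ref(chain, seq, aa="A", ss="H", number=None):
    number = seq + 1 if number is None else number
    return ResidueRef(chain_id=chain, number=number, icode="",
                      seq_index=seq, aa=aa, ss=ss)


def _graph(edges):
    g = nx.Graph()
    for a, b in edges:
        bonded = a.chain_id == b.chain_id and abs(a.seq_index - b.seq_index) == 1
        g.add_edge(a, b, support=1, bonded=bonded)
    return ContactGraph(graph=g)


def _helix_structure(refs_by_chain):
    """Skeleton Structure carrying only ss labels (for element checks)."""
    from ksdesign.structure import Residue
    chains = {}
    for chain_id, refs in refs_by_chain.items():
        chains[chain_id] = [
            Residue(chain_id=chain_id, number=r.number, icode="",
                    seq_index=r.seq_index, aa=r.aa, name3="ALA", atoms=[],
                    ss=r.ss)
            for r in sorted(refs, key=lambda r: r.seq_index)
        ]
    return Structure(chains=chains, source_id="skeleton")


class TestCliqueEnumeration:
    def test_k4_with_spaced_residues(self):
        refs = [_ref("A", s) for s in (0, 2, 4, 6)]  # no bonded pairs
        g = _graph(list(itertools.combinations(refs, 2)))
        c3, c4 = enumerate_packing_cliques(g)
        assert len(c3) == 4 and len(c4) == 1
        assert c4[0] == frozenset(refs)

    def test_empty_graph(self):
        c3, c4 = enumerate_packing_cliques(ContactGraph(graph=nx.Graph()))
        assert c3 == [] and c4 == []

    def test_contiguous_bonded_runs_discarded(self):
        refs = [_ref("A", s) for s in (0, 1, 2)]
        g = _graph(list(itertools.combinations(refs, 2)))
        c3, c4 = enumerate_packing_cliques(g)
        assert c3 == [] and c4 == []

    @pytest.mark.parametrize("seed", range(8))
    def test_random_graph_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 20))
        refs = [_ref("A", 2 * i) for i in range(n)]  # spacing 2: no bonded runs
        edges = [(refs[i], refs[j]) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.4]
        g = _graph(edges)
        c3, c4 = enumerate_packing_cliques(g)
        adj = {r: set(g.graph.neighbors(r)) for r in g.graph.nodes}
        brute3 = {frozenset(c) for c in itertools.combinations(adj, 3)
                  if all(b in adj[a] for a, b in itertools.combinations(c, 2))}
        brute4 = {frozenset(c) for c in itertools.combinations(adj, 4)
                  if all(b in adj[a] for a, b in itertools.combinations(c, 2))}
        assert set(c3) == brute3
        assert set(c4) == brute4

    def test_four_clique_closure(self, toy_complex):
        g = residue_contact_graph(atomic_contacts(toy_complex.structure))
        c3, c4 = enumerate_packing_cliques(g)
        triples = set(c3)
        for quad in c4:
            for triple in itertools.combinations(quad, 3):
                if not _is_run(triple):
                    assert frozenset(triple) in triples


def _is_run(residues):
    chains = {r.chain_id for r in residues}
    if len(chains) != 1:
        return False
    idx = sorted(r.seq_index for r in residues)
    return all(b - a == 1 for a, b in zip(idx, idx[1:]))


class TestClassifySocket:
    def test_helix_socket_roles_i_i1_i4(self):
        refs = [_ref("A", s) for s in (5, 6, 9)]
        st = _helix_structure({"A": [_ref("A", s) for s in range(12)]})
        socket = classify_socket(frozenset(refs), st)
        assert socket.ss_class == "helix"
        assert (socket.x.seq_index, socket.y.seq_index, socket.h.seq_index) == (5, 6, 9)
        assert socket.signature == (1, 3, 4)

    def test_cross_chain_socket_is_mixed_with_x_marks(self):
        ra = [_ref("A", 2), _ref("A", 4)]
        rb = [_ref("B", 0)]
        st = _helix_structure({"A": [_ref("A", s) for s in range(6)],
                               "B": [_ref("B", 0)]})
        socket = classify_socket(frozenset(ra + rb), st)
        assert socket.ss_class == "coil/mixed"
        assert "x" in socket.signature
        # X,Y must be the same-chain (finite-separation) pair
        assert {socket.x.chain_id, socket.y.chain_id} == {"A"}

    def test_smallest_separation_tie_goes_to_lower_index_pair(self):
        refs = [_ref("A", 0), _ref("A", 2), _ref("A", 4)]
        st = _helix_structure({"A": [_ref("A", s) for s in range(6)]})
        socket = classify_socket(frozenset(refs), st)
        assert (socket.x.seq_index, socket.y.seq_index) == (0, 2)

    def test_sheet_socket_needs_two_strands(self):
        strand_refs = ([_ref("A", s, ss="E") for s in range(0, 4)]
                       + [_ref("A", 4, ss="C")]
                       + [_ref("A", s, ss="E") for s in range(5, 9)])
        st = _helix_structure({"A": strand_refs})
        two_strand = frozenset([strand_refs[1], strand_refs[3], strand_refs[6]])
        assert classify_socket(two_strand, st).ss_class == "sheet"
        one_strand = frozenset([strand_refs[0], strand_refs[1], strand_refs[3]])
        assert classify_socket(one_strand, st).ss_class == "coil/mixed"

    def test_helix_fixture_sockets_have_local_separations(self, ideal_helix):
        g = residue_contact_graph(atomic_contacts(ideal_helix))
        c3, _ = enumerate_packing_cliques(g)
        seps = set()
        for clique in c3:
            socket = classify_socket(clique, ideal_helix)
            for s in socket.signature:
                seps.add(s)
        assert seps and all(isinstance(s, int) and 1 <= s <= 4 for s in seps)

    def test_canonical_helix_socket_present(self, ideal_helix):
        g = residue_contact_graph(atomic_contacts(ideal_helix))
        c3, _ = enumerate_packing_cliques(g)
        signatures = {classify_socket(c, ideal_helix).signature for c in c3
                      if classify_socket(c, ideal_helix).ss_class == "helix"}
        assert (1, 3, 4) in signatures  # the i, i+1, i+4 motif


class TestIdentifyKnobSockets:
    def test_toy_complex_yields_single_cross_chain_pair(self, toy_complex):
        st = toy_complex.structure
        g = residue_contact_graph(atomic_contacts(st))
        c3, c4 = enumerate_packing_cliques(g)
        pairs, free = identify_knob_sockets(c3, c4, st)
        cross = [p for p in pairs if p.knob.chain_id == "B"]
        assert len(cross) == 1
        pair = cross[0]
        assert sorted(r.number for r in pair.socket.residues) == \
            sorted(toy_complex.truth.socket_numbers[0])
        assert pair.socket.filled and not pair.ambiguous

    def test_isolated_helix_has_no_cross_chain_pairs(self, ideal_helix):
        g = residue_contact_graph(atomic_contacts(ideal_helix))
        c3, c4 = enumerate_packing_cliques(g)
        pairs, _ = identify_knob_sockets(c3, c4, ideal_helix)
        assert all(p.knob.chain_id == "A" for p in pairs)
        # one chain, one element: no eligible knobs at all
        assert pairs == []

    def test_filled_socket_count_bounded_by_four_cliques(self, toy_complex):
        st = toy_complex.structure
        g = residue_contact_graph(atomic_contacts(st))
        c3, c4 = enumerate_packing_cliques(g)
        pairs, free = identify_knob_sockets(c3, c4, st)
        assert len({p.socket.residue_set for p in pairs}) <= len(c4)
        universe = {s.residue_set for s in free} | {p.socket.residue_set for p in pairs}
        for p in pairs:
            assert p.socket.residue_set in universe


class TestInterfaceFilter:
    def _pipeline(self, toy):
        st = toy.structure
        g = residue_contact_graph(atomic_contacts(st))
        c3, c4 = enumerate_packing_cliques(g)
        return identify_knob_sockets(c3, c4, st)

    def test_forward_direction_keeps_constructed_pair(self, toy_complex):
        pairs, free = self._pipeline(toy_complex)
        interface = interface_filter(pairs, free, {"A"}, {"B"})
        assert len(interface.pairs) == 1
        assert interface.pairs[0].knob.chain_id == "B"

    def test_reverse_direction_is_empty(self, toy_complex):
        pairs, free = self._pipeline(toy_complex)
        interface = interface_filter(pairs, free, {"B"}, {"A"})
        assert interface.pairs == []

    def test_direction_partition_no_loss_no_duplication(self, toy_complex):
        pairs, free = self._pipeline(toy_complex)
        fwd = interface_filter(pairs, free, {"A"}, {"B"}).pairs
        rev = interface_filter(pairs, free, {"B"}, {"A"}).pairs
        cross = [p for p in pairs
                 if {p.knob.chain_id} | {r.chain_id for r in p.socket.residues}
                 == {"A", "B"}
                 and len({r.chain_id for r in p.socket.residues}) == 1]
        assert len(fwd) + len(rev) == len(cross)
        assert not (set(map(id, fwd)) & set(map(id, rev)))

    def test_overlapping_groups_error(self, toy_complex):
        pairs, free = self._pipeline(toy_complex)
        with pytest.raises(ValueError, match="overlap"):
            interface_filter(pairs, free, {"A"}, {"A", "B"})
        with pytest.raises(ValueError):
            interface_filter(pairs, free, set(), {"B"})

    def test_free_sockets_adjacent_to_filled_only(self, toy_complex):
        pairs, free = self._pipeline(toy_complex)
        interface = interface_filter(pairs, free, {"A"}, {"B"})
        kept = interface.pairs[0].socket.residue_set
        for s in interface.free_sockets:
            assert all(r.chain_id == "A" for r in s.residues)
            assert s.residue_set & kept


class TestTopologyMap:
    def test_single_filled_socket_row(self, toy_complex):
        pairs, free = TestInterfaceFilter()._pipeline(toy_complex)
        interface = interface_filter(pairs, free, {"A"}, {"B"})
        df = topology_map(interface)
        filled = df[df.status == "filled"]
        assert len(filled) == 1
        row = filled.iloc[0]
        assert row.knob_chain == "B"
        assert row.knob_aa == "W"
        assert sorted([row.res_x, row.res_y, row.res_h]) == \
            sorted(toy_complex.truth.socket_numbers[0])

    def test_rows_sorted_and_adjacency_mutual(self, toy_complex):
        pairs, free = TestInterfaceFilter()._pipeline(toy_complex)
        interface = interface_filter(pairs, free, {"A"}, {"B"})
        df = topology_map(interface)
        order = list(zip(df.chain, df.res_x, df.res_y, df.res_h))
        assert order == sorted(order)
        adj = interface.adjacency()
        for i, neigh in adj.items():
            for j in neigh:
                assert i in adj[j]

    def test_empty_interface_errors(self):
        from ksdesign.sockets import InterfaceMap
        empty = InterfaceMap(target_group=frozenset("A"),
                             partner_group=frozenset("B"))
        with pytest.raises(ValueError):
            topology_map(empty)
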