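"""Context-network channels, network distances and the GCN phylogeny."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pangcn.gcn import (
    ContextNetwork,
    GcnParams,
    build_gcn,
    fusion_edges,
    gcn_tree,
    neighbor_edges,
    network_distance,
    phylogenetic_profiles,
    profile_edges,
    strain_panel_evidence,
)
from pangcn.genomeio import GeneFeature, Genome
from pangcn.simulate import simulate_panel
from pangcn.trees import tree_splits

AAS = "ACDEFGHIKLMNPQRSTVWY"
CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def protein(rng, n=100):
    return "".join(AAS[i] for i in rng.integers(len(AAS), size=n))


def genome_from_proteins(gid, proteins):
    parts, feats, pos = [], [], 0
    for tag, prot in proteins:
        cds = "ATG" + "".join(CODON_OF[aa] for aa in prot) + "TAA"
        feats.append(GeneFeature(tag, "CDS", pos, pos + len(cds), "+"))
        parts.append(cds)
        pos += len(cds)
    return Genome(id=gid, sequence="".join(parts), features=feats)


@pytest.fixture(scope="module")
def planted_panel():
    """Strain with 6 genes; a panel of 4 genomes where genes g0,g1 co-occur
    (present in panel 0,1,2), g2 is everywhere, g3 nowhere, and g4,g5 are
    adjacent in every panel genome."""
    rng = np.random.default_rng(101)
    prots = {f"s_g{i}": protein(rng) for i in range(6)}
    strain = genome_from_proteins("s", sorted(prots.items()))
    panel = []
    for pi in range(4):
        members = []
        if pi < 3:
            members += [("p_a", prots["s_g0"]), ("p_b", prots["s_g1"])]
        members.append(("p_c", prots["s_g2"]))
        members += [("p_d", prots["s_g4"]), ("p_e", prots["s_g5"])]
        # spacer genes unrelated to the strain
        members += [(f"p_x{i}", protein(rng)) for i in range(4)]
        order = [members[i] for i in np.argsort([m[0] for m in members])]
        panel.append(genome_from_proteins(f"P{pi}", order))
    return strain, panel, prots


class TestProfiles:
    def test_row_sums_match_planted_presence(self, planted_panel):
        strain, panel, _ = planted_panel
        prof = phylogenetic_profiles(strain, panel)
        assert prof.loc["s_g0"].sum() == 3
        assert prof.loc["s_g2"].sum() == 4
        assert prof.loc["s_g3"].sum() == 0

    def test_planted_cooccurring_pair_linked(self, planted_panel):
        strain, panel, _ = planted_panel
        prof = phylogenetic_profiles(strain, panel)
        edges = profile_edges(prof, max_hamming=0)
        assert frozenset({"s_g0", "s_g1"}) in edges

    def test_uninformative_vectors_excluded(self, planted_panel):
        strain, panel, _ = planted_panel
        prof = phylogenetic_profiles(strain, panel)
        edges = profile_edges(prof, max_hamming=4)
        flat = set(itertools.chain.from_iterable(edges))
        assert "s_g2" not in flat and "s_g3" not in flat

    def test_complementary_vectors_not_linked(self):
        prof = pd.DataFrame(
            [[1, 1, 0, 0], [0, 0, 1, 1]], index=["a", "b"], columns=list("wxyz")
        )
        assert profile_edges(prof, max_hamming=3) == set()

    def test_mi_rule_links_identical_profiles(self):
        prof = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [1, 0, 1, 0]],
            index=["a", "b", "c"], columns=list("wxyz"),
        )
        edges = profile_edges(prof, rule="mi", min_mi=0.9)
        assert frozenset({"a", "b"}) in edges
        assert frozenset({"a", "c"}) not in edges


class TestNeighborEdges:
    def test_operon_pair_found_everywhere(self, planted_panel):
        strain, panel, _ = planted_panel
        edges = neighbor_edges(strain, panel, window=3, min_support=4)
        assert frozenset({"s_g4", "s_g5"}) in edges

    def test_support_counts_match_brute_force_scan(self, planted_panel):
        strain, panel, _ = planted_panel
        ev = strain_panel_evidence(strain, panel)
        # brute-force: recompute adjacency per panel genome from best hits
        for pi, pg in enumerate(panel):
            order = {f.locus_tag: i for i, f in enumerate(
                sorted(pg.cds_features(), key=lambda f: f.start))}
            n = len(order)
            from pangcn.orthology import best_hits

            hits = best_hits(strain, pg)
            expected = set()
            for ta, tb in itertools.combinations(sorted(hits), 2):
                d = abs(order[hits[ta].tag_b] - order[hits[tb].tag_b])
                d = min(d, n - d)
                if 0 < d <= 3:
                    expected.add(frozenset({ta, tb}))
            assert ev.neighbor_pairs[pi] == expected

    def test_distant_homologs_not_linked(self, planted_panel):
        strain, panel, _ = planted_panel
        edges = neighbor_edges(strain, panel, window=1, min_support=4)
        assert frozenset({"s_g0", "s_g2"}) not in edges


class TestFusionEdges:
    def _fusion_setup(self, overlap_aa):
        rng = np.random.default_rng(103)
        p1, p2 = protein(rng, 120), protein(rng, 120)
        strain = genome_from_proteins("s", [("s_g0", p1), ("s_g1", p2)])
        fused = p1 + p2[overlap_aa:] if overlap_aa >= 0 else p1 + p2
        panel = [genome_from_proteins("P0", [("p_fuse", fused),
                                             ("p_x", protein(rng, 90))])]
        return strain, panel

    def test_concatenated_fusion_linked(self):
        strain, panel = self._fusion_setup(0)
        edges = fusion_edges(strain, panel)
        assert frozenset({"s_g0", "s_g1"}) in edges

    def test_heavily_overlapping_windows_rejected(self):
        rng = np.random.default_rng(107)
        shared = protein(rng, 120)
        # both strain genes align to the same panel segment -> overlap 100%
        strain = genome_from_proteins("s", [("s_g0", shared), ("s_g1", shared)])
        panel = [genome_from_proteins("P0", [("p_one", shared)])]
        assert fusion_edges(strain, panel) == set()

    def test_no_multidomain_matches_empty(self, planted_panel):
        strain, panel, _ = planted_panel
        assert fusion_edges(strain, panel) == set()


class TestBuildGcn:
    def test_union_keeps_channel_labels(self, planted_panel):
        strain, panel, _ = planted_panel
        net = build_gcn(strain, panel)
        assert set(net.graph.nodes) == {f.locus_tag for f in strain.cds_features()}
        for _u, _v, data in net.graph.edges(data=True):
            assert data["channels"] <= {"profile", "neighbor", "fusion"}
            assert data["channels"]
        assert len(net.edges) <= sum(
            len(net.channel_edges(c)) for c in ("profile", "neighbor", "fusion")
        )

    def test_deterministic(self, planted_panel):
        strain, panel, _ = planted_panel
        e1 = build_gcn(strain, panel).edges
        e2 = build_gcn(strain, panel).edges
        assert e1 == e2


class TestNetworkDistance:
    @staticmethod
    def _net(gid, edges, nodes):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            g.add_edge(u, v, channels={"profile"})
        return ContextNetwork(strain_id=gid, graph=g)

    def test_self_distance_zero(self):
        net = self._net("a", [("x", "y"), ("y", "z")], "xyz")
        assert network_distance(net, net, {c: c for c in "xyz"}) == 0.0

    def test_disjoint_edges_distance_one(self):
        na = self._net("a", [("x", "y")], "xyzw")
        nb = self._net("b", [("z", "w")], "xyzw")
        assert network_distance(na, nb, {c: c for c in "xyzw"}) == 1.0

    def test_hand_computed_jaccard_on_six_nodes(self):
        # a: edges {12, 23, 45}; b (after translation): {12, 23, 56}
        na = self._net("a", [("a1", "a2"), ("a2", "a3"), ("a4", "a5")],
                       ["a1", "a2", "a3", "a4", "a5", "a6"])
        nb = self._net("b", [("b1", "b2"), ("b2", "b3"), ("b5", "b6")],
                       ["b1", "b2", "b3", "b4", "b5", "b6"])
        mapping = {f"a{i}": f"b{i}" for i in range(1, 7)}
        # translated a-edges {12,23,45}; union {12,23,45,56} = 4; inter = 2
        assert network_distance(na, nb, mapping) == pytest.approx(1 - 2 / 4)

    def test_unmapped_endpoints_penalize_unless_restricted(self):
        na = self._net("a", [("a1", "a2"), ("a3", "a9")], ["a1", "a2", "a3", "a9"])
        nb = self._net("b", [("b1", "b2")], ["b1", "b2", "b3"])
        mapping = {"a1": "b1", "a2": "b2", "a3": "b3"}
        assert network_distance(na, nb, mapping) == pytest.approx(0.5)
        assert network_distance(na, nb, mapping, restrict_to_shared=True) == 0.0

    def test_empty_map_rejected(self):
        net = self._net("a", [], "xy")
        with pytest.raises(ValueError):
            network_distance(net, net, {})

    def test_symmetry_on_simulated_strains(self, small_triplet):
        from pangcn.orthology import reciprocal_best_hits

        tri = small_triplet
        panel = simulate_panel(tri.ancestor, tri.params, n_panel=4, seed=9)
        nets = {s: build_gcn(tri.genomes[s], panel) for s in ("B", "C")}
        pairs = reciprocal_best_hits(tri.genomes["B"], tri.genomes["C"])
        fwd = {p.tag_a: p.tag_b for p in pairs}
        rev = {p.tag_b: p.tag_a for p in pairs}
        d1 = network_distance(nets["B"], nets["C"], fwd)
        d2 = network_distance(nets["C"], nets["B"], rev)
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestGcnTree:
    def test_two_strains_sharing_extra_edges_group_together(self, planted_panel):
        strain, panel, prots = planted_panel
        # four "strains": w,x carry all six genes; y,z lack the operon pair
        full = sorted(prots.items())
        reduced = [(t, p) for t, p in full if t not in ("s_g4", "s_g5")]
        strains = {
            "w": genome_from_proteins("w", full),
            "x": genome_from_proteins("x", full),
            "y": genome_from_proteins("y", reduced),
            "z": genome_from_proteins("z", reduced),
        }
        res = gcn_tree(strains, panel, n_bootstrap=5, seed=1)
        # the w,x | y,z bipartition canonicalizes to its anchor-free side
        assert frozenset({"y", "z"}) in tree_splits(res.tree)

    def test_triplet_with_outgroup_recovers_topology(self, small_triplet):
        tri = small_triplet
        panel = simulate_panel(tri.ancestor, tri.params, n_panel=6, seed=17)
        strains = dict(tri.genomes)
        strains["ancestor"] = tri.ancestor
        res = gcn_tree(strains, panel, n_bootstrap=20, seed=17)
        assert frozenset({"B", "C"}) in tree_splits(res.tree)
        assert res.supports[frozenset({"B", "C"})] > 70
        assert all(0 <= v <= 100 for v in res.supports.values())

    def test_fewer_than_three_strains_rejected(self, planted_panel):
        strain, panel, _ = planted_panel
        with pytest.raises(ValueError):
            gcn_tree({"only": strain, "two": strain}, panel)
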