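"""Genome-context networks and the context-network phylogeny.

For each strain, a graph over its genes is assembled from three evidence
channels computed against a reference panel of annotated genomes:

* ``profile`` — phylogenetic profiles: genes whose presence/absence vectors
  across the panel are (near-)identical are linked;
* ``neighbor`` — conserved gene neighborhood: genes whose panel homologs sit
  within a small circular window of each other in enough panel genomes;
* ``fusion`` — Rosetta-stone evidence: a single panel protein aligning to
  both genes on essentially non-overlapping segments.

Strains are then compared by translating one network's edges through an
ortholog map and taking 1 minus the edge Jaccard index; neighbor joining on
the resulting distance matrix gives the context-network phylogeny, with
bootstrap supports obtained by resampling the reference panel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .genomeio import Genome
from .orthology import (
    HomologyCriteria,
    _candidates,
    _kmer_index,
    align_proteins,
    proteome,
    reciprocal_best_hits,
)
from .trees import annotate_supports, neighbor_joining, tree_splits

__all__ = [
    "GcnParams",
    "ContextNetwork",
    "StrainEvidence",
    "phylogenetic_profiles",
    "profile_edges",
    "neighbor_edges",
    "fusion_edges",
    "build_gcn",
    "network_distance",
    "gcn_tree",
    "strain_panel_evidence",
]

Edge = frozenset  # frozenset of two locus tags


@dataclass(frozen=True)
class GcnParams:
    """Methods-gap decisions for the context network, all overridable."""

    profile_rule: str = "hamming"  # "hamming" | "mi"
    profile_max_hamming: int = 1
    profile_min_mi: float = 0.3
    neighbor_window: int = 3
    neighbor_min_support: int = 2
    fusion_max_overlap: float = 0.10
    #: when True, the network distance is computed only over node pairs
    #: mapped between the two strains; when False (default) edges lost with
    #: strain-specific genes count against the similarity, which is what
    #: carries the gene-content signal of genome decay.
    restrict_to_shared: bool = False


@dataclass
class ContextNetwork:
    strain_id: str
    graph: nx.Graph

    @property
    def edges(self) -> set[Edge]:
        return {frozenset(e) for e in self.graph.edges}

    def channel_edges(self, channel: str) -> set[Edge]:
        return {
            frozenset((u, v))
            for u, v, data in self.graph.edges(data=True)
            if channel in data["channels"]
        }


@dataclass
class StrainEvidence:
    """Per-panel-genome evidence for one strain, cached so the panel can be
    bootstrap-resampled without re-running any alignments."""

    strain_id: str
    genes: list[str]
    panel_ids: list[str]
    #: genes x panel presence matrix (0/1)
    presence: np.ndarray = field(repr=False)
    #: per panel genome: neighbor candidate pairs (window already applied)
    neighbor_pairs: list[set[Edge]] = field(repr=False)
    #: per panel genome: fusion pairs
    fusion_pairs: list[set[Edge]] = field(repr=False)


def _panel_gene_order(panel_genome: Genome) -> dict[str, int]:
    feats = sorted(panel_genome.cds_features(), key=lambda f: f.start)
    return {f.locus_tag: i for i, f in enumerate(feats)}


def strain_panel_evidence(
    strain: Genome,
    panel: list[Genome],
    criteria: HomologyCriteria | None = None,
    params: GcnParams | None = None,
    k: int = 5,
    min_shared_kmers: int = 2,
) -> StrainEvidence:
    """Run all strain-vs-panel homology searches once and cache the evidence."""
    criteria = criteria or HomologyCriteria()
    params = params or GcnParams()
    prot_s = proteome(strain)
    genes = sorted(prot_s)
    presence = np.zeros((len(genes), len(panel)), dtype=np.uint8)
    neighbor_pairs: list[set[Edge]] = []
    fusion_pairs: list[set[Edge]] = []
    for pi, pg in enumerate(panel):
        prot_p = proteome(pg)
        index = _kmer_index(prot_p, k)
        order = _panel_gene_order(pg)
        n_panel_genes = len(order)
        best: dict[str, tuple[float, float, str]] = {}
        by_panel_gene: dict[str, list[tuple[str, tuple[int, int]]]] = {}
        for gi, tag in enumerate(genes):
            q = prot_s[tag]
            for cand in _candidates(q, index, k, min_shared_kmers):
                r = align_proteins(q, prot_p[cand], criteria)
                shorter_cov = (
                    r.coverage_query if len(q) <= len(prot_p[cand]) else r.coverage_target
                )
                if (
                    r.score <= 0
                    or r.identity_percent < criteria.min_identity_percent
                    or shorter_cov < criteria.min_coverage
                ):
                    continue
                presence[gi, pi] = 1
                key = (r.score, r.identity_percent, cand)
                cur = best.get(tag)
                if cur is None or (key[0], key[1]) > (cur[0], cur[1]) or (
                    (key[0], key[1]) == (cur[0], cur[1]) and cand < cur[2]
                ):
                    best[tag] = key
                if r.target_span is not None:
                    by_panel_gene.setdefault(cand, []).append((tag, r.target_span))
        # neighbor channel: strain genes whose best-hit homologs are close
        # in this panel genome's circular gene order
        npairs: set[Edge] = set()
        hit_tags = sorted(best)
        for ta, tb in itertools.combinations(hit_tags, 2):
            ra, rb = order[best[ta][2]], order[best[tb][2]]
            dist = abs(ra - rb)
            if n_panel_genes > 0:
                dist = min(dist, n_panel_genes - dist)
            if 0 < dist <= params.neighbor_window:
                npairs.add(frozenset((ta, tb)))
        neighbor_pairs.append(npairs)
        # fusion channel: one panel protein covering two strain genes on
        # essentially disjoint segments
        fpairs: set[Edge] = set()
        for _panel_tag, hits in by_panel_gene.items():
            for (t1, s1), (t2, s2) in itertools.combinations(hits, 2):
                if t1 == t2:
                    continue
                overlap = max(0, min(s1[1], s2[1]) - max(s1[0], s2[0]))
                len1, len2 = s1[1] - s1[0], s2[1] - s2[0]
                if overlap <= params.fusion_max_overlap * min(len1, len2):
                    fpairs.add(frozenset((t1, t2)))
        fusion_pairs.append(fpairs)
    return StrainEvidence(
        strain_id=strain.id,
        genes=genes,
        panel_ids=[g.id for g in panel],
        presence=presence,
        neighbor_pairs=neighbor_pairs,
        fusion_pairs=fusion_pairs,
    )


# ---------------------------------------------------------------------------
# channels


def phylogenetic_profiles(
    strain: Genome,
    panel: list[Genome],
    criteria: HomologyCriteria | None = None,
) -> pd.DataFrame:
    """Binary gene x panel presence matrix for one strain."""
    ev = strain_panel_evidence(strain, panel, criteria)
    return pd.DataFrame(ev.presence, index=ev.genes, columns=ev.panel_ids)


def profile_edges(
    profile: pd.DataFrame,
    max_hamming: int = 1,
    rule: str = "hamming",
    min_mi: float = 0.3,
) -> set[Edge]:
    """Edges between genes with (near-)matching phylogenetic profiles.

    All-zero and all-one vectors are uninformative and excluded.  The default
    rule links profiles at Hamming distance <= ``max_hamming``; the mutual-
    information alternative links profiles with MI >= ``min_mi`` bits.
    """
    mat = profile.to_numpy(dtype=np.uint8)
    sums = mat.sum(axis=1)
    informative = (sums > 0) & (sums < mat.shape[1])
    genes = [g for g, keep in zip(profile.index, informative) if keep]
    sub = mat[informative]
    edges: set[Edge] = set()
    if len(genes) < 2:
        return edges
    if rule == "hamming":
        for i in range(len(genes)):
            diffs = (sub[i + 1 :] != sub[i]).sum(axis=1)
            for off in np.nonzero(diffs <= max_hamming)[0]:
                edges.add(frozenset((genes[i], genes[i + 1 + off])))
    elif rule == "mi":
        for i, j in itertools.combinations(range(len(genes)), 2):
            if _mutual_information(sub[i], sub[j]) >= min_mi:
                edges.add(frozenset((genes[i], genes[j])))
    else:
        raise ValueError(f"unknown profile rule {rule!r}")
    return edges


def _mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    mi = 0.0
    for xv in (0, 1):
        px = np.mean(x == xv)
        for yv in (0, 1):
            py = np.mean(y == yv)
            pxy = np.mean((x == xv) & (y == yv))
            if pxy > 0 and px > 0 and py > 0:
                mi += pxy * np.log2(pxy / (px * py))
    return float(mi)


def neighbor_edges(
    strain: Genome,
    panel: list[Genome],
    window: int = 3,
    min_support: int = 2,
    criteria: HomologyCriteria | None = None,
) -> set[Edge]:
    """Genes whose homologs are within ``window`` genes of each other
    (circular order) in at least ``min_support`` panel genomes."""
    params = GcnParams(neighbor_window=window, neighbor_min_support=min_support)
    ev = strain_panel_evidence(strain, panel, criteria, params)
    return _neighbor_from_evidence(ev, list(range(len(panel))), min_support)


def _neighbor_from_evidence(
    ev: StrainEvidence, panel_indices: list[int], min_support: int
) -> set[Edge]:
    support: dict[Edge, int] = {}
    for pi in panel_indices:
        for pair in ev.neighbor_pairs[pi]:
            support[pair] = support.get(pair, 0) + 1
    return {pair for pair, s in support.items() if s >= min_support}


def fusion_edges(
    strain: Genome,
    panel: list[Genome],
    criteria: HomologyCriteria | None = None,
    params: GcnParams | None = None,
) -> set[Edge]:
    """Rosetta-stone edges: a panel protein aligning to both genes on
    segments overlapping by at most the configured fraction."""
    ev = strain_panel_evidence(strain, panel, criteria, params)
    return set().union(*ev.fusion_pairs) if ev.fusion_pairs else set()


def _network_from_evidence(
    ev: StrainEvidence, panel_indices: list[int], params: GcnParams
) -> ContextNetwork:
    g = nx.Graph()
    g.add_nodes_from(ev.genes)
    cols = ev.presence[:, panel_indices]
    profile = pd.DataFrame(cols, index=ev.genes,
                           columns=[f"c{i}" for i in range(len(panel_indices))])
    channels = {
        "profile": profile_edges(
            profile, params.profile_max_hamming, params.profile_rule, params.profile_min_mi
        ),
        "neighbor": _neighbor_from_evidence(ev, panel_indices, params.neighbor_min_support),
        "fusion": set().union(*(ev.fusion_pairs[i] for i in panel_indices))
        if panel_indices
        else set(),
    }
    for name, edges in channels.items():
        for pair in edges:
            u, v = sorted(pair)
            if g.has_edge(u, v):
                g[u][v]["channels"].add(name)
            else:
                g.add_edge(u, v, channels={name})
    return ContextNetwork(strain_id=ev.strain_id, graph=g)


def build_gcn(
    strain: Genome,
    panel: list[Genome],
    params: GcnParams | None = None,
    criteria: HomologyCriteria | None = None,
) -> ContextNetwork:
    """Union of the three evidence channels, with channel labels kept."""
    params = params or GcnParams()
    ev = strain_panel_evidence(strain, panel, criteria, params)
    return _network_from_evidence(ev, list(range(len(panel))), params)


# ---------------------------------------------------------------------------
# distances and the tree


def network_distance(
    net_a: ContextNetwork,
    net_b: ContextNetwork,
    ortholog_map: dict[str, str],
    restrict_to_shared: bool = False,
) -> float:
    """1 minus the edge Jaccard index after translating ``net_a``'s edges
    into ``net_b``'s namespace through ``ortholog_map``.

    With ``restrict_to_shared`` both edge sets are first restricted to node
    pairs mapped between the strains; otherwise untranslatable edges (an
    endpoint with no ortholog) stay in the union and penalize similarity.
    Two empty edge sets give distance 0.
    """
    if not ortholog_map:
        raise ValueError("empty ortholog map; network distance undefined")
    edges_a = net_a.edges
    edges_b = net_b.edges
    translated: set[Edge] = set()
    untranslatable = 0
    for pair in edges_a:
        u, v = tuple(pair)
        if u in ortholog_map and v in ortholog_map:
            translated.add(frozenset((ortholog_map[u], ortholog_map[v])))
        elif not restrict_to_shared:
            untranslatable += 1
    if restrict_to_shared:
        image = set(ortholog_map.values())
        edges_b = {e for e in edges_b if all(x in image for x in e)}
    inter = len(translated & edges_b)
    union = len(translated | edges_b) + untranslatable
    if union == 0:
        return 0.0
    return 1.0 - inter / union


def _distance_matrix(
    networks: dict[str, ContextNetwork],
    maps: dict[tuple[str, str], dict[str, str]],
    restrict: bool,
) -> DistanceMatrix:
    ids = sorted(networks)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m = maps[(ids[i], ids[j])]
            d[i, j] = d[j, i] = network_distance(
                networks[ids[i]], networks[ids[j]], m, restrict
            )
    return DistanceMatrix(d, ids)


@dataclass
class GcnTreeResult:
    tree: TreeNode
    supports: dict[frozenset[str], float]
    distances: DistanceMatrix
    networks: dict[str, ContextNetwork]


def gcn_tree(
    strains: dict[str, Genome],
    panel: list[Genome],
    params: GcnParams | None = None,
    criteria: HomologyCriteria | None = None,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> GcnTreeResult:
    """Context-network phylogeny of >= 3 strains against a reference panel.

    Ortholog maps between strains come from reciprocal best hits.  Bootstrap
    replicates resample the panel genomes with replacement and rebuild
    networks, distances and the NJ tree from the cached per-panel evidence;
    supports are split frequencies in percent, written onto the main tree.
    """
    if len(strains) < 3:
        raise ValueError("need at least 3 strains")
    params = params or GcnParams()
    criteria = criteria or HomologyCriteria()
    proteomes = {sid: proteome(g) for sid, g in strains.items()}
    evidence = {
        sid: strain_panel_evidence(g, panel, criteria, params)
        for sid, g in sorted(strains.items())
    }
    maps: dict[tuple[str, str], dict[str, str]] = {}
    ids = sorted(strains)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            pairs = reciprocal_best_hits(proteomes[ids[i]], proteomes[ids[j]], criteria)
            maps[(ids[i], ids[j])] = {p.tag_a: p.tag_b for p in pairs}

    full = list(range(len(panel)))

    def networks_for(indices: list[int]) -> dict[str, ContextNetwork]:
        return {sid: _network_from_evidence(ev, indices, params) for sid, ev in evidence.items()}

    networks = networks_for(full)
    dm = _distance_matrix(networks, maps, params.restrict_to_shared)
    tree = neighbor_joining(dm)

    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 307]))
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_bootstrap):
        indices = [int(x) for x in rng.integers(len(panel), size=len(panel))]
        rep_dm = _distance_matrix(networks_for(indices), maps, params.restrict_to_shared)
        for split in tree_splits(neighbor_joining(rep_dm)):
            counts[split] = counts.get(split, 0) + 1
    supports = {s: 100.0 * c / n_bootstrap for s, c in counts.items()}
    annotate_supports(tree, supports)
    return GcnTreeResult(tree=tree, supports=supports, distances=dm, networks=networks)


def write_network_tsv(net: ContextNetwork, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("tag_a\ttag_b\tchannels\n")
        for u, v, data in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{','.join(sorted(data['channels']))}\n")
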