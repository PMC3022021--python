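"""Three-way pan-genome partition, ortholog variant classes and pathway
presence matrices.

The partition takes the three pairwise reciprocal-best-hit tables of a
strain triplet and resolves them into core gene triples (all three pairwise
maps mutually consistent), pairwise-shared genes and strain-specific genes;
an inconsistent "RBH triangle" is resolved conservatively by dropping its
weakest-scoring edge.  Ortholog pairs are classified by the kind of
divergence between their coding sequences: identical DNA, synonymous
substitutions only, amino-acid-changing substitutions, or INDEL.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .genomeio import CODON_TO_AA, Genome
from .molevo import codon_align
from .orthology import OrthologPair

__all__ = [
    "PanGenomePartition",
    "PathwayDefinition",
    "VARIANT_CLASSES",
    "three_way_partition",
    "classify_ortholog_pair",
    "pathway_presence",
    "lysine_pathway",
]

VARIANT_CLASSES = ("identical", "synonymous_only", "amino_acid_changing", "indel", "gain")

_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(n?\d+|-)$")


@dataclass
class PanGenomePartition:
    """Result of the three-way partition.

    ``core`` holds (tag_1, tag_2, tag_3) triples in input-genome order;
    ``pairwise_shared`` maps an unordered strain-index pair like (0, 1) to
    its list of gene pairs; ``strain_specific`` maps strain index to the
    set of unpaired tags, with ``specific_duplicated`` the subset that sits
    in a within-strain paralog family.
    """

    strain_ids: tuple[str, str, str]
    core: list[tuple[str, str, str]] = field(default_factory=list)
    pairwise_shared: dict[tuple[int, int], list[tuple[str, str]]] = field(default_factory=dict)
    strain_specific: dict[int, set[str]] = field(default_factory=dict)
    specific_duplicated: dict[int, set[str]] = field(default_factory=dict)
    dropped_edges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {"core": len(self.core)}
        for (i, j), pairs in sorted(self.pairwise_shared.items()):
            out[f"shared_{self.strain_ids[i]}_{self.strain_ids[j]}"] = len(pairs)
        for i, tags in sorted(self.strain_specific.items()):
            out[f"specific_{self.strain_ids[i]}"] = len(tags)
        return out

    def category_of(self) -> dict[tuple[str, str], str]:
        """(strain_id, tag) -> category, mirroring the simulator's truth labels."""
        out: dict[tuple[str, str], str] = {}
        for triple in self.core:
            for i, tag in enumerate(triple):
                out[(self.strain_ids[i], tag)] = "core"
        for (i, j), pairs in self.pairwise_shared.items():
            label = "shared_" + "".join(sorted((self.strain_ids[i], self.strain_ids[j])))
            for ta, tb in pairs:
                out[(self.strain_ids[i], ta)] = label
                out[(self.strain_ids[j], tb)] = label
        for i, tags in self.strain_specific.items():
            for tag in tags:
                out[(self.strain_ids[i], tag)] = "specific"
        return out


def three_way_partition(
    g1: Genome,
    g2: Genome,
    g3: Genome,
    rbh_12: list[OrthologPair],
    rbh_13: list[OrthologPair],
    rbh_23: list[OrthologPair],
    paralog_families_by_strain: list[list[set[str]]] | None = None,
) -> PanGenomePartition:
    """Partition three genomes into core / pairwise-shared / strain-specific.

    The RBH tables must come from the same homology criteria.  A core triple
    requires a <-> b, a <-> c and b <-> c to be mutually consistent; when two
    maps meet in a triangle whose third edge is absent or points elsewhere,
    the weakest edge (by alignment score) is dropped and the survivors are
    counted as pairwise-shared.
    """
    genomes = (g1, g2, g3)
    tags = [set(p.locus_tag for p in g.cds_features()) for g in genomes]
    tables = {(0, 1): rbh_12, (0, 2): rbh_13, (1, 2): rbh_23}
    for (i, j), table in tables.items():
        for p in table:
            if p.tag_a not in tags[i] or p.tag_b not in tags[j]:
                raise ValueError(
                    f"RBH pair ({p.tag_a}, {p.tag_b}) not found in genomes "
                    f"{genomes[i].id}/{genomes[j].id}"
                )
    # maps keyed on (strain_i, strain_j): tag_i -> (tag_j, score)
    fwd: dict[tuple[int, int], dict[str, tuple[str, float]]] = {}
    for (i, j), table in tables.items():
        fwd[(i, j)] = {p.tag_a: (p.tag_b, p.alignment.score) for p in table}
        fwd[(j, i)] = {p.tag_b: (p.tag_a, p.alignment.score) for p in table}

    dropped: set[frozenset[tuple[int, str]]] = set()
    dropped_log: list[tuple[str, str]] = []

    def alive(i: int, a: str, j: int) -> tuple[str, float] | None:
        hit = fwd.get((i, j), {}).get(a)
        if hit is None:
            return None
        if frozenset(((i, a), (j, hit[0]))) in dropped:
            return None
        return hit

    # resolve inconsistent triangles, centred on each strain in turn
    for i in (0, 1, 2):
        j, k = [x for x in range(3) if x != i]
        for a in sorted(tags[i]):
            hb = alive(i, a, j)
            hc = alive(i, a, k)
            if hb is None or hc is None:
                continue
            b, sb = hb
            c, sc = hc
            hbc = alive(j, b, k)
            if hbc is not None and hbc[0] == c:
                continue  # consistent triple
            edges = [(sb, (i, a), (j, b)), (sc, (i, a), (k, c))]
            if hbc is not None:
                edges.append((hbc[1], (j, b), (k, hbc[0])))
            weakest = min(edges, key=lambda e: (e[0], e[1][1], e[2][1]))
            dropped.add(frozenset((weakest[1], weakest[2])))
            dropped_log.append((weakest[1][1], weakest[2][1]))

    core: list[tuple[str, str, str]] = []
    in_core: set[tuple[int, str]] = set()
    for a in sorted(tags[0]):
        hb = alive(0, a, 1)
        hc = alive(0, a, 2)
        if hb is None or hc is None:
            continue
        hbc = alive(1, hb[0], 2)
        if hbc is not None and hbc[0] == hc[0]:
            core.append((a, hb[0], hc[0]))
            in_core.update(((0, a), (1, hb[0]), (2, hc[0])))

    pairwise: dict[tuple[int, int], list[tuple[str, str]]] = {k: [] for k in tables}
    paired: set[tuple[int, str]] = set(in_core)
    for (i, j), table in tables.items():
        for p in sorted(table, key=lambda p: p.tag_a):
            key_a, key_b = (i, p.tag_a), (j, p.tag_b)
            if key_a in in_core or key_b in in_core:
                continue
            if frozenset((key_a, key_b)) in dropped:
                continue
            pairwise[(i, j)].append((p.tag_a, p.tag_b))
            paired.update((key_a, key_b))

    specific: dict[int, set[str]] = {}
    specific_dup: dict[int, set[str]] = {}
    for i in range(3):
        specific[i] = {t for t in tags[i] if (i, t) not in paired}
        fams = paralog_families_by_strain[i] if paralog_families_by_strain else []
        in_family = set().union(*fams) if fams else set()
        specific_dup[i] = specific[i] & in_family
    return PanGenomePartition(
        strain_ids=tuple(g.id for g in genomes),
        core=core,
        pairwise_shared=pairwise,
        strain_specific=specific,
        specific_duplicated=specific_dup,
        dropped_edges=dropped_log,
    )


def classify_ortholog_pair(cds_a: str, cds_b: str) -> str:
    """Variant class of an ortholog pair from its two nucleotide CDSs:
    ``identical``, ``synonymous_only``, ``amino_acid_changing`` or ``indel``."""
    if cds_a == cds_b:
        return "identical"
    if len(cds_a) != len(cds_b) or len(cds_a) % 3 or len(cds_b) % 3:
        return "indel"
    aln = codon_align(cds_a, cds_b)
    if aln.had_gaps:
        return "indel"
    for ca, cb in aln.columns:
        if ca != cb and CODON_TO_AA[ca] != CODON_TO_AA[cb]:
            return "amino_acid_changing"
    return "synonymous_only"


# ---------------------------------------------------------------------------
# pathways


@dataclass(frozen=True)
class PathwayDefinition:
    """Ordered enzymatic steps, each a set of alternative EC numbers."""

    name: str
    step_names: tuple[str, ...]
    steps: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("pathway needs at least one step")
        for step in self.steps:
            for ec in step:
                if not _EC_RE.match(ec):
                    raise ValueError(f"malformed EC number {ec!r}")


def lysine_pathway() -> PathwayDefinition:
    """The packaged nine-step L-aspartate -> L-lysine pathway (lysC..lysA)."""
    text = resources.files("pangcn.data").joinpath("lysine_pathway.json").read_text()
    raw = json.loads(text)
    return PathwayDefinition(
        name=raw["name"],
        step_names=tuple(s["name"] for s in raw["steps"]),
        steps=tuple(frozenset(s["ec"]) for s in raw["steps"]),
    )


def pathway_presence(genomes: list[Genome], pathway: PathwayDefinition) -> pd.DataFrame:
    """Strain x step presence matrix plus a ``completeness`` column.

    A step is present in a strain iff any of its (non-pseudo) CDSs carries
    one of the step's alternative EC numbers.
    """
    rows = {}
    for g in genomes:
        ecs: set[str] = set()
        for f in g.cds_features(include_pseudo=False):
            ecs |= f.ec_numbers
        present = [bool(step & ecs) for step in pathway.steps]
        rows[g.id] = present + [sum(present)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(pathway.step_names) + ["completeness"]
    )
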