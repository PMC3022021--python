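"""Pairwise protein alignment, best hits, reciprocal-best-hit orthologs
and paralog families.

Local Smith–Waterman alignment with affine gaps under BLOSUM62 stands in
for BLASTP; candidate pairs for the all-vs-all searches are prefiltered by
shared amino-acid k-mers so genome-scale runs stay close to linear in gene
count.  An ortholog pair is a reciprocal best hit (BBH) under configurable
identity and shorter-sequence-coverage thresholds.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import networkx as nx
from Bio.Align import PairwiseAligner, substitution_matrices

from .genomeio import Genome, STOP_CODONS, extract_cds, translate

__all__ = [
    "AlignmentResult",
    "HomologyCriteria",
    "OrthologPair",
    "align_proteins",
    "best_hits",
    "reciprocal_best_hits",
    "paralog_families",
    "proteome",
    "longest_orf_protein",
    "pseudogene_protein",
    "write_ortholog_tsv",
]


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    identity_percent: float
    aligned_cols: int
    coverage_query: float
    coverage_target: float
    #: aligned interval on each protein, [start, end) — None when unaligned
    query_span: tuple[int, int] | None = None
    target_span: tuple[int, int] | None = None


@dataclass(frozen=True)
class HomologyCriteria:
    """BBH thresholds: identity over aligned columns and coverage of the
    shorter protein.  Defaults are a common conservative BBH standard."""

    min_identity_percent: float = 40.0
    min_coverage: float = 0.7
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity_percent <= 100:
            raise ValueError("min_identity_percent outside [0, 100]")
        if not 0 <= self.min_coverage <= 1:
            raise ValueError("min_coverage outside [0, 1]")


@dataclass(frozen=True)
class OrthologPair:
    tag_a: str
    tag_b: str
    alignment: AlignmentResult
    variant_class: str | None = None


_ALIGNER_CACHE: dict[tuple[str, float, float], PairwiseAligner] = {}


def _aligner(criteria: HomologyCriteria) -> PairwiseAligner:
    key = (criteria.matrix, criteria.gap_open, criteria.gap_extend)
    if key not in _ALIGNER_CACHE:
        al = PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = substitution_matrices.load(criteria.matrix)
        al.open_gap_score = -criteria.gap_open
        al.extend_gap_score = -criteria.gap_extend
        _ALIGNER_CACHE[key] = al
    return _ALIGNER_CACHE[key]


def align_proteins(a: str, b: str, criteria: HomologyCriteria | None = None) -> AlignmentResult:
    """Best local alignment of two proteins; identity is computed over all
    alignment columns (internal gaps included), coverage per protein is the
    aligned span over its full length."""
    criteria = criteria or HomologyCriteria()
    if not a or not b:
        raise ValueError("empty protein sequence")
    aligner = _aligner(criteria)
    alignments = aligner.align(a, b)
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentResult(0.0, 0.0, 0, 0.0, 0.0)
    aln = alignments[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    blocks_a, blocks_b = aln.aligned
    span_a = sum(e - s for s, e in blocks_a)
    span_b = sum(e - s for s, e in blocks_b)
    return AlignmentResult(
        score=float(aln.score),
        identity_percent=100.0 * counts.identities / cols if cols else 0.0,
        aligned_cols=cols,
        coverage_query=span_a / len(a),
        coverage_target=span_b / len(b),
        query_span=(int(blocks_a[0][0]), int(blocks_a[-1][1])) if len(blocks_a) else None,
        target_span=(int(blocks_b[0][0]), int(blocks_b[-1][1])) if len(blocks_b) else None,
    )


def _passes(
    a: str, b: str, r: AlignmentResult, criteria: HomologyCriteria, pseudo_pair: bool = False
) -> bool:
    # coverage is waived when a pseudogene is involved: its stitched protein
    # is legitimately partial, and INDEL orthologs must remain matchable
    shorter_cov = r.coverage_query if len(a) <= len(b) else r.coverage_target
    return (
        r.score > 0
        and r.identity_percent >= criteria.min_identity_percent
        and (pseudo_pair or shorter_cov >= criteria.min_coverage)
    )


# ---------------------------------------------------------------------------
# proteome extraction


def longest_orf_protein(dna: str, min_codons: int = 50) -> str | None:
    """Longest stop-free stretch across the three forward frames, translated.

    Used to make INDEL-disrupted pseudogenes matchable in homology searches;
    returns ``None`` when no frame yields at least ``min_codons`` codons.
    """
    best: list[str] = []
    for frame in range(3):
        run: list[str] = []
        for i in range(frame, len(dna) - 2, 3):
            codon = dna[i : i + 3]
            if codon in STOP_CODONS:
                if len(run) > len(best):
                    best = run
                run = []
            else:
                run.append(codon)
        if len(run) > len(best):
            best = run
    if len(best) < min_codons:
        return None
    return translate("".join(best))


def _stop_free_runs(dna: str) -> list[tuple[int, list[str]]]:
    """(start_bp, codons) of every maximal stop-free run in the 3 forward frames."""
    runs: list[tuple[int, list[str]]] = []
    for frame in range(3):
        cur: list[str] = []
        start = frame
        for i in range(frame, len(dna) - 2, 3):
            codon = dna[i : i + 3]
            if codon in STOP_CODONS:
                if cur:
                    runs.append((start, cur))
                cur = []
                start = i + 3
            else:
                if not cur:
                    start = i
                cur.append(codon)
        if cur:
            runs.append((start, cur))
    return runs


def pseudogene_protein(dna: str, min_codons: int = 50, max_overlap_bp: int = 300) -> str | None:
    """Frameshift-tolerant protein representation of a pseudogene.

    A single frameshifting INDEL splits the original protein into an
    in-frame prefix and a shifted-frame suffix, each read as a stop-free run
    in its own frame.  Both runs overshoot the frameshift into out-of-frame
    sequence before hitting a stop, so the two longest runs are stitched in
    chromosomal order with the overlapping junction trimmed symmetrically,
    recovering nearly the full ancestral protein; two orthologous
    pseudogenes disrupted at different points can then still find each
    other.  Returns ``None`` below ``min_codons``.
    """
    runs = sorted(_stop_free_runs(dna), key=lambda r: (-len(r[1]), r[0]))
    if not runs:
        return None
    chosen = [runs[0]]
    for cand in runs[1:]:
        s1, e1 = runs[0][0], runs[0][0] + 3 * len(runs[0][1])
        s2, e2 = cand[0], cand[0] + 3 * len(cand[1])
        if min(e1, e2) - max(s1, s2) <= max_overlap_bp and (s2 >= s1 or e2 <= e1):
            chosen.append(cand)
            break
    chosen.sort(key=lambda r: r[0])
    if len(chosen) == 2:
        (s1, run1), (s2, run2) = chosen
        overlap = (s1 + 3 * len(run1)) - s2
        if overlap > 0:
            trim1 = (overlap // 2) // 3
            trim2 = -(-(overlap - 3 * trim1) // 3)  # ceil of the remainder
            run1 = run1[: len(run1) - trim1] if trim1 else run1
            run2 = run2[trim2:]
            chosen = [(s1, run1), (s2 + 3 * trim2, run2)]
    total = sum(len(r[1]) for r in chosen)
    if total < min_codons:
        return None
    return "".join(translate("".join(r[1])) for r in chosen if r[1])


def proteome(genome: Genome, min_pseudo_codons: int = 50) -> dict[str, str]:
    """Locus tag -> protein for every CDS; pseudogenes contribute their
    stitched stop-free runs when they reach ``min_pseudo_codons`` in total."""
    out: dict[str, str] = {}
    for f in genome.cds_features():
        dna = extract_cds(genome, f.locus_tag)
        if f.pseudo:
            prot = pseudogene_protein(dna, min_pseudo_codons)
        else:
            prot = translate(dna)
        if prot:
            out[f.locus_tag] = prot
    return out


# ---------------------------------------------------------------------------
# k-mer prefilter


def _kmer_index(proteins: dict[str, str], k: int) -> dict[str, set[str]]:
    index: dict[str, set[str]] = defaultdict(set)
    for tag, seq in proteins.items():
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].add(tag)
    return index


def _candidates(
    query: str, index: dict[str, set[str]], k: int, min_shared: int
) -> list[str]:
    hits: dict[str, int] = defaultdict(int)
    seen = set()
    for i in range(len(query) - k + 1):
        kmer = query[i : i + k]
        if kmer in seen:
            continue
        seen.add(kmer)
        for tag in index.get(kmer, ()):
            hits[tag] += 1
    return sorted(tag for tag, n in hits.items() if n >= min_shared)


def pseudo_tags(genome: Genome | dict[str, str]) -> frozenset[str]:
    if isinstance(genome, dict):
        return frozenset()
    return frozenset(f.locus_tag for f in genome.cds_features() if f.pseudo)


def best_hits(
    genome_q: Genome | dict[str, str],
    genome_t: Genome | dict[str, str],
    criteria: HomologyCriteria | None = None,
    k: int = 5,
    min_shared_kmers: int = 2,
    pseudo_q: frozenset[str] | None = None,
    pseudo_t: frozenset[str] | None = None,
) -> dict[str, OrthologPair]:
    """Best passing hit in the target for every query gene.

    Ties on score break toward higher identity, then lexicographically
    smaller target tag.  Queries without a passing hit are absent.
    Accepts genomes or pre-extracted ``{tag: protein}`` maps (pass the
    pseudogene tag sets explicitly for the latter).
    """
    criteria = criteria or HomologyCriteria()
    ps_q = pseudo_tags(genome_q) if pseudo_q is None else pseudo_q
    ps_t = pseudo_tags(genome_t) if pseudo_t is None else pseudo_t
    prot_q = genome_q if isinstance(genome_q, dict) else proteome(genome_q)
    prot_t = genome_t if isinstance(genome_t, dict) else proteome(genome_t)
    index = _kmer_index(prot_t, k)
    result: dict[str, OrthologPair] = {}
    for tag_q in sorted(prot_q):
        q = prot_q[tag_q]
        best: tuple[float, float, str] | None = None
        best_aln: AlignmentResult | None = None
        for tag_t in _candidates(q, index, k, min_shared_kmers):
            r = align_proteins(q, prot_t[tag_t], criteria)
            if not _passes(q, prot_t[tag_t], r, criteria,
                           tag_q in ps_q or tag_t in ps_t):
                continue
            key = (r.score, r.identity_percent, tag_t)
            if best is None or (key[0], key[1]) > (best[0], best[1]) or (
                (key[0], key[1]) == (best[0], best[1]) and tag_t < best[2]
            ):
                best = key
                best_aln = r
        if best is not None and best_aln is not None:
            result[tag_q] = OrthologPair(tag_a=tag_q, tag_b=best[2], alignment=best_aln)
    return result


def reciprocal_best_hits(
    g1: Genome | dict[str, str],
    g2: Genome | dict[str, str],
    criteria: HomologyCriteria | None = None,
    **kw,
) -> list[OrthologPair]:
    """BBH ortholog pairs: (a, b) kept iff a's best hit is b and vice versa."""
    ps1, ps2 = pseudo_tags(g1), pseudo_tags(g2)
    fwd = best_hits(g1, g2, criteria, pseudo_q=ps1, pseudo_t=ps2, **kw)
    rev = best_hits(g2, g1, criteria, pseudo_q=ps2, pseudo_t=ps1, **kw)
    pairs = []
    for tag_a, hit in sorted(fwd.items()):
        back = rev.get(hit.tag_b)
        if back is not None and back.tag_b == tag_a:
            pairs.append(OrthologPair(tag_a=tag_a, tag_b=hit.tag_b, alignment=hit.alignment))
    return pairs


def paralog_families(
    genome: Genome | dict[str, str],
    criteria: HomologyCriteria | None = None,
    k: int = 5,
    min_shared_kmers: int = 2,
) -> list[set[str]]:
    """Within-genome multigene families by single-linkage clustering of
    passing hits (self-hits excluded); only families of size >= 2 returned."""
    criteria = criteria or HomologyCriteria()
    prots = genome if isinstance(genome, dict) else proteome(genome)
    index = _kmer_index(prots, k)
    g = nx.Graph()
    g.add_nodes_from(prots)
    for tag_a in sorted(prots):
        for tag_b in _candidates(prots[tag_a], index, k, min_shared_kmers):
            if tag_b <= tag_a:
                continue
            r = align_proteins(prots[tag_a], prots[tag_b], criteria)
            if _passes(prots[tag_a], prots[tag_b], r, criteria):
                g.add_edge(tag_a, tag_b)
    return sorted(
        (set(c) for c in nx.connected_components(g) if len(c) >= 2),
        key=lambda fam: min(fam),
    )


def write_ortholog_tsv(pairs: list[OrthologPair], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("tag_a\ttag_b\tscore\tidentity\tcoverage_a\tcoverage_b\n")
        for p in pairs:
            a = p.alignment
            fh.write(
                f"{p.tag_a}\t{p.tag_b}\t{a.score:g}\t{a.identity_percent:.2f}"
                f"\t{a.coverage_query:.3f}\t{a.coverage_target:.3f}\n"
            )
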