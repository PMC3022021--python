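"""Codon-aware alignment, Nei–Gojobori (1986) dN/dS and codon adaptation index.

``ng86_dnds`` implements the counting estimator: per-codon synonymous site
fractions, observed differences averaged over all shortest mutation paths
between codon pairs (paths through stop codons excluded), and the
Jukes–Cantor multiple-hit correction d = -(3/4)·ln(1 - 4p/3).  dN/dS (omega)
is undefined when dS = 0 and is carried as ``None`` with a flag rather than
as infinity.

The CAI follows Sharp & Li: relative adaptiveness w of each codon is its
count in a highly-expressed reference set divided by the count of the most
used codon of the same amino acid (zero counts replaced by 0.5 before
normalization), and a gene's CAI is the geometric mean of w over its codons,
excluding Met, Trp and stops.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.stats import mannwhitneyu

from Bio.Align import PairwiseAligner, substitution_matrices

from .genomeio import CODON_TO_AA, STOP_CODONS, translate

__all__ = [
    "CodonAlignment",
    "DnDsResult",
    "CodonWeights",
    "CAIResult",
    "codon_align",
    "ng86_dnds",
    "category_rates",
    "relative_adaptiveness",
    "cai",
]

_BASES = "ACGT"
SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TO_AA.items() if aa != "*"))


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free paired codon columns of two aligned CDSs."""

    columns: tuple[tuple[str, str], ...]
    had_gaps: bool = False

    @property
    def n_codons(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class DnDsResult:
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float | None
    dS: float | None
    omega: float | None
    flags: tuple[str, ...] = ()


_global_aligner: PairwiseAligner | None = None


def _protein_global_aligner() -> PairwiseAligner:
    global _global_aligner
    if _global_aligner is None:
        al = PairwiseAligner()
        al.mode = "global"
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -11.0
        al.extend_gap_score = -1.0
        _global_aligner = al
    return _global_aligner


def codon_align(cds_a: str, cds_b: str) -> CodonAlignment:
    """Protein-guided codon alignment of two in-frame CDSs.

    The proteins are globally aligned (Needleman–Wunsch, BLOSUM62, affine
    gaps) and the alignment is back-threaded to codons; gap columns and
    columns containing ambiguous bases are dropped.
    """
    prot_a = translate(cds_a)
    prot_b = translate(cds_b)
    if not prot_a or not prot_b:
        raise ValueError("empty protein after translation")
    alignments = _protein_global_aligner().align(prot_a, prot_b)
    if len(alignments) == 0:
        raise ValueError("no alignment between proteins")
    aln = alignments[0]
    blocks_a, blocks_b = aln.aligned
    columns: list[tuple[str, str]] = []
    aligned_aa = 0
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        for off in range(ea - sa):
            i, j = sa + off, sb + off
            ca = cds_a[3 * i : 3 * i + 3]
            cb = cds_b[3 * j : 3 * j + 3]
            aligned_aa += 1
            if set(ca + cb) <= set(_BASES):
                columns.append((ca, cb))
    had_gaps = aligned_aa < max(len(prot_a), len(prot_b))
    return CodonAlignment(columns=tuple(columns), had_gaps=had_gaps)


# ---------------------------------------------------------------------------
# NG86


def _site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one sense codon: at each
    position, the fraction of the three single-base changes that preserve
    the amino acid counts toward S (changes to stops count as nonsynonymous)."""
    s = 0.0
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if CODON_TO_AA[alt] == aa:
                s += 1.0 / 3.0
    return 3.0 - s, s


_SITE_CACHE: dict[str, tuple[float, float]] = {}


def _sites(codon: str) -> tuple[float, float]:
    if codon not in _SITE_CACHE:
        _SITE_CACHE[codon] = _site_counts(codon)
    return _SITE_CACHE[codon]


def _path_differences(ca: str, cb: str) -> tuple[float, float]:
    """(nonsyn, syn) differences between two codons, averaged over all
    orderings of the mutated positions; orderings passing through a stop
    codon are excluded (unless every ordering does)."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    stop_paths: list[tuple[float, float]] = []
    for order in permutations(diff_pos):
        cur = ca
        nd = sd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != cb:
                through_stop = True
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (stop_paths if through_stop else paths).append((nd, sd))
    if not paths:
        paths = stop_paths
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    return nd, sd


_DIFF_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _diffs(ca: str, cb: str) -> tuple[float, float]:
    key = (ca, cb)
    if key not in _DIFF_CACHE:
        _DIFF_CACHE[key] = _path_differences(ca, cb)
    return _DIFF_CACHE[key]


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; undefined at or beyond saturation."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(alignment: CodonAlignment) -> DnDsResult:
    """NG86 dN, dS and omega for one codon alignment.

    Site counts are averaged over the two sequences, so N + S = 3·n_codons
    exactly.  Stop codons inside the alignment (possible only on corrupt
    input) raise ``ValueError``.
    """
    if alignment.n_codons < 1:
        raise ValueError("empty codon alignment")
    N = S = Nd = Sd = 0.0
    for ca, cb in alignment.columns:
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon in alignment column ({ca}, {cb})")
        na, sa = _sites(ca)
        nb, sb = _sites(cb)
        N += (na + nb) / 2.0
        S += (sa + sb) / 2.0
        nd, sd = _diffs(ca, cb)
        Nd += nd
        Sd += sd
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0
    flags: list[str] = []
    dN = jukes_cantor(pN)
    dS = jukes_cantor(pS)
    if dN is None:
        flags.append("pN_saturated")
    if dS is None:
        flags.append("pS_saturated")
    omega: float | None = None
    if dS is not None and dN is not None:
        if dS == 0.0:
            flags.append("dS_zero")
        else:
            omega = dN / dS
    return DnDsResult(N=N, S=S, Nd=Nd, Sd=Sd, pN=pN, pS=pS, dN=dN, dS=dS,
                      omega=omega, flags=tuple(flags))


@dataclass(frozen=True)
class CategoryRates:
    label: str
    n_pairs: int
    n_defined_omega: int
    mean_dn: float
    mean_ds: float
    mean_omega: float | None
    mannwhitney_u: float | None
    p_value: float | None


def category_rates(
    results: list[DnDsResult], labels: list[str]
) -> dict[str, CategoryRates]:
    """Per-label mean dN, dS, omega plus a two-sided Mann–Whitney U test of
    each label's omega distribution against the complement."""
    if len(results) != len(labels):
        raise ValueError("results and labels differ in length")
    by_label: dict[str, list[DnDsResult]] = {}
    for r, lab in zip(results, labels):
        by_label.setdefault(lab, []).append(r)
    out: dict[str, CategoryRates] = {}
    for lab, rs in sorted(by_label.items()):
        omegas = [r.omega for r in rs if r.omega is not None]
        others = [
            r.omega for r, l2 in zip(results, labels)
            if l2 != lab and r.omega is not None
        ]
        u = p = None
        if omegas and others:
            u, p = mannwhitneyu(omegas, others, alternative="two-sided")
            u, p = float(u), float(p)
        dns = [r.dN for r in rs if r.dN is not None]
        dss = [r.dS for r in rs if r.dS is not None]
        out[lab] = CategoryRates(
            label=lab,
            n_pairs=len(rs),
            n_defined_omega=len(omegas),
            mean_dn=float(np.mean(dns)) if dns else 0.0,
            mean_ds=float(np.mean(dss)) if dss else 0.0,
            mean_omega=float(np.mean(omegas)) if omegas else None,
            mannwhitney_u=u,
            p_value=p,
        )
    return out


# ---------------------------------------------------------------------------
# CAI


_FAMILIES: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    _FAMILIES.setdefault(CODON_TO_AA[_c], ())
for _aa in _FAMILIES:
    _FAMILIES[_aa] = tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == _aa)

#: amino acids excluded from CAI averaging (no synonymous choice)
_CAI_EXCLUDED_AAS = frozenset("MW")


@dataclass(frozen=True)
class CodonWeights:
    weights: dict[str, float] = field(default_factory=dict)
    reference: str = ""

    def __getitem__(self, codon: str) -> float:
        return self.weights[codon]


@dataclass(frozen=True)
class CAIResult:
    locus_tag: str
    cai: float
    n_codons_used: int


def relative_adaptiveness(reference_cds: list[str], reference: str = "") -> CodonWeights:
    """Sharp & Li relative-adaptiveness weights from a reference gene set.

    Codon counts are pooled over all reference CDSs (stop codons skipped);
    zero counts are replaced by 0.5 before within-family normalization, so
    every sense codon gets a weight in (0, 1] with the family maximum at 1.
    """
    if len(reference_cds) < 10:
        raise ValueError("need at least 10 reference genes")
    counts: Counter[str] = Counter()
    for cds in reference_cds:
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i : i + 3].upper()
            if codon in CODON_TO_AA and codon not in STOP_CODONS:
                counts[codon] += 1
    weights: dict[str, float] = {}
    for _aa, fam in _FAMILIES.items():
        fam_counts = {c: (counts[c] if counts[c] > 0 else 0.5) for c in fam}
        top = max(fam_counts.values())
        for c in fam:
            weights[c] = fam_counts[c] / top
    return CodonWeights(weights=weights, reference=reference)


def cai(cds: str, weights: CodonWeights, locus_tag: str = "") -> CAIResult:
    """Codon adaptation index: geometric mean of w over the gene's codons,
    excluding Met, Trp and stop codons."""
    log_sum = 0.0
    n = 0
    cds = cds.upper()
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        aa = CODON_TO_AA.get(codon)
        if aa is None or aa == "*" or aa in _CAI_EXCLUDED_AAS:
            continue
        log_sum += math.log(weights[codon])
        n += 1
    if n == 0:
        raise ValueError("no codons usable for CAI")
    return CAIResult(locus_tag=locus_tag, cai=math.exp(log_sum / n), n_codons_used=n)
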