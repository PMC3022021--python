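"""Genome containers, annotation I/O, summary statistics and repeat detection.

A :class:`Genome` holds a single circular bacterial chromosome together with
its typed, stranded gene features (CDS / rRNA / tRNA).  Coordinates are
0-based half-open internally; GFF3 on disk uses the standard 1-based closed
convention.  The module also computes the usual per-genome summary table
(length, GC, GC3, coding fraction, intact vs. truncated CDS counts) and
detects large duplicated segments with an exact k-mer anchor-and-chain
strategy, a lightweight stand-in for a maximal-exact-match aligner.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "Genome",
    "GeneFeature",
    "GenomeStats",
    "DuplicatedSegment",
    "GenomeFormatError",
    "GenomeValidationError",
    "SequenceIntegrityError",
    "read_genome",
    "write_genome",
    "genome_stats",
    "extract_cds",
    "translate",
    "find_duplicated_segments",
    "write_segments_tsv",
]


class GenomeFormatError(ValueError):
    """Annotation and sequence files do not cross-reference."""


class GenomeValidationError(ValueError):
    """A genome or feature violates its structural invariants."""


class SequenceIntegrityError(ValueError):
    """A coding sequence is inconsistent with its annotation (e.g. internal stop)."""


FEATURE_TYPES = ("CDS", "rRNA", "tRNA", "other")

_BACTERIAL_TABLE = CodonTable.unambiguous_dna_by_id[11]
#: codon -> amino acid for the bacterial/plastid code; stops map to '*'
CODON_TO_AA: dict[str, str] = dict(_BACTERIAL_TABLE.forward_table)
for _stop in _BACTERIAL_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = frozenset(_BACTERIAL_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """One annotated feature on the chromosome.

    ``start``/``end`` are 0-based half-open.  A feature that wraps the
    replication origin is stored as two ordered segments in ``segments``;
    for ordinary features ``segments`` is ``None`` and the single interval
    is ``[start, end)``.
    """

    locus_tag: str
    type: str
    start: int
    end: int
    strand: str
    pseudo: bool = False
    product: str = ""
    ec_numbers: frozenset[str] = frozenset()
    segments: tuple[tuple[int, int], ...] | None = None

    def intervals(self) -> tuple[tuple[int, int], ...]:
        return self.segments if self.segments is not None else ((self.start, self.end),)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals())


@dataclass
class Genome:
    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    is_circular: bool = True

    def __post_init__(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end, f.locus_tag))
        self.validate()

    def validate(self) -> None:
        n = len(self.sequence)
        tags: set[str] = set()
        for f in self.features:
            if f.locus_tag in tags:
                raise GenomeValidationError(f"duplicate locus tag {f.locus_tag!r}")
            tags.add(f.locus_tag)
            if f.type not in FEATURE_TYPES:
                raise GenomeValidationError(f"{f.locus_tag}: unknown feature type {f.type!r}")
            if f.strand not in "+-":
                raise GenomeValidationError(f"{f.locus_tag}: bad strand {f.strand!r}")
            for s, e in f.intervals():
                if not (0 <= s < e <= n):
                    raise GenomeValidationError(
                        f"{f.locus_tag}: interval [{s},{e}) outside chromosome of length {n}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)

    def cds_features(self, include_pseudo: bool = True) -> list[GeneFeature]:
        return [f for f in self.features if f.type == "CDS" and (include_pseudo or not f.pseudo)]


@dataclass(frozen=True)
class GenomeStats:
    length_bp: int
    gc_percent: float
    n_cds_total: int
    n_cds_intact: int
    n_cds_pseudo: int
    total_cds_bp: int
    mean_cds_len_bp: int
    gc_in_cds_percent: float
    gc3_percent: float
    coding_fraction: float
    stable_rna_fraction: float


@dataclass(frozen=True)
class DuplicatedSegment:
    start1: int
    end1: int
    start2: int
    end2: int
    orientation: str  # "direct" | "inverted"
    length_bp: int
    identity_percent: float


# ---------------------------------------------------------------------------
# reading / writing


def _round_half_up(x: float, ndigits: int = 2) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


_GFF_TYPE_MAP = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = re.sub(r"%2C", ",", value.strip())
    return attrs


def _read_gff3(path: str, seq_id: str, seq_len: int) -> list[GeneFeature]:
    features: list[GeneFeature] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise GenomeFormatError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attr_text = cols
            if ftype not in _GFF_TYPE_MAP:
                continue
            if chrom != seq_id:
                raise GenomeFormatError(
                    f"GFF3 seqid {chrom!r} does not match FASTA record {seq_id!r}"
                )
            attrs = _parse_gff_attributes(attr_text)
            tag = attrs.get("locus_tag") or attrs.get("ID")
            if tag is None:
                raise GenomeFormatError(f"feature without ID/locus_tag: {line!r}")
            ecs = frozenset(e for e in attrs.get("ec_number", "").split(",") if e)
            s, e = int(start) - 1, int(end)
            if not (0 <= s < e <= seq_len):
                raise GenomeValidationError(f"{tag}: [{s},{e}) out of bounds (len {seq_len})")
            features.append(
                GeneFeature(
                    locus_tag=tag,
                    type=_GFF_TYPE_MAP[ftype],
                    start=s,
                    end=e,
                    strand=strand,
                    pseudo=attrs.get("pseudo", "").lower() == "true",
                    product=attrs.get("product", ""),
                    ec_numbers=ecs,
                )
            )
    return features


def _read_genbank(path: str) -> Genome:
    records = list(SeqIO.parse(path, "genbank"))
    if len(records) != 1:
        raise GenomeFormatError(f"expected exactly one GenBank record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    features: list[GeneFeature] = []
    counter = 0
    for feat in rec.features:
        if feat.type not in _GFF_TYPE_MAP:
            continue
        q = feat.qualifiers
        tag = q.get("locus_tag", [None])[0]
        if tag is None:
            counter += 1
            tag = f"{rec.id}_{feat.type}_{counter}"
        ecs = frozenset(q.get("EC_number", []))
        start, end = int(feat.location.start), int(feat.location.end)
        if not (0 <= start < end <= len(seq)):
            raise GenomeValidationError(f"{tag}: location out of bounds")
        features.append(
            GeneFeature(
                locus_tag=tag,
                type=_GFF_TYPE_MAP[feat.type],
                start=start,
                end=end,
                strand="+" if feat.location.strand != -1 else "-",
                pseudo="pseudo" in q or "pseudogene" in q,
                product=q.get("product", [""])[0],
                ec_numbers=ecs,
            )
        )
    topology = rec.annotations.get("topology", "circular")
    return Genome(id=rec.id, sequence=seq, features=features, is_circular=topology == "circular")


def read_genome(fasta_path: str | None, annotation_path: str, dialect: str = "gff3") -> Genome:
    """Read a genome from FASTA + GFF3, or from a GenBank flat file.

    For ``dialect='genbank'`` the sequence is taken from the flat file and
    ``fasta_path`` is ignored.
    """
    if dialect == "genbank":
        return _read_genbank(annotation_path)
    if dialect != "gff3":
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    records = list(SeqIO.parse(fasta_path, "fasta"))
    if len(records) != 1:
        raise GenomeFormatError(f"expected exactly one chromosome record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    features = _read_gff3(annotation_path, rec.id, len(seq))
    return Genome(id=rec.id, sequence=seq, features=features)


def write_genome(genome: Genome, fasta_path: str, gff3_path: str) -> None:
    """Write the chromosome as single-record FASTA plus a GFF3 annotation."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.id}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for f in genome.features:
            attrs = [f"ID={f.locus_tag}", f"locus_tag={f.locus_tag}"]
            if f.pseudo:
                attrs.append("pseudo=true")
            if f.product:
                attrs.append(f"product={f.product.replace(',', '%2C')}")
            if f.ec_numbers:
                attrs.append("ec_number=" + ",".join(sorted(f.ec_numbers)))
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        "pangcn",
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.type == "CDS" else ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# statistics


def _gc_count(seq: str) -> int:
    return seq.count("G") + seq.count("C")


def genome_stats(genome: Genome) -> GenomeStats:
    """Summary statistics for one chromosome.

    GC is computed over the full chromosome; in-CDS GC and GC3 are computed
    over the concatenated coding-strand sequences of *intact* (non-pseudo)
    CDSs, since GC3 needs a trustworthy reading frame.  Pseudogenes still
    count toward the CDS total and the mean CDS length: the "all genes"
    column of a genome report is intact plus truncated ORFs.
    """
    if not genome.sequence:
        raise GenomeValidationError("empty genome")
    n = len(genome)
    cds_all = genome.cds_features(include_pseudo=True)
    cds_intact = [f for f in cds_all if not f.pseudo]
    total_cds_bp = sum(f.length for f in cds_all)
    coding_concat = "".join(extract_cds(genome, f.locus_tag) for f in cds_intact)
    third = coding_concat[2::3]
    rna_bp = sum(f.length for f in genome.features if f.type in ("rRNA", "tRNA"))
    mean_len = round(total_cds_bp / len(cds_all)) if cds_all else 0
    return GenomeStats(
        length_bp=n,
        gc_percent=_round_half_up(100.0 * _gc_count(genome.sequence) / n),
        n_cds_total=len(cds_all),
        n_cds_intact=len(cds_intact),
        n_cds_pseudo=len(cds_all) - len(cds_intact),
        total_cds_bp=total_cds_bp,
        mean_cds_len_bp=mean_len,
        gc_in_cds_percent=(
            _round_half_up(100.0 * _gc_count(coding_concat) / len(coding_concat))
            if coding_concat
            else 0.0
        ),
        gc3_percent=_round_half_up(100.0 * _gc_count(third) / len(third)) if third else 0.0,
        coding_fraction=total_cds_bp / n,
        stable_rna_fraction=rna_bp / n,
    )


# ---------------------------------------------------------------------------
# CDS extraction and translation


def extract_cds(genome: Genome, locus_tag: str) -> str:
    """Coding-strand nucleotide sequence of a feature (minus strand rev-complemented)."""
    f = genome.feature(locus_tag)
    raw = "".join(genome.sequence[s:e] for s, e in f.intervals())
    return revcomp(raw) if f.strand == "-" else raw


def translate(dna: str, table: int = 11, allow_internal_stop: bool = False) -> str:
    """Translate a CDS with the bacterial code; terminal stop stripped.

    Codons containing non-ACGT characters translate to ``X``.  An internal
    stop raises :class:`SequenceIntegrityError` unless explicitly allowed
    (pseudogenes are translated through their longest intact frame upstream
    of this function, so internal stops here signal corrupt annotation).
    """
    if table != 11:
        raise ValueError("only the bacterial code (table 11) is supported")
    if len(dna) % 3 != 0:
        raise GenomeValidationError(f"CDS length {len(dna)} not divisible by 3")
    dna = dna.upper()
    aas = [CODON_TO_AA.get(dna[i : i + 3], "X") for i in range(0, len(dna), 3)]
    if aas and aas[-1] == "*":
        aas.pop()
    if "*" in aas and not allow_internal_stop:
        raise SequenceIntegrityError(f"internal stop codon at position {aas.index('*') * 3}")
    return "".join(aas)


# ---------------------------------------------------------------------------
# duplicated-segment detection


def _kmer_positions(seq: str, k: int, max_occ: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return {kmer: pos for kmer, pos in index.items() if len(pos) <= max_occ}


def _chain_anchors(
    anchors: list[tuple[int, int]], k: int, max_gap: int, inverted: bool
) -> list[tuple[int, int, int, int, int]]:
    """Greedy collinear chaining of (i, j) anchor starts sharing a diagonal.

    Returns chains as (start1, end1, start2, end2, matched_bp).  For direct
    repeats the diagonal is j - i; for inverted repeats it is i + j.
    """
    if not anchors:
        return []
    diag = (lambda a: a[0] + a[1]) if inverted else (lambda a: a[1] - a[0])
    anchors = sorted(anchors, key=lambda a: (diag(a), a[0]))
    chains: list[tuple[int, int, int, int, int]] = []
    cur: list[tuple[int, int]] = []
    cur_diag = None

    def flush() -> None:
        if not cur:
            return
        i0, i1 = cur[0][0], cur[-1][0] + k
        js = [j for _, j in cur]
        j0, j1 = min(js), max(js) + k
        # matched bp = union of anchor intervals on the first copy
        matched, last_end = 0, -1
        for i, _ in cur:
            s = max(i, last_end)
            matched += max(0, i + k - s)
            last_end = max(last_end, i + k)
        chains.append((i0, i1, j0, j1, matched))

    for a in anchors:
        d = diag(a)
        if cur and d == cur_diag and a[0] - cur[-1][0] <= max_gap:
            cur.append(a)
        else:
            flush()
            cur = [a]
            cur_diag = d
    flush()
    return chains


def find_duplicated_segments(
    genome: Genome | str,
    min_len: int = 1000,
    min_identity: float = 90.0,
    k: int = 20,
    max_gap: int = 500,
    max_kmer_occ: int = 50,
) -> list[DuplicatedSegment]:
    """Detect long duplicated segments on both strands of one chromosome.

    Exact ``k``-mer anchors shared between two loci are chained along a
    common (anti-)diagonal with gaps up to ``max_gap`` bp; each merged chain
    is reported with its orientation and an anchor-based identity (matched
    anchor bp over chain span — a conservative lower bound on alignment
    identity).  Trivial self-matches on the main diagonal are excluded, and
    each segment pair is reported once with ``start1 < start2``.
    """
    if min_len < 1000:
        raise GenomeValidationError("min_len must be >= 1000")
    seq = genome.sequence if isinstance(genome, Genome) else genome
    index = _kmer_positions(seq, k, max_kmer_occ)

    direct_anchors: list[tuple[int, int]] = []
    for positions in index.values():
        if len(positions) > 1:
            for ai in range(len(positions)):
                for bi in range(ai + 1, len(positions)):
                    direct_anchors.append((positions[ai], positions[bi]))

    inverted_anchors: list[tuple[int, int]] = []
    seen_rc: set[tuple[int, int]] = set()
    for kmer, positions in index.items():
        rc = revcomp(kmer)
        for j in index.get(rc, ()):
            for i in positions:
                if i == j:
                    continue
                pair = (min(i, j), max(i, j))
                if pair not in seen_rc:
                    seen_rc.add(pair)
                    inverted_anchors.append(pair)

    segments: list[DuplicatedSegment] = []
    for inverted, anchors in ((False, direct_anchors), (True, inverted_anchors)):
        for s1, e1, s2, e2, matched in _chain_anchors(anchors, k, max_gap, inverted):
            length = max(e1 - s1, e2 - s2)
            if length < min_len:
                continue
            if (s1, e1) == (s2, e2):
                continue
            identity = 100.0 * matched / length
            if identity < min_identity:
                continue
            segments.append(
                DuplicatedSegment(
                    start1=s1,
                    end1=e1,
                    start2=s2,
                    end2=e2,
                    orientation="inverted" if inverted else "direct",
                    length_bp=length,
                    identity_percent=round(identity, 2),
                )
            )
    segments.sort(key=lambda s: (s.start1, s.start2))
    return _merge_overlapping(segments)


def _merge_overlapping(segments: list[DuplicatedSegment]) -> list[DuplicatedSegment]:
    """Collapse chains that describe overlapping copies of the same repeat pair."""
    merged: list[DuplicatedSegment] = []
    for seg in segments:
        for idx, kept in enumerate(merged):
            if kept.orientation != seg.orientation:
                continue
            if (
                seg.start1 <= kept.end1
                and kept.start1 <= seg.end1
                and seg.start2 <= kept.end2
                and kept.start2 <= seg.end2
            ):
                s1, e1 = min(kept.start1, seg.start1), max(kept.end1, seg.end1)
                s2, e2 = min(kept.start2, seg.start2), max(kept.end2, seg.end2)
                length = max(e1 - s1, e2 - s2)
                ident = max(kept.identity_percent, seg.identity_percent)
                merged[idx] = replace(
                    kept, start1=s1, end1=e1, start2=s2, end2=e2,
                    length_bp=length, identity_percent=ident,
                )
                break
        else:
            merged.append(seg)
    return merged


def write_segments_tsv(segments: list[DuplicatedSegment], path: str, chrom: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart1\tend1\tstart2\tend2\torientation\tlength\tidentity\n")
        for s in segments:
            fh.write(
                f"{chrom}\t{s.start1}\t{s.end1}\t{s.start2}\t{s.end2}"
                f"\t{s.orientation}\t{s.length_bp}\t{s.identity_percent}\n"
            )
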