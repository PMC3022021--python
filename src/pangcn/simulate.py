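"""Synthetic pan-genome simulator with known ground truth.

Builds an ancestral circular chromosome (biased codon usage, intergenic
spacers, optional planted segmental duplication flanking a unique central
gene block) and evolves descendant strains from it by gene loss, tandem
duplication, synonymous/non-synonymous point substitution at a controlled
dN/dS, and frameshift pseudogenization.  Every stochastic event is recorded
in a :class:`TruthRecord`, so each downstream estimator (orthology, pan-genome
partition, NG86 omega, context-network phylogeny) can be scored against the
generating process.

The default parameters emulate a small dairy-lactobacillus chromosome:
~1.87 Mb, ~1,750 CDSs averaging ~860 bp, GC close to 50%, a 25 kb segmental
duplication flanking an 8.5 kb strain-specific central region, and a strain
triplet in which two collection-like strains (B, C) share an intermediate
ancestor — true topology ((B,C),A) with the ancestor as outgroup.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genomeio import CODON_TO_AA, STOP_CODONS, Genome, GeneFeature, extract_cds, revcomp

__all__ = [
    "SimParams",
    "GeneEvents",
    "TruthRecord",
    "Triplet",
    "simulate_ancestor",
    "evolve_strain",
    "make_triplet",
    "simulate_panel",
    "simulate_marker_alignment",
    "truth_categories",
    "LYSINE_STEP_ECS",
]

#: EC numbers of the nine L-aspartate -> L-lysine steps (lysC..lysA); step 5
#: admits two alternative N-acyltransferases.
LYSINE_STEP_ECS: list[set[str]] = [
    {"2.7.2.4"},
    {"1.2.1.11"},
    {"4.2.1.52"},
    {"1.3.1.26"},
    {"2.3.1.89", "2.3.1.117"},
    {"2.6.1.57"},
    {"3.5.1.47"},
    {"5.1.1.7"},
    {"4.1.1.20"},
]
#: subset of steps also present in the collection-strain backbone
_BACKBONE_STEPS = (0, 1, 5)  # lysC, asd, araT

_SENSE_CODONS = sorted(c for c in CODON_TO_AA if CODON_TO_AA[c] != "*")
_AA_TO_CODONS: dict[str, list[str]] = {}
for _c in _SENSE_CODONS:
    _AA_TO_CODONS.setdefault(CODON_TO_AA[_c], []).append(_c)
_AAS = sorted(_AA_TO_CODONS)
_BASES = "ACGT"


@dataclass
class SimParams:
    """Generator knobs; every stochastic draw is fixed by ``seed``."""

    n_genes: int = 1750
    mean_gene_len_codons: int = 286
    gc_target: float = 0.497
    codon_bias_strength: float = 0.5
    intergenic_mean_bp: int = 190
    loss_rate: float = 0.03
    dup_rate: float = 0.01
    snp_per_site: float = 0.01
    omega_true: float = 0.3
    pseudogenization_rate: float = 0.05
    gain_rate: float = 0.0
    planted_duplication_len_bp: int = 25000
    unique_central_len_bp: int = 8500
    #: divergence between the two planted duplication copies at the root —
    #: the duplication predates the strain split, so copy orthology is
    #: resolvable while the repeat stays easily detectable
    dup_block_divergence: float = 0.02
    plant_pathway_ecs: bool = True
    n_ribosomal_like: int = 40
    seed: int = 0

    def validate(self) -> None:
        for name in ("loss_rate", "dup_rate", "snp_per_site", "pseudogenization_rate",
                     "gain_rate", "codon_bias_strength", "gc_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.omega_true <= 0:
            raise ValueError("omega_true must be positive")


@dataclass
class GeneEvents:
    lost: bool = False
    duplicated: bool = False
    n_syn: int = 0
    n_nonsyn: int = 0
    indel_pseudo: bool = False

    def merge(self, other: "GeneEvents") -> "GeneEvents":
        return GeneEvents(
            lost=self.lost or other.lost,
            duplicated=self.duplicated or other.duplicated,
            n_syn=self.n_syn + other.n_syn,
            n_nonsyn=self.n_nonsyn + other.n_nonsyn,
            indel_pseudo=self.indel_pseudo or other.indel_pseudo,
        )


@dataclass
class TruthRecord:
    """Ground truth linking a descendant genome to its parent genome.

    ``ortholog_map`` maps each descendant locus tag to the parent tag it
    descends from (duplicates map to their template); ``lineage`` maps each
    descendant tag to the tag under which that gene *lineage* was born, so
    copies created on a shared internal branch can be traced across strains.
    """

    parent_id: str
    ortholog_map: dict[str, str] = field(default_factory=dict)
    lineage: dict[str, str] = field(default_factory=dict)
    event_log: dict[str, GeneEvents] = field(default_factory=dict)
    planted_segments: list[tuple[int, int]] = field(default_factory=list)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("descendant_tag\tparent_tag\tlineage\tevents\n")
            for tag in sorted(self.ortholog_map):
                ev = self.event_log.get(self.ortholog_map[tag], GeneEvents())
                parts = []
                if ev.duplicated:
                    parts.append("duplicated")
                if ev.indel_pseudo:
                    parts.append("indel_pseudo")
                parts.append(f"syn_snp:{ev.n_syn}")
                parts.append(f"nonsyn_snp:{ev.n_nonsyn}")
                fh.write(f"{tag}\t{self.ortholog_map[tag]}\t{self.lineage[tag]}\t{','.join(parts)}\n")


@dataclass
class _GeneUnit:
    tag: str
    seq: str  # coding-strand sequence, start..stop inclusive
    strand: str
    spacer_before: str
    pseudo: bool = False
    product: str = ""
    ecs: frozenset = frozenset()


def _assemble(genome_id: str, units: list[_GeneUnit], trailing_spacer: str) -> Genome:
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for u in units:
        parts.append(u.spacer_before)
        pos += len(u.spacer_before)
        chrom_seq = revcomp(u.seq) if u.strand == "-" else u.seq
        features.append(
            GeneFeature(
                locus_tag=u.tag,
                type="CDS",
                start=pos,
                end=pos + len(u.seq),
                strand=u.strand,
                pseudo=u.pseudo,
                product=u.product,
                ec_numbers=u.ecs,
            )
        )
        parts.append(chrom_seq)
        pos += len(u.seq)
    parts.append(trailing_spacer)
    return Genome(id=genome_id, sequence="".join(parts), features=features)


def _sample_codon_table(rng: np.random.Generator, bias: float) -> dict[str, float]:
    """Per-codon sampling distribution: amino acids uniform, one preferred
    codon per synonymous family carrying weight 1 against (1 - bias) each.

    The preferred codon is drawn among the most GC-rich of its family,
    mimicking the elevated third-position GC of the emulated chromosome;
    at ``bias`` 0 the distribution is uniform within each family.
    """
    table: dict[str, float] = {}
    for aa in _AAS:
        codons = _AA_TO_CODONS[aa]
        gc_max = max(c.count("G") + c.count("C") for c in codons)
        rich = [c for c in codons if c.count("G") + c.count("C") == gc_max]
        pref = rich[int(rng.integers(len(rich)))]
        weights = np.array([1.0 if c == pref else (1.0 - bias) for c in codons])
        weights /= weights.sum()
        for c, w in zip(codons, weights):
            table[c] = w / len(_AAS)
    return table


def _sample_gene(rng: np.random.Generator, n_codons: int, table: dict[str, float]) -> str:
    aas = [_AAS[i] for i in rng.integers(len(_AAS), size=n_codons)]
    codons = ["ATG"]
    for aa in aas:
        fam = _AA_TO_CODONS[aa]
        probs = np.array([table[c] for c in fam])
        probs /= probs.sum()
        codons.append(fam[int(rng.choice(len(fam), p=probs))])
    codons.append(["TAA", "TAG", "TGA"][int(rng.integers(3))])
    return "".join(codons)


def _sample_spacer(rng: np.random.Generator, mean_bp: int, gc: float) -> str:
    n = int(rng.poisson(mean_bp))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[i] for i in rng.choice(4, size=n, p=p))


def _gene_length(rng: np.random.Generator, mean_codons: int) -> int:
    n = int(round(rng.normal(mean_codons, 0.3 * mean_codons)))
    return max(30, n)


def simulate_ancestor(params: SimParams) -> tuple[Genome, dict[str, float]]:
    """Generate the ancestral genome and return it with the exact codon
    sampling distribution used for its genes.

    Locus-tag prefixes encode the planted architecture: ``G`` backbone genes,
    ``D1``/``D2`` the two copies of the planted duplication block, ``L`` the
    unique central block between them (which carries the full amino-acid
    biosynthesis pathway annotation when ``plant_pathway_ecs`` is set).
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    table = _sample_codon_table(rng, params.codon_bias_strength)

    units: list[_GeneUnit] = []
    riboset = set(
        rng.choice(params.n_genes, size=min(params.n_ribosomal_like, params.n_genes), replace=False)
    )
    for i in range(params.n_genes):
        seq = _sample_gene(rng, _gene_length(rng, params.mean_gene_len_codons), table)
        product = f"ribosomal protein L{i}" if i in riboset else f"protein {i}"
        units.append(
            _GeneUnit(
                tag=f"ANC_G{i:04d}",
                seq=seq,
                strand="+-"[int(rng.integers(2))],
                spacer_before=_sample_spacer(rng, params.intergenic_mean_bp, params.gc_target),
                product=product,
            )
        )

    if params.planted_duplication_len_bp > 0:
        dup_units: list[_GeneUnit] = []
        total = 0
        j = 0
        while total < params.planted_duplication_len_bp:
            n_codons = _gene_length(rng, params.mean_gene_len_codons)
            seq = _sample_gene(rng, n_codons, table)
            spacer = _sample_spacer(rng, params.intergenic_mean_bp, params.gc_target)
            dup_units.append(
                _GeneUnit(tag=f"D{j:03d}", seq=seq, strand="+-"[int(rng.integers(2))],
                          spacer_before=spacer, product=f"duplicated-block protein {j}")
            )
            total += len(seq) + len(spacer)
            j += 1

        central_units: list[_GeneUnit] = []
        total = 0
        j = 0
        while total < params.unique_central_len_bp or j < len(LYSINE_STEP_ECS):
            n_codons = _gene_length(rng, params.mean_gene_len_codons)
            seq = _sample_gene(rng, n_codons, table)
            spacer = _sample_spacer(rng, params.intergenic_mean_bp, params.gc_target)
            ecs = frozenset()
            product = f"central-region protein {j}"
            if params.plant_pathway_ecs and j < len(LYSINE_STEP_ECS):
                ecs = frozenset(sorted(LYSINE_STEP_ECS[j])[:1])
                product = f"lysine biosynthesis step {j + 1}"
            central_units.append(
                _GeneUnit(tag=f"ANC_L{j:03d}", seq=seq, strand="+-"[int(rng.integers(2))],
                          spacer_before=spacer, product=product, ecs=ecs)
            )
            total += len(seq) + len(spacer)
            j += 1

        insert_at = len(units) // 2
        copy1 = [
            _GeneUnit(tag=f"ANC_D1{u.tag}", seq=u.seq, strand=u.strand,
                      spacer_before=u.spacer_before, product=u.product) for u in dup_units
        ]
        copy2 = []
        for u in dup_units:
            seq2, _, _ = _mutate_coding(
                u.seq, int(rng.binomial(max(0, len(u.seq) - 6), params.dup_block_divergence)),
                1.0, rng,
            )
            copy2.append(
                _GeneUnit(tag=f"ANC_D2{u.tag}", seq=seq2, strand=u.strand,
                          spacer_before=u.spacer_before, product=u.product)
            )
        units = units[:insert_at] + copy1 + central_units + copy2 + units[insert_at:]

    if params.plant_pathway_ecs:
        backbone = [u for u in units if u.tag.startswith("ANC_G")]
        picks = rng.choice(len(backbone), size=len(_BACKBONE_STEPS), replace=False)
        for step_i, unit_i in zip(_BACKBONE_STEPS, picks):
            u = backbone[int(unit_i)]
            u.ecs = frozenset(sorted(LYSINE_STEP_ECS[step_i])[:1])
            u.product = f"lysine biosynthesis step {step_i + 1} (backbone)"

    trailing = _sample_spacer(rng, params.intergenic_mean_bp, params.gc_target)
    return _assemble("ancestor", units, trailing), table


# ---------------------------------------------------------------------------
# evolution


def _mutate_coding(
    seq: str, n_sub: int, omega: float, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Place ``n_sub`` accepted substitutions on a CDS by acceptance-rejection.

    Proposals are uniform single-base changes in the gene body (start and
    stop codons protected); a proposal creating a stop codon is rejected
    outright, a synonymous change is accepted with probability min(1, 1/omega)
    and a non-synonymous change with probability min(1, omega), so the
    realized nonsyn/syn count ratio targets omega times the neutral ratio.
    """
    body = bytearray(seq, "ascii")
    lo, hi = 3, len(seq) - 3
    if hi <= lo:
        return seq, 0, 0
    p_syn = min(1.0, 1.0 / omega)
    p_non = min(1.0, omega)
    n_syn = n_non = 0
    attempts = 0
    max_attempts = 200 * max(1, n_sub)
    while n_syn + n_non < n_sub and attempts < max_attempts:
        attempts += 1
        pos = int(rng.integers(lo, hi))
        old = chr(body[pos])
        new = _BASES[int(rng.integers(4))]
        if new == old:
            continue
        ci = (pos // 3) * 3
        if ci + 3 > len(body):  # trailing partial codon of a frameshifted CDS
            continue
        codon = body[ci : ci + 3].decode()
        new_codon = codon[: pos - ci] + new + codon[pos - ci + 1 :]
        if new_codon in STOP_CODONS:
            continue
        syn = CODON_TO_AA[new_codon] == CODON_TO_AA[codon]
        accept_p = p_syn if syn else p_non
        if accept_p < 1.0 and rng.random() >= accept_p:
            continue
        body[pos] = ord(new)
        if syn:
            n_syn += 1
        else:
            n_non += 1
    return body.decode(), n_syn, n_non


def _mutate_spacer(seq: str, rate: float, rng: np.random.Generator) -> str:
    if not seq or rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def evolve_strain(
    ancestor: Genome,
    params: SimParams,
    seed: int,
    strain_id: str = "S",
    rate_scale: float = 1.0,
    forced_losses: frozenset[str] = frozenset(),
    protected: frozenset[str] = frozenset(),
    loss_rate: float | None = None,
) -> tuple[Genome, TruthRecord]:
    """Evolve one descendant from ``ancestor`` and record every event.

    ``rate_scale`` multiplies the substitution rate (a branch-length knob);
    ``forced_losses`` deterministically removes the named parent genes (used
    to delete the unique central region on the collection-strain branch) and
    ``protected`` genes are exempt from stochastic loss and pseudogenization.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 17]))
    lrate = params.loss_rate if loss_rate is None else loss_rate
    truth = TruthRecord(parent_id=ancestor.id)
    units: list[_GeneUnit] = []
    feats = sorted(ancestor.features, key=lambda f: f.start)
    pending_spacer = ""
    prev_end = 0
    n_kept = 0
    for f in feats:
        spacer = _mutate_spacer(
            ancestor.sequence[prev_end : f.start], params.snp_per_site * rate_scale, rng
        )
        prev_end = f.end
        pending_spacer += spacer
        ev = GeneEvents()
        truth.event_log[f.locus_tag] = ev
        if f.locus_tag in forced_losses or (
            f.locus_tag not in protected and rng.random() < lrate
        ):
            ev.lost = True
            continue
        seq = extract_cds(ancestor, f.locus_tag)
        n_sub = int(rng.binomial(max(0, len(seq) - 6), params.snp_per_site * rate_scale))
        seq, n_syn, n_non = _mutate_coding(seq, n_sub, params.omega_true, rng)
        ev.n_syn, ev.n_nonsyn = n_syn, n_non
        base = f.locus_tag.split("_", 1)[-1]
        new_tag = f"{strain_id}_{base}"
        pseudo = f.pseudo
        if (
            not pseudo
            and f.locus_tag not in protected
            and rng.random() < params.pseudogenization_rate
        ):
            ev.indel_pseudo = True
            pseudo = True
            cut = int(rng.integers(3, len(seq) - 3))
            seq = seq[:cut] + seq[cut + 1 :]
        units.append(
            _GeneUnit(tag=new_tag, seq=seq, strand=f.strand, spacer_before=pending_spacer,
                      pseudo=pseudo, product=f.product, ecs=f.ec_numbers)
        )
        pending_spacer = ""
        truth.ortholog_map[new_tag] = f.locus_tag
        truth.lineage[new_tag] = f.locus_tag
        n_kept += 1
        if f.locus_tag not in protected and rng.random() < params.dup_rate:
            ev.duplicated = True
            # suffix carries the branch name so a re-duplication downstream
            # of an inherited duplicate cannot collide
            dup_tag = f"{strain_id}_{base}.{strain_id}d"
            # observed duplicates have had time to diverge from their
            # template; without this, copy orthology would be arbitrary
            dup_seq, _, _ = _mutate_coding(
                seq,
                int(rng.binomial(max(0, len(seq) - 6), params.dup_block_divergence)),
                1.0,
                rng,
            )
            units.append(
                _GeneUnit(tag=dup_tag, seq=dup_seq, strand=f.strand,
                          spacer_before=_sample_spacer(rng, 30, params.gc_target),
                          pseudo=pseudo, product=f.product, ecs=f.ec_numbers)
            )
            truth.ortholog_map[dup_tag] = f.locus_tag
            truth.lineage[dup_tag] = dup_tag  # new lineage born on this branch
    if n_kept == 0:
        raise ValueError("evolution lost every gene; lower loss_rate")
    trailing = pending_spacer + _mutate_spacer(
        ancestor.sequence[prev_end:], params.snp_per_site * rate_scale, rng
    )
    genome = _assemble(strain_id, units, trailing)
    return genome, truth


def _compose(child: TruthRecord, parent: TruthRecord) -> TruthRecord:
    """Chain a child-of-intermediate truth record through the intermediate."""
    out = TruthRecord(parent_id=parent.parent_id)
    for tag, mid in child.ortholog_map.items():
        if mid in parent.ortholog_map:
            anc = parent.ortholog_map[mid]
            born = parent.lineage[mid] if child.lineage[tag] == mid else child.lineage[tag]
        else:  # lineage born in the intermediate (duplicate of a duplicate)
            anc = mid
            born = child.lineage[tag]
        out.ortholog_map[tag] = anc
        out.lineage[tag] = born
    for anc_tag, ev in parent.event_log.items():
        out.event_log[anc_tag] = ev
    for mid_tag, ev in child.event_log.items():
        anc_tag = parent.ortholog_map.get(mid_tag, mid_tag)
        if anc_tag in out.event_log:
            out.event_log[anc_tag] = out.event_log[anc_tag].merge(ev)
        else:
            out.event_log[anc_tag] = ev
    return out


@dataclass
class Triplet:
    ancestor: Genome
    genomes: dict[str, Genome]
    truths: dict[str, TruthRecord]
    codon_usage: dict[str, float]
    params: SimParams


def make_triplet(params: SimParams) -> Triplet:
    """Simulate the three-strain study design with a known history.

    Strain A diverges directly from the ancestor on a short branch and keeps
    the planted central region between the two duplicated segments; B and C
    descend from a shared intermediate that lost the central region, so they
    share losses and substitutions.  The true unrooted topology with the
    ancestor as outgroup is ((B,C),A).
    """
    ancestor, usage = simulate_ancestor(params)
    ss = np.random.SeedSequence(params.seed)
    seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(4)]
    central = frozenset(f.locus_tag for f in ancestor.features if f.locus_tag.startswith("ANC_L"))
    planted = frozenset(
        f.locus_tag for f in ancestor.features if f.locus_tag.startswith(("ANC_D1", "ANC_D2"))
    )
    # enzyme-annotated genes stay under purifying selection on every branch:
    # the collection-strain backbone keeps its residual pathway steps
    ec_tagged = frozenset(f.locus_tag for f in ancestor.features if f.ec_numbers)
    a_genome, a_truth = evolve_strain(
        ancestor, params, seeds[0], strain_id="A", rate_scale=0.5,
        protected=central | planted | ec_tagged,
    )
    inter, i_truth = evolve_strain(
        ancestor, params, seeds[1], strain_id="I", rate_scale=0.5,
        forced_losses=central, protected=ec_tagged,
    )
    inter_ec = frozenset(f.locus_tag for f in inter.features if f.ec_numbers)
    b_genome, b_mid = evolve_strain(
        inter, params, seeds[2], strain_id="B", rate_scale=0.5, protected=inter_ec
    )
    c_genome, c_mid = evolve_strain(
        inter, params, seeds[3], strain_id="C", rate_scale=0.5, protected=inter_ec
    )
    b_truth = _compose(b_mid, i_truth)
    c_truth = _compose(c_mid, i_truth)
    for truth, strain in ((a_truth, a_genome),):
        truth.planted_segments = _planted_spans(strain)
    return Triplet(
        ancestor=ancestor,
        genomes={"A": a_genome, "B": b_genome, "C": c_genome},
        truths={"A": a_truth, "B": b_truth, "C": c_truth},
        codon_usage=usage,
        params=params,
    )


def _planted_spans(genome: Genome) -> list[tuple[int, int]]:
    spans = []
    for prefix in ("D1", "D2", "L"):
        feats = [f for f in genome.features if f.locus_tag.split("_", 1)[-1].startswith(prefix)]
        if feats:
            spans.append((min(f.start for f in feats), max(f.end for f in feats)))
    return spans


def simulate_panel(
    ancestor: Genome,
    params: SimParams,
    n_panel: int = 8,
    seed: int = 0,
    panel_loss_rate: float = 0.15,
    panel_rate_scale: float = 2.0,
) -> list[Genome]:
    """Evolve a reference panel of more divergent relatives of the ancestor.

    Panel genomes lose genes independently at ``panel_loss_rate``, which is
    what makes phylogenetic profiles informative, while gene order is largely
    preserved so conserved-neighborhood evidence survives.
    """
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 101])
    panel = []
    for i, child in enumerate(ss.spawn(n_panel)):
        g, _ = evolve_strain(
            ancestor,
            params,
            int(child.generate_state(1)[0] & 0x7FFFFFFF),
            strain_id=f"P{i:02d}",
            rate_scale=panel_rate_scale,
            loss_rate=panel_loss_rate,
        )
        panel.append(g)
    return panel


def simulate_marker_alignment(
    params: SimParams, length_bp: int = 1550, divergence: float = 0.02
) -> dict[str, str]:
    """Aligned 16S-like marker sequences for the triplet plus the ancestor.

    Substitution-only evolution along ((B,C),A) rooted at the ancestor; the
    sequences come back already aligned (equal length, no indels).
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed & 0x7FFFFFFF, 161]))
    gc = params.gc_target
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    root = "".join(_BASES[i] for i in rng.choice(4, size=length_bp, p=p))

    def mutate(seq: str, d: float) -> str:
        return _mutate_spacer(seq, d, rng)

    a = mutate(root, divergence)
    inter = mutate(root, divergence / 2)
    b = mutate(inter, divergence / 2)
    c = mutate(inter, divergence / 2)
    return {"ancestor": root, "A": a, "B": b, "C": c}


def truth_categories(triplet: Triplet) -> dict[tuple[str, str], str]:
    """Per-gene ground-truth pan-genome category from the event history.

    Keys are (strain, locus_tag); values are ``core``, ``shared_XY`` (present
    in exactly strains X and Y) or ``specific``.  Presence of a gene lineage
    in a strain is read off the composed truth maps, so duplicates born on
    the shared internal branch correctly count as shared between B and C.
    """
    presence: dict[str, set[str]] = {}
    for strain, truth in triplet.truths.items():
        for tag, born in truth.lineage.items():
            presence.setdefault(born, set()).add(strain)
    out: dict[tuple[str, str], str] = {}
    for strain, truth in triplet.truths.items():
        for tag, born in truth.lineage.items():
            strains = presence[born]
            if len(strains) == 3:
                cat = "core"
            elif len(strains) == 2:
                cat = "shared_" + "".join(sorted(strains))
            else:
                cat = "specific"
            out[(strain, tag)] = cat
    return out


def params_sidecar(params: SimParams, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(params), fh, indent=2, sort_keys=True)
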