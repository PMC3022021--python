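# Methods

This note documents the models, conventions and deliberate design choices
behind `pangcn`, and what the simulator-based validation does and does not
demonstrate.

## Genome representation and statistics

Genomes are single circular chromosomes with typed, stranded features
(CDS/rRNA/tRNA) carrying locus tags, products, EC numbers and a `pseudo`
flag. Coordinates are 0-based half-open internally; GFF3 on disk is
1-based closed. Origin-wrapping features are representable as ordered
segment pairs but the simulator never emits them.

Summary statistics follow the conventions of genome-report tables:

* `n_cds_total = intact + pseudo` ("all genes" includes truncated ORFs);
  the mean CDS length likewise averages all CDS features and is rounded to
  the nearest integer.
* GC is computed over the whole chromosome; in-CDS GC and GC3 (third codon
  position GC) are computed over concatenated coding-strand sequences of
  *intact* CDSs only, because GC3 needs a trustworthy reading frame.
* Percentages are reported to two decimals, half-up.
* The coding fraction is exposed but not targeted at any particular
  published value, since which CDS set (overlaps, pseudogenes) published
  tables use is typically ambiguous.

## Duplicated-segment detection

A lightweight stand-in for a maximal-exact-match aligner: exact 20-mer
anchors (both strands, k configurable) are chained along a common
(anti-)diagonal with gaps up to 500 bp, and chains ≥ `min_len` are
reported with orientation and an anchor-based identity (matched anchor bp
over chain span). This identity is a conservative lower bound on alignment
identity — at 3 % sequence divergence a true identity of 97 % reports as
roughly 60 % because every mismatch voids the 20-mers covering it — so
screens on diverged copies should use a permissive `min_identity`.
Substitution-only divergence preserves the diagonal; any indel between the
copies splits the chain, which is faithful to how MEM-based aligners
render such events.

## The simulator

`simulate_ancestor` draws genes codon-by-codon: amino acids uniform, one
preferred codon per synonymous family carrying weight 1 against
`1 - codon_bias_strength` for the others. The preferred codon is drawn
among the most GC-rich codons of its family, reproducing the
high-GC3/moderate-GC profile of the emulated chromosome: at the default
bias 0.5 a study-scale genome comes out at ≈ 50.7 % GC, ≈ 51 % GC in CDS
and ≈ 66 % GC3 with ≈ 1,770 CDSs averaging ≈ 860 bp in ≈ 1.87 Mb. The
exact sampling distribution is returned, so codon-usage estimators can be
scored against it. Intergenic spacers are i.i.d. at `gc_target`.

The planted architecture mirrors the characteristic structure of the
emulated genomes: two copies of a ~25 kb gene block flanking an ~8.5 kb
unique central region whose genes carry the nine EC numbers of the
L-aspartate → L-lysine pathway (three of those steps also occur in the
backbone, giving collection-like strains the residual 3-step row of the
pathway matrix). The two block copies diverge by 2 % at the root
(`dup_block_divergence`): an ancient duplication whose copies were
identical would make copy-orthology fundamentally unresolvable for any
method, while 2 % leaves the repeat trivially detectable.

`evolve_strain` applies, per gene: Bernoulli loss; tandem duplication
(with the same 2 % birth divergence, for the same identifiability reason,
and a branch-unique tag suffix so re-duplications cannot collide);
substitutions placed by acceptance–rejection — uniform single-base
proposals in the gene body, stop-creating proposals rejected, synonymous
changes accepted with probability min(1, 1/ω) and non-synonymous with
min(1, ω) — so the realized nonsyn/syn count ratio targets ω times the
neutral expectation, which is exactly what NG86 estimates; and frameshift
pseudogenization as a single 1 bp deletion plus the `pseudo` flag.
Enzyme-annotated (EC-carrying) genes are exempt from loss and
pseudogenization on every branch, modeling purifying selection on the
pathway steps each lineage retains. Intergenic sites mutate neutrally.

`make_triplet` evolves A directly from the ancestor (half-rate branch,
planted architecture protected), deletes the central region on the way to
a shared intermediate, and evolves B and C independently from it: true
unrooted topology ((B,C),A) with the ancestor as outgroup, and B/C sharing
the intermediate's losses and substitutions. The `TruthRecord` chains
descendant → parent → root maps and tracks the *birth branch* of every
gene lineage, so a duplicate created on the shared branch counts as
shared between B and C in the ground-truth pan-genome categories.

All randomness flows from `numpy.random.SeedSequence` fan-out of a single
seed; outputs are byte-identical across runs.

What the simulator does **not** emulate: recombination, inversions,
mobile elements, intra-population polymorphism, expression-dependent
codon bias (all genes share one codon usage table, so simulated CAI
values are compressed toward 1), and rRNA/tRNA genes (the stable-RNA
fraction of simulated genomes is 0). Passing tests certify estimator
correctness under substitution/loss/duplication dynamics, not performance
on real sequencing artifacts or annotation noise.

## Orthology

BLASTP is replaced by Biopython's C implementation of local alignment
(Smith–Waterman, BLOSUM62, gap open 11 / extend 1). All-vs-all searches
are prefiltered by shared amino-acid 5-mers (candidates need ≥ 2 shared),
which makes genome-scale BBH close to linear in gene count; unrelated
proteins essentially never share two 5-mers, and at the divergences where
BBH is meaningful homologs share many. Defaults of 40 % identity and 70 %
coverage of the shorter protein are a common conservative BBH standard
and fully configurable.

Pseudogenes must remain matchable, since frameshifted orthologs are a
first-class variant category. A pseudogene is represented by its two
longest stop-free runs across the three frames, stitched in chromosomal
order with the overlapping junction trimmed symmetrically — for a single
frameshift this recovers nearly the whole ancestral protein (the
originally specified "longest single ORF" representation systematically
failed to pair two orthologs truncated at different points). Stitched
proteins are legitimately partial, so pairs involving a pseudogene are
exempt from the coverage threshold (identity still applies); the floor is
50 codons.

Ties in best-hit selection break by score, then identity, then target
tag, making every result deterministic.

## Pan-genome partition

Core families require all three pairwise BBH maps to agree. An
inconsistent triangle (two edges present and the third absent or pointing
elsewhere) is resolved by dropping its weakest-scoring edge — conservative
and deterministic, at the cost of slightly undercounting core when a
pseudogene or paralog shadows the true ortholog. Surviving pairs are
pairwise-shared; unpaired genes are strain-specific, subdivided into
unique vs. duplicated by membership in a within-strain single-linkage
paralog family.

Variant classes: `identical` (equal DNA), else `indel` when lengths
differ or the protein-guided codon alignment has gaps, else
`synonymous_only` / `amino_acid_changing` by the code table.

## NG86 dN/dS

Canonical Nei–Gojobori counting with Jukes–Cantor correction, chosen over
an ML codon model because it is transparent and exhaustively
oracle-checkable: the test suite verifies site and difference counts
against brute-force enumeration for all 61 × 61 codon pairs. Conventions:
mutations to stop codons count as non-synonymous in site counting (so
N + S = 3 · codons exactly); multi-hit difference paths through stop
codons are excluded from path averaging unless no stop-free path exists;
ω is undefined (flagged, never infinite) when dS = 0 or a p exceeds the
correction's domain, and undefined values are excluded from category
means. Per-gene ω averaged over genes carries a small positive
ratio-of-estimates bias (≈ +0.08 at ω = 1, 300-codon genes, 0.05
substitutions/site); parameter-recovery validation uses the ±0.1 band
that dominates this bias.

Category contrasts use two-sided Mann–Whitney U of a label's ω values
against the complement.

## CAI

Sharp & Li: codon counts pooled over the reference set, zero counts
replaced by 0.5 before within-family normalization, CAI as the geometric
mean of w over a gene's codons excluding Met, Trp and stops. For real
annotated genomes the reference set defaults to CDSs whose product
contains "ribosomal protein" (the pipeline tags simulated genes the same
way); published CAI values are reference-set-sensitive, so comparisons
should treat them as approximate.

## Context-network phylogeny

The three evidence channels, with the methods-gap decisions exposed as
config keys on `GcnParams`:

* **profile**: presence/absence vectors across the panel (a gene is
  present in a panel genome iff it has a passing hit there); vectors that
  are all-zero or all-one are uninformative and excluded; edge iff
  Hamming distance ≤ 1 (a mutual-information rule is selectable).
* **neighbor**: edge iff the two genes' best-hit homologs lie within 3
  genes of each other in circular gene order in ≥ 2 panel genomes.
* **fusion**: edge iff one panel protein aligns to both genes on segments
  overlapping by ≤ 10 % of either aligned region.

Network distance translates one strain's edges through the pairwise BBH
map and takes 1 − Jaccard. By default edges whose endpoints have no
ortholog in the other strain stay in the union: gene content is exactly
what distinguishes strains whose shared genes have near-identical context
against a common panel, and restricting to shared nodes (available as
`restrict_to_shared=True`) would erase the genome-decay signal that the
tree is meant to read out. Bootstrap resamples the *panel genomes* with
replacement — panel composition is the stochastic input from which all
channel evidence accrues — and per-panel evidence is cached so replicates
re-run without re-aligning anything.

Trees come from an in-package Saitou–Nei neighbor joining (deterministic
lexicographic tie-breaks, negative branch lengths clamped to zero),
cross-checked against scikit-bio's implementation on additive matrices;
JC69 is the default distance for marker alignments (K80-style models out
of scope). Supports are split frequencies written onto internal node
labels in Newick output.

## Validation problem sizes

The suite and `scripts/acceptance.py` use desk-scale configurations
chosen to finish in minutes while keeping every effect measurable:
ω recovery at 50 genes × 300 codons × 20 seeds per ω; pan-genome truth
recovery on 150-gene triplets at low divergence (0.005 substitutions/site,
2 % pseudogenization); GCN topology recovery on 100-gene triplets against
6-genome panels, 20 seeds × 20 bootstrap replicates; NJ exactness on 100
random additive matrices of 4–10 taxa; chromosome-scale statistics on one
full-size (~1.87 Mb, ~1,770 CDS) simulated strain. Genome-scale BBH runs
(≈ 1,800 × 1,800 proteins) complete in tens of seconds thanks to the
k-mer prefilter and are exercised through the CLI rather than the suite.

## Known limitations

* Anchor-based repeat identity underestimates true identity on diverged
  copies (documented above); callers wanting alignment-grade identity
  should re-align reported segment pairs.
* BBH orthology has the usual failure modes: a truncated ortholog can be
  shadowed by an intact paralog, and recent identical duplicates tie.
* The GCN edge rules and distance are pragmatic reconstructions of a
  method whose exact thresholds are not published; conclusions should be
  read at the topology level, not branch lengths.
* Real-genome validation paths (GenBank reading, ribosomal-protein CAI
  reference) are implemented but only exercised on simulated data here;
  published counts are criteria-sensitive and reproduce only
  approximately under any one criteria choice.
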