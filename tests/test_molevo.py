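"""Codon alignment, NG86 dN/dS against an exhaustive enumeration oracle,
category statistics and CAI."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from pangcn.molevo import (
    SENSE_CODONS,
    CodonWeights,
    cai,
    category_rates,
    codon_align,
    ng86_dnds,
    relative_adaptiveness,
    CodonAlignment,
)

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


def aa_of(codon: str) -> str:
    return str(Seq(codon).translate(table=11))


def oracle_sites(codon: str):
    """NG86 site counts by direct enumeration (Biopython translation)."""
    syn = 0.0
    for pos, base in itertools.product(range(3), BASES):
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if alt not in STOPS and aa_of(alt) == aa_of(codon):
            syn += 1 / 3
    return 3 - syn, syn


def oracle_diffs(ca: str, cb: str):
    """Observed differences averaged over enumerated mutation orderings,
    excluding paths through stop codons when any stop-free path exists."""
    pos = [i for i in range(3) if ca[i] != cb[i]]
    clean, stopped = [], []
    for order in itertools.permutations(pos):
        cur, nd, sd, bad = ca, 0, 0, False
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if nxt in STOPS and nxt != cb:
                bad = True
            if aa_of(nxt) == aa_of(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (stopped if bad else clean).append((nd, sd))
    paths = clean or stopped
    return (sum(p[0] for p in paths) / len(paths), sum(p[1] for p in paths) / len(paths))


class TestCodonAlign:
    def test_identical_cds_drops_stop(self):
        cds = "ATGGCTAAAGTTTAA"
        aln = codon_align(cds, cds)
        assert aln.n_codons == len(cds) // 3 - 1
        assert not aln.had_gaps

    def test_inserted_codon_costs_exactly_one_column(self):
        a = "ATG" + "GCTAAAGTTCATCGT" * 4 + "TAA"
        b = "ATG" + "GCTAAAGTTCATCGT" * 2 + "GAA" + "GCTAAAGTTCATCGT" * 2 + "TAA"
        aln = codon_align(a, b)
        assert aln.had_gaps
        assert aln.n_codons == len(a) // 3 - 1

    def test_columns_are_three_times_protein_alignment(self):
        rng = np.random.default_rng(3)
        sense = [c for c in SENSE_CODONS if c != "ATG"]
        for _ in range(5):
            codons = [sense[i] for i in rng.integers(len(sense), size=60)]
            a = "ATG" + "".join(codons) + "TAA"
            aln = codon_align(a, a)
            assert sum(len(ca) + len(cb) for ca, cb in aln.columns) == 6 * aln.n_codons


class TestNg86Oracle:
    def test_site_counts_match_enumeration_for_all_sense_codons(self):
        for codon in SENSE_CODONS:
            aln = CodonAlignment(columns=((codon, codon),))
            r = ng86_dnds(aln)
            n, s = oracle_sites(codon)
            assert r.N == pytest.approx(n, abs=1e-9)
            assert r.S == pytest.approx(s, abs=1e-9)

    def test_differences_match_path_enumeration_for_all_codon_pairs(self):
        for ca in SENSE_CODONS:
            for cb in SENSE_CODONS:
                r = ng86_dnds(CodonAlignment(columns=((ca, cb),)))
                nd, sd = oracle_diffs(ca, cb)
                assert r.Nd == pytest.approx(nd, abs=1e-9), (ca, cb)
                assert r.Sd == pytest.approx(sd, abs=1e-9), (ca, cb)

    def test_phe_synonymous_single_difference(self):
        r = ng86_dnds(CodonAlignment(columns=(("TTT", "TTC"),)))
        assert r.Sd == 1.0 and r.Nd == 0.0

    def test_identical_sequences_zero_rates(self):
        cols = tuple(("ATG", "ATG") for _ in range(10))
        r = ng86_dnds(CodonAlignment(columns=cols))
        assert r.Nd == r.Sd == 0.0
        assert r.dN == r.dS == 0.0
        assert r.omega is None and "dS_zero" in r.flags

    def test_site_count_conservation(self):
        rng = np.random.default_rng(5)
        codons = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=200)]
        cols = tuple(
            (codons[i], SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))])
            for i in range(len(codons))
        )
        r = ng86_dnds(CodonAlignment(columns=cols))
        assert r.N + r.S == pytest.approx(3 * len(cols), abs=1e-9)

    def test_jukes_cantor_value(self):
        # pN chosen to give p = 0.10 exactly on one-codon alignment is
        # awkward; check the correction function through a constructed case
        from pangcn.molevo import jukes_cantor

        assert jukes_cantor(0.10) == pytest.approx(0.107326, abs=1e-6)
        assert jukes_cantor(0.8) is None


class TestCategoryRates:
    def test_identical_pairs_mean_zero(self):
        cols = tuple(("GCT", "GCT") for _ in range(5))
        rs = [ng86_dnds(CodonAlignment(columns=cols)) for _ in range(4)]
        out = category_rates(rs, ["x"] * 4)
        assert out["x"].mean_dn == 0.0 and out["x"].mean_ds == 0.0
        assert out["x"].mean_omega is None

    def test_label_means_equal_per_pair_means(self):
        rng = np.random.default_rng(9)
        results, labels = [], []
        for lab in ("u", "v"):
            for _ in range(6):
                cols = []
                for _i in range(80):
                    ca = SENSE_CODONS[int(rng.integers(61))]
                    cb = ca if rng.random() > 0.15 else SENSE_CODONS[int(rng.integers(61))]
                    cols.append((ca, cb))
                results.append(ng86_dnds(CodonAlignment(columns=tuple(cols))))
                labels.append(lab)
        out = category_rates(results, labels)
        for lab in ("u", "v"):
            omegas = [r.omega for r, l in zip(results, labels) if l == lab and r.omega is not None]
            assert out[lab].mean_omega == pytest.approx(float(np.mean(omegas)))

    def test_detects_omega_contrast_between_gene_classes(self):
        from pangcn.genomeio import extract_cds
        from pangcn.molevo import codon_align as ca
        from pangcn.simulate import SimParams, evolve_strain, simulate_ancestor

        results, labels = [], []
        for omega, lab in ((0.1, "slow"), (0.8, "fast")):
            p = SimParams(n_genes=50, mean_gene_len_codons=150, snp_per_site=0.05,
                          loss_rate=0, dup_rate=0, pseudogenization_rate=0,
                          planted_duplication_len_bp=0, omega_true=omega, seed=13)
            anc, _ = simulate_ancestor(p)
            strain, truth = evolve_strain(anc, p, seed=29, strain_id="X")
            for tag, anc_tag in truth.ortholog_map.items():
                r = ng86_dnds(ca(extract_cds(strain, tag), extract_cds(anc, anc_tag)))
                results.append(r)
                labels.append(lab)
        out = category_rates(results, labels)
        assert out["fast"].mean_omega > out["slow"].mean_omega
        assert out["fast"].p_value < 0.01


class TestCai:
    def test_reference_with_single_codon_per_family(self):
        # a reference using only GCT for Ala forces w(GCT)=1, others 0.5/count
        ref = ["ATG" + "GCT" * 30 + "TAA"] * 12
        w = relative_adaptiveness(ref)
        assert w["GCT"] == 1.0
        assert w["GCC"] == pytest.approx(0.5 / 360)

    def test_uniform_usage_gives_weights_near_one(self):
        rng = np.random.default_rng(15)
        sense = [c for c in SENSE_CODONS]
        ref = ["".join(sense[i] for i in rng.integers(61, size=400)) for _ in range(30)]
        w = relative_adaptiveness(ref)
        assert np.mean([w.weights[c] for c in sense]) > 0.8

    def test_biased_simulator_table_argmax_recovered(self):
        from pangcn.genomeio import extract_cds
        from pangcn.simulate import SimParams, simulate_ancestor

        p = SimParams(n_genes=60, mean_gene_len_codons=250, codon_bias_strength=0.8,
                      planted_duplication_len_bp=0, seed=19)
        genome, table = simulate_ancestor(p)
        ref = [extract_cds(genome, f.locus_tag) for f in genome.cds_features()][:40]
        w = relative_adaptiveness(ref)
        fams = {}
        for c in SENSE_CODONS:
            fams.setdefault(aa_of(c), []).append(c)
        agree = total = 0
        for aa, codons in fams.items():
            if aa in "MW" or len(codons) < 2:
                continue
            total += 1
            agree += max(codons, key=lambda c: w.weights[c]) == max(
                codons, key=lambda c: table[c]
            )
        assert agree >= total - 1  # sampling noise may flip one near-tie

    def test_gene_of_optimal_codons_scores_one(self):
        ref = ["ATG" + "GCTAAACGT" * 20 + "TAA"] * 15
        w = relative_adaptiveness(ref)
        r = cai("ATG" + "GCTAAACGT" * 5 + "TAA", w)
        assert r.cai == pytest.approx(1.0)

    def test_hand_computed_geometric_mean(self):
        weights = dict.fromkeys(SENSE_CODONS, 1.0)
        weights.update({"GCT": 1.0, "GCC": 0.5, "GCA": 0.25, "AAA": 1.0})
        w = CodonWeights(weights=weights)
        r = cai("GCTGCCGCAAAA", w)
        assert r.n_codons_used == 4
        assert r.cai == pytest.approx((1 * 0.5 * 0.25 * 1) ** 0.25, abs=1e-9)
        assert r.cai == pytest.approx(0.5946, abs=1e-4)

    def test_met_trp_and_stops_excluded(self):
        weights = dict.fromkeys(SENSE_CODONS, 0.5)
        weights["ATG"] = 1.0
        weights["TGG"] = 1.0
        w = CodonWeights(weights=weights)
        r = cai("ATGTGGGCTTAA", w)
        assert r.n_codons_used == 1
        assert r.cai == pytest.approx(0.5)

    def test_scale_free_under_equal_weight_permutation(self):
        weights = dict.fromkeys(SENSE_CODONS, 1.0)
        weights.update({"GCT": 0.3, "GCC": 0.3, "GCA": 0.3, "GCG": 0.3})
        w = CodonWeights(weights=weights)
        assert cai("GCTGCCGCA", w).cai == pytest.approx(cai("GCAGCGGCT", w).cai, abs=1e-12)

    def test_zero_usable_codons_is_an_error(self):
        w = CodonWeights(weights=dict.fromkeys(SENSE_CODONS, 1.0))
        with pytest.raises(ValueError):
            cai("ATGTGG", w)
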