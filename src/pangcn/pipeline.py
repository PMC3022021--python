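"""End-to-end orchestration: simulate (or load) a strain triplet, then run
statistics, orthology, pan-genome partition, dN/dS, CAI, duplicated-segment
detection and the context-network phylogeny into one output directory with
a checksummed manifest.

Every stochastic stage receives a seed derived deterministically from the
master seed via ``SeedSequence([master, stage_index])``, so two runs with
the same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gcn as gcn_mod
from .genomeio import Genome, find_duplicated_segments, genome_stats, read_genome, write_genome, write_segments_tsv
from .molevo import cai, codon_align, ng86_dnds, relative_adaptiveness
from .orthology import HomologyCriteria, paralog_families, reciprocal_best_hits, write_ortholog_tsv
from .pangenome import classify_ortholog_pair, lysine_pathway, pathway_presence, three_way_partition
from .simulate import SimParams, make_triplet, simulate_marker_alignment, simulate_panel
from .trees import jc_matrix, neighbor_joining, write_newick
from .genomeio import extract_cds

logger = logging.getLogger("pangcn")

_STAGE_SEEDS = {"simulate": 1, "panel": 2, "gcn": 3, "marker": 4}


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence([master & 0x7FFFFFFF, _STAGE_SEEDS[stage]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    sim: SimParams | None = None
    #: alternative to simulation: {strain_id: (fasta, gff3)}
    inputs: dict[str, tuple[str, str]] | None = None
    criteria: HomologyCriteria = field(default_factory=HomologyCriteria)
    gcn_params: gcn_mod.GcnParams = field(default_factory=gcn_mod.GcnParams)
    n_panel: int = 6
    n_bootstrap: int = 50
    run_gcn: bool = True

    def validate(self) -> None:
        if self.sim is None and self.inputs is None:
            raise ValueError("config needs either simulation parameters or input paths")
        if self.inputs is not None:
            if len(self.inputs) != 3:
                raise ValueError("exactly three input genomes required")
            for sid, (fasta, gff) in self.inputs.items():
                for p in (fasta, gff):
                    if not Path(p).exists():
                        raise ValueError(f"input file for {sid} not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report dict (also written as JSON)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    report: dict = {"seed": config.seed, "stages": {}}

    def emit(path: Path, stage: str) -> None:
        manifest.append({"file": path.name, "sha256": _sha256(path), "stage": stage})

    t0 = time.time()
    # ---- stage: genomes ---------------------------------------------------
    if config.sim is not None:
        sim = SimParams(**{**asdict(config.sim), "seed": _stage_seed(config.seed, "simulate")})
        triplet = make_triplet(sim)
        genomes = dict(triplet.genomes)
        ancestor = triplet.ancestor
        for sid, g in sorted(genomes.items()):
            write_genome(g, str(out / f"{sid}.fasta"), str(out / f"{sid}.gff3"))
            emit(out / f"{sid}.fasta", "simulate")
            emit(out / f"{sid}.gff3", "simulate")
            triplet.truths[sid].to_tsv(str(out / f"{sid}.truth.tsv"))
            emit(out / f"{sid}.truth.tsv", "simulate")
    else:
        triplet = None
        ancestor = None
        genomes = {
            sid: read_genome(fasta, gff)
            for sid, (fasta, gff) in sorted(config.inputs.items())
        }
    ids = sorted(genomes)
    logger.info("genomes ready (%.1fs)", time.time() - t0)

    # ---- stage: statistics ------------------------------------------------
    stats = {sid: asdict(genome_stats(g)) for sid, g in sorted(genomes.items())}
    pd.DataFrame(stats).T.to_csv(out / "genome_stats.tsv", sep="\t")
    emit(out / "genome_stats.tsv", "stats")
    report["stages"]["stats"] = stats

    # ---- stage: duplicated segments --------------------------------------
    first = genomes[ids[0]]
    segments = find_duplicated_segments(first, min_len=2000, min_identity=40.0)
    write_segments_tsv(segments, str(out / "duplicated_segments.tsv"), first.id)
    emit(out / "duplicated_segments.tsv", "segments")
    report["stages"]["segments"] = {"strain": first.id, "n_segments": len(segments)}

    # ---- stage: orthology + partition ------------------------------------
    rbh = {}
    for i in range(3):
        for j in range(i + 1, 3):
            pairs = reciprocal_best_hits(genomes[ids[i]], genomes[ids[j]], config.criteria)
            rbh[(i, j)] = pairs
            path = out / f"rbh_{ids[i]}_{ids[j]}.tsv"
            write_ortholog_tsv(pairs, str(path))
            emit(path, "orthology")
    families = [paralog_families(genomes[s], config.criteria) for s in ids]
    partition = three_way_partition(
        genomes[ids[0]], genomes[ids[1]], genomes[ids[2]],
        rbh[(0, 1)], rbh[(0, 2)], rbh[(1, 2)],
        paralog_families_by_strain=families,
    )
    report["stages"]["pangenome"] = partition.counts
    with open(out / "venn_counts.json", "w") as fh:
        json.dump(partition.counts, fh, indent=2, sort_keys=True)
    emit(out / "venn_counts.json", "pangenome")

    # variant classes + per-pair dN/dS over the first strain pair
    rows = []
    cds = {sid: {f.locus_tag: extract_cds(genomes[sid], f.locus_tag)
                 for f in genomes[sid].cds_features()} for sid in ids}
    for pair in rbh[(0, 1)]:
        a = cds[ids[0]][pair.tag_a]
        b = cds[ids[1]][pair.tag_b]
        vclass = classify_ortholog_pair(a, b)
        row = {"tag_a": pair.tag_a, "tag_b": pair.tag_b, "variant_class": vclass}
        if vclass in ("synonymous_only", "amino_acid_changing"):
            r = ng86_dnds(codon_align(a, b))
            row.update({"dN": r.dN, "dS": r.dS, "omega": r.omega})
        rows.append(row)
    dnds_df = pd.DataFrame(rows)
    dnds_df.to_csv(out / "variants_dnds.tsv", sep="\t", index=False)
    emit(out / "variants_dnds.tsv", "molevo")
    report["stages"]["variant_classes"] = (
        dnds_df["variant_class"].value_counts().to_dict() if len(dnds_df) else {}
    )

    # ---- stage: CAI -------------------------------------------------------
    ref_cds = [
        extract_cds(first, f.locus_tag)
        for f in first.cds_features(include_pseudo=False)
        if "ribosomal protein" in f.product
    ]
    if len(ref_cds) >= 10:
        weights = relative_adaptiveness(ref_cds, reference="ribosomal proteins")
        cai_rows = [
            {"locus_tag": f.locus_tag,
             "cai": cai(extract_cds(first, f.locus_tag), weights, f.locus_tag).cai}
            for f in first.cds_features(include_pseudo=False)
        ]
        pd.DataFrame(cai_rows).to_csv(out / "cai.tsv", sep="\t", index=False)
        emit(out / "cai.tsv", "cai")
        report["stages"]["cai"] = {
            "n_genes": len(cai_rows),
            "mean_cai": float(np.mean([r["cai"] for r in cai_rows])),
        }

    # ---- stage: pathway ---------------------------------------------------
    pathway = lysine_pathway()
    matrix = pathway_presence([genomes[s] for s in ids], pathway)
    matrix.to_csv(out / "pathway_matrix.tsv", sep="\t")
    emit(out / "pathway_matrix.tsv", "pathway")
    report["stages"]["pathway_completeness"] = matrix["completeness"].to_dict()

    # ---- stage: marker NJ tree (simulated runs) ---------------------------
    if triplet is not None:
        marker = simulate_marker_alignment(
            SimParams(**{**asdict(triplet.params), "seed": _stage_seed(config.seed, "marker")})
        )
        nj = neighbor_joining(jc_matrix(marker))
        write_newick(nj, str(out / "marker_nj.nwk"))
        emit(out / "marker_nj.nwk", "trees")

    # ---- stage: context-network phylogeny ---------------------------------
    if config.run_gcn and ancestor is not None:
        panel = simulate_panel(
            ancestor, triplet.params, n_panel=config.n_panel,
            seed=_stage_seed(config.seed, "panel"),
        )
        strains = dict(genomes)
        strains["ancestor"] = ancestor
        result = gcn_mod.gcn_tree(
            strains, panel, config.gcn_params, config.criteria,
            n_bootstrap=config.n_bootstrap, seed=_stage_seed(config.seed, "gcn"),
        )
        write_newick(result.tree, str(out / "gcn_tree.nwk"))
        emit(out / "gcn_tree.nwk", "gcn")
        result.distances.to_data_frame().to_csv(out / "gcn_distances.tsv", sep="\t")
        emit(out / "gcn_distances.tsv", "gcn")
        report["stages"]["gcn"] = {
            "newick": write_newick(result.tree).strip(),
            "supports": {"|".join(sorted(k)): v for k, v in result.supports.items()},
        }

    report["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(sorted(manifest, key=lambda m: m["file"]), fh, indent=2)
    return report
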