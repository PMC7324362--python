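"""End-to-end orchestration: simulate -> ORFs -> map -> profile -> quantify
-> families -> differential -> taxonomy, with a machine-readable run report.

Every stage communicates through plain files with stable names inside the
output directory, so any stage's input can be replaced by an externally
produced file (a user-supplied SAM, an external family table).  Reruns
with the same config and seed are byte-identical; the report carries a
sha256 digest of every output file.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import context, diffreg, families, mapping, orfs, profile, quantify
from .config import PipelineConfig, GenomeSet, read_fasta, write_fasta, write_protein_fasta
from .simulate import (
    FamilySpec,
    SignalModel,
    simulate_abundances,
    simulate_community,
    simulate_counts,
    simulate_reads,
)


@dataclass
class RunReport:
    config: dict
    seed: int
    stage_seconds: dict[str, float] = field(default_factory=dict)
    file_digests: dict[str, str] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "stage_seconds": self.stage_seconds,
            "file_digests": self.file_digests,
            "metrics": self.metrics,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    seed: Optional[int] = None,
    n_taxa: int = 3,
    genome_length_nt: int = 20_000,
    n_genes: int = 45,
    smorf_fraction: float = 0.3,
    n_ribo_reads: int = 30_000,
    n_rna_reads: int = 30_000,
    read_length_nt: int = 30,
    signal_model: Optional[SignalModel] = None,
    family_spec: Optional[FamilySpec] = None,
) -> RunReport:
    """Run the demo-scale pipeline on a simulated community."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed if seed is None else seed
    signal_model = signal_model or SignalModel()
    family_spec = family_spec or FamilySpec(
        n_families=3, members_per_family=4, aa_divergence=0.10, protein_len_aa=30
    )
    report = RunReport(config=vars(config).copy(), seed=seed)
    report.config["smorf_aa_range"] = list(config.smorf_aa_range)
    report.config["homolog_length_window"] = list(config.homolog_length_window)

    def stage(name: str):
        t0 = time.monotonic()

        def done() -> None:
            report.stage_seconds[name] = round(time.monotonic() - t0, 3)

        return done

    # --- simulate ---------------------------------------------------------
    done = stage("simulate")
    genomes, truth = simulate_community(
        n_taxa=n_taxa,
        genome_length_nt=genome_length_nt,
        n_genes=n_genes,
        smorf_fraction=smorf_fraction,
        family_spec=family_spec,
        seed=seed,
    )
    simulate_abundances(truth, lognormal_sigma=1.0, seed=seed + 1)
    write_fasta(genomes, out / "genomes.fasta")
    truth.write_tsv(out / "truth.tsv")
    truth.write_gff3(out / "truth.gff3")
    ribo_reads, ribo_truth = simulate_reads(
        genomes, truth, signal_model, "ribo", read_length_nt, n_ribo_reads,
        seed=seed + 2, fastq_path=out / "ribo.fastq", sam_path=out / "ribo.truth.sam",
    )
    rna_reads, _ = simulate_reads(
        genomes, truth, signal_model, "rna", read_length_nt, n_rna_reads,
        seed=seed + 3, fastq_path=out / "rna.fastq", sam_path=out / "rna.truth.sam",
    )
    done()

    # --- ORF catalog ------------------------------------------------------
    done = stage("orfs")
    all_orfs = orfs.find_orfs_genome(genomes, config.min_orf_nt)
    smorfs = orfs.select_smorfs(all_orfs, config.smorf_aa_range)
    orfs.write_gff3(all_orfs, out / "orfs.gff3")
    write_protein_fasta(((o.orf_id, o.protein) for o in smorfs), out / "smorfs.faa")
    done()

    # --- mapping ----------------------------------------------------------
    done = stage("map")
    index = mapping.build_index(genomes, k=min(21, read_length_nt))
    ribo_aln = mapping.filter_unique_perfect(mapping.map_reads(index, ribo_reads))
    rna_aln = mapping.filter_unique_perfect(mapping.map_reads(index, rna_reads))
    mapping.write_sam(ribo_aln, genomes, out / "ribo.mapped.sam")
    mapping.write_sam(rna_aln, genomes, out / "rna.mapped.sam")
    done()

    # --- signal diagnostics ----------------------------------------------
    done = stage("profile")
    truth_orfs = truth.orfs()
    track = profile.signal_track(ribo_aln, genomes)
    meta = profile.metagene_profile(
        track, truth_orfs, config.metagene_flank_nt, config.min_reads_metagene, "start"
    )
    periodicity = profile.frame_periodicity(track, truth_orfs)
    enrichment = profile.start_enrichment(meta, signal_model.start_window_nt)
    pd.DataFrame(
        {"offset": meta.offsets, "mean_signal": meta.mean_signal}
    ).to_csv(out / "metagene_start.tsv", sep="\t", index=False)
    done()

    # --- quantification ---------------------------------------------------
    done = stage("quantify")
    lengths = pd.Series({o.orf_id: o.nt_length for o in truth_orfs})
    ribo_counts, ribo_lib = quantify.count_features(ribo_aln, truth_orfs, "ribo")
    rna_counts, rna_lib = quantify.count_features(rna_aln, truth_orfs, "rna")
    ribo_rpkm = quantify.rpkm(ribo_counts, lengths, ribo_lib)
    rna_rpkm = quantify.rpkm(rna_counts, lengths, rna_lib)
    translated = {
        oid: quantify.call_translated(v, config.translation_rpkm_threshold)
        for oid, v in ribo_rpkm.items()
    }
    quant = pd.DataFrame(
        {
            "ribo_count": ribo_counts,
            "rna_count": rna_counts,
            "ribo_rpkm": ribo_rpkm,
            "rna_rpkm": rna_rpkm,
            "translated": pd.Series(translated),
        }
    )
    quant.to_csv(out / "quantify.tsv", sep="\t")
    done()

    # --- families ---------------------------------------------------------
    done = stage("families")
    smorf_truth = [g for g in truth if g.is_smorf]
    proteins = {g.gene_id: g.protein for g in smorf_truth}
    fams = (
        families.greedy_cluster(
            proteins,
            identity_c=config.family_identity_smorf,
            length_diff_cutoff=config.cluster_length_diff_cutoff,
            long_coverage=config.cluster_long_coverage,
        )
        if proteins
        else []
    )
    fam_frame = pd.DataFrame(
        {
            "family_id": [f.family_id for f in fams],
            "representative": [f.representative_id for f in fams],
            "n_members": [len(f.member_ids) for f in fams],
            "members": [",".join(f.member_ids) for f in fams],
        }
    )
    fam_frame.to_csv(out / "families.tsv", sep="\t", index=False)
    links = [(f.representative_id, f.family_id) for f in fams]
    families.family_synthesis_evidence(fams, links, translated)
    n_synth = sum(f.synthesized for f in fams)
    done()

    # --- differential -----------------------------------------------------
    done = stage("diffreg")
    simulate_abundances(
        truth, lognormal_sigma=1.0, n_regulated=(2, 3, 0), lfc_magnitude=2.0,
        seed=seed + 4,
    )
    counts, design = simulate_counts(truth, n_replicates=3, seed=seed + 5)
    results = diffreg.nb_fit_test(counts, design, "interaction")
    diffreg.call_differential(results, config.lfc_threshold, config.fdr_threshold)
    diffreg.results_frame(results).to_csv(out / "differential.tsv", sep="\t", index=False)
    n_diff = sum(r.call != "ns" for r in results)
    done()

    # --- taxonomy ---------------------------------------------------------
    done = stage("taxonomy")
    gene_taxa = {g.gene_id: g.taxon for g in truth}
    _, abundance = context.propagate_taxonomy(gene_taxa, ribo_aln, truth_orfs, "ribo")
    grouped = context.group_other(abundance.fractions, config.other_abundance_threshold)
    pd.Series(grouped, name="fraction").rename_axis("taxon").to_csv(
        out / "taxonomy_ribo.tsv", sep="\t"
    )
    done()

    report.metrics = {
        "n_orfs": len(all_orfs),
        "n_smorfs": len(smorfs),
        "n_reads_ribo_mapped": len(ribo_aln),
        "n_reads_rna_mapped": len(rna_aln),
        "n_translated": int(sum(translated.values())),
        "n_families": len(fams),
        "n_synthesized_families": int(n_synth),
        "n_differential_interaction": int(n_diff),
        "start_enrichment": float(enrichment),
        "frame_fraction_0": periodicity.frame_fractions[0],
        "frame_fraction_1": periodicity.frame_fractions[1],
        "frame_fraction_2": periodicity.frame_fractions[2],
        "metagene_genes_used": meta.n_genes_used,
    }
    for f in sorted(out.iterdir()):
        if f.is_file() and f.suffix != ".json":
            report.file_digests[f.name] = _digest(f)
    report.to_json(out / "run_report.json")
    return report
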