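"""End-to-end workflow: simulate -> call -> filter -> anchor -> catalog ->
design/sharing -> popgen.

``run_pipeline`` executes the whole discovery workflow on synthetic
multi-cultivar data: transcript-space reads per cultivar are piled up,
called, filtered through the configured chain, anchored onto the genome
through the identity/boundary gates, collapsed across cultivars,
restricted to biallelic sites, and exported as assay candidates plus a
sharing report; a simulated germplasm panel then yields group allele
frequencies, a Rogers distance matrix and a UPGMA tree.

Every stage's counts land in a JSON manifest whose conservation ledgers
(n_raw = n_pass + n_fail at every filter) are machine-checkable, and the
run is byte-reproducible for a fixed config + seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

from . import anchor as anchor_mod
from . import io as io_mod
from .config import RunConfig
from .ngs import apply_filter_chain, call_columns, calls_to_vcf_records
from .pileup import pileup_sam
from .popgen import (
    distance_matrix,
    group_allele_frequencies,
    upgma,
    write_distance_tsv,
    write_newick,
)
from .synthetic import (
    ReadSimConfig,
    generate_cultivar_haplotypes,
    generate_genome,
    generate_panel,
    simulate_reads,
    transcript_space_truth,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class Manifest:
    seed: int
    outputs: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "outputs": self.outputs, "counts": self.counts}, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: RunConfig) -> Manifest:
    """Run the full synthetic workflow described by ``config``.

    Returns the manifest; all artifacts are written under
    ``config.outdir``.  Identical config + seed produce identical files.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.outdir, exist_ok=True)
    manifest = Manifest(seed=config.seed)
    stage = "setup"
    try:
        stage = "simulate"
        sim = config.simulate
        genome = generate_genome(
            n_genes=sim.n_genes,
            exons_per_gene=sim.exons_per_gene,
            exon_len=sim.exon_len,
            intron_len=sim.intron_len,
            seed=config.seed,
        )
        genome_fa = os.path.join(config.outdir, "genome.fasta")
        transcripts_fa = os.path.join(config.outdir, "transcripts.fasta")
        models_gff = os.path.join(config.outdir, "gene_models.gff3")
        aln_gff = os.path.join(config.outdir, "exon_alignments.gff3")
        genome.write_fasta(genome_fa)
        genome.write_fasta(transcripts_fa, transcripts=True)
        genome.write_gff3(models_gff)
        genome.write_exon_alignments_gff3(aln_gff)
        manifest.outputs.update(
            genome=genome_fa,
            transcripts=transcripts_fa,
            gene_models=models_gff,
            exon_alignments=aln_gff,
        )

        cultivar_truths = {}
        read_sets = {}
        for i, name in enumerate(sim.cultivars):
            truth = generate_cultivar_haplotypes(
                genome,
                name=name,
                ploidy=sim.ploidy,
                snp_rate=sim.snp_rate,
                nonbiallelic_fraction=sim.nonbiallelic_fraction,
                seed=config.seed * 1000 + i + 1,
            )
            cfg = ReadSimConfig(
                read_length=sim.read_length,
                depth=sim.depth,
                error_rate=sim.error_rate,
                three_prime_multiplier=sim.three_prime_multiplier,
                indel_rate=sim.indel_rate,
                multi_map_fraction=sim.multi_map_fraction,
                space=sim.space,
                seed=config.seed * 1000 + 500 + i,
            )
            read_sets[name] = simulate_reads(genome, truth, cfg, config.outdir)
            cultivar_truths[name] = truth
            manifest.counts.setdefault("planted_sites", {})[name] = len(truth.sites)

        stage = "call+filter"
        caller_cfg = config.caller_config()
        ref_fa = transcripts_fa if sim.space == "transcript" else genome_fa
        anchored_all = []
        alignments = anchor_mod.load_exon_alignments(aln_gff)
        for name in sim.cultivars:
            pileups = pileup_sam(read_sets[name].sam, ref_fa, unique_only=True)
            raw = call_columns(pileups, cultivar=name)
            passed, ledger = apply_filter_chain(raw, pileups, caller_cfg)
            vcf_path = os.path.join(config.outdir, f"{name}.snps.vcf")
            io_mod.write_vcf(
                vcf_path,
                calls_to_vcf_records(raw),
                seed=config.seed,
                config=config.content_dict(),
            )
            manifest.outputs[f"snps_{name}"] = vcf_path
            manifest.counts.setdefault("raw_calls", {})[name] = ledger.n_raw
            manifest.counts.setdefault("filtered_calls", {})[name] = ledger.n_pass
            manifest.counts.setdefault("failed_calls", {})[name] = ledger.n_fail

            stage = "anchor"
            if sim.space == "transcript":
                snps, a_ledger = anchor_mod.anchor_calls(
                    passed,
                    alignments,
                    min_identity=config.anchor.min_identity,
                    min_boundary_distance=config.anchor.min_boundary_distance,
                )
                anchored_all.extend(snps)
                manifest.counts.setdefault("anchored", {})[name] = a_ledger.n_anchored
                manifest.counts.setdefault("anchor_drops", {})[name] = dict(
                    a_ledger.drops
                )
            else:
                for call in passed:
                    anchored_all.append(
                        anchor_mod.AnchoredSnp(
                            target=call.ref_name,
                            pos=call.pos,
                            ref=call.ref,
                            alleles_by_cultivar={
                                call.cultivar: set(call.alts) | {call.ref}
                            },
                        )
                    )
            stage = "call+filter"

        stage = "catalog"
        catalog = anchor_mod.collapse_redundant(anchored_all)
        manifest.counts["unique_positions"] = len(catalog)
        high_conf = anchor_mod.biallelic_gate(catalog)
        manifest.counts["high_confidence"] = len(high_conf)
        catalog_vcf = os.path.join(config.outdir, "catalog.vcf")
        io_mod.write_vcf(
            catalog_vcf,
            anchor_mod.catalog_to_vcf_records(high_conf),
            seed=config.seed,
            config=config.content_dict(),
        )
        manifest.outputs["catalog"] = catalog_vcf

        stage = "design"
        from pyfaidx import Fasta

        candidates = anchor_mod.extract_flanks(
            high_conf, Fasta(genome_fa), flank=config.anchor.flank
        )
        design_tsv = os.path.join(config.outdir, "design_candidates.tsv")
        anchor_mod.write_design_tsv(design_tsv, candidates, flank=config.anchor.flank)
        manifest.outputs["design"] = design_tsv
        manifest.counts["design_accepted"] = sum(
            1 for c in candidates if c.rejection is None
        )
        manifest.counts["design_rejected"] = sum(
            1 for c in candidates if c.rejection is not None
        )

        stage = "sharing"
        report = anchor_mod.tabulate_sharing(high_conf, cultivars=sim.cultivars)
        sharing_tsv = os.path.join(config.outdir, "sharing.tsv")
        with open(sharing_tsv, "w") as fh:
            for line in io_mod.provenance_lines(seed=config.seed, comment_char="#"):
                fh.write(line + "\n")
            fh.write("# per-cultivar totals and cultivar-restricted counts\n")
            report.per_cultivar.to_csv(fh, sep="\t")
            fh.write("# pairwise shared and pair-restricted counts\n")
            report.pairwise.to_csv(fh, sep="\t", index=False)
        manifest.outputs["sharing"] = sharing_tsv

        stage = "popgen"
        matrix, group_map, panel_truth = generate_panel(
            groups=[(g, n) for g, n in config.panel.groups],
            n_markers=config.panel.n_markers,
            divergence=config.panel.divergence,
            missing_rate=config.panel.missing_rate,
            seed=config.seed * 1000 + 999,
        )
        geno_tsv = os.path.join(config.outdir, "panel_genotypes.tsv")
        groups_tsv = os.path.join(config.outdir, "panel_groups.tsv")
        matrix.write_tsv(geno_tsv)
        group_map.write_tsv(groups_tsv)
        freqs = group_allele_frequencies(matrix, group_map)
        mat = distance_matrix(freqs)
        dist_tsv = os.path.join(config.outdir, "rogers_distances.tsv")
        write_distance_tsv(dist_tsv, mat, seed=config.seed, config=config.content_dict())
        tree = upgma(mat)
        newick_path = os.path.join(config.outdir, "upgma.nwk")
        write_newick(tree, newick_path)
        manifest.outputs.update(
            panel_genotypes=geno_tsv,
            panel_groups=groups_tsv,
            rogers_distances=dist_tsv,
            upgma=newick_path,
        )
        manifest.counts["panel_clones"] = len(matrix.clones)
        manifest.counts["panel_markers"] = len(matrix.markers)

        manifest_path = os.path.join(config.outdir, "manifest.json")
        manifest.write(manifest_path)
        manifest.outputs["manifest"] = manifest_path
        return manifest
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise PipelineError(stage, exc) from exc
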