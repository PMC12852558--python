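"""End-to-end orchestration of the triage stages.

Stages communicate only through files (FASTA/TSV) so each one is
independently replayable: simulate -> orfs -> profile -> curate ->
abundance -> hosts. Every produced TSV carries a comment header naming
the producing stage and the configuration hash, and the run emits a
manifest JSON listing every artifact with its content hash, so reruns
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from virome_triage import abundance as ab
from virome_triage import composition as comp
from virome_triage import curation as cur
from virome_triage import host_inference as hi
from virome_triage import io_formats as iof
from virome_triage import orf_tools as orf
from virome_triage import synthetic_data as syn

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated numeric and path configuration for a pipeline run."""

    outdir: str = "triage_out"
    seed: int = 0
    depth: int = 30
    rescue_depth: int = 10
    min_len: int = 500
    identity: float = 0.90
    fungal_identity: float = 90.0
    tpm_threshold: float = 1.0
    pseudocount: float = 1.0
    feature_mode: str = "concatenated"
    # synthetic-fixture shape for the simulate stage
    n_hosts: int = 5
    n_viruses: int = 10
    orf_codons: int = 300
    noise_fraction: float = 0.1
    planted_fold: float = 112.0
    n_libraries_per_group: int = 3

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 1 <= self.rescue_depth <= self.depth:
            raise ValueError("rescue_depth must be in [1, depth]")
        if self.min_len < 0:
            raise ValueError("min_len must be >= 0")
        if not 0 < self.identity <= 1:
            raise ValueError("identity must be in (0, 1]")
        if not 0 <= self.fungal_identity <= 100:
            raise ValueError("fungal_identity must be in [0, 100]")
        if self.tpm_threshold < 0:
            raise ValueError("tpm_threshold must be >= 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.feature_mode not in comp.FEATURE_BLOCKS:
            raise ValueError(f"feature_mode must be one of {comp.FEATURE_BLOCKS}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    def config_hash(self) -> str:
        # hash only the scientific parameters, not output paths, so the
        # same analysis written elsewhere yields identical artifacts
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, cfg_hash: str, index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None, index_label=index_label)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic fixtures and return the manifest."""
    outdir = Path(config.outdir)
    fixtures = outdir / "fixtures"
    fixtures.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    artifacts: dict[str, Path] = {}

    # --- simulate ---------------------------------------------------
    gen = syn.GeneratorConfig(
        seed=config.seed,
        n_hosts=config.n_hosts,
        n_viruses=config.n_viruses,
        orf_codons=config.orf_codons,
        noise_fraction=config.noise_fraction,
        planted_fold=config.planted_fold,
        n_libraries_per_group=config.n_libraries_per_group,
        hit_table_spec=[(5, True), (25, False), (8, False), (None, True), (None, False)],
    )
    hosts, viruses = syn.make_host_recovery_dataset(gen)
    viral_fasta = fixtures / "viruses.fasta"
    iof.write_fasta(
        [iof.NucleotideSequence(id=v, residues=o.nt_sequence) for v, _, o in viruses],
        viral_fasta,
    )
    blast_text, flags_text, domains_text = syn.make_hit_tables(
        gen.hit_table_spec, seed=config.seed
    )
    (fixtures / "blastx.tsv").write_text(blast_text)
    (fixtures / "viral_flags.tsv").write_text(flags_text)
    (fixtures / "domains.tsv").write_text(domains_text)
    expr = syn.make_expression_fixture(gen)
    for lib, text in expr.quant_tables.items():
        (fixtures / f"quant_{lib}.sf").write_text(text)
    (fixtures / "metadata.tsv").write_text(expr.metadata_tsv)
    artifacts["viral_fasta"] = viral_fasta

    # --- orfs -------------------------------------------------------
    seqs = iof.read_fasta(viral_fasta)
    orf_rows = []
    all_orfs: dict[str, list[orf.OrfRecord]] = {}
    for seq in seqs:
        found = orf.find_orfs(seq, mode="complete", min_len=30, strands="both")
        all_orfs[seq.id] = found
        for o in found:
            orf_rows.append(
                {
                    "parent_id": o.parent_id,
                    "start": o.start,
                    "end": o.end,
                    "strand": o.strand,
                    "length_nt": len(o),
                    "complete": o.has_start_codon and o.has_stop_codon,
                }
            )
    orfs_tsv = outdir / "orfs.tsv"
    _write_tsv(pd.DataFrame(orf_rows), orfs_tsv, "orfs", cfg_hash)
    artifacts["orfs_tsv"] = orfs_tsv

    # --- profile ----------------------------------------------------
    profiles = []
    for seq in seqs:
        cp = comp.codon_profile(all_orfs[seq.id], entity_id=seq.id)
        dp = comp.dinuc_profile([seq], entity_id=seq.id)
        profiles.append(cp.merged(dp))
    viral_table = comp.profile_matrix(profiles, features=config.feature_mode)
    profiles_tsv = outdir / "viral_profiles.tsv"
    _write_tsv(viral_table, profiles_tsv, "profile", cfg_hash, index_label="entity_id")
    artifacts["profiles_tsv"] = profiles_tsv

    # --- curate -----------------------------------------------------
    hits = iof.read_blast_tab(fixtures / "blastx.tsv")
    viral_set = iof.read_viral_flags(fixtures / "viral_flags.tsv")
    domain_rows = iof.read_domain_annotations(fixtures / "domains.tsv")
    decisions = cur.curate(
        hits, viral_set, domain_rows, depth=config.depth, rescue_depth=config.rescue_depth
    )
    dec_df = pd.DataFrame(
        [
            {
                "qseqid": d.qseqid,
                "first_viral_rank": "" if d.first_viral_rank is None else d.first_viral_rank,
                "has_viral_domain": d.has_viral_domain,
                "verdict": d.verdict,
                "rationale": d.rationale,
            }
            for d in decisions
        ]
    )
    decisions_tsv = outdir / "decisions.tsv"
    _write_tsv(dec_df, decisions_tsv, "curate", cfg_hash)
    artifacts["decisions_tsv"] = decisions_tsv

    # --- abundance --------------------------------------------------
    tables = {
        lib: iof.read_quant_table(fixtures / f"quant_{lib}.sf")
        for lib in expr.quant_tables
    }
    metadata = iof.read_library_metadata(fixtures / "metadata.tsv")
    matrix = ab.ExpressionMatrix.from_quant_tables(
        tables, metadata=metadata, control_ids=expr.control_ids
    )
    tpm_tsv = outdir / "tpm_matrix.tsv"
    _write_tsv(matrix.values, tpm_tsv, "abundance", cfg_hash, index_label="feature_id")
    prev_tsv = outdir / "prevalence.tsv"
    _write_tsv(
        ab.prevalence(matrix, config.tpm_threshold).to_frame("n_libraries_present"),
        prev_tsv,
        "abundance",
        cfg_hash,
        index_label="feature_id",
    )
    contrast = ab.GroupContrast(frozenset(expr.group_a), frozenset(expr.group_b))
    fold_tsv = outdir / "contrast.tsv"
    _write_tsv(
        ab.group_fold_change(matrix, contrast).to_frame("fold_change"),
        fold_tsv,
        "abundance",
        cfg_hash,
        index_label="feature_id",
    )
    heat, _, _ = ab.heatmap_matrix(matrix, pseudocount=config.pseudocount)
    heat_tsv = outdir / "heatmap_matrix.tsv"
    _write_tsv(heat, heat_tsv, "abundance", cfg_hash, index_label="feature_id")
    artifacts.update(
        tpm_matrix_tsv=tpm_tsv,
        prevalence_tsv=prev_tsv,
        contrast_tsv=fold_tsv,
        heatmap_tsv=heat_tsv,
    )

    # --- hosts ------------------------------------------------------
    host_table = comp.profile_matrix(hosts, features="codon_fractions")
    shared_viral = comp.profile_matrix(profiles, features="codon_fractions")
    corr = hi.spearman_matrix(shared_viral, host_table)
    corr_tsv = outdir / "correlation.tsv"
    _write_tsv(corr.rho, corr_tsv, "hosts", cfg_hash, index_label="virus_id")
    assign_rows = []
    for virus_id in corr.row_ids:
        a = hi.predict_host(corr, virus_id)
        assign_rows.append(
            {
                "virus_id": a.virus_id,
                "best_host": a.best_host,
                "rho": a.ranked_hosts[0][1],
                "margin": a.margin,
                "tie": a.tie,
            }
        )
    assign_tsv = outdir / "assignments.tsv"
    _write_tsv(pd.DataFrame(assign_rows), assign_tsv, "hosts", cfg_hash)
    pooled = pd.concat([shared_viral, host_table])
    link, _ = hi.hier_cluster(pooled)
    newick_path = outdir / "pooled_clustering.nwk"
    newick_path.write_text(hi.linkage_to_newick(link, list(pooled.index)) + "\n")
    artifacts.update(
        correlation_tsv=corr_tsv, assignments_tsv=assign_tsv, newick=newick_path
    )

    manifest = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "artifacts": {
            name: {"path": str(path), "sha256": _sha256(path)}
            for name, path in artifacts.items()
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
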