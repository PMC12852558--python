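"""Seeded generators emulating the data shapes of a virome triage study.

Every generator is a pure function of (config, seed): identical inputs
give byte-identical outputs. The generators produce

* host codon-usage profiles — one random simplex draw per synonymous
  family (Dirichlet with a shared concentration parameter; low
  concentration means divergent, strongly biased hosts);
* viral ORFs whose codon choice follows a chosen host profile with a
  controllable resampling-noise fraction (the amino-acid sequence
  itself is uniform, so codon bias is the only host signal);
* ranked hit tables with a planted first-viral-hit rank plus matching
  viral-flag and conserved-domain tables;
* per-library quantification tables with control genes at stable
  abundance and infection-associated features at a planted fold change
  between two library groups, with lognormal noise.

These emulate the statistical structure each pipeline stage assumes —
codon bias as a host signature, rank-based curation evidence, planted
expression contrasts — not the biology of real contigs (no assembly
artefacts, chimeras, or length variation).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from virome_triage.composition import CompositionProfile, synonymous_families
from virome_triage.io_formats import NucleotideSequence
from virome_triage.orf_tools import OrfRecord

__all__ = [
    "GeneratorConfig",
    "ExpressionFixture",
    "make_host_profiles",
    "sample_viral_orfs",
    "make_host_recovery_dataset",
    "make_hit_tables",
    "make_expression_fixture",
]

_AA_ORDER = tuple(sorted(synonymous_families(1)))  # 20 amino acids
_FAMILIES = synonymous_families(1)


@dataclass
class GeneratorConfig:
    """Knobs for all synthetic generators.

    ``host_divergence`` is the Dirichlet concentration of per-family
    codon distributions: 0.1 gives strongly biased, well-separated
    hosts; large values approach uniform usage (RSCU -> 1).
    ``noise_fraction`` is the probability a viral codon is drawn
    uniformly from its synonymous family instead of from the host
    profile. ``lognormal_sigma`` is expression noise on the log10
    scale.
    """

    seed: int = 0
    n_hosts: int = 5
    host_divergence: float = 0.1
    n_viruses: int = 30
    orf_codons: int = 300
    noise_fraction: float = 0.1
    planted_fold: float = 112.0
    n_libraries_per_group: int = 3
    n_viral_features: int = 5
    baseline_tpm: float = 2.0
    lognormal_sigma: float = 0.5
    hit_table_spec: list[tuple[int | None, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("n_hosts", "n_viruses", "orf_codons", "n_libraries_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in [0, 1]")
        if self.planted_fold <= 0:
            raise ValueError("planted_fold must be > 0")
        for rank, _ in self.hit_table_spec:
            if rank is not None and not 1 <= rank <= 30:
                raise ValueError(f"planted rank {rank} outside [1, 30]")


def make_host_profiles(config: GeneratorConfig) -> list[CompositionProfile]:
    """Draw per-host codon-usage profiles.

    For each host and each synonymous family, codon probabilities are a
    Dirichlet(concentration) draw. Reported codon fractions assume
    uniform amino-acid usage (fraction = p(codon | aa) / 20), matching
    the generative model of :func:`sample_viral_orfs`.
    """
    rng = np.random.default_rng(config.seed)
    profiles = []
    for i in range(config.n_hosts):
        fractions: dict[str, float] = {}
        rscu: dict[str, float] = {}
        for aa in _AA_ORDER:
            codons = _FAMILIES[aa]
            p = rng.dirichlet(np.full(len(codons), config.host_divergence))
            for codon, prob in zip(codons, p):
                fractions[codon] = prob / len(_AA_ORDER)
                rscu[codon] = prob * len(codons)
        counts = {c: int(round(f * 1_000_000)) for c, f in fractions.items()}
        profiles.append(
            CompositionProfile(
                entity_id=f"host{i + 1}",
                codon_counts=counts,
                codon_fractions=fractions,
                rscu=rscu,
                n_codons=sum(counts.values()),
            )
        )
    return profiles


def _conditional_codon_probs(profile: CompositionProfile) -> dict[str, np.ndarray]:
    """p(codon | amino acid) from a profile's codon fractions."""
    out = {}
    for aa in _AA_ORDER:
        codons = _FAMILIES[aa]
        weights = np.array([profile.codon_fractions.get(c, 0.0) for c in codons])
        total = weights.sum()
        out[aa] = (
            weights / total if total > 0 else np.full(len(codons), 1 / len(codons))
        )
    return out


def sample_viral_orfs(
    host_profile: CompositionProfile,
    orf_codons: int,
    noise_fraction: float,
    seed: int,
    virus_id: str = "virus1",
) -> tuple[NucleotideSequence, OrfRecord]:
    """Sample one complete viral ORF biased toward a host profile.

    The amino-acid sequence is uniform over the 20; each codon is drawn
    from the host's family distribution with probability
    (1 - noise_fraction) and uniformly within the family otherwise. An
    ATG start and a TAA stop flank the body.
    """
    if orf_codons < 10:
        raise ValueError("orf_codons must be >= 10")
    rng = np.random.default_rng(seed)
    conditional = _conditional_codon_probs(host_profile)
    aas = rng.choice(len(_AA_ORDER), size=orf_codons)
    noisy = rng.random(orf_codons) < noise_fraction
    codons = []
    for aa_idx, is_noisy in zip(aas, noisy):
        aa = _AA_ORDER[aa_idx]
        family = _FAMILIES[aa]
        probs = (
            np.full(len(family), 1 / len(family)) if is_noisy else conditional[aa]
        )
        codons.append(family[rng.choice(len(family), p=probs)])
    nt = "ATG" + "".join(codons) + "TAA"
    seq = NucleotideSequence(id=virus_id, residues=nt)
    orf = OrfRecord(
        parent_id=virus_id,
        start=0,
        end=len(nt),
        strand="+",
        has_start_codon=True,
        has_stop_codon=True,
        nt_sequence=nt,
        genetic_code=1,
    )
    return seq, orf


def make_host_recovery_dataset(
    config: GeneratorConfig,
) -> tuple[list[CompositionProfile], list[tuple[str, int, OrfRecord]]]:
    """Hosts plus viruses with known generating-host labels.

    Viruses are assigned to hosts round-robin; returns the host
    profiles and a list of (virus_id, true_host_index, OrfRecord).
    """
    hosts = make_host_profiles(config)
    rng = np.random.default_rng(config.seed + 1)
    viruses = []
    for v in range(config.n_viruses):
        host_idx = v % config.n_hosts
        _, orf = sample_viral_orfs(
            hosts[host_idx],
            config.orf_codons,
            config.noise_fraction,
            seed=int(rng.integers(0, 2**31 - 1)),
            virus_id=f"virus{v + 1}",
        )
        viruses.append((f"virus{v + 1}", host_idx, orf))
    return hosts, viruses


def make_hit_tables(
    hit_table_spec: list[tuple[int | None, bool]], seed: int
) -> tuple[str, str, str]:
    """Synthetic ranked hit tables with planted viral evidence.

    One query per spec entry; each query gets 30 hits with strictly
    decreasing bitscores. The subject at the planted rank (if any) is
    flagged viral in the accompanying flag table; a conserved viral
    domain row is emitted for queries marked with a domain.

    Returns (blast tabular text, viral-flag TSV, domain TSV).
    """
    rng = np.random.default_rng(seed)
    blast_lines = []
    flag_lines = ["sseqid\tis_viral"]
    domain_lines = ["qseqid\tdomain_accession\tis_viral_domain"]
    for q, (rank, has_domain) in enumerate(hit_table_spec, start=1):
        if rank is not None and not 1 <= rank <= 30:
            raise ValueError(f"planted rank {rank} outside [1, 30]")
        qseqid = f"query{q}"
        for r in range(1, 31):
            viral_here = rank == r
            sseqid = f"{'viral' if viral_here else 'other'}_subj_q{q}_r{r}"
            bitscore = 300.0 - r  # strictly decreasing
            evalue = 10.0 ** (-50 + r)
            pident = float(np.round(50 + 40 * rng.random(), 1))
            aln_len = int(rng.integers(80, 400))
            blast_lines.append(
                "\t".join(
                    [
                        qseqid,
                        sseqid,
                        f"{pident:.1f}",
                        str(aln_len),
                        str(int(aln_len * (1 - pident / 100))),
                        "0",
                        "1",
                        str(aln_len),
                        "1",
                        str(aln_len),
                        f"{evalue:.3g}",
                        f"{bitscore:.1f}",
                    ]
                )
            )
            flag_lines.append(f"{sseqid}\t{'true' if viral_here else 'false'}")
        if has_domain:
            domain_lines.append(f"{qseqid}\tcl40470\ttrue")
    return (
        "\n".join(blast_lines) + "\n",
        "\n".join(flag_lines) + "\n",
        "\n".join(domain_lines) + "\n",
    )


@dataclass
class ExpressionFixture:
    """Synthetic quantification tables with a planted group contrast."""

    quant_tables: dict[str, str]  # library_id -> quant.sf-style TSV text
    metadata_tsv: str
    truth_tpm: pd.DataFrame  # features x libraries planted TPM
    viral_ids: list[str]
    control_ids: list[str]
    group_a: list[str]
    group_b: list[str]


_CONTROLS = {"ACT7": (1500, 200.0), "H1": (1000, 150.0), "COX2": (800, 300.0)}
_FILLER_LENGTH = 2000
_LIBRARY_READS = 1_000_000


def make_expression_fixture(config: GeneratorConfig) -> ExpressionFixture:
    """Build per-library quant tables with a planted fold change.

    Control genes hold stable lognormal TPM across all libraries;
    viral features sit at ``baseline_tpm`` in group B and
    ``baseline_tpm * planted_fold`` in group A, each with lognormal
    noise of ``lognormal_sigma`` on the log10 scale. A bulk filler
    feature absorbs the rest of each library so planted TPMs survive
    re-normalisation, and read counts are back-computed so that TPM
    recomputed from counts reproduces the planted values.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_libraries_per_group
    group_a = [f"libA{i + 1}" for i in range(n)]
    group_b = [f"libB{i + 1}" for i in range(n)]
    libraries = group_a + group_b
    viral_ids = [f"virusF{i + 1}" for i in range(config.n_viral_features)]
    control_ids = list(_CONTROLS)
    feature_ids = viral_ids + control_ids + ["bulk"]
    lengths = {
        **{v: 1200 + 150 * i for i, v in enumerate(viral_ids)},
        **{c: _CONTROLS[c][0] for c in control_ids},
        "bulk": _FILLER_LENGTH,
    }

    def noisy(base: float) -> float:
        return base * 10.0 ** (config.lognormal_sigma * rng.standard_normal())

    tpm = pd.DataFrame(0.0, index=feature_ids, columns=libraries)
    for lib in libraries:
        in_group_a = lib in group_a
        for v in viral_ids:
            base = config.baseline_tpm * (config.planted_fold if in_group_a else 1.0)
            tpm.loc[v, lib] = noisy(base)
        for c in control_ids:
            tpm.loc[c, lib] = noisy(_CONTROLS[c][1])
        assigned = tpm[lib].sum()
        if assigned >= 1e6:
            raise ValueError("planted TPMs exceed one million; lower the fold/baseline")
        tpm.loc["bulk", lib] = 1e6 - assigned

    quant_tables = {}
    for lib in libraries:
        # counts proportional to TPM * length reproduce the planted TPM
        weights = np.array([tpm.loc[f, lib] * lengths[f] for f in feature_ids])
        reads = weights / weights.sum() * _LIBRARY_READS
        buf = io.StringIO()
        buf.write("Name\tLength\tEffectiveLength\tTPM\tNumReads\n")
        for f, c in zip(feature_ids, reads):
            buf.write(
                f"{f}\t{lengths[f]}\t{lengths[f]}\t{tpm.loc[f, lib]:.10g}\t{c:.10g}\n"
            )
        quant_tables[lib] = buf.getvalue()

    meta_lines = ["library_id\tproject_id\ttreatment"]
    for lib in group_a:
        meta_lines.append(f"{lib}\tPRJSYN1\tinoculated")
    for lib in group_b:
        meta_lines.append(f"{lib}\tPRJSYN1\tcontrol")

    return ExpressionFixture(
        quant_tables=quant_tables,
        metadata_tsv="\n".join(meta_lines) + "\n",
        truth_tpm=tpm,
        viral_ids=viral_ids,
        control_ids=control_ids,
        group_a=group_a,
        group_b=group_b,
    )
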