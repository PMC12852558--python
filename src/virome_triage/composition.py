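"""Codon-usage and dinucleotide-composition profiling.

The quantitative core of compositional host inference: per-entity codon
fractions, relative synonymous codon usage (RSCU), and Karlin-style
dinucleotide odds ratios

    odds(XY) = f(XY) / (f(X) * f(Y))

where f(XY) is the pooled overlapping-dinucleotide frequency and f(X)
the pooled mononucleotide frequency. Departure of odds(XY) from 1 marks
compositional bias and acts as a genome signature shared between a
virus and its host.

RSCU(c) = count(c) * family_size / family_total over the synonymous
family of c's amino acid, so every family with at least one count has
mean RSCU exactly 1. Stop codons are excluded by default (RSCU is
defined over sense codons); ``include_stops`` restores them as a
pseudo-family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from virome_triage.io_formats import NucleotideSequence
from virome_triage.orf_tools import OrfRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CompositionProfile",
    "codon_profile",
    "dinuc_profile",
    "profile_matrix",
    "ALL_CODONS",
    "ALL_DINUCLEOTIDES",
    "synonymous_families",
]

_BASES = "ACGT"
ALL_CODONS = tuple(sorted("".join(c) for c in itertools.product(_BASES, repeat=3)))
ALL_DINUCLEOTIDES = tuple(sorted("".join(d) for d in itertools.product(_BASES, repeat=2)))

FEATURE_BLOCKS = ("codon_fractions", "rscu", "dinuc_odds", "concatenated")


def synonymous_families(genetic_code: int = 1, include_stops: bool = False):
    """Map amino acid -> tuple of synonymous codons under a code table."""
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    families: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        families.setdefault(aa, []).append(codon)
    if include_stops:
        families["*"] = list(table.stop_codons)
    return {aa: tuple(sorted(codons)) for aa, codons in families.items()}


@dataclass
class CompositionProfile:
    """Compositional summary of one entity (virus, genome, gene set).

    Either the codon block (``codon_counts``/``codon_fractions``/
    ``rscu``) or the nucleotide block (``mono_freqs``/``dinuc_freqs``/
    ``dinuc_odds``) may be empty, depending on which profiler produced
    it; :meth:`merged` combines the two. A dinucleotide odds value of
    ``None`` means the denominator was zero (missing).
    """

    entity_id: str
    codon_counts: dict[str, int] = field(default_factory=dict)
    codon_fractions: dict[str, float] = field(default_factory=dict)
    rscu: dict[str, float] = field(default_factory=dict)
    mono_freqs: dict[str, float] = field(default_factory=dict)
    dinuc_freqs: dict[str, float] = field(default_factory=dict)
    dinuc_odds: dict[str, float | None] = field(default_factory=dict)
    n_codons: int = 0
    n_dinucs: int = 0

    def merged(self, other: "CompositionProfile") -> "CompositionProfile":
        """Combine a codon-block profile with a nucleotide-block profile."""
        if self.entity_id != other.entity_id:
            raise ValueError("cannot merge profiles of different entities")
        return CompositionProfile(
            entity_id=self.entity_id,
            codon_counts=self.codon_counts or other.codon_counts,
            codon_fractions=self.codon_fractions or other.codon_fractions,
            rscu=self.rscu or other.rscu,
            mono_freqs=self.mono_freqs or other.mono_freqs,
            dinuc_freqs=self.dinuc_freqs or other.dinuc_freqs,
            dinuc_odds=self.dinuc_odds or other.dinuc_odds,
            n_codons=self.n_codons or other.n_codons,
            n_dinucs=self.n_dinucs or other.n_dinucs,
        )


def codon_profile(
    orfs: list[OrfRecord],
    entity_id: str = "",
    genetic_code: int = 1,
    include_stops: bool = False,
) -> CompositionProfile:
    """Count in-frame codons over a set of ORFs (pooled at count level).

    Pooling is concatenation semantics: counts are summed over ORFs,
    never averaged per-ORF, matching genome-scale codon-usage runs.
    Terminal stop codons are dropped, and with the default
    ``include_stops=False`` every stop codon is excluded so fractions
    and RSCU are over sense codons. Codons containing a non-ACGT symbol
    are skipped.
    """
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    stops = set(table.stop_codons)
    counts: dict[str, int] = {}
    for orf in orfs:
        nt = orf.nt_sequence
        if len(nt) % 3 != 0:
            raise ValueError(f"ORF on {orf.parent_id!r} has length not divisible by 3")
        end = len(nt) - 3 if orf.has_stop_codon else len(nt)
        for i in range(0, end, 3):
            codon = nt[i : i + 3]
            if set(codon) - set(_BASES):
                continue
            if codon in stops and not include_stops:
                continue
            counts[codon] = counts.get(codon, 0) + 1
    n_codons = sum(counts.values())
    fractions = (
        {c: k / n_codons for c, k in counts.items()} if n_codons else {}
    )
    rscu: dict[str, float] = {}
    for codons in synonymous_families(genetic_code, include_stops).values():
        family_total = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            if family_total == 0:
                rscu[c] = 0.0
            else:
                rscu[c] = counts.get(c, 0) * len(codons) / family_total
    if n_codons == 0:
        rscu = {}
    return CompositionProfile(
        entity_id=entity_id,
        codon_counts=counts,
        codon_fractions=fractions,
        rscu=rscu,
        n_codons=n_codons,
    )


def dinuc_profile(
    seqs: list[NucleotideSequence], entity_id: str = ""
) -> CompositionProfile:
    """Pooled mono/dinucleotide frequencies and odds ratios.

    Overlapping dinucleotides are counted linearly per sequence (no
    wraparound) and pooled; any window containing a non-ACGT symbol is
    skipped and excluded from ``n_dinucs``. An odds ratio whose
    denominator is zero is reported as ``None``.
    """
    mono: dict[str, int] = {b: 0 for b in _BASES}
    dinuc: dict[str, int] = {}
    n_dinucs = 0
    for seq in seqs:
        s = seq.residues
        for ch in s:
            if ch in mono:
                mono[ch] += 1
        for i in range(len(s) - 1):
            window = s[i : i + 2]
            if set(window) - set(_BASES):
                continue
            dinuc[window] = dinuc.get(window, 0) + 1
            n_dinucs += 1
    n_mono = sum(mono.values())
    mono_freqs = {b: k / n_mono for b, k in mono.items()} if n_mono else {}
    dinuc_freqs = (
        {d: k / n_dinucs for d, k in dinuc.items()} if n_dinucs else {}
    )
    odds: dict[str, float | None] = {}
    if n_dinucs:
        for d in ALL_DINUCLEOTIDES:
            denom = mono_freqs.get(d[0], 0.0) * mono_freqs.get(d[1], 0.0)
            odds[d] = dinuc_freqs.get(d, 0.0) / denom if denom > 0 else None
    return CompositionProfile(
        entity_id=entity_id,
        mono_freqs=mono_freqs,
        dinuc_freqs=dinuc_freqs,
        dinuc_odds=odds,
        n_dinucs=n_dinucs,
    )


def _block(profile: CompositionProfile, name: str, keys) -> dict:
    source = getattr(profile, name)
    if name in {"codon_fractions", "rscu"}:
        if profile.n_codons == 0:
            raise ValueError(f"profile {profile.entity_id!r} has no codon data")
        return {k: source.get(k, 0.0) for k in keys}
    if profile.n_dinucs == 0:
        raise ValueError(f"profile {profile.entity_id!r} has no dinucleotide data")
    return {k: source.get(k) for k in keys}


def profile_matrix(
    profiles: list[CompositionProfile],
    features: str = "concatenated",
    missing_policy: str | float = "drop",
) -> pd.DataFrame:
    """Assemble an entities-by-features numeric table.

    ``features`` selects the block: ``codon_fractions`` (64 columns),
    ``rscu`` (sense codons), ``dinuc_odds`` (16 columns) or
    ``concatenated`` (codon fractions followed by dinucleotide odds).
    Column order is fixed alphabetical within each block. Odds values
    missing in any profile are handled per ``missing_policy``: the
    default ``"drop"`` removes the column (logged); a numeric policy
    imputes that value.
    """
    if not profiles:
        raise ValueError("profile list is empty")
    if features not in FEATURE_BLOCKS:
        raise ValueError(f"features must be one of {FEATURE_BLOCKS}")
    rows = []
    for p in profiles:
        row: dict[str, float | None] = {}
        if features in {"codon_fractions", "concatenated"}:
            row.update(_block(p, "codon_fractions", ALL_CODONS))
        if features == "rscu":
            sense = sorted(
                c for fam in synonymous_families().values() for c in fam
            )
            row.update(_block(p, "rscu", sense))
        if features in {"dinuc_odds", "concatenated"}:
            row.update(_block(p, "dinuc_odds", ALL_DINUCLEOTIDES))
        rows.append(row)
    df = pd.DataFrame(rows, index=[p.entity_id for p in profiles])
    missing = df.columns[df.isna().any()]
    if len(missing):
        if missing_policy == "drop":
            logger.info(
                "dropping %d feature column(s) with missing values: %s",
                len(missing),
                ", ".join(missing),
            )
            df = df.drop(columns=missing)
        else:
            df = df.fillna(float(missing_policy))
    return df.astype(float)
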