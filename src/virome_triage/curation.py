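"""Candidate-filtering logic for viral element triage.

Implements the decision rules used to separate genuine viral sequences
from noise after a similarity search:

* a candidate is retained when it has at least one viral hit within the
  top 30 ranked protein-level matches AND a conserved viral domain;
* without a conserved viral domain, it is retained only when the first
  viral hit falls within the top 10 matches;
* candidates failing both rules are excluded.

Also provided: the strictly-greater-than-500-nt exogenous contig
filter, CD-HIT-style greedy redundancy clustering at a 90% identity
threshold, and the over-90%-identity candidate-host selector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from virome_triage.io_formats import (
    DomainAnnotation,
    NucleotideSequence,
    TabularHit,
    ViralSubjectSet,
)

__all__ = [
    "HitList",
    "CurationDecision",
    "Cluster",
    "first_viral_rank",
    "classify_candidate",
    "curate",
    "length_filter",
    "greedy_cluster",
    "pairwise_identity",
    "select_candidate_hosts",
]

ORDER_POLICIES = ("file_order", "bitscore_desc")

VERDICTS = ("retained_domain_rule", "retained_top10_rule", "excluded")


@dataclass
class HitList:
    """Ranked similarity hits for one query.

    ``order_policy`` controls ranking: ``file_order`` replays the input
    file bit-exactly; ``bitscore_desc`` (default) sorts by bitscore
    descending with ties broken by evalue ascending then input order.
    """

    qseqid: str
    hits: list[TabularHit]
    order_policy: str = "bitscore_desc"

    def __post_init__(self) -> None:
        if self.order_policy not in ORDER_POLICIES:
            raise ValueError(f"order_policy must be one of {ORDER_POLICIES}")

    def ordered(self) -> list[TabularHit]:
        if self.order_policy == "file_order":
            return list(self.hits)
        return sorted(self.hits, key=lambda h: (-h.bitscore, h.evalue))


@dataclass(frozen=True)
class CurationDecision:
    qseqid: str
    first_viral_rank: int | None
    has_viral_domain: bool
    verdict: str
    rationale: str


@dataclass
class Cluster:
    """A redundancy cluster; the representative is the longest member."""

    representative_id: str
    member_ids: list[str]
    threshold: float


def first_viral_rank(
    hitlist: HitList, viral: ViralSubjectSet, depth: int = 30
) -> int | None:
    """1-based rank of the first viral hit within the top ``depth`` hits.

    Returns ``None`` when no viral subject appears in that window (or
    the hit list is empty).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    for rank, hit in enumerate(hitlist.ordered()[:depth], start=1):
        if hit.sseqid in viral:
            return rank
    return None


def classify_candidate(
    first_viral_rank_top30: int | None,
    has_viral_domain: bool,
    depth: int = 30,
    rescue_depth: int = 10,
) -> str:
    """Apply the retention rules to one candidate.

    ``retained_domain_rule``: a viral hit anywhere in the top ``depth``
    plus a conserved viral domain. ``retained_top10_rule``: no domain,
    but the first viral hit is within ``rescue_depth``. Anything else
    is ``excluded`` — in particular, a viral domain with no viral hit
    at all does not rescue a candidate.
    """
    rank = first_viral_rank_top30
    if rank is not None and not 1 <= rank <= depth:
        raise ValueError(f"first viral rank {rank} outside [1, {depth}]")
    if rank is not None and has_viral_domain:
        return "retained_domain_rule"
    if rank is not None and rank <= rescue_depth and not has_viral_domain:
        return "retained_top10_rule"
    return "excluded"


def curate(
    hits_by_query: dict[str, list[TabularHit]],
    viral: ViralSubjectSet,
    domains: list[DomainAnnotation],
    depth: int = 30,
    rescue_depth: int = 10,
    order_policy: str = "bitscore_desc",
) -> list[CurationDecision]:
    """Run the full decision rule over every query in a hit table."""
    viral_domain_queries = {
        d.qseqid for d in domains if d.is_viral_domain
    }
    decisions = []
    for qseqid, hits in hits_by_query.items():
        hitlist = HitList(qseqid=qseqid, hits=hits, order_policy=order_policy)
        rank = first_viral_rank(hitlist, viral, depth=depth)
        has_domain = qseqid in viral_domain_queries
        verdict = classify_candidate(
            rank, has_domain, depth=depth, rescue_depth=rescue_depth
        )
        rationale = _rationale(rank, has_domain, depth, rescue_depth, verdict)
        decisions.append(
            CurationDecision(
                qseqid=qseqid,
                first_viral_rank=rank,
                has_viral_domain=has_domain,
                verdict=verdict,
                rationale=rationale,
            )
        )
    return decisions


def _rationale(rank, has_domain, depth, rescue_depth, verdict) -> str:
    if verdict == "retained_domain_rule":
        return f"viral hit at rank {rank} (<= {depth}) and conserved viral domain"
    if verdict == "retained_top10_rule":
        return f"no viral domain but first viral hit at rank {rank} (<= {rescue_depth})"
    if rank is None:
        return f"no viral hit within the top {depth}"
    return (
        f"first viral hit at rank {rank} (> {rescue_depth}) without a "
        "conserved viral domain"
    )


def length_filter(
    seqs: list[NucleotideSequence], min_exclusive: int = 500
) -> list[NucleotideSequence]:
    """Retain sequences strictly longer than ``min_exclusive`` nt."""
    return [s for s in seqs if len(s) > min_exclusive]


def _make_aligner() -> Align.PairwiseAligner:
    # Scores only select the alignment; identity is computed from its
    # columns (matches / alignment length, gap columns included).
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity: exact matches / alignment columns."""
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    total = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / total if total else 0.0


def greedy_cluster(
    seqs: list[NucleotideSequence], identity_threshold: float = 0.90
) -> list[Cluster]:
    """CD-HIT-style greedy incremental clustering.

    Sequences are sorted by length descending (ties by id ascending);
    each joins the first existing cluster whose representative it
    matches at >= ``identity_threshold`` global-alignment identity,
    otherwise it founds a new cluster. Because of the sort order the
    founder is always the longest member. Output clusters partition the
    input and the procedure is deterministic.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    aligner = _make_aligner()
    ordered = sorted(seqs, key=lambda s: (-len(s), s.id))
    clusters: list[Cluster] = []
    reps: list[str] = []
    for seq in ordered:
        placed = False
        for cluster, rep in zip(clusters, reps):
            if pairwise_identity(seq.residues, rep, aligner) >= identity_threshold:
                cluster.member_ids.append(seq.id)
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(
                    representative_id=seq.id,
                    member_ids=[seq.id],
                    threshold=identity_threshold,
                )
            )
            reps.append(seq.residues)
    return clusters


def select_candidate_hosts(
    hits_by_query: dict[str, list[TabularHit]],
    min_identity: float = 90.0,
    allowed_subjects: set[str] | None = None,
) -> set[str]:
    """Subjects attaining strictly more than ``min_identity`` percent
    identity in at least one hit.

    ``allowed_subjects``, when given, further restricts the result —
    e.g. to species with an available mitochondrial genome.
    """
    selected = {
        hit.sseqid
        for hits in hits_by_query.values()
        for hit in hits
        if hit.pident > min_identity
    }
    if allowed_subjects is not None:
        selected &= set(allowed_subjects)
    return selected
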