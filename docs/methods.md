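# Methods

## Scope and assumptions

The package covers the decision-making and compositional analytics of
virome triage, taking the outputs of external search and quantification
tools as inputs. It deliberately does not run similarity searches,
assemble reads, or estimate abundances from raw reads: ranked hit
tables, domain calls and per-library quantification tables are parsed,
never produced. All sequence math runs on a DNA alphabet — RNA `U` is
normalised to `T` at ingest — and all internal coordinates are 0-based
half-open on the forward strand, with 1-based inclusive tabular
coordinates converted at the boundary.

## Curation rules

A candidate's evidence is summarised by two binary-ish facts: the rank
*r* of its first viral hit among the top `depth` ranked protein-level
matches, and whether a conserved viral domain was detected. Retention is
the pure function: retained-by-domain iff *r* exists and a domain is
present; retained-by-rank iff no domain but *r* ≤ `rescue_depth`;
excluded otherwise. A viral domain alone never rescues a candidate with
no viral hit — domain databases contain profiles that fire on cellular
proteins, so a hit-free candidate has no sequence-level viral evidence.

Hit ranking defaults to bitscore descending with ties broken by evalue
ascending, then input order; search tools emit per-query output already
sorted this way, so the default reproduces their ranking even if rows
were shuffled, while `file_order` replays a given file bit-exactly.

Defaults: `depth` 30, `rescue_depth` 10, exogenous length filter
strictly > 500 nt, redundancy threshold 0.90, candidate-host identity
strictly > 90%. The two strict inequalities are deliberate: "longer
than" and "over" are read as exclusive bounds.

## Redundancy clustering

Greedy incremental clustering in the CD-HIT style: sequences sorted by
length descending (ties by id ascending) so every cluster founder is
its longest member; each sequence joins the first cluster whose
representative it matches at ≥ threshold identity, else founds a new
cluster. Identity is exact matches divided by alignment columns of a
global alignment (match +1, mismatch 0, gap open −10, extend −1 — the
scores only select the alignment). Exact alignment is affordable at
triage scale and makes the procedure checkable against an all-pairs
identity oracle; word-filtering heuristics of production clusterers are
out of scope. The threshold is nucleotide identity, as the clustered
records are nucleotide ORFs.

## ORF prediction

`complete` mode returns ATG-to-first-in-frame-stop spans with the stop
codon included in the reported length; by default only the longest ORF
per (frame, stop) is reported and a flag exposes nested internal
starts. `region` mode returns maximal stop-free codon runs between
stops, flanking stops excluded, which is the getorf-like behaviour used
for genome-wide screens (default length window 100–6000 nt). Region
records therefore never carry a stop-codon flag. Any ORF containing a
non-ACGT symbol in a codon is dropped rather than translated through
ambiguity. The standard genetic code is the default; the mold
mitochondrial code (TGA = Trp) is exposed because mitochondria-resident
RNA viruses are translated by the organelle's machinery.

## Composition statistics

Codon counting pools in-frame counts across an entity's ORFs
(concatenation semantics, not per-ORF averaging), drops terminal stop
codons, and by default excludes stop codons entirely so RSCU is defined
over sense codons; a flag restores stops as a pseudo-family for
compatibility with tools that count them. RSCU(c) = n(c)·k/Σ with k the
synonymous family size; unobserved families report 0 by the 0/0 → 0
convention, and every observed family has mean RSCU exactly 1.

Dinucleotides are counted in overlapping windows linearly per sequence
(no wraparound across sequence boundaries), pooled across sequences;
windows containing ambiguity codes are excluded from both counts and
the denominator. The reported statistic is the odds ratio
f(XY)/(f(X)f(Y)) with mononucleotide frequencies from the pooled single-
base counts — the expected-frequency ratio, not a comparison against a
uniform 1/16. An odds ratio with a zero denominator is missing; the
profile-matrix builder either drops such feature columns (default,
logged) or imputes a configured value.

## Abundance

TPM is recomputed from counts and lengths whenever both are available,
guaranteeing each column sums to 10⁶ over the loaded feature set; an
externally supplied TPM column can be trusted instead. Control-relative
activity divides a feature's TPM by the arithmetic mean TPM of the
configured control genes per library, reported missing where that mean
is zero. Fold changes are ratios of arithmetic group means of TPM (not
of log-TPM), with an optional pseudocount on both means and a missing
result on zero denominators; this matches how such ratios are usually
quoted (a ratio of average abundances) and is scale-invariant at
pseudocount 0. The presence floor defaults to TPM ≥ 1 — a conventional
detection floor, configurable, with the documented edge that a zero
threshold marks everything present.

The heatmap matrix is log10(TPM + 1); the pseudocount of 1 is required
for zeros and keeps zero at zero on the transformed scale. Row distance
is 1 − Pearson r between transformed rows, agglomerated with average
linkage; zero-variance rows cannot have a defined correlation and are
assigned distance 1 to all other rows (logged). Leaf order is the
deterministic order of the linkage algorithm.

## Host inference

Spearman rank correlation (average ties, Pearson on ranks) between
viral and host profile rows, restricted to feature columns present in
both tables, requiring at least two shared features. The feature space
may be codon fractions, dinucleotide odds, or their concatenation
(default), since both signatures carry host signal. Assignment is the
argmax host per virus, ties broken by host id ascending and flagged.
Pooled dendrograms use distance 1 − ρ — anticorrelation is treated as
dissimilarity, not similarity, because a virus compositionally opposite
to a genome is not adapted to it — with average linkage. The linkage
method and distance transform are documented package choices, not
community standards; single or complete linkage would reorder leaves
but not change the correlation matrix.

## Synthetic data

The generators emulate the statistical structure the stages assume:

- **Hosts**: per synonymous family, a Dirichlet(α) draw over family
  codons; α (`host_divergence`, default 0.1) controls divergence — at
  0.1 each family is dominated by one codon and hosts are far apart in
  L1; large α approaches uniform usage (RSCU → 1).
- **Viruses**: amino-acid sequence uniform over the 20, codons drawn
  from the generating host's family distribution with probability
  1 − noise and uniformly within the family otherwise, flanked by ATG
  and TAA. Keeping the amino-acid sequence uniform isolates codon
  choice as the only host signal, which is exactly what host inference
  is supposed to detect. Default ORF length 300 codons — a typical
  single-protein viral ORF.
- **Hit tables**: 30 hits per query with strictly decreasing bitscores
  and the planted rank's subject flagged viral, so the curation truth
  table can be replayed end to end through the file readers.
- **Expression**: control genes at stable baseline TPM (150–300),
  infection-associated features at 2 TPM in the reference group times
  the planted fold in the treated group, all with lognormal noise of
  σ = 0.5 on the log10 scale (heavy-tailed, strictly positive — the
  standard expression noise model; no noise model is canonical here). A
  bulk filler feature absorbs the remainder of each library so planted
  TPMs survive renormalisation, and read counts are back-computed as
  TPM × length so TPM recomputed from counts reproduces the planted
  values exactly.

Every generator is a pure function of (config, seed). What the
generators do **not** emulate: assembly artefacts and chimeras, length
heterogeneity, amino-acid composition bias, phylogenetic correlation
among hosts, library-size variation, and mapping ambiguity. Passing
recovery tests therefore demonstrates the statistical machinery is
correct and well-calibrated on clean signal, not that real metavirome
data will be this separable.

## Problem sizes and numerical choices

The recovery analyses run at 30 viruses × 5 hosts × 300 codons over 20
seeds per noise level, and 200 replicates per planted fold with 3 vs 3
libraries — sizes at which the quantities of interest (assignment
accuracy, median fold) are stable to within a few percent while the
whole suite completes in well under a minute per analysis. Accuracy at
full noise sits near 1/n_hosts = 20% (chance). The median fold over
replicates is compared within 25% of the planted value; the lognormal
noise makes single-replicate estimates heavy-tailed, which the median
absorbs.

Degenerate inputs are handled explicitly rather than silently: empty
FASTA yields an empty list, a header with no body is an error naming
the record, all-zero counts make TPM undefined (error), all-ambiguous
sequences give empty dinucleotide profiles, single-row matrices yield
trivial clusterings, and constant profiles produce missing
correlations that assignment refuses to rank.

## Known limitations

- Clustering identity uses one optimal global alignment; co-optimal
  alignments with different identity are not explored (the scoring
  scheme makes this rare at triage scale).
- Codon profiles default to all ORFs of an entity; whether a single
  longest ORF would be more representative is data-dependent and left
  to the caller.
- Host assignment is a nearest-correlate heuristic with no significance
  statement; margins and tie flags are reported so callers can treat
  small margins as unresolved.
- TPM re-implementation is the plain length-normalised estimator; no
  effective-length modelling or inferential replicates.
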