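# virome-triage

Toolkit for the desk-side analytical stages of plant metatranscriptome
virome discovery: deciding which assembled contigs are genuinely viral,
whether they look endogenous or exogenous, how abundant they are
relative to host control genes, and which host their composition points
to.

The package is aimed at virologists and bioinformaticians who already
have the heavy external artifacts in hand — assembled contigs (FASTA),
ranked DIAMOND/BLAST hits (12-column tabular), conserved-domain calls,
and per-library quantification tables — and need the bespoke filtering
and compositional analytics that sit between those files and a figure.

## What it computes

**Curation rules.** For each candidate with ranked protein-level hits,
let *r* be the 1-based rank of the first viral subject within the top
30. The candidate is retained iff

- *r* exists **and** a conserved viral domain was detected, or
- no viral domain was detected but *r* ≤ 10;

everything else is excluded. Exogenous candidates additionally pass a
strict > 500 nt length filter, and redundancy is removed by CD-HIT-style
greedy clustering at 90% global-alignment identity.

**ORF prediction** in two modes: complete ATG→stop spans (stop included
in the length) and getorf-style maximal stop-free regions between stops,
on all six frames, under the standard genetic code or the mold
mitochondrial code (table 4, TGA = Trp) for mitochondria-associated
viruses.

**Composition.** Codon fractions; relative synonymous codon usage
RSCU(c) = n(c) · |family| / Σ_family n, whose mean over each observed
synonymous family is exactly 1; and Karlin dinucleotide odds ratios
ρ(XY) = f(XY) / (f(X)·f(Y)), the classic genome signature.

**Abundance.** TPM_i = (c_i/l_i) / Σ_j (c_j/l_j) · 10⁶ from counts and
lengths (columns sum to one million), per-library ratios to the mean of
endogenous control genes (e.g. ACT7, H1, COX2), presence calls at a TPM
floor, between-group fold changes of mean TPM, and the log10 matrix with
rows ordered by average-linkage clustering on 1 − Pearson r.

**Host inference.** Spearman rank correlation between viral and
candidate-host compositional profiles (codon fractions, dinucleotide
odds, or both concatenated), best-correlate host assignment with margins
and tie flags, and an average-linkage dendrogram of pooled viruses and
hosts on the distance 1 − ρ.

A seeded synthetic-data module generates hosts with divergent codon
usage, viral ORFs sampled from a chosen host profile with controllable
noise, hit tables with planted viral ranks, and expression tables with
planted fold changes — so the entire pipeline is testable offline.

## Worked example

```python
from virome_triage import NucleotideSequence, find_orfs, codon_profile, dinuc_profile
from virome_triage.composition import profile_matrix
from virome_triage.synthetic_data import GeneratorConfig, make_host_recovery_dataset
from virome_triage.host_inference import spearman_matrix, predict_host

contig = NucleotideSequence(id="contig1", residues="ATGGAAGAAGAAGAGCCACCCCCGCCTTAA")
(orf,) = find_orfs(contig, mode="complete", min_len=12)
print(f"ORF {orf.start}..{orf.end} strand {orf.strand}, {len(orf)} nt")
prof = codon_profile([orf], entity_id="contig1")
print(f"n_codons={prof.n_codons}  RSCU(GAA)={prof.rscu['GAA']:.2f}  "
      f"RSCU(GAG)={prof.rscu['GAG']:.2f}  RSCU(CCA)={prof.rscu['CCA']:.2f}")
d = dinuc_profile([contig], entity_id="contig1")
print(f"odds(CG)={d.dinuc_odds['CG']:.2f}  odds(AA)={d.dinuc_odds['AA']:.2f}")

cfg = GeneratorConfig(seed=11, n_hosts=3, n_viruses=3, orf_codons=300, noise_fraction=0.1)
hosts, viruses = make_host_recovery_dataset(cfg)
host_table = profile_matrix(hosts, features="codon_fractions")
viral_table = profile_matrix(
    [codon_profile([o], entity_id=v) for v, _, o in viruses], features="codon_fractions"
)
corr = spearman_matrix(viral_table, host_table)
for v, idx, _ in viruses:
    a = predict_host(corr, v)
    print(f"{v}: best={a.best_host} (rho={a.ranked_hosts[0][1]:.3f}, "
          f"margin={a.margin:.3f}) true=host{idx + 1}")
```

prints

```
ORF 0..30 strand +, 30 nt
n_codons=9  RSCU(GAA)=1.50  RSCU(GAG)=0.50  RSCU(CCA)=1.00
odds(CG)=0.49  odds(AA)=1.03
virus1: best=host1 (rho=0.824, margin=0.512) true=host1
virus2: best=host2 (rho=0.795, margin=0.584) true=host2
virus3: best=host3 (rho=0.823, margin=0.585) true=host3
```

The toy contig encodes glutamate three times as GAA for each GAG, so
RSCU splits 1.5 / 0.5 while the balanced proline family stays at 1; the
CG odds ratio below 1 is the familiar CpG suppression of such a GAA-rich
sequence. In the simulated panel, each virus's codon profile rank-
correlates most strongly with its generating host, with comfortable
margins over the runners-up.

The same stages are available from a shell:

```bash
virome-triage simulate --preset full --seed 4 --outdir fixtures/
virome-triage curate --blastx fixtures/blastx.tsv --domains fixtures/domains.tsv \
    --viral-flags fixtures/viral_flags.tsv --out-decisions decisions.tsv
virome-triage run --seed 4 --outdir run_out/   # full pipeline + manifest
```

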