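# domainhotspots

Recurrent somatic-mutation hotspot detection in protein domain families.

Tumor sequencing leaves a long tail of rarely mutated genes where per-gene
recurrence analysis has no power. `domainhotspots` pools missense mutations
across *paralogous instances* of a protein domain: all occurrences of one
Pfam-style domain accession are multiply aligned, each mutation is projected
onto its alignment column, and columns where mutations from many genes pile
up are scored against a uniform-placement null. A recurrent position in a
domain — even if each individual gene is mutated only once or twice — can
then reach significance, and the per-gene spread of the hotspot is
summarized by a normalized entropy score. The package is aimed at
computational cancer-genomics researchers who have protein-level missense
calls and a domain annotation and want domain-level hotspot statistics plus
the machinery (synthetic data, recovery evaluation) to validate them.

## Model

For one domain family with alignment length $L_d$ and $n_d$ mutations
mapped onto its alignment, the count $k_c$ at column $c$ is tested with the
exact binomial tail

$$P_c = \Pr(X \ge k_c), \qquad X \sim \mathrm{Binomial}(n_d,\, 1/L_d),$$

i.e. the chance of that much recurrence if the domain's mutations fell
uniformly over its columns. Columns enter the test only if they carry at
least 2 mutations and at least 3/4 of the alignment rows are non-gaps
there. P-values are Bonferroni-adjusted over the pooled candidate-position
count $N$ across all domains ($P^{\mathrm{adj}}_c = \min(1, N P_c)$);
positions with $P^{\mathrm{adj}}_c < 0.05$ are reported as hotspots.

The per-gene spread of a column is scored with normalized Shannon entropy:
with $f_g = m_g / \sum_g m_g$ the fraction of the column's mutations in
gene $g$ and $G$ the number of genes carrying retained instances of the
domain,

$$S_c = \frac{-\sum_{f_g > 0} f_g \ln f_g}{\ln G} \in [0, 1],$$

1 when every family gene contributes equally, 0 when a single gene
dominates (defined as 0 for $G = 1$).

Instances are filtered before analysis: hits with e-value $> 10^{-5}$ are
excluded (boundary inclusive), then families with fewer than two remaining
instances or with no mapped missense mutations are dropped. Alignments are
built with a progressive aligner (multiset k-mer distance → UPGMA guide
tree → profile–profile global alignment, BLOSUM80, affine gaps costing
open + ℓ·extend with open 10, extend 1); curated alignments can be supplied
instead via `--alignments`.

## Worked example

Generate a synthetic family of 10 paralogous domain instances (ancestral
length 50) with a hotspot of 10 mutations planted at ancestral column 12
plus 50 uniform background mutations, then analyze it:

```
$ cat spec.json
{"n_genes": 10, "instances_per_gene": 1, "length": 50, "seed": 11,
 "hotspots": [{"column": 12, "k": 10}], "n_background": 50}

$ domainhotspots simulate --spec spec.json --out ds
wrote synthetic dataset (60 mutations, 10 domain hits) to ds

$ domainhotspots run --mutations ds/mutations.tsv --proteome ds/proteome.fasta \
      --domains ds/domains.tsv --out run1
analyzed 14 candidate positions in 1 domains; 1 significant at adjusted P < 0.05
outputs written to run1

$ head -2 run1/results.tsv | cut -f3,4,5,6,7
column  n_mut   p_value                 adjusted_p              entropy
12      8       2.5919616266247384e-05  0.0003628746277274634   0.6773174902439576
```

The planted column is recovered as alignment column 12: 8 of its mutations
land in one column (two were frozen one column over by the greedy
progressive alignment — normal aligner behavior), giving an adjusted
P ≈ 3.6 × 10⁻⁴ across the 14 candidate positions, and an entropy of 0.68
reflecting mutations spread over five of the ten family genes. Recovery
against the generator's truth confirms it:

```
$ domainhotspots evaluate --truth ds/truth.json --results run1 --dataset ds
{
 "n_planted": 1,
 "n_detected": 1,
 "power": 1.0,
 ...
}
```

`run` writes `results.tsv`, per-domain aligned FASTA under `alignments/`,
three JSON payloads (`positions.json`, `domains.json`, `domains/<acc>.json`)
and a `run.log` with filter accounting; identical inputs and config
reproduce the directory byte for byte.

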