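# Methods

## Overview

`domainhotspots` detects recurrently mutated positions in protein domain
families. The unit of analysis is the *alignment column* of a multiple
sequence alignment of all retained instances of one domain accession.
Missense mutations given in protein coordinates are projected into the
instances containing them (offset = position − instance start + 1) and then
onto columns through each row's residue→column map. The statistical model,
filters and scores are described below, together with the design choices
that were genuinely open and the limits of what the synthetic-data tests
demonstrate.

## Input model and filters

Inputs are protein-level: a missense mutation TSV (gene, protein id,
1-based position, reference and alternate amino acid, sample, cancer-type
code), a proteome FASTA, and a domain-hit TSV with 1-based inclusive spans
and e-values, as produced by a Pfam-style scan. Genomic-coordinate
conversion and domain detection are out of scope; the package consumes
annotations, it does not compute them.

Exclusion rules, applied in order:

1. **e-value** — instances with e-value strictly greater than 1e-5 are
   removed. The boundary is inclusive (an instance at exactly 1e-5 is
   kept) because the exclusion is defined on "greater than".
2. **family size** — families with fewer than two remaining instances are
   dropped. The rule operates at the *instance* level: a family whose only
   instances are tandem repeats within one gene is retained, since
   intra-gene repeats align against each other exactly like cross-gene
   paralogs and carry the same homology signal.
3. **mutations** — families with zero mapped missense mutations are
   dropped.

Position-inclusion rules (both boundaries inclusive): a column enters the
test set only with ≥ 2 mutations and a non-gap fraction ≥ 0.75.

Mutation bookkeeping: exact duplicate rows (same gene, protein, position,
alleles, sample and cancer code) are deduplicated at load time; otherwise
every record counts once, so the same sample mutated in two repeats
contributes twice. A mutation inside two overlapping instances of one
family maps once per instance (rare; logged). A reference amino acid that
disagrees with the proteome is counted and warned about but not fatal,
because annotation-version skew between mutation calls and proteome
releases is routine in real exports.

## Alignment

The aligner is a standard progressive scheme, fully deterministic:

* **distance** — multiset k-mer distance (k = 3, falling back to k = 1 for
  very short sequences): 1 − shared/min(#kmers); cheap and adequate for
  the closely related paralogs this analysis targets.
* **guide tree** — UPGMA (average linkage). Merge ties break toward the
  lexicographically smallest member instance id.
* **merge step** — global profile–profile alignment under affine gap costs
  (Gotoh three-state recursion). A gap of length ℓ costs open + ℓ·extend,
  open 10 and extend 1 by default against the NCBI BLOSUM80 matrix
  (loaded from Biopython); BLOSUM80 suits the low divergence of
  within-species paralogs. Column pairs score the frequency-weighted
  expected substitution score with gap mass contributing zero, so a
  single-sequence profile reduces exactly to pairwise alignment.
  Traceback ties resolve diagonal > up > left; the traceback only ever
  selects among values the forward pass computed with identical floating
  operations, so alignments are bit-reproducible across runs.
* **terminal gaps** are penalized like internal gaps by default
  (`free_end_gaps` is available but off); domain instances are already
  trimmed to homologous spans, so end gaps are real signal, not overhang.
* **nonstandard residues** (B, J, O, U, X, Z) score the matrix minimum
  against everything — conservative, no fabricated similarity.

Exact reproduction of any particular third-party aligner's output is a
non-goal; users with curated alignments can supply them per domain
(`--alignments`), and the loader verifies row ids and degapped sequences
against the family before accepting them.

## Statistics

* **Recurrence test** — for a column with k of the domain's n_d mutations,
  P = Pr(X ≥ k), X ~ Binomial(n_d, 1/L_d), computed exactly via the
  regularized incomplete beta function (scipy), never a normal
  approximation. n_d counts *all* mutations mapped to the domain's
  alignment, including those at columns that later fail the position
  filters — the null is about the domain's total mutation load. L_d is the
  full alignment column count by default; `p0_mode=candidate_columns`
  restricts it to the candidate columns for users who prefer conditioning
  on testable positions (with a floor of 2 to keep the null proper).
* **Multiple testing** — Bonferroni over the pooled candidate-position
  count across all analyzed domains (`correction_scope=global`, default),
  with a per-domain option. Significance is adjusted P < α, α = 0.05.
* **Entropy score** — Shannon entropy of per-gene mutation fractions at
  the column, normalized by ln G where G is the number of distinct genes
  carrying *retained instances* of the domain (the family size), not the
  number of genes mutated at the position; the score is therefore < 1
  whenever some family gene is unmutated. Natural log; the base cancels
  under normalization. G = 1 is defined as score 0.
* **Ranking** — adjusted P ascending, ties by mutation count descending,
  then (accession, column). Per-domain summaries select the best position
  by smallest P or by highest entropy (a toggle).

## Synthetic data generator

The generator emulates exactly the structure the analysis assumes: one
ancestral domain sequence (i.i.d. uniform over the 20 amino acids), G genes
× R instances derived by i.i.d. substitutions and deletions, instances
embedded in host proteins with random 5–25-residue flanks and linkers,
uniform background mutations over all instance residues, and planted
hotspots concentrating k mutations on the descendants of one ancestral
column (multinomial gene allocation). Defaults: substitution rate 0.1 and
deletion rate 0.01 per site — the low-divergence regime of human paralog
families BLOSUM80 is designed for; e-values 1e-20, with a decoy option
emitting one instance at 1e-3 to exercise the e-value filter; cancer codes
drawn from a 4-code pool.

Deletions only, no insertions: this keeps every surviving residue
attributable to a unique ancestral column, so planted truth and recovered
columns compare without ambiguity. The generator does **not** model
mutational signatures, codon structure, selection, alignment-quality
heterogeneity, or Pfam boundary error. Passing tests on this data show the
engine's statistics are calibrated and its bookkeeping exact under the
model's own assumptions; they do not certify hotspot calls on real tumor
data, where alignment error and non-uniform background mutation rates are
material.

## Calibration and power (what the suite computes)

The acceptance suite checks, at sizes chosen for a single workstation: the
binomial tail against brute-force pmf summation (all k ≤ n ≤ 30, three null
rates, 1e-12); the affine DP against exhaustive enumeration of all global
alignments (200 random short pairs); family-wise error on 500 null
replicates (G=10, R=1, L=50, 200 background mutations each) within
Monte-Carlo slack of the nominal 5%; detection of a planted 10-of-60
hotspot in a ~50-column alignment under a fixed Bonferroni burden of 1,000
positions in ≥ 99/100 replicates (analytic tail ≈ 3.1e-7); entropy
extremes and range; the tandem-repeat coordinate example (offsets 12,
shared column 12, pooled tally); and byte-identical reruns.

## Numerical and degenerate-input choices

* DP scores are IEEE doubles; all tie-breaking is by exact selection among
  identically computed values, so results are platform-stable.
* Pairwise alignment allows one empty side (a single terminal gap of cost
  open + ℓ·extend); two empty sides are an error.
* Alignments of length < 2 columns cannot be tested (L_d ≥ 2 enforced).
* Malformed input rows are collected and reported; a file fails only when
  more than half its data rows are bad.
* Gap character is `-`; `.` is normalized on read.
* `run.log` uses a timestamp-free format so reruns are byte-identical.

## Known limitations

Greedy progressive alignment can freeze an early gap-placement error (on
the synthetic defaults ~99.8% of planted-hotspot mutations land in a single
column, but individual replicates can split a few counts to a neighboring
column); no iterative refinement is attempted. The binomial null assumes
uniform placement over columns, ignoring residue-specific mutability. The
Bonferroni correction is deliberately stringent; no FDR alternative is
provided. Isoform resolution and genomic parsing are out of scope.
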