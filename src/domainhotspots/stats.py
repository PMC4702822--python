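"""Per-column hotspot statistics.

Mutations mapped into a domain family are tallied per alignment column. A
column with k of the domain's n_d mutations is scored with the exact
binomial tail P(X ≥ k), X ~ Binomial(n_d, 1/L_d), i.e. the chance of seeing
at least that much recurrence if the domain's mutations fell uniformly over
its L_d alignment columns. P-values are Bonferroni-adjusted over all
candidate positions (≥ 2 mutations, ≥ 3/4 non-gap rows). A normalized
Shannon entropy over per-gene mutation fractions, divided by ln(family gene
count), summarizes how evenly a hotspot is spread across paralogs: 1 means
every family gene contributes equally, 0 a single gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.stats import binom

from .alignment import DomainAlignment
from .errors import ValidationError
from .families import MappedMutation
from .io import AA_ALPHABET

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_MUTATIONS = 2
DEFAULT_MIN_NONGAP = 0.75

#: Biochemical grouping of the 20 amino acids used for alternate-allele
#: breakdowns (positively charged, negatively charged, polar uncharged,
#: hydrophobic, plus the three special residues).
DEFAULT_AA_CLASSES: dict[str, str] = {
    **{aa: "positive" for aa in "RKH"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "polar" for aa in "STNQY"},
    **{aa: "hydrophobic" for aa in "AVLIMFW"},
    "C": "cysteine",
    "G": "glycine",
    "P": "proline",
}


@dataclass(frozen=True)
class AAClassScheme:
    """Total, disjoint mapping of the 20-AA alphabet onto class labels."""

    classes: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_AA_CLASSES))

    def __post_init__(self) -> None:
        if set(self.classes) != set(AA_ALPHABET):
            raise ValidationError("AA class scheme must cover exactly the "
                                  "20-letter alphabet")

    def of(self, aa: str) -> str:
        return self.classes[aa]


@dataclass
class PositionTally:
    """Mutation counts at one alignment column, with breakdowns."""

    domain_acc: str
    domain_name: str
    column: int
    n_mut: int
    per_gene: dict[str, int]
    per_cancer: dict[str, int]
    per_alt_class: dict[str, int]
    nongap_frac: float


@dataclass
class HotspotResult:
    """A scored alignment column."""

    tally: PositionTally
    p_value: float
    adjusted_p: float
    entropy: float
    significant: bool


@dataclass
class DomainSummary:
    """One domain's headline numbers plus its best position."""

    domain_acc: str
    domain_name: str
    n_instances: int
    n_genes: int
    n_mutations: int
    best: HotspotResult | None


def tally_positions(alignment: DomainAlignment,
                    mapped: Sequence[MappedMutation],
                    scheme: AAClassScheme | None = None,
                    domain_name: str = "") -> list[PositionTally]:
    """Tally mapped mutations per alignment column.

    Each mapped mutation contributes one count to the column its
    within-instance offset occupies in that instance's alignment row.
    Columns with zero mutations are omitted.
    """
    scheme = scheme or AAClassScheme()
    per_col: dict[int, list[MappedMutation]] = {}
    for m in mapped:
        col = alignment.column_of(m.instance_id, m.offset)
        per_col.setdefault(col, []).append(m)
    tallies = []
    for col in sorted(per_col):
        muts = per_col[col]
        genes: dict[str, int] = {}
        cancers: dict[str, int] = {}
        classes: dict[str, int] = {}
        for m in muts:
            genes[m.mutation.gene] = genes.get(m.mutation.gene, 0) + 1
            ct = m.mutation.cancer_type
            cancers[ct] = cancers.get(ct, 0) + 1
            cls = scheme.of(m.mutation.alt_aa)
            classes[cls] = classes.get(cls, 0) + 1
        tallies.append(PositionTally(
            domain_acc=alignment.domain_acc,
            domain_name=domain_name,
            column=col,
            n_mut=len(muts),
            per_gene=genes,
            per_cancer=cancers,
            per_alt_class=classes,
            nongap_frac=alignment.nongap_fraction(col),
        ))
    return tallies


def candidate_positions(tallies: Sequence[PositionTally],
                        min_mut: int = DEFAULT_MIN_MUTATIONS,
                        min_nongap: float = DEFAULT_MIN_NONGAP,
                        ) -> list[PositionTally]:
    """Position-inclusion filter: recurrence and gap-coverage, both inclusive."""
    return [t for t in tallies
            if t.n_mut >= min_mut and t.nongap_frac >= min_nongap]


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Exact upper binomial tail P(X ≥ k) for X ~ Binomial(n, p0).

    Returns 1.0 for k = 0. No normal approximation is used.
    """
    if k < 0 or n < 0 or k > n:
        raise ValidationError(f"invalid binomial arguments k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"p0 must be in (0,1), got {p0}")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p0))


def position_pvalue(tally: PositionTally, n_d: int, L_d: int) -> float:
    """Recurrence p-value of one column against the uniform-placement null.

    ``n_d`` is the total number of mutations mapped to the domain alignment
    (all columns, before position filters); ``L_d`` the number of columns.
    """
    if L_d < 2:
        raise ValidationError(f"alignment length {L_d} < 2")
    return binomial_tail(tally.n_mut, n_d, 1.0 / L_d)


def bonferroni(p_values: Sequence[float],
               n_tests: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, p · N), order-preserving.

    ``n_tests`` defaults to len(p_values) (the pooled candidate count).
    """
    if not p_values:
        return []
    N = n_tests if n_tests is not None else len(p_values)
    return [min(1.0, p * N) for p in p_values]


def entropy_score(per_gene: Mapping[str, int], family_gene_count: int) -> float:
    """Family-size-normalized Shannon entropy of per-gene mutation counts.

    H = −Σ f_g ln f_g over genes with nonzero counts, normalized by
    ln(G) where G is the number of distinct genes carrying retained
    instances of the domain. Defined as 0 when G = 1.
    """
    counts = [c for c in per_gene.values() if c > 0]
    total = sum(counts)
    if total < 1:
        raise ValidationError("entropy requires at least one mutation")
    if family_gene_count < len(counts):
        raise ValidationError(
            f"family gene count {family_gene_count} smaller than number of "
            f"mutated genes {len(counts)}"
        )
    if family_gene_count == 1:
        return 0.0
    h = -sum((c / total) * math.log(c / total) for c in counts)
    return min(1.0, h / math.log(family_gene_count)) + 0.0


def summarize(results: Sequence[HotspotResult],
              alpha: float = DEFAULT_ALPHA,
              best_by: str = "p") -> tuple[list[HotspotResult],
                                           list[DomainSummary]]:
    """Rank results and pick each domain's best position.

    Ranking: adjusted p ascending, ties by mutation count descending, then
    (domain_acc, column). ``best_by`` toggles the per-domain selection
    between smallest p-value ("p") and highest entropy ("entropy").
    """
    if best_by not in ("p", "entropy"):
        raise ValidationError(f"best_by must be 'p' or 'entropy', got {best_by!r}")
    ranked = sorted(results, key=lambda r: (
        r.adjusted_p, -r.tally.n_mut, r.tally.domain_acc, r.tally.column))
    by_domain: dict[str, list[HotspotResult]] = {}
    for r in ranked:
        by_domain.setdefault(r.tally.domain_acc, []).append(r)
    summaries = []
    for acc in sorted(by_domain):
        rs = by_domain[acc]
        if best_by == "p":
            best = min(rs, key=lambda r: (r.p_value, r.tally.column))
        else:
            best = max(rs, key=lambda r: (r.entropy, -r.tally.column))
        n_mut = sum(r.tally.n_mut for r in rs)
        genes = set()
        for r in rs:
            genes.update(r.tally.per_gene)
        summaries.append(DomainSummary(
            domain_acc=acc,
            domain_name=rs[0].tally.domain_name,
            n_instances=0,      # filled by the pipeline, which knows the family
            n_genes=len(genes),
            n_mutations=n_mut,
            best=best,
        ))
    return ranked, summaries


def make_results(tallies: Sequence[PositionTally],
                 p_values: Sequence[float],
                 adjusted: Sequence[float],
                 entropies: Sequence[float],
                 alpha: float = DEFAULT_ALPHA) -> list[HotspotResult]:
    """Zip parallel statistics into HotspotResult records."""
    out = []
    for t, p, ap, h in zip(tallies, p_values, adjusted, entropies):
        out.append(HotspotResult(tally=t, p_value=p, adjusted_p=ap,
                                 entropy=h, significant=ap < alpha))
    return out
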