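"""Domain families: instance extraction, exclusion filters, mutation mapping.

A domain *family* is the set of all occurrences (*instances*) of one domain
accession across the proteome. The analysis pools mutations across instances,
so families pass through three exclusion rules before scoring: instances with
a weak hit (e-value above threshold) are removed, then families with fewer
than two remaining instances or with no mapped missense mutations are
dropped. A single gene carrying several tandem repeats of a domain still
counts as multiple instances — intra-gene repeats align against each other
exactly like cross-gene paralogs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ValidationError
from .io import DomainHitTable, MissenseMutation, MutationTable

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_MAX = 1e-5


@dataclass(frozen=True)
class DomainInstance:
    """One occurrence of a domain on a protein, with its extracted sequence."""

    instance_id: str
    domain_acc: str
    domain_name: str
    protein_id: str
    gene: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    e_value: float
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DomainFamily:
    """All retained instances of one domain accession."""

    domain_acc: str
    domain_name: str
    instances: list[DomainInstance] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        return {i.gene for i in self.instances}

    def __len__(self) -> int:
        return len(self.instances)


@dataclass(frozen=True)
class MappedMutation:
    """A mutation placed inside one containing domain instance.

    ``offset`` is the 1-based position within the instance:
    offset = protein position − instance start + 1.
    """

    mutation: MissenseMutation
    domain_acc: str
    instance_id: str
    offset: int


def build_families(hits: DomainHitTable,
                   proteome: dict[str, str]) -> dict[str, DomainFamily]:
    """Group domain hits into families and extract instance sequences.

    Raises :class:`ValidationError` when a hit names an unknown protein or
    its span exceeds the protein length. Instances within a family are
    ordered by instance_id for determinism; duplicated (protein, span) pairs
    within one accession collapse to a single instance.
    """
    families: dict[str, DomainFamily] = {}
    seen: set[tuple[str, str, int, int]] = set()
    for hit in hits.rows:
        if hit.protein_id not in proteome:
            raise ValidationError(
                f"domain hit references unknown protein '{hit.protein_id}'"
            )
        seq = proteome[hit.protein_id]
        if hit.end > len(seq):
            raise ValidationError(
                f"hit span {hit.start}-{hit.end} on '{hit.protein_id}' exceeds "
                f"protein length {len(seq)}"
            )
        key = (hit.domain_acc, hit.protein_id, hit.start, hit.end)
        if key in seen:
            logger.warning("duplicate hit collapsed: %s %s:%d-%d", *key)
            continue
        seen.add(key)
        inst = DomainInstance(
            instance_id=f"{hit.protein_id}:{hit.start}-{hit.end}",
            domain_acc=hit.domain_acc,
            domain_name=hit.domain_name,
            protein_id=hit.protein_id,
            gene=hit.gene,
            start=hit.start,
            end=hit.end,
            e_value=hit.e_value,
            sequence=seq[hit.start - 1: hit.end],
        )
        fam = families.setdefault(
            hit.domain_acc, DomainFamily(hit.domain_acc, hit.domain_name)
        )
        fam.instances.append(inst)
    for fam in families.values():
        fam.instances.sort(key=lambda i: i.instance_id)
    return dict(sorted(families.items()))


def filter_instances_by_evalue(family: DomainFamily,
                               max_e: float = DEFAULT_EVALUE_MAX) -> DomainFamily:
    """Drop instances with e-value strictly greater than ``max_e``.

    The boundary is inclusive: an instance at exactly the threshold is kept.
    """
    kept, removed = [], []
    for inst in family.instances:
        (kept if inst.e_value <= max_e else removed).append(inst)
    for inst in removed:
        logger.info("excluded %s (%s): e-value %.3g > %.3g",
                    inst.instance_id, family.domain_acc, inst.e_value, max_e)
    return replace_instances(family, kept)


def replace_instances(family: DomainFamily,
                      instances: list[DomainInstance]) -> DomainFamily:
    return DomainFamily(family.domain_acc, family.domain_name, list(instances))


def map_mutations(mutations: MutationTable,
                  families: dict[str, DomainFamily],
                  ) -> tuple[list[MappedMutation], int, int]:
    """Place each mutation in every domain instance whose span contains it.

    Returns ``(mapped, n_unmapped, n_ref_mismatch)``. A mutation falling
    inside two overlapping instances maps once per instance; mutations
    outside all instances count as unmapped. A reference amino acid that
    disagrees with the instance sequence is a counted warning, not an error
    (annotation-version skew between mutation calls and the proteome is
    common in practice).
    """
    by_protein: dict[str, list[DomainInstance]] = {}
    for fam in families.values():
        for inst in fam.instances:
            by_protein.setdefault(inst.protein_id, []).append(inst)

    mapped: list[MappedMutation] = []
    n_unmapped = 0
    n_mismatch = 0
    for mut in mutations.rows:
        hit_any = False
        for inst in by_protein.get(mut.protein_id, ()):
            if inst.start <= mut.position <= inst.end:
                offset = mut.position - inst.start + 1
                if inst.sequence[offset - 1] != mut.ref_aa:
                    n_mismatch += 1
                mapped.append(MappedMutation(mut, inst.domain_acc,
                                             inst.instance_id, offset))
                hit_any = True
        if not hit_any:
            n_unmapped += 1
    if n_mismatch:
        logger.warning("%d mapped mutations disagree with the proteome "
                       "reference residue", n_mismatch)
    return mapped, n_unmapped, n_mismatch


def filter_families(families: dict[str, DomainFamily],
                    mapped: list[MappedMutation],
                    ) -> dict[str, DomainFamily]:
    """Drop families with < 2 instances or zero mapped mutations.

    Expects the e-value filter to have been applied already. Idempotent.
    """
    counts: dict[str, int] = {}
    for m in mapped:
        counts[m.domain_acc] = counts.get(m.domain_acc, 0) + 1
    kept: dict[str, DomainFamily] = {}
    for acc, fam in families.items():
        if len(fam.instances) < 2:
            logger.info("dropped %s: only %d instance(s)", acc, len(fam.instances))
            continue
        if counts.get(acc, 0) == 0:
            logger.info("dropped %s: no mapped missense mutations", acc)
            continue
        kept[acc] = fam
    return kept


def restrict_mapped(mapped: list[MappedMutation],
                    families: dict[str, DomainFamily]) -> list[MappedMutation]:
    """Keep mapped mutations whose family and instance survived filtering."""
    valid: set[tuple[str, str]] = {
        (fam.domain_acc, inst.instance_id)
        for fam in families.values() for inst in fam.instances
    }
    return [m for m in mapped if (m.domain_acc, m.instance_id) in valid]
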