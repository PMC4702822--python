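"""Readers and writers for the pipeline's tabular, FASTA and JSON formats.

Input tables are tab-separated with a header row. Mutation tables carry
protein-level missense calls (1-based protein positions); domain-hit tables
carry Pfam-style domain spans (1-based inclusive). Malformed rows are
collected and reported; a file aborts only when more than half of its data
rows fail to parse, so real-world exports with a few bad lines load while a
wrong file fails loudly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import GAP, DomainAlignment
from .errors import FormatError

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)

MUTATION_COLUMNS = (
    "gene", "protein_id", "position", "ref_aa", "alt_aa", "sample_id", "cancer_type",
)
DOMAIN_HIT_COLUMNS = (
    "domain_acc", "domain_name", "protein_id", "gene", "start", "end", "e_value",
)
RESULT_COLUMNS = (
    "domain_acc", "domain_name", "column", "n_mut", "p_value", "adjusted_p",
    "entropy", "genes", "cancers", "top_alt_class",
)


@dataclass(frozen=True)
class MissenseMutation:
    """One observed protein-level substitution with sample provenance."""

    gene: str
    protein_id: str
    position: int  # 1-based protein coordinate
    ref_aa: str
    alt_aa: str
    sample_id: str
    cancer_type: str


@dataclass(frozen=True)
class DomainHit:
    """One domain occurrence on a protein (1-based inclusive span)."""

    domain_acc: str
    domain_name: str
    protein_id: str
    gene: str
    start: int
    end: int
    e_value: float


@dataclass
class MutationTable:
    """Validated missense mutations plus load-time accounting."""

    rows: list[MissenseMutation]
    n_rejected: int = 0
    n_synonymous: int = 0
    n_duplicates: int = 0
    errors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class DomainHitTable:
    """Validated domain hits plus load-time accounting."""

    rows: list[DomainHit]
    n_rejected: int = 0
    errors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)


def _read_tsv(path: str | Path, required: Iterable[str],
              column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column '{col}' in {path}")
    return df


def read_mutations(path: str | Path,
                   column_map: Mapping[str, str] | None = None) -> MutationTable:
    """Read a protein-level missense mutation TSV.

    Rows failing validation (bad position, bad amino-acid code, empty field)
    are rejected and counted; synonymous rows (ref == alt) are dropped and
    counted separately; exact duplicate rows are deduplicated. The load
    aborts with :class:`FormatError` if more than 50% of data rows fail.
    """
    df = _read_tsv(path, MUTATION_COLUMNS, column_map)
    rows: list[MissenseMutation] = []
    errors: list[str] = []
    n_syn = 0
    seen: set[tuple] = set()
    n_dup = 0
    for idx, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            gene = str(rec.gene).strip()
            protein_id = str(rec.protein_id).strip()
            ref = str(rec.ref_aa).strip().upper()
            alt = str(rec.alt_aa).strip().upper()
            sample = str(rec.sample_id).strip()
            cancer = str(rec.cancer_type).strip()
            pos = int(str(rec.position).strip())
            if not all((gene, protein_id, ref, alt, sample, cancer)):
                raise ValueError("empty field")
            if pos < 1:
                raise ValueError(f"position {pos} < 1")
            if ref not in AA_SET or alt not in AA_SET:
                raise ValueError(f"amino acid not in 20-letter alphabet: {ref}>{alt}")
        except (ValueError, TypeError) as exc:
            errors.append(f"line {idx}: {exc}")
            continue
        if ref == alt:
            n_syn += 1
            continue
        key = (gene, protein_id, pos, ref, alt, sample, cancer)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        rows.append(MissenseMutation(gene, protein_id, pos, ref, alt, sample, cancer))
    n_data = len(df)
    if n_data and len(errors) > 0.5 * n_data:
        raise FormatError(
            f"{len(errors)}/{n_data} rows failed validation in {path}; "
            f"first error: {errors[0]}"
        )
    if errors:
        logger.warning("%s: rejected %d malformed mutation rows", path, len(errors))
    if n_syn:
        logger.info("%s: dropped %d synonymous rows", path, n_syn)
    if n_dup:
        logger.info("%s: deduplicated %d exact duplicate rows", path, n_dup)
    return MutationTable(rows, n_rejected=len(errors), n_synonymous=n_syn,
                         n_duplicates=n_dup, errors=errors)


def read_domain_hits(path: str | Path) -> DomainHitTable:
    """Read a Pfam-scan-style domain hit TSV (1-based inclusive spans)."""
    df = _read_tsv(path, DOMAIN_HIT_COLUMNS)
    rows: list[DomainHit] = []
    errors: list[str] = []
    for idx, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            start = int(str(rec.start).strip())
            end = int(str(rec.end).strip())
            e_value = float(str(rec.e_value).strip())
            if start < 1:
                raise ValueError(f"start {start} < 1")
            if start > end:
                raise ValueError(f"start {start} > end {end}")
            if e_value < 0 or math.isnan(e_value):
                raise ValueError(f"negative or NaN e_value {e_value}")
            acc = str(rec.domain_acc).strip()
            name = str(rec.domain_name).strip()
            pid = str(rec.protein_id).strip()
            gene = str(rec.gene).strip()
            if not all((acc, name, pid, gene)):
                raise ValueError("empty field")
        except (ValueError, TypeError) as exc:
            errors.append(f"line {idx}: {exc}")
            continue
        rows.append(DomainHit(acc, name, pid, gene, start, end, e_value))
    n_data = len(df)
    if n_data and len(errors) > 0.5 * n_data:
        raise FormatError(
            f"{len(errors)}/{n_data} rows failed validation in {path}; "
            f"first error: {errors[0]}"
        )
    if errors:
        logger.warning("%s: rejected %d malformed hit rows", path, len(errors))
    if not rows:
        logger.warning("%s: no valid domain hits", path)
    return DomainHitTable(rows, n_rejected=len(errors), errors=errors)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a plain proteome FASTA into an id -> sequence map."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"FASTA not found: {path}")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate protein_id in {path}: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_aligned_fasta(alignment: DomainAlignment, path: str | Path) -> None:
    """Write an alignment as gapped FASTA, one record per row."""
    records = [SeqRecord(Seq(seq), id=rid, description="")
               for rid, seq in alignment.rows]
    SeqIO.write(records, str(path), "fasta")


def read_aligned_fasta(path: str | Path, domain_acc: str = "") -> DomainAlignment:
    """Read gapped FASTA into a DomainAlignment.

    ``.`` gap characters are normalized to ``-``; unequal row lengths or
    duplicate ids raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"aligned FASTA not found: {path}")
    rows: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate row id in {path}: {rec.id}")
        seen.add(rec.id)
        rows.append((rec.id, str(rec.seq).upper().replace(".", GAP)))
    if not rows:
        raise FormatError(f"aligned FASTA is empty: {path}")
    lengths = {len(s) for _, s in rows}
    if len(lengths) != 1:
        raise FormatError(
            f"aligned FASTA rows have unequal lengths in {path}: {sorted(lengths)}"
        )
    return DomainAlignment(domain_acc=domain_acc, rows=rows)


# ---------------------------------------------------------------------------
# result tables and JSON payloads


def _result_row(res) -> dict:
    """Flatten a HotspotResult into the canonical result-table row."""
    t = res.tally
    genes = ";".join(f"{g}:{c}" for g, c in _sorted_counts(t.per_gene))
    cancers = ";".join(f"{g}:{c}" for g, c in _sorted_counts(t.per_cancer))
    top_class = _sorted_counts(t.per_alt_class)[0][0] if t.per_alt_class else ""
    return {
        "domain_acc": t.domain_acc,
        "domain_name": t.domain_name,
        "column": t.column,
        "n_mut": t.n_mut,
        "p_value": repr(res.p_value),
        "adjusted_p": repr(res.adjusted_p),
        "entropy": repr(res.entropy),
        "genes": genes,
        "cancers": cancers,
        "top_alt_class": top_class,
    }


def _sorted_counts(counts: Mapping[str, int]) -> list[tuple[str, int]]:
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def write_results_tsv(results, path: str | Path) -> None:
    """Write ranked hotspot results as TSV (full float precision)."""
    df = pd.DataFrame([_result_row(r) for r in results], columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame (round-trip partner)."""
    df = _read_tsv(path, RESULT_COLUMNS)
    for col in ("column", "n_mut"):
        df[col] = df[col].astype(int)
    for col in ("p_value", "adjusted_p", "entropy"):
        df[col] = df[col].astype(float)
    return df


def _position_entry(res) -> dict:
    t = res.tally
    return {
        "domain_acc": t.domain_acc,
        "domain_name": t.domain_name,
        "column": t.column,
        "n_mutations": t.n_mut,
        "p_value": res.p_value,
        "adjusted_p": res.adjusted_p,
        "entropy": res.entropy,
        "genes": [{"gene": g, "count": c} for g, c in _sorted_counts(t.per_gene)],
        "cancers": [{"cancer_type": g, "count": c}
                    for g, c in _sorted_counts(t.per_cancer)],
    }


def _dump(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


def write_positions_json(results, path: str | Path) -> None:
    """All analyzed positions as a single JSON object."""
    _dump({"positions": [_position_entry(r) for r in results]}, path)


def write_domains_json(summaries, path: str | Path) -> None:
    """Per-domain summary array, one entry per analyzed domain."""
    out = []
    for s in summaries:
        out.append({
            "domain_acc": s.domain_acc,
            "domain_name": s.domain_name,
            "n_instances": s.n_instances,
            "n_genes": s.n_genes,
            "n_mutations": s.n_mutations,
            "best_position": _position_entry(s.best) if s.best is not None else None,
        })
    _dump(out, path)


def write_domain_detail_json(family, alignment: DomainAlignment,
                             results, path: str | Path) -> None:
    """Single-domain detail: alignment rows plus per-column tallies."""
    inst_by_id = {i.instance_id: i for i in family.instances}
    aln_block = []
    for rid, seq in alignment.rows:
        inst = inst_by_id[rid]
        aln_block.append({
            "row_id": rid,
            "protein_id": inst.protein_id,
            "gene": inst.gene,
            "start": inst.start,
            "end": inst.end,
            "aligned_seq": seq,
        })
    positions = []
    for res in results:
        entry = _position_entry(res)
        entry["alt_classes"] = [
            {"alt_class": k, "count": c}
            for k, c in _sorted_counts(res.tally.per_alt_class)
        ]
        entry["nongap_frac"] = res.tally.nongap_frac
        positions.append(entry)
    _dump({
        "domain_acc": family.domain_acc,
        "domain_name": family.domain_name,
        "alignment": aln_block,
        "positions": positions,
    }, path)
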