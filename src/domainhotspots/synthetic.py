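"""Synthetic domain families with planted mutation hotspots.

The generator emulates the statistical structure the hotspot analysis
assumes: a family of paralogous domain instances diverged from a common
ancestor by point substitutions and deletions, embedded in padded host
proteins, with (a) background missense mutations placed uniformly over all
instance residues and (b) optional planted hotspots concentrating k
mutations on the descendants of one ancestral column.

Deletion-only divergence (no insertions) keeps the bookkeeping exact: every
surviving residue of every instance traces to a unique ancestral column, so
planted signal and recovered alignment columns can be compared without
ambiguity. Defaults model closely related human paralogs: per-site
substitution rate 0.1, per-site deletion rate 0.01.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io as io_mod
from .errors import ValidationError
from .families import DomainFamily
from .io import AA_ALPHABET, DomainHit, DomainHitTable, MissenseMutation, MutationTable
from .stats import HotspotResult

DEFAULT_CANCER_POOL = ("LUAD", "LUSC", "SKCM", "HNSC")


class FamilySpec(BaseModel):
    """Parameters of one simulated domain family."""

    domain_acc: str = "PF90001"
    domain_name: str = "SynDom"
    n_genes: int = Field(default=10, ge=1, description="G: genes in the family")
    instances_per_gene: int = Field(default=1, ge=1, description="R: tandem repeats")
    length: int = Field(default=50, ge=5, description="L0: ancestral length")
    sub_rate: float = Field(default=0.1, ge=0.0, lt=1.0)
    indel_rate: float = Field(default=0.01, ge=0.0, lt=1.0)
    decoy: bool = Field(default=False,
                        description="emit one extra instance with e-value 1e-3")
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "FamilySpec":
        if self.n_genes * self.instances_per_gene < 2:
            raise ValueError("family too small: need n_genes * instances_per_gene >= 2")
        return self


@dataclass
class SimulatedInstance:
    """One generated domain instance plus its ancestral-column map."""

    instance_id: str
    gene: str
    protein_id: str
    start: int
    end: int
    e_value: float
    sequence: str
    # ancestral column (1-based) -> within-instance offset (1-based), or
    # absent when the column was deleted in this instance
    anc_to_offset: dict[int, int]


@dataclass
class SimulatedFamily:
    """A generated family: proteome slice, hit rows and truth maps."""

    spec: FamilySpec
    ancestor: str
    proteome: dict[str, str]
    hits: list[DomainHit]
    instances: list[SimulatedInstance]

    def instances_of_gene(self, gene: str) -> list[SimulatedInstance]:
        return [i for i in self.instances if i.gene == gene]


@dataclass
class PlantedHotspot:
    """Truth record for one planted hotspot."""

    ancestral_column: int
    k: int
    records: list[tuple[str, int]]  # (protein_id, protein position)


@dataclass
class SyntheticTruth:
    """Complete provenance of every emitted mutation."""

    planted: list[PlantedHotspot] = field(default_factory=list)
    background: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_planted(self) -> int:
        return sum(h.k for h in self.planted)

    @property
    def n_background(self) -> int:
        return len(self.background)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _mutate_residue(rng: np.random.Generator, ref: str) -> str:
    choices = [aa for aa in AA_ALPHABET if aa != ref]
    return str(rng.choice(choices))


def simulate_family(spec: FamilySpec,
                    rng: np.random.Generator | None = None) -> SimulatedFamily:
    """Generate a family of paralogous domain instances from one ancestor.

    Each instance applies i.i.d. substitutions (``sub_rate``) and deletions
    (``indel_rate``) to the ancestor and is embedded in a host protein with
    random flanking pads (5-25 aa) and linkers between tandem repeats.
    Deterministic given ``spec.seed``.
    """
    rng = rng or np.random.default_rng(spec.seed)
    ancestor = _random_protein(rng, spec.length)
    proteome: dict[str, str] = {}
    hits: list[DomainHit] = []
    instances: list[SimulatedInstance] = []
    first = True
    for g in range(spec.n_genes):
        gene = f"GENE{g + 1:03d}"
        protein_id = f"{gene}_P"
        parts: list[str] = []
        pos = 0
        pending: list[tuple[int, str, dict[int, int], float]] = []
        for r in range(spec.instances_per_gene):
            pad = _random_protein(rng, int(rng.integers(5, 26)))
            parts.append(pad)
            pos += len(pad)
            derived: list[str] = []
            anc_to_offset: dict[int, int] = {}
            for c, ref in enumerate(ancestor, start=1):
                if rng.random() < spec.indel_rate:
                    continue  # deletion
                aa = _mutate_residue(rng, ref) if rng.random() < spec.sub_rate else ref
                derived.append(aa)
                anc_to_offset[c] = len(derived)
            seq = "".join(derived)
            if not seq:  # pathological rates; keep at least one residue
                seq = ancestor[0]
                anc_to_offset = {1: 1}
            e_value = 1e-3 if (spec.decoy and first) else 1e-20
            first = False
            pending.append((pos + 1, seq, anc_to_offset, e_value))
            parts.append(seq)
            pos += len(seq)
        tail = _random_protein(rng, int(rng.integers(5, 26)))
        parts.append(tail)
        protein = "".join(parts)
        proteome[protein_id] = protein
        for start, seq, anc_map, e_value in pending:
            end = start + len(seq) - 1
            hits.append(DomainHit(spec.domain_acc, spec.domain_name,
                                  protein_id, gene, start, end, e_value))
            instances.append(SimulatedInstance(
                instance_id=f"{protein_id}:{start}-{end}",
                gene=gene, protein_id=protein_id, start=start, end=end,
                e_value=e_value, sequence=seq, anc_to_offset=anc_map))
    return SimulatedFamily(spec=spec, ancestor=ancestor, proteome=proteome,
                           hits=hits, instances=instances)


def _emit_record(rng: np.random.Generator, sim: SimulatedFamily,
                 inst: SimulatedInstance, offset: int, sample_no: int,
                 cancer_pool: tuple[str, ...]) -> MissenseMutation:
    pos = inst.start + offset - 1
    ref = sim.proteome[inst.protein_id][pos - 1]
    alt = _mutate_residue(rng, ref)
    return MissenseMutation(
        gene=inst.gene, protein_id=inst.protein_id, position=pos,
        ref_aa=ref, alt_aa=alt, sample_id=f"S{sample_no:05d}",
        cancer_type=str(rng.choice(cancer_pool)))


def plant_hotspot(sim: SimulatedFamily, column: int, k: int,
                  gene_weights: dict[str, float] | None = None,
                  rng: np.random.Generator | None = None,
                  cancer_pool: tuple[str, ...] = DEFAULT_CANCER_POOL,
                  sample_offset: int = 0,
                  ) -> tuple[list[MissenseMutation], PlantedHotspot]:
    """Emit k missense records at the descendants of one ancestral column.

    Mutations are allocated across genes multinomially by ``gene_weights``
    (uniform over genes where the column survives, by default); within a
    gene the target instance is drawn uniformly among survivors.
    """
    rng = rng or np.random.default_rng(sim.spec.seed + 1)
    survivors: dict[str, list[SimulatedInstance]] = {}
    for inst in sim.instances:
        if column in inst.anc_to_offset:
            survivors.setdefault(inst.gene, []).append(inst)
    if not survivors:
        raise ValidationError(
            f"ancestral column {column} deleted in every instance")
    genes = sorted(survivors)
    if gene_weights:
        w = np.array([max(gene_weights.get(g, 0.0), 0.0) for g in genes])
        if w.sum() <= 0:
            raise ValidationError("gene_weights give zero mass to surviving genes")
    else:
        w = np.ones(len(genes))
    w = w / w.sum()
    records: list[MissenseMutation] = []
    truth_records: list[tuple[str, int]] = []
    alloc = rng.multinomial(k, w)
    n = 0
    for gene, count in zip(genes, alloc):
        for _ in range(int(count)):
            inst = survivors[gene][int(rng.integers(len(survivors[gene])))]
            offset = inst.anc_to_offset[column]
            rec = _emit_record(rng, sim, inst, offset,
                               sample_offset + n, cancer_pool)
            records.append(rec)
            truth_records.append((rec.protein_id, rec.position))
            n += 1
    return records, PlantedHotspot(ancestral_column=column, k=k,
                                   records=truth_records)


def simulate_background(n_bg: int, sim: SimulatedFamily,
                        rng: np.random.Generator | None = None,
                        cancer_pool: tuple[str, ...] = DEFAULT_CANCER_POOL,
                        sample_offset: int = 10000,
                        ) -> tuple[list[MissenseMutation], list[tuple[str, int]]]:
    """Place n_bg mutations uniformly over all (instance, offset) sites."""
    rng = rng or np.random.default_rng(sim.spec.seed + 2)
    sites = [(inst, off) for inst in sim.instances
             for off in range(1, len(inst.sequence) + 1)]
    records: list[MissenseMutation] = []
    truth: list[tuple[str, int]] = []
    for n in range(n_bg):
        inst, off = sites[int(rng.integers(len(sites)))]
        rec = _emit_record(rng, sim, inst, off, sample_offset + n, cancer_pool)
        records.append(rec)
        truth.append((rec.protein_id, rec.position))
    return records, truth


@dataclass
class SyntheticDataset:
    """In-memory dataset in exactly the dialects the readers consume."""

    sim: SimulatedFamily
    mutations: MutationTable
    hits: DomainHitTable
    truth: SyntheticTruth


def simulate_dataset(spec: FamilySpec,
                     hotspots: list[tuple[int, int]] | None = None,
                     n_background: int = 0,
                     gene_weights: dict[str, float] | None = None,
                     ) -> SyntheticDataset:
    """Convenience wrapper: family + planted hotspots + uniform background.

    ``hotspots`` is a list of (ancestral column, k) pairs. All randomness
    derives from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sim = simulate_family(spec, rng)
    truth = SyntheticTruth()
    records: list[MissenseMutation] = []
    offset = 0
    for column, k in hotspots or []:
        recs, planted = plant_hotspot(sim, column, k, gene_weights, rng,
                                      sample_offset=offset)
        records.extend(recs)
        truth.planted.append(planted)
        offset += k
    bg_recs, bg_truth = simulate_background(n_background, sim, rng,
                                            sample_offset=10000)
    records.extend(bg_recs)
    truth.background = bg_truth
    return SyntheticDataset(
        sim=sim,
        mutations=MutationTable(rows=records),
        hits=DomainHitTable(rows=list(sim.hits)),
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write mutations.tsv, proteome.fasta, domains.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mut_df = pd.DataFrame([vars(m) for m in dataset.mutations.rows],
                          columns=list(io_mod.MUTATION_COLUMNS))
    mut_df.to_csv(out / "mutations.tsv", sep="\t", index=False,
                  lineterminator="\n")
    hit_df = pd.DataFrame([vars(h) for h in dataset.hits.rows],
                          columns=list(io_mod.DOMAIN_HIT_COLUMNS))
    hit_df.to_csv(out / "domains.tsv", sep="\t", index=False,
                  lineterminator="\n")
    io_mod.write_fasta(dataset.sim.proteome, out / "proteome.fasta")
    truth = {
        "planted": [{
            "ancestral_column": h.ancestral_column,
            "k": h.k,
            "records": [{"protein_id": p, "position": pos}
                        for p, pos in h.records],
        } for h in dataset.truth.planted],
        "background": [{"protein_id": p, "position": pos}
                       for p, pos in dataset.truth.background],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
        fh.write("\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    with open(path) as fh:
        raw = json.load(fh)
    truth = SyntheticTruth()
    for h in raw.get("planted", []):
        truth.planted.append(PlantedHotspot(
            ancestral_column=h["ancestral_column"], k=h["k"],
            records=[(r["protein_id"], r["position"]) for r in h["records"]]))
    truth.background = [(r["protein_id"], r["position"])
                        for r in raw.get("background", [])]
    return truth


def evaluate_run_dir(truth_path: str | Path, run_dir: str | Path,
                     dataset_dir: str | Path, alpha: float = 0.05) -> dict:
    """Score a finished on-disk run against its synthetic truth.

    ``run_dir`` is the analysis output directory (results.tsv plus
    alignments/); ``dataset_dir`` the simulated input directory
    (proteome.fasta, domains.tsv). Families are rebuilt with default
    filters so residue -> column maps can be reconstructed.
    """
    from . import families as fam_mod
    from .msa import load_external_alignment
    from .stats import PositionTally

    run_dir, dataset_dir = Path(run_dir), Path(dataset_dir)
    truth = read_truth(truth_path)
    df = io_mod.read_results_tsv(run_dir / "results.tsv")
    proteome = io_mod.read_fasta(dataset_dir / "proteome.fasta")
    hits = io_mod.read_domain_hits(dataset_dir / "domains.tsv")
    fams = fam_mod.build_families(hits, proteome)
    fams = {acc: fam_mod.filter_instances_by_evalue(f)
            for acc, f in fams.items()}
    alignments = {}
    for acc in sorted(fams):
        path = run_dir / "alignments" / f"{acc}.fasta"
        if path.exists():
            alignments[acc] = load_external_alignment(path, fams[acc])
        else:  # domain dropped by the run's family filters
            fams.pop(acc)
    results = []
    for row in df.itertuples(index=False):
        tally = PositionTally(
            domain_acc=row.domain_acc, domain_name=row.domain_name,
            column=int(row.column), n_mut=int(row.n_mut),
            per_gene={}, per_cancer={}, per_alt_class={}, nongap_frac=1.0)
        results.append(HotspotResult(
            tally=tally, p_value=float(row.p_value),
            adjusted_p=float(row.adjusted_p), entropy=float(row.entropy),
            significant=float(row.adjusted_p) < alpha))
    return evaluate_recovery(truth, results, alignments, fams, alpha)


def evaluate_recovery(truth: SyntheticTruth,
                      results: list[HotspotResult],
                      alignments: dict[str, "object"],
                      families: dict[str, DomainFamily],
                      alpha: float = 0.05) -> dict:
    """Compare detected hotspot columns against the planted truth.

    A planted hotspot is *detected* when the alignment column holding the
    majority of its planted mutations is Bonferroni-significant. Significant
    columns containing no planted mutation are false positives.
    """
    # residue -> column lookup over every aligned instance
    pos_to_col: dict[tuple[str, int], set[tuple[str, int]]] = {}
    for acc, fam in families.items():
        aln = alignments[acc]
        for inst in fam.instances:
            for off in range(1, inst.length + 1):
                col = aln.column_of(inst.instance_id, off)
                key = (inst.protein_id, inst.start + off - 1)
                pos_to_col.setdefault(key, set()).add((acc, col))

    significant = {(r.tally.domain_acc, r.tally.column)
                   for r in results if r.significant}
    planted_cols: set[tuple[str, int]] = set()
    n_detected = 0
    details = []
    for hotspot in truth.planted:
        col_votes: dict[tuple[str, int], int] = {}
        for key in hotspot.records:
            for accol in pos_to_col.get(key, ()):
                col_votes[accol] = col_votes.get(accol, 0) + 1
        planted_cols.update(col_votes)
        if not col_votes:
            details.append({"ancestral_column": hotspot.ancestral_column,
                            "detected": False, "majority_column": None})
            continue
        majority = max(sorted(col_votes), key=lambda c: col_votes[c])
        detected = majority in significant
        n_detected += detected
        details.append({"ancestral_column": hotspot.ancestral_column,
                        "detected": bool(detected),
                        "majority_column": list(majority),
                        "column_votes": {f"{a}:{c}": v
                                         for (a, c), v in sorted(col_votes.items())}})
    false_pos = sorted(significant - planted_cols)
    n_planted = len(truth.planted)
    return {
        "n_planted": n_planted,
        "n_detected": n_detected,
        "power": (n_detected / n_planted) if n_planted else None,
        "false_positive_columns": [list(c) for c in false_pos],
        "n_false_positives": len(false_pos),
        "alpha": alpha,
        "hotspots": details,
    }
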