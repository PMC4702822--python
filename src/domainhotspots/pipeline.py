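"""End-to-end orchestration: inputs -> families -> MSA -> hotspot statistics.

Stage order: read -> build families -> e-value filter -> map mutations ->
family filters -> align (or load external) -> tally -> candidate filter ->
p-values -> Bonferroni -> entropy -> summarize -> write. Every filter logs
what it dropped; a full run with fixed inputs and config is deterministic
down to the output bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, model_validator

from . import families as fam_mod
from . import io as io_mod
from . import msa as msa_mod
from . import stats as stats_mod
from .alignment import DomainAlignment
from .errors import DomainHotspotsError, PipelineError
from .families import DomainFamily, MappedMutation
from .io import DomainHitTable, MutationTable
from .stats import DomainSummary, HotspotResult

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Tunable thresholds of the hotspot analysis (defaults are canonical)."""

    evalue_max: float = Field(default=1e-5, ge=0)
    min_mutations: int = Field(default=2, ge=1)
    min_nongap: float = Field(default=0.75, ge=0.0, le=1.0)
    alpha: float = Field(default=0.05, gt=0.0, le=1.0)
    gap_open: float = Field(default=10.0, ge=0)
    gap_extend: float = Field(default=1.0, ge=0)
    p0_mode: Literal["full_length", "candidate_columns"] = "full_length"
    correction_scope: Literal["global", "per_domain"] = "global"
    best_by: Literal["p", "entropy"] = "p"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")
        return self


@dataclass
class AnalysisResult:
    """Everything a run produces, in memory."""

    results: list[HotspotResult]
    summaries: list[DomainSummary]
    families: dict[str, DomainFamily]
    alignments: dict[str, DomainAlignment]
    mapped: list[MappedMutation]
    n_candidates: int
    counts: dict[str, int] = field(default_factory=dict)


def analyze(mutations: MutationTable,
            proteome: dict[str, str],
            hits: DomainHitTable,
            config: PipelineConfig | None = None,
            external_alignments: dict[str, str | Path] | None = None,
            ) -> AnalysisResult:
    """Run the full analysis on in-memory inputs.

    ``external_alignments`` optionally maps domain accessions to precomputed
    aligned-FASTA paths, bypassing the progressive aligner for those domains.
    """
    config = config or PipelineConfig()
    counts: dict[str, int] = {
        "mutations_in": len(mutations.rows),
        "hits_in": len(hits.rows),
    }

    families = fam_mod.build_families(hits, proteome)
    counts["families_built"] = len(families)
    n_inst = sum(len(f) for f in families.values())

    families = {acc: fam_mod.filter_instances_by_evalue(f, config.evalue_max)
                for acc, f in families.items()}
    counts["instances_dropped_evalue"] = n_inst - sum(
        len(f) for f in families.values())

    mapped, n_unmapped, n_mismatch = fam_mod.map_mutations(mutations, families)
    counts["mutations_unmapped"] = n_unmapped
    counts["ref_mismatches"] = n_mismatch

    families = fam_mod.filter_families(families, mapped)
    mapped = fam_mod.restrict_mapped(mapped, families)
    counts["families_retained"] = len(families)
    counts["mutations_mapped"] = len(mapped)

    alignments: dict[str, DomainAlignment] = {}
    matrix = msa_mod.blosum80()
    for acc, fam in families.items():
        if external_alignments and acc in external_alignments:
            alignments[acc] = msa_mod.load_external_alignment(
                external_alignments[acc], fam)
        else:
            alignments[acc] = msa_mod.progressive_align(
                fam, matrix, config.gap_open, config.gap_extend)

    scheme = stats_mod.AAClassScheme()
    mapped_by_acc: dict[str, list[MappedMutation]] = {}
    for m in mapped:
        mapped_by_acc.setdefault(m.domain_acc, []).append(m)

    all_candidates: list = []
    domain_of: list[str] = []
    for acc in sorted(families):
        fam = families[acc]
        aln = alignments[acc]
        dom_mapped = mapped_by_acc.get(acc, [])
        tallies = stats_mod.tally_positions(aln, dom_mapped, scheme,
                                            domain_name=fam.domain_name)
        cands = stats_mod.candidate_positions(
            tallies, config.min_mutations, config.min_nongap)
        n_d = sum(t.n_mut for t in tallies)
        L_d = aln.length if config.p0_mode == "full_length" else max(len(cands), 2)
        for t in cands:
            all_candidates.append((t, n_d, L_d, len(fam.genes)))
            domain_of.append(acc)
    counts["candidate_positions"] = len(all_candidates)

    p_values = [stats_mod.position_pvalue(t, n_d, L_d)
                for t, n_d, L_d, _ in all_candidates]
    if config.correction_scope == "global":
        adjusted = stats_mod.bonferroni(p_values)
    else:
        adjusted = list(p_values)
        for acc in sorted(set(domain_of)):
            idx = [i for i, a in enumerate(domain_of) if a == acc]
            sub = stats_mod.bonferroni([p_values[i] for i in idx])
            for i, ap in zip(idx, sub):
                adjusted[i] = ap
    entropies = [stats_mod.entropy_score(t.per_gene, G)
                 for t, _, _, G in all_candidates]

    results = stats_mod.make_results(
        [t for t, _, _, _ in all_candidates], p_values, adjusted, entropies,
        config.alpha)
    ranked, summaries = stats_mod.summarize(results, config.alpha,
                                            config.best_by)
    for s in summaries:
        fam = families[s.domain_acc]
        s.n_instances = len(fam.instances)
        s.n_genes = len(fam.genes)
    counts["significant"] = sum(r.significant for r in ranked)
    logger.info("analysis counts: %s", counts)
    return AnalysisResult(results=ranked, summaries=summaries,
                          families=families, alignments=alignments,
                          mapped=mapped, n_candidates=len(all_candidates),
                          counts=counts)


def run(mutations_path: str | Path,
        proteome_path: str | Path,
        domains_path: str | Path,
        out_dir: str | Path,
        config: PipelineConfig | None = None,
        alignments_dir: str | Path | None = None) -> AnalysisResult:
    """File-to-file pipeline run; writes the full output directory.

    Outputs: ``results.tsv``, ``alignments/<acc>.fasta``, ``positions.json``,
    ``domains.json``, ``domains/<acc>.json`` and ``run.log``.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    # timestamp-free format keeps reruns byte-identical
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("domainhotspots")
    root.addHandler(handler)
    prev_level = root.level
    if root.getEffectiveLevel() > logging.INFO:
        root.setLevel(logging.INFO)
    try:
        stage = "read"
        mutations = io_mod.read_mutations(mutations_path)
        proteome = io_mod.read_fasta(proteome_path)
        hits = io_mod.read_domain_hits(domains_path)
        external = None
        if alignments_dir is not None:
            external = {p.stem: p for p in sorted(Path(alignments_dir).glob("*.fasta"))}
        stage = "analyze"
        res = analyze(mutations, proteome, hits, config, external)
        stage = "write"
        io_mod.write_results_tsv(res.results, out_dir / "results.tsv")
        aln_dir = out_dir / "alignments"
        aln_dir.mkdir(exist_ok=True)
        for acc, aln in sorted(res.alignments.items()):
            io_mod.write_aligned_fasta(aln, aln_dir / f"{acc}.fasta")
        io_mod.write_positions_json(res.results, out_dir / "positions.json")
        io_mod.write_domains_json(res.summaries, out_dir / "domains.json")
        detail_dir = out_dir / "domains"
        detail_dir.mkdir(exist_ok=True)
        by_acc: dict[str, list[HotspotResult]] = {}
        for r in res.results:
            by_acc.setdefault(r.tally.domain_acc, []).append(r)
        for acc, fam in sorted(res.families.items()):
            io_mod.write_domain_detail_json(
                fam, res.alignments[acc], by_acc.get(acc, []),
                detail_dir / f"{acc}.json")
        if not mutations.rows:
            logger.warning("empty mutation table: outputs are empty")
        return res
    except DomainHotspotsError as exc:
        raise PipelineError(f"pipeline failed at stage '{stage}': {exc}") from exc
    finally:
        handler.close()
        root.removeHandler(handler)
        root.setLevel(prev_level)
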