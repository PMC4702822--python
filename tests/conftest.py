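"""Shared fixtures: small hand-built families and on-disk synthetic inputs."""

from __future__ import annotations

import numpy as np
import pytest

from domainhotspots.families import build_families
from domainhotspots.io import (AA_ALPHABET, DomainHit, DomainHitTable,
                               MissenseMutation, MutationTable)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


@pytest.fixture
def kelch_like():
    """Two tandem 46-aa repeats on one protein, spanning 412-457 and 459-504.

    The repeats differ by three substitutions, so they align without gaps;
    protein residues 423 and 470 both sit at within-repeat offset 12.
    """
    rng = np.random.default_rng(0)
    repeat = random_protein(rng, 46)
    second = list(repeat)
    for i in (5, 20, 33):
        second[i] = "A" if second[i] != "A" else "G"
    second = "".join(second)
    protein = (random_protein(rng, 411) + repeat
               + random_protein(rng, 1) + second + random_protein(rng, 20))
    hits = DomainHitTable(rows=[
        DomainHit("PF01344", "Kelch_1", "KEAP1_P", "KEAP1", 412, 457, 1e-12),
        DomainHit("PF01344", "Kelch_1", "KEAP1_P", "KEAP1", 459, 504, 1e-12),
    ])
    proteome = {"KEAP1_P": protein}
    families = build_families(hits, proteome)
    return proteome, hits, families


@pytest.fixture
def kelch_mutations(kelch_like):
    proteome, _, _ = kelch_like
    protein = proteome["KEAP1_P"]

    def alt_for(pos):
        ref = protein[pos - 1]
        return "C" if ref != "C" else "Y"

    rows = (
        [MissenseMutation("KEAP1", "KEAP1_P", 470, protein[469],
                          alt_for(470), f"S{i}", "LUSC") for i in range(6)]
        + [MissenseMutation("KEAP1", "KEAP1_P", 423, protein[422],
                            alt_for(423), f"T{i}", "LUAD") for i in range(2)]
    )
    return MutationTable(rows=rows)


@pytest.fixture
def tiny_dataset_dir(tmp_path):
    """A small planted-hotspot dataset written to disk via the generator."""
    from domainhotspots.synthetic import FamilySpec, simulate_dataset, write_dataset

    spec = FamilySpec(n_genes=6, instances_per_gene=1, length=40, seed=3)
    ds = simulate_dataset(spec, hotspots=[(10, 8)], n_background=30)
    out = tmp_path / "ds"
    write_dataset(ds, out)
    return out, ds
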