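#!/usr/bin/env python
"""Simulate the study dataset: a wild-type reference exon, an evolved
allele pool, the disrupted/restored indel variants, and a two-site
population sample.  Writes FASTA + TSV inputs for the downstream steps
under results/simdata/."""

from pathlib import Path

from prdm9znf import io
from prdm9znf.simulate import (
    SimConfig,
    evolve_allele_pool,
    inject_indel_pair,
    make_reference_exon,
    sample_genotypes,
)

SEED = 20160934  # study seed for the whole analysis
OUT = Path(__file__).resolve().parent.parent / "results" / "simdata"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    ref, truth = make_reference_exon(cfg, n_fingers=7)
    pool = evolve_allele_pool(truth, cfg, n_alleles=10, seed=SEED + 1)
    disrupted, restored = inject_indel_pair(ref, truth, seed=SEED + 2)
    spec = [
        ("siteA", 4, [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]),
        ("siteB", 4, [0, 0, 0, 1, 1, 1, 1, 1, 0, 0]),  # alleles 3,4 shared
        ("siteC", 3, [0, 0, 0, 0, 0, 0, 0, 0, 1, 1]),
    ]
    draws = sample_genotypes([e for e, _ in pool], spec, seed=SEED + 3)

    io.write_fasta([ref], OUT / "reference.fasta")
    io.write_fasta([e for e, _ in pool], OUT / "pool.fasta")
    io.write_fasta([disrupted, restored], OUT / "variants.fasta")
    with open(OUT / "genotype_draws.tsv", "w") as fh:
        fh.write("individual_id\tsite\tallele_1\tallele_2\n")
        for row in draws:
            a1, a2 = row["allele_seq_ids"]
            fh.write(f"{row['individual_id']}\t{row['site']}\t{a1}\t{a2}\n")

    n_units = [len(t.array_units) for _, t in pool]
    print(f"reference exon: {len(ref.nt)} bp, {len(truth.array_units)} repeats")
    print(f"allele pool: {len(pool)} alleles, {min(n_units)}-{max(n_units)} repeats")
    print(f"population sample: {len(draws)} individuals at 3 sites -> {OUT}")


if __name__ == "__main__":
    main()
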