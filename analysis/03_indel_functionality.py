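#!/usr/bin/env python
"""Classify the injected indel variants against the reference (wild-type
A, disrupted a, restored alpha) and write the allele-state table plus
the full genotype-fertility grid (results/indels/)."""

import itertools
from pathlib import Path

import pandas as pd

from prdm9znf import io
from prdm9znf.indels import classify_allele_state, classify_genotype_fertility

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "indels"
    out.mkdir(parents=True, exist_ok=True)
    (ref,) = io.read_fasta(ROOT / "simdata" / "reference.fasta")
    variants = io.read_fasta(ROOT / "simdata" / "variants.fasta")
    states = {ref.seq_id: classify_allele_state(ref, ref)}
    for v in variants:
        states[v.seq_id] = classify_allele_state(v, ref)

    rows = []
    for sid, st in states.items():
        rows.append(
            {
                "seq_id": sid,
                "state": st.label.value,
                "n_indels": len(st.indels),
                "n_pairs": len(st.pairs),
                "n_premature_stops": len(st.premature_stops),
                "indels": ";".join(
                    f"{e.kind.value}{e.length}@{e.ref_pos + 1}" for e in st.indels
                ),
            }
        )
    io.write_table(pd.DataFrame(rows), out / "allele_states.tsv")

    grid = []
    for (id1, s1), (id2, s2) in itertools.combinations_with_replacement(
        states.items(), 2
    ):
        grid.append(
            {
                "allele_1": s1.label.value,
                "allele_2": s2.label.value,
                "fertility": classify_genotype_fertility(s1, s2).value,
            }
        )
    io.write_table(pd.DataFrame(grid), out / "fertility_grid.tsv")

    for r in rows:
        print(f"{r['seq_id']}: {r['state']} "
              f"({r['indels'] or 'no indels'}, {r['n_premature_stops']} premature stops)")
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
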