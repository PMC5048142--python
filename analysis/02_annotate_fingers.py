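#!/usr/bin/env python
"""Segment every simulated exon into classified zinc fingers and tabulate
spans, ligand states and binding triplets (results/annotation.tsv)."""

from pathlib import Path

from prdm9znf import io
from prdm9znf.grammar import FingerClass, segment_exon

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    exons = io.read_fasta(ROOT / "simdata" / "pool.fasta")
    exons += io.read_fasta(ROOT / "simdata" / "reference.fasta")
    anns = [segment_exon(e) for e in exons]
    df = io.annotation_table(anns)
    io.write_table(df, ROOT / "annotation.tsv")
    n_c2h2 = (df["class"] == FingerClass.C2H2.value).sum()
    n_degen = (df["class"] == FingerClass.DEGENERATE_LIGAND.value).sum()
    print(f"{len(anns)} exons -> {len(df)} fingers "
          f"({n_c2h2} C2H2, {n_degen} ligand-degenerate)")
    print(f"annotation table -> {ROOT / 'annotation.tsv'}")


if __name__ == "__main__":
    main()
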