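"""FASTA / TSV / Newick input and output.

FASTA headers follow the pipe-delimited convention
``seqid|individual|species|region|site`` with missing fields tolerated.
Tables are TSV with a header row and deterministic column order;
coordinates in user-facing files are 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alleles import AlleleCall, GenotypeRecord
from .grammar import ExonAnnotation, ExonSequence, InputError
from .phylo import TreeNode, to_newick

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_newick",
    "annotation_table",
    "allele_table",
    "genotype_records_table",
    "write_table",
]


def read_fasta(path: str | Path) -> list[ExonSequence]:
    """Read exon sequences; headers parsed per the pipe convention."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        # species/site fields may contain spaces: parse the whole header
        fields = rec.description.split("|") + 4 * [""]
        try:
            out.append(
                ExonSequence(
                    seq_id=fields[0],
                    individual_id=fields[1],
                    species_label=fields[2],
                    region_label=fields[3],
                    site_label=fields[4],
                    nt=str(rec.seq).upper(),
                )
            )
        except InputError as e:
            raise InputError(f"{path}: record {rec.id!r}: {e}") from e
    return out


def write_fasta(seqs: Iterable[ExonSequence], path: str | Path) -> None:
    records = []
    for s in seqs:
        header = "|".join(
            [s.seq_id, s.individual_id, s.species_label, s.region_label, s.site_label]
        ).rstrip("|")
        records.append(SeqRecord(Seq(s.nt), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def annotation_table(annotations: Iterable[ExonAnnotation]) -> pd.DataFrame:
    """Per-finger annotation rows (1-based inclusive spans)."""
    rows = []
    for ann in annotations:
        for f in ann.fingers:
            try:
                trip = f.triplet
            except Exception:
                trip = ""
            try:
                quad = f.quadruplet
            except Exception:
                quad = ""
            rows.append(
                {
                    "seq_id": ann.exon.seq_id,
                    "finger_index": f.index_in_array,
                    "start": f.nt_span[0] + 1,
                    "end": f.nt_span[1],
                    "class": f.finger_class.value,
                    "ligand_states": ";".join(
                        f"{n}:{o}" for n, _, o, _ in f.ligand_states
                    ),
                    "triplet": trip,
                    "quadruplet": quad,
                    "in_array": f.nt_span[0] >= ann.c2h2_array_start,
                }
            )
    cols = ["seq_id", "finger_index", "start", "end", "class",
            "ligand_states", "triplet", "quadruplet", "in_array"]
    return pd.DataFrame(rows, columns=cols)


def allele_table(alleles: Iterable[AlleleCall]) -> pd.DataFrame:
    rows = [
        {
            "allele_id": a.allele_id,
            "n_c2h2": a.n_c2h2,
            "fingerprint": "-".join(a.fingerprint),
            "array_peptide": a.array_peptide,
            "seq_ids": ";".join(a.seq_ids),
        }
        for a in alleles
    ]
    cols = ["allele_id", "n_c2h2", "fingerprint", "array_peptide", "seq_ids"]
    return pd.DataFrame(rows, columns=cols)


def genotype_records_table(records: Iterable[GenotypeRecord]) -> pd.DataFrame:
    rows = [
        {
            "individual_id": r.individual_id,
            "species": r.species_label,
            "region": r.region_label,
            "site": r.site_label,
            "allele_1": r.allele_1.allele_id,
            "allele_2": r.allele_2.allele_id,
            "heterozygous": r.heterozygous,
            "fertility": r.fertility.value if r.fertility else "",
        }
        for r in records
    ]
    cols = ["individual_id", "species", "region", "site",
            "allele_1", "allele_2", "heterozygous", "fertility"]
    return pd.DataFrame(rows, columns=cols)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
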