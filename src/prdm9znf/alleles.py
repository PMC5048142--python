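"""Amino-acid-level allele calling on the C2H2 array and diversity summaries.

Alleles are defined at the amino-acid level (synonymous nucleotide
changes are excluded) and are restricted to the C2H2 array: two exons
carry the same allele iff their concatenated array peptides are
identical.  Ligand-degenerate fingers inside the array (e.g. a terminal
H->N finger) do not count toward the C2H2 finger number but do appear in
the binding-triplet fingerprint, flagged as degenerate.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .grammar import (
    ExonAnnotation,
    FingerClass,
    NotExtractableError,
    extract_triplet,
)
from .indels import AlleleLabel, Fertility, classify_genotype_fertility

__all__ = [
    "AlleleCall",
    "GenotypeRecord",
    "call_alleles",
    "genotype_table",
    "diversity_summary",
    "fingerprint_matrix",
]


@dataclass
class AlleleCall:
    allele_id: str
    n_c2h2: int
    array_peptide: str = ""
    fingerprint: list[str] = field(default_factory=list)
    degenerate_flags: list[bool] = field(default_factory=list)
    state: Optional[AlleleLabel] = None
    seq_ids: list[str] = field(default_factory=list)
    finger_peptides: list[str] = field(default_factory=list)


@dataclass
class GenotypeRecord:
    individual_id: str
    allele_1: AlleleCall
    allele_2: AlleleCall
    species_label: str = ""
    region_label: str = ""
    site_label: str = ""
    fertility: Optional[Fertility] = None

    @property
    def heterozygous(self) -> bool:
        return self.allele_1.allele_id != self.allele_2.allele_id

    @property
    def alleles(self) -> tuple[AlleleCall, AlleleCall]:
        return (self.allele_1, self.allele_2)


def _species_prefix(species_label: str) -> str:
    parts = species_label.replace("_", " ").split()
    if len(parts) >= 2 and parts[1] not in ("sp.", "sp"):
        return (parts[0][0] + parts[1][0]).upper()
    if parts:
        return (parts[0][0] + "SP").upper()
    return "AL"


def call_alleles(annotations: Iterable[ExonAnnotation]) -> list[AlleleCall]:
    """Collapse array peptides into amino-acid-level alleles.

    IDs are assigned in first-seen order within a species prefix;
    annotations without a C2H2 array are skipped.
    """
    calls: dict[str, AlleleCall] = {}
    counters: dict[str, int] = defaultdict(int)
    out: list[AlleleCall] = []
    for ann in annotations:
        fingers = ann.array_fingers
        if not any(f.finger_class is FingerClass.C2H2 for f in fingers):
            import warnings

            warnings.warn(f"{ann.exon.seq_id}: no C2H2 array, skipped")
            continue
        peptide = "".join(f.peptide for f in fingers)
        if peptide in calls:
            calls[peptide].seq_ids.append(ann.exon.seq_id)
            continue
        prefix = _species_prefix(ann.exon.species_label)
        counters[prefix] += 1
        fingerprint, degen = [], []
        for f in fingers:
            try:
                fingerprint.append(extract_triplet(f))
            except NotExtractableError:
                fingerprint.append("-")
            degen.append(f.finger_class is not FingerClass.C2H2)
        call = AlleleCall(
            allele_id=f"{prefix}{counters[prefix]}",
            n_c2h2=sum(1 for f in fingers if f.finger_class is FingerClass.C2H2),
            array_peptide=peptide,
            fingerprint=fingerprint,
            degenerate_flags=degen,
            seq_ids=[ann.exon.seq_id],
            finger_peptides=[f.peptide for f in fingers],
        )
        calls[peptide] = call
        out.append(call)
    return out


def genotype_table(
    individuals: Mapping[str, dict],
) -> list[GenotypeRecord]:
    """Build genotype records from a per-individual mapping.

    ``individuals`` maps individual_id to a dict with keys ``alleles``
    (list of 1 or 2 AlleleCall), and optional ``species``, ``region``,
    ``site``.  A single observed allele is recorded homozygous.
    """
    records = []
    for ind, info in individuals.items():
        alleles = list(info["alleles"])
        if not 1 <= len(alleles) <= 2:
            raise ValueError(
                f"{ind}: {len(alleles)} alleles (possible contamination)"
            )
        a1 = alleles[0]
        a2 = alleles[1] if len(alleles) == 2 else alleles[0]
        fert = None
        if a1.state is not None and a2.state is not None:
            fert = classify_genotype_fertility(a1.state, a2.state)
        records.append(
            GenotypeRecord(
                individual_id=ind,
                allele_1=a1,
                allele_2=a2,
                species_label=info.get("species", ""),
                region_label=info.get("region", ""),
                site_label=info.get("site", ""),
                fertility=fert,
            )
        )
    return records


def diversity_summary(records: list[GenotypeRecord]) -> dict:
    """Allelic-diversity counts across individuals, sites and regions."""
    if not records:
        raise ValueError("no genotype records")
    allele_sites: dict[str, set] = defaultdict(set)
    allele_regions: dict[str, set] = defaultdict(set)
    allele_n: dict[str, int] = {}
    region_individuals: dict[str, int] = defaultdict(int)
    region_sites: dict[str, set] = defaultdict(set)
    n_het = 0
    for rec in records:
        n_het += rec.heterozygous
        region_individuals[rec.region_label] += 1
        if rec.site_label:
            region_sites[rec.region_label].add(rec.site_label)
        for al in set(a.allele_id for a in rec.alleles):
            call = rec.allele_1 if rec.allele_1.allele_id == al else rec.allele_2
            allele_sites[al].add(rec.site_label)
            allele_regions[al].add(rec.region_label)
            allele_n[al] = call.n_c2h2
    alleles_per_region: dict[str, int] = defaultdict(int)
    exclusive_per_region: dict[str, int] = defaultdict(int)
    for al, regions in allele_regions.items():
        for r in regions:
            alleles_per_region[r] += 1
        if len(regions) == 1:
            exclusive_per_region[next(iter(regions))] += 1
    multi_site = {
        al: sorted(s for s in sites if s)
        for al, sites in allele_sites.items()
        if len({s for s in sites if s}) >= 2
    }
    return {
        "n_individuals": len(records),
        "n_alleles": len(allele_regions),
        "n_heterozygous": n_het,
        "n_homozygous": len(records) - n_het,
        "alleles_per_region": dict(alleles_per_region),
        "region_exclusive_alleles": dict(exclusive_per_region),
        "alleles_multi_site": multi_site,
        "n_alleles_multi_site": len(multi_site),
        "sites_per_region": {r: sorted(s) for r, s in region_sites.items()},
        "individuals_per_region": dict(region_individuals),
        "n_c2h2_min": min(allele_n.values()),
        "n_c2h2_max": max(allele_n.values()),
    }


def fingerprint_matrix(alleles: list[AlleleCall]) -> list[dict]:
    """Per-allele ordered binding-triplet rows.

    Marks the 5'-most and 3'-most fingers and flags fingers whose
    non-binding residues differ from the allele set's modal peptide for
    that triplet (the "dot" semantics: a nonsynonymous substitution apart
    from the shown binding amino acids).
    """
    # modal full peptide per triplet across all alleles
    peptide_counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for al in alleles:
        for trip, pep in zip(al.fingerprint, al.finger_peptides):
            peptide_counts[trip][pep] += 1
    modal = {
        trip: max(peps.items(), key=lambda kv: (kv[1], kv[0]))[0]
        for trip, peps in peptide_counts.items()
    }
    rows = []
    for al in alleles:
        flags = []
        for trip, pep in zip(al.fingerprint, al.finger_peptides):
            flags.append(pep != modal.get(trip, pep))
        rows.append(
            {
                "allele_id": al.allele_id,
                "triplets": list(al.fingerprint),
                "degenerate": list(al.degenerate_flags),
                "nonbinding_sub": flags,
                "five_prime_most": al.fingerprint[0] if al.fingerprint else "",
                "three_prime_most": al.fingerprint[-1] if al.fingerprint else "",
            }
        )
    return rows
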