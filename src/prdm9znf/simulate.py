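"""Synthetic zinc-finger exons, allele pools and genotype tables.

The generator emulates the structure the analysis assumes: an exon made
of a conserved 5' region — a leader, one ligand-degenerate finger
(C1 -> S) and a short spacer — followed by a tandem array of 3-12
canonical 84-bp C2H2 repeats and a terminal stop codon.  Allele pools
evolve by in-register repeat duplication/loss and point substitution
with an elevated rate at the three DNA-binding codons; a 2-bp insertion
plus a downstream frame-restoring deletion can be injected into the 5'
region to produce disrupted (a) and restored (alpha) variants.  The
spacer is engineered so that every shifted reading frame hits a stop
codon within two finger lengths, making premature-stop detection
deterministic for disrupted alleles.

All generators are pure functions of (config, seed): repeated invocation
is byte-identical.  The study's genotype table (23 individuals, 28
alleles) ships as a packaged fixture without sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .alleles import AlleleCall, GenotypeRecord
from .grammar import (
    FINGER_NT,
    FINGER_RES,
    LIGAND_OFFSETS,
    QUADRUPLET_OFFSETS,
    TRIPLET_OFFSETS,
    ExonSequence,
    FingerClass,
    InputError,
    translate_frame,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_reference_exon",
    "evolve_allele_pool",
    "replay_events",
    "inject_indel_pair",
    "sample_genotypes",
    "table1_fixture",
    "TABLE1_NUMERIC_IDS",
]

# canonical finger peptide (ligand template C-x2-C-x12-H-x3-H)
TEMPLATE_PEPTIDE = "CRECGRGFSQKSSKRNHIRTHTGEKPYV"
# leader peptide: conserved, cysteine/histidine-free so it cannot seed
# spurious finger windows
LEADER_PEPTIDE = "MESLKETQGVRF"
# spacer with stop codons in both shifted frames but none in frame 0
SPACER_NT = "CCTAACATGAGG"
TERMINAL_STOP = "TGA"

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "W": ["TGG"], "Y": ["TAT", "TAC"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
}
# residues drawn for randomized binding positions: no C/H (would fake
# ligands), no W/M (single-codon), no stops
_BINDING_RESIDUES = "QRSTNKILVDEGA"


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_fingers_range: tuple[int, int] = (3, 12)
    dup_rate: float = 0.08       # per-replication repeat birth probability
    del_rate: float = 0.05       # per-replication repeat death probability
    background_sub_rate: float = 0.002  # per-site per replication round
    binding_nonsyn_multiplier: float = 5.0
    n_rounds: int = 3
    ins_len: int = 2
    del_len: int = 2
    spacing: int = 40
    population_spec: tuple = ()

    def __post_init__(self) -> None:
        for r in (self.dup_rate, self.del_rate, self.background_sub_rate):
            if not 0 <= r <= 1:
                raise InputError("rates must lie in [0, 1]")
        if self.n_fingers_range[0] < 1:
            raise InputError("minimum finger number must be >= 1")


@dataclass
class GroundTruth:
    """Construction record of a simulated exon."""

    finger_spans: list[tuple[int, int]]
    finger_classes: list[FingerClass]
    c2h2_array_start: int
    array_units: list[str]          # 84-nt repeat units
    five_prime_nt: str
    event_log: list[tuple] = field(default_factory=list)


def _reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in peptide)


def _random_finger_peptide(rng: np.random.Generator) -> str:
    pep = list(TEMPLATE_PEPTIDE)
    for off in QUADRUPLET_OFFSETS:
        pep[off] = _BINDING_RESIDUES[rng.integers(0, len(_BINDING_RESIDUES))]
    return "".join(pep)


def make_reference_exon(
    config: SimConfig, n_fingers: Optional[int] = None, seq_id: str = "ref"
) -> tuple[ExonSequence, GroundTruth]:
    """Build a wild-type reference exon with known finger coordinates."""
    rng = np.random.default_rng(config.seed)
    if n_fingers is None:
        lo, hi = config.n_fingers_range
        n_fingers = int(rng.integers(lo, hi + 1))
    leader = _reverse_translate(LEADER_PEPTIDE, rng)
    degen_pep = "S" + TEMPLATE_PEPTIDE[1:]  # C1 -> serine: degenerate ligand
    degen_nt = _reverse_translate(degen_pep, rng)
    units = [
        _reverse_translate(_random_finger_peptide(rng), rng)
        for _ in range(n_fingers)
    ]
    five_prime = leader + degen_nt + SPACER_NT
    nt = five_prime + "".join(units) + TERMINAL_STOP
    array_start = len(five_prime)
    spans = [(len(leader), len(leader) + FINGER_NT)]
    classes = [FingerClass.DEGENERATE_LIGAND]
    for i in range(n_fingers):
        s = array_start + i * FINGER_NT
        spans.append((s, s + FINGER_NT))
        classes.append(FingerClass.C2H2)
    exon = ExonSequence(seq_id=seq_id, nt=nt)
    truth = GroundTruth(
        finger_spans=spans,
        finger_classes=classes,
        c2h2_array_start=array_start,
        array_units=units,
        five_prime_nt=five_prime,
    )
    assert "*" not in translate_frame(nt, 0)[:-1]
    return exon, truth


# ---------------------------------------------------------------------------
# repeat-array evolution

def _binding_nt_offsets() -> frozenset:
    out = set()
    for codon_idx in TRIPLET_OFFSETS:
        out.update(range(3 * codon_idx, 3 * codon_idx + 3))
    return frozenset(out)


_BINDING_NT = _binding_nt_offsets()
_LIGAND_NT = frozenset(
    p for off, _ in LIGAND_OFFSETS for p in range(3 * off, 3 * off + 3)
)


def evolve_allele_pool(
    reference_truth: GroundTruth,
    config: SimConfig,
    n_alleles: int,
    seed: Optional[int] = None,
) -> list[tuple[ExonSequence, GroundTruth]]:
    """Evolve an allele pool by repeat duplication/loss and substitution.

    Each allele descends from the reference array through ``n_rounds``
    replication rounds.  A round may duplicate a repeat unit in register,
    delete one, and applies point substitutions at the background rate,
    multiplied at the three DNA-binding codons; ligand codons are held
    fixed so fingers stay canonical.  The event log replays exactly to
    the emitted sequence.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pool = []
    for a in range(n_alleles):
        while True:
            units = list(reference_truth.array_units)
            log: list[tuple] = []
            for _ in range(config.n_rounds):
                if rng.random() < config.dup_rate:
                    i = int(rng.integers(0, len(units)))
                    units.insert(i + 1, units[i])
                    log.append(("dup", i))
                if len(units) > 1 and rng.random() < config.del_rate:
                    i = int(rng.integers(0, len(units)))
                    units.pop(i)
                    log.append(("del", i))
                for u in range(len(units)):
                    unit = units[u]
                    new = list(unit)
                    changed = False
                    for p in range(len(unit)):
                        if p in _LIGAND_NT:
                            continue
                        rate = config.background_sub_rate
                        if p in _BINDING_NT:
                            rate *= config.binding_nonsyn_multiplier
                        if rng.random() < rate:
                            alts = [b for b in "ACGT" if b != unit[p]]
                            b = alts[rng.integers(0, 3)]
                            cod = 3 * (p // 3)
                            trial = new[:]
                            trial[p] = b
                            codon = "".join(trial[cod : cod + 3])
                            if translate_frame(codon, 0) == "*":
                                continue  # stop-introducing changes rejected
                            new = trial
                            changed = True
                            log.append(("sub", u, p, b))
                    if changed:
                        units[u] = "".join(new)
                if not units:
                    break
            if units:
                break
        nt = reference_truth.five_prime_nt + "".join(units) + TERMINAL_STOP
        spans = list(reference_truth.finger_spans[:1])
        classes = [FingerClass.DEGENERATE_LIGAND]
        start = reference_truth.c2h2_array_start
        for i in range(len(units)):
            spans.append((start + i * FINGER_NT, start + (i + 1) * FINGER_NT))
            classes.append(FingerClass.C2H2)
        truth = GroundTruth(
            finger_spans=spans,
            finger_classes=classes,
            c2h2_array_start=start,
            array_units=units,
            five_prime_nt=reference_truth.five_prime_nt,
            event_log=log,
        )
        pool.append((ExonSequence(seq_id=f"allele{a}", nt=nt), truth))
    return pool


def replay_events(reference_truth: GroundTruth, log: Sequence[tuple]) -> list[str]:
    """Re-apply an event log to the reference array units."""
    units = list(reference_truth.array_units)
    for ev in log:
        if ev[0] == "dup":
            units.insert(ev[1] + 1, units[ev[1]])
        elif ev[0] == "del":
            units.pop(ev[1])
        elif ev[0] == "sub":
            _, u, p, b = ev
            s = list(units[u])
            s[p] = b
            units[u] = "".join(s)
        else:
            raise InputError(f"unknown event {ev!r}")
    return units


# ---------------------------------------------------------------------------
# indel injection

def inject_indel_pair(
    exon: ExonSequence,
    truth: GroundTruth,
    ins_len: int = 2,
    del_len: int = 2,
    spacing: int = 40,
    seed: int = 0,
) -> tuple[ExonSequence, ExonSequence]:
    """Create the disrupted (insertion-only) and restored (insertion +
    frame-restoring deletion) variants of a reference exon.

    The insertion lands inside the 5' degenerate finger; the deletion
    removes reference bases ``spacing`` bp downstream.  The restored
    variant requires (ins_len - del_len) = 0 mod 3.
    """
    rng = np.random.default_rng(seed)
    degen_start, degen_end = truth.finger_spans[0]
    pos_ins = degen_start + 10
    pos_del = pos_ins + spacing
    if pos_del + del_len > len(truth.five_prime_nt):
        raise InputError("insertion + spacing + deletion must fit in the 5' region")
    if (ins_len - del_len) % 3 != 0:
        raise InputError("net shift of the pair must be 0 mod 3")
    if ins_len % 3 == 0:
        raise InputError("the insertion must be frameshifting")
    ins_bases = "".join("ACGT"[rng.integers(0, 4)] for _ in range(ins_len))
    ref = exon.nt
    disrupted_nt = ref[:pos_ins] + ins_bases + ref[pos_ins:]
    restored_nt = (
        ref[:pos_ins] + ins_bases + ref[pos_ins:pos_del] + ref[pos_del + del_len :]
    )
    # the spacer guarantees a premature stop in every shifted frame
    pep = translate_frame(disrupted_nt, 0)
    terminus = len(disrupted_nt) // 3 - 1
    assert any(aa == "*" for aa in pep[:terminus]), "no planted stop found"
    disrupted = ExonSequence(seq_id=exon.seq_id + "_a", nt=disrupted_nt)
    restored = ExonSequence(seq_id=exon.seq_id + "_alpha", nt=restored_nt)
    return disrupted, restored


# ---------------------------------------------------------------------------
# codon-level star evolution (for the sitewise selection scan)

def simulate_codon_alignment(
    n_seqs: int,
    omega_by_site: Sequence[float],
    subs_per_codon: float = 0.5,
    seed: int = 0,
    ancestor: Optional[str] = None,
) -> tuple[list[str], str]:
    """Evolve codon rows along the edges of a star tree.

    Each sequence descends independently from the ancestor.  Per codon
    site, single-nucleotide changes occur with rate 1 for synonymous and
    ``omega`` for nonsynonymous changes (mutations to stop codons are
    forbidden), scaled so a neutral site expects ``subs_per_codon``
    substitution events per edge.  Returns (rows, ancestor).
    """
    from .grammar import _CODON_TABLE as CT

    rng = np.random.default_rng(seed)
    n_sites = len(omega_by_site)
    if ancestor is None:
        pep = _random_finger_peptide(rng)
        if n_sites != FINGER_RES:
            pep = "".join(
                _BINDING_RESIDUES[rng.integers(0, len(_BINDING_RESIDUES))]
                for _ in range(n_sites)
            )
        ancestor = _reverse_translate(pep, rng)
    if len(ancestor) != 3 * n_sites:
        raise InputError("ancestor length must match omega_by_site")
    mu = subs_per_codon / 9.0  # 9 single-nt neighbours per codon
    rows = []
    for _ in range(n_seqs):
        seq = []
        for s in range(n_sites):
            codon = ancestor[3 * s : 3 * s + 3]
            omega = omega_by_site[s]
            t = 0.0
            while True:
                neigh = []
                for pos in range(3):
                    for alt in "ACGT":
                        if alt == codon[pos]:
                            continue
                        mut = codon[:pos] + alt + codon[pos + 1 :]
                        if CT[mut] == "*":
                            continue
                        rate = mu * (1.0 if CT[mut] == CT[codon] else omega)
                        neigh.append((rate, mut))
                total = sum(r for r, _ in neigh)
                if total <= 0:
                    break
                t += rng.exponential(1.0 / total)
                if t >= 1.0:
                    break
                u = rng.random() * total
                acc = 0.0
                for rate, mut in neigh:
                    acc += rate
                    if u <= acc:
                        codon = mut
                        break
            seq.append(codon)
        rows.append("".join(seq))
    return rows, ancestor


# ---------------------------------------------------------------------------
# population sampling

def sample_genotypes(
    pool: Sequence[ExonSequence],
    population_spec: Sequence[tuple[str, int, Sequence[float]]],
    seed: int = 0,
) -> list[dict]:
    """Draw two alleles per individual at per-site frequencies.

    ``population_spec`` is a list of (site_label, n_individuals,
    allele-sharing weights over the pool).  Returns metadata rows in the
    pipeline's input format.
    """
    if not pool:
        raise InputError("empty allele pool")
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for site, n_ind, weights in population_spec:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(pool) or w.sum() <= 0:
            raise InputError(f"{site}: weights must cover the pool")
        w = w / w.sum()
        for _ in range(n_ind):
            counter += 1
            picks = rng.choice(len(pool), size=2, p=w)
            rows.append(
                {
                    "individual_id": f"IND{counter:03d}",
                    "site": site,
                    "allele_seq_ids": [pool[int(k)].seq_id for k in picks],
                    "allele_indices": [int(k) for k in picks],
                }
            )
    return rows


# ---------------------------------------------------------------------------
# random additive trees (for distance-method validation)

def random_additive_tree(n_leaves: int, seed: int = 0):
    """A random binary unrooted tree with positive branch lengths.

    Returns (tree, labels); pairwise path lengths form an additive
    distance matrix on which neighbor joining is consistent.
    """
    from .phylo import TreeNode

    if n_leaves < 4:
        raise InputError("need at least 4 leaves")
    rng = np.random.default_rng(seed)

    def blen() -> float:
        return float(rng.uniform(0.05, 1.0))

    labels = [f"t{i}" for i in range(n_leaves)]
    nodes = [TreeNode(label=l, length=blen()) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[a, b], length=blen()))
    return TreeNode(children=nodes), labels


# ---------------------------------------------------------------------------
# the published genotype table (no sequences)

_TABLE1_ROWS = [
    # species, individual, region, site, [(allele, n_c2h2), ...]
    ("Tarsius syrichta", "TSY", "Philippines", "", [("TS1", 3)]),
    ("Tarsius bancanus", "TBA", "Sundaland", "", [("TB1", 8), ("TB2", 7)]),
    ("Tarsius dentatus", "T111", "Wallacea", "Laone", [("TD1", 9), ("TD2", 8)]),
    ("Tarsius lariang", "T47", "Wallacea", "Koja", [("TL1", 10), ("TL2", 7)]),
    ("Tarsius sp.", "CD02", "Wallacea", "Ogatemuku", [("TSP1", 9), ("TSP2", 10)]),
    ("Tarsius sp.", "CD05", "Wallacea", "Ogatemuku", [("TSP3", 9), ("TSP4", 9)]),
    ("Tarsius sp.", "CD10", "Wallacea", "Ogatemuku", [("TSP1", 9), ("TSP4", 9)]),
    ("Tarsius dentatus", "CD14", "Wallacea", "Korosule", [("TD3", 6), ("TD4", 7)]),
    ("Tarsius dentatus", "CD16", "Wallacea", "Korosule", [("TD5", 8), ("TD6", 9)]),
    ("Tarsius dentatus", "CD17", "Wallacea", "Korosule", [("TD3", 6), ("TD7", 6)]),
    ("Tarsius dentatus", "CD19", "Wallacea", "Luwuk", [("TD1", 9)]),
    ("Tarsius dentatus", "CD24", "Wallacea", "Luwuk", [("TD1", 9)]),
    ("Tarsius dentatus", "CD26", "Wallacea", "Luwuk", [("TD1", 9)]),
    ("Tarsius dentatus", "CD27", "Wallacea", "Luwuk", [("TD1", 9)]),
    ("Tarsius sp.", "CD34", "Wallacea", "Labanu", [("TSP5", 6)]),
    ("Tarsius sp.", "CD36", "Wallacea", "Labanu", [("TSP6", 10), ("TSP7", 10)]),
    ("Tarsius sp.", "CD41", "Wallacea", "Kendari", [("TSP8", 7), ("TSP9", 12)]),
    ("Tarsius sp.", "CD43", "Wallacea", "Kendari", [("TSP10", 10), ("TSP11", 7)]),
    ("Tarsius sp.", "CD46", "Wallacea", "Duasaudara", [("TSP12", 10)]),
    ("Tarsius sp.", "CD48", "Wallacea", "Duasaudara", [("TSP13", 10)]),
    ("Tarsius sp.", "CD51", "Wallacea", "Duasaudara", [("TSP14", 10), ("TSP12", 10)]),
    ("Tarsius fuscus", "CD64", "Wallacea", "Bantimurung", [("TF1", 6), ("TF2", 11)]),
    ("Tarsius fuscus", "CD65", "Wallacea", "Bantimurung", [("TF1", 6), ("TF2", 11)]),
]

# cross-reference of mnemonic allele IDs to numeric labels, assigned in
# first-seen table order
TABLE1_NUMERIC_IDS: dict[str, int] = {}
for _, _, _, _, _alleles in _TABLE1_ROWS:
    for _aid, _ in _alleles:
        if _aid not in TABLE1_NUMERIC_IDS:
            TABLE1_NUMERIC_IDS[_aid] = len(TABLE1_NUMERIC_IDS) + 1


def table1_fixture() -> list[GenotypeRecord]:
    """The study's genotype table: 23 individuals, allele IDs and C2H2
    finger numbers per allele (packaged data, no sequences)."""
    calls: dict[str, AlleleCall] = {}
    records = []
    for species, ind, region, site, alleles in _TABLE1_ROWS:
        acs = []
        for aid, n in alleles:
            if aid not in calls:
                calls[aid] = AlleleCall(allele_id=aid, n_c2h2=n)
            acs.append(calls[aid])
        a1 = acs[0]
        a2 = acs[1] if len(acs) == 2 else acs[0]
        records.append(
            GenotypeRecord(
                individual_id=ind,
                allele_1=a1,
                allele_2=a2,
                species_label=species,
                region_label=region,
                site_label=site,
            )
        )
    return records
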