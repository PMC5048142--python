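"""Sitewise dN/dS scan over the 28 codon columns of aligned C2H2 fingers.

Per-site synonymous/nonsynonymous sites and substitutions are counted by
the Nei-Gojobori (1986) pathway method, proportions are Jukes-Cantor
corrected, omega = dN/dS is tested against neutrality with an exact
binomial test on substitution counts, and p-values are Benjamini-
Hochberg corrected across sites.  Sites are classified POSITIVE
(omega > 1, q < alpha_pos), NEGATIVE (omega < 1, q < alpha_neg) or
UNDETERMINED.

The default comparison set is each sequence against the codon-wise
consensus column — the edge set of a star tree centred on the consensus.
Summing over all sequence pairs instead counts every substitution once
per pair it appears in, which inflates the binomial test's sample size
and destroys its calibration; the all-pairs mode is retained for
exploratory use with that caveat.
"""

from __future__ import annotations

import enum
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import permutations
from typing import Literal, Optional, Sequence

from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .grammar import InputError, helix_position
from .grammar import _CODON_TABLE as CODON_TABLE

__all__ = [
    "SiteCounts",
    "SiteSelectionResult",
    "SiteClass",
    "codon_sites",
    "codon_path_counts",
    "site_counts",
    "site_omega_test",
    "bh_adjust",
    "classify_sites",
    "selection_scan",
]

NUCS = "ACGT"
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")


class SiteClass(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    UNDETERMINED = "UNDETERMINED"


@dataclass
class SiteCounts:
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_subs: float = 0.0
    nonsyn_subs: float = 0.0


@dataclass
class SiteSelectionResult:
    site_index: int          # 1-based residue index within the 28-mer
    helix_pos: int           # helix-relative position (-10..-1, 1..18; no 0)
    counts: SiteCounts
    omega: Optional[float]   # None when dN = dS = 0
    omega_infinite: bool
    p_value: float
    q_value: float = 1.0
    classification: SiteClass = SiteClass.UNDETERMINED


# ---------------------------------------------------------------------------
# Nei-Gojobori codon machinery (cached closed-over tables)

def _syn_nonsyn_sites() -> dict[str, tuple[float, float]]:
    out = {}
    for codon, aa in CODON_TABLE.items():
        if aa == "*":
            continue
        s = 0.0
        for pos in range(3):
            syn = valid = 0
            for alt in NUCS:
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1 :]
                if mut in STOP_CODONS:
                    continue  # mutations to stops excluded from site counts
                valid += 1
                syn += CODON_TABLE[mut] == aa
            if valid:
                s += syn / valid
        out[codon] = (s, 3.0 - s)
    return out


_SITES = _syn_nonsyn_sites()
_PATH_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of a sense codon."""
    try:
        return _SITES[codon]
    except KeyError:
        raise InputError(f"invalid or stop codon {codon!r}")


def codon_path_counts(a: str, b: str) -> tuple[float, float]:
    """(syn, nonsyn) substitution counts between two codons, averaged over
    all shortest mutational paths; paths through stop codons excluded
    (all-stop path sets fall back to including them)."""
    if a == b:
        return (0.0, 0.0)
    key = (a, b) if a <= b else (b, a)
    if key in _PATH_CACHE:
        return _PATH_CACHE[key]
    diff = [i for i in range(3) if a[i] != b[i]]
    paths = []
    for order in permutations(diff):
        cur = a
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            paths.append((syn, nonsyn))
    if not paths:  # every path crosses a stop: average over all of them
        for order in permutations(diff):
            cur = a
            syn = nonsyn = 0
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                aa_c = CODON_TABLE[cur]
                aa_n = CODON_TABLE[nxt]
                if aa_c == aa_n:
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            paths.append((syn, nonsyn))
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    _PATH_CACHE[key] = (s, n)
    return (s, n)


# ---------------------------------------------------------------------------
# per-site counting

def _valid_codon(c: str) -> bool:
    return len(c) == 3 and all(x in NUCS for x in c) and c not in STOP_CODONS


def _codon_columns(rows: Sequence[str]) -> list[list[str]]:
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise InputError("rows of unequal length")
    if L % 3 != 0:
        raise InputError("row length not a multiple of 3")
    return [[r[3 * i : 3 * i + 3] for r in rows] for i in range(L // 3)]


def site_counts(
    rows: Sequence[str],
    mode: Literal["consensus", "pairs"] = "consensus",
) -> list[SiteCounts]:
    """Per-codon-site Nei-Gojobori counts accumulated over the comparison set.

    ``consensus`` compares each sequence to the modal codon of its column
    (star-tree edges); ``pairs`` accumulates over all sequence pairs.
    Cells with gaps, Ns or stop codons are skipped with a warning.
    """
    columns = _codon_columns(rows)
    out = []
    for col in columns:
        sc = SiteCounts()
        valid = [c for c in col if _valid_codon(c)]
        n_skipped = len(col) - len(valid)
        if n_skipped:
            warnings.warn(f"skipped {n_skipped} invalid codon cells")
        if len(valid) < 2:
            out.append(sc)
            continue
        if mode == "consensus":
            consensus = min(Counter(valid).most_common(),
                            key=lambda kv: (-kv[1], kv[0]))[0]
            comparisons = [(consensus, c) for c in valid]
        elif mode == "pairs":
            comparisons = [
                (valid[i], valid[j])
                for i in range(len(valid))
                for j in range(i + 1, len(valid))
            ]
        else:
            raise InputError(f"unknown mode {mode!r}")
        for a, b in comparisons:
            sa, na = codon_sites(a)
            sb, nb = codon_sites(b)
            sc.syn_sites += (sa + sb) / 2
            sc.nonsyn_sites += (na + nb) / 2
            s_sub, n_sub = codon_path_counts(a, b)
            sc.syn_subs += s_sub
            sc.nonsyn_subs += n_sub
        out.append(sc)
    return out


# ---------------------------------------------------------------------------
# testing and classification

def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def site_omega_test(c: SiteCounts) -> tuple[Optional[float], bool, float]:
    """(omega, infinite_flag, p_value) for one site.

    omega = dN/dS with Jukes-Cantor correction of the substitution
    proportions; the p-value is a two-sided exact binomial test of the
    nonsynonymous substitution count against the neutral expectation
    nonsyn_sites / (syn_sites + nonsyn_sites).
    """
    total_sites = c.syn_sites + c.nonsyn_sites
    if total_sites <= 0:
        raise InputError("no sites")
    k = round(c.nonsyn_subs)
    n = round(c.nonsyn_subs + c.syn_subs)
    if n == 0:
        return None, False, 1.0
    p0 = c.nonsyn_sites / total_sites
    p_value = binomtest(min(k, n), n, p0).pvalue
    pn = c.nonsyn_subs / c.nonsyn_sites if c.nonsyn_sites > 0 else 0.0
    ps = c.syn_subs / c.syn_sites if c.syn_sites > 0 else 0.0
    dn, ds = _jc_correct(pn), _jc_correct(ps)
    if ds == 0.0:
        if dn == 0.0:
            return None, False, 1.0
        return None, True, p_value
    if math.isinf(ds):
        return 0.0 if not math.isinf(dn) else 1.0, False, p_value
    if math.isinf(dn):
        return None, True, p_value
    return dn / ds, False, p_value


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    if len(p_values) == 0:
        return []
    if any(not (0 <= p <= 1) for p in p_values):
        raise InputError("p-values must lie in [0, 1]")
    if len(p_values) == 1:
        return [float(p_values[0])]
    _, q, _, _ = multipletests(p_values, method="fdr_bh")
    return list(q)


def classify_sites(
    results: list[SiteSelectionResult],
    alpha_pos: float = 0.01,
    alpha_neg: float = 0.05,
) -> list[SiteSelectionResult]:
    """Assign POSITIVE / NEGATIVE / UNDETERMINED from omega and q."""
    for r in results:
        omega_gt1 = r.omega_infinite or (r.omega is not None and r.omega > 1)
        omega_lt1 = (not r.omega_infinite and r.omega is not None and r.omega < 1)
        if omega_gt1 and r.q_value < alpha_pos:
            r.classification = SiteClass.POSITIVE
        elif omega_lt1 and r.q_value < alpha_neg:
            r.classification = SiteClass.NEGATIVE
        else:
            r.classification = SiteClass.UNDETERMINED
    return results


def selection_scan(
    rows: Sequence[str],
    mode: Literal["consensus", "pairs"] = "consensus",
    alpha_pos: float = 0.01,
    alpha_neg: float = 0.05,
) -> list[SiteSelectionResult]:
    """Full sitewise scan over codon-aligned finger rows (84-nt canonical)."""
    counts = site_counts(rows, mode=mode)
    results = []
    for i, c in enumerate(counts, start=1):
        if c.syn_sites + c.nonsyn_sites <= 0:
            results.append(
                SiteSelectionResult(i, helix_position(i), c, None, False, 1.0)
            )
            continue
        omega, inf_flag, p = site_omega_test(c)
        results.append(
            SiteSelectionResult(i, helix_position(i), c, omega, inf_flag, p)
        )
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return classify_sites(results, alpha_pos=alpha_pos, alpha_neg=alpha_neg)
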