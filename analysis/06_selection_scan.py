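#!/usr/bin/env python
"""Sitewise selection scan over the 28 finger codon positions.

Scans (a) the C2H2 fingers of the simulated allele pool and (b) a
powered star-tree simulation with omega = 5 at the three DNA-binding
positions and 0.1 elsewhere, verifying that the scan recovers positive
selection at helix -1/3/6 and purifying selection at the zinc ligands
(results/selection/)."""

from pathlib import Path

from prdm9znf import io
from prdm9znf.grammar import FingerClass, helix_position, segment_exon
from prdm9znf.selection import SiteClass, selection_scan
from prdm9znf.simulate import simulate_codon_alignment

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20160936
BINDING = {9, 12, 15}


def write_scan(results, path) -> None:
    with open(path, "w") as fh:
        fh.write("# consensus-edge counting; see docs/methods.md for caveats\n")
        fh.write("site\thelix_pos\tomega\tp\tq\tclass\n")
        for r in results:
            om = ("inf" if r.omega_infinite
                  else "" if r.omega is None else f"{r.omega:.4f}")
            fh.write(f"{r.site_index}\t{r.helix_pos}\t{om}\t"
                     f"{r.p_value:.4g}\t{r.q_value:.4g}\t{r.classification.value}\n")


def main() -> None:
    out = ROOT / "selection"
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for exon in io.read_fasta(ROOT / "simdata" / "pool.fasta"):
        for f in segment_exon(exon).array_fingers:
            if f.finger_class is FingerClass.C2H2:
                rows.append(exon.nt[f.nt_span[0] : f.nt_span[1]])
    pool_results = selection_scan(rows)
    write_scan(pool_results, out / "scan_pool_fingers.tsv")

    omega = [5.0 if i in BINDING else 0.1 for i in range(28)]
    sim_rows, _ = simulate_codon_alignment(300, omega, subs_per_codon=0.5,
                                           seed=SEED)
    sim_results = selection_scan(sim_rows)
    write_scan(sim_results, out / "scan_powered_simulation.tsv")

    pos = sorted(helix_position(r.site_index) for r in sim_results
                 if r.classification is SiteClass.POSITIVE)
    neg = len([r for r in sim_results if r.classification is SiteClass.NEGATIVE])
    print(f"pool fingers: {len(rows)} sequences scanned "
          f"-> {out / 'scan_pool_fingers.tsv'}")
    print(f"powered simulation: POSITIVE at helix positions {pos} "
          f"(expected [-1, 3, 6]), {neg} sites NEGATIVE")


if __name__ == "__main__":
    main()
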