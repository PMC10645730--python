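#!/usr/bin/env python
"""Forge the screening cohort: 40 annotated genomes with planted truth.

Ten genomes carry their only rrn operons on a small Rep_3 plasmid
(positives); thirty negatives cover every exclusion rule of the screen:
chromosomal operons, an oversized (>35 kb) rrn contig, a single-copy
marker on the rrn contig, rRNA genes split over two contigs, and an rrn
contig without a Rep gene. FASTA/GFF3 go to scratch/ (regenerable); the
truth table goes to results/.
"""

import json
from pathlib import Path

import rrnplasmid as rp

SEED = 101
ROOT = Path(__file__).resolve().parents[1]
GENOME_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

TRAPS = ("none", "rrn_contig_too_long", "rrn_contig_has_marker",
         "two_rrn_contigs", "rrn_contig_no_rep")


def main():
    GENOME_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    mix = [(lambda g: rp.positive_scenario(g), 0.25)] + [
        (lambda g, t=t: rp.trap_scenario(t, g), 0.15) for t in TRAPS
    ]
    cohort = rp.forge_cohort(40, mix, SEED)
    truths = []
    for record, truth in cohort:
        rp.write_genome(record, GENOME_DIR / f"{record.genome_id}.fasta",
                        GENOME_DIR / f"{record.genome_id}.gff")
        truths.append(truth.__dict__)
    (RESULTS / "cohort_truth.json").write_text(json.dumps(truths, indent=2))
    n_pos = sum(t["is_plasmid_only_rrn"] for t in truths)
    print(f"forged {len(truths)} genomes ({n_pos} plasmid-only-rrn positives) "
          f"-> {GENOME_DIR}")


if __name__ == "__main__":
    main()
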