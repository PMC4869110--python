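"""Generate the synthetic chromatin-digestion experiment for the analysis.

Writes the genome, digestion and naked-DNA midpoint libraries, mappability
and conservation tracks, the PWM, and the ground-truth table under
results/experiment/.  Downstream drivers (02-07) consume these files, so
the whole chain exercises the package's I/O layer end to end.
"""

from pathlib import Path

import numpy as np

from nucfoot import io as nio
from nucfoot.simulate import SimConfig, make_informative_pwm, simulate_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "experiment"

# Study conditions: 1000 planted sites, 100 midpoints/site, occupied sites
# digested 3x deeper, phased arrays at 160 bp decaying over 1.5 kb.
# min_gap keeps even the wide +/- 2 kb profiling windows of driver 05 clear
# of the neighboring sites' digestion spread.
CONFIG = SimConfig(n_sites=1000, mean_reads=100.0, min_gap=4500,
                   seed=20160517)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    pwm = make_informative_pwm()
    data = simulate_dataset(CONFIG, pwm=pwm)

    nio.write_fasta(OUT / "genome.fa", data.genome)
    nio.write_bedgraph(OUT / "mappability.bedgraph", data.mappability)
    nio.write_bedgraph(OUT / "conservation.bedgraph", data.conservation)
    nio.write_midpoints_bed(OUT / "midpoints.bed", data.midpoints)
    nio.write_midpoints_bed(OUT / "control_midpoints.bed",
                            data.control_midpoints)
    truth = data.truth_table()
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    # counts, not frequencies: the reader's 0.5/cell pseudocount is then
    # negligible instead of flattening the matrix
    counts = np.round(pwm.probs * 1000).astype(int)
    with open(OUT / "factor.pwm", "w") as fh:
        fh.write(f">{pwm.name}\n")
        for row_label, col in zip("ACGT", counts.T):
            fh.write(f"{row_label} [ " +
                     "  ".join(str(v) for v in col) + " ]\n")

    print(f"genome: {sum(data.chrom_lengths.values()):,} bp")
    print(f"planted sites: {len(data.instances)}, "
          f"bound fraction {data.occupancy.mean():.3f}")
    print(f"digest midpoints: {data.midpoints.n:,}; "
          f"control midpoints: {data.control_midpoints.n:,}")
    print(f"wrote experiment files to {OUT}")


if __name__ == "__main__":
    main()
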