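"""Covariate GLM triage: is the PWM predictive of the footprint calls?

Fits the fractional-logistic GLM of posteriors on (PWM, GC, conservation)
for the real factor and, as a negative control, for a pseudo-factor whose
posteriors are permuted across sites (breaking every covariate link).
Writes results/triage.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nucfoot.triage import fit_covariate_glm, select_factors, triage_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    post = pd.read_csv(ROOT / "posteriors.tsv", sep="\t")
    cov = pd.DataFrame({"pwm": post["pwm_score"], "gc": post["gc_flank"],
                        "cons": post["cons_score"]})
    pi = post["posterior"].to_numpy()

    rng = np.random.default_rng(1)
    results = [
        fit_covariate_glm(pi, cov, factor="factor"),
        fit_covariate_glm(rng.permutation(pi), cov,
                          factor="permuted_control"),
    ]
    kept, scatter = select_factors(results)
    for r in results:
        print(f"{r.factor}: Z_pwm={r.z[1]:+.2f} Z_gc={r.z[2]:+.2f} "
              f"Z_cons={r.z[3]:+.2f} -> {'kept' if r.kept else 'dropped'}")
    print(f"factors kept (Z_pwm >= 5): {kept}")

    triage_table(results).to_csv(ROOT / "triage.tsv", sep="\t", index=False)
    scatter.to_csv(ROOT / "triage_scatter.tsv", sep="\t", index=False)
    print(f"wrote {ROOT / 'triage.tsv'}")


if __name__ == "__main__":
    main()
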