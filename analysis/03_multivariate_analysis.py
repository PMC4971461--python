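"""Full multivariate analysis of the simulated cohort.

Reads the strain sequences written by 01_simulate_cohort.py (regenerating
them if absent), resamples each to 800 frames, and runs per muscle: PCA
with Hotelling T2 ellipse, OPLS discrimination with leave-one-out
cross-validation and 20-model permutation validation, and the Mann-Whitney
test on cross-validated scores.  Writes the figure set, score/loading
tables and the JSON summary under results/pipeline/.
"""

import subprocess
import sys
from pathlib import Path

from neckstrain.pipeline import PipelineConfig, run_pipeline

COHORT_CSV = Path("results/cohort/strain_sequences.csv")


def main() -> None:
    if not COHORT_CSV.exists():
        subprocess.run([sys.executable, "analysis/01_simulate_cohort.py"],
                       check=True)
    config = PipelineConfig(input_mode="strain-csv",
                            strain_csv=str(COHORT_CSV),
                            n_perm=20, seed=2016,
                            out_dir="results/pipeline")
    summary = run_pipeline(config)

    print(f"{'muscle':<22}{'R2Y':>7}{'Q2Y':>7}{'correct':>9}{'p':>9}  sig")
    for muscle, entry in summary["muscles"].items():
        o, mw = entry["opls"], entry["mann_whitney"]
        print(f"{muscle:<22}{o['r2y']:>7.3f}{o['q2y']:>7.3f}"
              f"{o['n_correct']:>6d}/{o['n_total']:<2d}"
              f"{mw['p_value']:>9.4f}  {'*' if mw['significant'] else ''}")
    sig = summary["significant_muscles"]
    print(f"significant muscles (p <= 0.05): "
          f"{', '.join(sig) if sig else 'none'}")
    print("wrote results/pipeline/summary.json and figures")


if __name__ == "__main__":
    main()
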