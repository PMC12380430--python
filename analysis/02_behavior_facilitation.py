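"""Behavioral facilitation: p(POR) rises over trials and intensities become
discriminable only after the early trials.

Reads results/data/behavior_block.csv (run 01_simulate_data.py first);
writes results/por_curves.csv and results/intensity_tests.csv.
"""

from pathlib import Path

import pandas as pd

import odoradapt as oa

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main() -> None:
    table = oa.read_behavior_table(DATA / "behavior_block.csv")
    OUT.mkdir(exist_ok=True)

    curves = []
    for stim in ("hex_H", "hex_L"):
        s = oa.por_probability(table, stim)
        for t, p in zip(s.trial_ids, s.p_por):
            curves.append({"stimulus": stim, "trial": t, "p_por": p})
    pd.DataFrame(curves).to_csv(OUT / "por_curves.csv", index=False)

    full = oa.intensity_ttest(table, "hex")
    early, late = oa.early_late_comparison(table, "hex", split_trial=5)
    tests = pd.DataFrame(
        [
            {"window": "all trials", "t": full.t_statistic, "p": full.p_value,
             "n_pairs": full.n_pairs},
            {"window": "trials 1-5", "t": early.t_statistic, "p": early.p_value,
             "n_pairs": early.n_pairs},
            {"window": "trials 6-10", "t": late.t_statistic, "p": late.p_value,
             "n_pairs": late.n_pairs},
        ]
    )
    tests.to_csv(OUT / "intensity_tests.csv", index=False)

    first = [c for c in curves if c["trial"] == 1]
    last = [c for c in curves if c["trial"] == 10]
    print("p(POR) trial 1 :", {c["stimulus"]: round(c["p_por"], 3) for c in first})
    print("p(POR) trial 10:", {c["stimulus"]: round(c["p_por"], 3) for c in last})
    print(tests.to_string(index=False))
    print(
        "finding: response probability facilitates with repetition, and the "
        "low-vs-high intensity contrast strengthens in the late trials "
        f"(p_early={early.p_value:.3g} vs p_late={late.p_value:.3g})."
    )


if __name__ == "__main__":
    main()
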