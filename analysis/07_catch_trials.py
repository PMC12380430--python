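"""Catch-trial specificity: adaptation is odor-specific, neurally and
behaviorally.

Neural: correlation of each trial's population vector with the first
hex trial dips sharply at the deviant (iaa) trial.  Behavioral: p(POR)
drops to the deviant's unadapted level on the catch trial.  Writes
results/catch_correlations.csv and results/catch_por.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import odoradapt as oa

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"


def main() -> None:
    tensor = oa.read_tensor(DATA / "tensor_catch.h5")
    proto = oa.StimulusProtocol.from_yaml(DATA / "protocol_catch.yaml")
    corr = oa.catch_trial_correlation(tensor, 0)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    pd.DataFrame(
        {"trial": tensor.trial_labels, "stimulus": tensor.stimulus_labels, "r": corr}
    ).to_csv(out / "catch_correlations.csv", index=False)
    k = proto.catch_trial_index - 1
    print(f"correlation with trial-1 hex response: catch trial r={corr[k]:.3f}, "
          f"other trials min r={np.delete(corr, k).min():.3f}")

    btable = oa.read_behavior_table(DATA / "behavior_catch.csv")
    bproto = oa.StimulusProtocol.from_yaml(DATA / "protocol_behavior_catch.yaml")
    report = oa.catch_trial_por(btable, bproto)
    pd.DataFrame({"trial": report["trial_ids"], "p_por": report["p_por"]}).to_csv(
        out / "catch_por.csv", index=False
    )
    print(f"catch-trial p(POR) {report['catch_p']:.3f} "
          f"(drop vs flanking trials {report['catch_drop']:+.3f})")
    print(
        "finding: the deviant stimulus escapes the repeated odor's "
        "adaptation (correlation dip) and elicits its own unadapted "
        "behavioral response level."
    )


if __name__ == "__main__":
    main()
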