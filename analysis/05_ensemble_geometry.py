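"""Ensemble geometry: odor trajectories shrink without rotating; trials
cluster by identity then intensity; trials classify by correlation.

Reads the block tensor and the CP model from 04; writes trajectory
summaries, the trial-correlation matrix, the dendrogram (Newick), and the
classification report under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

import odoradapt as oa

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main() -> None:
    tensor = oa.read_tensor(DATA / "tensor_block.h5")
    model = oa.load_cp_model(OUT / "cp_model.h5")
    OUT.mkdir(exist_ok=True)

    trajs = oa.trial_trajectories(model)
    rows = []
    for tr in trajs:
        raw_mean = tr.mean_point(centered=False)
        rows.append(
            {
                "stimulus": tr.stimulus_label,
                "trial": tr.trial_label,
                "diameter": tr.diameter(),
                "path_length": tr.path_length(),
                "direction_x": raw_mean[0] / np.linalg.norm(raw_mean),
                "direction_y": raw_mean[1] / np.linalg.norm(raw_mean),
                "direction_z": raw_mean[2] / np.linalg.norm(raw_mean),
            }
        )
    traj_df = pd.DataFrame(rows)
    traj_df.to_csv(OUT / "trajectories.csv", index=False)

    hex_h = traj_df[traj_df.stimulus == "hex_H"].set_index("trial")
    shrink = hex_h.loc[25, "diameter"] / hex_h.loc[1, "diameter"]
    d1 = hex_h.loc[1, ["direction_x", "direction_y", "direction_z"]].to_numpy(float)
    d25 = hex_h.loc[25, ["direction_x", "direction_y", "direction_z"]].to_numpy(float)
    print(f"hex_H trajectory: trial-25/trial-1 diameter ratio {shrink:.3f}, "
          f"direction cosine {d1 @ d25:.4f}")

    matrix = oa.trial_correlation_matrix(tensor)
    header = ",".join(f"t{t}_{s}" for t, s in zip(matrix.trial_labels, matrix.stimulus_labels))
    np.savetxt(OUT / "trial_correlations.csv", matrix.values, delimiter=",",
               header=header, comments="")

    tree = oa.cluster_dendrogram(matrix)
    (OUT / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
    odor = [s.split("_")[0] for s in tensor.stimulus_labels]
    ari2 = adjusted_rand_score(odor, tree.cut(2))
    ari4 = adjusted_rand_score(tensor.stimulus_labels, tree.cut(4))
    print(f"dendrogram cuts: 2-cluster ARI vs odor {ari2:.2f}, "
          f"4-cluster ARI vs odor+intensity {ari4:.2f}")

    report = oa.classify_trials(tensor)
    pd.DataFrame(
        [{"class": c, "accuracy": a} for c, a in report.per_class_accuracy.items()]
        + [{"class": "overall", "accuracy": report.overall_accuracy}]
    ).to_csv(OUT / "classification.csv", index=False)
    report.confusion.to_csv(OUT / "confusion.csv")
    print(f"leave-one-trial-out accuracy {report.overall_accuracy:.3f} "
          f"over {report.n_trials} trials")
    print(
        "finding: trajectories shrink with repetition but keep their "
        "direction; identity and intensity stay linearly readable from "
        "vector direction across all trials."
    )


if __name__ == "__main__":
    main()
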