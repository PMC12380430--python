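"""Palp-opening-response (POR) analyses.

p(POR) is the fraction of animals responding on a trial.  Intensity
discrimination uses a paired left-tailed t-test on per-animal mean POR at
the low vs. high intensity of the same odor (the pairing is on animals);
the neural-behavioral link is an ordinary least-squares regression of
p(POR) on the total ensemble spike count of the same trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .adaptation import RegressionFit, _ols
from .errors import AlignmentError, PairingError, UsageError
from .protocol import HIGH_SUFFIX, LOW_SUFFIX, StimulusProtocol


@dataclass
class PORSummary:
    """Per-trial response probability for one stimulus."""

    p_por: np.ndarray
    trial_ids: np.ndarray
    n_animals: int
    stimulus_label: str


@dataclass
class PairedTestResult:
    t_statistic: float
    p_value: float
    n_pairs: int
    tail: str = "left"


def por_probability(table: pd.DataFrame, stimulus: str) -> PORSummary:
    """Fraction of animals responding per trial, trial order preserved."""
    sel = table.loc[table["stimulus_label"] == stimulus]
    if len(sel) == 0:
        raise UsageError(f"stimulus {stimulus!r} absent from the behavior table")
    grouped = sel.groupby("trial_id", sort=True)["por"]
    p = grouped.mean()
    return PORSummary(
        p_por=p.to_numpy(dtype=float),
        trial_ids=p.index.to_numpy(dtype=int),
        n_animals=int(sel["animal_id"].nunique()),
        stimulus_label=stimulus,
    )


def _paired_left_ttest(low: np.ndarray, high: np.ndarray) -> PairedTestResult:
    """Left-tailed paired t-test of H1: mean(low) < mean(high).

    When every pairwise difference is zero the statistic is defined as
    t = 0, p = 0.5 (the symmetric null center) rather than NaN.
    """
    diffs = np.asarray(low, dtype=float) - np.asarray(high, dtype=float)
    n = len(diffs)
    if n < 2:
        raise UsageError("need at least 2 pairs")
    sd = diffs.std(ddof=1)
    if sd == 0:
        if diffs[0] == 0:
            return PairedTestResult(0.0, 0.5, n)
        t = -np.inf if diffs[0] < 0 else np.inf
        return PairedTestResult(float(t), 0.0 if t < 0 else 1.0, n)
    t = diffs.mean() / (sd / np.sqrt(n))
    p = float(stats.t.cdf(t, df=n - 1))
    return PairedTestResult(float(t), p, n)


def intensity_ttest(table: pd.DataFrame, odor: str, trials=None) -> PairedTestResult:
    """Paired left-tailed t-test: is per-animal p(POR) at the low intensity
    of ``odor`` smaller than at the high intensity?

    The per-animal statistic is the mean POR over the selected 1-based
    trial numbers (all trials by default); every animal must have both
    intensities.
    """
    low_label, high_label = odor + LOW_SUFFIX, odor + HIGH_SUFFIX
    sel = table.loc[table["stimulus_label"].isin([low_label, high_label])].copy()
    if trials is not None:
        trials = set(int(t) for t in trials)
        sel = sel.loc[sel["trial_id"].isin(trials)]
    if len(sel) == 0:
        raise UsageError(f"no rows for odor {odor!r} in the selected trials")
    per_animal = sel.pivot_table(
        index="animal_id", columns="stimulus_label", values="por", aggfunc="mean"
    )
    for label in (low_label, high_label):
        if label not in per_animal.columns:
            raise PairingError(f"no animal has stimulus {label!r}")
    unpaired = per_animal.index[per_animal[[low_label, high_label]].isna().any(axis=1)]
    if len(unpaired):
        raise PairingError(
            f"animal(s) missing one intensity of {odor!r}: {sorted(unpaired)}"
        )
    return _paired_left_ttest(
        per_animal[low_label].to_numpy(), per_animal[high_label].to_numpy()
    )


def early_late_comparison(
    table: pd.DataFrame, odor: str, split_trial: int = 5
) -> tuple[PairedTestResult, PairedTestResult]:
    """Intensity t-test run separately on trials 1..split and split+1..end."""
    trials = sorted(table.loc[
        table["stimulus_label"].isin([odor + LOW_SUFFIX, odor + HIGH_SUFFIX]), "trial_id"
    ].unique())
    if not trials:
        raise UsageError(f"no rows for odor {odor!r}")
    if split_trial < trials[0] or split_trial >= trials[-1]:
        raise UsageError(
            f"split_trial {split_trial} leaves no trials on one side of 1..{trials[-1]}"
        )
    early = [t for t in trials if t <= split_trial]
    late = [t for t in trials if t > split_trial]
    return intensity_ttest(table, odor, early), intensity_ttest(table, odor, late)


def bonferroni(p_values, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values (capped at 1) for callers that pool
    several per-odor tests; the default analyses report per odor without
    correction."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if n_tests is None else n_tests
    if m < 1:
        raise UsageError("need at least one test to correct")
    return np.minimum(p * m, 1.0)


def neural_behavior_regression(counts, por: PORSummary | np.ndarray) -> RegressionFit:
    """OLS of per-trial p(POR) on per-trial total ensemble spike count.

    A negative slope quantifies the dissociation: neural responses shrink
    over trials while the behavioral response probability facilitates.
    """
    p = por.p_por if isinstance(por, PORSummary) else np.asarray(por, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if counts.shape != p.shape:
        raise AlignmentError(
            f"counts ({counts.shape}) and p(POR) ({p.shape}) must share trial count"
        )
    return _ols(counts, p)


def catch_trial_por(table: pd.DataFrame, protocol: StimulusProtocol) -> dict:
    """p(POR) sequence of a catch-trial block plus the catch drop.

    ``catch_drop`` is the catch-trial p(POR) minus the mean of the two
    flanking repeated-odor trials (negative = the deviant evokes fewer
    responses than the adapted, facilitated stream around it).
    """
    if not protocol.has_catch:
        raise UsageError("protocol declares no catch trial")
    repeated = protocol.block_sequence[0]
    idx = protocol.catch_trial_index
    per_trial = []
    for k in range(1, protocol.n_trials_per_block + 1):
        stim = protocol.stimulus_for(repeated, k)
        sel = table.loc[
            (table["stimulus_label"] == stim) & (table["trial_id"] == k), "por"
        ]
        if len(sel) == 0:
            raise UsageError(f"behavior table has no rows for trial {k} ({stim!r})")
        per_trial.append(float(sel.mean()))
    p = np.asarray(per_trial)
    flank = [k for k in (idx - 1, idx + 1) if 1 <= k <= protocol.n_trials_per_block]
    catch_drop = float(p[idx - 1] - np.mean([p[k - 1] for k in flank]))
    return {
        "p_por": p,
        "trial_ids": np.arange(1, protocol.n_trials_per_block + 1),
        "catch_trial_index": idx,
        "catch_p": float(p[idx - 1]),
        "catch_drop": catch_drop,
    }
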