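"""In-memory containers shared across the pipeline.

``TrialTensor`` is the central object: the Neuron x TimeBin x Trial
spike-count array, with named axes so that no analysis can silently
transpose dimensions.  Spike-event and behavior tables are plain pandas
DataFrames with documented schemas (see :mod:`odoradapt.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError, ValidationError

#: Valid reductions from a tensor slice to a per-unit population vector.
REDUCTIONS = ("sum_window", "mean_per_bin")


@dataclass
class TrialTensor:
    """Spike counts indexed (unit i, time bin j, trial k).

    Attributes
    ----------
    counts
        Integer array of shape ``(n_units, n_bins, n_trials)``.
    bin_edges_s
        Bin edges in seconds relative to odor onset, length ``n_bins + 1``.
    unit_labels, trial_labels, stimulus_labels
        Axis labels; ``trial_labels`` are 1-based trial numbers within
        their block and ``stimulus_labels`` give the stimulus presented on
        each trial (one entry per trial-axis position).
    """

    counts: np.ndarray
    bin_edges_s: np.ndarray
    unit_labels: list[str]
    trial_labels: list[int]
    stimulus_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.bin_edges_s = np.asarray(self.bin_edges_s, dtype=float)
        self.unit_labels = [str(u) for u in self.unit_labels]
        self.trial_labels = [int(t) for t in self.trial_labels]
        self.stimulus_labels = [str(s) for s in self.stimulus_labels]
        self.validate()

    def validate(self) -> None:
        if self.counts.ndim != 3:
            raise ValidationError(f"counts must be 3-way, got shape {self.counts.shape}")
        n_units, n_bins, n_trials = self.counts.shape
        if np.any(self.counts < 0):
            raise ValidationError("negative spike counts")
        if len(self.bin_edges_s) != n_bins + 1:
            raise ValidationError(
                f"{len(self.bin_edges_s)} bin edges for {n_bins} bins (need n_bins + 1)"
            )
        if len(self.unit_labels) != n_units:
            raise ValidationError("unit_labels length does not match unit axis")
        if len(self.trial_labels) != n_trials:
            raise ValidationError("trial_labels length does not match trial axis")
        if len(self.stimulus_labels) != n_trials:
            raise ValidationError("stimulus_labels length does not match trial axis")

    # -- convenience -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape  # type: ignore[return-value]

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[2]

    def trial_index(self, trial_label: int, stimulus: str | None = None) -> int:
        """0-based trial-axis position of a 1-based trial number.

        If the same trial number occurs in several blocks, ``stimulus``
        disambiguates.
        """
        hits = [
            k
            for k, (t, s) in enumerate(zip(self.trial_labels, self.stimulus_labels))
            if t == trial_label and (stimulus is None or s == stimulus)
        ]
        if not hits:
            raise UsageError(f"trial {trial_label!r} (stimulus {stimulus!r}) not in tensor")
        if len(hits) > 1:
            raise UsageError(
                f"trial {trial_label!r} is ambiguous across blocks; pass stimulus="
            )
        return hits[0]

    def equals(self, other: "TrialTensor") -> bool:
        return (
            np.array_equal(self.counts, other.counts)
            and np.array_equal(self.bin_edges_s, other.bin_edges_s)
            and self.unit_labels == other.unit_labels
            and self.trial_labels == other.trial_labels
            and self.stimulus_labels == other.stimulus_labels
        )


@dataclass
class PopulationVector:
    """Per-trial, per-unit activity vector (the object of correlation and
    clustering analyses).

    ``reduction`` records how the time axis was collapsed: ``sum_window``
    (total in-window count per unit) or ``mean_per_bin`` (time-averaged
    count per unit).  The two differ by the positive constant ``n_bins``,
    so Pearson correlations are identical under either.
    """

    values: np.ndarray
    trial_label: int
    stimulus_label: str
    reduction: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.reduction not in REDUCTIONS:
            raise UsageError(f"unknown reduction {self.reduction!r}; use one of {REDUCTIONS}")
        if self.values.ndim != 1:
            raise ValidationError("population vector must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("population vector contains non-finite values")
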