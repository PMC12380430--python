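"""Spike events -> tensors, PSTHs, population vectors, and unit QC.

Binning uses half-open bins ``[t, t + width)`` over the odor window; spikes
outside the window (including one exactly at the window end) are excluded,
and the tensor's total mass equals the number of in-window events exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import REDUCTIONS, PopulationVector, TrialTensor
from .errors import UsageError, ValidationError
from .io import QC_COLUMNS, validate_spike_events
from .protocol import StimulusProtocol

#: Single-unit acceptance thresholds from the spike-sorting procedure:
#: cluster separation > 5 noise SD, < 6.5% of spikes within 20 ms of
#: another spike of the same unit, waveform variance < 6.5 noise units.
QC_MIN_SEPARATION = 5.0
QC_MAX_ISI_VIOLATION = 0.065
QC_MAX_WAVEFORM_VARIANCE = 6.5


def bin_spikes(
    events: pd.DataFrame,
    protocol: StimulusProtocol,
    unit_labels: list[str] | None = None,
) -> TrialTensor:
    """Bin a spike-event table into a Neuron x TimeBin x Trial count tensor.

    Trials are ordered block-by-block in protocol order, earlier trials
    first.  ``unit_labels`` fixes the unit axis (required to represent
    silent units or an empty table); by default the sorted unit ids present
    in ``events`` are used.
    """
    validate_spike_events(events, protocol)
    if unit_labels is None:
        unit_labels = sorted(events["unit_id"].unique())
    unit_pos = {u: i for i, u in enumerate(unit_labels)}
    unknown = set(events["unit_id"]) - set(unit_labels)
    if unknown:
        raise ValidationError(f"events contain unit ids not in unit_labels: {sorted(unknown)}")

    edges = protocol.bin_edges()
    n_blocks = len(protocol.block_sequence)
    n_per = protocol.n_trials_per_block
    trial_labels = [k for _ in range(n_blocks) for k in range(1, n_per + 1)]
    stimulus_labels = [
        protocol.stimulus_for(block, k)
        for block in protocol.block_sequence
        for k in range(1, n_per + 1)
    ]
    counts = np.zeros((len(unit_labels), protocol.n_bins, n_blocks * n_per), dtype=int)

    start, end = protocol.odor_window_s
    t = events["spike_time_s"].to_numpy(dtype=float)
    in_window = (t >= start) & (t < end)  # half-open window
    sel = events.loc[in_window]
    if len(sel):
        i = np.fromiter((unit_pos[u] for u in sel["unit_id"]), dtype=int, count=len(sel))
        j = np.floor(
            (sel["spike_time_s"].to_numpy(dtype=float) - start) / protocol.bin_width_s
        ).astype(int)
        j = np.minimum(j, protocol.n_bins - 1)  # guard float edge of interior bins
        k = (sel["block_id"].to_numpy(dtype=int) - 1) * n_per + (
            sel["trial_id"].to_numpy(dtype=int) - 1
        )
        np.add.at(counts, (i, j, k), 1)
    return TrialTensor(counts, edges, list(unit_labels), trial_labels, stimulus_labels)


def psth(tensor: TrialTensor, trials) -> np.ndarray:
    """Peristimulus time histogram: mean count per bin per unit.

    ``trials`` is a sequence of 0-based trial-axis positions (or a single
    position); the PSTH averages over units and the selected trials, in
    units of spikes per bin per unit.
    """
    trials = np.atleast_1d(np.asarray(trials, dtype=int))
    if trials.size == 0:
        raise UsageError("empty trial selector")
    if trials.min() < 0 or trials.max() >= tensor.n_trials:
        raise UsageError(f"trial selector outside 0..{tensor.n_trials - 1}")
    return tensor.counts[:, :, trials].mean(axis=(0, 2))


def population_vector(tensor: TrialTensor, trial: int, reduction: str = "sum_window") -> PopulationVector:
    """Collapse one trial's slice to a per-unit vector.

    ``trial`` is the 0-based trial-axis position.  ``sum_window`` gives
    total in-window counts per unit; ``mean_per_bin`` the time-averaged
    count (the two differ by the positive factor ``n_bins``, so Pearson
    correlations are identical).
    """
    if reduction not in REDUCTIONS:
        raise UsageError(f"unknown reduction {reduction!r}; use one of {REDUCTIONS}")
    if not (0 <= trial < tensor.n_trials):
        raise UsageError(f"trial position {trial} outside 0..{tensor.n_trials - 1}")
    sums = tensor.counts[:, :, trial].sum(axis=1).astype(float)
    values = sums if reduction == "sum_window" else sums / tensor.n_bins
    return PopulationVector(
        values=values,
        trial_label=tensor.trial_labels[trial],
        stimulus_label=tensor.stimulus_labels[trial],
        reduction=reduction,
    )


def unit_qc_filter(metrics: pd.DataFrame) -> set[str]:
    """Apply the single-unit quality criteria; returns passing unit ids.

    A unit passes iff separation > 5 noise SD AND ISI-violation fraction
    < 0.065 AND waveform variance < 6.5 — all inequalities strict.
    """
    missing = [c for c in QC_COLUMNS if c not in metrics.columns]
    if missing:
        raise ValidationError(f"QC metrics missing column(s) {missing}")
    for col in QC_COLUMNS[1:]:
        vals = metrics[col]
        if vals.isna().any():
            unit = metrics.loc[vals.isna(), "unit_id"].iloc[0]
            raise ValidationError(f"missing {col} for unit {unit!r}")
        if (vals.to_numpy(dtype=float) < 0).any():
            raise ValidationError(f"negative {col}")
    ok = (
        (metrics["cluster_separation_noise_sd"].to_numpy(dtype=float) > QC_MIN_SEPARATION)
        & (metrics["isi_violation_fraction"].to_numpy(dtype=float) < QC_MAX_ISI_VIOLATION)
        & (metrics["waveform_variance_noise_sd"].to_numpy(dtype=float) < QC_MAX_WAVEFORM_VARIANCE)
    )
    return set(metrics.loc[ok, "unit_id"].astype(str))
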