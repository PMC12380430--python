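"""Stimulus protocol description.

A protocol declares the block design used both by the simulator and by the
binning/analysis code: trials per block, the odor window, bin width, and
(optionally) a catch trial embedded in the block.  Trial numbering is
1-based throughout ("the 26th trial" is ``trial_id == 26``); array indices
are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ValidationError

#: Suffixes conventionally used to tag stimulus intensity in labels such as
#: ``"hex_H"`` / ``"hex_L"``.
HIGH_SUFFIX = "_H"
LOW_SUFFIX = "_L"


def odor_of(label: str) -> str:
    """Strip an intensity suffix from a stimulus label, if present."""
    for suf in (HIGH_SUFFIX, LOW_SUFFIX):
        if label.endswith(suf):
            return label[: -len(suf)]
    return label


def intensity_of(label: str) -> str:
    """Return ``"H"`` or ``"L"`` from a stimulus label (default high)."""
    return "L" if label.endswith(LOW_SUFFIX) else "H"


@dataclass
class StimulusProtocol:
    """Block design of an odor-presentation experiment.

    Parameters
    ----------
    n_trials_per_block
        Number of trials in each block (25 in the repeated-odor design,
        30 in the catch-trial design).
    odor_window_s
        ``[start, end]`` of the odor presentation window in seconds
        relative to odor onset; the analysis window is half-open
        ``[start, end)``.
    inter_trial_interval_s
        Seconds between trial onsets (60 s in the reference design).
    bin_width_s
        Width of the non-overlapping spike-count bins (0.05 s).
    reset_interval_min
        Minutes of no-stimulation between consecutive blocks (15 min).
    block_sequence
        Ordered stimulus labels, one per block, e.g.
        ``["hex_H", "hex_L", "oct_H", "oct_L"]``.
    catch_trial_index
        1-based trial number at which a deviant stimulus replaces the
        repeated one (e.g. 26), or ``None`` for no catch trial.
    catch_stimulus
        Label of the deviant stimulus presented on the catch trial.
    """

    n_trials_per_block: int = 25
    odor_window_s: tuple[float, float] = (0.0, 4.0)
    inter_trial_interval_s: float = 60.0
    bin_width_s: float = 0.05
    reset_interval_min: float = 15.0
    block_sequence: list[str] = field(default_factory=lambda: ["odor_H"])
    catch_trial_index: int | None = None
    catch_stimulus: str | None = None

    def __post_init__(self) -> None:
        self.odor_window_s = (float(self.odor_window_s[0]), float(self.odor_window_s[1]))
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        start, end = self.odor_window_s
        if not (start < end):
            raise ValidationError(f"odor window start must precede end, got {self.odor_window_s}")
        if self.n_trials_per_block < 1:
            raise ValidationError("n_trials_per_block must be >= 1")
        if self.bin_width_s <= 0:
            raise ValidationError("bin_width_s must be positive")
        n = (end - start) / self.bin_width_s
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ValidationError(
                f"bin width {self.bin_width_s} s does not divide the odor window "
                f"{self.odor_window_s} (would give {n} bins)"
            )
        if not self.block_sequence:
            raise ValidationError("block_sequence must not be empty")
        if (self.catch_trial_index is None) != (self.catch_stimulus is None):
            raise ValidationError("catch_trial_index and catch_stimulus must be given together")
        if self.catch_trial_index is not None and not (
            1 <= self.catch_trial_index <= self.n_trials_per_block
        ):
            raise ValidationError(
                f"catch_trial_index {self.catch_trial_index} outside block of "
                f"{self.n_trials_per_block} trials"
            )

    # -- derived geometry ------------------------------------------------

    @property
    def n_bins(self) -> int:
        start, end = self.odor_window_s
        return round((end - start) / self.bin_width_s)

    @property
    def has_catch(self) -> bool:
        return self.catch_trial_index is not None

    def bin_edges(self):
        """Bin edges over the odor window (``n_bins + 1`` values)."""
        import numpy as np

        start, end = self.odor_window_s
        return start + self.bin_width_s * np.arange(self.n_bins + 1)

    def stimulus_for(self, block_label: str, trial_id: int) -> str:
        """Stimulus presented on a given trial of a block (catch-aware)."""
        if self.has_catch and trial_id == self.catch_trial_index:
            return self.catch_stimulus  # type: ignore[return-value]
        return block_label

    # -- serialization ---------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["odor_window_s"] = list(self.odor_window_s)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StimulusProtocol":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValidationError(f"protocol file {path} does not contain a mapping")
        try:
            d["odor_window_s"] = tuple(d["odor_window_s"])
            return cls(**d)
        except TypeError as exc:
            raise ValidationError(f"bad protocol file {path}: {exc}") from exc


def default_block_protocol(stimuli=("hex_H", "hex_L", "oct_H", "oct_L")) -> StimulusProtocol:
    """The 25-trial repeated-odor block design (4-s window, 50-ms bins)."""
    return StimulusProtocol(block_sequence=list(stimuli))


def default_catch_protocol(repeated="hex_H", catch="iaa_H") -> StimulusProtocol:
    """The 30-trial catch design: the deviant replaces trial 26."""
    return StimulusProtocol(
        n_trials_per_block=30,
        block_sequence=[repeated],
        catch_trial_index=26,
        catch_stimulus=catch,
    )
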