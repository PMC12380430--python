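"""On-disk formats: delimited text tables and the named-axis tensor container.

All text tables are comma-delimited UTF-8 with a mandatory header and '.'
decimal separator.  Tensors persist in HDF5 with one dataset per axis label
vector so that a round trip can never transpose axes silently.

Schemas
-------
spike events : ``unit_id,block_id,trial_id,stimulus_label,spike_time_s``
    One row per spike; times in seconds relative to odor onset (negative =
    pre-stimulus).  ``block_id`` is the 1-based block position in the
    protocol's ``block_sequence``; ``trial_id`` is the 1-based trial number
    within the block.
behavior : ``animal_id,trial_id,stimulus_label,por``
    One row per animal x trial; ``por`` is strictly binary
    ({0, 1, true, false}).
unit QC metrics : ``unit_id,cluster_separation_noise_sd,isi_violation_fraction,waveform_variance_noise_sd``
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py

from .containers import TrialTensor
from .errors import FormatError, IntegrityError, ParseError, ValidationError
from .protocol import StimulusProtocol

SPIKE_COLUMNS = ["unit_id", "block_id", "trial_id", "stimulus_label", "spike_time_s"]
BEHAVIOR_COLUMNS = ["animal_id", "trial_id", "stimulus_label", "por"]
QC_COLUMNS = [
    "unit_id",
    "cluster_separation_noise_sd",
    "isi_violation_fraction",
    "waveform_variance_noise_sd",
]

_BINARY_TRUE = {"1", "true"}
_BINARY_FALSE = {"0", "false"}

_TENSOR_FORMAT = "odoradapt-trial-tensor-v1"


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")


def _parse_numeric(series: pd.Series, name: str, path, as_int: bool = False) -> np.ndarray:
    parsed = pd.to_numeric(series, errors="coerce")
    bad = parsed.isna() & series.notna() | series.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric {name} {series.iloc[row]!r} at data row {row + 1}"
        )
    if as_int:
        vals = parsed.to_numpy()
        if np.any(vals != np.round(vals)):
            row = int(np.flatnonzero(vals != np.round(vals))[0])
            raise ParseError(f"{path}: non-integer {name} at data row {row + 1}")
        return vals.astype(int)
    return parsed.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# spike events
# ---------------------------------------------------------------------------


def validate_spike_events(df: pd.DataFrame, protocol: StimulusProtocol, source="<table>") -> pd.DataFrame:
    """Validate an in-memory spike-event table against a protocol."""
    if not np.all(np.isfinite(df["spike_time_s"].to_numpy(dtype=float))):
        raise ValidationError(f"{source}: non-finite spike times")
    n_blocks = len(protocol.block_sequence)
    blocks = df["block_id"].to_numpy()
    if len(blocks) and (blocks.min() < 1 or blocks.max() > n_blocks):
        raise ValidationError(
            f"{source}: block_id outside 1..{n_blocks} of the declared protocol"
        )
    trials = df["trial_id"].to_numpy()
    if len(trials) and (trials.min() < 1 or trials.max() > protocol.n_trials_per_block):
        bad = trials[(trials < 1) | (trials > protocol.n_trials_per_block)][0]
        raise ValidationError(
            f"{source}: trial_id {bad} outside 1..{protocol.n_trials_per_block} "
            "of the declared protocol"
        )
    for (b, t), grp in df.groupby(["block_id", "trial_id"], sort=False):
        expected = protocol.stimulus_for(protocol.block_sequence[int(b) - 1], int(t))
        got = set(grp["stimulus_label"])
        if got != {expected}:
            raise ValidationError(
                f"{source}: block {b} trial {t} labeled {sorted(got)}, protocol says "
                f"{expected!r}"
            )
    return df


def read_spike_events(path, protocol: StimulusProtocol) -> pd.DataFrame:
    """Read and validate a spike-event CSV.

    Returns a DataFrame with columns ``unit_id`` (str), ``block_id`` (int),
    ``trial_id`` (int), ``stimulus_label`` (str), ``spike_time_s`` (float).
    """
    raw = pd.read_csv(path, dtype=str)
    _require_columns(raw, SPIKE_COLUMNS, path)
    df = pd.DataFrame(
        {
            "unit_id": raw["unit_id"].astype(str),
            "block_id": _parse_numeric(raw["block_id"], "block_id", path, as_int=True),
            "trial_id": _parse_numeric(raw["trial_id"], "trial_id", path, as_int=True),
            "stimulus_label": raw["stimulus_label"].astype(str),
            "spike_time_s": _parse_numeric(raw["spike_time_s"], "spike_time_s", path),
        }
    )
    if len(raw) == 0:
        # preserve a valid empty schema
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            SPIKE_COLUMNS, [str, int, int, str, float])})
    return validate_spike_events(df, protocol, source=path)


def write_spike_events(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=SPIKE_COLUMNS)


# ---------------------------------------------------------------------------
# behavior tables
# ---------------------------------------------------------------------------


def _coerce_binary(series: pd.Series, path) -> np.ndarray:
    out = np.empty(len(series), dtype=bool)
    for row, val in enumerate(series):
        token = str(val).strip().lower()
        if token in _BINARY_TRUE:
            out[row] = True
        elif token in _BINARY_FALSE:
            out[row] = False
        else:
            raise ParseError(
                f"{path}: por value {val!r} at data row {row + 1} is not in "
                "{0, 1, true, false}"
            )
    return out


def read_behavior_table(path) -> pd.DataFrame:
    """Read a behavior CSV; ``por`` is coerced only from an explicit binary set."""
    raw = pd.read_csv(path, dtype=str)
    _require_columns(raw, BEHAVIOR_COLUMNS, path)
    df = pd.DataFrame(
        {
            "animal_id": raw["animal_id"].astype(str),
            "trial_id": _parse_numeric(raw["trial_id"], "trial_id", path, as_int=True),
            "stimulus_label": raw["stimulus_label"].astype(str),
            "por": _coerce_binary(raw["por"], path),
        }
    )
    if len(raw) == 0:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            BEHAVIOR_COLUMNS, [str, int, str, bool])})
    dupes = df.duplicated(subset=["animal_id", "trial_id", "stimulus_label"])
    if dupes.any():
        row = int(np.flatnonzero(dupes.to_numpy())[0])
        raise ValidationError(
            f"{path}: duplicate (animal_id, trial_id, stimulus_label) at data row {row + 1}"
        )
    if len(df) and (df["trial_id"].to_numpy() < 1).any():
        raise ValidationError(f"{path}: trial_id must be a positive integer")
    return df


def write_behavior_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["por"] = out["por"].astype(int)
    out.to_csv(path, index=False, columns=BEHAVIOR_COLUMNS)


# ---------------------------------------------------------------------------
# unit QC metrics
# ---------------------------------------------------------------------------


def read_unit_qc_metrics(path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str)
    _require_columns(raw, QC_COLUMNS, path)
    df = pd.DataFrame({"unit_id": raw["unit_id"].astype(str)})
    for col in QC_COLUMNS[1:]:
        df[col] = _parse_numeric(raw[col], col, path)
        if (df[col].to_numpy() < 0).any():
            raise ValidationError(f"{path}: negative {col}")
    return df


# ---------------------------------------------------------------------------
# tensor container
# ---------------------------------------------------------------------------


def write_tensor(tensor: TrialTensor, path) -> None:
    """Persist a trial tensor with named axes (HDF5)."""
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = _TENSOR_FORMAT
        fh.create_dataset("counts", data=tensor.counts)
        fh.create_dataset("bin_edges_s", data=tensor.bin_edges_s)
        fh.create_dataset("unit_labels", data=np.array(tensor.unit_labels, dtype=object), dtype=str_dt)
        fh.create_dataset("trial_labels", data=np.asarray(tensor.trial_labels, dtype=int))
        fh.create_dataset("stimulus_labels", data=np.array(tensor.stimulus_labels, dtype=object), dtype=str_dt)


def read_tensor(path) -> TrialTensor:
    """Read a trial tensor; axis/label mismatches raise ``IntegrityError``."""
    try:
        with h5py.File(path, "r") as fh:
            if fh.attrs.get("format") != _TENSOR_FORMAT:
                raise IntegrityError(f"{path}: not a trial-tensor container")
            required = ["counts", "bin_edges_s", "unit_labels", "trial_labels", "stimulus_labels"]
            missing = [k for k in required if k not in fh]
            if missing:
                raise IntegrityError(f"{path}: missing dataset(s) {missing}")
            counts = fh["counts"][()]
            edges = fh["bin_edges_s"][()]
            units = [u.decode() if isinstance(u, bytes) else str(u) for u in fh["unit_labels"][()]]
            trials = [int(t) for t in fh["trial_labels"][()]]
            stims = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["stimulus_labels"][()]]
    except OSError as exc:
        raise IntegrityError(f"{path}: unreadable or truncated container ({exc})") from exc
    try:
        return TrialTensor(counts, edges, units, trials, stims)
    except ValidationError as exc:
        raise IntegrityError(f"{path}: inconsistent container: {exc}") from exc
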