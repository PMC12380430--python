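"""Synthetic spike-train and behavior generator.

The generator produces spike-event and behavior tables with the statistical
structure the downstream analyses assume:

* odor-specific tuning directions across units, with intensity-dependent
  gain plus a partial re-draw of tuning for low intensity (so some units
  prefer the lower concentration);
* trial-wise response adaptation under three mechanisms —

  ``magnitude_only``
      every unit's evoked response is scaled by the same multiplier
      ``m_k = plateau + (1 - plateau) * exp(-(k-1)/tau)``: vector length
      shrinks, direction is preserved exactly in expectation;
  ``vesicle_depletion``
      suppression grows with a unit's own trial-1 drive,
      ``m_k(u) = 1 - strength * (1 - exp(-(k-1)/tau)) * r1(u)/max(r1)``
      applied to the evoked component (strong responders adapt most);
  ``lateral_inhibition``
      facilitating inhibition progressively silences the weakly driven
      half of the population: ``m_k(u) = 1 - strength *
      (1 - exp(-(k-1)/tau)) * sigmoid((0.5 - q_u)/0.05)`` with ``q_u`` the
      rank quantile of trial-1 drive, applied to the unit's *total*
      in-window rate (a silenced unit loses its baseline spikes too);

* catch-trial block designs in which a deviant stimulus replaces one trial,
  with a configurable cross-adaptation coupling; and
* per-animal binary palp-opening responses whose probability facilitates
  over trials, ``p_k = p_inf + (p0 - p_inf) * exp(-(k-1)/tau)``.

Spiking is an inhomogeneous Poisson process realized on 1-ms sub-bins with
rates piecewise-constant over the analysis bins, so closed-form expected
counts are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ModelError, ValidationError
from .io import SPIKE_COLUMNS, BEHAVIOR_COLUMNS
from .protocol import StimulusProtocol, intensity_of

MECHANISMS = ("magnitude_only", "vesicle_depletion", "lateral_inhibition")

_SUB_BIN_S = 0.001  # Poisson sub-bin width


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------


@dataclass
class AdaptationSpec:
    """Trial-wise adaptation mechanism and its time course.

    ``plateau`` is the asymptotic fraction of the trial-1 evoked response
    under ``magnitude_only``; ``strength`` is the asymptotic suppression
    depth under the two mechanistic modes; ``tau_trials`` the exponential
    time constant in trials.
    """

    mechanism: str = "magnitude_only"
    plateau: float = 0.4
    tau_trials: float = 5.0
    strength: float = 0.6

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValidationError(f"unknown mechanism {self.mechanism!r}; use one of {MECHANISMS}")
        if not (0 < self.plateau <= 1):
            raise ValidationError("plateau must be in (0, 1]")
        if self.tau_trials <= 0:
            raise ValidationError("tau_trials must be positive")
        if self.strength < 0:
            raise ValidationError("strength must be non-negative")

    def decay(self, trial_k: int | np.ndarray) -> np.ndarray:
        """``1 - exp(-(k-1)/tau)`` — the saturation of adaptation at trial k."""
        return 1.0 - np.exp(-(np.asarray(trial_k) - 1) / self.tau_trials)

    def multipliers(self, gains: np.ndarray, trial_k: int) -> np.ndarray:
        """Per-unit multiplier at 1-based trial ``trial_k``.

        For ``magnitude_only`` and ``vesicle_depletion`` the multiplier
        applies to the evoked component; for ``lateral_inhibition`` it
        applies to the unit's total in-window rate.
        """
        gains = np.asarray(gains, dtype=float)
        d = float(self.decay(trial_k))
        if self.mechanism == "magnitude_only":
            m = self.plateau + (1.0 - self.plateau) * (1.0 - d)
            return np.full_like(gains, m)
        if self.mechanism == "vesicle_depletion":
            r1n = gains / gains.max() if gains.max() > 0 else np.zeros_like(gains)
            return 1.0 - self.strength * d * r1n
        # lateral_inhibition: silence the weakly driven half (rank-based)
        order = np.argsort(np.argsort(gains, kind="stable"), kind="stable")
        q = order / max(len(gains) - 1, 1)
        w = 1.0 / (1.0 + np.exp(-(0.5 - q) / 0.05))
        return 1.0 - self.strength * d * w

    @property
    def scales_total_rate(self) -> bool:
        return self.mechanism == "lateral_inhibition"


@dataclass
class PopulationModel:
    """Generative model of one recorded antennal-lobe population.

    ``tuning`` maps each stimulus label to a length-``n_units`` vector of
    evoked peak rates (Hz above baseline at trial 1, at the peak of the
    temporal kernel).  ``temporal_kernel`` gives the per-analysis-bin
    multiplier of the evoked rate across the odor window (unit peak).
    """

    n_units: int
    baseline_rate_hz: float
    tuning: dict[str, np.ndarray]
    temporal_kernel: np.ndarray
    adaptation: AdaptationSpec = field(default_factory=AdaptationSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        self.temporal_kernel = np.asarray(self.temporal_kernel, dtype=float)
        self.tuning = {k: np.asarray(v, dtype=float) for k, v in self.tuning.items()}
        if self.baseline_rate_hz < 0:
            raise ValidationError("baseline rate must be non-negative")
        if np.any(self.temporal_kernel < 0) or np.any(self.temporal_kernel > 1):
            raise ValidationError("temporal kernel values must lie in [0, 1]")
        for label, g in self.tuning.items():
            if g.shape != (self.n_units,):
                raise ValidationError(
                    f"tuning[{label!r}] has shape {g.shape}, expected ({self.n_units},)"
                )
            if np.any(g < 0):
                raise ValidationError(f"tuning[{label!r}] has negative gains")

    def unit_labels(self) -> list[str]:
        width = len(str(self.n_units))
        return [f"u{idx + 1:0{width}d}" for idx in range(self.n_units)]

    def gains_for(self, stimulus: str) -> np.ndarray:
        if stimulus not in self.tuning:
            raise ModelError(f"stimulus {stimulus!r} absent from the tuning table")
        return self.tuning[stimulus]


@dataclass
class BehaviorModel:
    """Facilitating palp-opening-response model.

    Per animal and trial, a POR is Bernoulli with
    ``p_k = p_inf + (p0 - p_inf) * exp(-(k-1)/tau_trials)`` where ``p_inf``
    is ``p_inf_high`` or ``p_inf_low`` according to the intensity tag of
    the stimulus label.  ``p0_catch``, if set, is the (unadapted) response
    probability used on a catch trial.
    """

    p0: float = 0.2
    p_inf_high: float = 0.8
    p_inf_low: float = 0.55
    tau_trials: float = 2.0
    n_animals: int = 36
    seed: int = 0
    p0_catch: float | None = None

    def __post_init__(self) -> None:
        for name in ("p0", "p_inf_high", "p_inf_low"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.p0_catch is not None and not (0 <= self.p0_catch <= 1):
            raise ValidationError("p0_catch outside [0, 1]")
        if self.tau_trials <= 0:
            raise ValidationError("tau_trials must be positive")
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")
        if min(self.p_inf_high, self.p_inf_low) < self.p0:
            raise ValidationError("facilitation requires p_inf >= p0 for both intensities")

    def p_inf_for(self, stimulus: str) -> float:
        return self.p_inf_high if intensity_of(stimulus) == "H" else self.p_inf_low

    def p_curve(self, stimulus: str, trial_ids: np.ndarray) -> np.ndarray:
        """Closed-form p(POR) over 1-based trial numbers."""
        k = np.asarray(trial_ids, dtype=float)
        p_inf = self.p_inf_for(stimulus)
        return p_inf + (self.p0 - p_inf) * np.exp(-(k - 1) / self.tau_trials)


# ---------------------------------------------------------------------------
# default model construction (the study conditions)
# ---------------------------------------------------------------------------


def default_temporal_kernel(n_bins: int, bin_width_s: float) -> np.ndarray:
    """Rise-plateau-decay evoked-rate envelope, unit peak.

    Fast onset (tau 150 ms), sustained for ~1 s, slow decay (tau 2 s) —
    the typical shape of odor-evoked projection-neuron responses.
    """
    t = (np.arange(n_bins) + 0.5) * bin_width_s
    k = (1.0 - np.exp(-t / 0.15)) * np.exp(-np.maximum(0.0, t - 1.0) / 2.0)
    return k / k.max()


def make_population_model(
    odors=("hex", "oct"),
    protocol: StimulusProtocol | None = None,
    n_units: int = 80,
    baseline_rate_hz: float = 2.0,
    responsive_prob: float = 0.6,
    gain_shape: float = 3.0,
    gain_scale_hz: float = 10.0,
    intensity_gain: float = 0.6,
    rotation_fraction: float = 0.3,
    adaptation: AdaptationSpec | None = None,
    seed: int = 0,
    extra_stimuli: tuple[str, ...] = (),
) -> PopulationModel:
    """Build a population model with odor-specific tuning at two intensities.

    For each odor, a high-intensity gain vector is drawn (each unit
    responsive with probability ``responsive_prob``; responsive gains
    Gamma(``gain_shape``, ``gain_scale_hz``) Hz).  The low-intensity vector
    is ``intensity_gain`` times the high vector for a random
    ``1 - rotation_fraction`` subset of units and an independent re-draw
    (at the low-intensity scale) for the rest — the re-drawn units include
    low-intensity-preferring ones.  ``extra_stimuli`` adds independently
    tuned labels (e.g. a catch odor) at full intensity.
    """
    rng = np.random.default_rng(seed)
    if protocol is None:
        bins, width = 80, 0.05
    else:
        bins, width = protocol.n_bins, protocol.bin_width_s

    def draw_gains() -> np.ndarray:
        resp = rng.random(n_units) < responsive_prob
        return np.where(resp, rng.gamma(gain_shape, gain_scale_hz, n_units), 0.0)

    tuning: dict[str, np.ndarray] = {}
    for odor in odors:
        high = draw_gains()
        low = intensity_gain * high
        rotated = rng.random(n_units) < rotation_fraction
        redraw = intensity_gain * draw_gains()
        low = np.where(rotated, redraw, low)
        tuning[f"{odor}_H"] = high
        tuning[f"{odor}_L"] = low
    for label in extra_stimuli:
        tuning[label] = draw_gains()

    return PopulationModel(
        n_units=n_units,
        baseline_rate_hz=baseline_rate_hz,
        tuning=tuning,
        temporal_kernel=default_temporal_kernel(bins, width),
        adaptation=adaptation if adaptation is not None else AdaptationSpec(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# expected counts (analytic oracles)
# ---------------------------------------------------------------------------


def trial_rate_profile(
    model: PopulationModel,
    protocol: StimulusProtocol,
    stimulus: str,
    trial_k: int,
    multipliers: np.ndarray | None = None,
) -> np.ndarray:
    """Expected rate (Hz) per (unit, analysis bin) on one trial.

    ``multipliers`` overrides the adaptation state (used for catch trials);
    by default the mechanism's own trial-``k`` multipliers apply.
    """
    gains = model.gains_for(stimulus)
    if multipliers is None:
        multipliers = model.adaptation.multipliers(gains, trial_k)
    kern = model.temporal_kernel[np.newaxis, :]
    m = np.asarray(multipliers, dtype=float)[:, np.newaxis]
    evoked = gains[:, np.newaxis] * kern
    if model.adaptation.scales_total_rate:
        rates = m * (model.baseline_rate_hz + evoked)
    else:
        rates = model.baseline_rate_hz + m * evoked
    if np.any(rates < 0):
        raise ModelError(
            f"negative effective rate for stimulus {stimulus!r} at trial {trial_k} "
            "(adaptation strength too large for this model)"
        )
    return rates


def expected_in_window_counts(
    model: PopulationModel,
    protocol: StimulusProtocol,
    stimulus: str,
    trial_k: int,
    multipliers: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form expected in-window spike count per unit on one trial."""
    rates = trial_rate_profile(model, protocol, stimulus, trial_k, multipliers)
    return rates.sum(axis=1) * protocol.bin_width_s


# ---------------------------------------------------------------------------
# spike-train simulation
# ---------------------------------------------------------------------------


def _draw_spikes_for_trial(
    rng: np.random.Generator,
    rates_hz: np.ndarray,
    window: tuple[float, float],
    baseline_hz: float,
    pre_window_s: float,
    post_window_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson spikes on 1-ms sub-bins; returns (unit_index, time_s) arrays.

    ``rates_hz`` is the (n_units, n_bins) in-window rate profile; outside
    the window every unit fires at ``baseline_hz``.
    """
    n_units, n_bins = rates_hz.shape
    start, end = window
    bin_width = (end - start) / n_bins
    sub_per_bin = round(bin_width / _SUB_BIN_S)
    t0 = start - pre_window_s
    n_pre = round(pre_window_s / _SUB_BIN_S)
    n_post = round(post_window_s / _SUB_BIN_S)
    n_in = n_bins * sub_per_bin
    lam = np.empty((n_units, n_pre + n_in + n_post))
    lam[:, :n_pre] = baseline_hz
    lam[:, n_pre : n_pre + n_in] = np.repeat(rates_hz, sub_per_bin, axis=1)
    lam[:, n_pre + n_in :] = baseline_hz
    counts = rng.poisson(lam * _SUB_BIN_S)
    units, subs = np.nonzero(counts)
    reps = counts[units, subs]
    units = np.repeat(units, reps)
    subs = np.repeat(subs, reps)
    times = t0 + (subs + rng.random(len(subs))) * _SUB_BIN_S
    return units, times


def _simulate(
    model: PopulationModel,
    protocol: StimulusProtocol,
    rng: np.random.Generator,
    cross_adaptation: float,
    pre_window_s: float,
    post_window_s: float,
) -> pd.DataFrame:
    labels = model.unit_labels()
    frames = []
    for b, block_label in enumerate(protocol.block_sequence, start=1):
        for k in range(1, protocol.n_trials_per_block + 1):
            stimulus = protocol.stimulus_for(block_label, k)
            is_catch = protocol.has_catch and k == protocol.catch_trial_index
            if is_catch:
                # the catch stimulus arrives unadapted, optionally coupled to
                # the repeated stimulus' adaptation state at this trial
                repeated_gains = model.gains_for(block_label)
                m_repeated = model.adaptation.multipliers(repeated_gains, k)
                mult = 1.0 - cross_adaptation * (1.0 - m_repeated)
            else:
                mult = None
            rates = trial_rate_profile(model, protocol, stimulus, k, mult)
            units, times = _draw_spikes_for_trial(
                rng, rates, protocol.odor_window_s, model.baseline_rate_hz,
                pre_window_s, post_window_s,
            )
            frames.append(
                pd.DataFrame(
                    {
                        "unit_id": [labels[u] for u in units],
                        "block_id": b,
                        "trial_id": k,
                        "stimulus_label": stimulus,
                        "spike_time_s": times,
                    }
                )
            )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=SPIKE_COLUMNS)
    return out


def simulate_session(
    model: PopulationModel,
    protocol: StimulusProtocol,
    seed: int | None = None,
    pre_window_s: float = 0.5,
    post_window_s: float = 0.5,
) -> pd.DataFrame:
    """Simulate a full session (all blocks, no catch trials).

    Returns a spike-event table in the on-disk schema.  Identical
    ``(model, protocol, seed)`` give bit-identical tables.
    """
    if protocol.has_catch:
        raise ModelError("protocol declares a catch trial; use simulate_catch_session")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    return _simulate(model, protocol, rng, 0.0, pre_window_s, post_window_s)


def simulate_catch_session(
    model: PopulationModel,
    protocol: StimulusProtocol,
    cross_adaptation: float = 0.0,
    seed: int | None = None,
    pre_window_s: float = 0.5,
    post_window_s: float = 0.5,
) -> pd.DataFrame:
    """Simulate a catch-trial session.

    ``cross_adaptation`` in [0, 1] couples the catch stimulus to the
    adapted state of the repeated stimulus: 0 gives fully unadapted
    catch-trial responses (trial-1-like), 1 carries the repeated stimulus'
    full adaptation multiplier over to the deviant.
    """
    if not protocol.has_catch:
        raise ModelError("protocol declares no catch trial")
    if not (0 <= cross_adaptation <= 1):
        raise ModelError("cross_adaptation must lie in [0, 1]")
    model.gains_for(protocol.catch_stimulus)  # raises ModelError if absent
    rng = np.random.default_rng(model.seed if seed is None else seed)
    return _simulate(model, protocol, rng, cross_adaptation, pre_window_s, post_window_s)


# ---------------------------------------------------------------------------
# factor-structured tensors (rank-selection study condition)
# ---------------------------------------------------------------------------


def synthetic_rank3_tensor(
    n_units: int = 80,
    n_bins: int = 80,
    n_trials: int = 25,
    noise_sd_frac: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Exactly trilinear neural-shaped tensor plus i.i.d. Gaussian noise.

    The three ground-truth factors mimic antennal-lobe ensemble structure:
    sparse non-negative unit loadings (each factor recruits ~40% of units),
    Gaussian temporal bumps at distinct latencies, and three distinct
    trial-loading trends (adapting, stable, facilitating).  Noise SD is
    ``noise_sd_frac`` times the SD of the noiseless signal entries.

    Returns ``(tensor, (A, B, C))`` with the generating factors.
    """
    rng = np.random.default_rng(seed)
    a = rng.gamma(2.0, 1.0, (n_units, 3)) * (rng.random((n_units, 3)) < 0.4)
    t = np.arange(n_bins)
    centers = rng.permutation(np.array([0.2, 0.5, 0.8]) * n_bins)
    b = np.column_stack([np.exp(-0.5 * ((t - c) / (0.15 * n_bins)) ** 2) for c in centers])
    k = np.arange(n_trials)
    c = np.column_stack(
        [
            0.4 + 0.6 * np.exp(-k / rng.uniform(3, 7)),
            np.full(n_trials, rng.uniform(0.7, 1.0)),
            1.0 - 0.5 * np.exp(-k / rng.uniform(3, 7)),
        ]
    ) * rng.uniform(1, 2, 3)
    signal = np.einsum("if,jf,kf->ijk", a, b, c)
    x = signal + rng.standard_normal(signal.shape) * noise_sd_frac * signal.std()
    return x, (a, b, c)


# ---------------------------------------------------------------------------
# behavior simulation
# ---------------------------------------------------------------------------


def simulate_behavior(
    model: BehaviorModel,
    protocol: StimulusProtocol,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate per-animal binary PORs for every block and trial.

    On a catch trial the response probability is ``model.p0_catch`` if set
    (the deviant's unadapted level), otherwise the repeated stimulus' own
    ``p_k`` (a no-contrast catch).
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    animals = [f"a{idx + 1:03d}" for idx in range(model.n_animals)]
    rows_animal, rows_trial, rows_stim, rows_p = [], [], [], []
    for block_label in protocol.block_sequence:
        trials = np.arange(1, protocol.n_trials_per_block + 1)
        p = model.p_curve(block_label, trials)
        stims = [protocol.stimulus_for(block_label, int(k)) for k in trials]
        if protocol.has_catch and model.p0_catch is not None:
            p = p.copy()
            p[protocol.catch_trial_index - 1] = model.p0_catch
        for animal in animals:
            rows_animal.extend([animal] * len(trials))
            rows_trial.extend(trials.tolist())
            rows_stim.extend(stims)
            rows_p.extend(p.tolist())
    por = rng.random(len(rows_p)) < np.asarray(rows_p)
    return pd.DataFrame(
        {
            "animal_id": rows_animal,
            "trial_id": rows_trial,
            "stimulus_label": rows_stim,
            "por": por,
        },
        columns=BEHAVIOR_COLUMNS,
    )
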