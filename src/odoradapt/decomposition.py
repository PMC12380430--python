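"""Trilinear (CP/PARAFAC) decomposition by alternating least squares.

The Neuron x Time x Trial count tensor is approximated as

    x_ijk ~= sum_f a_if * b_jf * c_kf

with loading matrices A (neurons), B (time bins), C (trials).  The number
of factors F is chosen with the core-consistency diagnostic (CORCONDIA):
the least-squares Tucker core G for the fixed CP loadings is compared with
the ideal superdiagonal core T, and

    corcondia = 100 * (1 - sum((g_lmn - t_lmn)^2) / sum(t_lmn^2)).

A fit at the right rank keeps the core nearly superdiagonal (values near
100); overfactoring spreads mass off the superdiagonal and the value
collapses (it is unbounded below).

Conventions: after fitting, columns of A and B carry unit Euclidean norm
with all scale absorbed into C, and the largest-magnitude element of each
A and B column is made positive — this makes serialized models and factor
matching deterministic up to factor permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import h5py
from scipy.optimize import linear_sum_assignment

from .containers import TrialTensor
from .errors import DegenerateInputError, IntegrityError, UsageError


# ---------------------------------------------------------------------------
# multilinear algebra helpers
# ---------------------------------------------------------------------------


def unfold(x: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``n`` unfolding; remaining axes keep their original order with
    the first remaining axis varying slowest (C order)."""
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def khatri_rao(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Column-wise Khatri-Rao product with ``u`` rows varying slowest."""
    r = u.shape[1]
    if v.shape[1] != r:
        raise UsageError("khatri_rao operands must share column count")
    return (u[:, None, :] * v[None, :, :]).reshape(-1, r)


def _compose(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return np.einsum("if,jf,kf->ijk", a, b, c)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


@dataclass
class CPModel:
    """Fitted CP model: loadings, diagnostics, and the source tensor's axis
    labels (carried so downstream analyses never lose track of trials)."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    F: int
    fit_fraction: float
    n_iterations: int
    converged: bool
    iteration_errors: np.ndarray = field(default_factory=lambda: np.empty(0))
    unit_labels: list[str] | None = None
    bin_edges_s: np.ndarray | None = None
    trial_labels: list[int] | None = None
    stimulus_labels: list[str] | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.A.shape[0], self.B.shape[0], self.C.shape[0])


# ---------------------------------------------------------------------------
# alternating least squares
# ---------------------------------------------------------------------------


def _als_once(
    x: np.ndarray,
    f: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    nonnegative: bool,
) -> tuple[list[np.ndarray], float, int, bool, np.ndarray]:
    dims = x.shape
    norm_x2 = float(np.sum(x * x))
    factors = [rng.random((d, f)) for d in dims]  # uniform non-negative init
    unfoldings = [unfold(x, n) for n in range(3)]
    errors = []
    prev_fit = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            # kr with the first remaining mode slowest matches `unfold`
            z = khatri_rao(others[0], others[1])
            gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
            rhs = unfoldings[mode] @ z
            try:
                factors[mode] = np.linalg.solve(gram, rhs.T).T
            except np.linalg.LinAlgError:
                factors[mode] = rhs @ np.linalg.pinv(gram)
            if nonnegative:
                np.clip(factors[mode], 0.0, None, out=factors[mode])
        resid = x - _compose(*factors)
        err2 = float(np.sum(resid * resid))
        errors.append(np.sqrt(err2))
        fit = 1.0 - err2 / norm_x2
        if abs(fit - prev_fit) < tol:
            converged = True
            break
        prev_fit = fit
    return factors, fit, n_iter, converged, np.asarray(errors)


def _normalize(factors: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-normalize A and B columns, push scale into C, fix signs."""
    a, b, c = (f.copy() for f in factors)
    for mat in (a, b):
        norms = np.linalg.norm(mat, axis=0)
        norms[norms == 0] = 1.0
        mat /= norms
        c *= norms
    for mat in (a, b):
        signs = np.sign(mat[np.abs(mat).argmax(axis=0), np.arange(mat.shape[1])])
        signs[signs == 0] = 1.0
        mat *= signs
        c *= signs
    return a, b, c


def _as_array(tensor) -> tuple[np.ndarray, TrialTensor | None]:
    if isinstance(tensor, TrialTensor):
        return tensor.counts.astype(float), tensor
    return np.asarray(tensor, dtype=float), None


def cp_als(
    tensor,
    F: int,
    restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    nonnegative: bool = False,
) -> CPModel:
    """Fit a rank-``F`` CP model by ALS, keeping the best of ``restarts``
    random initializations.

    ``tensor`` may be a :class:`TrialTensor` or a raw 3-way array.  The
    per-sweep reconstruction error is recorded (``iteration_errors``) and is
    non-increasing; ``converged`` is set when the change in fit fraction
    between sweeps falls below ``tol``.
    """
    x, source = _as_array(tensor)
    if x.ndim != 3:
        raise UsageError(f"expected a 3-way array, got shape {x.shape}")
    if F < 1:
        raise UsageError("F must be >= 1")
    if F > min(x.shape):
        raise UsageError(f"F={F} exceeds the smallest tensor dimension {min(x.shape)}")
    if restarts < 1:
        raise UsageError("restarts must be >= 1")
    if not np.any(x):
        raise DegenerateInputError("all-zero tensor cannot be decomposed")

    best = None
    for restart_seed in np.random.SeedSequence(seed).spawn(restarts):
        rng = np.random.default_rng(restart_seed)
        factors, fit, n_iter, conv, errors = _als_once(x, F, rng, tol, max_iter, nonnegative)
        if best is None or fit > best[1]:
            best = (factors, fit, n_iter, conv, errors)
    factors, fit, n_iter, conv, errors = best
    a, b, c = _normalize(factors)
    model = CPModel(
        A=a, B=b, C=c, F=F, fit_fraction=float(fit),
        n_iterations=n_iter, converged=conv, iteration_errors=errors,
    )
    if source is not None:
        model.unit_labels = list(source.unit_labels)
        model.bin_edges_s = source.bin_edges_s.copy()
        model.trial_labels = list(source.trial_labels)
        model.stimulus_labels = list(source.stimulus_labels)
    return model


def reconstruct_tensor(model: CPModel) -> np.ndarray:
    """Denoised tensor ``x_hat_ijk = sum_f a_if b_jf c_kf`` (real-valued)."""
    return _compose(model.A, model.B, model.C)


# ---------------------------------------------------------------------------
# core consistency
# ---------------------------------------------------------------------------


def core_consistency(tensor, model: CPModel) -> float:
    """CORCONDIA percentage of a CP model on its source tensor.

    Computes the least-squares Tucker core for the fixed loadings via the
    factor pseudo-inverses and scores its distance from the superdiagonal
    identity core.  At most 100; unbounded below.
    """
    x, _ = _as_array(tensor)
    if x.shape != model.shape:
        raise UsageError(f"tensor shape {x.shape} does not match model {model.shape}")
    g = x
    for mode, mat in enumerate((model.A, model.B, model.C)):
        g = np.moveaxis(np.tensordot(np.linalg.pinv(mat), g, axes=(1, mode)), 0, mode)
    t = np.zeros((model.F,) * 3)
    idx = np.arange(model.F)
    t[idx, idx, idx] = 1.0
    return float(100.0 * (1.0 - np.sum((g - t) ** 2) / model.F))


@dataclass
class CorconReport:
    """Core-consistency curve over candidate ranks and the selected rank."""

    per_F: dict[int, float]
    selected_F: int
    threshold_pct: float
    warning: bool = False
    models: dict[int, CPModel] | None = None


def select_from_curve(per_F: dict[int, float], threshold_pct: float) -> tuple[int, bool]:
    """Apply the first-drop rule to a core-consistency curve.

    Returns ``(selected_F, warning)``: the largest rank reached before the
    curve first falls below ``threshold_pct`` (ranks scanned in ascending
    order); if the first rank already fails, it is returned with a warning.
    """
    cands = sorted(per_F)
    selected = None
    for f in cands:
        if per_F[f] >= threshold_pct:
            selected = f
        else:
            break
    if selected is None:
        return cands[0], True
    return selected, False


def select_num_factors(
    tensor,
    F_candidates,
    threshold_pct: float = 50.0,
    restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    keep_models: bool = False,
) -> CorconReport:
    """Scan candidate ranks in ascending order and select the largest rank
    reached before core consistency first drops below ``threshold_pct``.

    The scan stops at the first failing candidate: a diagnostic rebound at
    a higher rank (which does happen — an overfactored model can stumble on
    a clean local solution) never overrides an earlier collapse.  If the
    very first candidate fails, it is returned with ``warning=True``.
    """
    cands = list(F_candidates)
    if not cands:
        raise UsageError("F_candidates must not be empty")
    if cands != sorted(cands) or len(set(cands)) != len(cands):
        raise UsageError("F_candidates must be strictly ascending")
    per_f: dict[int, float] = {}
    models: dict[int, CPModel] = {}
    for f in cands:
        model = cp_als(tensor, f, restarts=restarts, tol=tol, max_iter=max_iter, seed=seed)
        per_f[f] = core_consistency(tensor, model)
        if keep_models:
            models[f] = model
    selected, warning = select_from_curve(per_f, threshold_pct)
    return CorconReport(per_f, selected, threshold_pct, warning=warning,
                        models=models if keep_models else None)


# ---------------------------------------------------------------------------
# factor matching (recovery scoring)
# ---------------------------------------------------------------------------


def match_factors(
    estimated: tuple[np.ndarray, np.ndarray, np.ndarray],
    truth: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> dict:
    """Match estimated CP factors to ground truth up to permutation and sign.

    The permutation maximizes total absolute column congruence (Hungarian
    assignment on the product of per-mode |cosines|); per matched factor the
    legal sign flips (an even number of negative flips across the three
    modes) maximizing the worst per-mode cosine are applied.  Returns the
    permutation and an ``(F, 3)`` array of signed per-mode cosines.
    """
    def unit_cols(m):
        m = np.asarray(m, dtype=float)
        n = np.linalg.norm(m, axis=0)
        n[n == 0] = 1.0
        return m / n

    est = [unit_cols(m) for m in estimated]
    tru = [unit_cols(m) for m in truth]
    f = est[0].shape[1]
    cos = [e.T @ t for e, t in zip(est, tru)]  # (F_est, F_true) per mode
    score = np.abs(cos[0]) * np.abs(cos[1]) * np.abs(cos[2])
    rows, cols = linear_sum_assignment(-score)
    perm = np.empty(f, dtype=int)
    perm[cols] = rows
    congruence = np.zeros((f, 3))
    flip_sets = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]
    for true_f in range(f):
        est_f = perm[true_f]
        raw = np.array([cos[m][est_f, true_f] for m in range(3)])
        best = max(flip_sets, key=lambda s: np.min(np.asarray(s) * raw))
        congruence[true_f] = np.asarray(best) * raw
    return {"permutation": perm, "congruence": congruence,
            "min_congruence": float(congruence.min())}


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_MODEL_FORMAT = "odoradapt-cp-model-v1"


def save_cp_model(model: CPModel, path) -> None:
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = _MODEL_FORMAT
        fh.attrs["F"] = model.F
        fh.attrs["fit_fraction"] = model.fit_fraction
        fh.attrs["n_iterations"] = model.n_iterations
        fh.attrs["converged"] = model.converged
        for name in ("A", "B", "C"):
            fh.create_dataset(name, data=getattr(model, name))
        fh.create_dataset("iteration_errors", data=model.iteration_errors)
        if model.unit_labels is not None:
            fh.create_dataset("unit_labels",
                              data=np.array(model.unit_labels, dtype=object), dtype=str_dt)
            fh.create_dataset("bin_edges_s", data=model.bin_edges_s)
            fh.create_dataset("trial_labels", data=np.asarray(model.trial_labels, dtype=int))
            fh.create_dataset("stimulus_labels",
                              data=np.array(model.stimulus_labels, dtype=object), dtype=str_dt)


def load_cp_model(path) -> CPModel:
    try:
        with h5py.File(path, "r") as fh:
            if fh.attrs.get("format") != _MODEL_FORMAT:
                raise IntegrityError(f"{path}: not a CP model container")
            model = CPModel(
                A=fh["A"][()], B=fh["B"][()], C=fh["C"][()],
                F=int(fh.attrs["F"]),
                fit_fraction=float(fh.attrs["fit_fraction"]),
                n_iterations=int(fh.attrs["n_iterations"]),
                converged=bool(fh.attrs["converged"]),
                iteration_errors=fh["iteration_errors"][()],
            )
            if "unit_labels" in fh:
                model.unit_labels = [u.decode() if isinstance(u, bytes) else str(u)
                                     for u in fh["unit_labels"][()]]
                model.bin_edges_s = fh["bin_edges_s"][()]
                model.trial_labels = [int(t) for t in fh["trial_labels"][()]]
                model.stimulus_labels = [s.decode() if isinstance(s, bytes) else str(s)
                                         for s in fh["stimulus_labels"][()]]
    except OSError as exc:
        raise IntegrityError(f"{path}: unreadable model container ({exc})") from exc
    if model.A.shape[1] != model.F or model.B.shape[1] != model.F or model.C.shape[1] != model.F:
        raise IntegrityError(f"{path}: loading-matrix column counts do not match F")
    return model
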