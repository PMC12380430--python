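"""Population-vector geometry: odor trajectories, trial correlations,
hierarchical clustering, and trial classification.

The central dissociation these tools quantify: adaptation shrinks the
*length* of the per-trial population vector while its *direction* (the
combination of active units) is preserved; identity and intensity live in
the direction.  Pearson correlation between two trials' vectors depends
only on direction after centering, so it is the natural invariant
similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import PopulationVector, TrialTensor
from .decomposition import CPModel, reconstruct_tensor
from .errors import DegenerateInputError, UndefinedCorrelationError, UsageError

#: Reductions accepted for trial-by-trial correlation analyses; the two
#: per-unit reductions give identical Pearson values (positive scale), the
#: concatenated form keeps within-trial temporal structure.
CORRELATION_REDUCTIONS = ("sum_window", "mean_per_bin", "concat_bins")


# ---------------------------------------------------------------------------
# Pearson correlation on population vectors
# ---------------------------------------------------------------------------


def _as_values(v) -> np.ndarray:
    if isinstance(v, PopulationVector):
        return v.values
    return np.asarray(v, dtype=float)


def pearson_trial_correlation(v1, v2) -> float:
    """Pearson r between two population vectors (cov / (sigma_i sigma_j)).

    Raises ``UndefinedCorrelationError`` on zero-variance input rather than
    returning NaN.
    """
    x = _as_values(v1)
    y = _as_values(v2)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError(f"vectors must be equal-length 1-D, got {x.shape} vs {y.shape}")
    if len(x) < 2:
        raise UsageError("need at least 2 entries for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance population vector")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def _trial_vectors(tensor: TrialTensor, reduction: str) -> np.ndarray:
    """(n_trials, p) matrix of per-trial vectors under a reduction."""
    if reduction not in CORRELATION_REDUCTIONS:
        raise UsageError(
            f"unknown reduction {reduction!r}; use one of {CORRELATION_REDUCTIONS}"
        )
    if reduction == "concat_bins":
        return tensor.counts.reshape(-1, tensor.n_trials).T.astype(float)
    mat = tensor.counts.sum(axis=1).T.astype(float)  # trials x units
    if reduction == "mean_per_bin":
        mat = mat / tensor.n_bins
    return mat


@dataclass
class TrialCorrelationMatrix:
    """Symmetric unit-diagonal matrix of trial-pair Pearson correlations,
    rows ordered block-by-block, earlier trials first."""

    values: np.ndarray
    trial_labels: list[int]
    stimulus_labels: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]


def trial_correlation_matrix(tensor: TrialTensor, reduction: str = "sum_window") -> TrialCorrelationMatrix:
    """All pairwise trial correlations under the chosen reduction."""
    if tensor.n_trials < 2:
        raise UsageError("need at least 2 trials")
    vecs = _trial_vectors(tensor, reduction)
    sd = vecs.std(axis=1)
    if np.any(sd == 0):
        k = int(np.flatnonzero(sd == 0)[0])
        raise UndefinedCorrelationError(
            f"trial {tensor.trial_labels[k]} ({tensor.stimulus_labels[k]}) has a "
            "zero-variance population vector"
        )
    values = np.corrcoef(vecs)
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    return TrialCorrelationMatrix(values, list(tensor.trial_labels), list(tensor.stimulus_labels))


# ---------------------------------------------------------------------------
# hierarchical clustering of trials
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Complete-linkage tree on correlation distance d = 1 - r.

    ``linkage`` is a scipy linkage matrix; leaves carry 1-based trial
    numbers (with their stimulus labels alongside).
    """

    linkage: np.ndarray
    trial_labels: list[int]
    stimulus_labels: list[str]

    def leaf_order(self) -> list[int]:
        return [int(i) for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster assignment (1-based ids) at ``n_clusters`` clusters."""
        return hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        """Nested-parenthesis export with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                name = f"t{self.trial_labels[node.id]}_{self.stimulus_labels[node.id]}"
                return f"{name}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});" if not tree.is_leaf() else ";"


def cluster_dendrogram(matrix: TrialCorrelationMatrix) -> Dendrogram:
    """Agglomerative complete-linkage tree on correlation distance.

    Complete linkage minimizes the furthest pairwise distance within each
    merged cluster; identical inputs give identical trees (scipy's merge
    tie-break is deterministic on the condensed ordering, i.e. lowest leaf
    indices first).
    """
    d = 1.0 - matrix.values
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    return Dendrogram(z, list(matrix.trial_labels), list(matrix.stimulus_labels))


# ---------------------------------------------------------------------------
# trial classification
# ---------------------------------------------------------------------------


@dataclass
class ClassificationReport:
    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    confusion: pd.DataFrame
    n_trials: int


def classify_trials(tensor: TrialTensor, reduction: str = "sum_window") -> ClassificationReport:
    """Leave-one-trial-out nearest-centroid classification of stimulus labels.

    Each held-out trial is assigned to the class whose centroid (mean of
    the remaining trials' population vectors) is most Pearson-similar;
    centroids are recomputed per fold.  This is a stand-in scheme for
    correlation-based decoding; the similarity measure is the same Pearson
    statistic used throughout.
    """
    vecs = _trial_vectors(tensor, reduction)
    labels = np.asarray(tensor.stimulus_labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise UsageError("need at least 2 stimulus classes")
    for cls in classes:
        if np.sum(labels == cls) < 2:
            raise UsageError(f"class {cls!r} has a single trial; cannot leave one out")
    predicted = []
    for k in range(len(labels)):
        sims = []
        for cls in classes:
            mask = (labels == cls)
            mask[k] = False
            centroid = vecs[mask].mean(axis=0)
            sims.append(pearson_trial_correlation(vecs[k], centroid))
        predicted.append(classes[int(np.argmax(sims))])
    predicted = np.asarray(predicted)
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for true, pred in zip(labels, predicted):
        confusion.loc[true, pred] += 1
    per_class = {
        cls: float(np.mean(predicted[labels == cls] == cls)) for cls in classes
    }
    return ClassificationReport(
        overall_accuracy=float(np.mean(predicted == labels)),
        per_class_accuracy=per_class,
        confusion=confusion,
        n_trials=len(labels),
    )


# ---------------------------------------------------------------------------
# catch-trial correlation profile
# ---------------------------------------------------------------------------


def catch_trial_correlation(
    tensor: TrialTensor, reference_trial: int, reduction: str = "sum_window"
) -> np.ndarray:
    """Pearson r of every trial's population vector against a reference
    trial's, in trial order (0-based ``reference_trial`` position)."""
    if not (0 <= reference_trial < tensor.n_trials):
        raise UsageError(f"reference trial {reference_trial} outside 0..{tensor.n_trials - 1}")
    vecs = _trial_vectors(tensor, reduction)
    ref = vecs[reference_trial]
    return np.array([pearson_trial_correlation(v, ref) for v in vecs])


# ---------------------------------------------------------------------------
# low-dimensional odor trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """One trial's odor-window trajectory in the top-3 principal plane.

    ``points`` is (n_bins, 3) in the centered principal coordinates;
    ``offset`` is the projected grand mean, so ``points + offset`` are the
    raw-space projections.  ``basis`` holds the three projection vectors
    (rows) shared by all trajectories of the call, with their
    explained-variance fractions.
    """

    points: np.ndarray
    trial_label: int
    stimulus_label: str
    basis: np.ndarray
    explained_variance: np.ndarray
    offset: np.ndarray

    def path_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def diameter(self) -> float:
        """Largest distance between two points of the loop (its size)."""
        d = self.points[:, None, :] - self.points[None, :, :]
        return float(np.linalg.norm(d, axis=2).max())

    def mean_point(self, centered: bool = True) -> np.ndarray:
        m = self.points.mean(axis=0)
        return m if centered else m + self.offset


def _running_average(points: np.ndarray, window: int) -> np.ndarray:
    """Centered running average; edge points use shrunken windows."""
    if window <= 1:
        return points
    half = window // 2
    n = len(points)
    out = np.empty_like(points, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = points[lo:hi].mean(axis=0)
    return out


def trial_trajectories(model: CPModel, smooth_points: int = 3) -> list[Trajectory]:
    """Trial-by-trial low-dimensional response trajectories.

    The CP-reconstructed (denoised) tensor is unfolded along trials into an
    (n_units x n_bins*n_trials) time series, each time-step vector is
    centered by the mean over all steps, the steps are projected onto the
    three leading eigenvectors of the unit-covariance matrix, and each
    trial's point sequence is smoothed with a ``smooth_points`` running
    average (shrunken windows at the edges).
    """
    if model.trial_labels is None:
        raise UsageError("model carries no axis labels; fit it on a TrialTensor")
    if smooth_points < 1:
        raise UsageError("smooth_points must be >= 1")
    xhat = reconstruct_tensor(model)
    n_units, n_bins, n_trials = xhat.shape
    series = np.moveaxis(xhat, 2, 1).reshape(n_units, n_trials * n_bins)
    centered = series - series.mean(axis=1, keepdims=True)
    if np.abs(centered).max() <= 1e-12 * max(1.0, np.abs(series).max()):
        # constant activity: every trajectory collapses to the origin
        basis = np.eye(3, n_units)
        offset = basis @ series.mean(axis=1)
        return [
            Trajectory(
                points=np.zeros((n_bins, 3)),
                trial_label=model.trial_labels[k],
                stimulus_label=model.stimulus_labels[k],
                basis=basis,
                explained_variance=np.zeros(3),
                offset=offset,
            )
            for k in range(n_trials)
        ]
    cov = np.cov(centered)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    tol = max(evals[0], 1.0) * 1e-12
    if np.sum(evals > tol) < 3:
        raise DegenerateInputError(
            "fewer than 3 non-degenerate covariance eigenvalues; trajectories "
            "would not span 3 dimensions"
        )
    basis = evecs[:, :3].T  # (3, n_units), orthonormal rows
    explained = evals[:3] / evals.sum()
    coords = basis @ centered  # (3, n_trials*n_bins)
    offset = basis @ series.mean(axis=1)
    out = []
    for k in range(n_trials):
        pts = coords[:, k * n_bins : (k + 1) * n_bins].T
        out.append(
            Trajectory(
                points=_running_average(pts, smooth_points),
                trial_label=model.trial_labels[k],
                stimulus_label=model.stimulus_labels[k],
                basis=basis,
                explained_variance=explained,
                offset=offset,
            )
        )
    return out
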