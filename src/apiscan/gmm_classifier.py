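"""Per-class Gaussian mixture models with frame-level majority voting.

A GMM acoustic model is structurally a 1-state HMM without temporal
dynamics: one diagonal-covariance mixture per class.  Training follows the
same stepwise recipe as the HMMs (flat start, EM cycles, mixture doubling)
but EM degenerates to plain GMM reestimation.  Classification scores every
frame under every class mixture; the clip label is the class that wins the
most frames, with silence frames set aside so pauses cannot flip an
activity decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hmm_core import GaussianMixtureState

ACTIVITY_LABELS = ("normal", "swarm")


@dataclass
class GmmClassModel:
    """One class-conditional Gaussian mixture (diagonal covariances)."""

    label: str
    mixture: GaussianMixtureState
    var_floor: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.mixture.n_components

    @property
    def dim(self) -> int:
        return self.mixture.dim

    def log_pdf(self, X: np.ndarray) -> np.ndarray:
        return self.mixture.log_pdf(X)


@dataclass
class FrameVote:
    """Frame-level scoring result for one clip."""

    labels: list[str]                 # class order used for columns
    log_density: np.ndarray           # (T, n_classes)
    winner: np.ndarray                # (T,) int column index

    @property
    def n_frames(self) -> int:
        return self.log_density.shape[0]

    def counts(self) -> dict[str, int]:
        return {lab: int(np.sum(self.winner == i))
                for i, lab in enumerate(self.labels)}


def _em_step(mix: GaussianMixtureState, X: np.ndarray,
             var_floor: np.ndarray) -> float:
    """One EM iteration on frames X (N, D); returns the pre-update loglik."""
    cl = mix.component_log_pdf(X) + np.log(mix.weights)[None, :]
    m = cl.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.sum(np.exp(cl - m), axis=1))
    loglik = float(lse.sum())
    r = np.exp(cl - lse[:, None])  # responsibilities (N, M)
    nk = r.sum(axis=0)
    live = nk > 1e-8
    nk_safe = np.where(live, nk, 1.0)
    means = np.where(live[:, None], (r.T @ X) / nk_safe[:, None], mix.means)
    var = np.where(live[:, None],
                   (r.T @ (X ** 2)) / nk_safe[:, None] - means ** 2,
                   mix.variances)
    mix.means = means
    mix.variances = np.maximum(var, var_floor[None, :])
    w = np.where(live, nk, 0.0)
    mix.weights = w / w.sum()
    return loglik


def _split(mix: GaussianMixtureState, perturb: float = 0.2) -> None:
    sigma = np.sqrt(mix.variances)
    mix.means = np.concatenate([mix.means + perturb * sigma,
                                mix.means - perturb * sigma], axis=0)
    mix.variances = np.concatenate([mix.variances, mix.variances], axis=0)
    mix.weights = np.concatenate([mix.weights, mix.weights]) / 2.0


def train_gmm(features_by_label: dict[str, list[np.ndarray]],
              target_components: int = 32, iters_per_cycle: int = 2,
              var_floor_scale: float = 1e-4,
              snapshot_at: tuple[int, ...] = ()
              ) -> tuple[dict[str, GmmClassModel],
                         dict[str, list[tuple[int, list[float]]]],
                         dict[int, dict[str, GmmClassModel]]]:
    """Train one mixture per class by the stepwise doubling schedule.

    Flat start at M=1 (class sample mean/variance — for a single state the
    global flat start and the first EM pass coincide at the class statistics),
    then cycles of ``iters_per_cycle`` EM iterations followed by component
    doubling until ``target_components`` is reached, with a final EM cycle
    at the target size.  A class whose frame count falls below twice its
    component count stops doubling early, with a warning.

    Returns the models, the per-class log-likelihood history (one
    ``(M, logliks)`` entry per doubling cycle; non-decreasing within each
    fixed-M cycle), and deep copies of the model set at each component
    count in ``snapshot_at``.
    """
    if not features_by_label:
        raise ValueError("training requires at least one class")
    models: dict[str, GmmClassModel] = {}
    history: dict[str, list[tuple[int, list[float]]]] = {}
    snapshots: dict[int, dict[str, GmmClassModel]] = {}
    for label, clips in sorted(features_by_label.items()):
        if not clips:
            raise ValueError(f"class {label!r} has no training clips")
        X = np.concatenate([np.asarray(c, dtype=np.float64) for c in clips], axis=0)
        mean = X.mean(axis=0)
        var = X.var(axis=0)
        floor = np.maximum(var_floor_scale * var, 1e-10)
        mix = GaussianMixtureState(np.ones(1), mean[None, :].copy(),
                                   np.maximum(var, floor)[None, :].copy())
        hist: list[tuple[int, list[float]]] = []
        while True:
            cycle = [_em_step(mix, X, floor) for _ in range(iters_per_cycle)]
            hist.append((mix.n_components, cycle))
            if mix.n_components in snapshot_at:
                snapshots.setdefault(mix.n_components, {})[label] = \
                    GmmClassModel(label, mix.copy(), floor.copy())
            if mix.n_components >= target_components:
                break
            if X.shape[0] < 2 * mix.n_components * 2:
                warnings.warn(
                    f"class {label!r}: too few frames to grow past "
                    f"{mix.n_components} components")
                break
            _split(mix)
        models[label] = GmmClassModel(label, mix, floor)
        history[label] = hist
    return models, history, snapshots


def score_frames(models: dict[str, GmmClassModel],
                 features: np.ndarray) -> FrameVote:
    """Score every frame under every class mixture; winner by argmax.

    Ties go to the earlier class in sorted label order (deterministic).
    """
    X = np.asarray(features, dtype=np.float64)
    labels = sorted(models)
    dims = {models[lab].dim for lab in labels}
    if dims != {X.shape[1]}:
        raise ValueError(f"feature dim {X.shape[1]} vs model dims {sorted(dims)}")
    dens = np.stack([models[lab].log_pdf(X) for lab in labels], axis=1)
    winner = np.argmax(dens, axis=1)  # argmax takes the first maximum: class order
    return FrameVote(labels=labels, log_density=dens, winner=winner)


def majority_vote(votes: FrameVote) -> str:
    """Clip label = class with the most frame votes.

    Silence frames are excluded from the normal/swarm tally unless every
    frame voted silence (then the clip is silence).  An exact tie between
    activity classes goes to the class with the higher summed log-density,
    then to sorted class order.
    """
    if votes.n_frames < 1:
        raise ValueError("majority vote needs at least one frame")
    counts = votes.counts()
    activity = {lab: n for lab, n in counts.items() if lab != "silence"}
    if sum(activity.values()) == 0:
        return "silence"
    best = max(activity.values())
    leaders = sorted(lab for lab, n in activity.items() if n == best)
    if len(leaders) == 1:
        return leaders[0]
    sums = {lab: float(votes.log_density[:, votes.labels.index(lab)].sum())
            for lab in leaders}
    top = max(sums.values())
    return sorted(lab for lab, s in sums.items() if s == top)[0]


def classify_clip(models: dict[str, GmmClassModel],
                  features: np.ndarray) -> tuple[str, FrameVote]:
    votes = score_frames(models, features)
    return majority_vote(votes), votes


# ---------------------------------------------------------------------------
# Serialization bridge: a GMM is stored as a 1-state HMM record

def to_hmm_record(model: GmmClassModel) -> "HmmModel":
    from .hmm_core import HmmModel
    floor = model.var_floor
    if floor is None:
        floor = np.full(model.dim, 1e-10)
    return HmmModel(model.label, [model.mixture.copy()],
                    trans=np.array([[0.5]]), exit_prob=np.array([0.5]),
                    var_floor=floor.copy())


def from_hmm_record(model: "HmmModel") -> GmmClassModel:
    if model.n_states != 1:
        raise ValueError("a GMM record must have exactly one state")
    return GmmClassModel(model.label, model.states[0].copy(),
                         None if model.var_floor is None
                         else model.var_floor.copy())
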