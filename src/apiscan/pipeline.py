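"""End-to-end training recipes, classification and evaluation.

Three architectures share one front-end and one evaluation path:

* ``hmm_15`` — 15-state left-right activity models (plus a short silence
  model), trained in two stages: flat start, mixture doubling to 16
  components with two Baum-Welch passes per cycle, forced-alignment outlier
  filtering, then re-initialization from class statistics and doubling to
  32 components with three passes per cycle.
* ``hmm_1`` — the same recipe with 1-state models.
* ``gmm`` — per-class mixtures trained by flat start plus doubling with two
  EM passes per cycle; clips are decided by frame-level majority vote.

Model snapshots at 2, 8 and 32 components are kept for the
complexity-versus-accuracy comparison.  Evaluation reports accuracy
(Acc = H/N * 100), precision/recall/F1 with swarm as the positive class,
the full confusion table, and optionally the real-time factor.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest

from . import features as feat
from . import gmm_classifier as gmmc
from . import hmm_core as hmm
from .audio_io import AudioClip
from .synthetic_data import SyntheticDataset

ARCHITECTURES = ("hmm_15", "hmm_1", "gmm")
FEATURE_KINDS = ("mfcc", "mfcc_cmn", "lpc")
SNAPSHOT_COMPONENTS = (2, 8, 32)


@dataclass(frozen=True)
class TrainingConfig:
    architecture: str = "hmm_15"
    feature_kind: str = "mfcc"
    stage1_target_m: int = 16
    stage2_target_m: int = 32
    stage1_iters_per_cycle: int = 2
    stage2_iters_per_cycle: int = 3
    seed: int = 0
    realign: bool = True
    snapshot_at: tuple[int, ...] = SNAPSHOT_COMPONENTS

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        for m in (self.stage1_target_m, self.stage2_target_m):
            if m < 1 or m & (m - 1):
                raise ValueError("mixture targets must be powers of two")
        if min(self.stage1_iters_per_cycle, self.stage2_iters_per_cycle) < 1:
            raise ValueError("need at least one iteration per cycle")

    @property
    def n_states(self) -> int:
        return 15 if self.architecture == "hmm_15" else 1

    @property
    def topology(self) -> dict[str, int]:
        n = self.n_states
        # short silence model: quiet stretches have little temporal structure
        return {"normal": n, "swarm": n, "silence": min(3, n)}


def extract_features(clip: AudioClip, kind: str) -> np.ndarray:
    """Front-end dispatch; returns the (T, 39) feature matrix."""
    if kind == "mfcc":
        return feat.mfcc(clip).data
    if kind == "mfcc_cmn":
        return feat.mfcc(clip, cmn=True).data
    if kind == "lpc":
        return feat.lpc(clip).data
    raise ValueError(f"unknown feature kind {kind!r}")


def dataset_features(ds: SyntheticDataset, split: str, kind: str
                     ) -> list[tuple[np.ndarray, str]]:
    """Extract features for every clip of a split, in manifest order."""
    out = []
    for e in ds.manifest.subset(split):
        out.append((extract_features(ds.clips[e.path], kind), e.label))
    return out


@dataclass
class TrainedSystem:
    """A trained model set with its complexity snapshots and training log."""

    architecture: str
    feature_kind: str
    final_models: dict
    snapshots: dict[int, dict] = field(default_factory=dict)
    log: dict = field(default_factory=dict)


def _mixture_schedule(models, dataset, target_m, iters, history, snapshots,
                      snapshot_at):
    """Run [iters x Baum-Welch -> double M] cycles until target_m.

    ``history`` collects one (M, logliks) entry per cycle; the loglik list
    is non-decreasing within a cycle (EM), while the mixture split between
    cycles may perturb it.
    """
    while True:
        m_now = models["normal"].states[0].n_components
        history.append((m_now, hmm.baum_welch(models, dataset, n_iter=iters)))
        if m_now in snapshot_at:
            snapshots[m_now] = {lab: m.copy() for lab, m in models.items()}
        if m_now >= target_m:
            return models
        models = hmm.split_mixtures(models)


def train_hmm_pipeline(dataset: list[tuple[np.ndarray, str]],
                       config: TrainingConfig) -> TrainedSystem:
    """The two-stage HMM recipe on labeled feature sequences.

    Stage 1 trains flat-started models to ``stage1_target_m`` components
    and uses them only to forced-align the training set and drop outlier
    clips.  Stage 2 restarts from per-class statistics on the filtered set
    and trains to ``stage2_target_m``, snapshotting at the requested
    component counts.
    """
    labels = {lab for _, lab in dataset}
    if not {"normal", "swarm"} <= labels:
        raise ValueError("training set must contain both activity classes")
    log: dict = {"stage1_loglik": [], "stage2_loglik": [],
                 "outlier_fraction": None}

    models = hmm.flat_start_init([X for X, _ in dataset], config.topology)
    models = _mixture_schedule(models, dataset, config.stage1_target_m,
                               config.stage1_iters_per_cycle,
                               log["stage1_loglik"], {}, ())

    if config.realign:
        kept, frac = hmm.forced_align_filter(models, dataset)
        log["outlier_fraction"] = frac
    else:
        kept = dataset

    by_label: dict[str, list[np.ndarray]] = {}
    for X, lab in kept:
        by_label.setdefault(lab, []).append(X)
    all_frames = np.concatenate([np.asarray(X) for X, _ in kept], axis=0)
    models = hmm.local_init(by_label, config.topology,
                            fallback_frames=all_frames)
    snapshots: dict[int, dict] = {}
    models = _mixture_schedule(models, kept, config.stage2_target_m,
                               config.stage2_iters_per_cycle,
                               log["stage2_loglik"], snapshots,
                               config.snapshot_at)
    return TrainedSystem(config.architecture, config.feature_kind,
                         final_models=models, snapshots=snapshots, log=log)


def train_gmm_pipeline(dataset: list[tuple[np.ndarray, str]],
                       config: TrainingConfig) -> TrainedSystem:
    """The single-stage GMM recipe (no forced realignment)."""
    by_label: dict[str, list[np.ndarray]] = {}
    for X, lab in dataset:
        by_label.setdefault(lab, []).append(X)
    models, history, snapshots = gmmc.train_gmm(
        by_label, target_components=config.stage2_target_m,
        iters_per_cycle=2, snapshot_at=config.snapshot_at)
    return TrainedSystem("gmm", config.feature_kind, final_models=models,
                         snapshots=snapshots,
                         log={"loglik": history, "outlier_fraction": None})


def train_pipeline(dataset: list[tuple[np.ndarray, str]],
                   config: TrainingConfig) -> TrainedSystem:
    if config.architecture == "gmm":
        return train_gmm_pipeline(dataset, config)
    return train_hmm_pipeline(dataset, config)


# ---------------------------------------------------------------------------
# Classification

def _decoding_networks(models: dict[str, hmm.HmmModel]) -> dict[str, hmm.Network]:
    """One composite network per candidate answer.

    Activity answers use optional-silence + activity + optional-silence;
    the silence answer is the bare silence model.
    """
    nets = {}
    sil = models.get("silence")
    for lab in ("normal", "swarm"):
        if lab not in models:
            continue
        if sil is not None:
            nets[lab] = hmm.build_network([(sil, True), (models[lab], False),
                                           (sil, True)])
        else:
            nets[lab] = hmm.build_network([(models[lab], False)])
    if sil is not None:
        nets["silence"] = hmm.build_network([(sil, False)])
    return nets


def classify(models: dict, features: np.ndarray,
             architecture: str) -> tuple[str, dict[str, float]]:
    """Classify one clip; returns (label, per-answer score).

    HMM architectures take the Viterbi argmax over the composite networks;
    a clip scoring best as pure silence is reported as silence.  The GMM
    architecture uses frame-level scoring plus majority vote (scores are
    summed per-class log-densities).  Ties break toward the earlier label
    in sorted order, deterministically.
    """
    X = np.asarray(features, dtype=np.float64)
    if architecture == "gmm":
        label, votes = gmmc.classify_clip(models, X)
        scores = {lab: float(votes.log_density[:, i].sum())
                  for i, lab in enumerate(votes.labels)}
        return label, scores
    dims = {m.dim for m in models.values()}
    if dims != {X.shape[1]}:
        raise ValueError(f"feature dim {X.shape[1]} does not match model "
                         f"dims {sorted(dims)}")
    scores = {}
    for lab, net in sorted(_decoding_networks(models).items()):
        res = hmm.viterbi(net, X)
        scores[lab] = res.log_likelihood
    best = max(sorted(scores), key=lambda lab: scores[lab])
    return best, scores


def classify_batch(models: dict, dataset: list[tuple[np.ndarray, str]],
                   architecture: str) -> list[str]:
    """Classify a list of (features, reference-label) clips efficiently.

    Equal-length clips are decoded together; output order matches input.
    """
    if architecture == "gmm":
        return [gmmc.classify_clip(models, X)[0] for X, _ in dataset]
    nets = _decoding_networks(models)
    out = [""] * len(dataset)
    groups: dict[int, list[int]] = {}
    for i, (X, _) in enumerate(dataset):
        groups.setdefault(np.asarray(X).shape[0], []).append(i)
    for T, idxs in sorted(groups.items()):
        X = np.stack([np.asarray(dataset[i][0], dtype=np.float64)
                      for i in idxs])
        labs = sorted(nets)
        all_scores = np.full((len(idxs), len(labs)), -np.inf)
        for j, lab in enumerate(labs):
            _, sc = hmm.viterbi_batch(nets[lab],
                                      hmm.network_log_emissions(nets[lab], X))
            all_scores[:, j] = sc
        winners = np.argmax(all_scores, axis=1)
        for i, w in zip(idxs, winners):
            out[i] = labs[int(w)]
    return out


# ---------------------------------------------------------------------------
# Evaluation

@dataclass
class EvaluationReport:
    """Clip-level evaluation: Acc = H/N*100, P/R/F1 with swarm positive."""

    H: int
    N: int
    acc: float
    precision: float
    recall: float
    f1: float
    confusion: dict[tuple[str, str], int]
    rtf: float | None = None

    def as_dict(self) -> dict:
        return {"H": self.H, "N": self.N, "acc_percent": self.acc,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1,
                "confusion": {f"{r}->{h}": n
                              for (r, h), n in sorted(self.confusion.items())},
                "rtf": self.rtf}


def evaluate(reference: list[str], hypothesis: list[str],
             positive: str = "swarm") -> EvaluationReport:
    """Score a hypothesis label list against the reference.

    H counts exact label matches; Acc = H/N*100.  Precision/recall/F1 treat
    ``positive`` (swarm: the alarm-worthy event) as the positive class; a
    silence hypothesis on an activity reference is an error (a miss for the
    positive class, never a false alarm).
    """
    if not reference or len(reference) != len(hypothesis):
        raise ValueError("need equal-length non-empty label lists")
    N = len(reference)
    H = sum(r == h for r, h in zip(reference, hypothesis))
    tp = sum(r == positive and h == positive
             for r, h in zip(reference, hypothesis))
    fp = sum(r != positive and h == positive
             for r, h in zip(reference, hypothesis))
    fn = sum(r == positive and h != positive
             for r, h in zip(reference, hypothesis))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    confusion: dict[tuple[str, str], int] = {}
    for r, h in zip(reference, hypothesis):
        confusion[(r, h)] = confusion.get((r, h), 0) + 1
    return EvaluationReport(H=H, N=N, acc=H / N * 100.0, precision=precision,
                            recall=recall, f1=f1, confusion=confusion)


def mcnemar_test(reference: list[str], hyp_a: list[str],
                 hyp_b: list[str]) -> float:
    """Exact McNemar p-value for paired system comparison.

    Uses the discordant-pair binomial test: clips system A got right and B
    got wrong versus the reverse.
    """
    b = sum(r == a and r != bb
            for r, a, bb in zip(reference, hyp_a, hyp_b))
    c = sum(r != a and r == bb
            for r, a, bb in zip(reference, hyp_a, hyp_b))
    if b + c == 0:
        return 1.0
    return float(binomtest(b, b + c, 0.5).pvalue)


# ---------------------------------------------------------------------------
# Footprint and timing utilities

@dataclass
class RtfMeasurement:
    """Wall-clock cost relative to audio duration.  Hardware-dependent:
    a profiling aid, never a correctness surface."""

    audio_seconds: float
    fe_seconds: float
    ca_seconds: float

    @property
    def rtf_fe(self) -> float:
        return self.fe_seconds / self.audio_seconds

    @property
    def rtf_ca(self) -> float:
        return self.ca_seconds / self.audio_seconds

    @property
    def rtf_total(self) -> float:
        return self.rtf_fe + self.rtf_ca

    @property
    def fe_ca_ratio(self) -> tuple[float, float]:
        tot = self.fe_seconds + self.ca_seconds
        return (self.fe_seconds / tot, self.ca_seconds / tot)


def measure_rtf(models: dict, clips: list[AudioClip], architecture: str,
                feature_kind: str = "mfcc") -> RtfMeasurement:
    """Time feature extraction and classification separately over clips."""
    if not clips:
        raise ValueError("RTF measurement needs at least one clip")
    audio_s = sum(c.duration_s for c in clips)
    t0 = time.perf_counter()
    feats = [extract_features(c, feature_kind) for c in clips]
    t1 = time.perf_counter()
    for X in feats:
        classify(models, X, architecture)
    t2 = time.perf_counter()
    return RtfMeasurement(audio_seconds=audio_s, fe_seconds=t1 - t0,
                          ca_seconds=t2 - t1)


def model_footprint(models: dict) -> dict[str, int]:
    """Parameter count and serialized byte size of a model set."""
    as_hmm = {}
    for lab, m in models.items():
        as_hmm[lab] = gmmc.to_hmm_record(m) if isinstance(m, gmmc.GmmClassModel) else m
    n_params = sum(m.n_parameters() for m in as_hmm.values())
    text = hmm.dumps_models(as_hmm)
    return {"n_parameters": n_params, "serialized_bytes": len(text.encode())}
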