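"""Left-right continuous-density HMMs with diagonal-covariance GMM emissions.

The acoustic models are strictly left-right: a state may self-loop or move
to its successor, entry is always through the first state and exit through
the last.  Clips are trained and decoded against small composite networks
(optional-silence + activity + optional-silence), which is how a silence
model absorbs the quiet stretches of nominally homogeneous clips without a
separate activity detector.

Training is embedded Baum-Welch: per clip, the forward-backward recursions
run over the composite network (scaled linear-domain implementation,
batched over clips of equal length), and sufficient statistics are pooled
back onto the shared underlying models.  Mixture growth follows the
doubling schedule: every component is cloned with its mean perturbed by
+-0.2 sigma and its weight halved.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

LOG_ZERO = -1e30
VAR_FLOOR_SCALE = 1e-4


@dataclass
class GaussianMixtureState:
    """Diagonal-covariance Gaussian mixture emission density."""

    weights: np.ndarray   # (M,)
    means: np.ndarray     # (M, D)
    variances: np.ndarray  # (M, D)

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def validate(self, var_floor: np.ndarray | None = None) -> None:
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        if var_floor is not None and np.any(self.variances < var_floor - 1e-12):
            raise ValueError("variance below floor")

    def component_log_pdf(self, X: np.ndarray) -> np.ndarray:
        """Per-component Gaussian log-densities for frames X (N, D) -> (N, M)."""
        inv_var = 1.0 / self.variances                       # (M, D)
        const = -0.5 * (self.dim * np.log(2.0 * np.pi)
                        + np.sum(np.log(self.variances), axis=1)
                        + np.sum(self.means ** 2 * inv_var, axis=1))  # (M,)
        quad = X ** 2 @ (0.5 * inv_var).T                    # (N, M)
        cross = X @ (self.means * inv_var).T                 # (N, M)
        return const[None, :] - quad + cross

    def log_pdf(self, X: np.ndarray) -> np.ndarray:
        """Mixture log-density log sum_m w_m N(x; mu_m, sigma2_m), (N,)."""
        cl = self.component_log_pdf(X) + np.log(self.weights)[None, :]
        m = cl.max(axis=1)
        return m + np.log(np.sum(np.exp(cl - m[:, None]), axis=1))

    def copy(self) -> "GaussianMixtureState":
        return GaussianMixtureState(self.weights.copy(), self.means.copy(),
                                    self.variances.copy())


@dataclass
class HmmModel:
    """Left-right model: per-state GMMs plus a row-stochastic transition matrix.

    ``trans[i, i]`` is the self-loop, ``trans[i, i+1]`` the forward move;
    ``exit_prob[i]`` is nonzero only for the last state.  The variance
    floor vector used during training travels with the model.
    """

    label: str
    states: list[GaussianMixtureState]
    trans: np.ndarray       # (S, S)
    exit_prob: np.ndarray   # (S,)
    var_floor: np.ndarray = field(default=None)  # (D,)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def dim(self) -> int:
        return self.states[0].dim

    def validate(self) -> None:
        S = self.n_states
        if self.trans.shape != (S, S):
            raise ValueError("transition matrix shape mismatch")
        rows = self.trans.sum(axis=1) + self.exit_prob
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("transition rows (incl. exit) must sum to 1")
        for i in range(S):
            for j in range(S):
                if j not in (i, i + 1) and self.trans[i, j] != 0.0:
                    raise ValueError("non-left-right transition present")
        if np.any(self.exit_prob[:-1] != 0.0):
            raise ValueError("only the last state may exit")
        for st in self.states:
            st.validate(self.var_floor)

    def copy(self) -> "HmmModel":
        return HmmModel(self.label, [s.copy() for s in self.states],
                        self.trans.copy(), self.exit_prob.copy(),
                        None if self.var_floor is None else self.var_floor.copy())

    def n_parameters(self) -> int:
        """Gaussian parameters (weight + mean + variance per component) plus
        free transition entries."""
        D = self.dim
        gauss = sum(s.n_components * (2 * D + 1) for s in self.states)
        trans = int(np.count_nonzero(self.trans)) + int(np.count_nonzero(self.exit_prob))
        return gauss + trans


def make_left_right(label: str, n_states: int, dim: int) -> HmmModel:
    """Skeleton left-right model: unit Gaussians, uniform legal transitions."""
    states = [GaussianMixtureState(np.ones(1), np.zeros((1, dim)),
                                   np.ones((1, dim))) for _ in range(n_states)]
    trans = np.zeros((n_states, n_states))
    exit_prob = np.zeros(n_states)
    for i in range(n_states - 1):
        trans[i, i] = trans[i, i + 1] = 0.5
    trans[-1, -1] = 0.5
    exit_prob[-1] = 0.5
    return HmmModel(label, states, trans, exit_prob,
                    var_floor=np.full(dim, 1e-8))


def _global_stats(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = frames.mean(axis=0)
    var = frames.var(axis=0)
    if np.any(var <= 0):
        warnings.warn("zero-variance feature dimension; flooring")
    return mean, var


def _init_model_from_stats(model: HmmModel, mean: np.ndarray, var: np.ndarray,
                           floor_scale: float = VAR_FLOOR_SCALE) -> None:
    floor = np.maximum(floor_scale * var, 1e-10)
    var = np.maximum(var, floor)
    for st in model.states:
        st.weights = np.ones(1)
        st.means = mean[None, :].copy()
        st.variances = var[None, :].copy()
    model.var_floor = floor


def flat_start_init(feature_list: list[np.ndarray],
                    topology: dict[str, int]) -> dict[str, HmmModel]:
    """Initialize every model's every state with the global data statistics.

    All models come out identical (single component, global mean/variance,
    uniform legal transitions) regardless of label — the class identities
    emerge only through subsequent reestimation.
    """
    if not feature_list:
        raise ValueError("flat start requires at least one training clip")
    frames = np.concatenate([np.asarray(f) for f in feature_list], axis=0)
    mean, var = _global_stats(frames)
    models = {}
    for label, n_states in topology.items():
        m = make_left_right(label, n_states, frames.shape[1])
        _init_model_from_stats(m, mean, var)
        models[label] = m
    return models


def local_init(features_by_label: dict[str, list[np.ndarray]],
               topology: dict[str, int],
               fallback_frames: np.ndarray | None = None) -> dict[str, HmmModel]:
    """Initialize each model from its own class's statistics.

    A label present in the topology but with no clips (typically silence
    when the corpus has no silence-only recordings) falls back to the
    pooled statistics when ``fallback_frames`` is given, else errors.
    """
    models = {}
    all_frames = [np.asarray(f) for fl in features_by_label.values() for f in fl]
    for label, n_states in topology.items():
        clips = features_by_label.get(label, [])
        if clips:
            frames = np.concatenate([np.asarray(f) for f in clips], axis=0)
        elif fallback_frames is not None:
            frames = fallback_frames
        elif all_frames:
            raise ValueError(f"class {label!r} has no training clips")
        else:
            raise ValueError("local init requires training data")
        mean, var = _global_stats(frames)
        m = make_left_right(label, n_states, frames.shape[1])
        _init_model_from_stats(m, mean, var)
        models[label] = m
    return models


def split_mixtures(models: dict[str, HmmModel], perturb: float = 0.2,
                   seed: int | None = None) -> dict[str, HmmModel]:
    """Double every state's component count.

    Each component is cloned into a +-``perturb``*sigma pair with half the
    weight, leaving the state's first moment unchanged.  Deterministic (the
    perturbation is along each dimension's standard deviation); ``seed`` is
    accepted for interface symmetry but unused.
    """
    out = {}
    for label, model in models.items():
        m2 = model.copy()
        for st in m2.states:
            sigma = np.sqrt(st.variances)
            st.means = np.concatenate([st.means + perturb * sigma,
                                       st.means - perturb * sigma], axis=0)
            st.variances = np.concatenate([st.variances, st.variances], axis=0)
            st.weights = np.concatenate([st.weights, st.weights]) / 2.0
        out[label] = m2
    return out


# ---------------------------------------------------------------------------
# Composite networks

@dataclass
class Network:
    """A left-to-right chain of models, some skippable, flattened to one HMM.

    ``state_ref`` maps each composite state to its (model label, state index)
    so sufficient statistics pool back onto the shared models.
    """

    models: dict[str, HmmModel]
    state_ref: list[tuple[str, int]]
    log_entry: np.ndarray  # (S,)
    log_trans: np.ndarray  # (S, S)
    log_exit: np.ndarray   # (S,)
    unit_of_state: np.ndarray  # (S,) int: which chain position a state belongs to

    @property
    def n_states(self) -> int:
        return len(self.state_ref)


def build_network(units: list[tuple[HmmModel, bool]],
                  skip_prob: float = 0.5) -> Network:
    """Flatten a chain of (model, optional) units into one decoding network.

    An optional unit is bypassed with probability ``skip_prob``; mass
    leaving a unit's last state is routed to the first state of the next
    occupied unit (or to network exit if everything downstream is skipped).
    """
    sizes = [m.n_states for m, _ in units]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    S = int(offsets[-1])
    trans = np.zeros((S, S))
    entry = np.zeros(S)
    exit_p = np.zeros(S)
    state_ref: list[tuple[str, int]] = []
    unit_of_state = np.zeros(S, dtype=int)
    models: dict[str, HmmModel] = {}

    for u, (m, _) in enumerate(units):
        models[m.label] = m
        o = offsets[u]
        trans[o:o + m.n_states, o:o + m.n_states] = m.trans
        for s in range(m.n_states):
            state_ref.append((m.label, s))
            unit_of_state[o + s] = u

    def continuation(start_unit: int) -> tuple[list[tuple[int, float]], float]:
        """(first-state, prob) per reachable downstream unit + exit prob."""
        targets = []
        carry = 1.0
        for j in range(start_unit, len(units)):
            mj, opt = units[j]
            p_enter = carry * (1.0 - skip_prob) if opt else carry
            targets.append((int(offsets[j]), p_enter))
            if opt:
                carry *= skip_prob
            else:
                carry = 0.0
                break
        return targets, carry

    tgt0, exit0 = continuation(0)
    for s0, p in tgt0:
        entry[s0] = p
    if exit0 > 0:
        raise ValueError("network must contain at least one mandatory unit")

    for u, (m, _) in enumerate(units):
        last = int(offsets[u]) + m.n_states - 1
        mass = m.exit_prob[m.n_states - 1]
        tgts, carry = continuation(u + 1)
        for s0, p in tgts:
            trans[last, s0] = mass * p
        exit_p[last] = mass * carry

    with np.errstate(divide="ignore"):
        return Network(models=models, state_ref=state_ref,
                       log_entry=np.where(entry > 0, np.log(entry), LOG_ZERO),
                       log_trans=np.where(trans > 0, np.log(trans), LOG_ZERO),
                       log_exit=np.where(exit_p > 0, np.log(exit_p), LOG_ZERO),
                       unit_of_state=unit_of_state)


def network_log_emissions(net: Network, X: np.ndarray) -> np.ndarray:
    """Per-state emission log-densities for a frame batch X (..., D) -> (..., S).

    Duplicate references to the same underlying state (e.g. leading and
    trailing silence) are computed once and broadcast.
    """
    flat = X.reshape(-1, X.shape[-1])
    cache: dict[tuple[str, int], np.ndarray] = {}
    cols = []
    for ref in net.state_ref:
        if ref not in cache:
            label, s = ref
            cache[ref] = net.models[label].states[s].log_pdf(flat)
        cols.append(cache[ref])
    out = np.stack(cols, axis=-1)
    return out.reshape(*X.shape[:-1], net.n_states)


# ---------------------------------------------------------------------------
# Forward / backward / Viterbi (batched, scaled linear domain)

def _scale_emissions(logB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = logB.max(axis=-1)
    m = np.maximum(m, LOG_ZERO)  # all-impossible frame guard
    Bhat = np.exp(logB - m[..., None])
    return Bhat, m


def forward_backward(net: Network, logB: np.ndarray):
    """Scaled forward-backward over a batch.

    ``logB`` has shape (N, T, S).  Returns (loglik (N,), gamma (N, T, S),
    xi_sum (N, S, S), exit_gamma (N, S)); sequences with no valid path get
    loglik -inf and zero posteriors.
    """
    N, T, S = logB.shape
    A = np.exp(np.maximum(net.log_trans, LOG_ZERO))
    entry = np.exp(np.maximum(net.log_entry, LOG_ZERO))
    exit_p = np.exp(np.maximum(net.log_exit, LOG_ZERO))
    Bhat, m = _scale_emissions(logB)

    alpha = np.zeros((N, T, S))
    c = np.zeros((N, T))
    a = entry[None, :] * Bhat[:, 0]
    c[:, 0] = a.sum(axis=1)
    ok = c[:, 0] > 0
    a[ok] /= c[ok, 0, None]
    alpha[:, 0] = a
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * Bhat[:, t]
        c[:, t] = a.sum(axis=1)
        ok = c[:, t] > 0
        a[ok] /= c[ok, t, None]
        alpha[:, t] = a

    term = alpha[:, -1] @ exit_p  # (N,)
    valid = (c > 0).all(axis=1) & (term > 0)
    loglik = np.full(N, -np.inf)
    loglik[valid] = (np.log(c[valid]).sum(axis=1) + m[valid].sum(axis=1)
                     + np.log(term[valid]))

    # backward pass normalized by its own per-frame maximum: gamma and xi
    # are renormalized per frame below, so any per-(clip, t) scale on beta
    # cancels, and max-normalization keeps the recursion overflow-free even
    # for states with vanishing forward probability
    beta = np.zeros((N, T, S))
    b = np.broadcast_to(exit_p[None, :], (N, S)).copy()
    mx = b.max(axis=1, keepdims=True)
    np.divide(b, mx, out=b, where=mx > 0)
    beta[:, -1] = b
    for t in range(T - 2, -1, -1):
        b = (Bhat[:, t + 1] * beta[:, t + 1]) @ A.T
        mx = b.max(axis=1, keepdims=True)
        np.divide(b, mx, out=b, where=mx > 0)
        beta[:, t] = b

    gamma = alpha * beta
    denom = gamma.sum(axis=2, keepdims=True)
    np.divide(gamma, denom, out=gamma, where=denom > 0)

    # expected transition counts summed over time
    xi_sum = np.zeros((N, S, S))
    for t in range(T - 1):
        w = Bhat[:, t + 1] * beta[:, t + 1]
        xi = alpha[:, t, :, None] * A[None, :, :] * w[:, None, :]
        tot = xi.sum(axis=(1, 2), keepdims=True)
        np.divide(xi, tot, out=xi, where=tot > 0)
        xi_sum += xi

    exit_gamma = alpha[:, -1] * exit_p[None, :]
    tot = exit_gamma.sum(axis=1, keepdims=True)
    np.divide(exit_gamma, tot, out=exit_gamma, where=tot > 0)

    gamma[~valid] = 0.0
    xi_sum[~valid] = 0.0
    exit_gamma[~valid] = 0.0
    return loglik, gamma, xi_sum, exit_gamma


def forward_loglik(net: Network, features: np.ndarray) -> float:
    """Total data log-likelihood of one sequence under the network."""
    logB = network_log_emissions(net, features[None, :, :])
    loglik, *_ = forward_backward(net, logB)
    return float(loglik[0])


@dataclass
class AlignmentResult:
    """Best-path decode of one clip against a network."""

    state_path: np.ndarray | None  # (T,) composite state indices, None if unalignable
    log_likelihood: float
    per_frame_log_likelihood: float

    @property
    def alignable(self) -> bool:
        return self.state_path is not None


def viterbi(net: Network, features: np.ndarray) -> AlignmentResult:
    """Max-probability state path for a single feature sequence."""
    paths, scores = viterbi_batch(net, network_log_emissions(net, features[None]))
    T = features.shape[0]
    if not np.isfinite(scores[0]):
        return AlignmentResult(None, -np.inf, -np.inf)
    return AlignmentResult(paths[0], float(scores[0]), float(scores[0]) / T)


def viterbi_batch(net: Network, logB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched Viterbi: logB (N, T, S) -> (paths (N, T), scores (N,))."""
    N, T, S = logB.shape
    delta = net.log_entry[None, :] + logB[:, 0]
    psi = np.zeros((N, T, S), dtype=np.int16)
    for t in range(1, T):
        cand = delta[:, :, None] + net.log_trans[None, :, :]  # (N, i, j)
        psi[:, t] = np.argmax(cand, axis=1)
        delta = np.max(cand, axis=1) + logB[:, t]
    final = delta + net.log_exit[None, :]
    last = np.argmax(final, axis=1)
    scores = final[np.arange(N), last]
    scores = np.where(scores <= LOG_ZERO / 2, -np.inf, scores)
    paths = np.zeros((N, T), dtype=np.int32)
    paths[:, -1] = last
    for t in range(T - 1, 0, -1):
        paths[:, t - 1] = psi[np.arange(N), t, paths[:, t]]
    return paths, scores


# ---------------------------------------------------------------------------
# Embedded Baum-Welch over labeled clips

def _network_for_label(models: dict[str, HmmModel], label: str,
                       with_silence: bool = True) -> Network:
    if label == "silence" or not with_silence or "silence" not in models:
        return build_network([(models[label], False)])
    sil = models["silence"]
    return build_network([(sil, True), (models[label], False), (sil, True)])


class _StateAccumulator:
    def __init__(self, model: HmmModel):
        S, D = model.n_states, model.dim
        self.gamma_w = [np.zeros(st.n_components) for st in model.states]
        self.mean_acc = [np.zeros((st.n_components, D)) for st in model.states]
        self.sq_acc = [np.zeros((st.n_components, D)) for st in model.states]
        self.trans_acc = np.zeros((S, S))
        self.exit_acc = np.zeros(S)


def _accumulate(models: dict[str, HmmModel], net: Network, X: np.ndarray,
                accs: dict[str, _StateAccumulator]) -> np.ndarray:
    """E-step for one batch X (N, T, D) against one network; returns logliks."""
    logB = network_log_emissions(net, X)
    loglik, gamma, xi_sum, exit_gamma = forward_backward(net, logB)

    # pool occupancy of duplicate composite states onto underlying states
    by_ref: dict[tuple[str, int], np.ndarray] = {}
    for s, ref in enumerate(net.state_ref):
        g = gamma[:, :, s]
        by_ref[ref] = by_ref.get(ref, 0) + g

    flat = X.reshape(-1, X.shape[-1])
    for (label, s_ix), g in by_ref.items():
        st = models[label].states[s_ix]
        acc = accs[label]
        gw = g.reshape(-1)  # (N*T,)
        cl = st.component_log_pdf(flat) + np.log(st.weights)[None, :]
        mx = cl.max(axis=1, keepdims=True)
        r = np.exp(cl - mx)
        r /= r.sum(axis=1, keepdims=True)
        W = r * gw[:, None]  # (N*T, M)
        acc.gamma_w[s_ix] += W.sum(axis=0)
        acc.mean_acc[s_ix] += W.T @ flat
        acc.sq_acc[s_ix] += W.T @ (flat ** 2)

    # transition statistics: within-unit mass -> model transitions;
    # mass leaving a unit (cross-unit or network exit) -> last-state exit
    xi_tot = xi_sum.sum(axis=0)  # (S, S)
    exit_tot = exit_gamma.sum(axis=0)  # (S,)
    S = net.n_states
    for i in range(S):
        lab_i, si = net.state_ref[i]
        acc = accs[lab_i]
        for j in range(S):
            if xi_tot[i, j] == 0:
                continue
            if net.unit_of_state[i] == net.unit_of_state[j]:
                acc.trans_acc[si, net.state_ref[j][1]] += xi_tot[i, j]
            else:
                acc.exit_acc[si] += xi_tot[i, j]
        acc.exit_acc[si] += exit_tot[i]
    return loglik


def baum_welch(models: dict[str, HmmModel],
               dataset: list[tuple[np.ndarray, str]],
               n_iter: int = 2, with_silence: bool = True,
               min_occupancy: float = 1e-3) -> list[float]:
    """Reestimate the shared model set on labeled clips.

    ``dataset`` is a list of (feature matrix (T, D), label).  Clips too
    short for their network (T below the minimum mandatory path length) or
    otherwise unalignable are skipped with a warning and counted once.
    Returns the total data log-likelihood before each update — a
    non-decreasing sequence (EM) up to the variance-floor projection.
    """
    history: list[float] = []
    for _ in range(n_iter):
        accs = {lab: _StateAccumulator(m) for lab, m in models.items()}
        total = 0.0
        n_skipped = 0
        for label, T, X in _grouped(dataset):
            min_len = models[label].n_states  # mandatory path length
            if T < min_len:
                n_skipped += X.shape[0]
                continue
            net = _network_for_label(models, label, with_silence)
            loglik = _accumulate(models, net, X, accs)
            bad = ~np.isfinite(loglik)
            n_skipped += int(bad.sum())
            total += float(loglik[np.isfinite(loglik)].sum())
        if n_skipped:
            warnings.warn(f"{n_skipped} clip(s) skipped (unalignable/too short)")
        _maximize(models, accs, min_occupancy)
        history.append(total)
    return history


def _grouped(dataset):
    """Yield (label, T, stacked X) batches of equal-length clips."""
    groups: dict[tuple[str, int], list[np.ndarray]] = {}
    for X, label in dataset:
        X = np.asarray(X, dtype=np.float64)
        groups.setdefault((label, X.shape[0]), []).append(X)
    for (label, T), clips in sorted(groups.items(), key=lambda kv: kv[0]):
        yield label, T, np.stack(clips)


def _maximize(models: dict[str, HmmModel], accs: dict[str, _StateAccumulator],
              min_occupancy: float) -> None:
    for label, model in models.items():
        acc = accs[label]
        for s_ix, st in enumerate(model.states):
            gw = acc.gamma_w[s_ix]
            tot = gw.sum()
            if tot < min_occupancy:
                continue  # state saw no data this pass; keep parameters
            live = gw > min_occupancy * max(1.0, tot) * 1e-6
            w = np.where(live, gw, 1e-12)
            means = np.where(live[:, None], acc.mean_acc[s_ix] / w[:, None],
                             st.means)
            var = np.where(live[:, None],
                           acc.sq_acc[s_ix] / w[:, None] - means ** 2,
                           st.variances)
            st.means = means
            st.variances = np.maximum(var, model.var_floor[None, :])
            new_w = np.where(live, gw, 0.0)
            if new_w.sum() > 0:
                st.weights = new_w / new_w.sum()
        # transitions: renormalize expected counts, preserving structure
        for i in range(model.n_states):
            row = acc.trans_acc[i].copy()
            ex = acc.exit_acc[i]
            tot = row.sum() + ex
            if tot <= 0:
                continue
            model.trans[i] = row / tot
            model.exit_prob[i] = ex / tot


def total_loglik(models: dict[str, HmmModel],
                 dataset: list[tuple[np.ndarray, str]],
                 with_silence: bool = True) -> float:
    """Data log-likelihood of the labeled set under the current models."""
    total = 0.0
    for label, T, X in _grouped(dataset):
        if T < models[label].n_states:
            continue
        net = _network_for_label(models, label, with_silence)
        loglik, *_ = forward_backward(net, network_log_emissions(net, X))
        total += float(loglik[np.isfinite(loglik)].sum())
    return total


def forced_align_filter(models: dict[str, HmmModel],
                        dataset: list[tuple[np.ndarray, str]],
                        n_sd: float = 3.0, with_silence: bool = True
                        ) -> tuple[list[tuple[np.ndarray, str]], float]:
    """Drop clips whose forced alignment marks them as outliers.

    Each clip is Viterbi-aligned against its own label's network; a clip is
    an outlier if it is unalignable or its per-frame normalized
    log-likelihood falls more than ``n_sd`` standard deviations below its
    class mean.  Returns the kept clips and the outlier fraction.
    """
    scores = np.zeros(len(dataset))
    labels = [lab for _, lab in dataset]
    groups: dict[tuple[str, int], list[int]] = {}
    for i, (X, lab) in enumerate(dataset):
        groups.setdefault((lab, np.asarray(X).shape[0]), []).append(i)
    for (lab, T), idxs in sorted(groups.items(), key=lambda kv: kv[0]):
        X = np.stack([np.asarray(dataset[i][0], dtype=np.float64) for i in idxs])
        if T < models[lab].n_states:
            for i in idxs:
                scores[i] = -np.inf
            continue
        net = _network_for_label(models, lab, with_silence)
        _, sc = viterbi_batch(net, network_log_emissions(net, X))
        for i, s in zip(idxs, sc):
            scores[i] = s / T

    outlier = np.zeros(len(dataset), dtype=bool)
    for lab in set(labels):
        ix = np.array([i for i, l in enumerate(labels) if l == lab])
        sc = scores[ix]
        finite = np.isfinite(sc)
        outlier[ix[~finite]] = True
        if finite.sum() >= 2:
            mu, sd = sc[finite].mean(), sc[finite].std()
            outlier[ix[finite]] = sc[finite] < mu - n_sd * sd
    kept = [dataset[i] for i in range(len(dataset)) if not outlier[i]]
    fraction = float(outlier.mean()) if len(dataset) else 0.0
    return kept, fraction


# ---------------------------------------------------------------------------
# Serialization: versioned plain-text model sets

FORMAT_VERSION = 1


def dumps_models(models: dict[str, HmmModel]) -> str:
    """Serialize a model set to the package's text format.

    Header line per model (label, states, components, dim), then the
    transition rows, exit vector, variance floor and one block per state
    with weight/mean/variance lines per component.  Full float precision
    (repr round-trip exact).
    """
    buf = io.StringIO()
    buf.write(f"apiscan-models v{FORMAT_VERSION}\n")
    buf.write(f"nmodels {len(models)}\n")
    for label in sorted(models):
        m = models[label]
        buf.write(f"model {label} states={m.n_states} "
                  f"components={m.states[0].n_components} dim={m.dim}\n")
        for i in range(m.n_states):
            buf.write("trans " + " ".join(repr(float(v)) for v in m.trans[i]) + "\n")
        buf.write("exit " + " ".join(repr(float(v)) for v in m.exit_prob) + "\n")
        buf.write("floor " + " ".join(repr(float(v)) for v in m.var_floor) + "\n")
        for s_ix, st in enumerate(m.states):
            buf.write(f"state {s_ix} M={st.n_components}\n")
            for c in range(st.n_components):
                buf.write("w " + repr(float(st.weights[c])) + "\n")
                buf.write("mu " + " ".join(repr(float(v)) for v in st.means[c]) + "\n")
                buf.write("var " + " ".join(repr(float(v)) for v in st.variances[c]) + "\n")
    return buf.getvalue()


def loads_models(text: str) -> dict[str, HmmModel]:
    lines = text.splitlines()
    if not lines or not lines[0].startswith("apiscan-models v"):
        raise ValueError("not an apiscan model file")
    version = int(lines[0].split("v")[-1])
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version}")
    pos = 1
    n_models = int(lines[pos].split()[1]); pos += 1
    models: dict[str, HmmModel] = {}
    for _ in range(n_models):
        head = lines[pos].split(); pos += 1
        label = head[1]
        S = int(head[2].split("=")[1])
        D = int(head[4].split("=")[1])
        trans = np.zeros((S, S))
        for i in range(S):
            trans[i] = [float(v) for v in lines[pos].split()[1:]]; pos += 1
        exit_prob = np.array([float(v) for v in lines[pos].split()[1:]]); pos += 1
        floor = np.array([float(v) for v in lines[pos].split()[1:]]); pos += 1
        states = []
        for _s in range(S):
            M = int(lines[pos].split("M=")[1]); pos += 1
            w = np.zeros(M); mu = np.zeros((M, D)); var = np.zeros((M, D))
            for c in range(M):
                w[c] = float(lines[pos].split()[1]); pos += 1
                mu[c] = [float(v) for v in lines[pos].split()[1:]]; pos += 1
                var[c] = [float(v) for v in lines[pos].split()[1:]]; pos += 1
            states.append(GaussianMixtureState(w, mu, var))
        models[label] = HmmModel(label, states, trans, exit_prob, floor)
    return models


def save_models(path: str, models: dict[str, HmmModel]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(dumps_models(models))


def load_models(path: str) -> dict[str, HmmModel]:
    with open(path, encoding="utf-8") as fh:
        return loads_models(fh.read())
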