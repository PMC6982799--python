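"""MFCC and LPC front-ends producing 39-dimensional feature sequences.

Both front-ends share the layout used by the acoustic models: 12 static
coefficients plus a log-energy term (13 statics), extended with first- and
second-order regression deltas to 39 dimensions per frame.

MFCC chain: preemphasis -> 25/10 ms Hamming frames -> |FFT|^2 (512 bins)
-> triangular mel filterbank -> floored log -> orthonormal DCT-II ->
coefficients c1..c12 + log raw-frame energy.  Cepstral mean normalization
(CMN), when requested, subtracts the per-coefficient mean of the statics
over the clip and recomputes the deltas.

LPC chain: same framing/window -> frame autocorrelation -> Levinson-Durbin
recursion of order 12 -> either the predictor coefficients or (default)
LPC-cepstra, + log energy, + deltas.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import dct
from scipy.linalg import solve_toeplitz

from .audio_io import AudioClip
from .preprocess import FFT_SIZE, FramingConfig, apply_window, frame_signal, preemphasize

LOG_FLOOR = 1e-10
ENERGY_FLOOR = 1e-10


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


@dataclass(frozen=True)
class MelFilterBank:
    """Triangular filters with centers equally spaced on the mel scale."""

    weights: np.ndarray  # (n_filters, fft_size//2 + 1), peak 1 per filter
    f_low_hz: float
    f_high_hz: float
    sample_rate_hz: int
    fft_size: int

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]


def build_mel_filterbank(n_filters: int = 26, f_low: float = 0.0,
                         f_high: float = 8000.0, fft_size: int = FFT_SIZE,
                         sample_rate: int = 16_000) -> MelFilterBank:
    """Construct a triangular mel filterbank over the rfft bin grid.

    Centers are equally spaced in mel between ``f_low`` and ``f_high``;
    each filter rises linearly (in Hz) from the previous center to its own
    and falls to the next, with peak weight 1, so adjacent filters overlap
    exactly at each other's centers.
    """
    if not f_low < f_high <= sample_rate / 2:
        raise ValueError("need f_low < f_high <= Nyquist")
    mel_pts = np.linspace(hz_to_mel(f_low), hz_to_mel(f_high), n_filters + 2)
    hz_pts = np.asarray(mel_to_hz(mel_pts))
    bin_freqs = np.arange(fft_size // 2 + 1) * sample_rate / fft_size

    weights = np.zeros((n_filters, fft_size // 2 + 1))
    for i in range(n_filters):
        left, center, right = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bin_freqs - left) / (center - left)
        down = (right - bin_freqs) / (right - center)
        weights[i] = np.clip(np.minimum(up, down), 0.0, None)
        if weights[i].max() == 0.0:
            raise ValueError(
                f"filter {i} covers no FFT bin: too many filters for "
                f"fft_size={fft_size} at {sample_rate} Hz")
        weights[i] /= weights[i].max()  # peak-normalize to 1
    return MelFilterBank(weights=weights, f_low_hz=f_low, f_high_hz=f_high,
                         sample_rate_hz=sample_rate, fft_size=fft_size)


@dataclass
class FeatureSequence:
    """(T, D) matrix of per-frame features with a kind tag.

    ``statics`` holds the first ``static_dim`` columns (cepstra + energy);
    the remaining columns are the delta and delta-delta blocks.
    """

    data: np.ndarray
    kind: str  # MFCC | MFCC_CMN | LPC
    static_dim: int = 13
    frame_shift_s: float = 0.010
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def dim(self) -> int:
        return self.data.shape[1]

    @property
    def statics(self) -> np.ndarray:
        return self.data[:, : self.static_dim]


def _frame_pipeline(clip: AudioClip, config: FramingConfig) -> tuple[np.ndarray, np.ndarray]:
    """Shared conditioning: preemphasis, framing, raw-frame log energy, window."""
    x = preemphasize(clip.samples, config.preemphasis_coeff)
    frames = frame_signal(x, config, clip.sample_rate_hz)
    log_energy = np.log(np.maximum(np.sum(frames ** 2, axis=1), ENERGY_FLOOR))
    windowed = apply_window(frames, config.window)
    return windowed, log_energy


def mfcc(clip: AudioClip, bank: MelFilterBank | None = None,
         n_cepstra: int = 12, config: FramingConfig = FramingConfig(),
         with_deltas: bool = True, cmn: bool = False) -> FeatureSequence:
    """Extract MFCC features (12 cepstra + log energy, optional deltas/CMN)."""
    if bank is None:
        bank = build_mel_filterbank(sample_rate=clip.sample_rate_hz)
    windowed, log_energy = _frame_pipeline(clip, config)
    power = np.abs(np.fft.rfft(windowed, n=bank.fft_size, axis=1)) ** 2
    fb_energies = power @ bank.weights.T
    log_fb = np.log(np.maximum(fb_energies, LOG_FLOOR))
    cepstra = dct(log_fb, type=2, norm="ortho", axis=1)[:, 1 : n_cepstra + 1]
    statics = np.concatenate([cepstra, log_energy[:, None]], axis=1)
    feats = FeatureSequence(data=statics, kind="MFCC",
                            static_dim=statics.shape[1],
                            frame_shift_s=config.frame_shift_s)
    if cmn:
        feats = cepstral_mean_normalize(feats, recompute_deltas=False)
    if with_deltas:
        feats = add_deltas(feats)
    return feats


def add_deltas(static: FeatureSequence, window_w: int = 2) -> FeatureSequence:
    """Append regression deltas and delta-deltas (D becomes 3 x static_dim).

    d_t = sum_{th=1..w} th*(c_{t+th} - c_{t-th}) / (2*sum th^2), with the
    first/last static frame replicated past the edges.
    """
    if static.data.shape[1] != static.static_dim:
        raise ValueError("add_deltas expects a statics-only sequence")
    T = static.n_frames
    if T < 2 * window_w + 1:
        raise ValueError(f"need at least {2 * window_w + 1} frames, got {T}")
    d1 = _regression_delta(static.data, window_w)
    d2 = _regression_delta(d1, window_w)
    data = np.concatenate([static.data, d1, d2], axis=1)
    return replace(static, data=data)


def _regression_delta(x: np.ndarray, w: int) -> np.ndarray:
    denom = 2.0 * sum(th * th for th in range(1, w + 1))
    padded = np.concatenate([np.repeat(x[:1], w, axis=0), x,
                             np.repeat(x[-1:], w, axis=0)], axis=0)
    out = np.zeros_like(x)
    for th in range(1, w + 1):
        out += th * (padded[w + th : w + th + x.shape[0]]
                     - padded[w - th : w - th + x.shape[0]])
    return out / denom


def cepstral_mean_normalize(features: FeatureSequence,
                            recompute_deltas: bool = True) -> FeatureSequence:
    """Subtract the per-coefficient mean of the statics over the clip.

    Deltas, being differences, are shift-invariant already; they are
    recomputed from the normalized statics for exactness.
    """
    if features.kind != "MFCC":
        raise ValueError(f"CMN applies to MFCC features, got kind {features.kind!r}")
    statics = features.statics - features.statics.mean(axis=0, keepdims=True)
    out = replace(features, data=statics, kind="MFCC_CMN")
    if recompute_deltas and features.dim > features.static_dim:
        out = add_deltas(out)
    return out


@dataclass(frozen=True)
class LpcConfig:
    """All-pole front-end settings: order and static representation."""

    order: int = 12
    representation: str = "cepstra"  # cepstra | coefficients


def levinson_durbin(r: np.ndarray, order: int) -> tuple[np.ndarray, float, np.ndarray]:
    """Solve the Toeplitz normal equations by the Levinson-Durbin recursion.

    Returns predictor coefficients ``a[1..p]`` (sign convention
    x_hat[t] = sum a_k x[t-k]), the final prediction-error energy ``E_p``,
    and the reflection coefficients ``k[1..p]``.  A white autocorrelation
    (r[1:] = 0) yields zero coefficients and E_p = r[0]; a silent frame
    (r[0] = 0) yields zeros with a floored error.
    """
    r = np.asarray(r, dtype=np.float64)
    if r.shape[0] < order + 1:
        raise ValueError(f"need {order + 1} autocorrelation lags, got {r.shape[0]}")
    if r[0] <= 0.0:
        return np.zeros(order), ENERGY_FLOOR, np.zeros(order)
    a = np.zeros(order + 1)
    E = float(r[0])
    ks = np.zeros(order)
    for i in range(1, order + 1):
        acc = r[i] - np.dot(a[1:i], r[i - 1 : 0 : -1])
        k = acc / E
        ks[i - 1] = k
        a_new = a.copy()
        a_new[i] = k
        a_new[1:i] = a[1:i] - k * a[i - 1 : 0 : -1]
        a = a_new
        E *= 1.0 - k * k
        if E <= 0.0:
            E = ENERGY_FLOOR
    return a[1:], E, ks


def lpc_to_cepstra(a: np.ndarray, n_cepstra: int) -> np.ndarray:
    """Convert predictor coefficients to LPC-cepstra by the standard recursion.

    c_1..c_n from a_1..a_p with c_n = a_n + sum_{k=1..n-1} (k/n) c_k a_{n-k}
    (a_n = 0 for n > p).
    """
    p = a.shape[0]
    c = np.zeros(n_cepstra)
    for n in range(1, n_cepstra + 1):
        an = a[n - 1] if n <= p else 0.0
        s = sum((k / n) * c[k - 1] * a[n - k - 1]
                for k in range(max(1, n - p), n))
        c[n - 1] = an + s
    return c


def lpc(clip: AudioClip, config: LpcConfig = LpcConfig(),
        framing: FramingConfig = FramingConfig(),
        with_deltas: bool = True) -> FeatureSequence:
    """Extract LPC features with the same 13-static / 39-total layout as MFCC."""
    windowed, log_energy = _frame_pipeline(clip, framing)
    T, L = windowed.shape
    if config.order >= L:
        raise ValueError("LPC order must be below the frame length")
    statics = np.zeros((T, 13))
    for t in range(T):
        frame = windowed[t]
        full = np.correlate(frame, frame, mode="full")
        r = full[L - 1 : L + config.order]
        a, _E, _ = levinson_durbin(r, config.order)
        if config.representation == "cepstra":
            vec = lpc_to_cepstra(a, 12)
        elif config.representation == "coefficients":
            vec = np.zeros(12)
            vec[: config.order] = a[:12]
        else:
            raise ValueError(f"unknown representation {config.representation!r}")
        statics[t, :12] = vec
    statics[:, 12] = log_energy
    feats = FeatureSequence(data=statics, kind="LPC", static_dim=13,
                            frame_shift_s=framing.frame_shift_s)
    if with_deltas:
        feats = add_deltas(feats)
    return feats


def toeplitz_lpc_oracle(r: np.ndarray, order: int) -> np.ndarray:
    """Dense Toeplitz solve of the LPC normal equations (test oracle)."""
    r = np.asarray(r, dtype=np.float64)
    return solve_toeplitz(r[:order], r[1 : order + 1])


# ---------------------------------------------------------------------------
# Persistence: small binary container + CSV export

_MAGIC = b"APFS"
_VERSION = 1
_KINDS = ("MFCC", "MFCC_CMN", "LPC")


def save_features(path: str, features: FeatureSequence) -> None:
    """Write features as a binary container.

    Layout: magic ``APFS``, u16 version, u16 kind index, u32 T, u32 D,
    u32 static_dim, f64 frame shift in seconds, then row-major float32
    payload (little-endian throughout).
    """
    header = struct.pack("<4sHHIIId", _MAGIC, _VERSION,
                         _KINDS.index(features.kind), features.n_frames,
                         features.dim, features.static_dim,
                         features.frame_shift_s)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(features.data.astype("<f4").tobytes())


def load_features(path: str) -> FeatureSequence:
    with open(path, "rb") as fh:
        header = fh.read(struct.calcsize("<4sHHIIId"))
        magic, version, kind_ix, T, D, static_dim, shift = struct.unpack(
            "<4sHHIIId", header)
        if magic != _MAGIC or version != _VERSION:
            raise ValueError(f"{path}: not a feature container (or wrong version)")
        data = np.frombuffer(fh.read(T * D * 4), dtype="<f4").reshape(T, D)
    return FeatureSequence(data=data.astype(np.float64), kind=_KINDS[kind_ix],
                           static_dim=static_dim, frame_shift_s=shift)


def export_csv(path: str, features: FeatureSequence) -> None:
    header = f"# kind={features.kind} static_dim={features.static_dim}"
    np.savetxt(path, features.data, delimiter=",", header=header)
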