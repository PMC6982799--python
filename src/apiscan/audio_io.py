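"""WAV audio input/output, canonicalization and dataset manifests.

The classification unit throughout the package is a 3-second mono clip at
16 kHz.  Long hive recordings are read as-is (any rate / channel count),
canonicalized by band-limited downsampling and channel averaging, and cut
into consecutive non-overlapping labeled segments.  Dataset composition is
tracked in a plain CSV manifest (``path,label,split``) so that training and
evaluation runs are reproducible from a single text file.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

CANONICAL_RATE = 16_000
SEGMENT_LEN_S = 3.0

LABELS = ("normal", "swarm", "silence", "unknown")


class AudioFormatError(ValueError):
    """Raised for unreadable or unsupported WAV content."""


class ManifestError(ValueError):
    """Raised for malformed or inconsistent dataset manifests."""


@dataclass
class AudioClip:
    """A labeled mono (or multichannel, pre-canonicalization) audio buffer.

    ``samples`` are float64 amplitudes in [-1, 1]; shape ``(n,)`` once mono,
    ``(n, channels)`` straight off a multichannel file.
    """

    samples: np.ndarray
    sample_rate_hz: int
    label: str = "unknown"
    source_id: str = ""
    offset_s: float = 0.0
    is_tail: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise ValueError("AudioClip requires non-empty samples")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        peak = float(np.max(np.abs(self.samples)))
        if peak > 1.0 + 1e-9:
            raise ValueError(f"amplitudes exceed full scale (peak {peak:.4g})")

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.sample_rate_hz


def read_wav(path: str | Path, label: str = "unknown") -> AudioClip:
    """Read a RIFF/WAVE file into an :class:`AudioClip`.

    Integer PCM (8/16/24/32-bit) is rescaled to [-1, 1] by its full-scale
    value; IEEE-float payloads are taken as already normalized.  Rate and
    channel count are preserved — call :func:`canonicalize` to reach the
    16 kHz mono convention.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on bad chunks
        raise AudioFormatError(f"{path}: cannot parse WAV data chunk ({exc})") from exc

    if data.dtype == np.uint8:  # 8-bit PCM is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:  # covers 24-bit (left-justified) and 32-bit PCM
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"{path}: unsupported sample format {data.dtype}")

    samples = np.clip(samples, -1.0, 1.0)
    return AudioClip(samples=samples, sample_rate_hz=int(rate), label=label,
                     source_id=path.stem)


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV (the storage convention)."""
    data = np.clip(clip.samples, -1.0, 1.0)
    pcm = np.round(data * 32767.0).astype(np.int16)
    wavfile.write(str(path), clip.sample_rate_hz, pcm)


def canonicalize(clip: AudioClip) -> AudioClip:
    """Reduce a clip to the 16 kHz mono convention.

    Multichannel audio is downmixed by unweighted channel mean; resampling
    is polyphase (band-limited / anti-aliased).  Upsampling is refused: the
    corpus convention only ever downsamples.
    """
    samples = clip.samples
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    rate = clip.sample_rate_hz
    if rate < CANONICAL_RATE:
        raise AudioFormatError(
            f"sample rate {rate} Hz < {CANONICAL_RATE} Hz: upsampling is not supported")
    if rate != CANONICAL_RATE:
        g = math.gcd(rate, CANONICAL_RATE)
        samples = resample_poly(samples, CANONICAL_RATE // g, rate // g)
        samples = np.clip(samples, -1.0, 1.0)
    if samples is clip.samples:
        return clip
    return replace(clip, samples=samples, sample_rate_hz=CANONICAL_RATE)


def segment(clip: AudioClip, seg_len_s: float = SEGMENT_LEN_S,
            keep_tail: bool = False) -> list[AudioClip]:
    """Cut a clip into consecutive non-overlapping segments.

    Each segment inherits the parent label.  A tail shorter than
    ``seg_len_s`` is dropped unless ``keep_tail`` is set, in which case it
    is returned flagged ``is_tail=True``.
    """
    seg_len = int(round(seg_len_s * clip.sample_rate_hz))
    n = clip.samples.shape[0]
    if n < seg_len:
        warnings.warn(f"clip shorter than {seg_len_s} s: no segments produced")
        return []
    out = []
    for i, start in enumerate(range(0, n - seg_len + 1, seg_len)):
        out.append(replace(clip, samples=clip.samples[start:start + seg_len],
                           offset_s=clip.offset_s + start / clip.sample_rate_hz))
    if keep_tail and n % seg_len:
        start = (n // seg_len) * seg_len
        out.append(replace(clip, samples=clip.samples[start:],
                           offset_s=clip.offset_s + start / clip.sample_rate_hz,
                           is_tail=True))
    return out


@dataclass
class ManifestEntry:
    path: str
    label: str
    split: str  # train | test

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ManifestError(f"unknown label {self.label!r}")
        if self.split not in ("train", "test"):
            raise ManifestError(f"unknown split {self.split!r}")


@dataclass
class DatasetManifest:
    """Ordered list of (path, label, split) rows plus provenance metadata."""

    entries: list[ManifestEntry] = field(default_factory=list)
    seed: int | None = None  # seed used for any random balancing, recorded for replay

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_split: dict[str, set[str]] = {"train": set(), "test": set()}
        for e in self.entries:
            by_split[e.split].add(e.path)
        both = by_split["train"] & by_split["test"]
        if both:
            raise ManifestError(f"paths present in both splits: {sorted(both)[:3]}")

    def counts(self, split: str | None = None) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            if split is None or e.split == split:
                out[e.label] = out.get(e.label, 0) + 1
        return out

    def subset(self, split: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == split]


def write_manifest(path: str | Path, manifest: DatasetManifest) -> None:
    """Persist a manifest as CSV: header ``path,label,split``, UTF-8, LF.

    The balancing seed, when set, is recorded in a ``# seed=`` comment line
    before the header so the random subset selection can be replayed.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if manifest.seed is not None:
            fh.write(f"# seed={manifest.seed}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["path", "label", "split"])
        for e in manifest.entries:
            writer.writerow([e.path, e.label, e.split])


def read_manifest(path: str | Path) -> DatasetManifest:
    seed: int | None = None
    entries: list[ManifestEntry] = []
    with open(path, encoding="utf-8", newline="") as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            if "seed=" in line:
                seed = int(line.split("seed=", 1)[1].strip())
        else:
            break
    rows = list(csv.reader(lines[body_start:]))
    if not rows or rows[0] != ["path", "label", "split"]:
        raise ManifestError(f"{path}: missing 'path,label,split' header")
    for lineno, row in enumerate(rows[1:], start=body_start + 2):
        if not row:
            continue
        if len(row) != 3:
            raise ManifestError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
        try:
            entries.append(ManifestEntry(*row))
        except ManifestError as exc:
            raise ManifestError(f"{path}:{lineno}: {exc}") from exc
    return DatasetManifest(entries=entries, seed=seed)


def balance_classes(entries: Sequence[ManifestEntry], seed: int,
                    labels: tuple[str, str] = ("normal", "swarm")) -> list[ManifestEntry]:
    """Randomly shorten the larger class so both classes have equal counts.

    Mirrors the corpus-preparation step in which the over-represented
    normal-activity recordings are randomly subsampled to match the swarm
    class, preventing one class from dominating training.  Entry order of
    the survivors is preserved; selection is driven by ``seed``.
    """
    rng = np.random.default_rng(seed)
    idx_by_label = {lab: [i for i, e in enumerate(entries) if e.label == lab]
                    for lab in labels}
    n_keep = min(len(v) for v in idx_by_label.values())
    kept: set[int] = set()
    for lab in labels:
        idx = idx_by_label[lab]
        chosen = rng.choice(len(idx), size=n_keep, replace=False)
        kept.update(idx[int(c)] for c in chosen)
    kept.update(i for i, e in enumerate(entries) if e.label not in labels)
    return [e for i, e in enumerate(entries) if i in kept]
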