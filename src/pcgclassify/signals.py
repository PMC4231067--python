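"""PCG audio I/O, preprocessing, and variable-size-window heart-tone segmentation.

A phonocardiogram (PCG) is a non-stationary signal: each heart tone (S1, S2,
extra sounds, murmurs) is a short burst whose length varies from beat to beat
and from pathology to pathology.  Fixed-size framing, as used in speech LPC,
smears tone boundaries, so segmentation here places a *variable-size* window
around every tone: a normalized Shannon-energy envelope is thresholded
relative to its own maximum, neighbouring active regions are merged across
short gaps, too-short regions are dropped, and the surviving regions (slightly
padded) become the analysis windows.

Times are in seconds, intervals half-open ``[start, end)``, samples 0-indexed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import ConfigurationError, InputError

#: Lowest sample rate at which the 15-1000 Hz PCG band is representable with
#: headroom; resampling below this is refused.
MIN_SAMPLE_RATE = 2000.0


@dataclass
class PCGRecording:
    """A single-channel heart-sound recording.

    Amplitudes are dimensionless and peak-normalized to [-1, 1]; the class
    label is optional (None for unlabeled field recordings).
    """

    samples: np.ndarray
    sample_rate: float
    label: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InputError("a recording needs a non-empty 1-D sample array")
        if self.sample_rate <= 0:
            raise InputError(f"sample_rate must be positive, got {self.sample_rate}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def normalized(self) -> "PCGRecording":
        """Return a copy scaled so that max |sample| = 1 (all-zero passes through)."""
        peak = float(np.max(np.abs(self.samples)))
        out = self.samples / peak if peak > 0 else self.samples.copy()
        return replace(self, samples=out)


@dataclass
class HeartToneSegment:
    """A variable-length excerpt holding one heart tone (or tone complex)."""

    samples: np.ndarray
    sample_rate: float
    start_time: float
    end_time: float
    parent_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not (0 <= self.start_time < self.end_time):
            raise InputError(
                f"segment needs 0 <= start < end, got [{self.start_time}, {self.end_time})"
            )

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class SegmentationConfig:
    """Constants of the envelope segmenter; all times in seconds."""

    frame_length: float = 0.02
    frame_hop: float = 0.01
    threshold_fraction: float = 0.2
    merge_gap: float = 0.05
    min_duration: float = 0.03
    pad: float = 0.01

    def __post_init__(self) -> None:
        for name in ("frame_length", "frame_hop", "merge_gap", "min_duration", "pad"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 < self.threshold_fraction < 1:
            raise ConfigurationError("threshold_fraction must lie in (0, 1)")


def load_recording(path: str | Path) -> PCGRecording:
    """Read a WAV file as a peak-normalized mono recording (channel 0)."""
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # unreadable / malformed
        raise InputError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.size == 0:
        raise InputError(f"WAV file {path} contains no samples")
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return PCGRecording(data, float(rate), source_id=path.stem).normalized()


def save_recording(rec: PCGRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM mono WAV."""
    peak = float(np.max(np.abs(rec.samples)))
    x = rec.samples / peak if peak > 0 else rec.samples
    wavfile.write(Path(path), int(round(rec.sample_rate)), np.round(x * 32767).astype(np.int16))


def resample(rec: PCGRecording, target_rate: float) -> PCGRecording:
    """Band-limited (polyphase) resampling to ``target_rate``."""
    if target_rate < MIN_SAMPLE_RATE:
        raise ConfigurationError(
            f"target rate {target_rate} Hz is below the {MIN_SAMPLE_RATE} Hz floor"
        )
    if abs(target_rate - rec.sample_rate) < 1e-9:
        return replace(rec, samples=rec.samples.copy())
    ratio = Fraction(int(round(target_rate)), int(round(rec.sample_rate)))
    out = resample_poly(rec.samples, ratio.numerator, ratio.denominator)
    return replace(rec, samples=np.asarray(out, dtype=np.float64), sample_rate=float(target_rate))


def _frame_indices(n_samples: int, frame: int, hop: int) -> int:
    return (n_samples - frame) // hop + 1


def compute_energy_envelope(
    rec: PCGRecording, cfg: SegmentationConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame normalized Shannon energy of a recording.

    Each frame contributes ``-mean(x^2 * log(x^2))`` with the convention
    ``0 * log 0 = 0``; the envelope is rescaled to a maximum of 1.  Shannon
    energy emphasises medium-intensity content over both the noise floor and
    isolated spikes, which makes the threshold robust for heart tones.

    Returns ``(times, envelope)`` where ``times`` are frame-center times.
    """
    cfg = cfg or SegmentationConfig()
    frame = int(round(cfg.frame_length * rec.sample_rate))
    hop = int(round(cfg.frame_hop * rec.sample_rate))
    if rec.samples.size < frame:
        raise InputError(
            f"recording has {rec.samples.size} samples, shorter than one "
            f"{frame}-sample frame"
        )
    n_frames = _frame_indices(rec.samples.size, frame, hop)
    sq = rec.samples**2
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(sq > 0, sq * np.log(sq), 0.0)
    # cumulative sums give O(n) frame means
    csum = np.concatenate([[0.0], np.cumsum(term)])
    starts = np.arange(n_frames) * hop
    env = -(csum[starts + frame] - csum[starts]) / frame
    env = np.maximum(env, 0.0)
    peak = env.max(initial=0.0)
    if peak > 0:
        env = env / peak
    times = (starts + frame / 2) / rec.sample_rate
    return times, env


def segment_heart_tones(
    rec: PCGRecording, cfg: SegmentationConfig | None = None
) -> list[HeartToneSegment]:
    """Isolate each heart tone with a variable-size time window.

    Contiguous envelope regions above ``threshold_fraction`` of the envelope
    maximum are merged across gaps shorter than ``merge_gap``, dropped if
    shorter than ``min_duration``, padded by ``pad`` on both sides, and
    clamped to the recording.  Silence yields an empty list.
    """
    cfg = cfg or SegmentationConfig()
    frame = int(round(cfg.frame_length * rec.sample_rate))
    hop = int(round(cfg.frame_hop * rec.sample_rate))
    _, env = compute_energy_envelope(rec, cfg)
    if env.max(initial=0.0) <= 0:
        return []
    active = env >= cfg.threshold_fraction

    # contiguous runs of active frames -> candidate [start_s, end_s) intervals
    intervals: list[list[float]] = []
    i = 0
    while i < active.size:
        if active[i]:
            j = i
            while j + 1 < active.size and active[j + 1]:
                j += 1
            start = i * hop / rec.sample_rate
            end = (j * hop + frame) / rec.sample_rate
            intervals.append([start, end])
            i = j + 1
        else:
            i += 1

    merged: list[list[float]] = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < cfg.merge_gap:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)

    kept = [iv for iv in merged if iv[1] - iv[0] >= cfg.min_duration]

    # pad, clamp, and re-merge any overlaps the padding introduced
    padded: list[list[float]] = []
    for start, end in kept:
        start = max(0.0, start - cfg.pad)
        end = min(rec.duration, end + cfg.pad)
        if padded and start <= padded[-1][1]:
            padded[-1][1] = end
        else:
            padded.append([start, end])

    segments = []
    for start, end in padded:
        i0 = int(math.floor(start * rec.sample_rate))
        i1 = int(math.ceil(end * rec.sample_rate))
        segments.append(
            HeartToneSegment(
                samples=rec.samples[i0:i1],
                sample_rate=rec.sample_rate,
                start_time=start,
                end_time=end,
                parent_id=rec.source_id,
            )
        )
    return segments
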