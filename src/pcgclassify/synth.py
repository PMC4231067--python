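"""Seeded generator of labeled synthetic PCG recordings for 12 heart-sound classes.

The generator emulates the waveform families a cardiologist distinguishes on
auscultation: the four fundamental tones (S1-S4) and eight variant or
pathological morphologies (ejection click, split S1/S2, opening snap, three
systolic murmurs, diastolic rumble).  Each class is a short non-stationary
burst built from damped sinusoids (valvular tones: narrow low-frequency
spectral peaks) and amplitude-enveloped bandpass noise (murmurs: broadband
turbulent-flow plateaus), plus white measurement noise at a configurable SNR.
Within-class variability comes from per-realization jitter of frequency,
duration and amplitude.

A dataset is a pure function of ``(per_class_count, sample_rate, seed)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import InputError
from .signals import PCGRecording, save_recording

#: The 12 recognizable heart-sound classes, in canonical order.
CLASS_NAMES: tuple[str, ...] = (
    "S1",
    "S2",
    "S3",
    "S4",
    "ejection click",
    "normal split S1",
    "normal split S2",
    "opening snap",
    "early systolic murmur",
    "late systolic murmur",
    "pansystolic murmur",
    "diastolic rumble",
)

PCG_BAND = (15.0, 1000.0)  # physiological PCG band, Hz
_LEAD_IN = 0.05  # silence before tone onset, s
_TAIL = 0.05  # silence after tone decay, s


@dataclass(frozen=True)
class ToneComponent:
    """One spectral building block of a heart-sound class."""

    center_hz: float
    bandwidth_hz: float
    onset_s: float
    duration_s: float
    amplitude: float
    kind: str = "damped_sinusoid"  # or "bandpass_noise"


@dataclass(frozen=True)
class Jitter:
    """Fractional per-realization variability."""

    frequency: float = 0.10
    duration: float = 0.20
    amplitude: float = 0.20


@dataclass(frozen=True)
class ToneClassSpec:
    """Recipe for one heart-sound class."""

    class_name: str
    components: tuple[ToneComponent, ...]
    jitter: Jitter = field(default_factory=Jitter)
    snr_db: float | None = 30.0

    def validate(self) -> None:
        if not self.components:
            raise InputError(f"{self.class_name}: spec has no components")
        for c in self.components:
            lo = c.center_hz - c.bandwidth_hz / 2
            hi = c.center_hz + c.bandwidth_hz / 2
            if lo < PCG_BAND[0] or hi > PCG_BAND[1]:
                raise InputError(
                    f"{self.class_name}: component band [{lo:.0f}, {hi:.0f}] Hz "
                    f"outside the {PCG_BAND[0]:.0f}-{PCG_BAND[1]:.0f} Hz PCG band"
                )
            if c.duration_s <= 0 or c.onset_s < 0 or c.amplitude <= 0:
                raise InputError(f"{self.class_name}: non-physical component {c}")
            if c.kind not in ("damped_sinusoid", "bandpass_noise"):
                raise InputError(f"{self.class_name}: unknown component kind {c.kind!r}")
        length = _LEAD_IN + max(c.onset_s + c.duration_s for c in self.components) + _TAIL
        if length > 2.0:
            raise InputError(f"{self.class_name}: rendered length {length:.2f} s exceeds 2 s")
        if self.class_name.startswith("normal split"):
            kinds = [c.kind for c in self.components]
            if len(self.components) != 2 or set(kinds) != {"damped_sinusoid"}:
                raise InputError(f"{self.class_name}: split tones need exactly two damped sinusoids")
            gap = abs(self.components[1].onset_s - self.components[0].onset_s)
            if not 0.03 <= gap <= 0.08:
                raise InputError(f"{self.class_name}: split gap {gap * 1e3:.0f} ms outside 30-80 ms")
        if "murmur" in self.class_name or "rumble" in self.class_name:
            if not any(c.kind == "bandpass_noise" for c in self.components):
                raise InputError(f"{self.class_name}: murmurs need a bandpass_noise component")


def _ds(f, bw, onset, dur, amp) -> ToneComponent:
    return ToneComponent(f, bw, onset, dur, amp, "damped_sinusoid")


def _bn(f, bw, onset, dur, amp) -> ToneComponent:
    return ToneComponent(f, bw, onset, dur, amp, "bandpass_noise")


def default_class_specs() -> dict[str, ToneClassSpec]:
    """Default recipes for all 12 classes.

    Frequencies follow auscultation teaching: S1/S2 are mid-low valvular
    tones (S2 higher-pitched), S3/S4 are very low gallop sounds, clicks and
    snaps are brief high-frequency transients, murmurs are broadband with the
    diastolic rumble confined below 150 Hz.  No two classes share the same set
    of component center frequencies.
    """
    table = {
        "S1": [_ds(61, 12, 0.0, 0.11, 1.0), _ds(119, 16, 0.0, 0.09, 0.7)],
        "S2": [
            _ds(76, 12, 0.0, 0.09, 1.0),
            _ds(186, 20, 0.0, 0.08, 0.7),
            _ds(280, 30, 0.0, 0.07, 0.5),
        ],
        "S3": [_ds(31, 9, 0.0, 0.12, 1.0)],
        "S4": [_ds(20, 8, 0.0, 0.14, 1.0)],
        "ejection click": [_ds(363, 60, 0.0, 0.04, 1.0), _ds(567, 90, 0.0, 0.035, 0.5)],
        "normal split S1": [_ds(47, 12, 0.0, 0.07, 1.0), _ds(51, 12, 0.055, 0.07, 0.9)],
        "normal split S2": [_ds(146, 16, 0.0, 0.06, 1.0), _ds(152, 16, 0.045, 0.06, 0.9)],
        "opening snap": [_ds(232, 50, 0.0, 0.05, 1.0), _ds(709, 110, 0.0, 0.04, 0.45)],
        "early systolic murmur": [_bn(245, 170, 0.0, 0.25, 1.0)],
        "late systolic murmur": [_bn(430, 260, 0.05, 0.25, 1.0)],
        "pansystolic murmur": [_bn(160, 140, 0.0, 0.45, 1.0), _bn(580, 200, 0.0, 0.45, 0.5)],
        "diastolic rumble": [_bn(85, 90, 0.0, 0.35, 1.0)],
    }
    specs = {
        name: ToneClassSpec(class_name=name, components=tuple(comps))
        for name, comps in table.items()
    }
    for spec in specs.values():
        spec.validate()
    return specs


def _render_damped_sinusoid(c: ToneComponent, t: np.ndarray) -> np.ndarray:
    """a * exp(-(t-t0)/tau) * sin(2*pi*f*(t-t0)) gated to the component window."""
    tau = 1.0 / (np.pi * c.bandwidth_hz)  # 3 dB resonance bandwidth -> decay time
    rel = t - (_LEAD_IN + c.onset_s)
    gate = (rel >= 0) & (rel < c.duration_s)
    out = np.zeros_like(t)
    r = rel[gate]
    out[gate] = c.amplitude * np.exp(-r / tau) * np.sin(2 * np.pi * c.center_hz * r)
    return out


def _render_bandpass_noise(
    c: ToneComponent, t: np.ndarray, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """White noise bandpass-filtered to the component band, Hann-enveloped."""
    lo = max(PCG_BAND[0], c.center_hz - c.bandwidth_hz / 2)
    hi = min(PCG_BAND[1], c.center_hz + c.bandwidth_hz / 2)
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    n = t.size
    noise = sosfiltfilt(sos, rng.standard_normal(n))
    rel = t - (_LEAD_IN + c.onset_s)
    env = np.zeros_like(t)
    gate = (rel >= 0) & (rel < c.duration_s)
    env[gate] = np.sin(np.pi * rel[gate] / c.duration_s) ** 2  # Hann bump
    out = noise * env
    peak = np.max(np.abs(out))
    return c.amplitude * out / peak if peak > 0 else out


def generate_tone(
    spec: ToneClassSpec, sample_rate: float = 4000.0, seed: int = 0
) -> PCGRecording:
    """Render one realization of a heart-sound class; deterministic per seed."""
    if sample_rate < 2000:
        raise InputError(f"sample_rate must be >= 2000 Hz, got {sample_rate}")
    spec.validate()
    rng = np.random.default_rng(seed)

    # jitter each component, then re-validate so jitter cannot leave the spec's domain
    jittered = []
    j = spec.jitter
    for c in spec.components:
        f = c.center_hz * (1 + rng.uniform(-j.frequency, j.frequency))
        d = c.duration_s * (1 + rng.uniform(-j.duration, j.duration))
        a = c.amplitude * (1 + rng.uniform(-j.amplitude, j.amplitude))
        f = np.clip(f, PCG_BAND[0] + c.bandwidth_hz / 2, PCG_BAND[1] - c.bandwidth_hz / 2)
        jittered.append(ToneComponent(float(f), c.bandwidth_hz, c.onset_s, float(d), float(a), c.kind))

    length = _LEAD_IN + max(c.onset_s + c.duration_s for c in jittered) + _TAIL
    n = int(round(length * sample_rate))
    t = np.arange(n) / sample_rate

    x = np.zeros(n)
    for c in jittered:
        if c.kind == "damped_sinusoid":
            x += _render_damped_sinusoid(c, t)
        else:
            x += _render_bandpass_noise(c, t, sample_rate, rng)

    if spec.snr_db is not None and np.any(x != 0):
        p_signal = float(np.mean(x**2))
        p_noise = p_signal / 10 ** (spec.snr_db / 10)
        x = x + rng.normal(0.0, np.sqrt(p_noise), n)

    peak = float(np.max(np.abs(x)))
    if peak > 0:
        x = x / peak
    sid = spec.class_name.replace(" ", "_")
    return PCGRecording(x, float(sample_rate), label=spec.class_name, source_id=f"{sid}-{seed}")


@dataclass
class LabeledDataset:
    """A stratified collection of labeled synthetic recordings."""

    samples: list[tuple[PCGRecording, str]]
    seed: int
    per_class_count: int

    def __len__(self) -> int:
        return len(self.samples)

    def write(self, out_dir: str | Path) -> Path:
        """Write WAV files plus a ``manifest.csv`` sidecar; returns the manifest path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = out_dir / "manifest.csv"
        with open(manifest, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["filename", "class_label", "seed"])
            for rec, label in self.samples:
                fname = f"{rec.source_id}.wav"
                save_recording(rec, out_dir / fname)
                writer.writerow([fname, label, self.seed])
        return manifest


def generate_dataset(
    per_class_count: int,
    sample_rate: float = 4000.0,
    seed: int = 42,
    specs: dict[str, ToneClassSpec] | None = None,
) -> LabeledDataset:
    """Generate ``per_class_count`` jittered realizations of every class.

    Ordering is stratified (realization 0 of every class, then realization 1,
    ...) and the whole dataset is a pure function of its arguments.
    """
    if per_class_count < 1:
        raise InputError("per_class_count must be >= 1")
    specs = specs or default_class_specs()
    samples: list[tuple[PCGRecording, str]] = []
    for rep in range(per_class_count):
        for ci, name in enumerate(CLASS_NAMES):
            if name not in specs:
                raise InputError(f"missing spec for class {name!r}")
            child = int(np.random.SeedSequence([seed, ci, rep]).generate_state(1)[0])
            rec = generate_tone(specs[name], sample_rate, seed=child)
            rec.source_id = f"{name.replace(' ', '_')}-{rep:02d}"
            samples.append((rec, name))
    return LabeledDataset(samples=samples, seed=seed, per_class_count=per_class_count)
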