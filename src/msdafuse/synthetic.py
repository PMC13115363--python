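"""Synthetic EEG, face-image and decision-probability generators.

The generators emulate the acquisition protocol of a standard multimodal
affect experiment: per subject, 40 one-minute video trials recorded at
128 Hz on 32 EEG channels (3 s preparation + 60 s task), with one face
frame every 0.5 s of the task span.

EEG background is 1/f (pink) noise, so band-pass filtering is
consequential; the class signal is a band-limited power increase on a
designated channel subset.  Face classes differ in spatial scale — one
compact bright blob versus two widely separated blobs — so that small and
large receptive fields are differentially informative.  Decision pairs
model two classifiers that are reliable on complementary subsets of
samples, the regime decision-level fusion is designed for.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .eeg_features import DEFAULT_BANDS, EEGTrial
from .io_formats import RecordingSet

__all__ = [
    "ProtocolSpec", "ClassSpec", "generate_eeg", "generate_faces",
    "generate_decisions", "DecisionPair",
]


@dataclasses.dataclass(frozen=True)
class ProtocolSpec:
    """Acquisition protocol constants."""

    n_subjects: int = 22
    n_trials: int = 40
    prep_seconds: float = 3.0
    task_seconds: float = 60.0
    frame_interval_seconds: float = 0.5
    fs: float = 128.0
    n_channels: int = 32
    image_size: int = 48

    def __post_init__(self):
        if self.task_seconds % self.frame_interval_seconds:
            raise ValueError("task span must divide evenly into frame intervals")

    @property
    def trial_samples(self) -> int:
        """Time points per trial per channel (e.g. 63 s x 128 Hz = 8064)."""
        return round(self.fs * (self.prep_seconds + self.task_seconds))

    @property
    def frames_per_trial(self) -> int:
        return round(self.task_seconds / self.frame_interval_seconds)

    @property
    def frames_per_subject(self) -> int:
        return self.n_trials * self.frames_per_trial

    @property
    def total_frames(self) -> int:
        return self.n_subjects * self.frames_per_subject


@dataclasses.dataclass(frozen=True)
class ClassSpec:
    """Class-conditional structure injected into the synthetic data."""

    eeg_band: str = "beta"
    eeg_channels: tuple[int, ...] = (2, 6, 20, 24)
    eeg_power_multiplier: float = 2.5  # class-1 amplitude factor in eeg_band
    eeg_osc_amplitude: float = 1.0    # baseline oscillation amplitude
    eeg_band_inset_hz: float = 2.0    # keep oscillation clear of band edges
    noise_sd: float = 1.0             # pink-noise scale (EEG) / 0-1 pixels (face)
    face_noise_sd: float = 0.08
    face_blob_sigma: float = 3.0
    face_separation: float = 24.0     # min centre distance of class-1 blobs

    def band(self):
        for b in DEFAULT_BANDS:
            if b.name == self.eeg_band:
                return b
        raise ValueError(f"unknown band {self.eeg_band!r}")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                fs: float) -> np.ndarray:
    """1/f-power noise along the last axis via spectral shaping."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=n, axis=-1)
    return pink / pink.std(axis=-1, keepdims=True)


def _band_limited_noise(rng: np.random.Generator, shape: tuple[int, ...],
                        low: float, high: float, fs: float) -> np.ndarray:
    """Unit-variance noise restricted to [low, high] Hz."""
    sos = sps.butter(8, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def generate_eeg(protocol: ProtocolSpec = ProtocolSpec(),
                 class_spec: ClassSpec = ClassSpec(),
                 seed: int = 0, subject_id: str = "s01") -> RecordingSet:
    """One subject's EEG trials with class-conditional band power.

    Background is pink noise on every channel.  All channels carry a weak
    oscillation in the designated band; on class-1 trials the designated
    channels' oscillation amplitude in the task span is multiplied by
    ``eeg_power_multiplier``.  The preparation span never carries the class
    effect, so baseline correction stays class-neutral.  Labels alternate
    (balanced); the trial order is shuffled deterministically.
    """
    rng = np.random.default_rng(seed)
    band = class_spec.band()
    # synthesise the oscillation strictly inside the nominal band so its
    # power does not straddle the edges shared with neighbouring bands
    osc_lo = band.low + class_spec.eeg_band_inset_hz
    osc_hi = band.high - class_spec.eeg_band_inset_hz
    labels = np.arange(protocol.n_trials) % 2
    rng.shuffle(labels)
    trials = []
    n_prep = round(protocol.fs * protocol.prep_seconds)
    for t in range(protocol.n_trials):
        shape = (protocol.n_channels, protocol.trial_samples)
        x = class_spec.noise_sd * _pink_noise(rng, shape, protocol.fs)
        osc = _band_limited_noise(rng, shape, osc_lo, osc_hi, protocol.fs)
        amp = np.full((protocol.n_channels, 1), class_spec.eeg_osc_amplitude)
        x += amp * osc
        if labels[t] == 1:
            extra = _band_limited_noise(
                rng, (len(class_spec.eeg_channels), protocol.trial_samples),
                osc_lo, osc_hi, protocol.fs)
            boost = class_spec.eeg_osc_amplitude * (class_spec.eeg_power_multiplier - 1.0)
            task_mask = np.zeros(protocol.trial_samples)
            task_mask[n_prep:] = 1.0
            x[list(class_spec.eeg_channels)] += boost * extra * task_mask
        trials.append(EEGTrial(samples=x, fs=protocol.fs,
                               prep_seconds=protocol.prep_seconds,
                               task_seconds=protocol.task_seconds,
                               trial_id=f"{subject_id}-t{t:02d}"))
    empty_frames = [np.zeros((0, protocol.image_size, protocol.image_size))
                    for _ in range(protocol.n_trials)]
    return RecordingSet(subject_id=subject_id, trials=trials,
                        face_frames=empty_frames, labels=labels)


def _render_blob(grid_y, grid_x, cy, cx, sigma, amplitude=1.0):
    return amplitude * np.exp(-((grid_y - cy) ** 2 + (grid_x - cx) ** 2)
                              / (2.0 * sigma ** 2))


def generate_faces(protocol: ProtocolSpec = ProtocolSpec(),
                   class_spec: ClassSpec = ClassSpec(),
                   seed: int = 0, labels: np.ndarray | None = None,
                   frames_per_trial: int | None = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Face frames for one subject: (images, frame_labels, trial_index).

    Class 0 renders one compact bright blob (a local-scale cue); class 1
    renders two dimmer blobs at least ``face_separation`` pixels apart (a
    long-range cue).  Pixel noise is added and values clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = np.arange(protocol.n_trials) % 2
        rng.shuffle(labels)
    labels = np.asarray(labels)
    fpt = frames_per_trial if frames_per_trial is not None else protocol.frames_per_trial
    size = protocol.image_size
    gy, gx = np.mgrid[0:size, 0:size].astype(float)
    sigma = class_spec.face_blob_sigma
    margin = 3.0 * sigma
    images = np.empty((len(labels) * fpt, size, size))
    frame_labels = np.empty(len(labels) * fpt, dtype=int)
    trial_index = np.empty(len(labels) * fpt, dtype=int)
    i = 0
    for t, lab in enumerate(labels):
        for _ in range(fpt):
            img = np.zeros((size, size))
            if lab == 0:
                cy, cx = rng.uniform(margin, size - margin, size=2)
                img += _render_blob(gy, gx, cy, cx, sigma, 1.0)
            else:
                while True:
                    cy1, cx1 = rng.uniform(margin, size - margin, size=2)
                    cy2, cx2 = rng.uniform(margin, size - margin, size=2)
                    if np.hypot(cy1 - cy2, cx1 - cx2) >= class_spec.face_separation:
                        break
                img += _render_blob(gy, gx, cy1, cx1, sigma, 0.55)
                img += _render_blob(gy, gx, cy2, cx2, sigma, 0.55)
            img += rng.normal(0.0, class_spec.face_noise_sd, (size, size))
            images[i] = np.clip(img, 0.0, 1.0)
            frame_labels[i] = lab
            trial_index[i] = t
            i += 1
    return images, frame_labels, trial_index


@dataclasses.dataclass
class SyntheticDecisionMeta:
    """Bookkeeping for generated decision pairs."""

    reliable_is_eeg: np.ndarray  # bool per sample
    reliable_accuracy: float
    weak_accuracy: float


def _decision_rows(rng, n_classes, true_label, correct, confident):
    lo, hi = (0.85, 0.99) if confident else (0.52, 0.70)
    top = rng.uniform(lo, hi)
    target = true_label if correct else int(
        rng.choice([c for c in range(n_classes) if c != true_label]))
    row = np.full(n_classes, (1.0 - top) / (n_classes - 1))
    row[target] = top
    return row


def generate_decisions(n: int, complementarity: float = 0.5, seed: int = 0,
                       accuracy: float = 0.85, n_classes: int = 2,
                       reliable_accuracy: float = 0.98):
    """Synthetic per-sample class-probability pairs for fusion experiments.

    Modality E (EEG) is *reliable* on a fraction ``complementarity`` of
    samples and modality F (face) on the complement.  A reliable modality
    emits a confident row that is correct with probability
    ``reliable_accuracy``; the other modality emits a low-confidence row
    whose accuracy is set so each modality's marginal accuracy equals
    ``accuracy``.  A modality that is reliable on a zero fraction emits
    uniform rows (uninformative).  Returns (DecisionPair, labels, meta).

    An oracle that trusts the reliable modality on every sample attains
    ``reliable_accuracy``, strictly above either marginal — the
    complementary regime in which learned fusion should beat both branches.
    """
    if not 0.0 <= complementarity <= 1.0:
        raise ValueError("complementarity must lie in [0,1]")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_classes, size=n)
    n_eeg = round(complementarity * n)
    reliable_is_eeg = np.zeros(n, dtype=bool)
    reliable_is_eeg[:n_eeg] = True
    rng.shuffle(reliable_is_eeg)

    def weak_acc(frac_reliable):
        if frac_reliable >= 1.0:
            return 0.5
        p = (accuracy - frac_reliable * reliable_accuracy) / (1.0 - frac_reliable)
        return float(np.clip(p, 1.0 / n_classes, 1.0))

    weak_e = weak_acc(complementarity)
    weak_f = weak_acc(1.0 - complementarity)
    p_eeg = np.empty((n, n_classes))
    p_face = np.empty((n, n_classes))
    for i in range(n):
        for arr, is_reliable, frac in (
                (p_eeg, reliable_is_eeg[i], complementarity),
                (p_face, not reliable_is_eeg[i], 1.0 - complementarity)):
            if is_reliable:
                correct = rng.random() < reliable_accuracy
                arr[i] = _decision_rows(rng, n_classes, labels[i], correct, True)
            elif frac == 0.0:
                arr[i] = np.full(n_classes, 1.0 / n_classes)
            else:
                weak = weak_e if arr is p_eeg else weak_f
                correct = rng.random() < weak
                arr[i] = _decision_rows(rng, n_classes, labels[i], correct, False)
    from .fusion import DecisionPair  # local import avoids a cycle
    pair = DecisionPair(p_eeg=p_eeg, p_face=p_face, labels=labels)
    meta = SyntheticDecisionMeta(reliable_is_eeg=reliable_is_eeg,
                                 reliable_accuracy=reliable_accuracy,
                                 weak_accuracy=(weak_e + weak_f) / 2.0)
    return pair, labels, meta
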