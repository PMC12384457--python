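"""Synthetic motor-imagery EEG with class-dependent ERD structure.

The generator emulates the statistical structure a motor-imagery decoder
exploits, without claiming biophysical realism: every electrode carries a
sensorimotor rhythm (default 11 Hz, the mu band) on top of a 1/f noise
floor, and each class attenuates the rhythm on its ERD electrodes —
event-related desynchronisation, lateralised contralateral to the imagined
movement (left hand -> C4, right hand -> C3, feet -> Cz, tongue -> broad
bilateral).  Volume conduction is emulated by mixing one shared pink-noise
source into all electrodes with distance-decaying weights; subjects differ
by a random global gain and noise scale.

``snr_db`` is the band-limited SNR of the *unattenuated* rhythm against the
noise power inside 8-13 Hz, so attenuation directly scales class
separability.  A fixed seed makes the output byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import welch

from .io import TrialSet
from .montage import ElectrodeMontage, load_builtin_montage

__all__ = [
    "SynthConfig",
    "default_erd_map",
    "generate_trials",
    "bandpower_oracle_classify",
    "band_power",
]

MU_BAND = (8.0, 13.0)

_CLASS_NAMES = {
    2: ("left_hand", "right_hand"),
    4: ("left_hand", "right_hand", "feet", "tongue"),
}


def default_erd_map(
    n_classes: int, attenuation: float = 0.75, band_center: float = 11.0
) -> dict[int, list[tuple[str, float, float]]]:
    """Physiologically laid-out ERD map for the 2- and 4-class paradigms."""
    if n_classes == 2:
        return {
            0: [("C4", band_center, attenuation)],  # left hand -> contralateral C4
            1: [("C3", band_center, attenuation)],
        }
    if n_classes == 4:
        return {
            0: [("C4", band_center, attenuation), ("C6", band_center, attenuation / 2)],
            1: [("C3", band_center, attenuation), ("C5", band_center, attenuation / 2)],
            2: [("Cz", band_center, attenuation), ("CPz", band_center, attenuation / 2)],
            3: [  # tongue: broad bilateral attenuation
                ("C3", band_center, attenuation / 2),
                ("C4", band_center, attenuation / 2),
                ("FC3", band_center, attenuation / 2),
                ("FC4", band_center, attenuation / 2),
            ],
        }
    raise ValueError(f"no default ERD map for {n_classes} classes")


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    Defaults mirror the 4-class, 22-channel paradigm: 250 Hz, 4.5 s epochs,
    72 trials per class per subject.
    """

    n_subjects: int = 1
    trials_per_class: int = 72
    n_classes: int = 4
    montage: ElectrodeMontage | None = None
    fs: float = 250.0
    epoch_s: float = 4.5
    erd_map: dict[int, list[tuple[str, float, float]]] | None = None
    noise_exponent: float = 1.0  # 1/f^beta slope (pink)
    snr_db: float = 0.0
    subject_gain_sd: float = 0.1  # log-sd of per-subject gain / noise scale
    am_depth: float = 0.2  # slow amplitude modulation of the rhythm
    n_sessions: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.montage is None:
            self.montage = load_builtin_montage("2a" if self.n_classes == 4 else "2b")
        if self.erd_map is None:
            self.erd_map = default_erd_map(self.n_classes)
        if self.n_classes not in _CLASS_NAMES:
            raise ValueError("n_classes must be 2 or 4")
        n_samp = self.fs * self.epoch_s
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("fs * epoch_s must be an integer sample count")
        names = set(self.montage.names)
        for cls, entries in self.erd_map.items():
            if not 0 <= cls < self.n_classes:
                raise ValueError(f"ERD map class {cls} outside [0, {self.n_classes})")
            for electrode, _band, att in entries:
                if electrode not in names:
                    raise ValueError(
                        f"ERD map references electrode {electrode!r} absent "
                        "from the montage"
                    )
                if not 0.0 <= att <= 1.0:
                    raise ValueError(f"attenuation must be in [0, 1], got {att}")
        if self.n_sessions is None:
            self.n_sessions = 2 if self.n_classes == 4 else 5

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_s))

    @property
    def class_names(self) -> tuple[str, ...]:
        return _CLASS_NAMES[self.n_classes]


def _pink_shape(n_samples: int, fs: float, beta: float) -> np.ndarray:
    """Per-rfft-bin amplitude shaping for 1/f^beta noise (DC removed)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)
    return shape


def _noise_band_fraction(n_samples: int, fs: float, beta: float) -> float:
    """Fraction of 1/f^beta noise variance inside the mu band (8-13 Hz)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    power = _pink_shape(n_samples, fs, beta) ** 2
    in_band = (freqs >= MU_BAND[0]) & (freqs <= MU_BAND[1])
    return float(power[in_band].sum() / power.sum())


def _pink_noise(rng: np.random.Generator, shape_coeffs: np.ndarray, n_samples: int,
                size: tuple[int, ...]) -> np.ndarray:
    """Unit-variance 1/f-shaped Gaussian noise, arbitrary leading dims."""
    n_bins = len(shape_coeffs)
    spec = (
        rng.standard_normal(size + (n_bins,))
        + 1j * rng.standard_normal(size + (n_bins,))
    ) * shape_coeffs
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    std = x.std(axis=-1, keepdims=True)
    return x / np.where(std == 0, 1.0, std)


def generate_trials(cfg: SynthConfig) -> TrialSet:
    """Draw a full labelled TrialSet under the configured study conditions."""
    rng = np.random.default_rng(cfg.seed)
    C = cfg.montage.n_channels
    T = cfg.n_samples
    t = np.arange(T) / cfg.fs
    shape_coeffs = _pink_shape(T, cfg.fs, cfg.noise_exponent)
    band_frac = _noise_band_fraction(T, cfg.fs, cfg.noise_exponent)
    # unattenuated rhythm amplitude fixing the band-limited SNR
    snr_lin = 10.0 ** (cfg.snr_db / 10.0)
    amp = np.sqrt(2.0 * snr_lin * band_frac)
    # distance-based mixing of the shared (volume-conducted) noise source
    dist = np.linalg.norm(cfg.montage.positions, axis=1)
    mix = np.exp(-dist / 2.0)
    norm = np.sqrt(1.0 + mix**2)  # unit channel variance after mixing

    # per-class rhythm amplitude per electrode
    class_amp = np.full((cfg.n_classes, C), amp)
    band_center = np.full(C, 11.0)
    for cls, entries in cfg.erd_map.items():
        for electrode, band, att in entries:
            ci = cfg.montage.index(electrode)
            class_amp[cls, ci] = amp * (1.0 - att)
            band_center[ci] = band

    n_per_subject = cfg.trials_per_class * cfg.n_classes
    data = np.empty((cfg.n_subjects * n_per_subject, C, T))
    labels = np.empty(cfg.n_subjects * n_per_subject, dtype=np.int64)
    subjects = np.empty_like(labels)
    sessions = np.empty_like(labels)

    row = 0
    for s in range(cfg.n_subjects):
        gain = np.exp(rng.normal(0.0, cfg.subject_gain_sd))
        noise_scale = np.exp(rng.normal(0.0, cfg.subject_gain_sd))
        lab = np.repeat(np.arange(cfg.n_classes), cfg.trials_per_class)
        rng.shuffle(lab)
        for k, cls in enumerate(lab):
            indep = _pink_noise(rng, shape_coeffs, T, (C,))
            shared = _pink_noise(rng, shape_coeffs, T, ())
            noise = (indep + mix[:, None] * shared[None, :]) / norm[:, None]
            phase = rng.uniform(0.0, 2 * np.pi, size=C)
            f_jitter = rng.uniform(-0.2, 0.2, size=C)
            env = 1.0 + cfg.am_depth * np.sin(
                2 * np.pi * rng.uniform(0.3, 1.0) * t + rng.uniform(0, 2 * np.pi)
            )
            rhythm = (
                class_amp[cls][:, None]
                * env[None, :]
                * np.sin(2 * np.pi * (band_center + f_jitter)[:, None] * t[None, :]
                         + phase[:, None])
            )
            data[row] = gain * (noise_scale * noise + rhythm)
            labels[row] = cls
            subjects[row] = s
            sessions[row] = (k % cfg.n_sessions) + 1
            row += 1
    return TrialSet(
        data=data, labels=labels, fs=cfg.fs,
        subjects=subjects, sessions=sessions, class_names=cfg.class_names,
    )


def band_power(x: np.ndarray, fs: float, f_lo: float, f_hi: float) -> np.ndarray:
    """Welch band power over the last axis; leading axes preserved."""
    freqs, psd = welch(x, fs=fs, nperseg=min(256, x.shape[-1]), axis=-1)
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    return np.trapezoid(psd[..., sel], freqs[sel], axis=-1)


def bandpower_oracle_classify(
    trials: TrialSet,
    erd_map: dict[int, list[tuple[str, float, float]]],
    montage: ElectrodeMontage | None = None,
    band_halfwidth: float = 2.5,
) -> np.ndarray:
    """Nearest-centroid prediction on log band power at the ERD electrodes.

    A deliberately simple decoder that knows the generating ERD layout; it
    serves as an independent ceiling/floor reference for the deep model.
    Predictions are 2-fold cross-predictions (centroids fitted on the
    opposite fold), so a null configuration scores at chance.
    """
    if montage is None:
        montage = load_builtin_montage("2a" if trials.n_channels == 22 else "2b")
    feats_spec = sorted(
        {(electrode, band) for entries in erd_map.values()
         for electrode, band, _att in entries}
    )
    feats = np.stack(
        [
            np.log(band_power(
                trials.data[:, montage.index(e), :], trials.fs,
                band - band_halfwidth, band + band_halfwidth,
            ))
            for e, band in feats_spec
        ],
        axis=1,
    )  # (n_trials, n_features)
    n = trials.n_trials
    fold = np.arange(n) % 2
    pred = np.empty(n, dtype=np.int64)
    classes = np.unique(trials.labels)
    for f in (0, 1):
        fit_mask = fold != f
        centroids = np.stack(
            [feats[fit_mask & (trials.labels == c)].mean(axis=0) for c in classes]
        )
        d = ((feats[fold == f, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        pred[fold == f] = classes[np.argmin(d, axis=1)]
    return pred
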