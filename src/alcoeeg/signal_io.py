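"""Recording containers, matrix stacking, segmentation, and synthetic EEG.

A recording holds a ``(channel, sample, trial)`` voltage block.  For feature
extraction the channels are stacked channel-major into a single
``(n_channels * n_samples) x n_trials`` matrix — e.g. 61 channels of 256
samples over 30 one-second trials stack to 15,616 x 30 — which is then cut
into equal, non-overlapping row segments.

The synthetic generator emulates the two-class (control vs. alcoholic)
structure of multichannel EEG: latent second-order autoregressive sources
with an oscillatory pole, mixed into channels by a class-specific linear
mixing matrix, plus white sensor noise.  The classes differ in their
inter-channel covariance (and mildly in spectral content) by a configurable
effect size.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EEGRecording",
    "StackedMatrix",
    "SegmentSet",
    "SyntheticConfig",
    "read_recording",
    "write_recording",
    "stack_channels",
    "segment_signal",
    "generate_synthetic_dataset",
]

logger = logging.getLogger(__name__)

LABELS = ("control", "alcoholic")


class RecordingParseError(ValueError):
    """Raised when a recording file violates its dialect."""


@dataclass
class EEGRecording:
    """Labelled multichannel signal block.

    ``data`` has axes ``(channel, sample, trial)``; voltages are on an
    arbitrary µV-like scale.
    """

    subject_id: str
    label: str
    data: np.ndarray
    sample_rate: float = 256.0
    channel_names: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be (channel, sample, trial); got shape {self.data.shape}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match channel axis")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def select_channels(self, channels: Sequence[int]) -> "EEGRecording":
        """Restrict to the given channel indices (order preserved)."""
        idx = list(channels)
        return replace(
            self,
            data=self.data[idx],
            channel_names=[self.channel_names[i] for i in idx],
        )


@dataclass
class StackedMatrix:
    """Channel-major stack: rows ordered (channel 0 samples..., channel 1 ...)."""

    values: np.ndarray  # (n_channels * n_samples) x n_trials
    row_origin: np.ndarray  # rows x 2 of (channel, sample)

    def __post_init__(self) -> None:
        if self.values.shape[0] != self.row_origin.shape[0]:
            raise ValueError("row_origin must map every row")


@dataclass
class SegmentSet:
    segments: list  # equal-shaped 2-D arrays
    n_segments: int
    rows_per_segment: int


@dataclass
class SyntheticConfig:
    """Conditions for the two-class synthetic EEG generator."""

    n_recordings_per_class: int = 10
    n_channels: int = 8
    n_samples: int = 256
    n_trials: int = 30
    class_separation: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0
    sample_rate: float = 256.0
    #: class_labels[0] receives the base mixing, class_labels[1] the perturbed
    #: one; swapping them swaps the class-conditional statistics.
    class_labels: tuple = ("control", "alcoholic")
    #: if given, the class-specific mixing perturbation touches only these
    #: channels (others carry no class signal).
    signal_channels: Sequence[int] | None = None

    def __post_init__(self) -> None:
        for name in ("n_recordings_per_class", "n_channels", "n_samples", "n_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if sorted(self.class_labels) != sorted(LABELS):
            raise ValueError(f"class_labels must be a permutation of {LABELS}")


# ---------------------------------------------------------------------------
# stacking and segmentation


def stack_channels(rec: EEGRecording) -> StackedMatrix:
    """Stack channels channel-major into a (C*S) x T matrix.

    Row ``c * n_samples + s`` holds channel ``c`` at sample ``s`` across
    trials; 61 x 256 x 30 stacks to 15,616 x 30.
    """
    c, s, t = rec.data.shape
    values = rec.data.reshape(c * s, t)
    origin = np.empty((c * s, 2), dtype=int)
    origin[:, 0] = np.repeat(np.arange(c), s)
    origin[:, 1] = np.tile(np.arange(s), c)
    return StackedMatrix(values=values, row_origin=origin)


def segment_signal(m: StackedMatrix, n_segments: int) -> SegmentSet:
    """Cut the stacked matrix into equal, consecutive, non-overlapping row chunks.

    Trailing rows that do not fill a chunk are dropped (with a warning).
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    total = m.values.shape[0]
    if n_segments > total:
        raise ValueError(f"n_segments={n_segments} exceeds row count {total}")
    rows = total // n_segments
    dropped = total - rows * n_segments
    if dropped:
        logger.warning("segment_signal: dropping %d trailing rows", dropped)
    segments = [m.values[i * rows : (i + 1) * rows] for i in range(n_segments)]
    return SegmentSet(segments=segments, n_segments=n_segments, rows_per_segment=rows)


# ---------------------------------------------------------------------------
# file I/O

_FORMATS = ("matrix-csv", "uci-kdd-text")


def _manifest_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_recording(rec: EEGRecording, path, format: str = "matrix-csv", force: bool = False) -> Path:
    """Write a recording; ``matrix-csv`` is the only writable dialect.

    One CSV row per (channel, sample) pair with the trial values, plus a JSON
    sidecar manifest carrying subject, label, rate and channel names.
    Refuses to overwrite unless ``force``.
    """
    if format != "matrix-csv":
        raise ValueError(f"unwritable format {format!r}")
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    c, s, t = rec.data.shape
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["channel", "sample"] + [f"trial_{j}" for j in range(t)])
        for ci in range(c):
            for si in range(s):
                writer.writerow(
                    [rec.channel_names[ci], si] + [repr(float(v)) for v in rec.data[ci, si]]
                )
    manifest = {
        "subject_id": rec.subject_id,
        "label": rec.label,
        "sample_rate": rec.sample_rate,
        "channel_names": list(rec.channel_names),
    }
    _manifest_path(path).write_text(json.dumps(manifest, indent=1))
    return path


def read_recording(path, format: str = "matrix-csv", error_budget: int = 0) -> EEGRecording:
    """Read a recording in either supported text dialect."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format tag {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "matrix-csv":
        return _read_matrix_csv(path)
    return _read_uci_kdd(path, error_budget=error_budget)


def _read_matrix_csv(path: Path) -> EEGRecording:
    channels: dict[str, dict[int, np.ndarray]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RecordingParseError(f"{path}:1: empty file") from None
        if header[:2] != ["channel", "sample"]:
            raise RecordingParseError(f"{path}:1: expected 'channel,sample,trial_0,...' header")
        n_trials = len(header) - 2
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != n_trials + 2:
                raise RecordingParseError(
                    f"{path}:{lineno}: expected {n_trials + 2} fields, got {len(row)}"
                )
            name, sample = row[0], row[1]
            try:
                si = int(sample)
                vals = np.array([float(v) for v in row[2:]])
            except ValueError as exc:
                raise RecordingParseError(f"{path}:{lineno}: {exc}") from None
            channels.setdefault(name, {})[si] = vals
    if not channels:
        raise RecordingParseError(f"{path}: no data rows")
    lengths = {len(d) for d in channels.values()}
    if len(lengths) != 1:
        raise RecordingParseError(
            f"{path}: inconsistent samples per channel: {sorted(lengths)}"
        )
    n_samples = lengths.pop()
    names = list(channels)
    data = np.empty((len(names), n_samples, n_trials))
    for ci, name in enumerate(names):
        per = channels[name]
        if sorted(per) != list(range(n_samples)):
            raise RecordingParseError(f"{path}: channel {name!r} has gapped sample indices")
        for si in range(n_samples):
            data[ci, si] = per[si]
    mpath = _manifest_path(path)
    meta = json.loads(mpath.read_text()) if mpath.exists() else {}
    return EEGRecording(
        subject_id=meta.get("subject_id", path.stem),
        label=meta.get("label", "control"),
        data=data,
        sample_rate=meta.get("sample_rate", 256.0),
        channel_names=meta.get("channel_names", names),
    )


def _read_uci_kdd(path: Path, error_budget: int = 0) -> EEGRecording:
    """Whitespace dialect: ``trial_index channel_name sample_index value``.

    ``#`` lines are comments.  Malformed lines are logged and skipped until
    the error budget is spent, after which parsing fails.
    """
    cells: dict[tuple[int, str, int], float] = {}
    channel_order: list[str] = []
    errors = 0
    label = "control"
    subject = path.stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                # the UCI headers name the subject (co2a... = alcoholic, co2c... = control)
                low = line.lower()
                if "co2a" in low or "alcoholic" in low:
                    label = "alcoholic"
                elif "co2c" in low:
                    label = "control"
                continue
            parts = line.split()
            try:
                if len(parts) != 4:
                    raise ValueError(f"expected 4 fields, got {len(parts)}")
                trial = int(parts[0])
                name = parts[1]
                sample = int(parts[2])
                value = float(parts[3])
            except ValueError as exc:
                errors += 1
                logger.warning("%s:%d: %s", path, lineno, exc)
                if errors > error_budget:
                    raise RecordingParseError(f"{path}:{lineno}: {exc}") from None
                continue
            if name not in channel_order:
                channel_order.append(name)
            cells[(trial, name, sample)] = value
    if not cells:
        raise RecordingParseError(f"{path}: no data lines")
    trials = sorted({k[0] for k in cells})
    samples = sorted({k[2] for k in cells})
    data = np.full((len(channel_order), len(samples), len(trials)), np.nan)
    smap = {s: i for i, s in enumerate(samples)}
    tmap = {t: i for i, t in enumerate(trials)}
    for (t, name, s), v in cells.items():
        data[channel_order.index(name), smap[s], tmap[t]] = v
    if np.isnan(data).any():
        raise RecordingParseError(f"{path}: missing (trial, channel, sample) cells")
    return EEGRecording(
        subject_id=subject, label=label, data=data, channel_names=channel_order
    )


# ---------------------------------------------------------------------------
# synthetic generator


def _ar2_coefficients(pole_radius: float, pole_freq: float) -> tuple[float, float]:
    """AR(2) with a complex pole pair r·e^{±iθ}: x_t = φ1 x_{t-1} + φ2 x_{t-2} + e_t."""
    phi1 = 2.0 * pole_radius * np.cos(pole_freq)
    phi2 = -pole_radius**2
    return phi1, phi2


def _class_mixing(cfg: SyntheticConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Mixing matrices for (class 0, class 1); identical when separation is 0.

    The class effect combines a systematic amplitude gain (altered band
    power/synchronization) with a random structural rotation of the mixing,
    both scaled by ``class_separation``.
    """
    n = cfg.n_channels
    sep = cfg.class_separation
    base = rng.normal(size=(n, n)) / np.sqrt(n)
    delta = rng.normal(size=(n, n)) * (0.2 / np.sqrt(n))
    gain = 1.0 + 0.15 * sep
    other = gain * (base + sep * delta)
    if cfg.signal_channels is not None:
        mask = np.zeros(n, dtype=bool)
        mask[list(cfg.signal_channels)] = True
        other[~mask, :] = base[~mask, :]
    return [base, other]


def _simulate_trial(
    mixing: np.ndarray,
    phi: tuple[float, float],
    n_samples: int,
    noise_sd: float,
    rng: np.random.Generator,
    burn_in: int = 100,
) -> np.ndarray:
    n_src = mixing.shape[1]
    total = n_samples + burn_in
    innov = rng.normal(size=(n_src, total))
    src = np.zeros((n_src, total))
    p1, p2 = phi
    for t in range(2, total):
        src[:, t] = p1 * src[:, t - 1] + p2 * src[:, t - 2] + innov[:, t]
    src = src[:, burn_in:]
    sensor = mixing @ src + noise_sd * rng.normal(size=(mixing.shape[0], n_samples))
    return sensor  # (channel, sample)


def generate_synthetic_dataset(cfg: SyntheticConfig) -> list[EEGRecording]:
    """Draw ``2 * n_recordings_per_class`` labelled recordings.

    Class 1 (``cfg.class_labels[1]``) uses a mixing matrix perturbed away from
    the shared base by ``class_separation``, and an oscillatory pole nudged
    slightly in frequency; with separation 0 the two classes are generated
    from identical parameters.  Deterministic given ``cfg.seed``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    struct_ss, data_ss = ss.spawn(2)
    mixings = _class_mixing(cfg, np.random.default_rng(struct_ss))

    base_theta = 2.0 * np.pi * 10.0 / cfg.sample_rate  # ~10 Hz alpha-band pole
    recordings: list[EEGRecording] = []
    rec_seeds = data_ss.spawn(2 * cfg.n_recordings_per_class)
    i = 0
    for class_idx, label in enumerate(cfg.class_labels):
        theta = base_theta * (1.0 + 0.02 * cfg.class_separation * class_idx)
        phi = _ar2_coefficients(0.92, theta)
        for r in range(cfg.n_recordings_per_class):
            rng = np.random.default_rng(rec_seeds[i])
            i += 1
            trials = np.stack(
                [
                    _simulate_trial(mixings[class_idx], phi, cfg.n_samples, cfg.noise_sd, rng)
                    for _ in range(cfg.n_trials)
                ],
                axis=2,
            )  # (channel, sample, trial)
            recordings.append(
                EEGRecording(
                    subject_id=f"{label}_{r:03d}",
                    label=label,
                    data=trials,
                    sample_rate=cfg.sample_rate,
                )
            )
    return recordings
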