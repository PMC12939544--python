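"""Reading recordings and assembling the balanced labeled cohort.

The preprocessing chain mirrors a standard affective-EEG pipeline:
band-pass 4-45 Hz, downsample to 128 Hz, screen trials for strongly
negative ratings (valence < 2.5 and arousal < 5), crop the steady-state
window 15-60 s after stimulus onset, select the 8 frontal/central analysis
channels, cut non-overlapping 7.5 s epochs, and down-sample the majority
class to a strict 1:1 ratio.

Artifact removal (ICA etc.) is out of scope: inputs are assumed pre-cleaned.
"""

from __future__ import annotations

import pickle
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt

from .containers import CohortSample, Epoch, RatedTrial
from .montage import CANONICAL_CHANNELS, DEAP_CHANNELS, FS


class ChannelError(ValueError):
    """A requested channel is absent from the input montage."""


class FormatError(ValueError):
    """Input file does not match the documented layout."""


class CohortError(ValueError):
    """Cohort-level precondition violated (e.g. a class is absent)."""


# ---------------------------------------------------------------------------
# Readers

def read_edf(path: str | Path, channels: list[str] | None = None):
    """Read a continuous EDF recording.

    Returns ``(data, fs, channel_names)`` with data in microvolts
    (channels x samples). If ``channels`` is given, missing ones raise
    :class:`ChannelError` naming the absentees.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on malformed headers
        raise FormatError(f"cannot parse {path} as EDF: {exc}") from exc
    names = list(raw.ch_names)
    if channels is not None:
        lower = {n.lower(): n for n in names}
        missing = [c for c in channels if c.lower() not in lower]
        if missing:
            raise ChannelError(f"channels missing from {path.name}: {', '.join(missing)}")
    data = raw.get_data(units="uV")
    return np.asarray(data, dtype=float), float(raw.info["sfreq"]), names


def read_deap_archive(path: str | Path) -> list[RatedTrial]:
    """Read one subject's preprocessed trial archive.

    Layout (the documented preprocessed-DEAP convention): a Python pickle or
    ``.npz`` containing ``data`` with shape (40 trials, >=32 channels,
    8064 samples) at 128 Hz and ``labels`` with shape (40, >=2) holding
    valence and arousal (SAM scale 1-9) in the first two columns. The first
    32 channels follow the DEAP (Geneva) electrode order.
    """
    path = Path(path)
    if path.suffix == ".npz":
        archive = np.load(path)
        payload = {"data": archive["data"], "labels": archive["labels"]}
    else:
        with open(path, "rb") as fh:
            payload = pickle.load(fh, encoding="latin1")
    data = np.asarray(payload["data"], dtype=float)
    labels = np.asarray(payload["labels"], dtype=float)
    if data.ndim != 3 or data.shape[0] != 40 or data.shape[1] < 32 or data.shape[2] != 8064:
        raise FormatError(
            f"expected data of shape 40 x (>=32) x 8064, got {data.shape}"
        )
    if labels.shape[0] != 40 or labels.shape[1] < 2:
        raise FormatError(f"expected 40 x (>=2) ratings, got {labels.shape}")
    names = list(DEAP_CHANNELS) + [
        f"periph{i}" for i in range(32, data.shape[1])
    ]
    trials = []
    for i in range(40):
        trials.append(
            RatedTrial(
                signal=data[i],
                valence=float(labels[i, 0]),
                arousal=float(labels[i, 1]),
                fs=FS,
                channel_names=tuple(names),
            )
        )
    return trials


# ---------------------------------------------------------------------------
# Signal conditioning

def bandpass(
    signal: np.ndarray, fs: float, lo: float = 4.0, hi: float = 45.0,
    order: int = 5,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Order 5 (forward-backward) keeps stop-band attenuation above 20 dB at
    1 Hz and 55 Hz while staying flat in the 4-45 Hz pass-band.
    """
    if fs <= 2 * hi:
        raise ValueError(f"fs={fs} must exceed twice the upper edge {hi}")
    sos = butter(order, [lo, hi], btype="band", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=-1)


def resample(signal: np.ndarray, fs_in: float, fs_out: float = FS) -> np.ndarray:
    """Polyphase anti-aliased downsampling along the last axis.

    Upsampling is refused; ``fs_in == fs_out`` is the identity.
    """
    if fs_in < fs_out:
        raise ValueError(f"upsampling refused: fs_in={fs_in} < fs_out={fs_out}")
    if fs_in == fs_out:
        return np.asarray(signal, dtype=float)
    frac = Fraction(int(round(fs_out * 1000)), int(round(fs_in * 1000)))
    return resample_poly(np.asarray(signal, dtype=float), frac.numerator, frac.denominator, axis=-1)


# ---------------------------------------------------------------------------
# Trial screening and epoching

def screen_trial(trial: RatedTrial, valence_max: float = 2.5, arousal_max: float = 5.0) -> bool:
    """True iff the trial is a strongly negative one: valence < 2.5 AND
    arousal < 5 (both strict)."""
    return trial.valence < valence_max and trial.arousal < arousal_max


def crop_steady_state(
    trial: RatedTrial,
    start_s: float = 15.0,
    end_s: float = 60.0,
    baseline_s: float | None = None,
) -> np.ndarray:
    """Return the steady-state window [start_s, end_s) measured from stimulus
    onset.

    ``baseline_s`` is the pre-trial baseline preceding stimulus onset; if
    None it is inferred as ``duration - 60`` (63 s preprocessed-DEAP trials
    carry a 3 s baseline, a bare 60 s trial none).
    """
    if end_s <= start_s:
        raise ValueError("empty steady-state window (end_s <= start_s)")
    dur = trial.duration_s
    if baseline_s is None:
        baseline_s = max(0.0, dur - 60.0)
    if dur + 1e-9 < baseline_s + end_s:
        raise ValueError(
            f"trial of {dur:.2f}s too short for window [{start_s}, {end_s})s "
            f"after a {baseline_s:.2f}s baseline"
        )
    i0 = int(round((baseline_s + start_s) * trial.fs))
    i1 = int(round((baseline_s + end_s) * trial.fs))
    return trial.signal[:, i0:i1]


def segment(
    signal: np.ndarray,
    fs: float = FS,
    win_s: float = 7.5,
    overlap: float = 0.0,
    channel_names: tuple[str, ...] | None = None,
) -> list[Epoch]:
    """Cut a (channels x samples) signal into consecutive ``win_s`` epochs.

    Non-overlapping by default; the trailing remainder shorter than one
    window is discarded. A signal shorter than one window yields an empty
    list.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    win = int(round(win_s * fs))
    step = max(1, int(round(win * (1.0 - overlap))))
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(signal.shape[0]))
    out = []
    for start in range(0, signal.shape[1] - win + 1, step):
        out.append(Epoch(data=signal[:, start : start + win].copy(), fs=fs,
                         channel_names=channel_names))
    return out


def select_channels(
    epoch_like,
    names: tuple[str, ...] = CANONICAL_CHANNELS,
) -> Epoch:
    """Reorder an epoch's rows to ``names`` (canonical order by default).

    Accepts an :class:`Epoch` or a ``(data, channel_names)`` pair; channel
    matching is case-insensitive. A missing channel raises
    :class:`ChannelError` naming it.
    """
    if isinstance(epoch_like, Epoch):
        data, have, fs = epoch_like.data, epoch_like.channel_names, epoch_like.fs
    else:
        data, have = epoch_like
        fs = FS
    index = {n.lower(): i for i, n in enumerate(have)}
    rows = []
    for name in names:
        if name.lower() not in index:
            raise ChannelError(f"channel {name!r} missing from input montage")
        rows.append(index[name.lower()])
    return Epoch(data=np.asarray(data, dtype=float)[rows], fs=fs, channel_names=tuple(names))


def balance_cohort(samples: list[CohortSample], seed: int = 0) -> list[CohortSample]:
    """Down-sample the majority class (without replacement) to the minority
    size; deterministic under ``seed``; original relative order is kept."""
    labels = np.array([s.label for s in samples])
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise CohortError("both classes must be present to balance")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(labels == cls)
        if cnt > n_min:
            idx = np.sort(rng.choice(idx, size=n_min, replace=False))
        keep.extend(idx.tolist())
    keep.sort()
    return [samples[i] for i in keep]


# ---------------------------------------------------------------------------
# End-to-end assembly from rated trials

def epochs_from_rated_trials(
    trials: list[RatedTrial],
    label: int,
    source: str,
    valence_max: float = 2.5,
    arousal_max: float = 5.0,
    start_s: float = 15.0,
    end_s: float = 60.0,
) -> tuple[list[CohortSample], dict]:
    """Screen, crop, channel-select and segment rated trials into labeled
    standardized epochs.

    Returns the samples and a count dictionary reporting both the number of
    passing trials and the number of epochs (45 s / 7.5 s = 6 per trial).
    """
    samples: list[CohortSample] = []
    n_pass = 0
    for trial in trials:
        if not screen_trial(trial, valence_max, arousal_max):
            continue
        n_pass += 1
        cropped = crop_steady_state(trial, start_s, end_s)
        selected = select_channels((cropped, trial.channel_names))
        for epoch in segment(selected.data, fs=trial.fs, channel_names=CANONICAL_CHANNELS):
            samples.append(CohortSample(epoch=epoch, label=label, source=source))
    counts = {"trials_in": len(trials), "trials_passing": n_pass, "epochs": len(samples)}
    return samples, counts
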