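"""Multi-domain feature extraction: the 24-dimensional epoch descriptor.

Three families, eight channels each, in fixed column order:

* **F1 — alpha/beta band-power ratio** (``ratio_<ch>``): a four-level
  wavelet packet decomposition splits the 0-64 Hz axis into sixteen 4 Hz
  leaves; the leaves overlapping a band are reconstructed and the Welch
  power spectral density of that reconstruction is integrated over the
  exact band. The ratio of alpha [8,13) to beta [14,30) power is a
  relative spectral marker, invariant to per-channel rescaling.
* **F2 — normalized alpha asymmetry** (``asym_<ch>``):
  ``(P_alpha(ch) - P_alpha(mirror)) / (P_alpha(ch) + P_alpha(mirror))``
  over the homologous pairs Fp1-Fp2, F3-F4, F7-F8, C3-C4; bounded in
  [-1, 1] and antisymmetric between mirrored channels.
* **F3 — sample entropy** (``sampen_<ch>``): SampEn(m=2, r=0.2*SD) of the
  raw channel series, the negative log of the conditional probability that
  sequences matching for m points still match at m+1. Lower values mean a
  more regular, less complex signal.

The asymmetry is computed per channel (not per pair), accepting the
built-in redundancy A(left) = -A(right), so the three families tile the
8 channels uniformly into a 24-vector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.signal import welch
from sklearn.base import BaseEstimator, TransformerMixin

from .bands import ALPHA, BETA, BandDefinition
from .containers import CohortSample, Epoch
from .montage import CANONICAL_CHANNELS, FS, MIRROR

logger = logging.getLogger(__name__)

FAMILIES = ("ratio", "asym", "sampen")

#: fixed column order of the feature matrix: F1 block, F2 block, F3 block
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{family}_{ch}" for family in FAMILIES for ch in CANONICAL_CHANNELS
)


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters: embedding dimension m, tolerance factor
    r = r_factor * SD(x), valid series length 100 <= N <= 5000."""

    m: int = 2
    r_factor: float = 0.2

    def validate(self, n: int) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be > 0")
        if not 100 <= n <= 5000:
            raise ValueError(f"series length {n} outside the valid range [100, 5000]")


@dataclass(frozen=True)
class FeatureConfig:
    """All extraction parameters, recorded verbatim in the JSON sidecar."""

    wavelet: str = "db16"
    level: int = 4
    welch_nperseg: int = 128
    welch_noverlap: int = 64
    welch_window: str = "hann"
    sampen: SampEnParams = field(default_factory=SampEnParams)
    ratio_cap: float = 1e6

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = {"alpha": [ALPHA.lo, ALPHA.hi], "beta": [BETA.lo, BETA.hi]}
        d["band_power"] = "total band power (integrated Welch PSD over [lo, hi))"
        return d


DEFAULT_CONFIG = FeatureConfig()


# ---------------------------------------------------------------------------
# Wavelet packet decomposition

def _check_orthogonal(wavelet: str) -> pywt.Wavelet:
    w = pywt.Wavelet(wavelet)
    if not w.orthogonal:
        raise ValueError(
            f"wavelet {wavelet!r} is not orthogonal; the leaf-energy "
            "conservation invariant requires an orthogonal filter bank"
        )
    return w


def wpd_decompose(
    x: np.ndarray, level: int = 4, wavelet: str = "db16", fs: float = FS
) -> list[tuple[np.ndarray, tuple[float, float]]]:
    """Four-level wavelet packet decomposition in frequency (sequency) order.

    Returns ``2**level`` pairs ``(coeffs, (lo, hi))``; leaf k nominally
    covers ``[k*fs/2**(level+1), (k+1)*fs/2**(level+1))`` Hz — 4 Hz leaves
    at 128 Hz. Periodized orthogonal transform, so the summed leaf energies
    equal the signal energy.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("wpd_decompose expects a 1-D series")
    if len(x) < 2**level:
        raise ValueError(f"series of length {len(x)} too short for level {level}")
    w = _check_orthogonal(wavelet)
    wp = pywt.WaveletPacket(data=x, wavelet=w, mode="periodization", maxlevel=level)
    nodes = wp.get_level(level, order="freq")
    step = fs / 2 ** (level + 1)
    return [
        (np.asarray(node.data, dtype=float), (k * step, (k + 1) * step))
        for k, node in enumerate(nodes)
    ]


def wpd_reconstruct_band(
    x: np.ndarray,
    band: BandDefinition,
    level: int = 4,
    wavelet: str = "db16",
    fs: float = FS,
) -> np.ndarray:
    """Reconstruct the part of ``x`` carried by WPD leaves overlapping
    ``[band.lo, band.hi)``."""
    x = np.asarray(x, dtype=float)
    w = _check_orthogonal(wavelet)
    wp = pywt.WaveletPacket(data=x, wavelet=w, mode="periodization", maxlevel=level)
    nodes = wp.get_level(level, order="freq")
    step = fs / 2 ** (level + 1)
    out = pywt.WaveletPacket(
        data=None, wavelet=w, mode="periodization", maxlevel=level
    )
    kept = 0
    for k, node in enumerate(nodes):
        lo, hi = k * step, (k + 1) * step
        if lo < band.hi and hi > band.lo:  # leaf overlaps the band
            out[node.path] = node.data
            kept += 1
    if kept == 0:
        raise ValueError(f"no WPD leaf overlaps band [{band.lo}, {band.hi})")
    rec = out.reconstruct(update=False)
    return np.asarray(rec[: len(x)], dtype=float)


# ---------------------------------------------------------------------------
# Band power and the two spectral families

def band_power(
    x: np.ndarray,
    band: BandDefinition,
    fs: float = FS,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> float:
    """Total power of ``x`` in ``[band.lo, band.hi)`` (microvolt^2).

    The band signal is reconstructed from the overlapping WPD leaves, its
    Welch PSD estimated (1 s Hann windows, 50% overlap), and the density
    integrated over exactly the band interval.
    """
    if band.hi > fs / 2:
        raise ValueError(f"band upper edge {band.hi} above Nyquist {fs / 2}")
    rec = wpd_reconstruct_band(x, band, level=config.level, wavelet=config.wavelet, fs=fs)
    f, pxx = welch(
        rec,
        fs=fs,
        window=config.welch_window,
        nperseg=min(config.welch_nperseg, len(rec)),
        noverlap=min(config.welch_noverlap, len(rec) - 1),
    )
    df = f[1] - f[0]
    mask = (f >= band.lo) & (f < band.hi)
    return float(np.sum(pxx[mask]) * df)


def _alpha_beta_powers(
    epoch: Epoch, config: FeatureConfig = DEFAULT_CONFIG
) -> tuple[np.ndarray, np.ndarray]:
    p_alpha = np.empty(epoch.n_channels)
    p_beta = np.empty(epoch.n_channels)
    for i in range(epoch.n_channels):
        p_alpha[i] = band_power(epoch.data[i], ALPHA, fs=epoch.fs, config=config)
        p_beta[i] = band_power(epoch.data[i], BETA, fs=epoch.fs, config=config)
    return p_alpha, p_beta


def psd_ratio(epoch: Epoch, config: FeatureConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Per-channel alpha/beta band-power ratio (8 positive reals)."""
    p_alpha, p_beta = _alpha_beta_powers(epoch, config)
    ratio = np.empty_like(p_alpha)
    for i in range(len(ratio)):
        if p_beta[i] == 0.0:
            warnings.warn(
                f"zero beta power on {epoch.channel_names[i]}; ratio clamped",
                RuntimeWarning,
                stacklevel=2,
            )
            ratio[i] = config.ratio_cap
        else:
            ratio[i] = min(p_alpha[i] / p_beta[i], config.ratio_cap)
    return ratio


def alpha_asymmetry(epoch: Epoch, config: FeatureConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Per-channel normalized alpha asymmetry against the homologous mirror.

    ``A(ch) = (P_alpha(ch) - P_alpha(m(ch))) / (P_alpha(ch) + P_alpha(m(ch)))``,
    bounded in [-1, 1], antisymmetric between mirrored channels. Both powers
    zero is defined as 0.
    """
    p_alpha = np.empty(epoch.n_channels)
    for i in range(epoch.n_channels):
        p_alpha[i] = band_power(epoch.data[i], ALPHA, fs=epoch.fs, config=config)
    index = {name: i for i, name in enumerate(epoch.channel_names)}
    out = np.empty(epoch.n_channels)
    for i, name in enumerate(epoch.channel_names):
        mirror = MIRROR.get(name)
        if mirror is None or mirror not in index:
            raise ValueError(f"channel {name!r} has no homologous mirror in the epoch")
        a, b = p_alpha[i], p_alpha[index[mirror]]
        if a + b == 0.0:
            warnings.warn(
                f"zero alpha power on pair {name}/{mirror}; asymmetry set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            out[i] = 0.0
        else:
            out[i] = (a - b) / (a + b)
    return out


# ---------------------------------------------------------------------------
# Sample entropy

def sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Template-match counts (A, B) for sample entropy.

    B counts unordered pairs i < j of m-length templates within Chebyshev
    distance r, A the same for (m+1)-length templates; both use template
    start indices 0 .. N-m-1 so the two counts are comparable, and
    self-matches are excluded.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    nt = n - m  # number of (m+1)-length templates
    if nt < 2:
        raise ValueError("series too short for the requested embedding dimension")
    close = np.abs(x[:, None] - x[None, :]) <= r
    match = close[:nt, :nt].copy()
    for k in range(1, m):
        match &= close[k : nt + k, k : nt + k]
    b = (int(match.sum()) - nt) // 2
    match &= close[m : nt + m, m : nt + m]
    a = (int(match.sum()) - nt) // 2
    return a, b


def sample_entropy(
    x: np.ndarray, params: SampEnParams = SampEnParams()
) -> float:
    """SampEn(m, r_factor * SD) of a series; -ln(A/B) over template matches.

    Degenerate rules: a constant series returns 0 (no variability implies no
    complexity); A = 0 returns the largest estimable value
    ``ln((N-m)*(N-m-1))`` instead of infinity so feature matrices stay
    finite. Affine rescaling x -> a*x + b (a > 0) leaves the result
    unchanged because r scales with the SD.
    """
    x = np.asarray(x, dtype=float)
    params.validate(len(x))
    sd = float(np.std(x))
    if sd == 0.0:
        warnings.warn("constant series: sample entropy defined as 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    a, b = sampen_counts(x, params.m, params.r_factor * sd)
    nt = len(x) - params.m
    cap = float(np.log(nt * (nt - 1)))
    if b == 0 or a == 0:
        logger.info("sample entropy saturated (A=%d, B=%d); returning cap %.3f", a, b, cap)
        return cap
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# Feature vectors and the N x 24 matrix

@dataclass
class FeatureVector:
    """The 24-dimensional descriptor of one epoch."""

    f1_ratio: np.ndarray
    f2_asym: np.ndarray
    f3_sampen: np.ndarray

    def to_array(self) -> np.ndarray:
        v = np.concatenate([self.f1_ratio, self.f2_asym, self.f3_sampen])
        assert v.shape == (24,)
        return v


def extract_features(
    epoch: Epoch, config: FeatureConfig = DEFAULT_CONFIG
) -> FeatureVector:
    """Compute F1/F2/F3 for one standardized epoch."""
    p_alpha, p_beta = _alpha_beta_powers(epoch, config)
    ratio = np.minimum(
        np.divide(
            p_alpha,
            p_beta,
            out=np.full_like(p_alpha, config.ratio_cap),
            where=p_beta != 0,
        ),
        config.ratio_cap,
    )
    index = {name: i for i, name in enumerate(epoch.channel_names)}
    asym = np.empty(epoch.n_channels)
    for i, name in enumerate(epoch.channel_names):
        j = index[MIRROR[name]]
        denom = p_alpha[i] + p_alpha[j]
        asym[i] = 0.0 if denom == 0 else (p_alpha[i] - p_alpha[j]) / denom
    sampen = np.array(
        [sample_entropy(epoch.data[i], config.sampen) for i in range(epoch.n_channels)]
    )
    return FeatureVector(f1_ratio=ratio, f2_asym=asym, f3_sampen=sampen)


def build_feature_matrix(
    cohort: list[CohortSample], config: FeatureConfig = DEFAULT_CONFIG
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the N x 24 feature matrix and label vector for a cohort.

    Columns follow :data:`FEATURE_COLUMNS` (``ratio_Fp1`` ... ``sampen_C4``).
    Rows with any non-finite feature are rejected and logged, never imputed.
    """
    rows, labels = [], []
    for i, sample in enumerate(cohort):
        if not sample.epoch.is_standard():
            raise ValueError(f"sample {i} is not in the standardized epoch format")
        vec = extract_features(sample.epoch, config).to_array()
        if not np.all(np.isfinite(vec)):
            logger.warning("sample %d produced non-finite features; row rejected", i)
            continue
        rows.append(vec)
        labels.append(sample.label)
    X = pd.DataFrame(np.asarray(rows), columns=list(FEATURE_COLUMNS))
    return X, np.asarray(labels, dtype=int)


class MultiDomainFeatureExtractor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer mapping epochs to the 24-feature space.

    ``transform`` accepts an (N, 8, 960) array, a list of :class:`Epoch`, or
    a list of :class:`CohortSample`, and returns the (N, 24) matrix with
    columns in :data:`FEATURE_COLUMNS` order. Stateless: ``fit`` only
    validates parameters.
    """

    def __init__(self, config: FeatureConfig = DEFAULT_CONFIG):
        self.config = config

    def fit(self, X, y=None):
        _check_orthogonal(self.config.wavelet)
        self.n_features_out_ = len(FEATURE_COLUMNS)
        return self

    def transform(self, X) -> np.ndarray:
        epochs = []
        for item in X:
            if isinstance(item, CohortSample):
                epochs.append(item.epoch)
            elif isinstance(item, Epoch):
                epochs.append(item)
            else:
                epochs.append(Epoch(data=np.asarray(item, dtype=float)))
        return np.vstack(
            [extract_features(e, self.config).to_array() for e in epochs]
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_COLUMNS, dtype=object)
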