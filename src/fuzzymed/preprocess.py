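"""Signal segmentation, FFT spectral features, and PCA dimensionality reduction.

Raw fixed-rate signal records (e.g. single-channel EEG) are cut into
non-overlapping segments, each segment is represented by its one-sided FFT
magnitude spectrum, and the resulting feature matrix is reduced to a small
number of variance-ranked principal components before fuzzification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

__all__ = [
    "SignalRecord",
    "FeatureMatrix",
    "PCAModel",
    "segment_signal",
    "fft_features",
    "pca_fit",
    "pca_transform",
    "pca_fit_transform",
]

log = logging.getLogger(__name__)


@dataclass
class SignalRecord:
    samples: np.ndarray
    sampling_rate: float
    label: str
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.size < 2:
            raise ValueError("signal record needs at least 2 samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class FeatureMatrix:
    """K x s numeric feature table with named columns and per-row class labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains missing/non-finite values")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("labels length mismatch")
        if self.values.shape[1] < 1:
            raise ValueError("need at least one feature")
        self.feature_names = list(self.feature_names)
        self.labels = list(self.labels)


def segment_signal(rec: SignalRecord, segment_seconds: float) -> list[SignalRecord]:
    """Cut a record into consecutive non-overlapping segments.

    Segment length is floor(segment_seconds * rate) samples; a trailing
    remainder shorter than one segment is discarded.  Labels are inherited.
    """
    if segment_seconds <= 0:
        raise ValueError("segment_seconds must be positive")
    if segment_seconds > rec.duration + 1e-12:
        raise ValueError(
            f"segment of {segment_seconds} s longer than record of {rec.duration} s"
        )
    n = int(np.floor(segment_seconds * rec.sampling_rate))
    n_seg = rec.samples.size // n
    return [
        SignalRecord(
            samples=rec.samples[i * n : (i + 1) * n],
            sampling_rate=rec.sampling_rate,
            label=rec.label,
            record_id=f"{rec.record_id}#{i}",
        )
        for i in range(n_seg)
    ]


def fft_features(segments: list[SignalRecord], *, window: str = "rectangular") -> FeatureMatrix:
    """One-sided FFT magnitude spectrum per segment.

    Features are |X[f]| at bins 0..N//2 (rectangular window by default so
    pure bin-aligned tones stay exact; ``window="hann"`` applies a Hann
    taper).  Feature names carry the bin frequency in Hz.
    """
    if not segments:
        raise ValueError("no segments")
    n = segments[0].samples.size
    rate = segments[0].sampling_rate
    for s in segments:
        if s.samples.size != n or s.sampling_rate != rate:
            raise ValueError("segments must share length and sampling rate")
    if window == "rectangular":
        win = np.ones(n)
    elif window == "hann":
        win = np.hanning(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    data = np.stack([s.samples * win for s in segments])
    spec = np.abs(np.fft.rfft(data, axis=1))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    names = [f"mag_{f:.4g}Hz" for f in freqs]
    return FeatureMatrix(values=spec, feature_names=names, labels=[s.label for s in segments])


@dataclass
class PCAModel:
    """Standardize-then-project PCA with a deterministic sign convention."""

    means: np.ndarray
    scales: np.ndarray
    kept_columns: np.ndarray  # indices of non-constant input columns
    loadings: np.ndarray  # s_kept x n_components, column-orthonormal
    component_variances: np.ndarray  # non-increasing
    feature_names: list[str]


def pca_fit(fm: FeatureMatrix, n_components: int) -> PCAModel:
    k, s = fm.values.shape
    if not 1 <= n_components <= min(k - 1, s):
        raise ValueError(
            f"n_components={n_components} out of range [1, {min(k - 1, s)}]"
        )
    means = fm.values.mean(axis=0)
    scales = fm.values.std(axis=0, ddof=0)
    keep = np.where(scales > 0)[0]
    if keep.size < s:
        log.warning("dropping %d zero-variance feature columns before PCA", s - keep.size)
    if keep.size < n_components:
        raise ValueError("fewer non-constant columns than requested components")
    z = (fm.values[:, keep] - means[keep]) / scales[keep]
    sk = _SkPCA(n_components=n_components, svd_solver="full")
    sk.fit(z)
    loadings = sk.components_.T.copy()  # s_kept x n_components
    # Orient each component so its largest-magnitude loading is positive.
    for c in range(loadings.shape[1]):
        col = loadings[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, c] = -col
    return PCAModel(
        means=means,
        scales=scales,
        kept_columns=keep,
        loadings=loadings,
        component_variances=sk.explained_variance_.copy(),
        feature_names=list(fm.feature_names),
    )


def pca_transform(model: PCAModel, fm: FeatureMatrix) -> FeatureMatrix:
    z = (fm.values[:, model.kept_columns] - model.means[model.kept_columns]) / model.scales[
        model.kept_columns
    ]
    proj = z @ model.loadings
    names = [f"PC{i + 1}" for i in range(proj.shape[1])]
    return FeatureMatrix(values=proj, feature_names=names, labels=list(fm.labels))


def pca_fit_transform(fm: FeatureMatrix, n_components: int) -> tuple[PCAModel, FeatureMatrix]:
    """Standardize (z-score), fit PCA, and project onto the top components."""
    model = pca_fit(fm, n_components)
    return model, pca_transform(model, fm)
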