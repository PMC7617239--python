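"""Broad/narrow waveform classification.

Extracellular spike waveforms of cortical neurons fall into two classes:
broad waveforms (putative excitatory cells, slow repolarization) and narrow
waveforms (putative fast-spiking interneurons). The recipe: average the
first up-to-10000 aligned snippets per unit, upsample x3 by spline, center
on the median of the first 10 samples, normalize by the absolute negative
peak, embed the 80 post-trough samples with t-SNE (perplexity 80) and cut a
Ward dendrogram of the 2-D embedding at two clusters. Class semantics are
re-derived from trough-to-peak time (the shorter cluster is "narrow"), so
labels never depend on embedding chirality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.manifold import TSNE

__all__ = [
    "WaveformEntry",
    "mean_waveform",
    "ClassificationResult",
    "classify_waveforms",
    "UPSAMPLE_FACTOR",
    "N_POST_TROUGH",
]

UPSAMPLE_FACTOR = 3
N_POST_TROUGH = 80  # samples after the trough used for embedding (upsampled grid)
MAX_SNIPPETS = 10_000


@dataclass
class WaveformEntry:
    """One unit's normalized mean waveform and derived features."""

    unit_id: int | str
    waveform: np.ndarray  # normalized, upsampled
    fs_upsampled: float
    trough_index: int
    trough_to_peak_ms: float
    discarded: bool  # positive absolute peak -> not classifiable


def mean_waveform(
    snippets: np.ndarray,
    unit_id: int | str = 0,
    fs: float = 30000.0,
    upsample: int = UPSAMPLE_FACTOR,
) -> WaveformEntry:
    """Normalized mean waveform of one unit.

    ``snippets`` is (n_snippets, n_samples); up to the first 10000 snippets
    are averaged. The mean is upsampled by cubic spline on the index grid
    ``j / upsample``, j = 0 .. n*upsample - 1 (84 raw samples -> 252 output
    samples; the last upsample-1 points extend the spline fractionally past
    the final raw sample), the median of the first 10 upsampled samples is
    subtracted, and the result is divided by the absolute value of the
    negative peak so the trough equals -1 exactly. Waveforms whose largest
    absolute excursion is positive are flagged ``discarded``.
    """
    snippets = np.atleast_2d(np.asarray(snippets, dtype=float))
    if snippets.shape[0] < 1 or snippets.shape[1] < 2:
        raise ValueError("need at least one snippet of at least two samples")
    mean = snippets[:MAX_SNIPPETS].mean(axis=0)
    if np.allclose(mean, 0.0):
        raise ValueError("all-zero mean waveform")
    n = mean.size
    grid = np.arange(n * upsample) / upsample  # j/upsample, j = 0 .. n*upsample-1
    up = CubicSpline(np.arange(n), mean)(grid)
    up = up - np.median(up[:10])
    fs_up = fs * upsample

    trough = int(np.argmin(up))
    peak = int(np.argmax(up))
    discarded = abs(up[peak]) > abs(up[trough])  # positive absolute peak
    if not discarded:
        up = up / abs(up[trough])
    else:
        up = up / max(abs(up[peak]), abs(up[trough]))

    # trough-to-peak: time from the trough to the subsequent positive maximum
    after = up[trough + 1 :]
    if after.size:
        t2p = (int(np.argmax(after)) + 1) / fs_up * 1e3
    else:
        t2p = float("nan")
    return WaveformEntry(
        unit_id=unit_id,
        waveform=up,
        fs_upsampled=fs_up,
        trough_index=trough,
        trough_to_peak_ms=t2p,
        discarded=discarded,
    )


@dataclass
class ClassificationResult:
    """Per-unit labels plus bookkeeping about how they were obtained."""

    unit_ids: List
    labels: np.ndarray  # 'broad' | 'narrow' | 'discarded'
    trough_to_peak_ms: np.ndarray
    method: str  # 'tsne+ward' | 'threshold-fallback' | 'single-class'
    embedding: Optional[np.ndarray] = None


def _post_trough_features(entries: Sequence[WaveformEntry]) -> np.ndarray:
    feats = np.zeros((len(entries), N_POST_TROUGH))
    for i, e in enumerate(entries):
        seg = e.waveform[e.trough_index + 1 : e.trough_index + 1 + N_POST_TROUGH]
        feats[i, : seg.size] = seg
        if seg.size < N_POST_TROUGH and seg.size:
            feats[i, seg.size :] = seg[-1]  # pad with the endpoint
    return feats


def classify_waveforms(
    entries: Sequence[WaveformEntry],
    seed: int = 0,
    perplexity: float = 80.0,
) -> ClassificationResult:
    """Two-class waveform typing via t-SNE + hierarchical clustering.

    Discarded (positive-peak) units are excluded from the embedding and
    labeled ``'discarded'``. With fewer than ``2 * perplexity`` usable units
    a two-means split of the trough-to-peak times is used instead
    (flagged ``'threshold-fallback'``); with indistinguishable waveforms a
    single class is assigned and flagged. The cluster with the shorter mean
    trough-to-peak is labeled ``'narrow'``.
    """
    if len(entries) < 5:
        raise ValueError("need at least 5 units to classify")
    unit_ids = [e.unit_id for e in entries]
    t2p = np.array([e.trough_to_peak_ms for e in entries])
    labels = np.array(["discarded"] * len(entries), dtype=object)
    usable = np.array([not e.discarded for e in entries])
    idx = np.nonzero(usable)[0]
    if idx.size < 5:
        raise ValueError("fewer than 5 usable (negative-peak) waveforms")
    feats = _post_trough_features([entries[i] for i in idx])

    if np.allclose(feats, feats[0], atol=1e-12):
        labels[idx] = "broad" if np.nanmean(t2p[idx]) >= 0.45 else "narrow"
        return ClassificationResult(unit_ids, labels, t2p, method="single-class")

    if idx.size < 2 * perplexity:
        # 1-D two-means split on trough-to-peak (robust to outlier gaps)
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(
            t2p[idx].reshape(-1, 1)
        )
        narrow_cluster = int(np.argmin(km.cluster_centers_.ravel()))
        labels[idx] = np.where(km.labels_ == narrow_cluster, "narrow", "broad")
        return ClassificationResult(unit_ids, labels, t2p, method="threshold-fallback")

    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    ).fit_transform(feats)
    cluster = AgglomerativeClustering(n_clusters=2, linkage="ward").fit_predict(emb)
    mean_t2p = [t2p[idx][cluster == c].mean() for c in (0, 1)]
    narrow_cluster = int(np.argmin(mean_t2p))
    labels[idx] = np.where(cluster == narrow_cluster, "narrow", "broad")
    return ClassificationResult(
        unit_ids, labels, t2p, method="tsne+ward", embedding=emb
    )
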