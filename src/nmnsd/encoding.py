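"""Latency encoders: turn raw inputs into parallel spike trains.

Static intensities are encoded by time-to-first-spike: a bright pixel (or
pixel field) fires early, a dark one late, through the affine relation
``t_i = (Imax - I_i)/Imax * t_range`` with ``t_range = 25`` ms by default
(the maximum latency, assigned to an unwritten pixel).  Multichannel time
series are reduced to per-channel peak times; informative channel subsets
are selected from the stability of pairwise peak-time differences across
trials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structure import ParallelSpikeTrain

__all__ = [
    "ImageEncodingParams",
    "PeakFeatureConfig",
    "image_to_train",
    "peak_times",
    "select_channels",
    "features_to_train",
]


@dataclass(frozen=True)
class ImageEncodingParams:
    """Intensity-to-latency parameters.

    ``field_size`` groups the image into square pixel fields (side length);
    each field contributes one branch, encoded from its mean intensity.
    """

    Imax: float = 255.0
    t_range: float = 25.0
    field_size: int = 1

    def __post_init__(self) -> None:
        if self.Imax <= 0 or self.t_range <= 0:
            raise ValueError("Imax and t_range must be positive")
        if self.field_size < 1:
            raise ValueError("field_size must be >= 1")


@dataclass(frozen=True)
class PeakFeatureConfig:
    """Channel-pair selection settings for the peak-time pipeline."""

    window: tuple[float, float] = (0.0, 400.0)
    min_mean_gap: float = 10.0
    n_channels: int = 8
    mean_tol: float = 1e-9  # equality tolerance for cross-class de-dup

    def __post_init__(self) -> None:
        if self.window[1] <= self.window[0]:
            raise ValueError("analysis window must be non-empty")
        if self.min_mean_gap < 0:
            raise ValueError("min_mean_gap must be >= 0")


def image_to_train(image: np.ndarray,
                   p: ImageEncodingParams = ImageEncodingParams(),
                   ) -> ParallelSpikeTrain:
    """Encode a grayscale intensity matrix as a parallel spike train.

    The image is partitioned into ``(side/field_size)**2`` square fields;
    each field's *mean* intensity maps to the latency
    ``t = (Imax - I)/Imax * t_range``.  Branches are ordered row-major over
    fields (adjacent fields feed adjacent branches, which matters because
    STDP couples neighbouring branches; supply a custom order by permuting
    the image beforehand).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity matrix")
    if np.any(img < 0) or np.any(img > p.Imax):
        raise ValueError(f"intensities must lie in [0, {p.Imax}]")
    f = p.field_size
    h, w = img.shape
    if h % f or w % f:
        raise ValueError(f"image shape {img.shape} not divisible by "
                         f"field_size {f}")
    fields = img.reshape(h // f, f, w // f, f).mean(axis=(1, 3))
    t = (p.Imax - fields.ravel()) / p.Imax * p.t_range
    return ParallelSpikeTrain(times=t)


def peak_times(series: np.ndarray, sample_rate: float,
               window: tuple[float, float] | None = None) -> np.ndarray:
    """Per-channel time (ms) of the absolute maximum within ``window``.

    ``series`` is channels x samples; ``sample_rate`` in Hz.  Ties resolve
    to the earliest sample.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a channels x samples array")
    t_ms = np.arange(arr.shape[1]) / sample_rate * 1000.0
    if window is None:
        mask = np.ones(arr.shape[1], dtype=bool)
    else:
        lo, hi = window
        mask = (t_ms >= lo) & (t_ms <= hi)
        if not mask.any():
            raise ValueError("analysis window contains no samples")
    sel = t_ms[mask]
    idx = np.argmax(arr[:, mask], axis=1)  # first occurrence on ties
    return sel[idx]


def _pair_stats(peaks: np.ndarray) -> pd.DataFrame:
    """Mean/std of peak-time differences for every channel pair.

    ``peaks`` is trials x channels; returns a frame with columns
    ``ch_a, ch_b, mean, std`` (a < b, difference ``a - b``).
    """
    n_ch = peaks.shape[1]
    rows = []
    for a, b in itertools.combinations(range(n_ch), 2):
        d = peaks[:, a] - peaks[:, b]
        rows.append((a, b, float(np.mean(d)), float(np.std(d, ddof=1))))
    return pd.DataFrame(rows, columns=["ch_a", "ch_b", "mean", "std"])


def select_channels(peaks_by_class: Mapping[object, np.ndarray],
                    cfg: PeakFeatureConfig = PeakFeatureConfig(),
                    ) -> dict[object, list[int]]:
    """Select informative channels per class from peak-time tables.

    For each class (``trials x channels`` peak times, >= 2 trials): rank
    all channel pairs by ascending std of the pairwise peak-time
    difference, keep pairs with ``|mean| >= min_mean_gap``, and greedily
    accept pairs until ``n_channels`` distinct channels are covered.
    Pairs selected by both classes with equal means (within ``mean_tol``)
    are discriminatively useless and are removed from both before the
    greedy cover.  Returns the ordered channel list per class (possibly
    shorter than ``n_channels`` if few pairs qualify).
    """
    stats: dict[object, pd.DataFrame] = {}
    for label, peaks in peaks_by_class.items():
        arr = np.asarray(peaks, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError(f"class {label!r}: need >= 2 trials of "
                             "per-channel peak times")
        df = _pair_stats(arr)
        df = df[np.abs(df["mean"]) >= cfg.min_mean_gap]
        stats[label] = df.sort_values(["std", "ch_a", "ch_b"],
                                      kind="stable").reset_index(drop=True)

    # cross-class de-duplication of pairs with identical means
    labels = list(stats)
    if len(labels) == 2:
        a, b = labels
        merged = stats[a].merge(stats[b], on=["ch_a", "ch_b"],
                                suffixes=("_a", "_b"))
        dup = merged[np.abs(merged["mean_a"] - merged["mean_b"])
                     <= cfg.mean_tol][["ch_a", "ch_b"]]
        if len(dup):
            key = set(map(tuple, dup.to_numpy()))
            for lab in labels:
                df = stats[lab]
                keep = [tuple(r) not in key
                        for r in df[["ch_a", "ch_b"]].to_numpy()]
                stats[lab] = df[keep].reset_index(drop=True)

    out: dict[object, list[int]] = {}
    for label, df in stats.items():
        chosen: list[int] = []
        for _, row in df.iterrows():
            if len(chosen) >= cfg.n_channels:
                break
            for ch in (int(row["ch_a"]), int(row["ch_b"])):
                if ch not in chosen and len(chosen) < cfg.n_channels:
                    chosen.append(ch)
        out[label] = chosen
    return out


def features_to_train(v: Sequence[float], lo: float, hi: float,
                      t_range: float = 25.0) -> ParallelSpikeTrain:
    """Affine, order-preserving map of a feature vector onto spike times in
    ``[0, t_range]`` (``lo`` maps to 0, ``hi`` to ``t_range``)."""
    if not hi > lo:
        raise ValueError("require hi > lo")
    arr = np.asarray(v, dtype=float)
    t = (arr - lo) / (hi - lo) * t_range
    return ParallelSpikeTrain(times=t)
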