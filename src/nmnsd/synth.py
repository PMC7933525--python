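"""Synthetic generators with the statistical structure the method assumes.

Parallel-spike-train classes are defined by *templates*: a vector of
relative intervals plus per-branch Gaussian jitter, mimicking trial-to-
trial variability of peak-time features.  Multichannel trials plant
Gaussian bumps at the template latencies over noise channels (exercising
the peak-time pipeline), and toy binary images (bars/crosses) stand in for
handwritten digits at desk scale.  Every generator is a pure function of
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

from .structure import ParallelSpikeTrain

__all__ = [
    "ClassTemplate",
    "gen_templates",
    "gen_trials",
    "gen_multichannel",
    "gen_toy_images",
    "TOY_PATTERNS",
]


@dataclass(frozen=True)
class ClassTemplate:
    """A class of parallel spike trains.

    ``intervals`` are the target relative intervals (ms, adjacent-branch
    convention ``t[i] - t[i+1]``); ``jitter_sd`` the per-branch Gaussian
    jitter; ``times`` the canonical absolute times (cumulative form
    anchored at the earliest spike = 0).
    """

    intervals: tuple[float, ...]
    jitter_sd: float = 1.0
    label: Hashable = 0

    @property
    def n(self) -> int:
        return len(self.intervals) + 1

    @property
    def times(self) -> np.ndarray:
        t = np.concatenate([[0.0], -np.cumsum(self.intervals)])
        return t - t.min()


def gen_templates(n_features: int, n_classes: int,
                  min_separation: float = 10.0, seed: int | None = None,
                  jitter_sd: float = 1.0, spread: float = 15.0,
                  max_draws: int = 10_000) -> list[ClassTemplate]:
    """Random class templates with pairwise interval distance (L-infinity)
    at least ``min_separation`` ms.

    Absolute template times are drawn uniformly in ``[0, spread]`` so that
    every implied latency stays well inside the 25 ms latency range.
    Raises if the separation cannot be achieved within ``max_draws``.
    """
    if n_features < 2:
        raise ValueError("templates need >= 2 features")
    if min_separation > 2 * spread:
        raise ValueError("requested separation infeasible within the "
                         "latency range")
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    draws = 0
    while len(chosen) < n_classes:
        if draws >= max_draws:
            raise RuntimeError("could not place separated templates; "
                               "lower min_separation or raise spread")
        draws += 1
        t = rng.uniform(0.0, spread, size=n_features)
        iv = t[:-1] - t[1:]
        if all(np.max(np.abs(iv - o)) >= min_separation for o in chosen):
            chosen.append(iv)
    return [ClassTemplate(intervals=tuple(iv), jitter_sd=jitter_sd,
                          label=i) for i, iv in enumerate(chosen)]


def gen_trials(template: ClassTemplate, n_trials: int,
               seed: int | None = None, offset_range: float = 5.0,
               ) -> list[ParallelSpikeTrain]:
    """Jittered realisations of a template.

    Each trial is ``random offset + template times + N(0, jitter_sd^2)``
    per branch; the random offset (uniform in ``[0, offset_range]``)
    exercises translation invariance by default.  A fixed 6-sigma safety
    margin keeps times positive without truncating the jitter
    distribution (recognition is translation-invariant, so the shift is
    immaterial).
    """
    if template.jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = template.times + 6.0 * template.jitter_sd
    out = []
    for _ in range(n_trials):
        off = rng.uniform(0.0, offset_range) if offset_range > 0 else 0.0
        t = off + base + rng.normal(0.0, template.jitter_sd, size=base.size)
        out.append(ParallelSpikeTrain(times=np.maximum(t, 0.0)))
    return out


def gen_multichannel(templates: Sequence[ClassTemplate], n_trials: int,
                     noise_sd: float = 0.2, sample_rate: float = 1000.0,
                     duration_ms: float = 100.0, n_noise_channels: int = 4,
                     bump_width_ms: float = 5.0,
                     seed: int | None = None):
    """Labelled multichannel trials for the peak-time pipeline.

    Channels are laid out as one disjoint informative block per class
    followed by ``n_noise_channels`` pure-noise channels.  On a trial of
    class ``k``, the channels of block ``k`` carry unit-amplitude Gaussian
    bumps peaking at the class's template latencies (plus jitter); all
    other channels carry ``N(0, noise_sd^2)`` samples only.

    Returns ``(trials, labels)`` with ``trials`` a list of channels x
    samples arrays.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    start = 0
    for tpl in templates:
        blocks.append(range(start, start + tpl.n))
        start += tpl.n
    n_ch = start + n_noise_channels
    n_samp = int(round(duration_ms / 1000.0 * sample_rate))
    t_ms = np.arange(n_samp) / sample_rate * 1000.0
    trials, labels = [], []
    for _ in range(n_trials):
        for k, tpl in enumerate(templates):
            arr = rng.normal(0.0, noise_sd, size=(n_ch, n_samp))
            peak = tpl.times + rng.normal(0.0, tpl.jitter_sd,
                                          size=tpl.n)
            for ch, pk in zip(blocks[k], peak):
                arr[ch] += np.exp(-0.5 * ((t_ms - pk) / bump_width_ms) ** 2)
            trials.append(arr)
            labels.append(tpl.label)
    return trials, labels


# 7x7 binary strokes, scaled up by repetition to the requested side
TOY_PATTERNS: dict[str, np.ndarray] = {
    "vbar": np.array([[1 if c == 3 else 0 for c in range(7)]
                      for _ in range(7)]),
    "hbar": np.array([[1 if r == 3 else 0 for c in range(7)]
                      for r in range(7)]),
    "cross": np.array([[1 if (r == 3 or c == 3) else 0 for c in range(7)]
                       for r in range(7)]),
    "diag": np.eye(7, dtype=int),
}


def gen_toy_images(pattern_set: Sequence[str], n: int,
                   flip_prob: float = 0.02, seed: int | None = None,
                   side: int = 28):
    """Binary bar/cross images with salt-and-pepper perturbation.

    Each named pattern (see :data:`TOY_PATTERNS`) is upscaled to
    ``side x side`` (side must be a multiple of 7), mapped to intensities
    {0, 255}, and each pixel flipped independently with ``flip_prob``.
    Returns ``(images, labels)``; ``n`` images per pattern.
    """
    if side % 7:
        raise ValueError("side must be a multiple of 7")
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must be a probability")
    rng = np.random.default_rng(seed)
    rep = side // 7
    images, labels = [], []
    for name in pattern_set:
        base = np.kron(TOY_PATTERNS[name], np.ones((rep, rep), dtype=int))
        for _ in range(n):
            img = base.copy()
            flips = rng.random(img.shape) < flip_prob
            img = np.where(flips, 1 - img, img)
            images.append((img * 255).astype(float))
            labels.append(name)
    return images, labels
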