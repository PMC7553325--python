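"""Rotational comparison of panoramic views.

Two views taken at the same place but in different orientations differ only
by a circular shift of azimuth columns. Both metrics therefore scan all
integer-pixel shifts ``alpha`` of the current view against a memorized view:

* the rotational image difference function (rotIDF) is the elevation-
  weighted root-mean-square brightness difference per shift; its minimum
  marks the best alignment and measures how familiar the view is;
* the rotational similarity function (rotSimF) is the elevation-weighted
  normalized cross-correlation used for contrast-weighted-nearness views;
  its maximum plays the same role (1 means a perfect match).

Equirectangular images oversample the sphere near the poles, so each pixel
row is weighted by ``w(v) = sin(pi (v + 0.5) / N_v)``: weight ~1 at the
equator, vanishing toward the poles.

Both functions are evaluated with FFT cross-correlation along the azimuth
axis, which is algebraically identical to the direct sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElevationWeights",
    "RotProfile",
    "elevation_weights",
    "rotidf",
    "rotsimf",
]


@dataclass(frozen=True)
class ElevationWeights:
    """Per-row sphere-sampling weights for an equirectangular image."""

    w: np.ndarray  # (n_v,), all positive, symmetric about the equator

    @property
    def n_v(self) -> int:
        return self.w.size

    @property
    def total(self) -> float:
        return float(self.w.sum())


def elevation_weights(n_v: int) -> ElevationWeights:
    """Sine weights ``w(v) = sin(pi (v + 0.5) / n_v)`` for rows 0..n_v-1."""
    if n_v <= 0:
        raise ValueError("n_v must be a positive integer")
    v = np.arange(n_v)
    return ElevationWeights(np.sin(np.pi * (v + 0.5) / n_v))


@dataclass(frozen=True)
class RotProfile:
    """A rotational difference or similarity profile over all shifts.

    ``alpha_deg[k]`` is the azimuthal rotation of the current view tested at
    index ``k`` (wrapped to (-180, 180]); ``value[k]`` the difference or
    similarity at that shift. The extremum is the minimum for a difference
    profile and the maximum for a similarity profile; shift ties are broken
    toward the smallest ``|alpha|``, then toward positive ``alpha``.
    """

    alpha_deg: np.ndarray
    value: np.ndarray
    kind: str  # "difference" | "similarity"

    def __post_init__(self) -> None:
        if self.kind not in ("difference", "similarity"):
            raise ValueError(f"unknown profile kind {self.kind!r}")

    @property
    def extremum_index(self) -> int:
        m = self.value.min() if self.kind == "difference" else self.value.max()
        ties = np.flatnonzero(self.value == m)
        order = np.lexsort((-np.sign(self.alpha_deg[ties]), np.abs(self.alpha_deg[ties])))
        return int(ties[order[0]])

    @property
    def extremum_value(self) -> float:
        return float(self.value[self.extremum_index])

    @property
    def extremum_shift(self) -> float:
        return float(self.alpha_deg[self.extremum_index])


def _as_array(image) -> np.ndarray:
    for attr in ("brightness", "values"):
        if hasattr(image, attr):
            return np.asarray(getattr(image, attr), dtype=float)
    return np.asarray(image, dtype=float)


def _deg_per_px(image, arr: np.ndarray) -> float:
    return float(getattr(image, "deg_per_px", 360.0 / arr.shape[1]))


def _alpha_axis(n_u: int, deg_per_px: float) -> np.ndarray:
    alpha = np.arange(n_u) * deg_per_px
    return (alpha + 180.0) % 360.0 - 180.0


def _weighted_cross(cur: np.ndarray, mem_w: np.ndarray) -> np.ndarray:
    """cross(alpha) = sum_{u,v} w(v) cur(u+alpha, v) mem(u, v), via rFFT."""
    f_cur = np.fft.rfft(cur, axis=1)
    f_mem = np.fft.rfft(mem_w, axis=1)
    return np.fft.irfft((f_cur * np.conj(f_mem)).sum(axis=0), n=cur.shape[1])


def rotidf(current, memory) -> RotProfile:
    """Rotational image difference function between two brightness views.

    For each shift ``alpha`` the profile holds the weighted r.m.s.
    brightness difference; identical views give an exact 0 at shift 0.
    """
    cur = _as_array(current)
    mem = _as_array(memory)
    if cur.shape != mem.shape:
        raise ValueError(f"shape mismatch: {cur.shape} vs {mem.shape}")
    n_v, n_u = cur.shape
    w = elevation_weights(n_v).w
    wc = w[:, None]
    norm = n_u * w.sum()
    s_cur = float((wc * cur * cur).sum())
    s_mem = float((wc * mem * mem).sum())
    cross = _weighted_cross(cur, wc * mem)
    sq = np.maximum(s_cur + s_mem - 2.0 * cross, 0.0) / norm
    # FFT round-off leaves O(eps)-scale residue where the match is perfect;
    # clamp it so identical (shifted) views score an exact zero
    sq[sq < 1e-12 * (s_cur + s_mem) / norm] = 0.0
    d = np.sqrt(sq)
    return RotProfile(_alpha_axis(n_u, _deg_per_px(current, cur)), d, "difference")


def rotsimf(current, memory) -> RotProfile:
    """Rotational similarity (normalized cross-correlation) between views.

    Intended for non-negative contrast-weighted-nearness images; the profile
    lies in [0, 1] for such inputs, with 1 only at a perfect (scaled) match.
    """
    cur = _as_array(current)
    mem = _as_array(memory)
    if cur.shape != mem.shape:
        raise ValueError(f"shape mismatch: {cur.shape} vs {mem.shape}")
    n_v, n_u = cur.shape
    w = elevation_weights(n_v).w
    wc = w[:, None]
    s_cur = float((wc * cur * cur).sum())
    s_mem = float((wc * mem * mem).sum())
    if s_cur <= 0.0 or s_mem <= 0.0:
        raise ValueError("correlation undefined: an input image is all zero")
    cross = _weighted_cross(cur, wc * mem)
    sim = cross / np.sqrt(s_cur * s_mem)
    return RotProfile(_alpha_axis(n_u, _deg_per_px(current, cur)), sim, "similarity")
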