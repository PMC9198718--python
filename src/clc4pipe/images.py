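"""Synthetic two-channel punctate images for colocalization analysis.

Each image pair emulates a confocal plane of a cell co-expressing two
fluorescently tagged proteins in punctate (vesicular) structures. Channel 1
receives ``n_puncta_ch1`` Gaussian puncta; each is duplicated into channel 2
with probability ``overlap_prob`` (shared position, independently drawn
brightness), and channel 2 additionally receives ``n_ch2_only`` puncta of its
own. Both channels get a constant background and, optionally, noise.

The noise-free ground-truth channels are retained so the designed overlap can
be computed exactly by an oracle, and ``calibrate_overlap_prob`` bisects on
that oracle to hit a target coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["ImageSynthSpec", "ImagePair", "synth_image_pair",
           "oracle_overlap", "calibrate_overlap_prob"]


@dataclass(frozen=True)
class ImageSynthSpec:
    """Parameters of a synthetic two-channel image pair."""

    shape: tuple[int, int] = (256, 256)
    n_puncta_ch1: int = 120
    overlap_prob: float = 0.7
    n_ch2_only: int = 30
    psf_sigma: float = 2.0       # pixels
    bg_level: float = 5.0        # a.u.
    noise_model: str = "gaussian"  # "gaussian", "poisson" or "none"
    noise_sd: float = 2.0        # a.u., gaussian model only
    amp_mean: float = 100.0      # mean punctum peak brightness
    amp_sigma_ln: float = 0.3    # lognormal spread of brightness

    def __post_init__(self) -> None:
        if len(self.shape) != 2 or min(self.shape) < 1:
            raise ValueError("shape must be two positive integers")
        if not 0.0 <= self.overlap_prob <= 1.0:
            raise ValueError("overlap_prob must lie in [0, 1]")
        if (self.bg_level < 0 or self.noise_sd < 0 or self.psf_sigma <= 0
                or self.amp_mean <= 0):
            raise ValueError("intensities and psf_sigma must be non-negative")
        if self.noise_model not in ("gaussian", "poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class ImagePair:
    """Two co-registered single-plane intensity images.

    ``clean_ch1``/``clean_ch2`` are the noise-free, background-free
    ground-truth channels when the pair was synthesized (None for imported
    data).
    """

    ch1: np.ndarray
    ch2: np.ndarray
    clean_ch1: Optional[np.ndarray] = None
    clean_ch2: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, float)
        self.ch2 = np.asarray(self.ch2, float)
        if self.ch1.shape != self.ch2.shape:
            raise ValueError("channels must have identical dimensions")
        if self.ch1.ndim != 2:
            raise ValueError("channels must be single-plane (2-D)")


def _render(shape, positions, amplitudes, sigma):
    """Render Gaussian puncta onto a zero image (vectorized per punctum)."""
    img = np.zeros(shape)
    if len(positions) == 0:
        return img
    half = int(np.ceil(4 * sigma))
    size = 2 * half + 1
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    h, w = shape
    for (py, px), amp in zip(positions, amplitudes):
        iy, ix = int(round(py)), int(round(px))
        dy, dx = py - iy, px - ix
        stamp = amp * np.exp(-((yy - dy) ** 2 + (xx - dx) ** 2)
                             / (2 * sigma ** 2))
        y0, y1 = max(0, iy - half), min(h, iy + half + 1)
        x0, x1 = max(0, ix - half), min(w, ix + half + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        img[y0:y1, x0:x1] += stamp[y0 - (iy - half):size - (iy + half + 1 - y1),
                                   x0 - (ix - half):size - (ix + half + 1 - x1)]
    return img


def synth_image_pair(spec: ImageSynthSpec, seed=0) -> ImagePair:
    """Generate one synthetic image pair with known ground truth.

    Punctum positions, the per-punctum duplication draw and all noise are
    fixed by ``seed``. The duplication draw uses one uniform variate per
    channel-1 punctum compared against ``overlap_prob``, so for a fixed seed
    the set of shared puncta grows monotonically with ``overlap_prob`` -- the
    property the bisection calibration relies on.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    margin = 3 * spec.psf_sigma
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError("image too small for the requested psf_sigma")

    def draw_positions(n):
        return np.column_stack([
            rng.uniform(margin, h - margin, n),
            rng.uniform(margin, w - margin, n),
        ])

    def draw_amps(n):
        return spec.amp_mean * np.exp(rng.normal(0, spec.amp_sigma_ln, n))

    pos1 = draw_positions(spec.n_puncta_ch1)
    amp1 = draw_amps(spec.n_puncta_ch1)
    u = rng.uniform(size=spec.n_puncta_ch1)
    shared = u < spec.overlap_prob
    # A duplicated punctum is the same physical structure seen in both
    # channels: position and brightness are preserved.
    amp2_shared = amp1[shared]
    pos2_only = draw_positions(spec.n_ch2_only)
    amp2_only = draw_amps(spec.n_ch2_only)

    clean1 = _render(spec.shape, pos1, amp1, spec.psf_sigma)
    pos2 = np.vstack([pos1[shared], pos2_only]) if len(pos2_only) or shared.any() \
        else np.empty((0, 2))
    amp2 = np.concatenate([amp2_shared, amp2_only])
    clean2 = _render(spec.shape, pos2, amp2, spec.psf_sigma)

    ch1 = clean1 + spec.bg_level
    ch2 = clean2 + spec.bg_level
    if spec.noise_model == "gaussian" and spec.noise_sd > 0:
        ch1 = ch1 + rng.normal(0, spec.noise_sd, spec.shape)
        ch2 = ch2 + rng.normal(0, spec.noise_sd, spec.shape)
    elif spec.noise_model == "poisson":
        ch1 = rng.poisson(np.clip(ch1, 0, None)).astype(float)
        ch2 = rng.poisson(np.clip(ch2, 0, None)).astype(float)
    ch1 = np.clip(ch1, 0, None)
    ch2 = np.clip(ch2, 0, None)

    return ImagePair(
        ch1=ch1, ch2=ch2, clean_ch1=clean1, clean_ch2=clean2,
        meta={"overlap_prob": spec.overlap_prob,
              "n_shared_true": int(shared.sum()),
              "n_ch2_only": spec.n_ch2_only},
    )


def oracle_overlap(pair: ImagePair) -> float:
    """Designed overlap coefficient from the noise-free ground-truth channels.

    Computed directly on the clean channels over the union of their supports:
    R = sum(c1*c2) / sqrt(sum(c1^2) * sum(c2^2)).
    """
    if pair.clean_ch1 is None or pair.clean_ch2 is None:
        raise ValueError("pair has no ground-truth channels")
    c1, c2 = pair.clean_ch1, pair.clean_ch2
    mask = (c1 > 0) | (c2 > 0)
    a, b = c1[mask], c2[mask]
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def calibrate_overlap_prob(
    target: float,
    base_spec: ImageSynthSpec | None = None,
    seed: int = 0,
    n_avg: int = 5,
    tol: float = 2e-3,
    max_iter: int = 40,
) -> float:
    """Find the overlap_prob whose noise-free oracle coefficient hits a target.

    Bisects on ``overlap_prob``; at each probe the oracle coefficient is
    averaged over ``n_avg`` noise-free pairs generated from a fixed set of
    seeds (identical across probes), so the probed function is deterministic
    and monotone and bisection converges.
    """
    from dataclasses import replace

    base_spec = base_spec or ImageSynthSpec()
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(seed).spawn(n_avg)]

    def measure(p: float) -> float:
        spec = replace(base_spec, overlap_prob=p, noise_model="none")
        return float(np.mean([oracle_overlap(synth_image_pair(spec, s))
                              for s in seeds]))

    lo, hi = 0.0, 1.0
    f_lo, f_hi = measure(lo), measure(hi)
    if not f_lo <= target <= f_hi:
        raise ValueError(
            f"target {target} outside achievable range [{f_lo:.3f}, {f_hi:.3f}]"
            " for this spec; adjust n_ch2_only or background"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = measure(mid)
        if abs(f_mid - target) < tol:
            return mid
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
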