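"""Spatial-frequency filtered scene stimuli and band-limited noise.

Scene photographs are turned into full-spectrum (FS), low-spatial-frequency
(LSF) and high-spatial-frequency (HSF) versions by multiplying a Butterworth
gain with the Fourier amplitude spectrum while leaving the phase spectrum
untouched, then jointly normalizing contrast and luminance so all three
versions have equal mean and standard deviation and span [0, 1] together.
Frequencies are expressed in cycles per degree (cpd) of visual angle; the
default field of view is 22.7° × 17°.

Band-limited noise stimuli are synthesized by imposing a band-pass
Butterworth amplitude on a random phase spectrum and inverse-transforming
to image space.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import stats as _sps

__all__ = [
    "GrayImage",
    "FrequencyFilter",
    "StimulusTriplet",
    "NoiseSpec",
    "butterworth_gain",
    "radial_frequency_grid",
    "apply_frequency_filter",
    "joint_contrast_normalize",
    "make_triplet",
    "cpd_to_cpi",
    "synthesize_noise",
    "load_image",
    "save_image",
    "generate_stimulus_set",
]

DEFAULT_FOV_DEG = (22.7, 17.0)  # (width, height) in degrees of visual angle
DEFAULT_SHAPE = (600, 800)  # (H, W) pixels for the default field of view

# Rec. 601 luma weights for converting RGB photographs to luminance.
_REC601 = np.array([0.299, 0.587, 0.114])


class StimulusError(ValueError):
    """Invalid stimulus parameters or degenerate image input."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D luminance matrix with an angular field of view.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Dimensionless luminance values; finite. Normalized stimuli live in
        [0, 1], filtered intermediates may be signed.
    fov_deg : tuple of float
        (width°, height°) angular extent of the image.
    """

    pixels: np.ndarray
    fov_deg: tuple[float, float] = DEFAULT_FOV_DEG

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise StimulusError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise StimulusError("pixels contain non-finite values")
        w, h = self.fov_deg
        if w <= 0 or h <= 0:
            raise StimulusError(f"fov_deg must be strictly positive, got {self.fov_deg}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "fov_deg", (float(w), float(h)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class FrequencyFilter:
    """Parametric Butterworth gain specification in cycles per degree.

    ``kind`` is one of ``lowpass``, ``highpass``, ``bandpass``. For the
    band-pass case ``cutoff_cpd`` is a (lower, upper) pair and the gain is
    the product of a high-pass at the lower edge and a low-pass at the
    upper edge. The gain is bounded in [0, 1] with the half-power point
    (1/sqrt(2)) at each cutoff.
    """

    kind: str
    cutoff_cpd: float | tuple[float, float]
    order: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise StimulusError(f"unknown filter kind {self.kind!r}")
        if self.order < 1 or int(self.order) != self.order:
            raise StimulusError(f"order must be a positive integer, got {self.order}")
        if self.kind == "bandpass":
            if isinstance(self.cutoff_cpd, numbers.Real):
                raise StimulusError("bandpass filter needs a (lower, upper) cutoff pair")
            lo, hi = self.cutoff_cpd
            if lo <= 0 or hi <= 0:
                raise StimulusError(f"cutoffs must be positive, got {self.cutoff_cpd}")
            if not lo < hi:
                raise StimulusError(f"bandpass needs lower < upper, got {self.cutoff_cpd}")
            object.__setattr__(self, "cutoff_cpd", (float(lo), float(hi)))
        else:
            fc = float(self.cutoff_cpd)
            if fc <= 0:
                raise StimulusError(f"cutoff must be positive, got {fc}")
            object.__setattr__(self, "cutoff_cpd", fc)

    def gain(self, f) -> np.ndarray:
        return butterworth_gain(f, self)


def _lowpass_gain(f: np.ndarray, fc: float, n: int) -> np.ndarray:
    # 1/sqrt(1 + (f/fc)^(2n)) in an overflow-safe form
    return fc**n / np.sqrt(f ** (2 * n) + fc ** (2 * n))


def _highpass_gain(f: np.ndarray, fc: float, n: int) -> np.ndarray:
    # 1/sqrt(1 + (fc/f)^(2n)); gain(0) = 0
    return f**n / np.sqrt(f ** (2 * n) + fc ** (2 * n))


def butterworth_gain(f, filt: FrequencyFilter) -> np.ndarray:
    """Evaluate the Butterworth gain of ``filt`` at frequency ``f`` (cpd).

    The low-pass gain is ``1/sqrt(1 + (f/fc)^(2n))``, the high-pass gain
    ``1/sqrt(1 + (fc/f)^(2n))`` with ``gain(0) = 0``, and the band-pass gain
    the product of a high-pass at the lower edge with a low-pass at the
    upper edge. Accepts scalars or arrays; ``f`` must be non-negative.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise StimulusError("frequencies must be non-negative")
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    n = int(filt.order)
    if filt.kind == "lowpass":
        g = _lowpass_gain(f, filt.cutoff_cpd, n)
    elif filt.kind == "highpass":
        g = _highpass_gain(f, filt.cutoff_cpd, n)
    else:
        lo, hi = filt.cutoff_cpd
        g = _highpass_gain(f, lo, n) * _lowpass_gain(f, hi, n)
    g = np.clip(g, 0.0, 1.0)  # guard against float round-off above 1
    return float(g[0]) if scalar else g


def radial_frequency_grid(shape: tuple[int, int], fov_deg=DEFAULT_FOV_DEG) -> np.ndarray:
    """Radial spatial frequency (cpd) at each discrete Fourier coefficient.

    Entry (u, v) — u, v signed integer cycle counts per image axis, DC at
    index 0 — equals sqrt((u/height°)² + (v/width°)²). The grid is even
    under negation of either axis, matching the conjugate symmetry of the
    spectrum of a real image.
    """
    H, W = shape
    if H < 2 or W < 2:
        raise StimulusError(f"grid needs at least 2 samples per axis, got {shape}")
    w_deg, h_deg = fov_deg
    fy = np.fft.fftfreq(H, d=1.0 / H) / h_deg  # cycles per degree along height
    fx = np.fft.fftfreq(W, d=1.0 / W) / w_deg  # cycles per degree along width
    return np.hypot(fy[:, None], fx[None, :])


def apply_frequency_filter(img: GrayImage, filt: FrequencyFilter) -> GrayImage:
    """Filter ``img`` by scaling its Fourier amplitudes, preserving phase.

    The real-valued gain multiplies each complex Fourier coefficient, so the
    amplitude spectrum is attenuated while the phase spectrum is unchanged.
    The output is the real part of the inverse transform (imaginary residue
    is at numerical noise level) and is a signed intermediate — not yet
    normalized to [0, 1].
    """
    grid = radial_frequency_grid(img.shape, img.fov_deg)
    spec = np.fft.fft2(img.pixels)
    out = np.fft.ifft2(spec * butterworth_gain(grid, filt)).real
    return GrayImage(out, img.fov_deg)


def joint_contrast_normalize(images: list[GrayImage]) -> list[GrayImage]:
    """Equalize contrast and luminance across a set of images.

    Each image is first z-scored on its own (zero mean, unit SD), then a
    single affine map — the same for all images — sends the pooled minimum
    to 0 and the pooled maximum to 1. All outputs therefore share identical
    mean and identical standard deviation, and the pooled dynamic range is
    exactly [0, 1].
    """
    if not images:
        raise StimulusError("empty image list")
    z = []
    for i, im in enumerate(images):
        sd = im.pixels.std()
        if sd == 0:
            raise StimulusError(f"image {i} has zero variance; cannot normalize contrast")
        z.append((im.pixels - im.pixels.mean()) / sd)
    lo = min(zi.min() for zi in z)
    hi = max(zi.max() for zi in z)
    if hi == lo:  # all-identical degenerate set; cannot span [0, 1]
        raise StimulusError("degenerate set: pooled range collapses to a point")
    a = 1.0 / (hi - lo)
    return [GrayImage(a * (zi - lo), im.fov_deg) for zi, im in zip(z, images)]


@dataclass(frozen=True)
class StimulusTriplet:
    """Jointly normalized FS / LSF / HSF versions of one scene image."""

    fs: GrayImage
    lsf: GrayImage
    hsf: GrayImage

    def __post_init__(self) -> None:
        shapes = {self.fs.shape, self.lsf.shape, self.hsf.shape}
        fovs = {self.fs.fov_deg, self.lsf.fov_deg, self.hsf.fov_deg}
        if len(shapes) != 1 or len(fovs) != 1:
            raise StimulusError("triplet members must share dimensions and field of view")

    def __iter__(self):
        return iter((self.fs, self.lsf, self.hsf))


def make_triplet(
    img: GrayImage,
    lsf_cutoff_cpd: float = 0.75,
    hsf_cutoff_cpd: float = 6.0,
    order: int = 2,
) -> StimulusTriplet:
    """Produce the contrast- and luminance-matched FS/LSF/HSF triplet.

    FS is the unfiltered image; LSF keeps frequencies below
    ``lsf_cutoff_cpd`` (default 0.75 cpd); HSF keeps frequencies above
    ``hsf_cutoff_cpd`` (default 6 cpd). The HSF contrast polarity is chosen
    to show dark edges on a light background: the signed high-pass output is
    negated whenever its skewness would place the extreme edge values on the
    light side. All three are jointly normalized.
    """
    if not lsf_cutoff_cpd < hsf_cutoff_cpd:
        raise StimulusError("LSF cutoff must be below HSF cutoff")
    lsf = apply_frequency_filter(img, FrequencyFilter("lowpass", lsf_cutoff_cpd, order))
    hsf = apply_frequency_filter(img, FrequencyFilter("highpass", hsf_cutoff_cpd, order))
    # Dark edges: the heavy tail of the signed edge distribution must point
    # down so that, after normalization, edge extremes map near 0 (dark).
    if _sps.skew(hsf.pixels, axis=None) > 0:
        hsf = GrayImage(-hsf.pixels, hsf.fov_deg)
    fs_n, lsf_n, hsf_n = joint_contrast_normalize([img, lsf, hsf])
    return StimulusTriplet(fs_n, lsf_n, hsf_n)


def cpd_to_cpi(f_cpd: float, fov_width_deg: float = DEFAULT_FOV_DEG[0]) -> int:
    """Convert cycles per degree to integer cycles per image width.

    Round-half-up to the nearest integer: 0.75 cpd over a 22.7° image gives
    17 cpi, 6 cpd gives 136 cpi.
    """
    if f_cpd <= 0 or fov_width_deg <= 0:
        raise StimulusError("frequency and field width must be positive")
    return int(np.floor(f_cpd * fov_width_deg + 0.5))


@dataclass(frozen=True)
class NoiseSpec:
    """Band-limited noise specification.

    ``center_cpd`` is the band center; the band edges are
    ``center * 2**(±bandwidth_octaves/2)`` with Butterworth roll-off of
    ``edge_order`` at each edge. The default one-octave band with order-4
    edges concentrates ≥90% of the spectral energy within one octave of the
    center.
    """

    center_cpd: float
    bandwidth_octaves: float = 1.0
    seed: int = 0
    edge_order: int = 4

    def __post_init__(self) -> None:
        if self.center_cpd <= 0:
            raise StimulusError("center_cpd must be positive")
        if self.bandwidth_octaves <= 0:
            raise StimulusError("bandwidth_octaves must be positive")

    @property
    def band_edges(self) -> tuple[float, float]:
        half = 2.0 ** (self.bandwidth_octaves / 2.0)
        return self.center_cpd / half, self.center_cpd * half


def synthesize_noise(
    spec: NoiseSpec,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    fov_deg=DEFAULT_FOV_DEG,
    target_mean: float = 0.5,
    target_sd: float = 0.2,
) -> GrayImage:
    """Synthesize a band-limited random-phase noise stimulus.

    A uniform amplitude spectrum is band-pass filtered by the Butterworth
    gain of ``spec`` and combined with a random phase spectrum (conjugate
    symmetric, so the image is real). The result is rescaled to
    ``target_mean`` / ``target_sd`` so noise stimuli match the luminance and
    contrast of the scene stimulus set. Deterministic given ``spec.seed``.
    """
    lo, hi = spec.band_edges
    w_deg, h_deg = fov_deg
    nyquist = min(shape[0] / 2.0 / h_deg, shape[1] / 2.0 / w_deg)
    if hi > nyquist:
        raise StimulusError(
            f"band edge {hi:.3g} cpd exceeds the Nyquist frequency {nyquist:.3g} cpd"
        )
    amplitude = butterworth_gain(
        radial_frequency_grid(shape, fov_deg),
        FrequencyFilter("bandpass", (lo, hi), spec.edge_order),
    )
    # Random phase with the conjugate symmetry of a real image: take the
    # phase of the spectrum of white Gaussian noise.
    rng = np.random.default_rng(spec.seed)
    phase = np.angle(np.fft.fft2(rng.standard_normal(shape)))
    img = np.fft.ifft2(amplitude * np.exp(1j * phase)).real
    sd = img.std()
    if sd == 0:
        raise StimulusError("degenerate noise image (empty band?)")
    img = (img - img.mean()) / sd * target_sd + target_mean
    return GrayImage(img, fov_deg)


# ---------------------------------------------------------------------------
# Image file I/O


def load_image(path: str | Path, fov_deg=DEFAULT_FOV_DEG) -> GrayImage:
    """Read a PNG/JPEG file as a luminance image in [0, 1].

    Color inputs are converted with the Rec. 601 weighting.
    """
    arr = np.asarray(Image.open(path), dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _REC601
    return GrayImage(arr / 255.0, fov_deg)


def save_image(img: GrayImage, path: str | Path) -> None:
    """Write a [0, 1] luminance image as 8-bit grayscale PNG."""
    px = np.clip(img.pixels, 0.0, 1.0)
    Image.fromarray(np.round(px * 255.0).astype(np.uint8)).save(path)


def generate_stimulus_set(
    input_paths: dict[str, list[str | Path]],
    out_dir: str | Path,
    lsf_cutoff_cpd: float = 0.75,
    hsf_cutoff_cpd: float = 6.0,
    order: int = 2,
    fov_deg=DEFAULT_FOV_DEG,
    noise_bands_cpd=(0.75, 1.5, 3.0, 6.0),
    n_noise_per_band: int = 60,
    noise_shape: tuple[int, int] = DEFAULT_SHAPE,
    seed: int = 0,
):
    """Build the full stimulus set: scene triplets plus noise stimuli.

    ``input_paths`` maps a category name to its photograph files. Writes PNG
    stimuli plus a TSV manifest (stimulus_id, category, condition, seed,
    source_file) to ``out_dir`` and returns the manifest as a DataFrame.
    Noise targets for mean/SD are taken from the generated scene stimuli so
    the whole set is luminance- and contrast-matched.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    means, sds = [], []
    for category, paths in input_paths.items():
        for j, p in enumerate(paths):
            trip = make_triplet(load_image(p, fov_deg), lsf_cutoff_cpd, hsf_cutoff_cpd, order)
            for cond, im in zip(("FS", "LSF", "HSF"), trip):
                sid = f"{category}_{j:03d}_{cond}"
                save_image(im, out_dir / f"{sid}.png")
                rows.append((sid, category, cond, "", str(p)))
                means.append(im.pixels.mean())
                sds.append(im.pixels.std())
    target_mean = float(np.mean(means)) if means else 0.5
    target_sd = float(np.mean(sds)) if sds else 0.2
    rng = np.random.default_rng(seed)
    for band in noise_bands_cpd:
        for j in range(n_noise_per_band):
            sub = int(rng.integers(2**31))
            im = synthesize_noise(
                NoiseSpec(band, seed=sub), noise_shape, fov_deg, target_mean, target_sd
            )
            sid = f"noise_{band:g}cpd_{j:03d}"
            save_image(im, out_dir / f"{sid}.png")
            rows.append((sid, "", f"noise_{band:g}", str(sub), ""))
    manifest = pd.DataFrame(
        rows, columns=["stimulus_id", "category", "condition", "seed", "source_file"]
    )
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
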