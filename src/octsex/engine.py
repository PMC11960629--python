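"""SD-OCT forward model and B-scan reconstruction.

Spectral-domain OCT acquires, at each lateral beam position, an
interference spectrum between a reference field and the light backscattered
from depth.  A reflector at depth ``z`` imprints a cosine fringe of phase
``2kz`` on the spectrum; the depth-resolved amplitude profile (A-line) is
the envelope — the magnitude — of the Fourier transform of that spectrum
over wavenumber.  A B-scan is a stack of adjacent A-lines.

The processing chain mirrors a standard SD-OCT pipeline: reference
background subtraction, FFT envelope, per-image normalization by the
maximum envelope amplitude, logarithmic dynamic-range compression and
8-bit quantization.

Conventions
-----------
* Spectra are sampled uniformly in wavenumber (ideal spectrometer); the
  sample spacing is chosen so that one FFT bin equals one depth pixel of
  ``depth_pitch_um``.
* Reflectivity-map values are treated as field amplitudes, scaled by a
  small ``sample_scale`` so the reference beam dominates and sample-arm
  autocorrelation terms are negligible — the linear-imaging regime of a
  real system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import ReflectivityMap, ScanGeometry

__all__ = [
    "SourceSpectrum",
    "ScanConfig",
    "Interferogram",
    "BScan",
    "simulate_interferogram",
    "reconstruct_aline",
    "normalize_bscan",
    "log_compress_to_u8",
    "scan_bscan",
    "axial_resolution_um",
]


@dataclass(frozen=True)
class SourceSpectrum:
    """Gaussian broadband source sampled uniformly in wavenumber.

    The 31 nm default bandwidth makes the coherence length — the axial
    resolution — come out at ≈10 µm for an 840 nm center wavelength via
    l_c = (2 ln 2 / π) · λ₀² / Δλ.
    """

    center_wavelength_nm: float = 840.0
    fwhm_bandwidth_nm: float = 31.0
    n_spectral_samples: int = 2048

    def __post_init__(self) -> None:
        if self.center_wavelength_nm <= 0 or self.fwhm_bandwidth_nm <= 0:
            raise ValueError("wavelength and bandwidth must be positive")
        n = self.n_spectral_samples
        if n < 2 or (n & (n - 1)) != 0:
            raise ValueError("n_spectral_samples must be a power of two")

    @property
    def center_wavenumber(self) -> float:
        """k₀ in rad/µm."""
        return 2.0 * np.pi / (self.center_wavelength_nm * 1e-3)

    @property
    def fwhm_wavenumber(self) -> float:
        """FWHM of the power spectrum in rad/µm."""
        lam = self.center_wavelength_nm * 1e-3
        return 2.0 * np.pi * (self.fwhm_bandwidth_nm * 1e-3) / lam**2

    def wavenumbers(self, depth_pitch_um: float) -> np.ndarray:
        """Sampling grid in k chosen so one FFT bin spans one depth pixel."""
        n = self.n_spectral_samples
        dk = np.pi / (depth_pitch_um * n)
        return self.center_wavenumber + (np.arange(n) - n / 2) * dk

    def envelope(self, k: np.ndarray) -> np.ndarray:
        """Gaussian source power envelope S(k), peak 1."""
        return np.exp(-4.0 * np.log(2.0) * ((k - self.center_wavenumber) / self.fwhm_wavenumber) ** 2)


def axial_resolution_um(source: SourceSpectrum) -> float:
    """Closed-form coherence length (axial PSF FWHM), l_c = 4 ln2 / Δk."""
    return 4.0 * np.log(2.0) / source.fwhm_wavenumber


@dataclass(frozen=True)
class ScanConfig:
    """B-scan geometry: 4×4 mm field at 1000×1000 px, stored as 1000×600.

    The acquisition grid is ``depth_pixels`` rows deep; stored images keep
    only the top ``depth_crop`` rows, which contain the tissue.
    """

    lateral_fov_mm: float = 4.0
    n_alines: int = 1000
    depth_pixels: int = 1000
    depth_crop: int = 600
    depth_pitch_um: float = 4.0

    def __post_init__(self) -> None:
        if self.depth_crop > self.depth_pixels:
            raise ValueError("depth_crop cannot exceed depth_pixels")
        if min(self.lateral_fov_mm, self.n_alines, self.depth_pixels, self.depth_pitch_um) <= 0:
            raise ValueError("scan geometry values must be positive")

    @property
    def lateral_pitch_um(self) -> float:
        return 1000.0 * self.lateral_fov_mm / self.n_alines

    def geometry(self) -> ScanGeometry:
        """Acquisition grid (pre-crop) for rasterizing phantoms."""
        return ScanGeometry(
            n_depth=self.depth_pixels,
            n_lateral=self.n_alines,
            depth_pitch_um=self.depth_pitch_um,
            lateral_pitch_um=self.lateral_pitch_um,
        )


@dataclass
class Interferogram:
    """One detected spectrum: nonnegative intensity per wavenumber sample."""

    intensities: np.ndarray
    depth_pitch_um: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 1:
            raise ValueError("interferogram must be a 1-D intensity vector")
        if self.intensities.size and self.intensities.min() < -1e-12:
            raise ValueError("intensities must be nonnegative")


@dataclass
class BScan:
    """Reconstructed 8-bit grayscale cross-section plus acquisition metadata."""

    pixels: np.ndarray
    chick_id: int = -1
    frame_index: int = -1
    label: str = ""
    quality_score: float = float("nan")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise ValueError("B-scan pixels must be uint8")


_REFERENCE_AMPLITUDE = 1.0
_SAMPLE_SCALE = 1e-3  # field-amplitude scale of the sample arm relative to reference


def simulate_interferogram(
    profile: np.ndarray,
    source: SourceSpectrum | None = None,
    depth_pitch_um: float = 4.0,
    sample_scale: float = _SAMPLE_SCALE,
) -> Interferogram:
    """Synthesize the spectrum detected for one depth reflectivity profile.

    ``profile[i]`` is the field reflectivity at depth ``i · depth_pitch_um``.
    The detected intensity is the source envelope times the squared
    magnitude of the total field — reference plus each reflector delayed by
    phase ``2kz`` — so it contains the DC terms, the imaging cross terms
    and the (tiny) sample autocorrelation, as in a real spectrometer.
    """
    source = source or SourceSpectrum()
    profile = np.asarray(profile, dtype=np.float64)
    if profile.size == 0:
        raise ValueError("empty reflectivity profile")
    if profile.min() < 0 or profile.max() > 1:
        raise ValueError("profile values must lie in [0, 1]")

    k = source.wavenumbers(depth_pitch_um)
    z = np.arange(profile.size) * depth_pitch_um
    field = _REFERENCE_AMPLITUDE + (np.exp(2j * np.outer(k, z)) @ (sample_scale * profile))
    intensities = source.envelope(k) * np.abs(field) ** 2
    return Interferogram(intensities=intensities, depth_pitch_um=depth_pitch_um)


def reference_background(source: SourceSpectrum, depth_pitch_um: float = 4.0) -> np.ndarray:
    """Reference-arm-only spectrum: what the detector sees with no sample."""
    k = source.wavenumbers(depth_pitch_um)
    return source.envelope(k) * _REFERENCE_AMPLITUDE**2


def reconstruct_aline(
    ig: Interferogram,
    depth_pixels: int,
    source: SourceSpectrum | None = None,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Envelope of the Fourier-transformed spectrum over positive depths.

    The reference background is removed first — otherwise its DC peak would
    dominate the envelope maximum used later as the normalization factor.
    An explicit ``background`` spectrum takes precedence; with only a
    ``source`` the reference term is estimated by projecting the measured
    spectrum onto the source envelope shape.
    """
    sig = ig.intensities
    if source is not None and sig.size != source.n_spectral_samples:
        raise ValueError(
            f"interferogram length {sig.size} does not match the configured "
            f"{source.n_spectral_samples} spectral samples"
        )
    if depth_pixels > sig.size // 2:
        raise ValueError("depth_pixels exceeds the positive-frequency range")

    if background is not None:
        sig = sig - background
    elif source is not None:
        env = source.envelope(source.wavenumbers(ig.depth_pitch_um))
        sig = sig - env * (sig @ env) / (env @ env)
    else:
        sig = sig - sig.mean()

    return np.abs(np.fft.fft(sig))[:depth_pixels]


def normalize_bscan(amplitudes: np.ndarray) -> np.ndarray:
    """Divide the whole envelope grid by its maximum amplitude.

    The per-image maximum is the reference scaling factor; the output
    maximum is exactly 1.0 and value ordering is preserved.
    """
    amplitudes = np.asarray(amplitudes, dtype=np.float64)
    peak = amplitudes.max(initial=0.0)
    if peak <= 0.0:
        raise ValueError("cannot normalize an all-zero envelope (no scale factor)")
    return amplitudes / peak


def log_compress_to_u8(normalized: np.ndarray, floor_db: float = -50.0) -> np.ndarray:
    """Map normalized envelope amplitudes to 8-bit via a dB-linear ramp.

    ``u8 = round(255 · clip(1 + dB(x)/|floor_db|, 0, 1))`` with
    ``dB(x) = 20 log10(x)``: amplitude 1.0 maps to 255, anything at or
    below the floor maps to 0, and the mapping is monotone.
    """
    if floor_db >= 0:
        raise ValueError("floor_db must be negative (a dynamic-range floor)")
    x = np.asarray(normalized, dtype=np.float64)
    if x.size and (x.min() < 0 or x.max() > 1.0 + 1e-9):
        raise ValueError("normalized amplitudes must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(np.clip(x, 0.0, 1.0))
    ramp = np.clip(1.0 + db / abs(floor_db), 0.0, 1.0)
    return np.rint(255.0 * ramp).astype(np.uint8)


def scan_bscan(
    rmap: ReflectivityMap,
    source: SourceSpectrum | None = None,
    config: ScanConfig | None = None,
    speckle_scale: float = 0.0,
    noise_floor: float = 0.0,
    floor_db: float = -50.0,
    rng: np.random.Generator | int | None = None,
    chick_id: int = -1,
    frame_index: int = -1,
    label: str = "",
) -> BScan:
    """Simulate and reconstruct a full B-scan from a reflectivity map.

    One spectrum is synthesized and reconstructed per lateral column (all
    columns batched through a single matrix product and FFT).  Speckle is
    modelled as multiplicative gamma noise of unit mean and relative
    standard deviation ``speckle_scale`` on the envelope amplitudes;
    ``noise_floor`` adds a Rayleigh-distributed detector floor expressed
    relative to the envelope maximum.  The envelope stack is cropped to the
    top ``depth_crop`` rows, normalized to its maximum and log-compressed
    to 8 bits.
    """
    source = source or SourceSpectrum()
    config = config or ScanConfig()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    values = rmap.values
    if values.shape != (config.depth_pixels, config.n_alines):
        raise ValueError(
            f"reflectivity map shape {values.shape} does not match scan geometry "
            f"({config.depth_pixels}, {config.n_alines})"
        )
    if config.depth_pixels > source.n_spectral_samples // 2:
        raise ValueError("depth_pixels exceeds the spectrometer's positive-frequency range")

    k = source.wavenumbers(config.depth_pitch_um)
    z = np.arange(config.depth_pixels) * config.depth_pitch_um
    phases = np.exp(2j * np.outer(k, z)).astype(np.complex64)
    fields = _REFERENCE_AMPLITUDE + phases @ (_SAMPLE_SCALE * values).astype(np.complex64)
    env_k = source.envelope(k)
    intensities = env_k[:, None] * np.abs(fields).astype(np.float64) ** 2
    intensities -= reference_background(source, config.depth_pitch_um)[:, None]

    envelopes = np.abs(np.fft.fft(intensities, axis=0))[: config.depth_pixels]

    if speckle_scale > 0:
        shape = 1.0 / speckle_scale**2
        envelopes = envelopes * rng.gamma(shape, 1.0 / shape, size=envelopes.shape)
    if noise_floor > 0:
        peak = envelopes.max(initial=0.0)
        scale = noise_floor * (peak if peak > 0 else 1.0)
        envelopes = envelopes + rng.rayleigh(scale, size=envelopes.shape)

    cropped = envelopes[: config.depth_crop]
    pixels = log_compress_to_u8(normalize_bscan(cropped), floor_db=floor_db)
    return BScan(
        pixels=pixels,
        chick_id=chick_id,
        frame_index=frame_index,
        label=label,
    )
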