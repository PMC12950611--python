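"""Acquisition constants of the pulse-sampling FLIm instrument.

The instrument delivers 355-nm pulsed excitation through a single fiber at a
460-Hz repetition rate while the biopsy core is translated at 2.5 mm/s under
the probe.  Fluorescence decays are resolved simultaneously in four spectral
bands matched to the emission of endogenous fluorophores (collagen /
proteoglycans, NAD(P)H, FAD, porphyrins) and digitized at 2.5 GS/s.
Consecutive pulses are averaged in blocks of four, so one point measurement
is produced every ``scan_speed * avg_factor / rep_rate`` of travel
(~22 um with the default constants).

Everything downstream (simulator, deconvolution, registration, QC) derives
its geometry from :class:`InstrumentConfig` rather than hard-coding numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "SpectralBand",
    "InstrumentConfig",
    "DEFAULT_BANDS",
    "default_instrument",
    "gaussian_irf",
    "point_spacing_um",
]


@dataclass(frozen=True)
class SpectralBand:
    """One detection channel of the wavelength-selection module."""

    name: str
    center_nm: float
    halfwidth_nm: float
    fluorophore_tag: str = ""

    def __post_init__(self):
        if self.center_nm <= 0 or self.halfwidth_nm <= 0:
            raise InvalidParameterError(
                f"band {self.name!r}: center and halfwidth must be positive"
            )


#: The four default detection bands (center +/- halfwidth, nm).
DEFAULT_BANDS: List[SpectralBand] = [
    SpectralBand("band390", 390.0, 20.0, "collagen/proteoglycans"),
    SpectralBand("band470", 470.0, 14.0, "NAD(P)H"),
    SpectralBand("band542", 542.0, 25.0, "FAD"),
    SpectralBand("band629", 629.0, 26.5, "porphyrins/lipofuscin"),
]


def gaussian_irf(
    n_samples: int,
    sample_rate_gsps: float,
    fwhm_ns: float = 1.5,
    peak_ns: float = 16.0,
) -> np.ndarray:
    """Normalized Gaussian instrument response kernel on the digitizer grid.

    ``peak_ns`` places the excitation pulse away from the start of the
    record so that a pre-pulse baseline region exists (used for background
    subtraction).  The kernel is truncated at t=0 and normalized to unit sum.
    """
    if fwhm_ns <= 0 or n_samples < 1:
        raise InvalidParameterError("fwhm_ns and n_samples must be positive")
    dt = 1.0 / sample_rate_gsps
    t = np.arange(n_samples) * dt
    sigma = fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    k = np.exp(-0.5 * ((t - peak_ns) / sigma) ** 2)
    s = k.sum()
    if s <= 0:
        raise InvalidParameterError("IRF kernel sums to zero")
    return k / s


@dataclass
class InstrumentConfig:
    """Fixed acquisition constants from which all geometry derives.

    Units: rates in Hz / GS/s, speeds in mm/s, wavelengths in nm,
    the digitizer step is ``1 / sample_rate_gsps`` nanoseconds.
    """

    rep_rate_hz: float = 460.0
    sample_rate_gsps: float = 2.5
    scan_speed_mm_s: float = 2.5
    avg_factor: int = 4
    excitation_nm: float = 355.0
    lateral_resolution_um: float = 400.0
    n_samples: int = 680
    bands: List[SpectralBand] = field(default_factory=lambda: list(DEFAULT_BANDS))
    #: per-band instrument response kernels; ``None`` entries fall back to
    #: a normalized Gaussian of ``irf_fwhm_ns`` peaking at ``irf_peak_ns``.
    irf: Optional[Dict[str, np.ndarray]] = None
    irf_fwhm_ns: float = 1.5
    irf_peak_ns: float = 16.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.rep_rate_hz <= 0:
            raise InvalidParameterError("rep_rate_hz must be positive")
        if self.sample_rate_gsps <= 0:
            raise InvalidParameterError("sample_rate_gsps must be positive")
        if self.scan_speed_mm_s < 0:
            raise InvalidParameterError("scan_speed_mm_s must be nonnegative")
        if self.avg_factor < 1:
            raise InvalidParameterError("avg_factor must be >= 1")
        if self.n_samples < 2:
            raise InvalidParameterError("n_samples must be >= 2")
        if self.irf is not None:
            for name, k in self.irf.items():
                k = np.asarray(k, float)
                if np.any(k < 0) or k.sum() <= 0:
                    raise InvalidParameterError(
                        f"IRF for {name!r} must be nonnegative with positive sum"
                    )

    # -- derived quantities -------------------------------------------------

    @property
    def dt_ns(self) -> float:
        """Digitizer sampling step in nanoseconds."""
        return 1.0 / self.sample_rate_gsps

    @property
    def time_axis_ns(self) -> np.ndarray:
        """t(n) = n * dt, 0-based sample indexing."""
        return np.arange(self.n_samples) * self.dt_ns

    @property
    def band_names(self) -> List[str]:
        return [b.name for b in self.bands]

    def band_irf(self, name: str) -> np.ndarray:
        """IRF kernel for one band (explicit if given, Gaussian default)."""
        if self.irf is not None and name in self.irf:
            return np.asarray(self.irf[name], float)
        return gaussian_irf(
            self.n_samples, self.sample_rate_gsps, self.irf_fwhm_ns, self.irf_peak_ns
        )

    def with_(self, **kwargs) -> "InstrumentConfig":
        return replace(self, **kwargs)


def default_instrument(**overrides) -> InstrumentConfig:
    return InstrumentConfig(**overrides)


def point_spacing_um(config: InstrumentConfig) -> float:
    """Distance between consecutive point measurements, in micrometers.

    One point is emitted per block of ``avg_factor`` laser pulses while the
    stage moves at ``scan_speed_mm_s``, so the spacing is
    ``scan_speed * avg_factor / rep_rate``.  The exact (unrounded) value is
    returned; with the default constants it rounds to 22 um.
    """
    mm = config.scan_speed_mm_s * (config.avg_factor / config.rep_rate_hz)
    return mm * 1000.0
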