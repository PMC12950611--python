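"""Derived protocol constants and the reference clinical cohort composition.

The scan protocol fixes a handful of numbers that recur throughout the
analysis: the point spacing (~22 um), the physical extent of the 25-point
transition-exclusion zone (~0.54 mm), the 18-point smoothing window used by
the repeatability statistic (~0.4 mm), the ratio of point spacing to the
400-um lateral resolution (~5%, the effective independent-sample fraction),
and the classifier feature count (4 bands x (1 lifetime + 12 Laguerre
coefficients) = 52).  They are all derived here from
:class:`~flimcore.instrument.InstrumentConfig` so a config change propagates
consistently.

``REFERENCE_COHORT_POINTS`` records the per-class labeled point counts of
the 20-patient / 133-core clinical feasibility cohort whose protocol this
package follows.  The clinical waveforms themselves are not public; the
counts serve as the prevalence reference for the synthetic cohort and as a
bookkeeping cross-check (they sum to 91,213).
"""

from __future__ import annotations

from typing import Dict

from .instrument import InstrumentConfig, point_spacing_um

__all__ = [
    "REFERENCE_COHORT_POINTS",
    "REFERENCE_N_PATIENTS",
    "REFERENCE_N_CORES",
    "total_reference_points",
    "TRANSITION_EXCLUSION_POINTS",
    "SMOOTHING_WINDOW_POINTS",
    "LAGUERRE_ORDER",
    "n_stored_features",
    "n_classifier_features",
    "protocol_constants",
]

#: Labeled FLIm point measurements per tissue class in the reference cohort.
REFERENCE_COHORT_POINTS: Dict[str, int] = {
    "benign": 80614,
    "GP3": 3936,
    "GP4_noncribriform": 4562,
    "GP4_cribriform": 2012,
    "GP5": 89,
}

REFERENCE_N_PATIENTS = 20
REFERENCE_N_CORES = 133

#: Points removed on each label transition (straddling it) and the smoothing
#: window of the repeatability statistic, both in point units.
TRANSITION_EXCLUSION_POINTS = 25
SMOOTHING_WINDOW_POINTS = 18

#: Laguerre expansion order used for every spectral band.
LAGUERRE_ORDER = 12


def total_reference_points() -> int:
    """Total labeled points in the reference cohort (sums to 91,213)."""
    return sum(REFERENCE_COHORT_POINTS.values())


def n_stored_features(n_bands: int = 4, order: int = LAGUERRE_ORDER) -> int:
    """Stored parameters per point: per band one lifetime, one intensity
    and ``order`` Laguerre coefficients."""
    return n_bands * (2 + order)


def n_classifier_features(n_bands: int = 4, order: int = LAGUERRE_ORDER) -> int:
    """Classification subset: the stored set minus the per-band intensities."""
    return n_bands * (1 + order)


def protocol_constants(config: InstrumentConfig | None = None) -> Dict[str, float]:
    """All derived protocol constants for a given instrument configuration.

    Returns both exact and conventionally rounded values, the latter being
    the numbers quoted when the protocol is described (22 um, 0.54 mm,
    0.4 mm, 5%).
    """
    if config is None:
        config = InstrumentConfig()
    spacing = point_spacing_um(config)
    excl_mm = TRANSITION_EXCLUSION_POINTS * spacing / 1000.0
    window_mm = SMOOTHING_WINDOW_POINTS * spacing / 1000.0
    eff_frac = spacing / config.lateral_resolution_um
    n_bands = len(config.bands)
    return {
        "point_spacing_um": spacing,
        "point_spacing_um_rounded": round(spacing),
        "transition_exclusion_mm": excl_mm,
        "transition_exclusion_mm_rounded": round(excl_mm, 2),
        "smoothing_window_mm": window_mm,
        "smoothing_window_mm_rounded": round(window_mm, 1),
        "effective_sample_fraction": eff_frac,
        "effective_sample_pct_rounded": round(eff_frac * 100.0),
        "n_stored_features": n_stored_features(n_bands),
        "n_classifier_features": n_classifier_features(n_bands),
    }
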