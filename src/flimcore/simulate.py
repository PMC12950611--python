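"""Synthetic multi-patient biopsy cohort with known ground truth.

The generator emulates the statistical structure the downstream analysis
relies on, without claiming to reproduce real tissue optics:

* four spectral bands with class-specific multi-exponential decays whose
  NAD(P)H-band (470 nm) average lifetime shortens from benign through GP3
  to GP4/GP5, mirroring the glycolytic shift of high-grade tumors;
* patient-level random effects (a per-patient, per-band lifetime offset and
  a patient-specific tissue-class composition), which is what makes naive
  point-level cross-validation optimistic relative to leave-one-patient-out;
* multi-segment cores up to 19 mm scanned bidirectionally: both passes
  share the same true decays, with independent pulse noise (the
  repeatability null), plus an optional drift hook that perturbs pass 1;
* uniform fixation shrinkage/stretching between fresh-core and histology
  coordinates;
* additive zero-mean Gaussian noise on every pre-average pulse, averaged in
  blocks of ``avg_factor`` exactly as the instrument does.

All randomness flows from a single seeded generator, so a cohort is
bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .deconvolve import average_pulses
from .errors import ConfigurationError, InvalidParameterError
from .instrument import InstrumentConfig, point_spacing_um
from .labeling import AnnotationTrack

__all__ = [
    "TissueClassSpec",
    "CoreLayout",
    "CohortConfig",
    "WaveformScan",
    "CohortSample",
    "default_class_specs",
    "true_average_lifetime",
    "apply_shrinkage",
    "sample_cohort",
    "lifetime_trace_pairs",
]

MALIGNANT_CLASSES = ("GP3", "GP4", "GP5")


@dataclass(frozen=True)
class TissueClassSpec:
    """Decay model of one tissue class: per band a list of
    (amplitude_fraction, lifetime_ns) exponential components, plus the
    between-patient and within-core lifetime variability (ns)."""

    label: str
    components: Dict[str, List[Tuple[float, float]]]
    patient_sd_ns: float = 0.40
    point_sd_ns: float = 0.35

    def __post_init__(self):
        for band, comps in self.components.items():
            amps = [a for a, _ in comps]
            taus = [t for _, t in comps]
            if any(t <= 0 for t in taus):
                raise InvalidParameterError(f"{self.label}/{band}: lifetimes must be > 0")
            if abs(sum(amps) - 1.0) > 1e-9:
                raise InvalidParameterError(
                    f"{self.label}/{band}: amplitude fractions must sum to 1"
                )


def default_class_specs() -> Dict[str, TissueClassSpec]:
    """Synthetic default decay parameters (not measured values).

    Chosen so that in the 470-nm band the class-mean average lifetime obeys
    GP5 < GP4 < GP3 < benign with overlap between neighbors, and the other
    bands carry the same ordering with weaker contrast.
    """
    table = {
        "benign": {
            "band390": [(0.5, 5.5), (0.5, 2.5)],
            "band470": [(0.6, 5.0), (0.4, 2.0)],
            "band542": [(0.5, 4.5), (0.5, 2.0)],
            "band629": [(0.6, 6.0), (0.4, 2.5)],
        },
        "GP3": {
            "band390": [(0.5, 5.2), (0.5, 2.4)],
            "band470": [(0.5, 4.2), (0.5, 1.8)],
            "band542": [(0.5, 4.3), (0.5, 1.9)],
            "band629": [(0.6, 5.6), (0.4, 2.4)],
        },
        "GP4": {
            "band390": [(0.5, 5.0), (0.5, 2.3)],
            "band470": [(0.45, 3.5), (0.55, 1.5)],
            "band542": [(0.5, 4.0), (0.5, 1.8)],
            "band629": [(0.6, 5.2), (0.4, 2.3)],
        },
        "GP5": {
            "band390": [(0.5, 4.9), (0.5, 2.2)],
            "band470": [(0.4, 3.2), (0.6, 1.4)],
            "band542": [(0.5, 3.9), (0.5, 1.7)],
            "band629": [(0.6, 5.0), (0.4, 2.2)],
        },
    }
    return {lbl: TissueClassSpec(lbl, comps) for lbl, comps in table.items()}


def true_average_lifetime(spec: TissueClassSpec, band: str, form: str = "intensity") -> float:
    """Ground-truth average lifetime of a class/band decay.

    ``form="intensity"`` returns sum(a t^2)/sum(a t), the center of mass of
    the full decay integral (matches the deconvolution's estimator);
    ``form="amplitude"`` returns sum(a t)/sum(a).
    """
    comps = spec.components[band]
    a = np.array([c[0] for c in comps], float)
    t = np.array([c[1] for c in comps], float)
    if form == "intensity":
        return float((a * t**2).sum() / (a * t).sum())
    if form == "amplitude":
        return float((a * t).sum() / a.sum())
    raise InvalidParameterError(f"unknown lifetime form {form!r}")


@dataclass
class CoreLayout:
    """Ground-truth segmentation of one fresh core into labeled intervals."""

    core_id: str
    patient_id: str
    fresh_length_mm: float
    segments: List[Tuple[str, float, float]]  # (label, start_mm, end_mm)

    def label_at(self, x_mm: float) -> Optional[str]:
        for lbl, s, e in self.segments:
            if s <= x_mm < e or (x_mm == e == self.fresh_length_mm):
                return lbl
        return None


@dataclass
class WaveformScan:
    """One pass of one core: averaged waveforms per band at each position.

    ``positions_mm`` are in acquisition order along the pass direction, so
    the reverse pass (pass_index=1) lists the same physical positions in
    decreasing order.
    """

    core_id: str
    patient_id: str
    pass_index: int
    positions_mm: np.ndarray
    waveforms: Dict[str, np.ndarray]  # band -> (n_positions, n_samples)


@dataclass
class CohortConfig:
    n_patients: int = 20
    cores_per_patient: Tuple[int, int] = (4, 8)
    core_length_mm: Tuple[float, float] = (5.0, 12.0)
    max_core_length_mm: float = 19.0
    min_segment_mm: float = 1.0
    prevalence: Dict[str, float] = field(
        default_factory=lambda: {"benign": 0.60, "GP3": 0.18, "GP4": 0.15, "GP5": 0.07}
    )
    #: concentration of the per-patient Dirichlet around the prevalence
    #: (smaller = more heterogeneous patient composition)
    composition_concentration: float = 20.0
    noise_sd: float = 0.01          # additive pulse noise, fraction of peak
    intensity_sigma: float = 0.15   # lognormal sd of per-point intensity
    shrink_factor_range: Tuple[float, float] = (0.85, 1.15)
    drift_fraction: float = 0.0     # fraction of cores with a pass-1 drift
    drift_delta_ns: float = 0.0     # lifetime offset injected in pass 1
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise InvalidParameterError("n_patients must be >= 2")
        w = list(self.prevalence.values())
        if any(v < 0 for v in w) or sum(w) <= 0:
            raise InvalidParameterError("prevalence weights must be nonnegative, not all zero")
        lo, hi = self.core_length_mm
        if not (0 < lo <= hi <= self.max_core_length_mm):
            raise InvalidParameterError("core_length_mm range invalid")


@dataclass
class CohortSample:
    scans: List[WaveformScan]
    layouts: List[CoreLayout]
    tracks: List[AnnotationTrack]
    truth: pd.DataFrame
    config: CohortConfig
    instrument: InstrumentConfig


def apply_shrinkage(layout: CoreLayout, shrink_factor: float) -> AnnotationTrack:
    """Map a fresh-core layout to histology coordinates under uniform
    deformation: every boundary is multiplied by ``shrink_factor``."""
    if shrink_factor <= 0:
        raise InvalidParameterError("shrink_factor must be > 0")
    intervals = [
        (lbl, s * shrink_factor, e * shrink_factor) for lbl, s, e in layout.segments
    ]
    return AnnotationTrack(
        core_id=layout.core_id,
        histology_length_mm=layout.fresh_length_mm * shrink_factor,
        intervals=intervals,
    )


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _sample_layouts(config: CohortConfig, rng: np.random.Generator,
                    class_labels: Sequence[str]) -> List[CoreLayout]:
    labels = list(class_labels)
    prev = np.array([config.prevalence.get(l, 0.0) for l in labels], float)
    if prev.sum() <= 0:
        raise ConfigurationError("prevalence selects no available class")
    prev = prev / prev.sum()

    # per-patient composition around the prevalence (patient enrichment)
    conc = config.composition_concentration
    patient_w = {}
    for p in range(config.n_patients):
        alpha = np.maximum(prev * conc, 1e-3)
        patient_w[p] = rng.dirichlet(alpha)

    layouts: List[CoreLayout] = []
    cum_len = np.zeros(len(labels))  # self-balancing toward prevalence
    for p in range(config.n_patients):
        pid = f"P{p:02d}"
        lo, hi = config.cores_per_patient
        n_cores = int(rng.integers(lo, hi + 1))
        for c in range(n_cores):
            cid = f"{pid}C{c:02d}"
            length = float(rng.uniform(*config.core_length_mm))
            nseg = int(rng.choice([1, 2, 3, 4], p=[0.50, 0.30, 0.15, 0.05]))
            max_seg = int(length // config.min_segment_mm)
            nseg = max(1, min(nseg, max_seg))
            frac = rng.dirichlet(np.ones(nseg) * 2.0)
            seg_len = config.min_segment_mm + frac * (length - nseg * config.min_segment_mm)
            bounds = np.concatenate([[0.0], np.cumsum(seg_len)])
            bounds[-1] = length
            segments = []
            for s in range(nseg):
                total = max(cum_len.sum(), 1e-9)
                deficit = np.maximum(prev - cum_len / total, 0.01)
                w = patient_w[p] * deficit
                w = w / w.sum()
                lbl = labels[int(rng.choice(len(labels), p=w))]
                segments.append((lbl, float(bounds[s]), float(bounds[s + 1])))
                cum_len[labels.index(lbl)] += seg_len[s]
            layouts.append(CoreLayout(cid, pid, length, segments))
    return layouts


def _ensure_class_coverage(layouts: List[CoreLayout], class_labels: Sequence[str],
                           rng: np.random.Generator) -> None:
    """Relabel segments if needed so every class appears in >= 2 patients
    (required for leave-one-patient-out evaluation of every class)."""
    for lbl in class_labels:
        patients = {l.patient_id for l in layouts for (s, _, _) in l.segments if s == lbl}
        missing = 2 - len(patients)
        if missing <= 0:
            continue
        candidates = [l for l in layouts if l.patient_id not in patients]
        rng.shuffle(candidates)
        seen = set()
        for layout in candidates:
            if missing <= 0:
                break
            if layout.patient_id in seen:
                continue
            # overwrite the longest segment not of a rare class
            idx = max(
                range(len(layout.segments)),
                key=lambda i: layout.segments[i][2] - layout.segments[i][1],
            )
            old, s, e = layout.segments[idx]
            layout.segments[idx] = (lbl, s, e)
            seen.add(layout.patient_id)
            missing -= 1


def _segment_label_per_position(layout: CoreLayout, positions: np.ndarray) -> List[str]:
    out = []
    for x in positions:
        lbl = layout.label_at(float(x))
        out.append(lbl if lbl is not None else layout.segments[-1][0])
    return out


def sample_cohort(
    config: CohortConfig,
    instrument: Optional[InstrumentConfig] = None,
    class_specs: Optional[Dict[str, TissueClassSpec]] = None,
    seed: Optional[int] = None,
) -> CohortSample:
    """Generate a full synthetic cohort: raw averaged waveforms for both
    scan passes of every core, ground-truth layouts, shrunk histology
    annotation tracks and a per-position truth table.

    Deterministic given the seed (``config.rng_seed`` unless overridden).
    """
    if instrument is None:
        instrument = InstrumentConfig()
    if class_specs is None:
        class_specs = default_class_specs()
    for lbl, w in config.prevalence.items():
        if w > 0 and lbl not in class_specs:
            raise ConfigurationError(f"prevalence selects class {lbl!r} with no spec")
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)

    labels = [l for l in class_specs if config.prevalence.get(l, 0.0) > 0]
    layouts = _sample_layouts(config, rng, labels)
    _ensure_class_coverage(layouts, labels, rng)

    spacing_mm = point_spacing_um(instrument) / 1000.0
    n = instrument.n_samples
    t = instrument.time_axis_ns
    band_names = instrument.band_names
    irfs = {b: instrument.band_irf(b) for b in band_names}

    # per-patient, per-band lifetime offsets (class-independent random effect)
    patient_ids = sorted({l.patient_id for l in layouts})
    patient_offset = {
        (pid, b): 0.0 for pid in patient_ids for b in band_names
    }
    for pid in patient_ids:
        for b in band_names:
            sd = np.mean([class_specs[l].patient_sd_ns for l in labels])
            patient_offset[(pid, b)] = float(rng.normal(0.0, sd))

    drift_cores = set()
    if config.drift_fraction > 0:
        k = int(round(config.drift_fraction * len(layouts)))
        idx = rng.choice(len(layouts), size=min(k, len(layouts)), replace=False)
        drift_cores = {layouts[i].core_id for i in idx}

    scans: List[WaveformScan] = []
    tracks: List[AnnotationTrack] = []
    truth_rows = []
    for layout in layouts:
        npos = int(np.floor(layout.fresh_length_mm / spacing_mm))
        positions = np.arange(npos) * spacing_mm
        pos_labels = _segment_label_per_position(layout, positions)
        for x, lbl in zip(positions, pos_labels):
            truth_rows.append((layout.core_id, layout.patient_id, float(x), lbl))

        # per-position draws shared by both passes
        point_jitter = {
            b: rng.normal(0.0, 1.0, npos) for b in band_names
        }
        intensity_scale = np.exp(rng.normal(0.0, config.intensity_sigma, npos))
        drift = config.drift_delta_ns if layout.core_id in drift_cores else 0.0

        per_pass_wf: List[Dict[str, np.ndarray]] = []
        for pass_index in (0, 1):
            wf_bands: Dict[str, np.ndarray] = {}
            for b in band_names:
                H = np.zeros((npos, n))
                for i, lbl in enumerate(pos_labels):
                    spec = class_specs[lbl]
                    off = patient_offset[(layout.patient_id, b)]
                    jit = point_jitter[b][i] * spec.point_sd_ns
                    extra = drift if pass_index == 1 else 0.0
                    for a, tau in spec.components[b]:
                        tau_eff = max(tau + off + jit + extra, 0.2)
                        H[i] += a * np.exp(-t / tau_eff)
                Y = fftconvolve(H, irfs[b][None, :], axes=1)[:, :n]
                peak = Y.max(axis=1, keepdims=True)
                peak[peak <= 0] = 1.0
                Y = Y / peak * intensity_scale[:, None]
                if config.noise_sd > 0:
                    pulses = np.repeat(Y, instrument.avg_factor, axis=0)
                    pulses = pulses + rng.normal(
                        0.0, config.noise_sd, pulses.shape
                    )
                    Y = average_pulses(pulses, instrument.avg_factor)
                # float32 storage: quantization (~1e-7) is far below the
                # pulse noise floor and halves cohort memory
                wf_bands[b] = Y.astype(np.float32)
            per_pass_wf.append(wf_bands)

        scans.append(
            WaveformScan(layout.core_id, layout.patient_id, 0, positions.copy(),
                         per_pass_wf[0])
        )
        rev = slice(None, None, -1)
        scans.append(
            WaveformScan(
                layout.core_id, layout.patient_id, 1, positions[rev].copy(),
                {b: wf[rev].copy() for b, wf in per_pass_wf[1].items()},
            )
        )
        shrink = float(rng.uniform(*config.shrink_factor_range))
        tracks.append(apply_shrinkage(layout, shrink))

    truth = pd.DataFrame(
        truth_rows, columns=["core_id", "patient_id", "position_mm", "label"]
    )
    return CohortSample(scans, layouts, tracks, truth, config, instrument)


def lifetime_trace_pairs(
    n_cores: int,
    n_points: int,
    noise_sd_ns: float,
    seed: int = 0,
    base_lifetime_ns: float = 4.0,
    drift_delta_ns: float = 0.0,
    drift_fraction: float = 0.0,
) -> List[Tuple[np.ndarray, np.ndarray, bool]]:
    """Lightweight repeat-scan lifetime traces for QC calibration studies.

    Each core contributes a pair of lifetime traces sharing the same smooth
    truth with independent additive Gaussian noise; a ``drift_fraction`` of
    cores gets ``drift_delta_ns`` added to the second pass.  Returns
    ``(trace0, trace1, drifted)`` triples.
    """
    rng = np.random.default_rng(seed)
    out = []
    n_drift = int(round(drift_fraction * n_cores))
    drifted = np.zeros(n_cores, bool)
    if n_drift:
        drifted[rng.choice(n_cores, n_drift, replace=False)] = True
    for c in range(n_cores):
        base = base_lifetime_ns + rng.normal(0.0, 0.3)
        truth = np.full(n_points, base)
        t0 = truth + rng.normal(0.0, noise_sd_ns, n_points)
        shift = drift_delta_ns if drifted[c] else 0.0
        t1 = truth + shift + rng.normal(0.0, noise_sd_ns, n_points)
        out.append((t0, t1, bool(drifted[c])))
    return out
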