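"""Single-pulse photoplethysmogram QC and expert-defined features."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

#: samples per pulse waveform
PPG_LENGTH = 100
#: two-sided cohort percentile bounds for the four QC statistics
QC_PERCENTILES = (0.1, 99.9)
#: default notch prominence threshold, fraction of pulse amplitude
NOTCH_PROMINENCE = 0.02


@dataclass
class PPGRecord:
    """One 100-sample pulse in relative amplitude units."""

    samples: np.ndarray
    qc_pass: bool | None = None
    qc_reasons: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (PPG_LENGTH,):
            raise ValueError(
                f"PPG waveform must have {PPG_LENGTH} samples, "
                f"got {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("PPG waveform contains non-finite values")


@dataclass
class PPGEDFs:
    """The five PPG expert-defined features.

    Positions are sample indices in [0, 99]; ``notch_position`` is None
    iff the notch is absent. ``peak_to_peak_time`` is in samples.
    """

    notch_present: bool
    notch_position: int | None
    peak_position: int
    shoulder_position: int
    peak_to_peak_time: float

    def as_array(self) -> np.ndarray:
        notch = self.notch_position if self.notch_present else -1.0
        return np.array([float(self.notch_present), float(notch),
                         float(self.peak_position),
                         float(self.shoulder_position),
                         float(self.peak_to_peak_time)])


EDF_NAMES = ("notch_present", "notch_position", "peak_position",
             "shoulder_position", "peak_to_peak_time")


def ppg_qc(waveforms: np.ndarray,
           percentiles: tuple[float, float] = QC_PERCENTILES,
           min_cohort: int = 1000) -> np.ndarray:
    """Cohort-level keep mask.

    Per waveform, compute min/max/mean/median; keep a waveform iff each of
    the four statistics lies within the cohort's [0.1, 99.9] percentile
    bounds (inclusive) for that statistic. Ordering-invariant.
    """
    x = np.asarray(waveforms, dtype=float)
    if x.ndim != 2 or x.shape[1] != PPG_LENGTH:
        raise ValueError(f"expected (n, {PPG_LENGTH}) waveform matrix")
    if x.shape[0] < min_cohort:
        import warnings
        warnings.warn(f"cohort of {x.shape[0]} < {min_cohort}: percentile "
                      "bounds may be unstable", stacklevel=2)
    stats = np.column_stack([x.min(axis=1), x.max(axis=1),
                             x.mean(axis=1), np.median(x, axis=1)])
    lo = np.percentile(stats, percentiles[0], axis=0)
    hi = np.percentile(stats, percentiles[1], axis=0)
    return np.all((stats >= lo) & (stats <= hi), axis=1)


def extract_ppg_edfs(record: PPGRecord,
                     notch_prominence: float = NOTCH_PROMINENCE,
                     pulse_span: float = float(PPG_LENGTH)) -> PPGEDFs:
    """Heuristic feature detectors on a single pulse.

    Peak = global argmax. Shoulder = first downward zero crossing of the
    second derivative after the peak (the convex-to-concave transition on
    the falling edge). Notch = deepest local minimum between the peak and
    the last secondary maximum, present iff its prominence exceeds
    ``notch_prominence`` of the pulse amplitude. ``peak_to_peak_time``
    defaults to the configured pulse span when no beat-rate metadata exists.

    Positional features are invariant to positive amplitude scaling.
    """
    y = record.samples
    amplitude = float(y.max() - y.min())
    if amplitude <= 0:
        raise ValueError("flat waveform: features undefined")
    peak = int(np.argmax(y))

    d2 = np.diff(y, n=2)  # d2[i] approximates y''(i + 1)
    shoulder = peak
    for i in range(peak, d2.size - 1):
        if d2[i] >= 0 > d2[i + 1]:
            shoulder = i + 1
            break
    else:
        shoulder = int(min(peak + 1, PPG_LENGTH - 1))

    notch_present = False
    notch_position: int | None = None
    # candidate secondary maxima after the systolic peak
    tail = y[peak:]
    sec_peaks, _ = find_peaks(tail)
    if sec_peaks.size:
        sec = peak + int(sec_peaks[-1])
        trough_idx, props = find_peaks(-y[peak:sec + 1],
                                       prominence=notch_prominence * amplitude)
        if trough_idx.size:
            deepest = trough_idx[np.argmin(y[peak + trough_idx])]
            notch_present = True
            notch_position = peak + int(deepest)

    return PPGEDFs(notch_present=notch_present, notch_position=notch_position,
                   peak_position=peak, shoulder_position=int(shoulder),
                   peak_to_peak_time=float(pulse_span))


def extract_cohort_edfs(waveforms: np.ndarray, **kwargs) -> np.ndarray:
    """(n, 5) EDF matrix; rows follow :data:`EDF_NAMES`."""
    return np.vstack([
        extract_ppg_edfs(PPGRecord(w), **kwargs).as_array()
        for w in np.asarray(waveforms, dtype=float)
    ])
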