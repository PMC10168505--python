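"""Spirogram preprocessing: flow derivation, length normalization, QC,
flow-volume resampling and expert-defined features (EDFs).

Volume is handled in liters and flow in liters/second on a 10 ms grid.
Raw exhalation records in milliliters must be divided by 1000 on ingest
(:func:`ml_to_liters`); the QC ranges below only make sense in L and L/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: sampling interval of the volume-time series, seconds
DT = 0.01
#: number of samples after length normalization
TARGET_LENGTH = 1000
#: inclusive flow QC range, L/s
FLOW_RANGE = (-10.0, 20.0)
#: inclusive volume QC range, L
VOLUME_RANGE = (-5.0, 10.0)
#: minimum fraction of nonzero flow samples
MIN_NONZERO_FRACTION = 0.20
#: upper endpoint of the fixed flow-volume resampling grid, L
FLOW_VOLUME_MAX = 6.58
#: two-sided tail fraction removed from FEV1/FVC/PEF cohort distributions
EDF_TAIL_FRACTION = 0.005


@dataclass
class SpirogramRecord:
    """One forced-expiration blow.

    ``volume_time`` (L) and ``flow_time`` (L/s) share a 10 ms grid;
    ``flow_volume`` holds 1000 flows on the fixed volume grid once computed.
    """

    volume_time: np.ndarray
    flow_time: np.ndarray | None = None
    flow_volume: np.ndarray | None = None
    acceptability: bool = True
    qc_pass: bool | None = None
    qc_reasons: list[str] = field(default_factory=list)


@dataclass
class SpirogramEDFs:
    """The five spirogram expert-defined features."""

    fev1: float
    fvc: float
    fev1_fvc: float
    pef: float
    fef25_75: float

    def as_array(self) -> np.ndarray:
        return np.array([self.fev1, self.fvc, self.fev1_fvc, self.pef,
                         self.fef25_75])


EDF_NAMES = ("fev1", "fvc", "fev1_fvc", "pef", "fef25_75")


def ml_to_liters(volume_ml: np.ndarray) -> np.ndarray:
    return np.asarray(volume_ml, dtype=float) / 1000.0


def derive_flow_time(volume_time: np.ndarray) -> np.ndarray:
    """Flow as the forward finite difference of volume over the 10 ms step.

    The last difference is repeated so the output length matches the input.
    """
    v = np.asarray(volume_time, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("volume_time needs at least 2 samples")
    if not np.all(np.isfinite(v)):
        raise ValueError("volume_time contains non-finite values")
    flow = np.diff(v) / DT
    return np.append(flow, flow[-1])


def normalize_length(curve: np.ndarray, kind: str,
                     target: int = TARGET_LENGTH) -> np.ndarray:
    """Truncate to ``target`` samples, or right-pad: flows with 0, volumes
    with their final value."""
    c = np.asarray(curve, dtype=float)
    if c.size == 0:
        raise ValueError("empty curve")
    if kind not in ("volume", "flow"):
        raise ValueError(f"kind must be 'volume' or 'flow', got {kind!r}")
    if c.size >= target:
        return c[:target].copy()
    pad_value = 0.0 if kind == "flow" else c[-1]
    return np.concatenate([c, np.full(target - c.size, pad_value)])


def qc_spirogram(record: SpirogramRecord,
                 flow_range: tuple[float, float] = FLOW_RANGE,
                 volume_range: tuple[float, float] = VOLUME_RANGE,
                 min_nonzero_fraction: float = MIN_NONZERO_FRACTION,
                 ) -> SpirogramRecord:
    """Apply the per-blow QC rules; sets ``qc_pass``/``qc_reasons`` in place.

    Failure codes: ACCEPTABILITY, FLOW_RANGE, VOLUME_RANGE, FLOW_SPARSITY.
    Range bounds are inclusive.
    """
    reasons = []
    if not record.acceptability:
        reasons.append("ACCEPTABILITY")
    flow = record.flow_time
    if flow is None:
        flow = derive_flow_time(record.volume_time)
    if flow.min() < flow_range[0] or flow.max() > flow_range[1]:
        reasons.append("FLOW_RANGE")
    vol = record.volume_time
    if vol.min() < volume_range[0] or vol.max() > volume_range[1]:
        reasons.append("VOLUME_RANGE")
    if np.mean(flow != 0) < min_nonzero_fraction:
        reasons.append("FLOW_SPARSITY")
    record.qc_pass = not reasons
    record.qc_reasons = reasons
    return record


def edf_tail_filter(edfs: np.ndarray,
                    tail: float = EDF_TAIL_FRACTION,
                    min_cohort: int = 200) -> np.ndarray:
    """Keep mask removing individuals with any of FEV1/FVC/PEF strictly
    outside the cohort's [tail, 1-tail] empirical percentiles.

    ``edfs``: (n, 3) columns fev1, fvc, pef. Percentiles use numpy's default
    linear interpolation. Below ``min_cohort`` individuals the filter is a
    no-op (too few samples for stable tail estimates).
    """
    x = np.asarray(edfs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of FEV1, FVC, PEF")
    n = x.shape[0]
    if n < min_cohort:
        return np.ones(n, dtype=bool)
    lo = np.percentile(x, 100 * tail, axis=0)
    hi = np.percentile(x, 100 * (1 - tail), axis=0)
    return np.all((x >= lo) & (x <= hi), axis=1)


def flow_volume_grid(n: int = TARGET_LENGTH,
                     vmax: float = FLOW_VOLUME_MAX) -> np.ndarray:
    """The fixed volume grid: ``n`` evenly spaced values on [0, vmax] L."""
    return np.linspace(0.0, vmax, n)


def to_flow_volume(volume_time: np.ndarray, flow_time: np.ndarray,
                   grid: np.ndarray | None = None) -> np.ndarray:
    """Resample flow onto the fixed volume grid.

    Volume is monotonized by running maximum before linear interpolation;
    grid volumes beyond the subject's maximum volume map to flow 0.
    """
    v = np.asarray(volume_time, dtype=float)
    q = np.asarray(flow_time, dtype=float)
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite input")
    if grid is None:
        grid = flow_volume_grid()
    vmono = np.maximum.accumulate(v)
    # collapse duplicate volumes (flat segments) to keep interp well-defined
    keep = np.concatenate([[True], np.diff(vmono) > 0])
    out = np.interp(grid, vmono[keep], q[keep], left=q[keep][0], right=0.0)
    out[grid > vmono[-1]] = 0.0
    return out


def compute_spirogram_edfs(record: SpirogramRecord,
                           monotone_tol: float = 0.05) -> SpirogramEDFs:
    """EDFs from a normalized, QC-passing record.

    FVC = final volume; FEV1 = volume at t = 1 s (linear interpolation);
    PEF = max flow; FEF25-75 = 0.5*FVC / (t75 - t25), the mean
    mid-expiratory flow, with t25/t75 the times at 25%/75% of FVC.
    """
    v = np.asarray(record.volume_time, dtype=float)
    flow = record.flow_time
    if flow is None:
        flow = derive_flow_time(v)
    drops = np.diff(v)
    if drops.size and drops.min() < -monotone_tol:
        raise ValueError("volume curve decreases beyond tolerance")
    t = np.arange(v.size) * DT
    fvc = float(v[-1])
    fev1 = float(np.interp(1.0, t, v))
    pef = float(np.max(flow))
    vmono = np.maximum.accumulate(v)
    t25 = float(np.interp(0.25 * fvc, vmono, t))
    t75 = float(np.interp(0.75 * fvc, vmono, t))
    fef = 0.5 * fvc / (t75 - t25) if t75 > t25 else np.nan
    return SpirogramEDFs(fev1=fev1, fvc=fvc, fev1_fvc=fev1 / fvc, pef=pef,
                         fef25_75=fef)


def preprocess_record(volume_time: np.ndarray, acceptability: bool = True,
                      target: int = TARGET_LENGTH) -> SpirogramRecord:
    """Full per-blow pipeline: derive flow, normalize lengths, QC, and
    resample flow-volume (idempotent on already-normalized input)."""
    flow = derive_flow_time(volume_time)
    vol_n = normalize_length(volume_time, "volume", target)
    flow_n = normalize_length(flow, "flow", target)
    rec = SpirogramRecord(volume_time=vol_n, flow_time=flow_n,
                          acceptability=acceptability)
    qc_spirogram(rec)
    rec.flow_volume = to_flow_volume(vol_n, flow_n)
    return rec


def first_acceptable_blow(records: list[SpirogramRecord]) -> SpirogramRecord | None:
    """First record with acceptability True, or None."""
    for rec in records:
        if rec.acceptability:
            return rec
    return None
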