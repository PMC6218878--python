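"""The ten per-recording cardiorespiratory parameters.

Cardiac: mean heart rate (HR, beats/min), root-mean-square of successive
RR-interval differences (RMSSD, ms) and its natural log (lnRMSSD).
Respiratory: mean breathing rate (RR, breaths/min) and five coefficients of
variation — of the instantaneous breathing rate (ciRR), the inspiratory and
expiratory phase durations (cInsT, cExpT) and amplitudes (cInsV, cExpV).
The Breathing Regularity index compresses the five CVs into one 0-100%
score:

    BR = 100 - 20 * [tanh(ciRR) + tanh(cInsT) + tanh(cExpT)
                     + tanh(cInsV) + tanh(cExpV)]

The tanh saturation keeps each CV's contribution in [0, 20), so perfectly
regular breathing scores 100% and extreme variability drives the score
toward 0%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cardioresp import signals as sig
from cardioresp.types import BeatSeries, BreathSeries, ParameterTable, SignalRecord

__all__ = [
    "cardiac_params",
    "respiratory_params",
    "breathing_regularity",
    "parameter_vector",
    "extract_table",
    "ExtractionLog",
]


def _cv(values: np.ndarray, ddof: int = 1) -> float:
    mean = float(np.mean(values))
    if mean == 0:
        raise ValueError("zero mean: coefficient of variation undefined")
    return float(np.std(values, ddof=ddof) / mean)


def cardiac_params(beats: BeatSeries) -> tuple[float, float, float]:
    """(HR, RMSSD, lnRMSSD) from an RR-interval series.

    HR = 60000 / mean(RR in ms); RMSSD = sqrt(mean of squared successive
    differences).  A constant RR series has RMSSD = 0, which leaves lnRMSSD
    undefined; that degenerate case raises so callers can flag the record.
    """
    rr = beats.rr_intervals
    if len(rr) < 3:
        raise ValueError("at least 3 RR intervals required")
    hr = 60000.0 / float(np.mean(rr))
    rmssd = float(np.sqrt(np.mean(np.diff(rr) ** 2)))
    if rmssd == 0:
        raise ValueError("RMSSD is zero: lnRMSSD undefined (constant RR)")
    return hr, rmssd, math.log(rmssd)


def respiratory_params(
    breaths: BreathSeries, ddof: int = 1
) -> tuple[float, float, float, float, float, float]:
    """(RR, ciRR, cInsT, cExpT, cInsV, cExpV) from a breath series.

    RR is 60 over the mean inspiratory-onset-to-onset period; each CV is the
    sample standard deviation (n-1 denominator by default) over the mean of
    the respective per-breath sequence.
    """
    if breaths.n_breaths < 3:
        raise ValueError("at least 3 complete breaths required")
    rr = 60.0 / float(np.mean(breaths.periods))
    return (
        rr,
        _cv(breaths.irr, ddof),
        _cv(breaths.ins_durations, ddof),
        _cv(breaths.exp_durations, ddof),
        _cv(breaths.ins_amplitudes, ddof),
        _cv(breaths.exp_amplitudes, ddof),
    )


def breathing_regularity(
    ci_rr: float, c_ins_t: float, c_exp_t: float, c_ins_v: float, c_exp_v: float
) -> float:
    """Breathing Regularity in percent, 100 = perfectly regular."""
    cvs = (ci_rr, c_ins_t, c_exp_t, c_ins_v, c_exp_v)
    for cv in cvs:
        if not np.isfinite(cv) or cv < 0:
            raise ValueError("all five CVs must be finite and >= 0")
    return 100.0 - 20.0 * sum(math.tanh(cv) for cv in cvs)


def parameter_vector(beats: BeatSeries, breaths: BreathSeries, ddof: int = 1) -> dict:
    """All ten parameters for one recording, keyed by canonical name."""
    hr, rmssd, ln_rmssd = cardiac_params(beats)
    rr, ci_rr, c_ins_t, c_exp_t, c_ins_v, c_exp_v = respiratory_params(breaths, ddof)
    return {
        "HR": hr,
        "RMSSD": rmssd,
        "lnRMSSD": ln_rmssd,
        "RR": rr,
        "ciRR": ci_rr,
        "cInsT": c_ins_t,
        "cExpT": c_exp_t,
        "cInsV": c_ins_v,
        "cExpV": c_exp_v,
        "BR": breathing_regularity(ci_rr, c_ins_t, c_exp_t, c_ins_v, c_exp_v),
    }


@dataclass
class ExtractionLog:
    """Per-record outcome of table extraction; exclusions carry the failing stage."""

    included: list = field(default_factory=list)
    excluded: list = field(default_factory=list)  # (subject_id, position, stage, message)

    def record_exclusion(self, subject_id, position, stage, message) -> None:
        self.excluded.append((subject_id, position, stage, str(message)))


def process_record(record: SignalRecord) -> tuple[BeatSeries, BreathSeries]:
    """Run the full preprocessing chain on one recording."""
    detrended = sig.detrend_ecg(record)
    beats = sig.detect_r_peaks(detrended)
    if beats.flagged or beats.n_beats < 4:
        raise ValueError("detect_r_peaks: no usable beats")
    cleaned = sig.remove_cardiac_component(detrended, beats)
    smoothed = sig.smooth_ip(cleaned)
    breaths = sig.delimit_breaths(smoothed)
    return beats, breaths


def extract_table(
    records: list[SignalRecord],
    position: str | None = None,
    log: ExtractionLog | None = None,
) -> ParameterTable:
    """One parameter row per recording; failing records are excluded and logged.

    A record failing any stage is dropped with the failing stage recorded in
    the log (never silently), mirroring how artifact-laden recordings are
    excluded wholesale from cohort analyses.
    """
    if log is None:
        log = ExtractionLog()
    rows, ids = [], []
    seen = set()
    for record in records:
        key = (record.subject_id, record.position)
        if key in seen:
            raise ValueError(f"duplicate subject/position: {key}")
        seen.add(key)
        if position is not None and record.position != position:
            continue
        stage = "detrend_ecg"
        try:
            detrended = sig.detrend_ecg(record)
            stage = "detect_r_peaks"
            beats = sig.detect_r_peaks(detrended)
            if beats.flagged or beats.n_beats < 4:
                raise ValueError("no usable beats")
            stage = "remove_cardiac_component"
            cleaned = sig.remove_cardiac_component(detrended, beats)
            stage = "smooth_ip"
            smoothed = sig.smooth_ip(cleaned)
            stage = "delimit_breaths"
            breaths = sig.delimit_breaths(smoothed)
            stage = "parameter_vector"
            rows.append(parameter_vector(beats, breaths))
            ids.append(record.subject_id)
            log.included.append(key)
        except ValueError as err:
            log.record_exclusion(record.subject_id, record.position, stage, err)
    if not rows:
        raise ValueError("no records survived extraction")
    df = pd.DataFrame(rows, index=ids)
    return ParameterTable(df, position=position)
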