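"""ECG and impedance-pneumography preprocessing.

The chain mirrors a standard resting-recording workflow: the ECG is
baseline-aligned by nonlinear (median-filter) detrending and R peaks are
found with the Pan-Tompkins algorithm; the IP channel has the heartbeat
artifact subtracted with a normalized-LMS adaptive filter referenced to the
detected beats, is smoothed with a 400 ms averaging window, and is then
differentiated so breathing phases can be delimited from the flow-related
signal with an adaptive lobe-area threshold.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from cardioresp.types import BeatSeries, BreathSeries, SignalRecord

__all__ = [
    "detrend_ecg",
    "detect_r_peaks",
    "remove_cardiac_component",
    "smooth_ip",
    "delimit_breaths",
]


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def detrend_ecg(record: SignalRecord, window_s: float = 0.6) -> SignalRecord:
    """Remove the ECG baseline with a running-median estimate.

    A median filter of ``window_s`` seconds tracks the slow baseline without
    being dragged by the brief QRS complexes; subtracting it aligns the
    baseline to zero.  Any residual mean is removed as well.
    """
    if record.n_samples == 0:
        raise ValueError("empty ECG channel")
    kernel = int(round(window_s * record.fs))
    kernel += 1 - kernel % 2  # odd
    if kernel > record.n_samples:
        raise ValueError("detrending window longer than the signal")
    baseline = sps.medfilt(record.ecg, kernel_size=kernel)
    ecg = record.ecg - baseline
    ecg = ecg - ecg.mean()
    return record.replace(ecg=ecg)


def _pan_tompkins_candidates(ecg: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Band-pass 5-15 Hz, differentiate, square, 150 ms moving integration."""
    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, 15.0 / nyq], btype="band")
    filtered = sps.filtfilt(b, a, ecg)
    deriv = np.gradient(filtered)
    squared = deriv ** 2
    win = max(int(round(0.150 * fs)), 1)
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")
    locs, _ = sps.find_peaks(integrated, distance=int(round(0.2 * fs)))
    return integrated, locs


def detect_r_peaks(record: SignalRecord, refine_window_s: float = 0.05) -> BeatSeries:
    """Pan-Tompkins R-peak detection with adaptive dual thresholds.

    Candidate peaks from the integrated signal are classified with the
    classic running signal/noise levels (update weights 0.125, threshold at
    noise + 0.25 x (signal - noise)); a missed-beat search-back at half the
    threshold fires when the current RR exceeds 1.66 x the running average.
    Accepted peaks are refined to the local ECG maximum within +/-50 ms and
    physiologically impossible intervals (< 200 ms) are merged.

    An empty, flagged series (never an exception) signals that no beats
    were found.
    """
    ecg, fs = record.ecg, record.fs
    if record.duration_s < 10:
        raise ValueError("at least 10 s of ECG required for beat detection")
    integrated, locs = _pan_tompkins_candidates(ecg, fs)
    if len(locs) == 0 or np.ptp(ecg) == 0:
        return BeatSeries(r_peak_times=np.array([]), flagged=True)

    spk = float(np.percentile(integrated[locs], 75))
    npk = float(np.percentile(integrated[locs], 25)) * 0.5
    accepted: list[int] = []
    rr_avg = None
    refractory = int(round(0.2 * fs))

    def refine(idx: int) -> int:
        w = int(round(refine_window_s * fs))
        lo, hi = max(idx - w, 0), min(idx + w + 1, len(ecg))
        return lo + int(np.argmax(ecg[lo:hi]))

    last_loc = None
    for loc in locs:
        threshold = npk + 0.25 * (spk - npk)
        val = integrated[loc]
        if val > threshold:
            accepted.append(loc)
            spk = 0.125 * val + 0.875 * spk
            if last_loc is not None:
                rr = loc - last_loc
                rr_avg = rr if rr_avg is None else 0.125 * rr + 0.875 * rr_avg
            last_loc = loc
        else:
            # search-back: accept at half threshold if a beat is overdue
            overdue = (
                last_loc is not None
                and rr_avg is not None
                and (loc - last_loc) > 1.66 * rr_avg
            )
            if overdue and val > 0.5 * threshold:
                accepted.append(loc)
                spk = 0.25 * val + 0.75 * spk
                last_loc = loc
            else:
                npk = 0.125 * val + 0.875 * npk

    if not accepted:
        return BeatSeries(r_peak_times=np.array([]), flagged=True)

    peaks = sorted({refine(loc) for loc in accepted})
    # merge impossible intervals: keep the larger ECG value of the pair
    cleaned: list[int] = []
    for p in peaks:
        if cleaned and (p - cleaned[-1]) < refractory:
            if ecg[p] > ecg[cleaned[-1]]:
                cleaned[-1] = p
        else:
            cleaned.append(p)
    times = np.array(cleaned, dtype=float) / fs
    # the band-pass transient can fake a peak right at the record edges
    edge = 0.3
    times = times[(times >= edge) & (times <= record.duration_s - edge)]
    return BeatSeries(r_peak_times=times, flagged=len(times) == 0)


# ---------------------------------------------------------------------------
# IP cardiac-artifact removal (normalized LMS)
# ---------------------------------------------------------------------------

def remove_cardiac_component(
    record: SignalRecord,
    beats: BeatSeries,
    filter_s: float = 0.4,
    step: float = 0.05,
) -> SignalRecord:
    """Subtract the heartbeat artifact from the IP channel.

    The reference input is a unit impulse train at the R-peak samples; an
    adaptive FIR filter (``filter_s`` seconds of taps, normalized-LMS step
    ``step``) then learns the beat-locked artifact template.  Weights are
    adapted in a first pass and frozen for a second, so early beats are
    cleaned as well as late ones and the output is deterministic.

    With no beats available the input is returned unchanged with a
    ``cardiac_removal`` warning flag.
    """
    if beats.n_beats == 0:
        out = record.replace()
        out.flags["cardiac_removal"] = "skipped: no beats detected"
        return out
    ip, fs = record.ip, record.fs
    n = len(ip)
    taps = max(int(round(filter_s * fs)), 1)
    # impulses placed half a window early so the taps span the beat
    # symmetrically (the artifact extends before the R peak as well)
    ref = np.zeros(n)
    idx = np.round(beats.r_peak_times * fs).astype(int) - taps // 2
    idx = idx[(idx >= 0) & (idx < n)]
    ref[idx] = 1.0
    target = ip - ip.mean()

    w = np.zeros(taps)
    eps = 1e-12
    buf = np.zeros(taps)
    w_sum = np.zeros(taps)
    n_snap = 0
    for sweep in range(2):  # adapt twice over the record, then freeze
        buf[:] = 0.0
        for i in range(n):
            buf[1:] = buf[:-1]
            buf[0] = ref[i]
            norm = float(buf @ buf)
            if norm == 0.0:
                continue
            e = target[i] - float(w @ buf)
            w += (step * e / (norm + eps)) * buf
            if sweep == 1:  # average the taps over the final sweep:
                w_sum += w  # kills the recency bias of the LMS estimate
                n_snap += 1
    if n_snap:
        w = w_sum / n_snap

    # The artifact is compact around the beat, so the true template vanishes
    # at the window edges; any edge-anchored linear trend in the learned taps
    # is leaked respiratory baseline (locally ~linear over 0.4 s) — remove it.
    k = max(taps // 10, 1)
    x0, x1 = (k - 1) / 2.0, taps - 1 - (k - 1) / 2.0
    y0, y1 = float(w[:k].mean()), float(w[-k:].mean())
    slope = (y1 - y0) / (x1 - x0) if x1 > x0 else 0.0
    w = w - (y0 + slope * (np.arange(taps) - x0))

    # frozen-weight pass: artifact estimate everywhere
    estimate = np.convolve(ref, w)[:n]
    out = record.replace(ip=ip - estimate)
    out.flags["cardiac_removal"] = "applied"
    return out


# ---------------------------------------------------------------------------
# IP smoothing and breath delimitation
# ---------------------------------------------------------------------------

def smooth_ip(record: SignalRecord, window_s: float = 0.4) -> SignalRecord:
    """Centered moving average over ``window_s`` (edges use a shrinking window)."""
    win = max(int(round(window_s * record.fs)), 1)
    kernel = np.ones(win)
    num = np.convolve(record.ip, kernel, mode="same")
    den = np.convolve(np.ones_like(record.ip), kernel, mode="same")
    return record.replace(ip=num / den)


def delimit_breaths(
    record: SignalRecord,
    accept_frac: float = 0.2,
    memory: int = 8,
) -> BreathSeries:
    """Delimit breathing phases from the differentiated (flow-related) IP.

    Upward zero-crossings of the flow signal open inspirations, downward
    ones open expirations.  A crossing is accepted only when the area of the
    same-sign flow lobe that follows it exceeds ``accept_frac`` of the
    running median lobe area over the last ``memory`` accepted lobes
    (initialized from the upper quartile of all lobe areas); smaller lobes
    are treated as ripple and merged into the ongoing phase.  Because the
    flow is the derivative of IP, a lobe's area equals the IP excursion
    across it, which makes the rule invariant to offset and positive
    scaling of the channel.
    """
    ip, fs = record.ip, record.fs
    flow = np.gradient(ip) * fs
    sign = np.sign(flow)
    sign[sign == 0] = 1
    change = np.nonzero(np.diff(sign))[0] + 1
    if len(change) < 3:
        raise ValueError("insufficient respiratory activity")

    bounds = np.concatenate([[0], change, [len(flow)]])
    lobes = []  # (start_idx, sign, area)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        area = abs(float(ip[min(hi, len(ip) - 1)] - ip[lo]))
        lobes.append((int(lo), float(sign[lo]), area))

    areas = np.array([a for _, _, a in lobes])
    if areas.max() <= 0:
        raise ValueError("insufficient respiratory activity")
    # seed the running median from breath-sized lobes only: ripple and
    # artifact residue produce many tiny lobes that would drag a plain
    # percentile down
    seed_area = float(np.median(areas[areas >= 0.25 * areas.max()]))
    if seed_area <= 0:
        raise ValueError("insufficient respiratory activity")
    recent = [seed_area] * memory

    ins_idx: list[int] = []
    exp_idx: list[int] = []
    phase = None  # None | "ins" | "exp"
    for start, s, area in lobes:
        threshold = accept_frac * float(np.median(recent))
        if area < threshold:
            continue  # ripple: ongoing phase continues
        if s > 0 and phase != "ins":
            ins_idx.append(start)
            phase = "ins"
            recent.append(area)
        elif s < 0 and phase == "ins":
            exp_idx.append(start)
            phase = "exp"
            recent.append(area)
        if len(recent) > memory:
            recent.pop(0)

    # a first "inspiration" opening at sample 0 is a partial breath whose
    # true onset precedes the recording: drop it rather than impute
    if ins_idx and ins_idx[0] == 0:
        ins_idx = ins_idx[1:]
        while exp_idx and ins_idx and exp_idx[0] < ins_idx[0]:
            exp_idx = exp_idx[1:]

    # assemble complete breaths: ins[k] < exp[k] < ins[k+1]
    n_complete = min(len(exp_idx), len(ins_idx) - 1)
    if n_complete < 3:
        raise ValueError("insufficient respiratory activity")
    ins = np.array(ins_idx[: n_complete + 1], dtype=int)
    exp = np.array(exp_idx[:n_complete], dtype=int)

    t = np.arange(len(ip)) / fs
    ins_on = t[ins]
    exp_on = t[exp]
    ins_dur = exp_on - ins_on[:-1]
    exp_dur = ins_on[1:] - exp_on
    periods = np.diff(ins_on)
    ins_amp = ip[exp] - ip[ins[:-1]]
    exp_amp = np.abs(ip[ins[1:]] - ip[exp])
    valid = (ins_dur > 0) & (exp_dur > 0) & (ins_amp > 0) & (exp_amp > 0)
    if valid.sum() < 3:
        raise ValueError("insufficient respiratory activity")

    return BreathSeries(
        ins_onsets=ins_on[:-1][valid],
        exp_onsets=exp_on[valid],
        ins_durations=ins_dur[valid],
        exp_durations=exp_dur[valid],
        ins_amplitudes=ins_amp[valid],
        exp_amplitudes=exp_amp[valid],
        periods=periods[valid],
    )
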