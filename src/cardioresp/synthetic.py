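"""Synthetic cardiorespiratory signals and SCM-sampled parameter tables.

Two generators back the whole test strategy:

* :func:`generate_signals` builds a two-channel recording (ECG + impedance
  pneumography) with known ground truth: beat times with controllable mean
  heart rate, RMSSD and respiratory sinus arrhythmia (RSA) coupling, and a
  breath train with controllable per-breath duration/amplitude variability,
  a heartbeat-synchronous artifact on the IP channel and white noise.
* :func:`generate_scm_table` samples a subjects x parameters table from a
  user-specified structural causal model (linear or additive-nonlinear
  mechanisms, Gaussian noise), returning the generating DAG as ground truth.

Both are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from cardioresp.types import ParameterTable, SignalRecord

__all__ = [
    "SignalScenario",
    "SCMSpec",
    "GroundTruth",
    "generate_signals",
    "generate_scm_table",
    "MECHANISM_LIBRARY",
]


# ---------------------------------------------------------------------------
# scenario / spec containers
# ---------------------------------------------------------------------------

@dataclass
class SignalScenario:
    """Generating conditions for one synthetic recording.

    Defaults emulate a resting recording of a fit adult: ~6 min at 250 Hz,
    supine-range heart rate and vagal tone, spontaneous breathing near
    14 breaths/min with mild breath-to-breath variability.
    """

    duration_s: float = 360.0
    fs: float = 250.0
    mean_hr: float = 60.0            # beats/min
    rmssd_target: float = 50.0       # ms
    resp_rate: float = 14.0          # breaths/min
    rsa_gain: float = 30.0           # ms of RR modulation per unit respiratory excursion
    ins_frac: float = 0.4            # fraction of the breath period spent inspiring
    cv_breath_duration: float = 0.10
    cv_breath_amplitude: float = 0.15
    cardiac_artifact_gain: float = 0.05  # fraction of IP amplitude
    noise_sd: float = 0.01           # white noise SD, per channel, signal units
    seed: int = 0

    def validate(self) -> None:
        numeric = {k: v for k, v in asdict(self).items() if k != "seed"}
        for name, value in numeric.items():
            if not np.isfinite(value):
                raise ValueError(f"scenario field {name} must be finite")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if self.mean_hr <= 0 or self.resp_rate <= 0:
            raise ValueError("mean_hr and resp_rate must be positive")
        if not 0 < self.ins_frac < 1:
            raise ValueError("ins_frac must lie strictly between 0 and 1")
        if min(self.cv_breath_duration, self.cv_breath_amplitude) < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.rmssd_target < 0 or self.noise_sd < 0 or self.cardiac_artifact_gain < 0:
            raise ValueError("rmssd_target, noise_sd, cardiac_artifact_gain must be >= 0")


def sample_scenarios(
    n: int, seed: int = 0, duration_s: float = 180.0
) -> list[SignalScenario]:
    """Draw ``n`` physiologically plausible resting scenarios.

    Ranges cover the span seen across fit adults at rest in either body
    position: heart rate 50-90 beats/min, RMSSD 20-80 ms, breathing
    10-20 breaths/min with mild-to-moderate breath-to-breath variability,
    a small cardiac artifact on the IP channel and measurement noise.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(SignalScenario(
            duration_s=duration_s,
            mean_hr=float(rng.uniform(50, 90)),
            rmssd_target=float(rng.uniform(20, 80)),
            resp_rate=float(rng.uniform(10, 20)),
            rsa_gain=float(rng.uniform(10, 40)),
            ins_frac=float(rng.uniform(0.35, 0.45)),
            cv_breath_duration=float(rng.uniform(0.05, 0.20)),
            cv_breath_amplitude=float(rng.uniform(0.05, 0.25)),
            cardiac_artifact_gain=float(rng.uniform(0.0, 0.10)),
            noise_sd=float(rng.uniform(0.0, 0.02)),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return out


#: Closed library of additive nonlinear mechanisms, keeping ground truth
#: serializable.  ``exp`` is applied to a clipped argument to keep child
#: variances finite for unit-scale parents.
MECHANISM_LIBRARY = {
    "square": lambda x: x ** 2,
    "cube": lambda x: x ** 3,
    "exp": lambda x: np.exp(np.clip(x, -6.0, 6.0)),
    "sin": lambda x: np.sin(x),
}


@dataclass
class SCMSpec:
    """A structural causal model over named nodes.

    ``edges`` holds ``(parent, child, mechanism)`` triples where mechanism is
    ``("linear", coefficient)`` or ``(tag,)`` / ``(tag, scale)`` with ``tag``
    one of :data:`MECHANISM_LIBRARY`.  Children are sums of their parent
    mechanisms plus independent Gaussian noise.
    """

    node_names: tuple
    edges: tuple = ()
    noise_sd: dict | float = 1.0
    n: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.node_names = tuple(self.node_names)
        self.edges = tuple(tuple(e) for e in self.edges)

    def noise_for(self, node: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd[node])
        return float(self.noise_sd)

    def validate(self) -> None:
        if len(set(self.node_names)) != len(self.node_names):
            raise ValueError("node names must be unique")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        names = set(self.node_names)
        for parent, child, mech in self.edges:
            if parent not in names or child not in names:
                raise ValueError(f"edge endpoint not in node_names: {(parent, child)}")
            tag = mech[0]
            if tag != "linear" and tag not in MECHANISM_LIBRARY:
                raise ValueError(f"unknown mechanism tag {tag!r}")
            if tag == "linear" and len(mech) < 2:
                raise ValueError("linear mechanism needs a coefficient")
        for node in self.node_names:
            if self.noise_for(node) <= 0:
                raise ValueError(f"noise_sd must be positive (node {node})")
        self._topological_order()  # raises on cycles

    def _topological_order(self) -> list:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        g.add_edges_from((p, c) for p, c, _ in self.edges)
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(a) for a, _ in cycle) + f" -> {cycle[0][0]}"
            raise ValueError(f"edge set contains a cycle: {path}") from None
        # deterministic order among unconstrained nodes
        rank = {n: i for i, n in enumerate(self.node_names)}
        return sorted(order, key=lambda n: (order.index(n), rank[n]))


@dataclass
class GroundTruth:
    """What the generator actually produced, for recovery testing."""

    true_dag: tuple = ()              # (parent, child) pairs
    true_params: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)  # beat times, breath onsets
    scenario: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# signal generator
# ---------------------------------------------------------------------------

def _lognormal_multipliers(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Positive multipliers with unit mean and the requested CV."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=n)


def _breath_train(scenario: SignalScenario, rng: np.random.Generator):
    """Breath onset times, per-breath periods/amplitudes, and the ideal IP waveform."""
    base_period = 60.0 / scenario.resp_rate
    # draw enough breaths to cover the recording
    n_guess = int(math.ceil(scenario.duration_s / base_period * 2.5)) + 8
    dur_mult = _lognormal_multipliers(rng, n_guess, scenario.cv_breath_duration)
    amp_mult = _lognormal_multipliers(rng, n_guess, scenario.cv_breath_amplitude)
    periods = base_period * dur_mult
    onsets = np.concatenate([[0.0], np.cumsum(periods)[:-1]])
    keep = onsets < scenario.duration_s
    onsets, periods, amps = onsets[keep], periods[keep], amp_mult[keep]

    n = int(round(scenario.duration_s * scenario.fs))
    t = np.arange(n) / scenario.fs
    ip = np.zeros(n)
    for onset, period, amp in zip(onsets, periods, amps):
        t_ins = scenario.ins_frac * period
        t_exp = period - t_ins
        i0 = int(np.searchsorted(t, onset))
        i1 = min(int(np.searchsorted(t, onset + period)), n)
        seg = t[i0:i1] - onset
        wave = np.empty_like(seg)
        ins = seg < t_ins
        # monotone quarter-sine rise to the peak, then exponential decay
        wave[ins] = amp * np.sin(0.5 * np.pi * seg[ins] / t_ins)
        tau = t_exp / 4.0
        wave[~ins] = amp * np.exp(-(seg[~ins] - t_ins) / tau)
        ip[i0:i1] = wave
    return t, ip, onsets, periods, amps


def _qrs_template(fs: float) -> np.ndarray:
    """80 ms symmetric biphasic spike with its maximum at the centre sample."""
    half = int(round(0.04 * fs))
    tt = (np.arange(-half, half + 1)) / fs * 1000.0  # ms
    wave = np.exp(-((tt / 10.0) ** 2)) - 0.35 * np.exp(-(((tt - 20.0) / 12.0) ** 2))
    wave[half] = 1.0  # exact unique maximum at the nominal R time
    return wave


def generate_signals(scenario: SignalScenario) -> tuple[SignalRecord, GroundTruth]:
    """Generate a two-channel recording with known cardiac/respiratory truth.

    The RR series is ``60000/mean_hr`` plus RSA modulation proportional to
    the (noise-free) IP excursion at the beat time, plus white jitter scaled
    so the realized RMSSD of the RR list matches ``rmssd_target``.  The IP
    channel is the breath train plus a heartbeat-synchronous bump scaled by
    ``cardiac_artifact_gain`` plus white noise.

    Returns
    -------
    (SignalRecord, GroundTruth)
        The record and the generating truth (beat times, breath onsets and
        the realized parameter values).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)

    t, ip_clean, breath_onsets, periods, amps = _breath_train(scenario, rng)
    fs = scenario.fs
    n = len(t)
    phi = ip_clean - ip_clean.mean()  # respiratory excursion driving RSA

    def resp_at(time_s: float) -> float:
        idx = min(int(time_s * fs), n - 1)
        return phi[idx]

    base_rr = 60000.0 / scenario.mean_hr  # ms

    def beat_times(jitter: np.ndarray | None):
        times, rrs = [0.5], []
        k = 0
        while True:
            rr = base_rr + scenario.rsa_gain * resp_at(times[-1])
            if jitter is not None and k < len(jitter):
                rr = rr + jitter[k]
            rr = max(rr, 250.0)  # physiological floor
            nxt = times[-1] + rr / 1000.0
            if nxt >= scenario.duration_s - 0.2:
                break
            times.append(nxt)
            rrs.append(rr)
            k += 1
        return np.array(times), np.array(rrs)

    # pass 1: RSA only, to find how much RMSSD the coupling already produces
    _, rr_rsa = beat_times(None)
    n_beats_est = len(rr_rsa) + 8
    raw_jitter = rng.normal(0.0, 1.0, size=n_beats_est)

    if scenario.rmssd_target > 0 and len(rr_rsa) >= 3:
        # Solve for the jitter scale c so the realized RMSSD of
        # d_rsa + c*d_e equals the target: quadratic in c.
        _, rr_test = beat_times(raw_jitter)
        m = min(len(rr_rsa), len(rr_test))
        d_rsa = np.diff(rr_rsa[:m])
        d_tot = np.diff(rr_test[:m])
        d_e = d_tot - d_rsa
        a = float(np.mean(d_rsa ** 2))
        b = float(np.mean(d_rsa * d_e))
        c2 = float(np.mean(d_e ** 2))
        target2 = scenario.rmssd_target ** 2
        disc = b * b - c2 * (a - target2)
        if c2 > 0 and disc >= 0:
            scale = max((-b + math.sqrt(disc)) / c2, 0.0)
        else:
            scale = 0.0  # RSA alone already exceeds the target
        jitter = raw_jitter * scale
    else:
        jitter = np.zeros(n_beats_est)

    r_times, rr_ms = beat_times(jitter)

    # ECG channel: QRS template at beat samples
    ecg = np.zeros(n)
    template = _qrs_template(fs)
    half = len(template) // 2
    for bt in r_times:
        idx = int(round(bt * fs))
        lo, hi = idx - half, idx + half + 1
        s0, s1 = max(lo, 0), min(hi, n)
        ecg[s0:s1] += template[s0 - lo: len(template) - (hi - s1)]

    # IP channel: breaths + heartbeat-synchronous artifact + noise
    ip = ip_clean.copy()
    if scenario.cardiac_artifact_gain > 0 and len(r_times):
        amp_scale = scenario.cardiac_artifact_gain * (amps.mean() if len(amps) else 1.0)
        width = 0.05  # s; energy concentrated in the ~1-2 Hz beat band
        for bt in r_times:
            idx = int(round(bt * fs))
            lo = max(idx - int(3 * width * fs), 0)
            hi = min(idx + int(3 * width * fs) + 1, n)
            tt = t[lo:hi] - bt
            ip[lo:hi] += amp_scale * np.exp(-(tt / width) ** 2)
    if scenario.noise_sd > 0:
        ecg = ecg + rng.normal(0.0, scenario.noise_sd, n)
        ip = ip + rng.normal(0.0, scenario.noise_sd, n)

    record = SignalRecord(ecg=ecg, ip=ip, fs=fs)

    diffs = np.diff(rr_ms)
    realized_rmssd = float(np.sqrt(np.mean(diffs ** 2))) if len(diffs) else 0.0
    ins_onsets = breath_onsets
    cv = lambda v: float(np.std(v, ddof=1) / np.mean(v)) if len(v) > 2 else 0.0
    irr = 60.0 / periods
    truth = GroundTruth(
        true_params={
            "HR": 60000.0 / float(np.mean(rr_ms)) if len(rr_ms) else float("nan"),
            "RMSSD": realized_rmssd,
            "RR": 60.0 / float(np.mean(periods)),
            "ciRR": cv(irr),
            "cInsT": cv(periods * scenario.ins_frac),
            "cExpT": cv(periods * (1 - scenario.ins_frac)),
            "cInsV": cv(amps),
            "cExpV": cv(amps),
        },
        events={
            "r_peak_times": r_times,
            "rr_intervals_ms": rr_ms,
            "ins_onsets": ins_onsets,
            "breath_periods": periods,
            "breath_amplitudes": amps,
        },
        scenario=asdict(scenario),
    )
    return record, truth


# ---------------------------------------------------------------------------
# SCM table generator
# ---------------------------------------------------------------------------

def _apply_mechanism(mech: tuple, values: np.ndarray) -> np.ndarray:
    tag = mech[0]
    if tag == "linear":
        return float(mech[1]) * values
    scale = float(mech[1]) if len(mech) > 1 else 1.0
    return scale * MECHANISM_LIBRARY[tag](values)


def generate_scm_table(spec: SCMSpec) -> tuple[ParameterTable, GroundTruth]:
    """Sample a parameter table from a structural causal model.

    Nodes are sampled in topological order; each child is the sum of its
    parent mechanisms plus independent Gaussian noise.  Column order follows
    ``spec.node_names``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    order = spec._topological_order()
    parents = {node: [] for node in spec.node_names}
    for p, c, mech in spec.edges:
        parents[c].append((p, mech))

    values: dict[str, np.ndarray] = {}
    for node in order:
        x = rng.normal(0.0, spec.noise_for(node), size=spec.n)
        for p, mech in parents[node]:
            x = x + _apply_mechanism(mech, values[p])
        values[node] = x

    df = pd.DataFrame({name: values[name] for name in spec.node_names})
    df.index = [f"S{i:04d}" for i in range(spec.n)]
    table = ParameterTable(df)
    truth = GroundTruth(
        true_dag=tuple((p, c) for p, c, _ in spec.edges),
        true_params={f"noise_sd[{n}]": spec.noise_for(n) for n in spec.node_names},
        scenario={"n": spec.n, "seed": spec.seed},
    )
    return table, truth
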