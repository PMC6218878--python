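"""Core containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical column order of the per-subject parameter table.
PARAMETER_COLUMNS = (
    "HR",
    "RMSSD",
    "lnRMSSD",
    "RR",
    "ciRR",
    "cInsT",
    "cExpT",
    "cInsV",
    "cExpV",
    "BR",
)

POSITIONS = ("supine", "standing")


@dataclass
class SignalRecord:
    """One subject/position two-channel recording.

    Parameters
    ----------
    ecg : ndarray
        Single-lead ECG samples, arbitrary units.
    ip : ndarray
        Impedance-pneumography samples, uncalibrated impedance units
        (linearly related to tidal volume).
    fs : float
        Sampling rate in Hz.
    subject_id : str
        Subject label.
    position : str
        Body position, ``"supine"`` or ``"standing"``.
    flags : dict
        Processing annotations accumulated along the pipeline
        (e.g. ``{"cardiac_removal": "skipped: no beats"}``).
    """

    ecg: np.ndarray
    ip: np.ndarray
    fs: float
    subject_id: str = "anonymous"
    position: str = "supine"
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ip = np.asarray(self.ip, dtype=float)
        if self.ecg.ndim != 1 or self.ip.ndim != 1:
            raise ValueError("channels must be one-dimensional sample arrays")
        if len(self.ecg) != len(self.ip):
            raise ValueError("ECG and IP channels must have equal length")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError("sampling rate must be positive and finite")
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def replace(self, **kwargs) -> "SignalRecord":
        data = dict(
            ecg=self.ecg, ip=self.ip, fs=self.fs,
            subject_id=self.subject_id, position=self.position,
            flags=dict(self.flags),
        )
        data.update(kwargs)
        return SignalRecord(**data)


@dataclass
class BeatSeries:
    """Cardiac event series: R-peak times and the RR intervals between them."""

    r_peak_times: np.ndarray  # seconds, strictly increasing
    flagged: bool = False     # True when detection failed / series is empty

    def __post_init__(self) -> None:
        self.r_peak_times = np.asarray(self.r_peak_times, dtype=float)
        if self.r_peak_times.size and np.any(np.diff(self.r_peak_times) <= 0):
            raise ValueError("R-peak times must be strictly increasing")

    @property
    def rr_intervals(self) -> np.ndarray:
        """Successive RR intervals in milliseconds."""
        return np.diff(self.r_peak_times) * 1000.0

    @property
    def n_beats(self) -> int:
        return len(self.r_peak_times)


@dataclass
class BreathSeries:
    """Respiratory event series delimited from the IP channel.

    One breath k spans ``ins_onsets[k] -> exp_onsets[k] -> ins_onsets[k+1]``.
    Amplitudes are uncalibrated impedance excursions; all downstream use is
    through coefficients of variation, which are unit-free.
    """

    ins_onsets: np.ndarray      # s
    exp_onsets: np.ndarray      # s
    ins_durations: np.ndarray   # s (InsT)
    exp_durations: np.ndarray   # s (ExpT)
    ins_amplitudes: np.ndarray  # IP units (InsV)
    exp_amplitudes: np.ndarray  # IP units (ExpV)
    periods: np.ndarray         # s, inspiratory onset to next inspiratory onset

    def __post_init__(self) -> None:
        for name in ("ins_onsets", "exp_onsets", "ins_durations",
                     "exp_durations", "ins_amplitudes", "exp_amplitudes",
                     "periods"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.n_breaths
        for name in ("exp_onsets", "ins_durations", "exp_durations",
                     "ins_amplitudes", "exp_amplitudes", "periods"):
            if len(getattr(self, name)) != n:
                raise ValueError("all per-breath arrays must share length")

    @property
    def n_breaths(self) -> int:
        return len(self.ins_onsets)

    @property
    def irr(self) -> np.ndarray:
        """Instantaneous breathing rate, breaths/min, between inspiratory onsets."""
        return 60.0 / self.periods


class ParameterTable:
    """Subjects x parameters table, the unit of all statistical analysis.

    Thin wrapper over a :class:`pandas.DataFrame` indexed by subject id.
    For physiological tables the columns follow :data:`PARAMETER_COLUMNS`;
    tables produced from a structural causal model may carry arbitrary
    column names.
    """

    def __init__(self, data: pd.DataFrame, position: str | None = None):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(data)
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        if position is not None and position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}")
        canonical = [c for c in PARAMETER_COLUMNS if c in data.columns]
        if set(canonical) == set(PARAMETER_COLUMNS):
            data = data[list(PARAMETER_COLUMNS)]
        self.data = data.astype(float)
        self.position = position

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()

    def __repr__(self) -> str:  # pragma: no cover
        pos = f", position={self.position!r}" if self.position else ""
        return (f"ParameterTable({self.n_subjects} subjects x "
                f"{len(self.columns)} parameters{pos})")


@dataclass
class CausalGraph:
    """A learned graph over parameter labels.

    Edges are ``(a, b, kind)`` with ``kind`` in ``{"directed", "undirected"}``;
    a directed edge is a -> b, an undirected one is stored once with
    ``a < b`` lexicographically.
    """

    nodes: tuple
    edges: tuple   # of (a, b, kind)
    method: str
    score: float | None = None

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        node_set = set(self.nodes)
        norm = []
        for a, b, kind in self.edges:
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge endpoint not in node set: {(a, b)}")
            if kind not in ("directed", "undirected"):
                raise ValueError(f"unknown edge kind {kind!r}")
            if kind == "undirected" and a > b:
                a, b = b, a
            norm.append((a, b, kind))
        self.edges = tuple(sorted(set(norm)))

    @property
    def directed_edges(self) -> list[tuple]:
        return [(a, b) for a, b, k in self.edges if k == "directed"]

    @property
    def undirected_edges(self) -> list[tuple]:
        return [(a, b) for a, b, k in self.edges if k == "undirected"]

    @property
    def skeleton(self) -> set:
        return {frozenset((a, b)) for a, b, _ in self.edges}

    def has_directed_cycle(self) -> bool:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed_edges)
        return not nx.is_directed_acyclic_graph(g)
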