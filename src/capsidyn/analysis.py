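"""Translocation observables: per-chain native-contact fractions Q_i,
first-passage events, position-resolved counts N_i(t), ensemble statistics
and Q probability distributions with intermediate-peak detection.

A native contact is *formed* in a frame when the atom-pair distance is
less than ``formed_factor`` (default 1.5) times its distance in the
mature reference.  A chain has *translocated* when at least the
``translocation_threshold`` fraction (default 0.8, inclusive) of the
mature-specific intermolecular tail contacts are formed; the event time
is the first passage, with no hysteresis (an optional dwell requirement
exists for noisy toy systems).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .contacts import ContactMap
from .structures import MolecularStructure, radius_of_gyration
from .trajectory import Trajectory

__all__ = ["AnalysisParams", "QTrace", "TranslocationEvent", "QDistribution",
           "EmptyContactSubsetError", "tail_contact_subset", "q_fraction",
           "q_trace", "rg_trace", "detect_translocation",
           "count_events_by_position", "event_count_curve",
           "ensemble_statistics", "q_probability_distribution",
           "equilibration_cutoff"]


class EmptyContactSubsetError(ValueError):
    """The chain has no tail contacts under the requested scope."""


@dataclass(frozen=True)
class AnalysisParams:
    """Observable definitions.

    formed_factor : contact formed when r < formed_factor * r_native
    translocation_threshold : inclusive Q threshold for an event
    tail_range : residue interval defining the tail (1-based, inclusive);
        None uses each chain's annotated range
    contact_scope : 'intermolecular_only' restricts the Q denominator to
        contacts with another chain (the translocation criterion);
        'all_tail_contacts' keeps intramolecular tail contacts too
    histogram_bins : bins of the Q probability distribution on [0, 1]
    dwell_frames : frames Q must stay above threshold (0 = first crossing)
    """

    formed_factor: float = 1.5
    translocation_threshold: float = 0.8
    tail_range: tuple[int, int] | None = None
    contact_scope: str = "intermolecular_only"
    histogram_bins: int = 50
    dwell_frames: int = 0

    def __post_init__(self) -> None:
        if self.formed_factor <= 1:
            raise ValueError("formed_factor must be > 1")
        if not 0 < self.translocation_threshold <= 1:
            raise ValueError("translocation_threshold must be in (0, 1]")
        if self.contact_scope not in ("intermolecular_only", "all_tail_contacts"):
            raise ValueError(f"unknown contact_scope {self.contact_scope!r}")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")


@dataclass
class QTrace:
    """Per-chain fraction of native tail contacts as a function of time."""

    chain_id: str
    position_label: str
    times: np.ndarray
    q_values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.q_values = np.asarray(self.q_values, dtype=float)
        if len(self.times) != len(self.q_values):
            raise ValueError("times/q length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.q_values < 0) | (self.q_values > 1)):
            raise ValueError("Q values must lie in [0, 1]")


@dataclass(frozen=True)
class TranslocationEvent:
    chain_id: str
    position_label: str
    run_id: int
    first_passage_time: float


@dataclass
class QDistribution:
    """Normalized Q histogram for one monomer position, with detected peaks.

    ``peaks`` is a list of dicts with keys ``q`` (bin centre),
    ``probability`` and ``kind`` (endpoint_low / intermediate /
    endpoint_high).
    """

    position_label: str
    bin_edges: np.ndarray
    probabilities: np.ndarray
    peaks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.probabilities < 0):
            raise ValueError("negative probability")
        if abs(float(np.sum(self.probabilities)) - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    @property
    def intermediate_peaks(self) -> list:
        return [p for p in self.peaks if p["kind"] == "intermediate"]


def tail_contact_subset(cmap: ContactMap, structure: MolecularStructure,
                        chain_id: str,
                        params: AnalysisParams | None = None) -> ContactMap:
    """Contacts with at least one atom in a chain's tail residues.

    Under ``intermolecular_only`` scope the subset is further restricted
    to contacts with a different chain (the mature-specific trans-shell
    contacts).  Raises :class:`EmptyContactSubsetError` when nothing
    remains -- such a chain cannot be analyzed.
    """
    params = params or AnalysisParams()
    ann = structure.annotation(chain_id)
    tail_range = params.tail_range or ann.tail_range
    res_span = structure.residue_indices[structure.chain_mask(chain_id)]
    if len(res_span) == 0:
        raise KeyError(f"chain {chain_id!r} not in structure")
    if tail_range[0] < res_span.min() or tail_range[1] > res_span.max():
        raise ValueError(f"tail_range {tail_range} outside chain {chain_id} "
                         f"residue span ({res_span.min()}-{res_span.max()})")
    tail_idx = set(structure.atom_indices(chain_id, tail_range).tolist())
    in_tail = (np.isin(cmap.atom_i, list(tail_idx))
               | np.isin(cmap.atom_j, list(tail_idx)))
    mask = in_tail
    if params.contact_scope == "intermolecular_only":
        mask = mask & cmap.intermolecular
    subset = cmap.subset(mask)
    if len(subset) == 0:
        raise EmptyContactSubsetError(
            f"chain {chain_id!r} has no tail contacts under scope "
            f"{params.contact_scope!r}")
    return subset


def q_fraction(positions: np.ndarray, subset: ContactMap,
               formed_factor: float = 1.5) -> float:
    """Fraction of the subset's contacts formed in one frame."""
    if len(subset) == 0:
        raise EmptyContactSubsetError("empty contact subset")
    pos = np.asarray(positions, dtype=float)
    d = np.linalg.norm(pos[subset.atom_i] - pos[subset.atom_j], axis=1)
    return float(np.mean(d < formed_factor * subset.r_native))


def q_trace(trajectory: Trajectory, subset: ContactMap,
            chain_id: str = "", position_label: str = "",
            params: AnalysisParams | None = None) -> QTrace:
    """Q value for every saved frame of a trajectory."""
    params = params or AnalysisParams()
    d = np.linalg.norm(
        trajectory.positions[:, subset.atom_i] - trajectory.positions[:, subset.atom_j],
        axis=2)
    q = np.mean(d < params.formed_factor * subset.r_native, axis=1)
    return QTrace(chain_id=chain_id, position_label=position_label,
                  times=trajectory.times, q_values=q)


def rg_trace(trajectory: Trajectory,
             atom_indices: np.ndarray | None = None) -> np.ndarray:
    """Radius of gyration per frame (nm)."""
    frames = (trajectory.positions if atom_indices is None
              else trajectory.positions[:, atom_indices])
    return np.array([radius_of_gyration(fr) for fr in frames])


def detect_translocation(trace: QTrace, threshold: float = 0.8,
                         run_id: int = 0,
                         dwell_frames: int = 0) -> TranslocationEvent | None:
    """First-passage detection: earliest frame with Q >= threshold.

    The comparison is inclusive ("at least" the threshold fraction).
    With ``dwell_frames > 0`` the trace must stay at or above the
    threshold for that many consecutive frames (optional de-bouncing for
    noisy toy systems; default off).  Returns None if never reached.
    """
    above = trace.q_values >= threshold
    if dwell_frames > 0:
        ok = np.zeros(len(above), dtype=bool)
        run = 0
        for idx in range(len(above) - 1, -1, -1):
            run = run + 1 if above[idx] else 0
            ok[idx] = run >= dwell_frames
        above = ok
    hits = np.flatnonzero(above)
    if len(hits) == 0:
        return None
    return TranslocationEvent(chain_id=trace.chain_id,
                              position_label=trace.position_label,
                              run_id=run_id,
                              first_passage_time=float(trace.times[hits[0]]))


def count_events_by_position(events: list[TranslocationEvent],
                             position_labels: list[str],
                             chains_per_position: int,
                             n_runs: int) -> dict[str, int]:
    """Total event counts per monomer position across an ensemble.

    The denominator for each position is ``chains_per_position x n_runs``
    tails.  A duplicate event for one (run, chain) pair is a consistency
    error.
    """
    seen: set[tuple[int, str]] = set()
    counts = {lab: 0 for lab in position_labels}
    for ev in events:
        key = (ev.run_id, ev.chain_id)
        if key in seen:
            raise ValueError(f"duplicate event for run {ev.run_id} "
                             f"chain {ev.chain_id}")
        seen.add(key)
        if ev.position_label not in counts:
            raise KeyError(f"unknown position label {ev.position_label!r}")
        counts[ev.position_label] += 1
    limit = chains_per_position * n_runs
    for lab, c in counts.items():
        if c > limit:
            raise ValueError(f"position {lab}: {c} events exceed "
                             f"{limit} available tails")
    return counts


def event_count_curve(events: list[TranslocationEvent], position_label: str,
                      time_grid: np.ndarray) -> np.ndarray:
    """N_i(t): cumulative translocation count for one position.

    A non-decreasing step function evaluated on the given time grid.
    """
    times = np.sort([ev.first_passage_time for ev in events
                     if ev.position_label == position_label])
    return np.searchsorted(times, np.asarray(time_grid, dtype=float),
                           side="right").astype(float)


def ensemble_statistics(curves: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sample SD (n-1 denominator) across per-run curves.

    ``curves`` has shape (n_runs, n_times); at least two runs are needed
    for an SD.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2:
        raise ValueError("curves must be 2-D (runs x times)")
    if curves.shape[0] < 2:
        raise ValueError("standard deviation requires at least two runs")
    return curves.mean(axis=0), curves.std(axis=0, ddof=1)


def equilibration_cutoff(rg_series: np.ndarray, plateau_fraction: float = 0.95,
                         tail_fraction: float = 0.1) -> int:
    """First frame where Rg reaches ``plateau_fraction`` of its plateau.

    The plateau is estimated from the trailing ``tail_fraction`` of the
    series; used to discard the expansion phase before histogramming.
    """
    rg = np.asarray(rg_series, dtype=float)
    n_tail = max(1, int(len(rg) * tail_fraction))
    plateau = float(np.mean(rg[-n_tail:]))
    hits = np.flatnonzero(rg >= plateau_fraction * plateau)
    return int(hits[0]) if len(hits) else 0


def q_probability_distribution(q_samples_by_position: dict[str, np.ndarray],
                               params: AnalysisParams | None = None,
                               peak_prominence: float = 0.02,
                               endpoint_low: float = 0.2,
                               endpoint_high: float = 0.8,
                               ) -> dict[str, QDistribution]:
    """Normalized Q histograms per position with peak classification.

    Peaks are local maxima of the histogram above the given prominence
    (as a fraction of the maximum bin); a peak is *intermediate* when its
    bin centre lies in (endpoint_low, endpoint_high), otherwise it is an
    endpoint peak.  The stored distribution is never floored -- any
    display flooring of empty bins is a rendering concern.
    """
    params = params or AnalysisParams()
    out: dict[str, QDistribution] = {}
    edges = np.linspace(0.0, 1.0, params.histogram_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    for label, samples in q_samples_by_position.items():
        samples = np.asarray(samples, dtype=float).ravel()
        if len(samples) == 0:
            raise ValueError(f"position {label}: no Q samples")
        hist, _ = np.histogram(samples, bins=edges)
        prob = hist / hist.sum()
        # pad so peaks at the first/last bin are detectable
        padded = np.concatenate([[0.0], prob, [0.0]])
        idx, _ = find_peaks(padded, prominence=peak_prominence * prob.max())
        peaks = []
        for i in idx - 1:
            q = float(centers[i])
            kind = ("endpoint_low" if q < endpoint_low
                    else "endpoint_high" if q > endpoint_high
                    else "intermediate")
            peaks.append({"q": q, "probability": float(prob[i]), "kind": kind})
        out[label] = QDistribution(position_label=label, bin_edges=edges,
                                   probabilities=prob, peaks=peaks)
    return out
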