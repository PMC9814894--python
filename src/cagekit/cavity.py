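"""Cavity radius-of-gyration analysis of host trajectories.

The cavity volume of a container molecule is tracked through the radius
of gyration (Rg) of the cavity-lining atom selection.  A breathing host
shows a baseline Rg with transient excursions ("spikes") above a portal-
opening threshold; :func:`detect_spikes` operationalizes the open state
as Rg above a configurable threshold (default 5.70 Angstrom) and counts
maximal above-threshold runs.  Replicate simulations are summarized with
the standard error taken across replicate means, never across frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DEFAULT_FRAME_INTERVAL_NS, Conformation, Trajectory

#: default portal-open threshold (Angstrom)
OPEN_THRESHOLD = 5.70


def _weights(masses: np.ndarray, selection: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "mass":
        return masses[selection]
    if weighting == "uniform":
        return np.ones(len(selection))
    raise ValueError(f"unknown weighting {weighting!r}")


def radius_of_gyration(conf: Conformation, selection=None,
                       weighting: str = "mass") -> float:
    """Weighted radius of gyration of the selected atoms, Angstrom.

    Rg = sqrt(sum_i w_i |r_i - rbar|^2 / sum_i w_i) with rbar the
    weighted centroid; invariant under rigid motion and homogeneous of
    degree one in the coordinates.
    """
    sel = np.arange(conf.n_atoms) if selection is None else np.asarray(selection, int)
    if len(sel) == 0:
        raise ValueError("empty selection")
    w = _weights(conf.masses, sel, weighting)
    x = conf.coords[sel]
    w = w / w.sum()
    c = x - w @ x
    return float(np.sqrt(np.sum(w * np.sum(c * c, axis=1))))


@dataclass
class RgSeries:
    """Per-frame cavity Rg values with the selection that produced them."""

    values: np.ndarray
    selection: np.ndarray
    weighting: str = "mass"
    frame_interval: float | None = None  # ns; None = unknown

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if np.any(self.values < 0):
            raise ValueError("Rg values must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    def time_axis(self) -> np.ndarray:
        dt = self.frame_interval or DEFAULT_FRAME_INTERVAL_NS
        return np.arange(self.n_frames) * dt


def rg_time_series(traj: Trajectory, selection=None,
                   weighting: str = "mass") -> RgSeries:
    """Cavity Rg for every frame, order-preserving."""
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, int)
    if len(sel) == 0:
        raise ValueError("empty selection")
    w = _weights(traj.masses, sel, weighting)
    w = w / w.sum()
    x = traj.coords[:, sel, :]  # (F, S, 3)
    centroid = np.einsum("s,fsd->fd", w, x)
    c = x - centroid[:, None, :]
    vals = np.sqrt(np.einsum("s,fsd,fsd->f", w, c, c))
    return RgSeries(values=vals, selection=sel, weighting=weighting,
                    frame_interval=traj.frame_interval)


@dataclass
class SpikeSummary:
    """Portal-opening statistics of an Rg series at one threshold."""

    threshold: float
    spike_count: int
    spike_frequency: float  # events per ns
    dwell_above: float
    dwell_below: float
    interval_assumed: bool = False  # True when the default frame time was used

    @property
    def dwell_fractions(self) -> tuple[float, float]:
        return (self.dwell_above, self.dwell_below)


def detect_spikes(series: RgSeries, threshold: float = OPEN_THRESHOLD) -> SpikeSummary:
    """Count maximal above-threshold runs and dwell fractions.

    A spike is a maximal run of consecutive frames with Rg strictly above
    the threshold.  The frequency is count / total simulated time; when
    the series has no time metadata the default frame interval
    (:data:`cagekit.core.DEFAULT_FRAME_INTERVAL_NS`) is assumed and the
    summary flags that.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = series.values > threshold
    # run starts: above and (first frame or previous below)
    starts = above & np.concatenate([[True], ~above[:-1]])
    count = int(starts.sum())
    assumed = series.frame_interval is None
    dt = series.frame_interval or DEFAULT_FRAME_INTERVAL_NS
    total_ns = series.n_frames * dt
    freq = count / total_ns if total_ns > 0 else 0.0
    frac_above = float(above.mean()) if series.n_frames else 0.0
    return SpikeSummary(threshold=float(threshold), spike_count=count,
                        spike_frequency=float(freq), dwell_above=frac_above,
                        dwell_below=1.0 - frac_above, interval_assumed=assumed)


@dataclass
class RgSummary:
    """Replicate-level Rg summary: mean of per-replicate time averages
    plus the standard error across replicates."""

    per_replicate_means: list[float] = field(default_factory=list)
    grand_mean: float = 0.0
    standard_error: float = 0.0

    @property
    def n_replicates(self) -> int:
        return len(self.per_replicate_means)


def summarize_replicates(series_list: list[RgSeries]) -> RgSummary:
    """Grand mean and standard error over independent replicate series.

    The grand mean is the mean of per-replicate time averages; the SE is
    the sample standard deviation of those means divided by sqrt(k).
    Fewer than two replicates raise (the SE is undefined).
    """
    if len(series_list) < 2:
        raise ValueError("need at least 2 replicates for a standard error")
    means = np.array([float(np.mean(s.values)) for s in series_list])
    se = float(np.std(means, ddof=1) / np.sqrt(len(means)))
    return RgSummary(per_replicate_means=[float(m) for m in means],
                     grand_mean=float(np.mean(means)), standard_error=se)
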