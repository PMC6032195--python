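"""Inter-helical distance of the binding groove and metric-series summaries.

The groove-opening metric is directional: for every Cα of the α-chain
helix, take the distance to the *closest* Cα of the β-chain helix, then
average over the α-helix Cαs. Falling values of its time series indicate
a closing motion of the groove; the per-trajectory summary is mean ± SD
plus the ordinary-least-squares slope in Å/ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import linregress

from .io import GrooveDefinition, Structure, Trajectory, calpha_indices, select_calpha

__all__ = [
    "MetricSeries",
    "SeriesSummary",
    "inter_helical_distance",
    "groove_distance_series",
    "summarize_series",
]


@dataclass
class MetricSeries:
    """A per-frame scalar paired with its time axis (ns)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def summarize(self) -> "SeriesSummary":
        return summarize_series(self)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_ns": self.times, "value": self.values})


@dataclass(frozen=True)
class SeriesSummary:
    """Mean, sample SD (n−1) and OLS slope (per ns) of a metric series."""

    mean: float
    sd: float
    slope: float
    n_frames: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "slope": self.slope,
            "n_frames": self.n_frames,
        }


def _helix_coords(frame: Structure, g: GrooveDefinition) -> tuple[np.ndarray, np.ndarray]:
    a = select_calpha(frame, g.alpha_chain, g.alpha_helix)
    b = select_calpha(frame, g.beta_chain, g.beta_helix)
    if not a or not b:
        raise ValueError("empty helix selection for inter-helical distance")
    return (
        np.array([at.xyz for at in a], dtype=float),
        np.array([at.xyz for at in b], dtype=float),
    )


def _ihd_from_coords(alpha: np.ndarray, beta: np.ndarray) -> float:
    return float(cdist(alpha, beta).min(axis=1).mean())


def inter_helical_distance(
    frame: Structure, g: GrooveDefinition, symmetrize: bool = False
) -> float:
    """Mean nearest-neighbour Cα distance from the α helix to the β helix, Å.

    The metric is directional (α→β) by default; ``symmetrize=True``
    averages both directions instead. Invariant to any rigid motion of the
    whole frame.
    """
    alpha, beta = _helix_coords(frame, g)
    d = _ihd_from_coords(alpha, beta)
    if symmetrize:
        d = 0.5 * (d + _ihd_from_coords(beta, alpha))
    return d


def groove_distance_series(
    t: Trajectory, g: GrooveDefinition, symmetrize: bool = False
) -> MetricSeries:
    """Inter-helical distance evaluated on every frame of a trajectory."""
    ia = calpha_indices(t.topology, g.alpha_chain, g.alpha_helix)
    ib = calpha_indices(t.topology, g.beta_chain, g.beta_helix)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty helix selection for inter-helical distance")
    values = np.empty(t.n_frames)
    for k in range(t.n_frames):
        d = _ihd_from_coords(t.coords[k, ia], t.coords[k, ib])
        if symmetrize:
            d = 0.5 * (d + _ihd_from_coords(t.coords[k, ib], t.coords[k, ia]))
        values[k] = d
    return MetricSeries(times=t.times, values=values, label="inter-helical distance")


def summarize_series(s: MetricSeries) -> SeriesSummary:
    """Mean, sample SD and OLS slope (value regressed on time) of a series.

    No detrending or smoothing is applied before the fit — the slope is
    read off the raw curve.
    """
    if len(s) < 2:
        raise ValueError("series summary requires at least 2 points")
    fit = linregress(s.times, s.values)
    return SeriesSummary(
        mean=float(np.mean(s.values)),
        sd=float(np.std(s.values, ddof=1)),
        slope=float(fit.slope),
        n_frames=len(s),
    )
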