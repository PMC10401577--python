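"""Torsion time series, distributions, H-bond-motif flip detection, cell averages.

Flip detection uses a committed-state automaton: a torsion is "committed"
to a motif basin, and only a continuous residence of at least the dwell
time inside a *different* basin records a flip and moves the commitment.
Short excursions — including visits to the ±180° metastable region, which
is deliberately not a basin — change nothing.  A genuine out-and-back
episode with both residences exceeding the dwell counts as two flips.

Default basins follow the thiol-motif convention of disordered amino-acid
crystals: SH···S-like at τ ∈ [30°, 150°], SH···O-like at τ ∈ [−150°, −30°]
(basin centres near +87° / −78°), dwell 0.5 ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError
from .structures import TorsionSpec, measure_torsion, lattice_parameters

__all__ = [
    "TorsionTrajectory",
    "FlipEvent",
    "DEFAULT_BASINS",
    "torsion_timeseries",
    "torsion_distribution",
    "detect_flips",
    "motif_occupancy",
    "average_cell",
]

DEFAULT_BASINS = {
    "SH...S-like": (30.0, 150.0),
    "SH...O-like": (-150.0, -30.0),
}
METASTABLE_LABEL = "metastable-180"
DEFAULT_DWELL_PS = 0.5


@dataclass
class TorsionTrajectory:
    """Per-torsion angle series over time.

    times : ps, shape (n_frames,).
    wrapped : degrees in (−180, 180], shape (n_frames, n_torsions).
    unwrapped : continuous view (no inter-frame jump > 180°).
    specs : list of TorsionSpec (one per column).
    """

    times: np.ndarray
    wrapped: np.ndarray
    unwrapped: np.ndarray
    specs: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.wrapped = np.atleast_2d(np.asarray(self.wrapped, dtype=float))
        self.unwrapped = np.atleast_2d(np.asarray(self.unwrapped, dtype=float))

    @property
    def n_torsions(self):
        return self.wrapped.shape[1]

    @classmethod
    def from_angles(cls, times, angles, specs=None):
        """Build from raw angle series (degrees, any wrapping)."""
        angles = np.atleast_2d(np.asarray(angles, dtype=float))
        if angles.shape[0] != len(np.atleast_1d(times)):
            angles = angles.T
        unwrapped = np.unwrap(angles, axis=0, period=360.0)
        wrapped = np.mod(angles, 360.0)
        wrapped[wrapped > 180.0] -= 360.0
        return cls(np.atleast_1d(times), wrapped, unwrapped, specs or [])


@dataclass(frozen=True)
class FlipEvent:
    torsion: int
    time: float          # ps, first frame inside the new basin
    from_basin: str
    to_basin: str
    dwell: float         # ps of confirmed residence in the new basin


# --------------------------------------------------------------------------

def torsion_timeseries(frames, specs, dt_ps: float = 1.0, times=None) -> TorsionTrajectory:
    """Measure torsions on every trajectory frame.

    *frames* is a sequence of :class:`crysvib.fileio.Frame` (or Crystal)
    objects carrying cells; per-frame minimum-image dihedrals are taken
    and the series unwrapped continuously.
    """
    specs = [s if isinstance(s, TorsionSpec) else TorsionSpec(*s) for s in specs]
    angles = np.empty((len(frames), len(specs)))
    for fi, frame in enumerate(frames):
        crystal = frame if hasattr(frame, "bond_graph") else frame.as_crystal()
        for si, spec in enumerate(specs):
            for i in spec.ids:
                if i >= crystal.n_sites:
                    raise FormatError(f"frame {fi}: torsion site {i} missing")
            angles[fi, si] = measure_torsion(crystal, spec)
    if times is None:
        times = np.arange(len(frames)) * dt_ps
    return TorsionTrajectory.from_angles(times, angles, specs)


def torsion_distribution(series, bin_width: float = 5.0) -> pd.DataFrame:
    """Normalized angle histogram over (−180°, 180°], integrated area = 100.

    *series* is any array of wrapped angles (all torsions pooled); the
    returned frame has bin centres and densities with
    Σ density·bin_width = 100 exactly.
    """
    if not np.isclose(360.0 / bin_width, round(360.0 / bin_width)):
        raise ConfigurationError("bin width must divide 360")
    data = np.asarray(series, dtype=float).ravel()
    if data.size == 0:
        raise ConfigurationError("empty angle series")
    wrapped = np.mod(data, 360.0)
    wrapped[wrapped > 180.0] -= 360.0
    edges = np.arange(-180.0, 180.0 + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(wrapped, bins=edges)
    density = 100.0 * counts / (data.size * bin_width)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"angle_deg": centres, "density": density})


def _validate_basins(basins: dict):
    items = list(basins.items())
    for i in range(len(items)):
        lo_i, hi_i = items[i][1]
        if lo_i >= hi_i:
            raise ConfigurationError(f"basin {items[i][0]} has lo ≥ hi")
        for j in range(i + 1, len(items)):
            lo_j, hi_j = items[j][1]
            if lo_i < hi_j and lo_j < hi_i:
                raise ConfigurationError(
                    f"basins {items[i][0]} and {items[j][0]} overlap"
                )


def _basin_labels(angles: np.ndarray, basins: dict) -> np.ndarray:
    """Per-frame basin label index (−1 = none/metastable)."""
    labels = np.full(angles.shape, -1, dtype=int)
    for k, (lo, hi) in enumerate(basins.values()):
        labels[(angles >= lo) & (angles <= hi)] = k
    return labels


def detect_flips(
    traj: TorsionTrajectory,
    basins: dict | None = None,
    dwell: float = DEFAULT_DWELL_PS,
) -> list:
    """Committed-basin flip detection on every torsion of a trajectory.

    A flip is recorded when the series, currently committed to one basin,
    resides continuously in a different basin for at least *dwell* ps; the
    event time is the first frame of that residence.  Frames outside every
    basin (the ±180° metastable region included) never commit.
    """
    basins = basins or DEFAULT_BASINS
    if dwell <= 0:
        raise ConfigurationError("dwell must be > 0")
    _validate_basins(basins)
    names = list(basins.keys())
    times = traj.times
    events: list[FlipEvent] = []
    for col in range(traj.n_torsions):
        labels = _basin_labels(traj.wrapped[:, col], basins)
        # maximal runs of a single in-basin label
        runs = []  # (label, start_idx, end_idx inclusive)
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                if labels[start] >= 0:
                    runs.append((labels[start], start, i - 1))
                start = i
        committed = None
        for lab, s, e in runs:
            duration = times[e] - times[s]
            confirmed = duration >= dwell
            if committed is None:
                if confirmed:
                    committed = lab
                continue
            if lab != committed and confirmed:
                events.append(
                    FlipEvent(
                        torsion=col,
                        time=float(times[s]),
                        from_basin=names[committed],
                        to_basin=names[lab],
                        dwell=float(duration),
                    )
                )
                committed = lab
    return events


def motif_occupancy(traj: TorsionTrajectory, basins: dict | None = None) -> pd.DataFrame:
    """Fraction of frames spent in each basin, per torsion.

    Rows sum to ≤ 1; the remainder is metastable/unassigned time.
    """
    basins = basins or DEFAULT_BASINS
    _validate_basins(basins)
    names = list(basins.keys())
    rows = []
    for col in range(traj.n_torsions):
        labels = _basin_labels(traj.wrapped[:, col], basins)
        n = len(labels)
        row = {name: float(np.sum(labels == k)) / n for k, name in enumerate(names)}
        row[METASTABLE_LABEL] = float(np.sum(labels < 0)) / n
        rows.append(row)
    return pd.DataFrame(rows)


def average_cell(frames) -> pd.DataFrame:
    """Mean and standard deviation of lattice parameters over NPT frames.

    Accepts Frame or Crystal objects with cells; returns a two-row frame
    (``mean``, ``std``) over (a, b, c, alpha, beta, gamma, volume).
    """
    params = []
    for fr in frames:
        lattice = fr.lattice
        if lattice is None:
            raise FormatError("frame without a cell record in average_cell")
        a, b, c, al, be, ga = lattice_parameters(lattice)
        params.append((a, b, c, al, be, ga, abs(float(np.linalg.det(lattice)))))
    if not params:
        raise ConfigurationError("average_cell needs at least one frame")
    arr = np.array(params)
    cols = ["a", "b", "c", "alpha", "beta", "gamma", "volume"]
    return pd.DataFrame(
        [arr.mean(axis=0), arr.std(axis=0)], index=["mean", "std"], columns=cols
    )
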