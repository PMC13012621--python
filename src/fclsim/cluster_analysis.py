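"""Cluster-dynamics statistics of a simulated trajectory.

Reproduces the observables used to characterise flat clathrin lattice
dynamics: membrane-bound clathrin counts, the equilibration time t_c (first
time the membrane-bound count exceeds 90% of its end-of-run value), the
counted-cluster number per frame (clusters with more than a threshold
number of clathrins, 10 by default), the "most possible pattern" (modal
counted-cluster number over the post-t_c frames), per-pattern mean cluster
areas, and dwelling times (maximal runs of constant counted-cluster
number).  Cluster membrane areas are convex hulls of the member x-y centers
dilated by the clathrin footprint radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint

NM2_PER_UM2 = 1e6
US_PER_MIN = 6e7

#: circle discretisation for the footprint dilation (segments = 4 x this)
BUFFER_QUAD_SEGS = 64


class InsufficientDataError(ValueError):
    """The requested statistic has no frames to draw on."""


@dataclass(frozen=True)
class ClusterRecord:
    """One connected assembly in one frame."""

    member_ids: tuple
    n_clathrin: int
    n_ap2: int
    area: float | None  # um^2, None for clusters without AP-2
    is_membrane_bound: bool
    is_large: bool


def find_clusters(
    cc_bonds: np.ndarray,
    ap2_bound: np.ndarray,
    positions: np.ndarray | None = None,
    footprint_radius: float = 12.5,
    large_threshold: int = 10,
) -> list[ClusterRecord]:
    """Connected components of the clathrin bond graph.

    ``cc_bonds`` is an (m, 4) array of (i, site_i, j, site_j) edges,
    ``ap2_bound`` a boolean per clathrin.  Molecules with no bonds and no
    AP-2 are excluded; an AP-2-bound monomer is a (singleton) membrane-bound
    cluster.  Areas are computed when ``positions`` is given.
    """
    ap2_bound = np.asarray(ap2_bound, dtype=bool)
    n = len(ap2_bound)
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for row in np.asarray(cc_bonds, dtype=int).reshape(-1, 4):
        i, _, j, _ = row
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    bonded = np.zeros(n, dtype=bool)
    for row in np.asarray(cc_bonds, dtype=int).reshape(-1, 4):
        bonded[row[0]] = bonded[row[2]] = True

    groups: dict[int, list[int]] = {}
    for i in range(n):
        if bonded[i] or ap2_bound[i]:
            groups.setdefault(find(i), []).append(i)

    records = []
    for members in groups.values():
        members_arr = np.array(members)
        n_ap2 = int(np.sum(ap2_bound[members_arr]))
        membrane = n_ap2 >= 1
        area = None
        if membrane and positions is not None:
            area = cluster_area_from_points(
                positions[members_arr, :2], footprint_radius
            )
        records.append(
            ClusterRecord(
                member_ids=tuple(int(m) for m in members),
                n_clathrin=len(members),
                n_ap2=n_ap2,
                area=area,
                is_membrane_bound=membrane,
                is_large=len(members) > large_threshold,
            )
        )
    return records


def cluster_area_from_points(xy_nm: np.ndarray, footprint_radius: float) -> float:
    """Convex hull of the member centers dilated by the footprint disc, um^2.

    A single member yields pi r^2; two members a stadium around the segment.
    """
    pts = MultiPoint([tuple(p) for p in np.atleast_2d(xy_nm)])
    shape = pts.convex_hull.buffer(footprint_radius, quad_segs=BUFFER_QUAD_SEGS)
    return shape.area / NM2_PER_UM2


def cluster_area(cluster: ClusterRecord, positions: np.ndarray, footprint_radius: float) -> float:
    """Membrane footprint area (um^2) of one membrane-bound cluster."""
    if not cluster.is_membrane_bound:
        raise InsufficientDataError("area is defined for membrane-bound clusters only")
    idx = np.array(cluster.member_ids)
    return cluster_area_from_points(positions[idx, :2], footprint_radius)


def membrane_bound_clathrin_count(records: list[ClusterRecord]) -> int:
    """Number of clathrins in AP-2-containing clusters (monomers included)."""
    return sum(r.n_clathrin for r in records if r.is_membrane_bound)


def counted_cluster_number(records: list[ClusterRecord]) -> int:
    """Number of large membrane-bound clusters (> threshold clathrins)."""
    return sum(1 for r in records if r.is_membrane_bound and r.is_large)


def compute_tc(membrane_bound_series, times) -> float | None:
    """First time the membrane-bound count exceeds 90% of the final value.

    Returns None (undefined) when the final count is zero.
    """
    series = np.asarray(membrane_bound_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(series) == 0:
        raise InsufficientDataError("empty series")
    final = series[-1]
    if final == 0:
        return None
    above = np.flatnonzero(series > 0.9 * final)
    return float(times[above[0]])


def pattern_statistics(cluster_number_series) -> tuple[dict, int]:
    """Frequencies of each counted-cluster number and the modal value.

    Ties break toward the smaller cluster number.  The series should be
    restricted to post-t_c frames by the caller.
    """
    series = np.asarray(cluster_number_series, dtype=int)
    if len(series) == 0:
        raise InsufficientDataError("no frames after t_c")
    values, counts = np.unique(series, return_counts=True)
    freqs = {int(v): c / len(series) for v, c in zip(values, counts)}
    best = values[np.argmax(counts)]  # np.unique sorts: first max is smallest
    return freqs, int(best)


def mean_cluster_size(records: list[ClusterRecord]) -> float:
    """Total counted-cluster area divided by the counted-cluster number, um^2."""
    counted = [r for r in records if r.is_membrane_bound and r.is_large]
    if not counted:
        raise InsufficientDataError("no counted clusters in frame")
    if any(r.area is None for r in counted):
        raise InsufficientDataError("cluster areas were not computed")
    return float(np.mean([r.area for r in counted]))


@dataclass(frozen=True)
class Dwell:
    """One maximal constant run of the counted-cluster number."""

    pattern: int
    duration: float  # minutes
    censored: bool  # truncated by the analysis-window boundary


def dwelling_times(cluster_number_series, times, pattern: int | None = None) -> list[Dwell]:
    """Run-length decomposition of the counted-cluster number series.

    Run durations are (run length x frame spacing); the first and last runs
    are flagged censored (truncated by the window).  Durations sum exactly
    to the window length (n_frames x spacing).  ``pattern`` filters to runs
    at one cluster number.
    """
    series = np.asarray(cluster_number_series, dtype=int)
    times = np.asarray(times, dtype=float)
    if len(series) != len(times):
        raise InsufficientDataError("series and times must align")
    if len(series) == 0:
        return []
    spacing = float(times[1] - times[0]) if len(times) > 1 else 0.0
    change = np.flatnonzero(np.diff(series) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(series) - 1]])
    out = []
    for s, e in zip(starts, ends):
        val = int(series[s])
        if pattern is not None and val != pattern:
            continue
        duration = (e - s + 1) * spacing / US_PER_MIN
        censored = s == 0 or e == len(series) - 1
        out.append(Dwell(pattern=val, duration=duration, censored=censored))
    return out


def mean_dwell(dwells: list[Dwell], include_censored: bool = False) -> float:
    """Mean dwell in minutes; boundary-truncated runs excluded by default."""
    durations = [d.duration for d in dwells if include_censored or not d.censored]
    if not durations:
        raise InsufficientDataError("no uncensored dwells")
    return float(np.mean(durations))


@dataclass
class AnalysisSummary:
    """All trajectory-level statistics in one bundle."""

    times_min: np.ndarray
    cluster_number_series: np.ndarray
    membrane_bound_series: np.ndarray
    mean_size_series: np.ndarray  # um^2, NaN where no counted cluster
    tc_min: float | None
    pattern_frequencies: dict = field(default_factory=dict)
    most_possible_pattern: int | None = None
    mean_cluster_size_by_pattern: dict = field(default_factory=dict)
    dwelling_times_by_pattern: dict = field(default_factory=dict)
    large_cluster_threshold: int = 10
    frame_interval_min: float = 0.0

    def to_dict(self) -> dict:
        return {
            "times_min": self.times_min.tolist(),
            "cluster_number_series": self.cluster_number_series.tolist(),
            "membrane_bound_series": self.membrane_bound_series.tolist(),
            "mean_size_series_um2": self.mean_size_series.tolist(),
            "tc_min": self.tc_min,
            "pattern_frequencies": {str(k): v for k, v in self.pattern_frequencies.items()},
            "most_possible_pattern": self.most_possible_pattern,
            "mean_cluster_size_by_pattern_um2": {
                str(k): v for k, v in self.mean_cluster_size_by_pattern.items()
            },
            "mean_dwell_by_pattern_min": {
                str(k): (mean_dwell(v) if any(not d.censored for d in v) else None)
                for k, v in self.dwelling_times_by_pattern.items()
            },
            "large_cluster_threshold": self.large_cluster_threshold,
            "frame_interval_min": self.frame_interval_min,
        }


def analyze_trajectory(traj, large_threshold: int | None = None) -> AnalysisSummary:
    """Full per-frame and post-t_c analysis of a Trajectory.

    When t_c is undefined (no membrane-bound clathrin at the end), pattern
    statistics fall back to the second half of the run so that degenerate
    no-assembly conditions still report a modal cluster number (zero).
    """
    cfg = traj.config
    threshold = cfg.large_cluster_threshold if large_threshold is None else large_threshold
    footprint = cfg.geometry.footprint_radius

    times_us = traj.times
    n_frames = len(traj.frames)
    cluster_numbers = np.zeros(n_frames, dtype=int)
    membrane_bound = np.zeros(n_frames, dtype=int)
    mean_sizes = np.full(n_frames, np.nan)
    for k, frame in enumerate(traj.frames):
        records = find_clusters(
            frame.cc_bonds,
            frame.ap2_id >= 0,
            positions=frame.pos,
            footprint_radius=footprint,
            large_threshold=threshold,
        )
        cluster_numbers[k] = counted_cluster_number(records)
        membrane_bound[k] = membrane_bound_clathrin_count(records)
        try:
            mean_sizes[k] = mean_cluster_size(records)
        except InsufficientDataError:
            pass

    tc_us = compute_tc(membrane_bound, times_us)
    if tc_us is None:
        window = times_us >= times_us[len(times_us) // 2]
        tc_min = None
    else:
        window = times_us >= tc_us
        tc_min = tc_us / US_PER_MIN

    freqs, mode = pattern_statistics(cluster_numbers[window])
    sizes_by_pattern = {}
    dwells_all = dwelling_times(cluster_numbers[window], times_us[window])
    dwells_by_pattern: dict[int, list[Dwell]] = {}
    for d in dwells_all:
        dwells_by_pattern.setdefault(d.pattern, []).append(d)
    for patt in freqs:
        sel = cluster_numbers[window] == patt
        vals = mean_sizes[window][sel]
        vals = vals[~np.isnan(vals)]
        if len(vals):
            sizes_by_pattern[patt] = float(np.mean(vals))

    spacing_min = (
        (times_us[1] - times_us[0]) / US_PER_MIN if len(times_us) > 1 else 0.0
    )
    return AnalysisSummary(
        times_min=times_us / US_PER_MIN,
        cluster_number_series=cluster_numbers,
        membrane_bound_series=membrane_bound,
        mean_size_series=mean_sizes,
        tc_min=tc_min,
        pattern_frequencies=freqs,
        most_possible_pattern=mode,
        mean_cluster_size_by_pattern=sizes_by_pattern,
        dwelling_times_by_pattern=dwells_by_pattern,
        large_cluster_threshold=threshold,
        frame_interval_min=spacing_min,
    )


def plot_summary(summary: AnalysisSummary, path: str) -> None:
    """Time courses and post-t_c histograms, mirroring the standard figure
    layout (cluster number + membrane-bound vs time; frequency bars)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    ax = axes[0]
    ax.plot(summary.times_min, summary.cluster_number_series, color="tab:blue")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("counted clusters", color="tab:blue")
    ax2 = ax.twinx()
    ax2.plot(summary.times_min, summary.membrane_bound_series, color="tab:red")
    ax2.set_ylabel("membrane-bound clathrins", color="tab:red")
    if summary.tc_min is not None:
        ax.axvline(summary.tc_min, ls="--", color="gray")

    patt = sorted(summary.pattern_frequencies)
    axes[1].bar(patt, [summary.pattern_frequencies[p] for p in patt])
    axes[1].set_xlabel("cluster number")
    axes[1].set_ylabel("frequency after t_c")

    sizes = summary.mean_size_series
    sizes = sizes[~np.isnan(sizes)]
    if len(sizes):
        axes[2].hist(sizes, bins=20)
    axes[2].set_xlabel("mean cluster size (um$^2$)")
    axes[2].set_ylabel("frames")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
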