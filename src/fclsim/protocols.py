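"""Desk-scale study protocols: scaled-down replicas of the reference
membrane-patch conditions.

The reference conditions (1 um box, 300 clathrins, 30 simulated minutes at
3 us steps) need ~6e8 steps per run and are cluster-compute scale.  For
interactive testing and for the parameter-sweep comparisons this module
fixes one scaled-down protocol:

* geometry: box edge halved to 500 nm; molecule counts divided by 5
  (60 clathrins), preserving concentrations to within a factor ~1.6;
* kinetics: the AP-2 capture/release step is reaction-limited (its rates
  are far below the diffusion limit) and is compressed by ``AP2_TIME_SCALE``
  so membrane loading equilibrates within the shortened run; the
  clathrin-clathrin dissociation rate is compressed by ``CC_OFF_SCALE`` so
  bond turnover is resolved; the gated clathrin-clathrin association is
  diffusion-limited already and is left at its reference value;
* duration: 0.3 simulated seconds (1e5 steps), frames every 3 ms.

These choices trade absolute timescales for feasibility while preserving
the mechanism under study: AP-2 availability controls membrane loading,
and membrane loading controls whether many small or one giant lattice
forms.  Modal cluster numbers from this protocol are therefore compared to
the reference-scale phenomenology only qualitatively (0 clusters at scarce
AP-2, one giant cluster at abundant AP-2, monotone trends in the sweeps).
"""

from __future__ import annotations

import numpy as np

from .brownian_engine import SimulationConfig
from .cluster_analysis import analyze_trajectory
from .reaction_kinetics import RateTable

#: compression of the reaction-limited AP-2 capture/release kinetics
AP2_TIME_SCALE = 3000.0
#: compression of clathrin-clathrin dissociation
CC_OFF_SCALE = 10.0
#: desk box edge, nm
DESK_BOX = 500.0
#: desk clathrin count (reference 300 divided by COUNT_SCALE)
COUNT_SCALE = 5
DESK_N_CLATHRIN = 60
#: desk run length, us (0.3 simulated seconds)
DESK_DURATION = 3.0e5
#: desk frame interval, us (3 ms; sets the dwell-time resolution)
DESK_FRAME_INTERVAL = 3.0e3


def desk_config(
    n_ap2_reference: int,
    seed: int,
    k_cc_mult: float = 1.0,
    d_clat_mult: float = 1.0,
    duration: float = DESK_DURATION,
) -> SimulationConfig:
    """Scaled-down analogue of a reference-scale condition.

    ``n_ap2_reference`` is the AP-2 number quoted at reference scale (e.g.
    10, 150, 400); it is divided by COUNT_SCALE for the desk box.
    ``k_cc_mult`` and ``d_clat_mult`` scale the gated clathrin-clathrin
    rate and clathrin translational diffusion relative to the reference
    values (k = 50 x 0.913 uM^-1 s^-1, D = 13 um^2/s).
    """
    from .model_core import DiffusionSpec

    rates = RateTable().scaled(
        k_ap2_clat=AP2_TIME_SCALE,
        koff_ap2_clat=AP2_TIME_SCALE,
        koff_cc=CC_OFF_SCALE,
        k_cc_gated=k_cc_mult,
    )
    base = DiffusionSpec.clathrin_default()
    diff = DiffusionSpec(
        tuple(np.asarray(base.d_trans) * d_clat_mult), base.d_rot
    )
    return SimulationConfig(
        box_edge=DESK_BOX,
        n_clathrin=DESK_N_CLATHRIN,
        n_ap2=max(0, round(n_ap2_reference / COUNT_SCALE)),
        rates=rates,
        clathrin_diffusion=diff,
        duration=duration,
        frame_interval=DESK_FRAME_INTERVAL,
        seed=seed,
    )


#: counted-cluster threshold scaled with the population: the reference
#: definition (> 10 of 300 clathrins) maps to > 2 of the 60 desk clathrins
DESK_SCALED_THRESHOLD = 2


def run_condition(
    n_ap2_reference: int,
    seeds,
    k_cc_mult: float = 1.0,
    d_clat_mult: float = 1.0,
    duration: float = DESK_DURATION,
):
    """Run one desk-scale condition over several seeds.

    Returns the list of per-seed trajectories (analyse with
    :func:`summarize` at the threshold appropriate to the comparison).
    """
    from .brownian_engine import run_simulation

    return [
        run_simulation(
            desk_config(
                n_ap2_reference,
                int(seed),
                k_cc_mult=k_cc_mult,
                d_clat_mult=d_clat_mult,
                duration=duration,
            )
        )
        for seed in seeds
    ]


def summarize(trajectories, large_threshold: int | None = None):
    """Per-seed AnalysisSummary objects at a chosen counted threshold."""
    return [
        analyze_trajectory(t, large_threshold=large_threshold)
        for t in trajectories
    ]


def pooled_modal_pattern(summaries) -> int:
    """Modal counted-cluster number over the pooled post-t_c frames of
    replicate runs (ties toward the smaller number)."""
    pooled = []
    for s in summaries:
        times = s.times_min
        if s.tc_min is None:
            window = times >= times[len(times) // 2]
        else:
            window = times >= s.tc_min
        pooled.append(s.cluster_number_series[window])
    series = np.concatenate(pooled)
    values, counts = np.unique(series, return_counts=True)
    return int(values[np.argmax(counts)])


def mean_cluster_numbers(summaries) -> np.ndarray:
    """Per-seed mean counted-cluster number over post-t_c frames."""
    out = []
    for s in summaries:
        times = s.times_min
        if s.tc_min is None:
            window = times >= times[len(times) // 2]
        else:
            window = times >= s.tc_min
        out.append(float(np.mean(s.cluster_number_series[window])))
    return np.array(out)


def mean_cluster_sizes(summaries) -> np.ndarray:
    """Per-seed mean counted-cluster area (um^2) over post-t_c frames;
    NaN for seeds that never formed a counted cluster."""
    out = []
    for s in summaries:
        times = s.times_min
        if s.tc_min is None:
            window = times >= times[len(times) // 2]
        else:
            window = times >= s.tc_min
        vals = s.mean_size_series[window]
        vals = vals[~np.isnan(vals)]
        out.append(float(np.mean(vals)) if len(vals) else np.nan)
    return np.array(out)
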