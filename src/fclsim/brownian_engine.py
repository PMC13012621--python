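"""Per-step update loop of the membrane-patch simulator.

Each 3 us step: (1) dissociation tests over all bonds, (2) association
tests (implicit AP-2 capture layer first, then clathrin-clathrin site
pairs) with analytic bound-pose placement, rejected when the bound cluster
would leave the domain or violate excluded volume, (3) rigid-body diffusion
of every entity (molecule or bonded cluster) not involved in a reaction,
with reflecting boundaries and excluded-volume resampling of overlapping
proposals.  Parameters may change mid-run through a piecewise-constant
schedule (the EGF stimulus protocol).

State is kept as flat numpy arrays over the fixed clathrin population;
bound AP-2 molecules are bookkept per host clathrin and their coordinates
derived from the host's AP-2 site (always on z = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from . import _quat
from .model_core import (
    ClathrinGeometry,
    DiffusionSpec,
    compose_cluster_diffusion,
)
from .reaction_kinetics import AP2Pool, RateTable, sample_events

EZ = np.array([0.0, 0.0, 1.0])

#: geometric tolerance (nm) for domain-boundary and ring-closure tests
GEOM_TOL = 1e-9
#: slack (nm) around the exact bond gap accepted for intra-cluster ring closure
RING_CLOSURE_TOL = 0.5
#: maximum tilt (rad) of a free cluster's plane for whole-cluster membrane snap
SNAP_TILT_TOL = 0.2


class ConfigError(ValueError):
    """Invalid simulation configuration or schedule."""


class SimulationAbortError(RuntimeError):
    """A state invariant was violated during stepping."""


@dataclass(frozen=True)
class ParameterSchedule:
    """Piecewise-constant parameter overrides, e.g. the EGF protocol.

    ``breakpoints`` is an ordered tuple of ``(time_us, overrides)``; from a
    breakpoint onward the overrides replace the baseline until the next one.
    An empty override dict reverts to baseline.  Allowed keys: ``n_ap2``
    (absolute count) and the multipliers ``k_cc_gated_mult``,
    ``k_cc_free_mult``, ``k_ap2_clat_mult``, ``koff_cc_mult``,
    ``koff_ap2_mult``, ``d_clat_mult``.
    """

    breakpoints: tuple = ()

    ALLOWED_KEYS = frozenset(
        {
            "n_ap2",
            "k_cc_gated_mult",
            "k_cc_free_mult",
            "k_ap2_clat_mult",
            "koff_cc_mult",
            "koff_ap2_mult",
            "d_clat_mult",
        }
    )

    def __post_init__(self) -> None:
        times = [bp[0] for bp in self.breakpoints]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ConfigError("schedule breakpoint times must be strictly increasing")
        for _, overrides in self.breakpoints:
            unknown = set(overrides) - self.ALLOWED_KEYS
            if unknown:
                raise ConfigError(f"unknown schedule override(s): {sorted(unknown)}")

    def segment_at(self, t: float) -> dict:
        current: dict = {}
        for bp_time, overrides in self.breakpoints:
            if t >= bp_time:
                current = overrides
            else:
                break
        return current


@dataclass(frozen=True)
class SimulationConfig:
    """All physical, kinetic and scheduling parameters of one run.

    Units: nm, us.  Defaults are the reference membrane-patch conditions:
    a 1 um box, 3 us steps, 300 clathrins, 150 AP-2.
    """

    box_edge: float = 1000.0
    dt: float = 3.0
    n_clathrin: int = 300
    n_ap2: int = 150
    rates: RateTable = field(default_factory=RateTable)
    clathrin_diffusion: DiffusionSpec = field(
        default_factory=DiffusionSpec.clathrin_default
    )
    ap2_diffusion: DiffusionSpec = field(default_factory=DiffusionSpec.ap2_default)
    geometry: ClathrinGeometry = field(default_factory=ClathrinGeometry)
    duration: float = 1.8e9  # 30 simulated minutes
    frame_interval: float = 1e5  # 0.1 simulated seconds
    seed: int = 0
    schedule: ParameterSchedule | None = None
    reaction_radius: float = 5.0
    capture_height: float = 10.0
    max_retries: int = 100
    large_cluster_threshold: int = 10
    debug_checks: bool = False

    def __post_init__(self) -> None:
        if min(self.box_edge, self.dt, self.frame_interval) <= 0:
            raise ConfigError("box_edge, dt and frame_interval must be > 0")
        if self.duration < 0:
            raise ConfigError("duration must be >= 0")
        if self.frame_interval < self.dt:
            raise ConfigError("frame_interval must be >= dt")
        if self.n_clathrin < 0 or self.n_ap2 < 0:
            raise ConfigError("molecule counts must be >= 0")
        if self.reaction_radius <= 0 or self.capture_height <= 0:
            raise ConfigError("reaction_radius and capture_height must be > 0")


@dataclass(frozen=True)
class EffectiveParameters:
    """Schedule-resolved parameters for one instant."""

    rates: RateTable
    clathrin_diffusion: DiffusionSpec
    ap2_diffusion: DiffusionSpec
    n_ap2: int


def apply_schedule(
    config: SimulationConfig, schedule: ParameterSchedule | None, t: float
) -> EffectiveParameters:
    """Resolve the piecewise-constant parameters in force at time ``t``."""
    overrides = schedule.segment_at(t) if schedule is not None else {}
    rate_mults = {}
    for key, fieldname in (
        ("k_cc_gated_mult", "k_cc_gated"),
        ("k_cc_free_mult", "k_cc_free"),
        ("k_ap2_clat_mult", "k_ap2_clat"),
        ("koff_cc_mult", "koff_cc"),
        ("koff_ap2_mult", "koff_ap2_clat"),
    ):
        if key in overrides:
            rate_mults[fieldname] = overrides[key]
    rates = config.rates.scaled(**rate_mults) if rate_mults else config.rates
    diff = config.clathrin_diffusion
    if "d_clat_mult" in overrides:
        m = overrides["d_clat_mult"]
        diff = DiffusionSpec(tuple(np.asarray(diff.d_trans) * m), diff.d_rot)
    return EffectiveParameters(
        rates=rates,
        clathrin_diffusion=diff,
        ap2_diffusion=config.ap2_diffusion,
        n_ap2=int(overrides.get("n_ap2", config.n_ap2)),
    )


# --------------------------------------------------------------------------
# state
# --------------------------------------------------------------------------


@dataclass
class SystemState:
    """Full molecular snapshot: clathrin poses, bond graph, AP-2 pool.

    ``leg_partner[i, s]`` / ``leg_partner_site[i, s]`` give the clathrin id
    and site index bound to clathrin ``i``'s leg site ``s`` (-1 when free).
    ``ap2_id[i]`` is the molecule id of the AP-2 bound at clathrin ``i``'s
    AP-2 site (-1 when free); AP-2 coordinates are derived from the host's
    site and always lie on z = 0.
    """

    time: float
    box_edge: float
    pos: np.ndarray  # (N, 3)
    quat: np.ndarray  # (N, 4), scipy xyzw order
    leg_partner: np.ndarray  # (N, 3) int
    leg_partner_site: np.ndarray  # (N, 3) int
    ap2_id: np.ndarray  # (N,) int
    ap2_pool: AP2Pool
    next_ap2_id: int
    #: memoised cluster labels; invalidated whenever the bond graph changes
    cached_labels: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_clathrin(self) -> int:
        return len(self.pos)

    def copy(self) -> "SystemState":
        return SystemState(
            time=self.time,
            box_edge=self.box_edge,
            pos=self.pos.copy(),
            quat=self.quat.copy(),
            leg_partner=self.leg_partner.copy(),
            leg_partner_site=self.leg_partner_site.copy(),
            ap2_id=self.ap2_id.copy(),
            ap2_pool=replace(self.ap2_pool),
            next_ap2_id=self.next_ap2_id,
        )  # cached_labels deliberately not copied

    def site_coords(self, geom: ClathrinGeometry) -> np.ndarray:
        """(N, 4, 3) world coordinates of all clathrin sites."""
        mats = _quat.to_matrix(self.quat.reshape(-1, 4))
        return self.pos[:, None, :] + np.einsum(
            "nij,sj->nsi", mats, geom.site_offsets
        )

    def cc_bonds(self) -> list:
        """Unique clathrin-clathrin bonds as (i, site_i, j, site_j), i < j."""
        ii, ss = np.nonzero(self.leg_partner >= 0)
        jj = self.leg_partner[ii, ss]
        keep = jj > ii
        tt = self.leg_partner_site[ii, ss]
        return list(
            zip(
                ii[keep].tolist(),
                ss[keep].tolist(),
                jj[keep].tolist(),
                tt[keep].tolist(),
            )
        )

    def cluster_labels(self) -> np.ndarray:
        """Connected-component label per clathrin over the bond graph."""
        if self.cached_labels is not None:
            return self.cached_labels
        n = self.n_clathrin
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        ii, ss = np.nonzero(self.leg_partner >= 0)
        for i, s in zip(ii.tolist(), ss.tolist()):
            j = int(self.leg_partner[i, s])
            if j > i:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[rb] = ra
        roots = np.fromiter((find(i) for i in range(n)), dtype=int, count=n)
        _, labels = np.unique(roots, return_inverse=True)
        self.cached_labels = labels
        return labels

    def cluster_info(self):
        """(labels, has_ap2-per-label): membrane-bound flag by cluster."""
        labels = self.cluster_labels()
        n_lab = labels.max() + 1 if len(labels) else 0
        has = np.zeros(n_lab, dtype=bool)
        np.maximum.at(has, labels, self.ap2_id >= 0)
        return labels, has

    def bond_symmetry_check(self) -> None:
        for i in range(self.n_clathrin):
            for s in range(3):
                j = self.leg_partner[i, s]
                if j >= 0:
                    t = self.leg_partner_site[i, s]
                    if (
                        self.leg_partner[j, t] != i
                        or self.leg_partner_site[j, t] != s
                    ):
                        raise SimulationAbortError(
                            f"asymmetric bond {i}:{s} <-> {j}:{t}"
                        )

    def check_invariants(self, geom: ClathrinGeometry) -> None:
        L = self.box_edge
        if np.any(~np.isfinite(self.pos)):
            raise SimulationAbortError("non-finite position")
        if np.any(self.pos < -GEOM_TOL) or np.any(self.pos > L + GEOM_TOL):
            raise SimulationAbortError("position outside [0, L]^3")
        if self.n_clathrin > 1:
            d2 = _pairwise_sq(self.pos)
            np.fill_diagonal(d2, np.inf)
            if d2.min() < (geom.excluded_diameter - 1e-6) ** 2:
                raise SimulationAbortError(
                    f"excluded volume violated: min distance {np.sqrt(d2.min()):.3f} nm"
                )
        self.bond_symmetry_check()
        self.ap2_pool.check()
        if self.ap2_pool.n_bound != int(np.sum(self.ap2_id >= 0)):
            raise SimulationAbortError("AP-2 pool out of sync with bound instances")


from functools import lru_cache


@lru_cache(maxsize=4096)
def _composed_spec(clat_spec, ap2_spec, n_clat, n_ap2):
    """Memoised cluster-diffusion composition for n_clat + n_ap2 members."""
    return compose_cluster_diffusion([clat_spec] * n_clat + [ap2_spec] * n_ap2)


def _pairwise_sq(pos: np.ndarray) -> np.ndarray:
    diff = pos[:, None, :] - pos[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


# --------------------------------------------------------------------------
# boundary handling
# --------------------------------------------------------------------------


def reflect_into_domain(position, L: float):
    """Mirror coordinates into [0, L] per axis (reflecting walls).

    Applies pos -> -pos at 0 and pos -> 2L - pos at L, iterated until the
    point is inside; the closed form folds over the period 2L.
    """
    p = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(p)):
        raise SimulationAbortError("non-finite position in reflection")
    r = np.mod(p, 2.0 * L)
    return np.where(r > L, 2.0 * L - r, r)


def _reflect_entity(block: np.ndarray, L: float):
    """Reflect a rigid multi-molecule block by mirror translations of its
    extreme coordinate; returns the shifted block or None if it cannot fit."""
    out = block.copy()
    for _ in range(8):
        lo = out.min(axis=0)
        hi = out.max(axis=0)
        if np.all(lo >= 0.0) and np.all(hi <= L):
            return out
        for ax in range(3):
            if lo[ax] < 0.0:
                out[:, ax] += -2.0 * lo[ax]
            elif hi[ax] > L:
                out[:, ax] += 2.0 * (L - hi[ax])
        if np.any(out.max(axis=0) - out.min(axis=0) > L):
            return None
    lo, hi = out.min(axis=0), out.max(axis=0)
    return out if np.all(lo >= 0.0) and np.all(hi <= L) else None


def reject_out_of_domain_association(points: np.ndarray, L: float) -> bool:
    """True (reject) iff any post-binding center/site lies strictly outside
    the closed domain [0, L]^3."""
    pts = np.asarray(points, dtype=float)
    return bool(np.any(pts < -GEOM_TOL) or np.any(pts > L + GEOM_TOL))


# --------------------------------------------------------------------------
# bond placement (association execution)
# --------------------------------------------------------------------------


def _leg_target_rotation(u: np.ndarray, n: np.ndarray, site: int) -> Rotation:
    """Orientation for a clathrin bound head-to-head via leg ``site`` whose
    bound leg points along -u in the plane of normal n."""
    x_axis = -u
    y_axis = np.cross(n, x_axis)
    base = Rotation.from_matrix(np.column_stack([x_axis, y_axis, n]))
    return base * Rotation.from_euler("z", -120.0 * site, degrees=True)


class _BindExecutor:
    """validate-and-apply callback handed to sample_events.

    Computes the analytic bound pose for each proposed association, rejects
    events whose placement would leave the domain or violate excluded
    volume, and mutates the state in place for accepted ones.
    """

    def __init__(self, state: SystemState, config: SimulationConfig, labels, has_ap2):
        self.state = state
        self.config = config
        self.labels = labels.copy()
        self.has_ap2 = has_ap2
        self.geom = config.geometry

    def __call__(self, event) -> bool:
        if event.kind == "bind_cc":
            return self._bind_cc(event)
        if event.kind == "bind_ap2":
            return self._bind_ap2(event)
        return True

    # -- clathrin-clathrin --------------------------------------------------

    def _bind_cc(self, event) -> bool:
        (i, si), (j, sj) = event.participants
        st, geom = self.state, self.geom
        sites = st.site_coords(geom)
        dist = float(np.linalg.norm(sites[i, si] - sites[j, sj]))
        if dist > self.config.reaction_radius + GEOM_TOL:
            return False  # candidate went stale after an earlier placement
        li, lj = self.labels[i], self.labels[j]
        if li == lj:
            # ring closure inside one rigid cluster: no pose change possible,
            # accept only if the sites already sit at the bond gap
            if abs(dist - geom.bond_gap) > RING_CLOSURE_TOL:
                return False
            self._set_bond(i, si, j, sj)
            return True

        mem_i, mem_j = bool(self.has_ap2[li]), bool(self.has_ap2[lj])
        members_i = np.flatnonzero(self.labels == li)
        members_j = np.flatnonzero(self.labels == lj)
        # the cytosolic side moves onto the membrane side; among equals the
        # smaller cluster moves (tie resolved toward the second participant)
        if mem_i != mem_j:
            mover_is_i = not mem_i
        else:
            mover_is_i = len(members_i) <= len(members_j)
        if mover_is_i:
            m, sm, s_, ss, movers = i, si, j, sj, members_i
        else:
            m, sm, s_, ss, movers = j, sj, i, si, members_j

        site_s = sites[s_, ss]
        u = site_s - st.pos[s_]
        u /= np.linalg.norm(u)
        n = Rotation.from_quat(st.quat[s_]).apply(EZ)
        target_site = site_s + geom.bond_gap * u
        target_center = target_site + geom.leg_radius * u
        rot_new = _leg_target_rotation(u, n, sm)
        rot_old = Rotation.from_quat(st.quat[m])
        r_delta = rot_new * rot_old.inv()

        new_pos = r_delta.apply(st.pos[movers] - st.pos[m]) + target_center
        new_quat = (r_delta * Rotation.from_quat(st.quat[movers])).as_quat()

        # domain: centers and all sites of the moved block must stay inside
        mats = Rotation.from_quat(new_quat).as_matrix()
        if mats.ndim == 2:
            mats = mats[None]
        new_sites = new_pos[:, None, :] + np.einsum(
            "nij,sj->nsi", mats, geom.site_offsets
        )
        probe = np.vstack([new_pos, new_sites.reshape(-1, 3)])
        if reject_out_of_domain_association(probe, st.box_edge):
            return False

        # excluded volume against everything outside the moved block
        others = np.setdiff1d(np.arange(st.n_clathrin), movers, assume_unique=False)
        if len(others):
            d2 = (
                (new_pos[:, None, :] - st.pos[others][None, :, :]) ** 2
            ).sum(axis=-1)
            if d2.min() < (geom.excluded_diameter - GEOM_TOL) ** 2:
                return False

        # moving a membrane-bound block must keep its AP-2 on the membrane
        if (mem_i if mover_is_i else mem_j):
            hosts = movers[st.ap2_id[movers] >= 0]
            idx = np.searchsorted(movers, hosts)
            ap2_z = new_sites[idx, geom.AP2_SITE, 2]
            if np.any(np.abs(ap2_z) > 1e-6):
                return False

        st.pos[movers] = new_pos
        st.quat[movers] = new_quat
        self._set_bond(i, si, j, sj)
        # merged component: relabel mover side so later gating sees the union
        self.labels[movers] = self.labels[s_]
        return True

    def _set_bond(self, i, si, j, sj) -> None:
        st = self.state
        st.cached_labels = None
        st.leg_partner[i, si] = j
        st.leg_partner_site[i, si] = sj
        st.leg_partner[j, sj] = i
        st.leg_partner_site[j, sj] = si

    # -- AP-2 capture -------------------------------------------------------

    def _bind_ap2(self, event) -> bool:
        (i, _site), _ = event.participants
        st, geom = self.state, self.geom
        members = np.flatnonzero(self.labels == self.labels[i])
        if len(members) == 1 and not self.has_ap2[self.labels[i]]:
            ok = self._snap_monomer(i)
        elif self.has_ap2[self.labels[i]]:
            # cluster already membrane-aligned: attach without moving
            site_z = st.site_coords(geom)[i, geom.AP2_SITE, 2]
            ok = abs(site_z) <= 1e-3
        else:
            ok = self._snap_cluster(members)
        if not ok:
            return False
        st.ap2_id[i] = st.next_ap2_id
        st.next_ap2_id += 1
        self.has_ap2[self.labels[i]] = True
        return True

    def _snap_monomer(self, i: int) -> bool:
        st, geom = self.state, self.geom
        rot = Rotation.from_quat(st.quat[i])
        bx = rot.apply(np.array([1.0, 0.0, 0.0]))
        bxp = np.array([bx[0], bx[1], 0.0])
        if np.linalg.norm(bxp) < 1e-12:
            by = rot.apply(np.array([0.0, 1.0, 0.0]))
            bxp = np.array([by[1], -by[0], 0.0])
        x_axis = bxp / np.linalg.norm(bxp)
        y_axis = np.cross(EZ, x_axis)
        rot_new = Rotation.from_matrix(np.column_stack([x_axis, y_axis, EZ]))
        new_pos = np.array([st.pos[i, 0], st.pos[i, 1], geom.ap2_site_depth])
        leg_pts = new_pos + rot_new.apply(geom.leg_site_offsets)
        if reject_out_of_domain_association(
            np.vstack([new_pos[None], leg_pts]), st.box_edge
        ):
            return False
        others = np.arange(st.n_clathrin) != i
        if np.any(others):
            d2 = ((st.pos[others] - new_pos) ** 2).sum(axis=-1)
            if d2.min() < (geom.excluded_diameter - GEOM_TOL) ** 2:
                return False
        st.pos[i] = new_pos
        st.quat[i] = rot_new.as_quat()
        return True

    def _snap_cluster(self, members: np.ndarray) -> bool:
        """Rigidly rotate/translate a free planar cluster onto the membrane,
        allowed only when it is already nearly upright."""
        st, geom = self.state, self.geom
        n = Rotation.from_quat(st.quat[members[0]]).apply(EZ)
        if n[2] < np.cos(SNAP_TILT_TOL):
            return False
        axis = np.cross(n, EZ)
        s = np.linalg.norm(axis)
        r_delta = (
            Rotation.identity()
            if s < 1e-12
            else Rotation.from_rotvec(axis / s * np.arcsin(np.clip(s, -1, 1)))
        )
        pivot = st.pos[members].mean(axis=0)
        new_pos = r_delta.apply(st.pos[members] - pivot) + pivot
        new_pos[:, 2] += geom.ap2_site_depth - new_pos[0, 2]
        new_quat = (r_delta * Rotation.from_quat(st.quat[members])).as_quat()
        mats = Rotation.from_quat(new_quat).as_matrix()
        if mats.ndim == 2:
            mats = mats[None]
        new_sites = new_pos[:, None, :] + np.einsum(
            "nij,sj->nsi", mats, geom.site_offsets
        )
        probe = np.vstack([new_pos, new_sites.reshape(-1, 3)])
        if reject_out_of_domain_association(probe, st.box_edge):
            return False
        others = np.setdiff1d(np.arange(st.n_clathrin), members)
        if len(others):
            d2 = ((new_pos[:, None, :] - st.pos[others][None, :, :]) ** 2).sum(-1)
            if d2.min() < (geom.excluded_diameter - GEOM_TOL) ** 2:
                return False
        st.pos[members] = new_pos
        st.quat[members] = new_quat
        return True


# --------------------------------------------------------------------------
# diffusion
# --------------------------------------------------------------------------


def diffusion_step(spec: DiffusionSpec, dt: float, rng: np.random.Generator):
    """Draw one rigid Brownian move: per-axis Gaussian displacement with
    variance 2 D dt and per-axis rotation angle with variance 2 D_R dt,
    composed extrinsically about the world x, y, z axes."""
    delta = rng.standard_normal(3) * np.sqrt(2.0 * spec.trans * dt)
    angles = rng.standard_normal(3) * np.sqrt(2.0 * spec.rot * dt)
    return delta, Rotation.from_euler("xyz", angles)


def resolve_overlaps(
    current_pos: np.ndarray,
    proposed_pos: np.ndarray,
    entity_of: np.ndarray,
    excluded_diameter: float,
    redraw,
    revert,
    max_retries: int,
) -> None:
    """Resample proposed moves until no clathrin pair is closer than the
    excluded diameter.

    ``entity_of[i]`` maps a molecule to its mobile entity index (-1 for
    frozen molecules).  ``redraw(entities)`` draws fresh moves for the given
    entity indices (mutating ``proposed_pos``); after ``max_retries``
    exhausted retries ``revert(entities)`` restores pre-move poses.
    Mutates ``proposed_pos`` in place.
    """
    lim2 = (excluded_diameter - GEOM_TOL) ** 2

    def offending_entities():
        d2 = _pairwise_sq(proposed_pos)
        np.fill_diagonal(d2, np.inf)
        ii, jj = np.nonzero(d2 < lim2)
        ents = set()
        for a, b in zip(ii, jj):
            if entity_of[a] >= 0:
                ents.add(int(entity_of[a]))
            if entity_of[b] >= 0:
                ents.add(int(entity_of[b]))
        return sorted(ents)

    for _ in range(max_retries):
        bad = offending_entities()
        if not bad:
            return
        redraw(bad)
    # exhausted: conflicting mobile entities keep their pre-move poses
    while True:
        bad = offending_entities()
        if not bad:
            return
        revert(bad)


def step(
    state: SystemState,
    config: SimulationConfig,
    rng: np.random.Generator,
    effective: EffectiveParameters | None = None,
) -> SystemState:
    """Advance the system by one time step of ``config.dt`` us in place."""
    eff = effective if effective is not None else apply_schedule(config, None, state.time)
    geom = config.geometry

    labels, has_ap2 = state.cluster_info()
    binder = _BindExecutor(state, config, labels, has_ap2)
    events, frozen = sample_events(
        state,
        geom,
        eff.rates,
        config.dt,
        rng,
        reaction_radius=config.reaction_radius,
        capture_height=config.capture_height,
        validate_bind=binder,
        cluster=(labels, has_ap2),
    )
    # bind events were applied inline by the executor; apply dissociations now
    for ev in events:
        if ev.kind == "unbind_cc":
            (i, si), (j, sj) = ev.participants
            state.cached_labels = None
            state.leg_partner[i, si] = -1
            state.leg_partner_site[i, si] = -1
            state.leg_partner[j, sj] = -1
            state.leg_partner_site[j, sj] = -1
        elif ev.kind == "unbind_ap2":
            (i, _), _ = ev.participants
            state.ap2_id[i] = -1
            state.ap2_pool.release_bound()

    _diffuse_all(state, config, eff, rng, frozen, labels=None if events else labels)
    state.time += config.dt
    if config.debug_checks:
        state.check_invariants(geom)
    return state


def _diffuse_all(state, config, eff, rng, frozen, labels=None) -> None:
    geom = config.geometry
    dt = config.dt
    L = state.box_edge
    if labels is None:  # topology changed this step
        labels = state.cluster_labels()
    n = state.n_clathrin
    n_lab = labels.max() + 1 if n else 0
    frozen_lab = np.zeros(n_lab, dtype=bool)
    np.maximum.at(frozen_lab, labels, frozen)

    has_ap2_mol = state.ap2_id >= 0
    sizes = np.bincount(labels, minlength=n_lab)
    ap2_per_lab = np.bincount(labels[has_ap2_mol], minlength=n_lab)
    rep = np.empty(n_lab, dtype=int)
    rep[labels] = np.arange(n)

    mobile = ~frozen_lab
    free_single_labs = np.flatnonzero(mobile & (sizes == 1) & (ap2_per_lab == 0))
    mem_single_labs = np.flatnonzero(mobile & (sizes == 1) & (ap2_per_lab == 1))
    multi_labs = np.flatnonzero(mobile & (sizes > 1))

    clat_spec = eff.clathrin_diffusion
    ap2_spec = eff.ap2_diffusion
    sig_free_t = np.sqrt(2.0 * clat_spec.trans * dt)
    sig_free_r = np.sqrt(2.0 * clat_spec.rot * dt)
    mem_spec = _composed_spec(clat_spec, ap2_spec, 1, 1)
    sig_mem_t = np.sqrt(2.0 * mem_spec.trans * dt)
    sig_mem_r = np.sqrt(2.0 * mem_spec.rot * dt)

    # entity table: singles first (member, sigmas), then multi clusters
    single_members = np.concatenate([rep[free_single_labs], rep[mem_single_labs]])
    m_single = len(single_members)
    sig_t_list = [
        np.broadcast_to(sig_free_t, (len(free_single_labs), 3)),
        np.broadcast_to(sig_mem_t, (len(mem_single_labs), 3)),
    ]
    sig_r_list = [
        np.broadcast_to(sig_free_r, (len(free_single_labs), 3)),
        np.broadcast_to(sig_mem_r, (len(mem_single_labs), 3)),
    ]
    multi_entities = []  # (members, pivot)
    multi_sig_t = []
    multi_sig_r = []
    sites = state.site_coords(geom) if np.any(ap2_per_lab[multi_labs] > 0) else None
    for lab in multi_labs:
        members = np.flatnonzero(labels == lab)
        n_ap2_members = int(ap2_per_lab[lab])
        spec = _composed_spec(clat_spec, ap2_spec, len(members), n_ap2_members)
        if n_ap2_members:
            hosts = members[has_ap2_mol[members]]
            pts = np.vstack([state.pos[members], sites[hosts, geom.AP2_SITE, :]])
        else:
            pts = state.pos[members]
        multi_entities.append((members, pts.mean(axis=0)))
        multi_sig_t.append(np.sqrt(2.0 * spec.trans * dt))
        multi_sig_r.append(np.sqrt(2.0 * spec.rot * dt))

    m_total = m_single + len(multi_entities)
    if m_total == 0:
        return
    sig_t = np.vstack(sig_t_list + [np.array(multi_sig_t).reshape(-1, 3)])
    sig_r = np.vstack(sig_r_list + [np.array(multi_sig_r).reshape(-1, 3)])

    pre_pos = state.pos.copy()
    pre_quat = state.quat.copy()
    prop_pos = state.pos.copy()
    prop_quat = state.quat.copy()
    entity_of = np.full(n, -1, dtype=int)
    entity_of[single_members] = np.arange(m_single)
    for k, (members, _pivot) in enumerate(multi_entities):
        entity_of[members] = m_single + k

    def draw(entity_indices):
        idx = np.asarray(list(entity_indices), dtype=int)
        if not len(idx):
            return
        deltas = rng.standard_normal((len(idx), 3)) * sig_t[idx]
        angles = rng.standard_normal((len(idx), 3)) * sig_r[idx]
        qd = _quat.from_euler_xyz(angles)
        sing = idx < m_single
        if np.any(sing):
            mem = single_members[idx[sing]]
            prop_quat[mem] = _quat.normalize(
                _quat.multiply(qd[sing], pre_quat[mem])
            )
            prop_pos[mem] = reflect_into_domain(pre_pos[mem] + deltas[sing], L)
        multi_sel = np.flatnonzero(~sing)
        if not len(multi_sel):
            return
        # batched rigid transform over the concatenated members of all
        # selected clusters, then per-cluster boundary reflection
        ent_ids = idx[multi_sel] - m_single
        member_blocks = [multi_entities[e][0] for e in ent_ids]
        counts = np.array([len(b) for b in member_blocks])
        mem_all = np.concatenate(member_blocks)
        pivots = np.repeat(
            np.stack([multi_entities[e][1] for e in ent_ids]), counts, axis=0
        )
        q_rep = np.repeat(qd[multi_sel], counts, axis=0)
        d_rep = np.repeat(deltas[multi_sel], counts, axis=0)
        moved_all = _quat.apply(q_rep, pre_pos[mem_all] - pivots) + pivots + d_rep
        newq_all = _quat.normalize(_quat.multiply(q_rep, pre_quat[mem_all]))
        offset = 0
        for e, cnt in zip(ent_ids, counts):
            members = multi_entities[e][0]
            moved = moved_all[offset : offset + cnt]
            reflected = (
                moved
                if np.all(moved >= 0.0) and np.all(moved <= L)
                else _reflect_entity(moved, L)
            )
            if reflected is None:
                prop_pos[members] = pre_pos[members]
                prop_quat[members] = pre_quat[members]
            else:
                prop_pos[members] = reflected
                prop_quat[members] = newq_all[offset : offset + cnt]
            offset += cnt

    def revert(entity_indices):
        for e in entity_indices:
            if e < m_single:
                members = single_members[[e]]
            else:
                members = multi_entities[e - m_single][0]
            prop_pos[members] = pre_pos[members]
            prop_quat[members] = pre_quat[members]

    draw(range(m_total))
    resolve_overlaps(
        pre_pos,
        prop_pos,
        entity_of,
        geom.excluded_diameter,
        draw,
        revert,
        config.max_retries,
    )
    state.pos[:] = prop_pos
    state.quat[:] = prop_quat


# --------------------------------------------------------------------------
# trajectory
# --------------------------------------------------------------------------


@dataclass
class Frame:
    """One stored snapshot (copies, decoupled from the live state)."""

    time: float
    pos: np.ndarray
    quat: np.ndarray
    ap2_id: np.ndarray
    cc_bonds: np.ndarray  # (m, 4) int: i, site_i, j, site_j
    pool_total: int
    pool_bound: int
    pool_pending: int


@dataclass
class Trajectory:
    """Frames of one run plus the configuration and seed that produced it."""

    frames: list
    config: SimulationConfig
    seed: int

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


def snapshot(state: SystemState) -> Frame:
    bonds = state.cc_bonds()
    return Frame(
        time=state.time,
        pos=state.pos.copy(),
        quat=state.quat.copy(),
        ap2_id=state.ap2_id.copy(),
        cc_bonds=np.array(bonds, dtype=int).reshape(-1, 4),
        pool_total=state.ap2_pool.total,
        pool_bound=state.ap2_pool.n_bound,
        pool_pending=state.ap2_pool.pending_removal,
    )


def run_simulation(
    config: SimulationConfig, initial_state: SystemState | None = None
) -> Trajectory:
    """Run a full simulation: deterministic for a fixed config seed.

    Frames are recorded at t = 0 and every ``frame_interval`` thereafter.
    Mid-run AP-2 count changes from the schedule add to the free pool, or
    remove free AP-2 first and flag the remainder for removal upon their
    next unbinding.
    """
    from .fixtures_io import random_initial_condition  # deferred: avoids cycle

    rng = np.random.default_rng(config.seed)
    if initial_state is None:
        state = random_initial_condition(config, rng)
    else:
        state = initial_state.copy()

    n_steps = int(round(config.duration / config.dt))
    frame_every = max(1, int(round(config.frame_interval / config.dt)))
    frames = [snapshot(state)]
    applied_n_ap2 = config.n_ap2
    base_eff = apply_schedule(config, None, 0.0)
    for k in range(1, n_steps + 1):
        if config.schedule is not None:
            eff = apply_schedule(config, config.schedule, state.time)
            if eff.n_ap2 != applied_n_ap2:
                delta = eff.n_ap2 - applied_n_ap2
                if delta > 0:
                    state.ap2_pool.add_free(delta)
                else:
                    state.ap2_pool.schedule_removal(-delta)
                applied_n_ap2 = eff.n_ap2
        else:
            eff = base_eff
        step(state, config, rng, eff)
        if k % frame_every == 0:
            frames.append(snapshot(state))
    return Trajectory(frames=frames, config=config, seed=config.seed)
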