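"""Reaction rates, per-step probabilities and the implicit AP-2 pool.

Bimolecular rates are configured in uM^-1 s^-1 and converted to microscopic
volume rates in nm^3/us.  Association uses a Doi-style acceptance: a free
site pair within the reaction radius sigma reacts with probability
1 - exp(-lambda dt), lambda = k_micro / V_reaction.  The clathrin-clathrin
rate is gated: it is zero unless at least one partner belongs to an
AP-2-containing (membrane-bound) cluster.  Unbound AP-2 is an implicit
well-mixed membrane pool; capture of a clathrin whose AP-2 site dips into a
thin layer above the membrane follows pseudo-first-order kinetics in the
free-pool surface density.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model_core import InvalidParameterError

#: molecules per nm^3 at a concentration of 1 uM
MICROMOLAR_PER_NM3 = 6.02214076e-7


class InternalConsistencyError(RuntimeError):
    """The bond graph or pool bookkeeping is in an impossible state."""


def convert_bimolecular_rate(k: float) -> float:
    """Convert a bimolecular rate from uM^-1 s^-1 to nm^3/us.

    1 uM^-1 s^-1 = (1 / 6.022e-7 nm^-3) / 1e6 us/s ~= 1.6605 nm^3/us.
    """
    if k < 0:
        raise InvalidParameterError("bimolecular rate must be >= 0")
    return k / MICROMOLAR_PER_NM3 / 1e6


def dissociation_probability(koff: float, dt: float) -> float:
    """Poisson-process unbinding probability 1 - exp(-koff dt).

    ``koff`` in s^-1, ``dt`` in us.
    """
    if koff < 0:
        raise InvalidParameterError("koff must be >= 0")
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    return -np.expm1(-koff * 1e-6 * dt)


@dataclass(frozen=True)
class RateTable:
    """Kinetic parameters, association in uM^-1 s^-1, dissociation in s^-1.

    ``k_cc_gated`` applies to clathrin pairs of which at least one is bound
    to AP-2 (via its cluster); ``k_cc_free`` to pairs where neither is
    (zero in the reference model).  Defaults: the reference clathrin-clathrin
    rate 50 x 0.913 uM^-1 s^-1 and AP-2-clathrin rate 0.0012 uM^-1 s^-1;
    the dissociation rates are documented placeholders chosen to reproduce
    long-lived membrane clusters, and should be set explicitly in configs.
    """

    k_cc_gated: float = 50 * 0.913
    k_cc_free: float = 0.0
    k_ap2_clat: float = 0.0012
    koff_cc: float = 1.0
    koff_ap2_clat: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("k_cc_gated", "k_cc_free", "k_ap2_clat", "koff_cc", "koff_ap2_clat"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    def scaled(self, **multipliers: float) -> "RateTable":
        """New table with named fields multiplied (e.g. ``k_cc_gated=50``)."""
        updates = {}
        for name, mult in multipliers.items():
            if not hasattr(self, name):
                raise InvalidParameterError(f"unknown rate field {name!r}")
            updates[name] = getattr(self, name) * mult
        return replace(self, **updates)


@dataclass
class AP2Pool:
    """Implicit pool of membrane AP-2.

    ``total`` = free + bound; clathrin-bound instances are explicit molecules
    tracked by the engine, free ones only as a count.  ``pending_removal``
    supports mid-run AP-2 decreases: bound AP-2 flagged here leave the system
    upon their next unbinding instead of returning to the free pool.
    """

    total: int
    n_bound: int = 0
    pending_removal: int = 0

    @property
    def free_count(self) -> int:
        return self.total - self.n_bound

    def check(self) -> None:
        if not (0 <= self.n_bound <= self.total):
            raise InternalConsistencyError(
                f"AP-2 pool inconsistent: total={self.total} bound={self.n_bound}"
            )

    def take_free(self) -> None:
        if self.free_count <= 0:
            raise InternalConsistencyError("no free AP-2 to bind")
        self.n_bound += 1

    def release_bound(self) -> None:
        if self.n_bound <= 0:
            raise InternalConsistencyError("no bound AP-2 to release")
        self.n_bound -= 1
        if self.pending_removal > 0:
            # scheduled decrease: this AP-2 leaves instead of rejoining the pool
            self.pending_removal -= 1
            self.total -= 1

    def add_free(self, n: int) -> None:
        self.total += n

    def schedule_removal(self, n: int) -> None:
        """Remove up to ``n`` AP-2: free ones immediately, the rest flagged."""
        from_free = min(n, self.free_count)
        self.total -= from_free
        self.pending_removal += n - from_free


@dataclass(frozen=True)
class ReactionEvent:
    """One sampled reaction: kind in {bind_cc, unbind_cc, bind_ap2, unbind_ap2};
    participants is a tuple of (molecule_id, site_index) pairs."""

    kind: str
    participants: tuple
    time: float  # us


def gate_cc_rate(state_a: bool, state_b: bool, rates: RateTable) -> float:
    """Gated clathrin-clathrin rate: zero (k_cc_free) unless at least one
    partner is bound to AP-2 through its cluster."""
    return rates.k_cc_gated if (state_a or state_b) else rates.k_cc_free


def reaction_volume(reaction_radius: float, dims: int) -> float:
    if dims == 3:
        return 4.0 / 3.0 * np.pi * reaction_radius**3
    if dims == 2:
        return np.pi * reaction_radius**2
    raise InvalidParameterError("dims must be 2 or 3")


def association_acceptance(
    site_distance: float,
    k_micro: float,
    dt: float,
    reaction_radius: float,
    dims: int = 3,
) -> float:
    """Doi-style acceptance probability for a candidate site pair.

    ``k_micro`` in nm^3/us (3D) or nm^2/us (2D, i.e. already divided by the
    confinement height).  Zero outside the reaction radius; otherwise
    1 - exp(-k_micro / V_sigma * dt).
    """
    if site_distance < 0:
        raise InvalidParameterError("site_distance must be >= 0")
    if site_distance > reaction_radius or k_micro == 0.0:
        return 0.0
    lam = k_micro / reaction_volume(reaction_radius, dims)
    return -np.expm1(-lam * dt)


def ap2_binding_probability(
    ap2_site_height: float,
    free_count: int,
    box_edge: float,
    rates: RateTable,
    dt: float,
    capture_height: float,
) -> float:
    """Per-step capture probability of implicit AP-2 by a clathrin AP-2 site.

    The 3D rate is reduced to a 2D surface rate k2D = k3D / h over the
    capture layer of height ``h`` above the membrane; the free pool is
    well mixed with surface density free_count / L^2.
    """
    if free_count <= 0 or ap2_site_height > capture_height:
        return 0.0
    k2d = convert_bimolecular_rate(rates.k_ap2_clat) / capture_height  # nm^2/us
    rho = free_count / box_edge**2  # nm^-2
    return -np.expm1(-k2d * rho * dt)


def sample_events(
    state,
    geometry,
    rates: RateTable,
    dt: float,
    rng: np.random.Generator,
    *,
    reaction_radius: float,
    capture_height: float,
    validate_bind=None,
    cluster=None,
):
    """Sample one time step of reactions on ``state`` (a SystemState).

    Dissociations are tested first over all bonds, then AP-2 captures, then
    clathrin-clathrin associations over candidate site pairs within the
    reaction radius (both layers visited in RNG-shuffled order).  A molecule
    participates in at most one event per step; all participants are frozen
    (excluded from diffusion).  ``validate_bind(event) -> bool`` lets the
    caller veto a bind event on geometric grounds (overlap / domain); vetoed
    events are dropped and leave no trace.

    Returns ``(events, frozen_ids)``; the events are *not* applied here.
    """
    n = state.n_clathrin
    frozen = np.zeros(n, dtype=bool)
    events: list[ReactionEvent] = []
    t = state.time

    # --- dissociations first -------------------------------------------------
    p_cc = dissociation_probability(rates.koff_cc, dt)
    p_ap2 = dissociation_probability(rates.koff_ap2_clat, dt)
    bonds = state.cc_bonds()  # list of (i, site_i, j, site_j), i < j
    ap2_hosts = np.flatnonzero(state.ap2_id >= 0)
    m_diss = len(bonds) + len(ap2_hosts)
    if m_diss:
        perm = rng.permutation(m_diss)
        u = rng.random(m_diss)
        p_arr = np.where(perm < len(bonds), p_cc, p_ap2)
        for idx in perm[u < p_arr].tolist():
            if idx < len(bonds):
                i, si, j, sj = bonds[idx]
                if frozen[i] or frozen[j]:
                    continue
                events.append(ReactionEvent("unbind_cc", ((i, si), (j, sj)), t))
                frozen[i] = frozen[j] = True
            else:
                i = int(ap2_hosts[idx - len(bonds)])
                if frozen[i]:
                    continue
                events.append(
                    ReactionEvent(
                        "unbind_ap2",
                        ((i, geometry.AP2_SITE), (int(state.ap2_id[i]), 0)),
                        t,
                    )
                )
                frozen[i] = True

    sites = state.site_coords(geometry)  # (n, 4, 3)
    labels, cluster_has_ap2 = cluster if cluster is not None else state.cluster_info()

    # --- AP-2 capture layer --------------------------------------------------
    free0 = state.ap2_pool.free_count  # density frozen at start of step
    if free0 > 0 and rates.k_ap2_clat > 0:
        heights = sites[:, geometry.AP2_SITE, 2]
        eligible = np.flatnonzero(
            (state.ap2_id < 0) & ~frozen & (heights <= capture_height)
        )
        if len(eligible):
            # same capture probability for every eligible site this step
            p = ap2_binding_probability(
                0.0, free0, state.box_edge, rates, dt, capture_height
            )
            perm = rng.permutation(len(eligible))
            u = rng.random(len(eligible))
            for k in perm[u[perm] < p].tolist():
                i = int(eligible[k])
                if state.ap2_pool.free_count <= 0:
                    break
                if frozen[i]:
                    continue
                ev = ReactionEvent("bind_ap2", ((i, geometry.AP2_SITE), (-1, 0)), t)
                if validate_bind is not None and not validate_bind(ev):
                    continue
                events.append(ev)
                frozen[i] = True
                state.ap2_pool.take_free()  # reserve; engine instantiates

    # --- clathrin-clathrin association --------------------------------------
    gating_possible = bool(np.any(cluster_has_ap2)) or rates.k_cc_free > 0
    if gating_possible and (rates.k_cc_gated > 0 or rates.k_cc_free > 0):
        cand = _cc_candidates(state, sites, reaction_radius, frozen, geometry)
        if len(cand):
            k_gated = convert_bimolecular_rate(rates.k_cc_gated)
            k_free = convert_bimolecular_rate(rates.k_cc_free)
            bound_flag = cluster_has_ap2[labels]
            ci = cand[:, 0].astype(int)
            cj = cand[:, 2].astype(int)
            dist = cand[:, 4]
            a_b = bound_flag[ci]
            b_b = bound_flag[cj]
            k_micro = np.where(a_b | b_b, k_gated, k_free)
            both_2d = a_b & b_b
            vol3 = reaction_volume(reaction_radius, 3)
            vol2 = reaction_volume(reaction_radius, 2)
            lam = np.where(
                both_2d, (k_micro / capture_height) / vol2, k_micro / vol3
            )
            p_arr = -np.expm1(-lam * dt)
            perm = rng.permutation(len(cand))
            u = rng.random(len(cand))
            for idx in perm[u[perm] < p_arr[perm]].tolist():
                i, si, j, sj = int(ci[idx]), int(cand[idx, 1]), int(cj[idx]), int(cand[idx, 3])
                if frozen[i] or frozen[j]:
                    continue
                if state.leg_partner[i, si] >= 0 or state.leg_partner[j, sj] >= 0:
                    continue  # site consumed earlier this step
                ev = ReactionEvent("bind_cc", ((i, si), (j, sj)), t)
                if validate_bind is not None and not validate_bind(ev):
                    continue
                events.append(ev)
                frozen[i] = frozen[j] = True

    return events, frozen


def _cc_candidates(state, sites, reaction_radius, frozen, geometry):
    """Free leg-site pairs within the reaction radius, as an (m, 5) float
    array of rows (i, site_i, j, site_j, distance)."""
    free = state.leg_partner < 0  # (n, 3)
    active = ~frozen
    # broad phase on centers: sites cannot touch beyond this separation
    cutoff = 2 * geometry.leg_radius + reaction_radius
    pos = state.pos
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    ii, jj = np.nonzero(np.triu(d2 <= cutoff**2, k=1))
    rows = []
    for a, b in zip(ii, jj):
        if not (active[a] and active[b]):
            continue
        sa = np.flatnonzero(free[a])
        sb = np.flatnonzero(free[b])
        if not len(sa) or not len(sb):
            continue
        da = sites[a, sa][:, None, :] - sites[b, sb][None, :, :]
        dd = np.sqrt(np.sum(da**2, axis=-1))
        for x, y in zip(*np.nonzero(dd <= reaction_radius)):
            rows.append((a, sa[x], b, sb[y], dd[x, y]))
    return np.array(rows, dtype=float) if rows else np.empty((0, 5))
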