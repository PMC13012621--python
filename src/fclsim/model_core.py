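"""Rigid-body model of the clathrin triskelion and membrane-bound AP-2.

Clathrin is a rigid planar pinwheel: three clathrin-binding leg sites at
120 deg intervals in the body x-y plane, plus one AP-2-binding site offset
along the body -z axis.  AP-2 is a zero-volume dot confined to the membrane
plane z = 0.  This module owns the physical environment (Stokes-Einstein
diffusion coefficients), the per-species anisotropic diffusion specs, the
cluster diffusion composition rule, and the analytic post-binding pose
construction for both bond types.

Internal units throughout the package: nm, us (microseconds), K, Pa*s.
Note 1 um^2/s == 1 nm^2/us, so diffusion coefficients quoted in um^2/s can
be used verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

BOLTZMANN_J_PER_K = 1.380649e-23

#: squared-norm tolerance for unit quaternions
QUAT_NORM_TOL = 1e-9
#: coplanarity tolerance for bound poses, nm
COPLANAR_TOL = 1e-6
#: perpendicularity tolerance (dot product with the membrane normal)
PERP_TOL = 1e-9


class InvalidParameterError(ValueError):
    """A physical parameter violates its domain (e.g. non-positive radius)."""


class PlacementFailureError(RuntimeError):
    """A bound-partner pose could not be constructed without overlap."""


@dataclass(frozen=True)
class PhysicalEnvironment:
    """Thermal bath: temperature, solvent viscosity and k_B.

    Defaults are water at 25 C, the medium assumed for all diffusion
    coefficients derived here.
    """

    temperature: float = 298.15  # K
    viscosity: float = 8.9e-4  # Pa*s
    boltzmann_constant: float = BOLTZMANN_J_PER_K  # J/K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be > 0 K")
        if self.viscosity <= 0:
            raise InvalidParameterError("viscosity must be > 0 Pa*s")

    @property
    def kbt(self) -> float:
        """Thermal energy k_B*T in joules."""
        return self.boltzmann_constant * self.temperature


DEFAULT_ENV = PhysicalEnvironment()


def stokes_einstein(
    radius: float,
    env: PhysicalEnvironment = DEFAULT_ENV,
    mode: str = "translational",
) -> float:
    """Stokes-Einstein diffusion coefficient for a sphere of ``radius`` nm.

    ``mode='translational'`` returns k_BT / (6 pi eta r) in nm^2/us;
    ``mode='rotational'`` returns k_BT / (8 pi eta r^3) in rad^2/us.
    """
    if radius <= 0:
        raise InvalidParameterError(f"radius must be > 0 nm, got {radius}")
    r_m = radius * 1e-9
    if mode == "translational":
        d_si = env.kbt / (6.0 * np.pi * env.viscosity * r_m)  # m^2/s
        return d_si * 1e18 / 1e6  # -> nm^2/us
    if mode == "rotational":
        d_si = env.kbt / (8.0 * np.pi * env.viscosity * r_m**3)  # rad^2/s
        return d_si / 1e6  # -> rad^2/us
    raise InvalidParameterError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class DiffusionSpec:
    """Anisotropic diffusion coefficients of one rigid species.

    ``d_trans`` is (D_x, D_y, D_z) in nm^2/us; ``d_rot`` is
    (D_R,x, D_R,y, D_R,z) in rad^2/us, each about the body-through-centroid
    world axis.  Membrane confinement of AP-2 is expressed by D_z = 0 and
    D_R,x = D_R,y = 0.
    """

    d_trans: tuple[float, float, float]
    d_rot: tuple[float, float, float]

    def __post_init__(self) -> None:
        for v in (*self.d_trans, *self.d_rot):
            if v < 0:
                raise InvalidParameterError("diffusion coefficients must be >= 0")

    @property
    def trans(self) -> np.ndarray:
        return np.asarray(self.d_trans, dtype=float)

    @property
    def rot(self) -> np.ndarray:
        return np.asarray(self.d_rot, dtype=float)

    @staticmethod
    def isotropic(d_trans: float, d_rot: float) -> "DiffusionSpec":
        return DiffusionSpec((d_trans,) * 3, (d_rot,) * 3)

    @staticmethod
    def clathrin_default(
        d_trans: float = 13.0,
        rotation_radius: float = 12.5,
        env: PhysicalEnvironment = DEFAULT_ENV,
    ) -> "DiffusionSpec":
        """Free triskelion: reported translational D (13 um^2/s) on all axes,
        rotational D from Stokes-Einstein at the leg radius."""
        d_rot = stokes_einstein(rotation_radius, env, "rotational")
        return DiffusionSpec.isotropic(d_trans, d_rot)

    @staticmethod
    def ap2_default(
        radius: float = 5.0, env: PhysicalEnvironment = DEFAULT_ENV
    ) -> "DiffusionSpec":
        """Membrane-confined AP-2: in-plane Stokes-Einstein translation,
        rotation about the membrane normal only."""
        d = stokes_einstein(radius, env, "translational")
        d_r = stokes_einstein(radius, env, "rotational")
        return DiffusionSpec((d, d, 0.0), (0.0, 0.0, d_r))


def compose_cluster_diffusion(members) -> DiffusionSpec:
    """Diffusion spec of a rigidly bound cluster.

    Per axis, D_cluster = [sum_i D_i^-1]^-1 for translation and
    D_R,cluster = [sum_i D_R,i^(-1/3)]^-3 for rotation; a zero member
    component (infinite drag) forces the cluster component to zero, so any
    AP-2-containing cluster has D_z = 0 and D_R,x = D_R,y = 0 and cannot
    leave the membrane.
    """
    members = list(members)
    if not members:
        raise InvalidParameterError("cluster must have at least one member")
    trans = np.stack([m.trans for m in members])
    rot = np.stack([m.rot for m in members])

    out_t = np.zeros(3)
    out_r = np.zeros(3)
    for ax in range(3):
        t = trans[:, ax]
        out_t[ax] = 0.0 if np.any(t == 0) else 1.0 / np.sum(1.0 / t)
        r = rot[:, ax]
        out_r[ax] = 0.0 if np.any(r == 0) else np.sum(r ** (-1.0 / 3.0)) ** -3.0
    return DiffusionSpec(tuple(out_t), tuple(out_r))


def _default_leg_offsets(leg_radius: float) -> np.ndarray:
    angles = np.deg2rad([0.0, 120.0, 240.0])
    return np.column_stack(
        [leg_radius * np.cos(angles), leg_radius * np.sin(angles), np.zeros(3)]
    )


@dataclass(frozen=True)
class ClathrinGeometry:
    """Body-frame geometry of the rigid triskelion.

    Three leg (clathrin-binding) sites lie at ``leg_radius`` nm from the
    center at 120 deg intervals in the body x-y plane; the AP-2 site sits
    ``ap2_site_depth`` nm below the center along -z.  ``excluded_diameter``
    is the minimum allowed center-center distance between clathrins;
    ``bond_gap`` is the head-to-head site separation of a formed bond;
    ``footprint_radius`` buffers membrane-area calculations.
    """

    leg_radius: float = 12.5
    ap2_site_depth: float = 2.0
    excluded_diameter: float = 10.0
    bond_gap: float = 5.0
    footprint_radius: float = 12.5

    AP2_SITE: int = field(default=3, init=False, repr=False)

    def __post_init__(self) -> None:
        if self.excluded_diameter <= 0:
            raise InvalidParameterError("excluded_diameter must be > 0")
        if self.bond_gap <= 0:
            raise InvalidParameterError("bond_gap must be > 0")
        if self.leg_radius <= 0 or self.footprint_radius <= 0:
            raise InvalidParameterError("radii must be > 0")

    @property
    def leg_site_offsets(self) -> np.ndarray:
        """(3, 3) body-frame leg site coordinates, nm."""
        return _default_leg_offsets(self.leg_radius)

    @property
    def ap2_site_offset(self) -> np.ndarray:
        return np.array([0.0, 0.0, -self.ap2_site_depth])

    @property
    def site_offsets(self) -> np.ndarray:
        """(4, 3) body-frame site coordinates: legs 0-2, AP-2 site 3."""
        return np.vstack([self.leg_site_offsets, self.ap2_site_offset])


DEFAULT_GEOMETRY = ClathrinGeometry()


@dataclass
class RigidMolecule:
    """One molecule: a clathrin triskelion or a membrane-bound AP-2.

    ``orientation`` is a unit quaternion in scipy (x, y, z, w) order.
    ``bonds`` holds (own_site_index, partner_id, partner_site_index); a
    clathrin has sites 0-2 (legs) and 3 (AP-2 site), an AP-2 has site 0.
    """

    id: int
    species: str  # "clathrin" | "ap2"
    position: np.ndarray
    orientation: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0])
    )
    bonds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.species not in ("clathrin", "ap2"):
            raise InvalidParameterError(f"unknown species {self.species!r}")
        if abs(self.orientation @ self.orientation - 1.0) > QUAT_NORM_TOL:
            raise InvalidParameterError("orientation quaternion is not unit norm")
        own_sites = [b[0] for b in self.bonds]
        if len(own_sites) != len(set(own_sites)):
            raise InvalidParameterError("a site may be bound at most once")
        if self.species == "ap2" and abs(self.position[2]) > COPLANAR_TOL:
            raise InvalidParameterError("AP-2 must sit on the membrane (z = 0)")

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.orientation)


def site_world_coordinates(
    mol: RigidMolecule, geom: ClathrinGeometry = DEFAULT_GEOMETRY
) -> np.ndarray:
    """World coordinates of the four clathrin sites, shape (4, 3), nm."""
    return mol.position + mol.rotation.apply(geom.site_offsets)


def plane_normal(mol: RigidMolecule) -> np.ndarray:
    """World-frame normal of the triskelion leg plane (body +z)."""
    return mol.rotation.apply(np.array([0.0, 0.0, 1.0]))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise InvalidParameterError("zero-length vector has no direction")
    return v / n


def place_bound_partner(
    mol_a: RigidMolecule,
    site_index: int,
    geom: ClathrinGeometry = DEFAULT_GEOMETRY,
    kind: str = "clathrin_clathrin",
    partner_id: int = -1,
):
    """Analytic pose construction for a newly formed bond at ``site_index``.

    ``clathrin_clathrin``: returns the partner clathrin posed head-to-head
    against ``mol_a``'s leg site: bound sites exactly ``bond_gap`` apart,
    both centers and all six leg sites coplanar, the partner bound via its
    leg site 0.

    ``clathrin_ap2``: returns ``(snapped_a, ap2)`` where ``snapped_a`` is a
    copy of ``mol_a`` reoriented so its AP-2-site axis is perpendicular to
    the membrane (leg plane parallel to z = 0, preserving azimuth) and
    translated so the AP-2 site touches z = 0, and ``ap2`` is the new AP-2
    instance directly beneath it.
    """
    if kind == "clathrin_clathrin":
        if site_index not in (0, 1, 2):
            raise InvalidParameterError("clathrin-clathrin bonds use leg sites 0-2")
        sites = site_world_coordinates(mol_a, geom)
        site_a = sites[site_index]
        u = _unit(site_a - mol_a.position)
        n = plane_normal(mol_a)
        site_b = site_a + geom.bond_gap * u
        center_b = site_b + geom.leg_radius * u
        # partner body x axis points back along -u, sharing the leg plane
        x_axis = -u
        z_axis = n
        y_axis = np.cross(z_axis, x_axis)
        rot_b = Rotation.from_matrix(np.column_stack([x_axis, y_axis, z_axis]))
        if np.linalg.norm(center_b - mol_a.position) < geom.excluded_diameter:
            raise PlacementFailureError("partner pose overlaps excluded volume")
        return RigidMolecule(
            id=partner_id,
            species="clathrin",
            position=center_b,
            orientation=rot_b.as_quat(),
            bonds=[(0, mol_a.id, site_index)],
        )

    if kind == "clathrin_ap2":
        if site_index != geom.AP2_SITE:
            raise InvalidParameterError("AP-2 binds at the dedicated site 3")
        snapped = membrane_snap_pose(mol_a, geom)
        ap2 = RigidMolecule(
            id=partner_id,
            species="ap2",
            position=np.array([snapped.position[0], snapped.position[1], 0.0]),
            bonds=[(0, mol_a.id, geom.AP2_SITE)],
        )
        snapped.bonds = list(mol_a.bonds) + [(geom.AP2_SITE, partner_id, 0)]
        return snapped, ap2

    raise InvalidParameterError(f"unknown bond kind {kind!r}")


def membrane_snap_pose(
    mol: RigidMolecule, geom: ClathrinGeometry = DEFAULT_GEOMETRY
) -> RigidMolecule:
    """Copy of ``mol`` in the membrane-bound pose.

    Body +z is aligned with the world +z (AP-2 site pointing straight down),
    the in-plane azimuth of the body x axis is preserved, and the center is
    raised to z = ap2_site_depth so the AP-2 site sits exactly on z = 0.
    """
    bx = mol.rotation.apply(np.array([1.0, 0.0, 0.0]))
    bx_plane = np.array([bx[0], bx[1], 0.0])
    if np.linalg.norm(bx_plane) < 1e-12:
        by = mol.rotation.apply(np.array([0.0, 1.0, 0.0]))
        bx_plane = np.array([by[1], -by[0], 0.0])  # fallback azimuth from body y
    x_axis = _unit(bx_plane)
    z_axis = np.array([0.0, 0.0, 1.0])
    y_axis = np.cross(z_axis, x_axis)
    rot = Rotation.from_matrix(np.column_stack([x_axis, y_axis, z_axis]))
    return RigidMolecule(
        id=mol.id,
        species=mol.species,
        position=np.array([mol.position[0], mol.position[1], geom.ap2_site_depth]),
        orientation=rot.as_quat(),
        bonds=list(mol.bonds),
    )
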