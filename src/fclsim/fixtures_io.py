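"""Synthetic initial conditions, config parsing and trajectory persistence.

Configs are YAML with explicit unit strings ("1 um", "3 us",
"50x0.913 uM-1s-1"); all values are normalised to the internal nm/us units
and unknown keys are rejected.  Trajectories are persisted as a pair of
CSV tables (molecules, bonds) plus a JSON manifest carrying the config
snapshot, seed, code version and SHA-256 checksums, verified on reload.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from . import __version__
from .brownian_engine import (
    ConfigError,
    Frame,
    ParameterSchedule,
    SimulationConfig,
    SystemState,
    Trajectory,
)
from .model_core import ClathrinGeometry, DiffusionSpec, place_bound_partner, RigidMolecule
from .reaction_kinetics import AP2Pool, RateTable

logger = logging.getLogger("fclsim")

#: rate-table defaults the parser warns about when left unset (placeholders)
_PLACEHOLDER_KOFFS = ("koff_cc", "koff_ap2_clat")


class TrajectoryFormatError(ValueError):
    """Corrupt, truncated or schema-mismatched trajectory files."""


def _suffixed(prefix, suffix: str) -> Path:
    return Path(str(prefix) + suffix)


# --------------------------------------------------------------------------
# initial conditions
# --------------------------------------------------------------------------


def random_initial_condition(
    config: SimulationConfig, rng: np.random.Generator
) -> SystemState:
    """Clathrins uniform in the box with pairwise distance >= the excluded
    diameter (rejection sampling), uniform random orientations, no bonds,
    AP-2 pool fully free."""
    n = config.n_clathrin
    L = config.box_edge
    excl2 = config.geometry.excluded_diameter**2
    if n > 0 and n * (4.0 / 3.0) * np.pi * (config.geometry.excluded_diameter / 2) ** 3 > 0.25 * L**3:
        raise ConfigError("packing infeasible: too many clathrins for the box")
    pos = np.empty((n, 3))
    placed = 0
    attempts = 0
    max_attempts = 1000 * max(n, 1)
    while placed < n:
        if attempts > max_attempts:
            raise ConfigError("packing failed: could not place clathrins")
        attempts += 1
        cand = rng.uniform(0.0, L, size=3)
        if placed and np.min(np.sum((pos[:placed] - cand) ** 2, axis=1)) < excl2:
            continue
        pos[placed] = cand
        placed += 1
    quat = Rotation.random(num=max(n, 1), random_state=rng).as_quat()[:n].reshape(n, 4)
    return SystemState(
        time=0.0,
        box_edge=L,
        pos=pos,
        quat=quat,
        leg_partner=np.full((n, 3), -1, dtype=int),
        leg_partner_site=np.full((n, 3), -1, dtype=int),
        ap2_id=np.full(n, -1, dtype=int),
        ap2_pool=AP2Pool(total=config.n_ap2),
        next_ap2_id=n,
    )


def preassembled_cluster_state(
    config: SimulationConfig,
    rng: np.random.Generator,
    cluster_size: int = 60,
    ap2_bound_fraction: float = 0.5,
) -> SystemState:
    """One membrane-bound hexagonal cluster plus cytosolic monomers.

    Used as the pre-stimulus condition of the EGF protocol: a lattice of
    ``cluster_size`` clathrins is grown bond-by-bond at the box center via
    the analytic head-to-head placement, a fraction of its members receive
    AP-2, and the remaining clathrins are scattered in the cytosol.
    """
    geom = config.geometry
    n = config.n_clathrin
    cluster_size = min(cluster_size, n)
    L = config.box_edge

    state = random_initial_condition(config, rng)
    if cluster_size == 0:
        return state

    # grow the lattice with RigidMolecule plumbing, then write into arrays
    seed_mol = RigidMolecule(
        id=0,
        species="clathrin",
        position=np.array([L / 2, L / 2, geom.ap2_site_depth]),
    )
    mols = [seed_mol]
    occupied = {0: seed_mol}
    frontier = [(0, s) for s in range(3)]
    bonds = []
    while len(mols) < cluster_size and frontier:
        mol_id, site = frontier.pop(0)
        mol = occupied[mol_id]
        if any(b[0] == site for b in mol.bonds):
            continue
        partner = place_bound_partner(mol, site, geom, "clathrin_clathrin", len(mols))
        # ring closure: an existing member already at that spot?
        clash = [
            m for m in mols if np.linalg.norm(m.position - partner.position) < 1.0
        ]
        if clash:
            other = clash[0]
            osites = other.position + other.rotation.apply(geom.leg_site_offsets)
            msite = mol.position + mol.rotation.apply(geom.leg_site_offsets)[site]
            ds = np.linalg.norm(osites - (msite), axis=1)
            best = int(np.argmin(ds))
            if ds[best] <= geom.bond_gap + 0.5 and not any(
                b[0] == best for b in other.bonds
            ):
                mol.bonds.append((site, other.id, best))
                other.bonds.append((best, mol.id, site))
                bonds.append((mol.id, site, other.id, best))
            continue
        mol.bonds.append((site, partner.id, site_of(partner)))
        occupied[partner.id] = partner
        mols.append(partner)
        bonds.append((mol.id, site, partner.id, 0))
        frontier.extend((partner.id, s) for s in range(1, 3))

    members = len(mols)
    # overwrite the first `members` molecules with the lattice
    for k, m in enumerate(mols):
        state.pos[k] = m.position
        state.quat[k] = m.orientation.copy()
    state.leg_partner[:members] = -1
    state.leg_partner_site[:members] = -1
    for i, si, j, sj in bonds:
        state.leg_partner[i, si] = j
        state.leg_partner_site[i, si] = sj
        state.leg_partner[j, sj] = i
        state.leg_partner_site[j, sj] = si

    n_ap2_assign = min(int(round(ap2_bound_fraction * members)), config.n_ap2)
    hosts = rng.choice(members, size=n_ap2_assign, replace=False) if n_ap2_assign else []
    for h in hosts:
        state.ap2_id[h] = state.next_ap2_id
        state.next_ap2_id += 1
        state.ap2_pool.take_free()

    # rescatter the cytosolic remainder clear of the lattice
    excl2 = geom.excluded_diameter**2
    for k in range(members, n):
        for _ in range(10000):
            cand = rng.uniform(0.0, L, size=3)
            if np.min(np.sum((state.pos[:k] - cand) ** 2, axis=1)) >= excl2:
                state.pos[k] = cand
                break
        else:
            raise ConfigError("packing failed around preassembled cluster")
    return state


def site_of(partner: RigidMolecule) -> int:
    return partner.bonds[0][0] if partner.bonds else 0


# --------------------------------------------------------------------------
# config parsing
# --------------------------------------------------------------------------

_UNIT_FACTORS = {
    "length": {"nm": 1.0, "um": 1e3},
    "time": {"us": 1.0, "ms": 1e3, "s": 1e6, "min": 6e7},
    "k_bi": {"uM-1s-1": 1.0},
    "k_off": {"s-1": 1.0},
    "diffusion": {"um2/s": 1.0, "nm2/us": 1.0},
    "rot_diffusion": {"rad2/us": 1.0, "rad2/s": 1e-6},
    "plain": {"": 1.0},
}

_QTY_RE = re.compile(
    r"^\s*(?:(?P<mult>[0-9.eE+-]+)\s*[xX]\s*)?(?P<num>[0-9.eE+-]+)\s*(?P<unit>[^\s]*)\s*$"
)


def parse_quantity(value, kind: str, field: str) -> float:
    """Parse a number or a "value unit" / "AxB unit" string to internal units."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _QTY_RE.match(str(value))
    if not m:
        raise ConfigError(f"{field}: cannot parse quantity {value!r}")
    factors = _UNIT_FACTORS[kind]
    unit = m.group("unit")
    if unit not in factors:
        raise ConfigError(
            f"{field}: unit {unit!r} not valid for {kind} (expected one of {sorted(factors)})"
        )
    num = float(m.group("num"))
    if m.group("mult") is not None:
        num *= float(m.group("mult"))
    return num * factors[unit]


_TOP_KEYS = {
    "box_edge": ("length",),
    "dt": ("time",),
    "duration": ("time",),
    "frame_interval": ("time",),
    "reaction_radius": ("length",),
    "capture_height": ("length",),
    "n_clathrin": None,
    "n_ap2": None,
    "seed": None,
    "max_retries": None,
    "large_cluster_threshold": None,
    "rates": None,
    "diffusion": None,
    "geometry": None,
    "schedule": None,
    "initial_condition": None,
    "sweep": None,
}

_RATE_KEYS = {
    "k_cc_gated": "k_bi",
    "k_cc_free": "k_bi",
    "k_ap2_clat": "k_bi",
    "koff_cc": "k_off",
    "koff_ap2_clat": "k_off",
}

_GEOM_KEYS = {
    "leg_radius": "length",
    "ap2_site_depth": "length",
    "excluded_diameter": "length",
    "bond_gap": "length",
    "footprint_radius": "length",
}


def parse_config(source) -> SimulationConfig:
    """Parse a YAML config file (path) or pre-loaded mapping.

    Missing keys get the reference defaults (1 um box, 3 us step, 300
    clathrins); leaving the placeholder dissociation rates at their
    defaults logs a warning.  Unknown keys raise ConfigError naming them.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    unknown = set(raw) - set(_TOP_KEYS)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    kwargs: dict = {}
    for key, kinds in _TOP_KEYS.items():
        if key not in raw or key in ("rates", "diffusion", "geometry", "schedule",
                                     "initial_condition", "sweep"):
            continue
        if kinds is None:
            kwargs[key] = int(raw[key]) if key != "seed" else int(raw[key])
        else:
            kwargs[key] = parse_quantity(raw[key], kinds[0], key)

    rates_raw = dict(raw.get("rates") or {})
    unknown = set(rates_raw) - set(_RATE_KEYS)
    if unknown:
        raise ConfigError(f"unknown rates key(s): {sorted(unknown)}")
    rate_kwargs = {
        k: parse_quantity(v, _RATE_KEYS[k], f"rates.{k}") for k, v in rates_raw.items()
    }
    for k in _PLACEHOLDER_KOFFS:
        if k not in rate_kwargs:
            logger.warning(
                "rates.%s not set; using the documented placeholder default %s s^-1",
                k,
                getattr(RateTable(), k),
            )
    kwargs["rates"] = RateTable(**rate_kwargs)

    diff_raw = dict(raw.get("diffusion") or {})
    unknown = set(diff_raw) - {"d_clat", "d_clat_rot", "d_ap2", "d_ap2_rot"}
    if unknown:
        raise ConfigError(f"unknown diffusion key(s): {sorted(unknown)}")
    clat = DiffusionSpec.clathrin_default()
    if "d_clat" in diff_raw or "d_clat_rot" in diff_raw:
        d = parse_quantity(diff_raw.get("d_clat", clat.d_trans[0]), "diffusion", "d_clat")
        dr = parse_quantity(
            diff_raw.get("d_clat_rot", clat.d_rot[0]), "rot_diffusion", "d_clat_rot"
        )
        clat = DiffusionSpec.isotropic(d, dr)
    ap2 = DiffusionSpec.ap2_default()
    if "d_ap2" in diff_raw or "d_ap2_rot" in diff_raw:
        d = parse_quantity(diff_raw.get("d_ap2", ap2.d_trans[0]), "diffusion", "d_ap2")
        dr = parse_quantity(
            diff_raw.get("d_ap2_rot", ap2.d_rot[2]), "rot_diffusion", "d_ap2_rot"
        )
        ap2 = DiffusionSpec((d, d, 0.0), (0.0, 0.0, dr))
    kwargs["clathrin_diffusion"] = clat
    kwargs["ap2_diffusion"] = ap2

    geom_raw = dict(raw.get("geometry") or {})
    unknown = set(geom_raw) - set(_GEOM_KEYS)
    if unknown:
        raise ConfigError(f"unknown geometry key(s): {sorted(unknown)}")
    kwargs["geometry"] = ClathrinGeometry(
        **{
            k: parse_quantity(v, _GEOM_KEYS[k], f"geometry.{k}")
            for k, v in geom_raw.items()
        }
    )

    sched_raw = raw.get("schedule")
    if sched_raw:
        breakpoints = []
        for bp in sched_raw:
            bp = dict(bp)
            if "time" not in bp:
                raise ConfigError("each schedule breakpoint needs a time")
            t = parse_quantity(bp.pop("time"), "time", "schedule.time")
            if "n_ap2" in bp:
                bp["n_ap2"] = int(bp["n_ap2"])
            for k in list(bp):
                if k.endswith("_mult"):
                    bp[k] = float(bp[k])
            breakpoints.append((t, bp))
        kwargs["schedule"] = ParameterSchedule(tuple(breakpoints))

    try:
        return SimulationConfig(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc


def builtin_config_path(name: str) -> Path:
    """Path of a shipped reference config (baseline, sweep_ap2,
    egf_protocol4, desk_small)."""
    p = Path(__file__).parent / "configs" / f"{name}.yaml"
    if not p.exists():
        raise ConfigError(f"no builtin config named {name!r}")
    return p


# --------------------------------------------------------------------------
# trajectory persistence
# --------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Reproducibility metadata written next to every trajectory."""

    config: dict
    seed: int
    code_version: str
    start_time_us: float
    end_time_us: float
    n_frames: int
    checksums: dict


def _config_to_dict(config: SimulationConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {
                f.name: convert(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
                if f.init
            }
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, tuple):
            return [convert(x) for x in obj]
        return obj

    return convert(config)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_trajectory(traj: Trajectory, prefix: str | Path) -> RunManifest:
    """Persist a trajectory as <prefix>.molecules.csv, <prefix>.bonds.csv
    and <prefix>.manifest.json.  AP-2 rows carry the membrane-layer
    coordinates derived from their host's AP-2 site and identity
    orientation."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    geom = traj.config.geometry

    mol_rows = []
    bond_rows = []
    for frame in traj.frames:
        n = len(frame.pos)
        quat_wxyz = frame.quat[:, [3, 0, 1, 2]] if n else frame.quat.reshape(0, 4)
        mats = Rotation.from_quat(frame.quat).as_matrix() if n else np.zeros((0, 3, 3))
        if n and mats.ndim == 2:
            mats = mats[None]
        ap2_sites = frame.pos + np.einsum("nij,j->ni", mats, geom.ap2_site_offset) if n else frame.pos
        for i in range(n):
            mol_rows.append(
                (frame.time, i, "clathrin", *frame.pos[i], *quat_wxyz[i])
            )
            if frame.ap2_id[i] >= 0:
                mol_rows.append(
                    (
                        frame.time,
                        int(frame.ap2_id[i]),
                        "ap2",
                        ap2_sites[i, 0],
                        ap2_sites[i, 1],
                        0.0,
                        1.0,
                        0.0,
                        0.0,
                        0.0,
                    )
                )
                bond_rows.append(
                    (frame.time, i, geom.AP2_SITE, int(frame.ap2_id[i]), 0)
                )
        for i, si, j, sj in frame.cc_bonds:
            bond_rows.append((frame.time, int(i), int(si), int(j), int(sj)))

    mol_df = pd.DataFrame(
        mol_rows,
        columns=[
            "frame_time_us", "mol_id", "species",
            "x", "y", "z", "qw", "qx", "qy", "qz",
        ],
    )
    bond_df = pd.DataFrame(
        bond_rows, columns=["frame_time_us", "mol_a", "site_a", "mol_b", "site_b"]
    )
    mol_path = _suffixed(prefix, ".molecules.csv")
    bond_path = _suffixed(prefix, ".bonds.csv")
    mol_df.to_csv(mol_path, index=False, float_format="%.17g")
    bond_df.to_csv(bond_path, index=False)

    manifest = RunManifest(
        config=_config_to_dict(traj.config),
        seed=traj.seed,
        code_version=__version__,
        start_time_us=float(traj.frames[0].time) if traj.frames else 0.0,
        end_time_us=float(traj.frames[-1].time) if traj.frames else 0.0,
        n_frames=len(traj.frames),
        checksums={
            mol_path.name: _sha256(mol_path),
            bond_path.name: _sha256(bond_path),
        },
    )
    with open(_suffixed(prefix, ".manifest.json"), "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=1)
    return manifest


def read_trajectory(prefix: str | Path) -> Trajectory:
    """Reload a persisted trajectory, verifying checksums; corrupt or
    truncated files raise TrajectoryFormatError rather than loading
    partially."""
    prefix = Path(prefix)
    man_path = _suffixed(prefix, ".manifest.json")
    mol_path = _suffixed(prefix, ".molecules.csv")
    bond_path = _suffixed(prefix, ".bonds.csv")
    for p in (man_path, mol_path, bond_path):
        if not p.exists():
            raise TrajectoryFormatError(f"missing trajectory file {p}")
    with open(man_path) as fh:
        man = json.load(fh)
    for name, expected in man["checksums"].items():
        actual = _sha256(prefix.parent / name)
        if actual != expected:
            raise TrajectoryFormatError(
                f"checksum mismatch for {name}: file corrupt or truncated"
            )

    config = _config_from_dict(man["config"])
    if man["n_frames"] == 0:
        return Trajectory(frames=[], config=config, seed=man["seed"])
    mol_df = pd.read_csv(mol_path, float_precision="round_trip")
    bond_df = pd.read_csv(bond_path)

    n = config.n_clathrin
    frames = []
    times = (
        mol_df["frame_time_us"].unique()
        if len(mol_df)
        else np.array([man["start_time_us"]])
    )
    for t in times:
        sub = mol_df[mol_df["frame_time_us"] == t]
        clat = sub[sub["species"] == "clathrin"].sort_values("mol_id")
        if len(clat) != n:
            raise TrajectoryFormatError(
                f"frame {t}: expected {n} clathrins, found {len(clat)}"
            )
        pos = clat[["x", "y", "z"]].to_numpy()
        quat = clat[["qx", "qy", "qz", "qw"]].to_numpy()
        bsub = bond_df[bond_df["frame_time_us"] == t]
        ap2_id = np.full(n, -1, dtype=int)
        cc = []
        for _, row in bsub.iterrows():
            if row["site_a"] == config.geometry.AP2_SITE:
                ap2_id[int(row["mol_a"])] = int(row["mol_b"])
            else:
                cc.append(
                    (int(row["mol_a"]), int(row["site_a"]), int(row["mol_b"]), int(row["site_b"]))
                )
        frames.append(
            Frame(
                time=float(t),
                pos=pos,
                quat=quat,
                ap2_id=ap2_id,
                cc_bonds=np.array(cc, dtype=int).reshape(-1, 4),
                pool_total=-1,
                pool_bound=int(np.sum(ap2_id >= 0)),
                pool_pending=0,
            )
        )
    return Trajectory(frames=frames, config=config, seed=man["seed"])


def _config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["rates"] = RateTable(**d["rates"])
    d["clathrin_diffusion"] = DiffusionSpec(
        tuple(d["clathrin_diffusion"]["d_trans"]), tuple(d["clathrin_diffusion"]["d_rot"])
    )
    d["ap2_diffusion"] = DiffusionSpec(
        tuple(d["ap2_diffusion"]["d_trans"]), tuple(d["ap2_diffusion"]["d_rot"])
    )
    d["geometry"] = ClathrinGeometry(**d["geometry"])
    if d.get("schedule"):
        d["schedule"] = ParameterSchedule(
            tuple((bp[0], dict(bp[1])) for bp in d["schedule"]["breakpoints"])
        )
    else:
        d["schedule"] = None
    return SimulationConfig(**d)


def trajectory_roundtrip(traj: Trajectory, prefix: str | Path) -> Trajectory:
    """write + read; the identity on stored precision (testing helper)."""
    write_trajectory(traj, prefix)
    return read_trajectory(prefix)
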