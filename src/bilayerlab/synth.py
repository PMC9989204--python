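"""Synthetic planar-bilayer trajectories with fully known ground truth.

The generator builds a two-leaflet bilayer on a square lateral grid with
prescribed area per lipid and inter-leaflet phosphate-plane separation,
then evolves it kinematically: rigid-molecule lateral Brownian motion
with a prescribed diffusion coefficient, per-frame resampling of rigid
acyl-chain tilt, scripted leaflet translocations, and optional guest
amphiphiles planted at a prescribed depth below the phosphate plane.
There are no forces or thermostats — dynamics are resampled geometry,
chosen so every downstream observable has a closed-form expectation.

Each lipid carries one phosphate bead (charge −1), one amine headgroup
bead (charge +1) and a single rigid acyl chain of ``chain_sites`` beads;
guests carry a carboxylate bead (charge −1), two hydroxyl beads and two
chains.  Masses, charges and electron counts are nominal per-bead values
of the right magnitude, present so that density, charge and potential
profiles have non-trivial, conserved totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import BilayerError, Frame, SiteTable, Trajectory

TILT_MODES = ("fixed_angle", "isotropic", "wrapped_gaussian")

# nominal per-bead properties: (mass u, charge e, electrons)
_BEAD_PROPS = {
    "PO4": (94.97, -1.0, 47.0),
    "NH3": (45.0, +1.0, 26.0),
    "C": (56.0, 0.0, 31.0),
    "COO": (44.0, -1.0, 23.0),
    "ROH": (17.0, 0.0, 9.0),
    "W": (18.0, 0.0, 10.0),
}


@dataclass(frozen=True)
class FlipEvent:
    """Scripted translocation: molecule crosses at ``start_ps`` and
    returns after ``residency_ps`` (unless that extends past the end)."""

    molecule_id: int
    start_ps: float
    residency_ps: float


@dataclass(frozen=True)
class GuestSpec:
    n_guests: int
    depth_below_phosphate: float  # nm


@dataclass
class BilayerSpec:
    """Ground-truth parameters of a synthetic bilayer.

    n_per_leaflet must be a perfect square (lipids sit on a square
    grid); apl is the area per lipid in nm^2; phosphate_plane_sep the
    inter-leaflet phosphate-plane distance in nm; d_lat the lateral
    diffusion coefficient in nm^2/ps; tilt_param is degrees (the fixed
    angle, or the Gaussian sigma).
    """

    n_per_leaflet: int = 64
    apl: float = 0.5625
    phosphate_plane_sep: float = 4.0
    chain_sites: int = 4
    tilt_mode: str = "fixed_angle"
    tilt_param: float = 0.0
    d_lat: float = 1e-3
    flip_script: Sequence[FlipEvent] = field(default_factory=tuple)
    guest_spec: Optional[GuestSpec] = None
    n_water: int = 0
    seed: int = 0
    bond_length: float = 0.3  # nm, chain-bead spacing
    headgroup_offset: float = 0.3  # nm, amine bead above the phosphate
    box_z: Optional[float] = None  # nm; computed from geometry if None

    def __post_init__(self) -> None:
        if self.apl <= 0 or self.phosphate_plane_sep <= 0:
            raise BilayerError("apl and phosphate_plane_sep must be > 0")
        if self.d_lat < 0:
            raise BilayerError("d_lat must be >= 0")
        if self.tilt_mode not in TILT_MODES:
            raise BilayerError(f"tilt_mode must be one of {TILT_MODES}")
        k = int(round(np.sqrt(self.n_per_leaflet)))
        if k * k != self.n_per_leaflet:
            raise BilayerError("n_per_leaflet must be a perfect square (grid layout)")
        if self.guest_spec is not None:
            d = self.guest_spec.depth_below_phosphate
            if d <= 0 or d >= self.phosphate_plane_sep / 2:
                raise BilayerError(
                    "guest depth must lie within the monolayer: "
                    f"0 < depth < {self.phosphate_plane_sep / 2} nm"
                )

    @property
    def box_xy(self) -> float:
        return float(np.sqrt(self.n_per_leaflet * self.apl))

    @property
    def box_z_actual(self) -> float:
        if self.box_z is not None:
            return self.box_z
        span = self.chain_sites * self.bond_length + self.headgroup_offset
        return self.phosphate_plane_sep + 2 * span + 2.0


def _sample_directions(mode: str, param_deg: float, n: int, rng) -> np.ndarray:
    """Unit vectors with non-negative z; the caller flips the sign per leaflet."""
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    if mode == "fixed_angle":
        theta = np.full(n, np.deg2rad(param_deg))
    elif mode == "isotropic":
        theta = np.arccos(rng.uniform(0.0, 1.0, size=n))
    else:  # wrapped_gaussian: folded normal around 0
        theta = np.abs(rng.normal(0.0, np.deg2rad(param_deg), size=n))
    st = np.sin(theta)
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


class _System:
    """Index bookkeeping shared by the builder and the propagator."""

    def __init__(self):
        self.records: List[dict] = []
        self.coords: List[Tuple[float, float, float]] = []
        # per chain: (anchor site, ordered chain-site ids, owning molecule,
        #             lateral start offset relative to the anchor)
        self.chains: List[Tuple[int, np.ndarray, int, np.ndarray]] = []
        self.mol_sites: dict = {}
        self.mol_leaflet: dict = {}
        self.mol_mobile: dict = {}

    def add_site(self, mol_id, resname, name, pol, xyz, chain_label=None, chain_pos=None):
        sid = len(self.records)
        key = "ROH" if name.startswith("RO") else ("C" if name.startswith("C") and name != "COO" else name)
        mass, charge, electrons = _BEAD_PROPS[key]
        self.records.append(
            dict(
                site_id=sid,
                site_name=name,
                residue_name=resname,
                molecule_id=mol_id,
                mass=mass,
                charge=charge,
                electrons=electrons,
                polarity_class=pol,
                chain_label=chain_label,
                chain_position=chain_pos,
            )
        )
        self.coords.append(tuple(xyz))
        self.mol_sites.setdefault(mol_id, []).append(sid)
        return sid


def build_bilayer(spec: BilayerSpec) -> Tuple[SiteTable, Frame]:
    """Construct the t=0 frame and its site table.

    Phosphate planes sit at ``z_mid ± sep/2``; chains extend toward the
    midplane with orientation drawn from the tilt model; guests are
    planted with their carboxylate bead exactly ``depth_below_phosphate``
    below the nearer phosphate plane, half in each leaflet.
    """
    rng = np.random.default_rng(spec.seed)
    sys = _System()
    k = int(round(np.sqrt(spec.n_per_leaflet)))
    a = np.sqrt(spec.apl)
    Lxy = spec.box_xy
    Lz = spec.box_z_actual
    zc = Lz / 2.0
    b = spec.bond_length
    mol_id = 0
    for leaflet in (+1, -1):
        zp = zc + leaflet * spec.phosphate_plane_sep / 2.0
        dirs = _sample_directions(spec.tilt_mode, spec.tilt_param, spec.n_per_leaflet, rng)
        dirs[:, 2] *= -leaflet  # chains point toward the midplane
        for g in range(spec.n_per_leaflet):
            mol_id += 1
            gx, gy = (g % k + 0.5) * a, (g // k + 0.5) * a
            anchor = sys.add_site(mol_id, "LIP", "PO4", "phosphate", (gx, gy, zp))
            sys.add_site(
                mol_id, "LIP", "NH3", "headgroup_amine",
                (gx, gy, zp + leaflet * spec.headgroup_offset),
            )
            csites = []
            for j in range(1, spec.chain_sites + 1):
                csites.append(
                    sys.add_site(
                        mol_id, "LIP", f"C{j}", "apolar",
                        (gx + j * b * dirs[g, 0], gy + j * b * dirs[g, 1],
                         zp + j * b * dirs[g, 2]),
                        chain_label="sn1", chain_pos=j,
                    )
                )
            sys.chains.append((anchor, np.array(csites), mol_id, np.zeros(3)))
            sys.mol_leaflet[mol_id] = leaflet
            sys.mol_mobile[mol_id] = True
    if spec.guest_spec is not None:
        gs = spec.guest_spec
        for gi in range(gs.n_guests):
            mol_id += 1
            leaflet = +1 if gi % 2 == 0 else -1
            zp = zc + leaflet * spec.phosphate_plane_sep / 2.0
            z0 = zp - leaflet * gs.depth_below_phosphate
            gx, gy = rng.uniform(0, Lxy, size=2)
            anchor = sys.add_site(mol_id, "RHL", "COO", "headgroup_carboxylate", (gx, gy, z0))
            sys.add_site(mol_id, "RHL", "RO1", "hydroxyl",
                         (gx + 0.10, gy, z0 + leaflet * 0.05))
            sys.add_site(mol_id, "RHL", "RO2", "hydroxyl",
                         (gx - 0.10, gy, z0 + leaflet * 0.05))
            dirs = _sample_directions(spec.tilt_mode, spec.tilt_param, 2, rng)
            dirs[:, 2] *= -leaflet
            for ci, clabel in enumerate(("guest_chain1", "guest_chain2")):
                off = np.array([0.15 if ci == 0 else -0.15, 0.0, 0.0])
                csites = []
                for j in range(1, spec.chain_sites + 1):
                    csites.append(
                        sys.add_site(
                            mol_id, "RHL", f"C{j}", "apolar",
                            (gx + off[0] + j * b * dirs[ci, 0],
                             gy + j * b * dirs[ci, 1],
                             z0 + j * b * dirs[ci, 2]),
                            chain_label=clabel, chain_pos=j,
                        )
                    )
                sys.chains.append((anchor, np.array(csites), mol_id, off))
            sys.mol_leaflet[mol_id] = leaflet
            sys.mol_mobile[mol_id] = True
    # optional uniform water slabs outside the membrane region
    if spec.n_water > 0:
        z_excl = spec.phosphate_plane_sep / 2.0 + spec.headgroup_offset + 0.1
        placed = 0
        while placed < spec.n_water:
            xyz = rng.uniform(0, 1, size=3) * np.array([Lxy, Lxy, Lz])
            if abs(xyz[2] - zc) <= z_excl:
                continue
            mol_id += 1
            sys.add_site(mol_id, "SOL", "W", "water", xyz)
            sys.mol_leaflet[mol_id] = 0
            sys.mol_mobile[mol_id] = False
            placed += 1
    table = SiteTable.from_records(sys.records)
    frame = Frame(time=0.0, box=np.array([Lxy, Lxy, Lz]), coords=np.array(sys.coords))
    frame._synth_system = sys  # handed to simulate_dynamics
    return table, frame


def simulate_dynamics(
    table: SiteTable,
    frame0: Frame,
    n_frames: int,
    dt: float,
    spec: BilayerSpec,
) -> Trajectory:
    """Propagate the bilayer kinematically for ``n_frames`` frames.

    Lateral displacements are rigid per molecule, with independent
    Gaussian steps of variance ``2 * d_lat * dt`` per axis per step;
    chain tilt is re-sampled every frame; scripted flips mirror the
    molecule's z-template through the midplane for their residency
    window.  Coordinates are emitted unwrapped.  Bit-reproducible for a
    given spec.seed.
    """
    if dt <= 0:
        raise BilayerError("dt must be positive")
    if n_frames < 2:
        raise BilayerError("need at least 2 frames")
    sys = getattr(frame0, "_synth_system", None)
    if sys is None:
        raise BilayerError("frame0 must come from build_bilayer")
    rng = np.random.default_rng([int(spec.seed), 1])
    coords0 = frame0.coords
    zc = frame0.box[2] / 2.0
    b = spec.bond_length

    mobile = sorted(m for m, mob in sys.mol_mobile.items() if mob)
    midx = {m: i for i, m in enumerate(mobile)}
    site_mol_rows = [(np.array(sys.mol_sites[m]), midx[m]) for m in mobile]
    n_chains = len(sys.chains)
    chain_anchor = np.array([c[0] for c in sys.chains])
    chain_sites_mat = np.stack([c[1] for c in sys.chains])  # (n_chains, chain_sites)
    chain_mol = np.array([c[2] for c in sys.chains])
    chain_start_off = np.stack([c[3] for c in sys.chains])  # (n_chains, 3)
    base_leaflet = np.array([sys.mol_leaflet[m] for m in chain_mol])
    steps_j = np.arange(1, chain_sites_mat.shape[1] + 1) * b

    flips = list(spec.flip_script)
    t_end = (n_frames - 1) * dt
    for ev in flips:
        if not (0.0 <= ev.start_ps <= t_end):
            raise BilayerError(
                f"flip_script start {ev.start_ps} ps outside trajectory [0, {t_end}] ps"
            )

    offsets = np.zeros((len(mobile), 2))
    frames = []
    sigma = np.sqrt(2.0 * spec.d_lat * dt)
    for i in range(n_frames):
        t = i * dt
        if i > 0:
            offsets = offsets + rng.normal(0.0, 1.0, size=offsets.shape) * sigma
        pos = coords0.copy()
        flipped_mols = {
            ev.molecule_id
            for ev in flips
            if ev.start_ps <= t
            and (t < ev.start_ps + ev.residency_ps or ev.start_ps + ev.residency_ps > t_end)
        }
        for m in flipped_mols:
            sites = np.array(sys.mol_sites[m])
            pos[sites, 2] = 2 * zc - coords0[sites, 2]
        for sites, row in site_mol_rows:
            pos[sites, 0] += offsets[row, 0]
            pos[sites, 1] += offsets[row, 1]
        # re-sample rigid chain tilt (frame 0 keeps the built geometry)
        if i > 0:
            dirs = _sample_directions(spec.tilt_mode, spec.tilt_param, n_chains, rng)
            leaflet_now = base_leaflet.copy()
            if flipped_mols:
                leaflet_now[np.isin(chain_mol, list(flipped_mols))] *= -1
            dirs[:, 2] *= -leaflet_now
            start = pos[chain_anchor] + chain_start_off  # (n_chains, 3)
            pos[chain_sites_mat] = (
                start[:, None, :] + steps_j[None, :, None] * dirs[:, None, :]
            )
        frames.append(Frame(time=t, box=frame0.box.copy(), coords=pos))
    return Trajectory(frames, dt=dt)


def generate(spec: BilayerSpec, n_frames: int, dt: float) -> Tuple[SiteTable, Trajectory]:
    """Convenience: build and propagate in one call."""
    table, frame0 = build_bilayer(spec)
    return table, simulate_dynamics(table, frame0, n_frames, dt, spec)
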