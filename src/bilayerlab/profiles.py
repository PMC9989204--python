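"""Profiles along the membrane normal: density and dipole potential.

Densities (mass, charge, electron) are histogrammed on wrapped z
coordinates after recentring each frame on the bilayer midplane, then
averaged over frames and divided by the bin volume.  The dipole
potential is obtained from the charge-density profile by double
integration of Poisson's equation,

    Psi(z) = -(1/eps0) * int_0^z dz' int_0^z'' rho_q(z'') dz'',

with the potential and the field pinned to zero at the lower box edge.
The profile is in volts when charge densities are in e/nm^3; eps0 is
expressed in e V^-1 nm^-1 accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd
from scipy import constants
from scipy.integrate import cumulative_trapezoid

from .core import BilayerError, SiteTable, Trajectory, wrap_coords
from .select import SelectionExpr, select

#: vacuum permittivity in elementary charges per volt per nanometre
EPSILON0_E_PER_V_NM = constants.epsilon_0 / constants.elementary_charge * 1e-9

WEIGHTS = ("mass", "charge", "electron")


@dataclass
class ProfileResult:
    """A binned quantity along z, midplane-centred.

    ``bin_centers`` in nm; ``values`` in (units of weight)/nm^3 for
    densities or volts for the potential; bins are uniform and
    half-open [z, z + bin_width).
    """

    bin_centers: np.ndarray
    values: np.ndarray
    bin_width: float
    kind: str
    warnings: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_nm": self.bin_centers, "value": self.values})

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_xvg(self, path: Union[str, Path]) -> None:
        lines = [f"# bilayerlab profile kind={self.kind} bin_width_nm={self.bin_width:g}"]
        for w in self.warnings:
            lines.append(f"# warning: {w}")
        for z, v in zip(self.bin_centers, self.values):
            lines.append(f"{z:.6f} {v:.8g}")
        Path(path).write_text("\n".join(lines) + "\n")

    def integral(self) -> float:
        """Integral of the profile over z (value units * nm)."""
        return float(np.sum(self.values) * self.bin_width)


def _constant_box(traj: Trajectory) -> np.ndarray:
    boxes = traj.boxes()
    if not np.allclose(boxes, boxes[0], rtol=0, atol=1e-9):
        raise BilayerError("profiles require a constant box across frames")
    return boxes[0]


def density_profile(
    traj: Trajectory,
    table: SiteTable,
    sel: Union[SelectionExpr, str] = "all",
    weight: str = "mass",
    n_bins: int = 100,
    center_sel: Optional[Union[SelectionExpr, str]] = None,
) -> ProfileResult:
    """Weighted z-density profile of the selected sites.

    Each frame is recentred on the mean wrapped z of ``center_sel``
    (default: the phosphate sites if any exist, else the box centre)
    before binning, which removes bilayer drift.  The integral of the
    profile times the lateral box area recovers the total selected
    weight exactly.
    """
    if weight not in WEIGHTS:
        raise BilayerError(f"weight must be one of {WEIGHTS}")
    if n_bins < 4:
        raise BilayerError("n_bins must be at least 4")
    idx = select(table, sel)
    if len(idx) == 0:
        raise BilayerError("selection matches no sites")
    w = {"mass": table.masses, "charge": table.charges, "electron": table.electrons}[
        weight
    ][idx]
    box = _constant_box(traj)
    lz = box[2]
    if center_sel is None:
        phos = select(table, "polarity_class == phosphate")
        cidx = phos if len(phos) else None
    else:
        cidx = select(table, center_sel)
        if len(cidx) == 0:
            raise BilayerError("center selection matches no sites")
    edges = np.linspace(-lz / 2, lz / 2, n_bins + 1)
    dz = lz / n_bins
    area = box[0] * box[1]
    acc = np.zeros(n_bins)
    for fr in traj.frames:
        z = wrap_coords(fr.coords[:, 2], lz)
        zc = z[cidx].mean() if cidx is not None else lz / 2
        rel = np.mod(z[idx] - zc + lz / 2, lz) - lz / 2
        rel = np.clip(rel, -lz / 2, np.nextafter(lz / 2, -np.inf))
        hist, _ = np.histogram(rel, bins=edges, weights=w)
        acc += hist
    values = acc / traj.n_frames / (area * dz)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ProfileResult(bin_centers=centers, values=values, bin_width=dz, kind=weight)


def charge_density_profile(
    traj: Trajectory, table: SiteTable, n_bins: int = 100, **kw
) -> ProfileResult:
    return density_profile(traj, table, "all", weight="charge", n_bins=n_bins, **kw)


def potential_from_charge_density(
    rho: np.ndarray, z: np.ndarray
) -> np.ndarray:
    """Double-integrate a charge density (e/nm^3 on grid z in nm) to volts.

    Both the field and the potential are zero at the first grid point;
    trapezoidal rule throughout.
    """
    efield = cumulative_trapezoid(rho, z, initial=0.0) / EPSILON0_E_PER_V_NM
    return -cumulative_trapezoid(efield, z, initial=0.0)


def dipole_potential(
    traj: Trajectory,
    table: SiteTable,
    n_bins: int = 100,
    center_sel: Optional[Union[SelectionExpr, str]] = None,
) -> ProfileResult:
    """Electrostatic (dipole) potential profile across the bilayer.

    Computed from the binned charge density by double trapezoidal
    integration with Psi and the field pinned at the lower box edge.
    The double integration assumes a (near-)neutral system; a non-zero
    net charge above 1e-3 e attaches a warning to the result.
    """
    rho = density_profile(traj, table, "all", "charge", n_bins, center_sel)
    box = _constant_box(traj)
    area = box[0] * box[1]
    warnings_ = []
    net_q = rho.integral() * area
    if abs(net_q) > 1e-3:
        warnings_.append(
            f"net charge {net_q:.4g} e != 0: potential is not periodic-consistent"
        )
    psi = potential_from_charge_density(rho.values, rho.bin_centers)
    return ProfileResult(
        bin_centers=rho.bin_centers,
        values=psi,
        bin_width=rho.bin_width,
        kind="potential",
        warnings=warnings_,
    )
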