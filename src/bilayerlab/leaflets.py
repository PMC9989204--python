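"""Leaflet assignment, membrane thickness and area per lipid.

All three observables assume a planar bilayer whose normal is the z
axis: leaflets are separated by the instantaneous mean z of the
reference sites (one per lipid, typically the phosphate), thickness is
the distance between the mean reference planes, and the area per lipid
is the lateral box area divided by the per-leaflet lipid count.  This
is a deliberate simplification relative to local-normal surface-fitting
methods, appropriate for flat bilayers only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import BilayerError, SiteTable, Trajectory
from .select import SelectionExpr, select

LABEL_NAMES = {1: "upper", -1: "lower", 0: "transiting"}


class LeafletError(BilayerError):
    pass


@dataclass
class LeafletAssignment:
    """Per-frame, per-molecule leaflet labels.

    ``labels`` is (n_frames, n_molecules) int8 with +1 = upper,
    -1 = lower, 0 = transiting; ``molecule_ids`` gives the column order.
    """

    times: np.ndarray
    molecule_ids: np.ndarray
    labels: np.ndarray
    ref: str
    transit_band: float

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def counts(self) -> pd.DataFrame:
        """Per-frame upper/lower/transiting counts."""
        return pd.DataFrame(
            {
                "time_ps": self.times,
                "upper": (self.labels == 1).sum(axis=1),
                "lower": (self.labels == -1).sum(axis=1),
                "transiting": (self.labels == 0).sum(axis=1),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_ps, molecule_id, label."""
        nf, nm = self.labels.shape
        return pd.DataFrame(
            {
                "time_ps": np.repeat(self.times, nm),
                "molecule_id": np.tile(self.molecule_ids, nf),
                "label": [LABEL_NAMES[v] for v in self.labels.ravel()],
            }
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def assign_leaflets(
    traj: Trajectory,
    table: SiteTable,
    ref: Union[SelectionExpr, str],
    transit_band: float = 0.3,
) -> LeafletAssignment:
    """Label each reference-bearing molecule upper/lower/transiting per frame.

    ``ref`` must select exactly one site per molecule for every molecule
    it touches; molecules with no selected site (e.g. water) are left
    out of the assignment.  A molecule within ``transit_band`` nm of the
    mean reference plane is labelled transiting.
    """
    ref_str = ref if isinstance(ref, str) else ref.source
    idx = select(table, ref)
    if len(idx) == 0:
        raise LeafletError(f"reference selection {ref_str!r} matches no sites")
    mols = table.molecule_ids[idx]
    uniq, counts = np.unique(mols, return_counts=True)
    bad = uniq[counts > 1]
    if len(bad):
        raise LeafletError(
            f"reference selection {ref_str!r} matches more than one site for "
            f"molecule(s) {bad[:5].tolist()}"
        )
    mol_ids = uniq  # ascending molecule id
    ref_sites = idx[np.argsort(mols, kind="stable")]
    zs = traj.coords_array()[:, ref_sites, 2]  # (n_frames, n_mol)
    z_mid = zs.mean(axis=1, keepdims=True)
    dz = zs - z_mid
    labels = np.where(dz > 0, 1, -1).astype(np.int8)
    labels[np.abs(dz) < transit_band] = 0
    return LeafletAssignment(
        times=traj.times,
        molecule_ids=mol_ids,
        labels=labels,
        ref=ref_str,
        transit_band=transit_band,
    )


def membrane_thickness(
    traj: Trajectory,
    table: SiteTable,
    ref: Union[SelectionExpr, str],
    transit_band: float = 0.3,
    assignment: Optional[LeafletAssignment] = None,
) -> pd.DataFrame:
    """Per-frame thickness: mean upper reference z minus mean lower.

    Transiting lipids are excluded; frames where a leaflet empties are
    flagged ``valid=False`` with NaN thickness.  Returns columns
    ``time_ps, thickness_nm, valid``.
    """
    if assignment is None:
        assignment = assign_leaflets(traj, table, ref, transit_band)
    idx = select(table, ref)
    mols = table.molecule_ids[idx]
    ref_sites = idx[np.argsort(mols, kind="stable")]
    zs = traj.coords_array()[:, ref_sites, 2]
    up = assignment.labels == 1
    lo = assignment.labels == -1
    n_up = up.sum(axis=1)
    n_lo = lo.sum(axis=1)
    valid = (n_up > 0) & (n_lo > 0)
    with np.errstate(invalid="ignore"):
        mean_up = np.where(up, zs, np.nan)
        mean_lo = np.where(lo, zs, np.nan)
        thickness = np.nanmean(mean_up, axis=1) - np.nanmean(mean_lo, axis=1)
    thickness = np.where(valid, thickness, np.nan)
    return pd.DataFrame(
        {"time_ps": traj.times, "thickness_nm": thickness, "valid": valid}
    )


def area_per_lipid(
    traj: Trajectory,
    assignment: LeafletAssignment,
    guest_assignment: Optional[LeafletAssignment] = None,
) -> pd.DataFrame:
    """Per-frame area per lipid, APL = Lx*Ly / mean(upper, lower count).

    ``assignment`` should cover the lipids only; pass the guests as a
    second assignment to additionally report the convention that counts
    them as lipids.  Per-leaflet APLs are reported alongside the
    symmetric mean-count convention.  Transiting molecules are excluded
    from all counts.
    """
    boxes = traj.boxes()
    area = boxes[:, 0] * boxes[:, 1]
    n_up = (assignment.labels == 1).sum(axis=1).astype(float)
    n_lo = (assignment.labels == -1).sum(axis=1).astype(float)
    if np.any((n_up + n_lo) == 0):
        raise LeafletError("zero lipid count in at least one frame")
    out = pd.DataFrame(
        {
            "time_ps": traj.times,
            "apl_nm2": area / ((n_up + n_lo) / 2.0),
            "apl_upper_nm2": np.where(n_up > 0, area / np.where(n_up > 0, n_up, 1), np.nan),
            "apl_lower_nm2": np.where(n_lo > 0, area / np.where(n_lo > 0, n_lo, 1), np.nan),
        }
    )
    if guest_assignment is not None:
        g_up = (guest_assignment.labels == 1).sum(axis=1)
        g_lo = (guest_assignment.labels == -1).sum(axis=1)
        out["apl_with_guests_nm2"] = area / ((n_up + g_up + n_lo + g_lo) / 2.0)
    return out
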