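"""Radial distribution functions and contact-recurrence fingerprints.

The contact-recurrence matrix scores, for each (guest atom group,
lipid atom class) pair, the fraction of trajectory frames in which the
minimum periodic distance between the two groups falls below a cutoff.
With a heavy-atom cutoff of 0.35 nm between polar groups this is the
usual proxy for hydrogen bonds and salt bridges; 0.50 nm between
apolar groups captures van der Waals adhesion.  Recurrence is binary
per frame, so the score is robust to group size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import BilayerError, SiteTable, Trajectory, minimum_image_vector, wrap_coords
from .select import SelectionExpr, select

POLAR_CUTOFF_NM = 0.35
APOLAR_CUTOFF_NM = 0.50


class SelectionEmptyError(BilayerError):
    pass


def radial_distribution(
    traj: Trajectory,
    table: SiteTable,
    selA: Union[SelectionExpr, str],
    selB: Union[SelectionExpr, str],
    r_max: float,
    dr: float,
) -> pd.DataFrame:
    """Pair distribution g(r) between two selections under PBC.

    Distances are histogrammed with minimum-image convention and
    normalized by the ideal-gas shell expectation and the frame count;
    self-pairs are excluded when the selections overlap.  ``r_max``
    must not exceed half the smallest box edge.  Returns columns
    ``r_nm`` (bin centres) and ``g``.
    """
    idx_a = select(table, selA)
    idx_b = select(table, selB)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise SelectionEmptyError("both RDF selections must match at least one site")
    if r_max <= 0 or dr <= 0 or dr >= r_max:
        raise BilayerError("need 0 < dr < r_max")
    boxes = traj.boxes()
    if r_max > boxes.min() / 2 + 1e-12:
        raise BilayerError(
            f"r_max {r_max} nm violates the minimum-image bound "
            f"(half smallest box edge = {boxes.min() / 2:.4g} nm)"
        )
    n_overlap = len(np.intersect1d(idx_a, idx_b))
    edges = np.arange(0.0, r_max + dr / 2, dr)
    n_bins = len(edges) - 1
    counts = np.zeros(n_bins)
    same = len(idx_a) == len(idx_b) and np.array_equal(idx_a, idx_b)
    norm = 0.0
    for fr in traj.frames:
        box = fr.box
        vol = float(np.prod(box))
        pa = wrap_coords(fr.coords[idx_a], box)
        pb = wrap_coords(fr.coords[idx_b], box)
        tree_a = cKDTree(pa, boxsize=box)
        tree_b = tree_a if same else cKDTree(pb, boxsize=box)
        # per-interval counts; zero-distance self pairs land in the
        # leading (d <= 0) slot, which is dropped
        per_bin = tree_a.count_neighbors(tree_b, edges, cumulative=False).astype(float)
        counts += per_bin[1:]
        norm += (len(idx_a) * len(idx_b) - n_overlap) / vol
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = norm * shell
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, counts / ideal, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"r_nm": centers, "g": g})


@dataclass
class ContactRecurrenceMatrix:
    """Fraction-of-frames contact scores, guest groups x lipid classes."""

    df: pd.DataFrame  # rows: guest groups, columns: lipid classes
    cutoff_nm: float
    n_frames: int

    def value(self, row: str, col: str) -> float:
        return float(self.df.loc[row, col])

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# contact recurrence: fraction of {self.n_frames} frames with "
                f"min distance < {self.cutoff_nm:g} nm\n"
            )
            self.df.to_csv(fh, sep="\t", index_label="group")


def contact_recurrence(
    traj: Trajectory,
    table: SiteTable,
    guest_groups: Dict[str, Union[SelectionExpr, str]],
    lipid_classes: Dict[str, Union[SelectionExpr, str]],
    cutoff: float = POLAR_CUTOFF_NM,
) -> ContactRecurrenceMatrix:
    """Score each (guest group, lipid class) pair by contact recurrence.

    A frame counts as a contact iff the minimum minimum-image distance
    over all site pairs is below ``cutoff``.  Groups that select no
    sites score 0 against everything.
    """
    if cutoff <= 0:
        raise BilayerError("cutoff must be positive")
    g_idx = {name: select(table, s) for name, s in guest_groups.items()}
    c_idx = {name: select(table, s) for name, s in lipid_classes.items()}
    rows = list(guest_groups)
    cols = list(lipid_classes)
    hits = np.zeros((len(rows), len(cols)))
    for fr in traj.frames:
        for i, rn in enumerate(rows):
            gi = g_idx[rn]
            if len(gi) == 0:
                continue
            pg = fr.coords[gi]
            for j, cn in enumerate(cols):
                ci = c_idx[cn]
                if len(ci) == 0:
                    continue
                d = minimum_image_vector(
                    pg[:, None, :], fr.coords[ci][None, :, :], fr.box
                )
                dmin = np.sqrt((d**2).sum(axis=2)).min()
                if dmin < cutoff:
                    hits[i, j] += 1
    df = pd.DataFrame(hits / traj.n_frames, index=rows, columns=cols)
    return ContactRecurrenceMatrix(df=df, cutoff_nm=cutoff, n_frames=traj.n_frames)
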