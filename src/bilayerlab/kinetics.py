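"""Lateral diffusion (Einstein relation) and flip-flop detection.

The mean-squared displacement is computed over x,y only, from
unwrapped molecular centres of mass, averaged over molecules and all
time origins (FFT algorithm).  Per-frame leaflet centre-of-mass motion
is subtracted first so that collective drift does not masquerade as
diffusion, and molecules that change leaflet are excluded.

A flip-flop is a leaflet crossing followed by residency in the
destination leaflet for at least ``min_residency`` ps (default 10 ns).
Transiting frames bridge: they extend a pending residency rather than
resetting it.  Crossings whose residency window runs past the end of
the trajectory without reaching the threshold are reported as
censored, not accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple, Union

import numpy as np
import pandas as pd

from .core import BilayerError, SiteTable, Trajectory
from .leaflets import LeafletAssignment
from .select import SelectionExpr, select


class WrappedCoordinatesError(BilayerError):
    pass


@dataclass
class MSDResult:
    table: pd.DataFrame  # columns lag_ps, msd_nm2
    excluded_molecules: List[int]
    n_molecules: int

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """MSD over all time origins for one coordinate series (length n)."""
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * f.conjugate(), nfft)[:n]  # S2(m) = sum_k x_k x_{k+m}
    sq = x**2
    csum = np.cumsum(sq)
    total = csum[-1]
    m = np.arange(n)
    # S1(m) = sum_{k=m}^{n-1} x_k^2 + sum_{k=0}^{n-m-1} x_k^2
    tail = total - np.concatenate([[0.0], csum[:-1]])
    head = np.concatenate([[total], csum[-2::-1]])
    return (tail + head - 2 * acf) / (n - m)


def lateral_msd(
    traj: Trajectory,
    table: SiteTable,
    sel: Union[SelectionExpr, str],
    assignment: LeafletAssignment,
    max_lag_frac: float = 0.5,
    remove_drift: bool = True,
) -> MSDResult:
    """Lateral (x,y) MSD averaged over molecules and time origins.

    ``sel`` picks the sites whose mass-weighted centre defines each
    molecule's position; coordinates must be unwrapped (a jump larger
    than half a box edge between consecutive frames raises
    :class:`WrappedCoordinatesError`).  Molecules whose leaflet label
    changes are excluded and reported; per-frame leaflet
    centre-of-mass motion is subtracted unless ``remove_drift=False``.
    """
    idx = select(table, sel)
    if len(idx) == 0:
        raise BilayerError("selection matches no sites")
    coords = traj.coords_array()[:, idx, :2]  # (nf, ns, 2)
    masses = table.masses[idx]
    mols = table.molecule_ids[idx]
    mol_ids = np.unique(mols)
    nf = traj.n_frames
    if nf < 4:
        raise BilayerError("need at least 4 frames for an MSD")
    # wrapped-input check on the lateral coordinates of the selected sites
    steps = np.abs(np.diff(coords, axis=0))
    half = traj.boxes()[:-1, None, :2] / 2
    if np.any(steps > half):
        raise WrappedCoordinatesError(
            "consecutive-frame lateral jumps exceed half a box edge: "
            "coordinates appear wrapped; the MSD needs unwrapped input"
        )
    com = np.empty((nf, len(mol_ids), 2))
    for k, m in enumerate(mol_ids):
        mask = mols == m
        w = masses[mask]
        com[:, k] = (coords[:, mask] * w[None, :, None]).sum(axis=1) / w.sum()
    # leaflet bookkeeping
    a_ids = assignment.molecule_ids
    pos_in_assign = {m: i for i, m in enumerate(a_ids)}
    keep, excluded, leaflet0 = [], [], []
    for k, m in enumerate(mol_ids):
        if m not in pos_in_assign:
            excluded.append(int(m))
            continue
        lab = assignment.labels[:, pos_in_assign[m]]
        nz = lab[lab != 0]
        if len(nz) == 0 or np.any(nz != nz[0]):
            excluded.append(int(m))
            continue
        keep.append(k)
        leaflet0.append(int(nz[0]))
    if not keep:
        raise BilayerError("no molecules left after leaflet filtering")
    com = com[:, keep]
    leaflet0 = np.asarray(leaflet0)
    if remove_drift:
        # subtract per-frame leaflet centre-of-mass motion
        for s in (1, -1):
            cols = np.flatnonzero(leaflet0 == s)
            if len(cols):
                com[:, cols] -= com[:, cols].mean(axis=1, keepdims=True)
    max_lag = max(2, int(np.floor(nf * max_lag_frac)))
    msd = np.zeros(nf)
    for k in range(com.shape[1]):
        msd += _msd_fft_1d(np.ascontiguousarray(com[:, k, 0]))
        msd += _msd_fft_1d(np.ascontiguousarray(com[:, k, 1]))
    msd /= com.shape[1]
    lags = (traj.times - traj.times[0])[:max_lag + 1]
    out = pd.DataFrame({"lag_ps": lags, "msd_nm2": msd[: len(lags)]})
    return MSDResult(table=out, excluded_molecules=excluded, n_molecules=com.shape[1])


def fit_diffusion(
    msd: pd.DataFrame, window: Tuple[float, float] = (0.1, 0.5)
) -> float:
    """Least-squares Einstein fit: D = slope/4 over a fractional lag window.

    ``window`` is (lower, upper) as fractions of the maximum lag; at
    least 5 MSD points must fall inside it.  Returns D in nm^2/ps.
    """
    lo, hi = window
    if not (0 <= lo < hi <= 1):
        raise BilayerError("window must satisfy 0 <= lower < upper <= 1")
    lags = msd["lag_ps"].to_numpy()
    vals = msd["msd_nm2"].to_numpy()
    lmax = lags.max()
    mask = (lags >= lo * lmax) & (lags <= hi * lmax)
    if mask.sum() < 5:
        raise BilayerError(f"only {int(mask.sum())} MSD points in window {window}")
    slope, _ = np.polyfit(lags[mask], vals[mask], 1)
    return float(slope / 4.0)


@dataclass
class FlipFlopEvent:
    molecule_id: int
    departure_leaflet: str  # leaflet the molecule left
    t_cross_ps: float
    residency_ps: float
    accepted: bool
    censored: bool = False


def detect_flipflops(
    assignment: LeafletAssignment, min_residency: float = 10000.0
) -> List[FlipFlopEvent]:
    """Detect leaflet translocations and apply the residency criterion.

    A crossing happens at the first frame carrying the opposite leaflet
    label after frames with the original label; transiting frames in
    between are attributed to neither leaflet and simply bridge.  The
    event is accepted iff the molecule keeps the destination label
    (transiting frames again bridging) for at least ``min_residency``
    ps.  If the trajectory ends before either a return or the
    threshold, the event is censored and not accepted.
    """
    if assignment.n_frames < 2:
        raise BilayerError("flip-flop detection needs more than one frame")
    times = assignment.times
    t_end = times[-1]
    events: List[FlipFlopEvent] = []
    for ci, mol in enumerate(assignment.molecule_ids):
        lab = assignment.labels[:, ci]
        nz = np.flatnonzero(lab != 0)
        if len(nz) == 0:
            continue
        home = int(lab[nz[0]])
        i = nz[0]
        while i < len(lab):
            if lab[i] == -home:
                t_cross = float(times[i])
                # scan forward for a return to the original leaflet
                j = i + 1
                ret = None
                while j < len(lab):
                    if lab[j] == home:
                        ret = j
                        break
                    j += 1
                if ret is None:
                    residency = float(t_end - t_cross)
                    accepted = residency >= min_residency
                    events.append(
                        FlipFlopEvent(
                            molecule_id=int(mol),
                            departure_leaflet="upper" if home == 1 else "lower",
                            t_cross_ps=t_cross,
                            residency_ps=residency,
                            accepted=accepted,
                            censored=not accepted,
                        )
                    )
                    break
                residency = float(times[ret] - t_cross)
                accepted = residency >= min_residency
                events.append(
                    FlipFlopEvent(
                        molecule_id=int(mol),
                        departure_leaflet="upper" if home == 1 else "lower",
                        t_cross_ps=t_cross,
                        residency_ps=residency,
                        accepted=accepted,
                    )
                )
                if accepted:
                    home = -home
                    i = ret  # the return is the next candidate crossing
                else:
                    i = ret + 1
            else:
                i += 1
    return events


def flipflops_to_tsv(events: List[FlipFlopEvent], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            {
                "molecule_id": e.molecule_id,
                "departure_leaflet": e.departure_leaflet,
                "t_cross_ps": e.t_cross_ps,
                "residency_ps": e.residency_ps,
                "accepted": e.accepted,
                "censored": e.censored,
            }
            for e in events
        ],
        columns=[
            "molecule_id", "departure_leaflet", "t_cross_ps",
            "residency_ps", "accepted", "censored",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
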