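"""Chain order parameters with respect to the membrane normal (z).

Two conventions are implemented:

* the coarse-grained bond order parameter
  ``P2 = <(3 cos^2 theta - 1)/2>`` where theta is the angle between a
  bead-bead bond and +z.  P2 is 1 for perfect alignment, -0.5 for
  in-plane bonds and 0 for an isotropic orientation distribution;

* the deuterium order parameter per acyl carbon,
  ``S_CD(k) = |<(3 cos^2 theta_CH - 1)/2>|`` with theta_CH the C-H bond
  angle to z, reported as an absolute value.  When no explicit
  hydrogens exist, two ideal tetrahedral C-H unit vectors are
  reconstructed in the plane perpendicular to the C(k-1) -> C(k+1)
  axis, so terminal carbons are omitted from the profile.

Uncertainties are standard deviations over equal-length frame blocks
(5 blocks by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import BilayerError, SiteTable, Trajectory, minimum_image_vector

HALF_TETRAHEDRAL_DEG = np.rad2deg(np.arccos(1.0 / np.sqrt(3.0)))  # 54.7356...


@dataclass
class OrderParameterResult:
    """Per-bond (CG) or per-carbon (AA) order parameters.

    ``labels`` identifies each bond group or carbon position; ``mean``
    and ``sd`` are the block-averaged value and its spread; ``n_skipped``
    counts degenerate (zero-length) vector samples that were dropped.
    """

    labels: List
    mean: np.ndarray
    sd: np.ndarray
    block_len_ps: float
    kind: str  # "p2" or "scd"
    n_samples: int = 0
    n_skipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        key = "bond" if self.kind == "p2" else "carbon_index"
        val = "p2" if self.kind == "p2" else "scd"
        return pd.DataFrame({key: self.labels, val: self.mean, "sd": self.sd})

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _block_stats(samples: np.ndarray, times: np.ndarray, n_blocks: int):
    """Mean and block-SD of per-frame sample rows (frames, groups)."""
    with warnings.catch_warnings():
        # all-NaN groups (fully degenerate bonds) legitimately yield NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(samples, axis=0)
        nf = samples.shape[0]
        n_blocks = max(1, min(n_blocks, nf))
        edges = np.linspace(0, nf, n_blocks + 1).astype(int)
        blocks = np.array(
            [np.nanmean(samples[a:b], axis=0)
             for a, b in zip(edges[:-1], edges[1:]) if b > a]
        )
    sd = np.std(blocks, axis=0, ddof=1) if len(blocks) > 1 else np.zeros_like(mean)
    span = times[-1] - times[0] if nf > 1 else 0.0
    return mean, sd, span / n_blocks


def _p2(cos_theta: np.ndarray) -> np.ndarray:
    return 1.5 * cos_theta**2 - 0.5


def cg_order_p2(
    traj: Trajectory,
    bonds: Sequence[Tuple[int, int]],
    labels: Optional[Sequence] = None,
    n_blocks: int = 5,
) -> OrderParameterResult:
    """P2 of each bond (or bond group) against the membrane normal.

    ``bonds`` are ordered site-index pairs; equivalent bonds may share a
    label, in which case they are averaged together.  Zero-length bond
    vectors are skipped and counted; a warning is raised if more than 1%
    of samples are degenerate.
    """
    bonds = np.asarray(bonds, dtype=int).reshape(-1, 2)
    if labels is None:
        labels = [f"{i}-{j}" for i, j in bonds]
    if len(labels) != len(bonds):
        raise BilayerError("labels must match bonds one-to-one")
    col, uniq = pd.factorize(np.asarray(labels, dtype=object))
    uniq_labels = list(uniq)

    nf = traj.n_frames
    per_frame = np.full((nf, len(uniq_labels)), np.nan)
    n_skipped = 0
    n_samples = 0
    for fi, fr in enumerate(traj.frames):
        vec = minimum_image_vector(fr.coords[bonds[:, 0]], fr.coords[bonds[:, 1]], fr.box)
        norm = np.linalg.norm(vec, axis=1)
        ok = norm > 0
        n_skipped += int((~ok).sum())
        n_samples += len(bonds)
        p2 = np.full(len(bonds), np.nan)
        p2[ok] = _p2(vec[ok, 2] / norm[ok])
        sums = np.bincount(col[ok], weights=p2[ok], minlength=len(uniq_labels))
        cnts = np.bincount(col[ok], minlength=len(uniq_labels))
        with np.errstate(invalid="ignore"):
            per_frame[fi] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    if n_samples and n_skipped / n_samples > 0.01:
        warnings.warn(
            f"{n_skipped}/{n_samples} bond samples had zero length and were skipped",
            stacklevel=2,
        )
    mean, sd, block_len = _block_stats(per_frame, traj.times, n_blocks)
    return OrderParameterResult(
        labels=uniq_labels, mean=mean, sd=sd, block_len_ps=block_len,
        kind="p2", n_samples=n_samples, n_skipped=n_skipped,
    )


def chain_bonds(table: SiteTable, chain_label: str):
    """Consecutive-bead bond list for one chain class, labelled by position.

    Returns (bonds, labels): bonds between chain_position k and k+1 of
    each molecule bearing ``chain_label``, labelled ``"k-(k+1)"`` so that
    equivalent bonds across molecules are pooled.
    """
    df = table.df
    sub = df[df["chain_label"] == chain_label]
    bonds, labels = [], []
    for (_, _), grp in sub.groupby(["molecule_id", "chain_label"], sort=True):
        grp = grp.sort_values("chain_position")
        sids = grp["site_id"].to_numpy()
        poss = grp["chain_position"].to_numpy()
        for a, b, pa, pb in zip(sids[:-1], sids[1:], poss[:-1], poss[1:]):
            if pb == pa + 1:
                bonds.append((int(a), int(b)))
                labels.append(f"{int(pa)}-{int(pb)}")
    return bonds, labels


def _chain_triplets(table: SiteTable, chain_label: str):
    """(k-1, k, k+1) site triples per molecule, keyed by carbon index k."""
    df = table.df
    sub = df[df["chain_label"] == chain_label]
    if sub.empty:
        raise BilayerError(f"no sites with chain_label {chain_label!r}")
    triplets: Dict[int, List[Tuple[int, int, int]]] = {}
    for _, grp in sub.groupby("molecule_id", sort=True):
        grp = grp.sort_values("chain_position")
        sids = grp["site_id"].to_numpy()
        poss = grp["chain_position"].to_numpy(dtype=int)
        for i in range(1, len(sids) - 1):
            if poss[i - 1] + 1 == poss[i] == poss[i + 1] - 1:
                triplets.setdefault(int(poss[i]), []).append(
                    (int(sids[i - 1]), int(sids[i]), int(sids[i + 1]))
                )
    return triplets


def _reconstructed_ch_cosines(fr, trip: np.ndarray) -> np.ndarray:
    """cos(theta_CH) for the two ideal tetrahedral C-H vectors of each triple.

    Both C-H unit vectors lie in the plane perpendicular to the
    C(k-1)->C(k+1) axis, split symmetrically about the in-plane bend
    direction by the ideal H-C-H angle.
    """
    r_prev, r_k, r_next = fr.coords[trip[:, 0]], fr.coords[trip[:, 1]], fr.coords[trip[:, 2]]
    u = minimum_image_vector(r_prev, r_next, fr.box)
    un = np.linalg.norm(u, axis=1, keepdims=True)
    ok = un[:, 0] > 1e-12
    u = np.divide(u, np.where(un > 0, un, 1.0))
    s = minimum_image_vector(r_k, r_prev, fr.box) + minimum_image_vector(r_k, r_next, fr.box)
    v1 = s - (np.sum(s * u, axis=1, keepdims=True)) * u
    v1n = np.linalg.norm(v1, axis=1, keepdims=True)
    # collinear chain: any in-plane direction is equivalent; build one
    deg = v1n[:, 0] < 1e-10
    if deg.any():
        helper = np.tile(np.array([1.0, 0.0, 0.0]), (deg.sum(), 1))
        nearly_x = np.abs(u[deg, 0]) > 0.9
        helper[nearly_x] = np.array([0.0, 1.0, 0.0])
        w = helper - np.sum(helper * u[deg], axis=1, keepdims=True) * u[deg]
        v1[deg] = w
        v1n[deg] = np.linalg.norm(w, axis=1, keepdims=True)
    v1 = v1 / v1n
    nrm = np.cross(u, v1)
    eta = np.deg2rad(HALF_TETRAHEDRAL_DEG)
    h1 = np.cos(eta) * v1 + np.sin(eta) * nrm
    h2 = np.cos(eta) * v1 - np.sin(eta) * nrm
    cos = np.concatenate([h1[:, 2], h2[:, 2]])
    okmask = np.concatenate([ok, ok])
    return np.where(okmask, cos, np.nan)


def deuterium_order_scd(
    traj: Trajectory,
    table: SiteTable,
    chain: str,
    h_mode: str = "reconstructed",
    h_map: Optional[Dict[int, Sequence[int]]] = None,
    n_blocks: int = 5,
) -> OrderParameterResult:
    """S_CD profile per carbon position of one chain class.

    ``h_mode='explicit_H'`` uses measured C-H vectors and needs
    ``h_map``: carbon site_id -> hydrogen site_ids.  In
    ``'reconstructed'`` mode ideal C-H directions are rebuilt from the
    neighbouring carbons, so the first and last carbons are absent from
    the profile.
    """
    if h_mode not in ("explicit_H", "reconstructed"):
        raise BilayerError("h_mode must be 'explicit_H' or 'reconstructed'")
    df = table.df
    sub = df[df["chain_label"] == chain]
    if sub.empty:
        raise BilayerError(f"no sites with chain_label {chain!r}")

    if h_mode == "explicit_H":
        if not h_map:
            raise BilayerError("explicit_H mode requires h_map (carbon -> H site ids)")
        carbons = sub.sort_values(["molecule_id", "chain_position"])
        pos_of = dict(zip(carbons["site_id"], carbons["chain_position"].astype(int)))
        pairs, pos_col = [], []
        for c_sid, h_sids in h_map.items():
            if c_sid not in pos_of:
                raise BilayerError(f"h_map carbon {c_sid} is not on chain {chain!r}")
            for h in h_sids:
                pairs.append((c_sid, int(h)))
                pos_col.append(pos_of[c_sid])
        pairs = np.asarray(pairs, int)
        positions = sorted(set(pos_col))
        colmap = {p: i for i, p in enumerate(positions)}
        col = np.array([colmap[p] for p in pos_col])
        nf = traj.n_frames
        per_frame = np.full((nf, len(positions)), np.nan)
        for fi, fr in enumerate(traj.frames):
            vec = minimum_image_vector(fr.coords[pairs[:, 0]], fr.coords[pairs[:, 1]], fr.box)
            nrm = np.linalg.norm(vec, axis=1)
            okv = nrm > 0
            p2 = np.full(len(pairs), np.nan)
            p2[okv] = _p2(vec[okv, 2] / nrm[okv])
            sums = np.bincount(col[okv], weights=p2[okv], minlength=len(positions))
            cnts = np.bincount(col[okv], minlength=len(positions))
            per_frame[fi] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        mean, sd, block_len = _block_stats(per_frame, traj.times, n_blocks)
        return OrderParameterResult(
            labels=positions, mean=np.abs(mean), sd=sd,
            block_len_ps=block_len, kind="scd",
        )

    triplets = _chain_triplets(table, chain)
    if not triplets:
        raise BilayerError(
            f"chain {chain!r} has no interior carbons; reconstructed mode "
            "needs at least three consecutive positions"
        )
    positions = sorted(triplets)
    nf = traj.n_frames
    per_frame = np.full((nf, len(positions)), np.nan)
    trip_arrays = {p: np.asarray(triplets[p], int) for p in positions}
    for fi, fr in enumerate(traj.frames):
        for ci, p in enumerate(positions):
            cos = _reconstructed_ch_cosines(fr, trip_arrays[p])
            per_frame[fi, ci] = np.nanmean(_p2(cos))
    mean, sd, block_len = _block_stats(per_frame, traj.times, n_blocks)
    return OrderParameterResult(
        labels=positions, mean=np.abs(mean), sd=sd, block_len_ps=block_len, kind="scd",
    )
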