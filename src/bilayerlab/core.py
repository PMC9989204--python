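"""Core domain types for bilayer trajectory analysis.

Units follow the GROMACS/GRO conventions throughout the package:
lengths in nanometres, times in picoseconds, masses in unified atomic
mass units, charges in elementary-charge units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

POLARITY_CLASSES = frozenset(
    {
        "polar",
        "apolar",
        "phosphate",
        "headgroup_amine",
        "headgroup_carboxylate",
        "hydroxyl",
        "water",
        "ion",
        "other",
    }
)

CHAIN_LABELS = frozenset({"sn1", "sn2", "guest_chain1", "guest_chain2", "sterol_body"})

SITE_TABLE_COLUMNS = [
    "site_id",
    "site_name",
    "residue_name",
    "molecule_id",
    "mass",
    "charge",
    "electrons",
    "polarity_class",
    "chain_label",
    "chain_position",
]


class BilayerError(Exception):
    """Base class for errors raised by this package."""


class SiteTableError(BilayerError):
    pass


class GeometryError(BilayerError):
    pass


@dataclass
class SiteTable:
    """Per-site static metadata backed by a :class:`pandas.DataFrame`.

    Columns: ``site_id`` (0-based, contiguous), ``site_name``,
    ``residue_name``, ``molecule_id``, ``mass`` (u), ``charge`` (e),
    ``electrons`` (count), ``polarity_class``, ``chain_label``
    (nullable), ``chain_position`` (nullable, 1-based carbon index
    counted from the carbonyl end of the chain).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SITE_TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SiteTableError(f"site table missing columns: {missing}")
        self.df = self.df[SITE_TABLE_COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        sid = np.asarray(self.df["site_id"], dtype=int)
        if len(sid) and not np.array_equal(sid, np.arange(len(sid))):
            raise SiteTableError("site_id values must be unique and contiguous from 0")
        if (np.asarray(self.df["mass"], dtype=float) <= 0).any():
            raise SiteTableError("all site masses must be > 0")
        if (np.asarray(self.df["electrons"], dtype=float) < 0).any():
            raise SiteTableError("electron counts must be >= 0")
        bad_pol = set(self.df["polarity_class"].unique()) - POLARITY_CLASSES
        if bad_pol:
            raise SiteTableError(f"unknown polarity_class values: {sorted(bad_pol)}")
        cl = self.df["chain_label"]
        bad_cl = set(cl.dropna().unique()) - CHAIN_LABELS
        if bad_cl:
            raise SiteTableError(f"unknown chain_label values: {sorted(bad_cl)}")
        has_pos = self.df["chain_position"].notna()
        if (has_pos & cl.isna()).any():
            raise SiteTableError("every site with a chain_position needs a chain_label")

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "SiteTable":
        df = pd.DataFrame.from_records(list(records))
        for col, default in (
            ("mass", 1.0),
            ("charge", 0.0),
            ("electrons", 0.0),
            ("polarity_class", "other"),
            ("chain_label", None),
            ("chain_position", None),
        ):
            if col not in df.columns:
                df[col] = default
        if "site_id" not in df.columns:
            df["site_id"] = np.arange(len(df))
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def column(self, name: str) -> np.ndarray:
        return np.asarray(self.df[name])

    @property
    def molecule_ids(self) -> np.ndarray:
        return np.asarray(self.df["molecule_id"], dtype=int)

    @property
    def masses(self) -> np.ndarray:
        return np.asarray(self.df["mass"], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.asarray(self.df["charge"], dtype=float)

    @property
    def electrons(self) -> np.ndarray:
        return np.asarray(self.df["electrons"], dtype=float)


@dataclass
class Frame:
    """A single snapshot: time (ps), orthorhombic box edges (nm), coords (nm)."""

    time: float
    box: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise GeometryError("coords must have shape (n_sites, 3)")
        if not np.all(self.box > 0):
            raise GeometryError("box edges must be strictly positive")

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """Time-ordered sequence of frames sharing one site table.

    ``dt`` is the nominal frame spacing in ps; frame times must be
    strictly increasing and all frames must have the same site count.
    """

    frames: Sequence[Frame]
    dt: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.frames = list(self.frames)
        if not self.frames:
            raise BilayerError("trajectory needs at least one frame")
        times = np.array([f.time for f in self.frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise BilayerError("frame times must be strictly increasing")
        n = {f.n_sites for f in self.frames}
        if len(n) != 1:
            raise BilayerError("all frames must have the same number of sites")
        if self.dt <= 0 and len(times) > 1:
            self.dt = float(np.median(np.diff(times)))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_sites(self) -> int:
        return self.frames[0].n_sites

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def coords_array(self) -> np.ndarray:
        """Stack coordinates as (n_frames, n_sites, 3)."""
        return np.stack([f.coords for f in self.frames])

    def boxes(self) -> np.ndarray:
        return np.stack([f.box for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def minimum_image_vector(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement ``b - a`` in an orthorhombic box.

    Each component is wrapped into ``(-L/2, L/2]``.  ``a`` and ``b`` may
    be arrays of points (broadcast against each other); ``box`` is the
    three edge lengths in nm.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise GeometryError("box edges must be strictly positive")
    d = np.subtract(b, a, dtype=float)
    # ceil(x - 1/2) maps the component into (-L/2, L/2]; in-place to
    # avoid temporaries on large bond lists
    t = d * (1.0 / box)
    t -= 0.5
    np.ceil(t, out=t)
    t *= box
    return d - t


def wrap_coords(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, L) per axis."""
    box = np.asarray(box, dtype=float)
    return np.mod(coords, box)
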