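"""Configuration-driven orchestration and condition comparison.

One YAML config drives a whole run: either an inline synthetic bilayer
spec or paths to input files, the selections, the list of analyses and
their parameters.  ``run_pipeline`` executes the analyses in
dependency order (leaflets -> geometry -> order/profiles ->
contacts/kinetics), writes every result as TSV plus a machine-readable
``manifest.json``, and is bit-reproducible for a fixed config and
seed.  ``compare_conditions`` builds paired with/without-guest delta
tables from two result bundles, refusing to compare bundles whose
parameters differ.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import BilayerError, Trajectory
from .io import read_gro, read_site_table, read_trjtxt, write_gro, write_site_table, write_trjtxt
from .select import SelectionExpr
from .synth import BilayerSpec, FlipEvent, GuestSpec, build_bilayer, simulate_dynamics
from .leaflets import area_per_lipid, assign_leaflets, membrane_thickness
from .order import cg_order_p2, chain_bonds, deuterium_order_scd
from .profiles import density_profile, dipole_potential
from .contacts import contact_recurrence, radial_distribution
from .kinetics import detect_flipflops, fit_diffusion, flipflops_to_tsv, lateral_msd

log = logging.getLogger("bilayerlab")

KNOWN_ANALYSES = [
    "geometry", "p2", "scd", "density", "potential",
    "rdf", "contacts", "msd", "flipflops",
]

_FLOAT_FMT = "%.10g"


class ConfigError(BilayerError):
    pass


class ConfigMismatchError(BilayerError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    seed: int = 0
    outdir: Path = Path("results")
    synthetic: Optional[dict] = None
    inputs: Optional[dict] = None
    selections: Dict[str, str] = field(default_factory=dict)
    analyses: List[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'synthetic' or 'inputs' must be given")
        unknown = [a for a in self.analyses if a not in KNOWN_ANALYSES]
        if unknown:
            raise ConfigError(f"unknown analyses {unknown}; known: {KNOWN_ANALYSES}")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(
        cls,
        path: Union[str, Path],
        seed: Optional[int] = None,
        outdir: Optional[Union[str, Path]] = None,
    ) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if seed is not None:
            raw["seed"] = seed
        if outdir is not None:
            raw["outdir"] = str(outdir)
        return cls(
            seed=int(raw.get("seed", 0)),
            outdir=Path(raw.get("outdir", "results")),
            synthetic=raw.get("synthetic"),
            inputs=raw.get("inputs"),
            selections={k: str(v) for k, v in (raw.get("selections") or {}).items()},
            analyses=list(raw.get("analyses") or []),
            parameters=raw.get("parameters") or {},
            log_level=str(raw.get("log_level", "INFO")),
        )

    def comparable_dict(self) -> dict:
        """The parameter-locked part compared across conditions."""
        return {
            "selections": self.selections,
            "analyses": sorted(self.analyses),
            "parameters": self.parameters,
        }


def _build_spec(synth: dict, seed: int) -> tuple:
    kwargs = dict(synth)
    n_frames = int(kwargs.pop("n_frames", 100))
    dt = float(kwargs.pop("dt_ps", 10.0))
    guests = kwargs.pop("guests", None)
    flips = kwargs.pop("flips", [])
    kwargs["guest_spec"] = (
        GuestSpec(int(guests["n_guests"]), float(guests["depth_below_phosphate"]))
        if guests
        else None
    )
    kwargs["flip_script"] = tuple(
        FlipEvent(int(f["molecule_id"]), float(f["start_ps"]), float(f["residency_ps"]))
        for f in flips
    )
    kwargs.setdefault("seed", seed)
    return BilayerSpec(**kwargs), n_frames, dt


def load_inputs(config: RunConfig):
    """Resolve the (table, trajectory) pair the config describes."""
    if config.synthetic is not None:
        spec, n_frames, dt = _build_spec(config.synthetic, config.seed)
        table, frame0 = build_bilayer(spec)
        traj = simulate_dynamics(table, frame0, n_frames, dt, spec)
        return table, traj
    inp = config.inputs
    if "site_table" not in inp:
        raise ConfigError("inputs.site_table is required")
    table = read_site_table(inp["site_table"])
    if "trjtxt" in inp:
        traj = read_trjtxt(inp["trjtxt"])
    elif "gro" in inp:
        _, obj = read_gro(inp["gro"])
        traj = obj if isinstance(obj, Trajectory) else Trajectory([obj])
    else:
        raise ConfigError("inputs needs 'trjtxt' or 'gro'")
    if traj.n_sites != len(table):
        raise ConfigError("site table and trajectory disagree on site count")
    return table, traj


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analyses; returns the manifest dict.

    Every requested analysis runs even if an earlier one fails; each
    failure is recorded in the manifest with its error message.  The
    manifest lists every file written, the parameters used and the
    seed, and the run is deterministic for a fixed config + seed.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    params = config.parameters
    sel = config.selections
    ref = sel.get("reference", "polarity_class == phosphate")
    for name, expr in sel.items():
        SelectionExpr.parse(expr)  # fail early on any bad selection

    manifest = {
        "package": "bilayerlab",
        "version": __version__,
        "seed": config.seed,
        "inputs": config.inputs or {"synthetic": config.synthetic},
        "selections": sel,
        "parameters": params,
        "analyses": {},
        "files": [],
    }

    table, traj = load_inputs(config)
    if config.synthetic is not None:
        write_site_table(table, out / "site_table.tsv")
        write_gro(table, traj.frames[0], out / "frame0.gro")
        write_trjtxt(traj, out / "trajectory.trjtxt")
        manifest["files"] += ["site_table.tsv", "frame0.gro", "trajectory.trjtxt"]

    transit = float(params.get("transit_band_nm", 0.3))
    assignment = None
    guest_assignment = None

    def _assignment():
        nonlocal assignment, guest_assignment
        if assignment is None:
            assignment = assign_leaflets(traj, table, ref, transit)
            assignment.to_tsv(out / "leaflets.tsv")
            manifest["files"].append("leaflets.tsv")
            gref = sel.get("guest_reference")
            if gref:
                try:
                    guest_assignment = assign_leaflets(traj, table, gref, transit)
                except BilayerError:
                    guest_assignment = None
        return assignment

    def _run(name, fn):
        try:
            fn()
            manifest["analyses"][name] = {"status": "ok"}
            log.info("analysis %s: ok", name)
        except Exception as exc:  # recorded, not fatal to the rest
            manifest["analyses"][name] = {"status": "failed", "error": str(exc)}
            log.error("analysis %s failed: %s", name, exc)

    if "geometry" in config.analyses:
        def _geometry():
            a = _assignment()
            th = membrane_thickness(traj, table, ref, transit, assignment=a)
            _write(th, out / "thickness.tsv")
            apl = area_per_lipid(traj, a, guest_assignment)
            _write(apl, out / "apl.tsv")
            manifest["files"] += ["thickness.tsv", "apl.tsv"]
        _run("geometry", _geometry)

    if "p2" in config.analyses:
        def _p2():
            chain = params.get("p2_chain", "sn1")
            bonds, labels = chain_bonds(table, chain)
            res = cg_order_p2(traj, bonds, labels, n_blocks=int(params.get("n_blocks", 5)))
            res.to_tsv(out / "p2.tsv")
            manifest["files"].append("p2.tsv")
        _run("p2", _p2)

    if "scd" in config.analyses:
        def _scd():
            chain = params.get("scd_chain", "sn1")
            res = deuterium_order_scd(
                traj, table, chain,
                h_mode=params.get("scd_mode", "reconstructed"),
                n_blocks=int(params.get("n_blocks", 5)),
            )
            res.to_tsv(out / "scd.tsv")
            manifest["files"].append("scd.tsv")
        _run("scd", _scd)

    n_bins = int(params.get("n_bins", 100))
    if "density" in config.analyses:
        def _density():
            for weight in ("mass", "charge"):
                prof = density_profile(traj, table, "all", weight, n_bins)
                prof.to_tsv(out / f"density_{weight}.tsv")
                manifest["files"].append(f"density_{weight}.tsv")
        _run("density", _density)

    if "potential" in config.analyses:
        def _potential():
            prof = dipole_potential(traj, table, n_bins)
            prof.to_tsv(out / "potential.tsv")
            manifest["files"].append("potential.tsv")
        _run("potential", _potential)

    if "rdf" in config.analyses:
        def _rdf():
            rp = params.get("rdf", {})
            g = radial_distribution(
                traj, table,
                rp.get("selA", "polarity_class == phosphate"),
                rp.get("selB", "polarity_class == phosphate"),
                float(rp.get("r_max_nm", 2.0)),
                float(rp.get("dr_nm", 0.02)),
            )
            _write(g, out / "rdf.tsv")
            manifest["files"].append("rdf.tsv")
        _run("rdf", _rdf)

    if "contacts" in config.analyses:
        def _contacts():
            cp = params.get("contacts", {})
            guest_groups = cp.get(
                "guest_groups",
                {
                    "carboxylate": "polarity_class == headgroup_carboxylate",
                    "hydroxyl": "polarity_class == hydroxyl",
                },
            )
            lipid_classes = cp.get(
                "lipid_classes",
                {
                    "phosphate": "polarity_class == phosphate",
                    "amine": "polarity_class == headgroup_amine",
                },
            )
            cutoff = float(cp.get("cutoff_nm", 0.35))
            mat = contact_recurrence(traj, table, guest_groups, lipid_classes, cutoff)
            mat.to_tsv(out / "contacts.tsv")
            manifest["files"].append("contacts.tsv")
        _run("contacts", _contacts)

    if "msd" in config.analyses:
        def _msd():
            a = _assignment()
            msel = sel.get("msd", "residue_name == LIP")
            res = lateral_msd(traj, table, msel, a)
            res.to_tsv(out / "msd.tsv")
            manifest["files"].append("msd.tsv")
            window = tuple(params.get("msd_window", (0.1, 0.5)))
            d = fit_diffusion(res.table, window)
            pd.DataFrame({"D_nm2_per_ps": [d]}).to_csv(
                out / "diffusion.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
            )
            manifest["files"].append("diffusion.tsv")
        _run("msd", _msd)

    if "flipflops" in config.analyses:
        def _flipflops():
            a = _assignment()
            events = detect_flipflops(a, float(params.get("min_residency_ps", 10000)))
            flipflops_to_tsv(events, out / "flipflops.tsv")
            manifest["files"].append("flipflops.tsv")
        _run("flipflops", _flipflops)

    manifest["comparable"] = config.comparable_dict()
    manifest["files"].append("manifest.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def pipeline_failed(manifest: dict) -> bool:
    return any(a.get("status") != "ok" for a in manifest["analyses"].values())


# --- condition comparison --------------------------------------------------

def _diff_dicts(a: dict, b: dict, prefix="") -> List[str]:
    diffs = []
    keys = sorted(set(a) | set(b))
    for k in keys:
        pa, pb = a.get(k), b.get(k)
        if isinstance(pa, dict) and isinstance(pb, dict):
            diffs += _diff_dicts(pa, pb, prefix + k + ".")
        elif pa != pb:
            diffs.append(f"{prefix}{k}: {pa!r} != {pb!r}")
    return diffs


def compare_conditions(
    dir_a: Union[str, Path],
    dir_b: Union[str, Path],
    outdir: Optional[Union[str, Path]] = None,
) -> Dict[str, pd.DataFrame]:
    """Paired (A, B, delta = B - A) tables for two result bundles.

    Both bundles must have been produced with identical selections and
    parameters; otherwise the comparison refuses with a diff of the two
    configurations.  Observables compared when present in both bundles:
    mean thickness, mean APL, per-bond P2, per-carbon S_CD, the
    dipole-potential extremum, and the fitted diffusion coefficient.
    """
    dir_a, dir_b = Path(dir_a), Path(dir_b)
    man_a = json.loads((dir_a / "manifest.json").read_text())
    man_b = json.loads((dir_b / "manifest.json").read_text())
    diffs = _diff_dicts(
        man_a.get("comparable", {}).get("parameters", {}),
        man_b.get("comparable", {}).get("parameters", {}),
    )
    if diffs:
        raise ConfigMismatchError(
            "bundles were produced with different parameters:\n  " + "\n  ".join(diffs)
        )
    out: Dict[str, pd.DataFrame] = {}

    def _scalar(name, fname, col):
        fa, fb = dir_a / fname, dir_b / fname
        if fa.exists() and fb.exists():
            a = pd.read_csv(fa, sep="\t")[col].mean()
            b = pd.read_csv(fb, sep="\t")[col].mean()
            out[name] = pd.DataFrame(
                {"observable": [name], "A": [a], "B": [b], "delta": [b - a]}
            )

    _scalar("thickness_nm", "thickness.tsv", "thickness_nm")
    _scalar("apl_nm2", "apl.tsv", "apl_nm2")
    _scalar("diffusion_nm2_per_ps", "diffusion.tsv", "D_nm2_per_ps")

    def _profilemax(name, fname):
        fa, fb = dir_a / fname, dir_b / fname
        if fa.exists() and fb.exists():
            pa = pd.read_csv(fa, sep="\t")
            pb = pd.read_csv(fb, sep="\t")
            va = pa.loc[pa["value"].abs().idxmax(), "value"]
            vb = pb.loc[pb["value"].abs().idxmax(), "value"]
            out[name] = pd.DataFrame(
                {"observable": [name], "A": [va], "B": [vb], "delta": [vb - va]}
            )

    _profilemax("potential_extremum_V", "potential.tsv")

    def _percol(name, fname, key, col):
        fa, fb = dir_a / fname, dir_b / fname
        if fa.exists() and fb.exists():
            a = pd.read_csv(fa, sep="\t").set_index(key)[col]
            b = pd.read_csv(fb, sep="\t").set_index(key)[col]
            common = a.index.intersection(b.index)
            if len(common) == 0:
                raise ConfigMismatchError(f"{fname}: no shared {key} entries")
            out[name] = pd.DataFrame(
                {key: common, "A": a[common].values, "B": b[common].values,
                 "delta": (b[common] - a[common]).values}
            )

    _percol("p2", "p2.tsv", "bond", "p2")
    _percol("scd", "scd.tsv", "carbon_index", "scd")

    if not out:
        raise ConfigMismatchError("the two bundles share no comparable observables")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            _write(df, outdir / f"delta_{name}.tsv")
    return out
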