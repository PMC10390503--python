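"""End-to-end pipeline orchestration.

A :class:`RunConfig` names either input files (topology PDB, trajectory,
parameter TSV) or a synthetic fixture spec, plus the stages to run and
their knobs.  :func:`run_pipeline` executes the requested stages in
dependency order (I/O -> RDF -> cutoffs -> shells -> sites -> geometry ->
density -> energetics -> convergence), writes TSV/OpenDX outputs and a
plain-text summary, and is deterministic given (inputs, config, seed).
Every output table carries a comment line recording the package version,
a hash of the configuration and the seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import Role, Trajectory
from .io import read_topology, read_trajectory
from .synthetic import SyntheticSpec, default_fixture_spec, generate_trajectory
from . import shells as sh
from . import geometry as geo
from . import energetics as en

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "parse_config", "ALL_STAGES"]

log = logging.getLogger("mgshells")

ALL_STAGES = [
    "rdf",
    "shells",
    "sites",
    "hbonds",
    "geometry",
    "density",
    "energy",
    "converge",
]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of (``topology_path`` + ``trajectory_path``) or
    ``synthetic`` must be supplied.  ``hbonds`` rows are
    (donor_res, donor_atom, hydrogen_atom, acceptor_res, acceptor_atom);
    ``order_params`` rows are (name, side_a, side_b) where each side is a
    ``res:atom`` token or a ``+``-joined list of them (reduced to a
    mass-weighted center).
    """

    topology_path: str | None = None
    trajectory_path: str | None = None
    params_path: str | None = None
    synthetic: SyntheticSpec | None = None
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    stride: int = 1
    inner_cutoff: float = sh.INNER_CUTOFF
    outer_cutoff: float = sh.OUTER_CUTOFF
    rdf_bin_width: float = 0.05
    rdf_r_max: float = 10.0
    window: tuple[int, int] | None = None
    energy_threshold: float = -2.0
    n_blocks: int = 4
    hbonds: list[tuple[int, str, str, int, str]] = field(default_factory=list)
    order_params: list[tuple[str, str, str]] = field(default_factory=list)
    rmsf_exclude: tuple[int, int] | None = None
    seed: int = 0
    out_dir: str = "mgshells_out"

    def __post_init__(self) -> None:
        has_files = self.topology_path is not None and self.trajectory_path is not None
        if has_files == (self.synthetic is not None):
            raise ValueError("provide exactly one of input paths or a synthetic spec")
        if self.inner_cutoff <= 0 or self.outer_cutoff <= self.inner_cutoff:
            raise ValueError("cutoffs must satisfy 0 < inner < outer")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def config_hash(self) -> str:
        # out_dir is where results land, not part of the analysis identity
        blob = repr(
            sorted(
                (f.name, repr(getattr(self, f.name)))
                for f in fields(self)
                if f.name != "out_dir"
            )
        ).encode()
        return hashlib.md5(blob).hexdigest()[:12]


def parse_config(path) -> RunConfig:
    """Parse a flat ``key = value`` text config into a RunConfig.

    List-valued keys: ``stages`` is comma-separated; ``hbond`` and
    ``order_param.<name>`` may repeat.  A line ``synthetic = default``
    requests the built-in fixture (honouring ``seed`` and ``n_frames``).
    """
    kv: dict[str, str] = {}
    hbonds: list[tuple[int, str, str, int, str]] = []
    order_params: list[tuple[str, str, str]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "hbond":
            d_res, d_atom, h_atom, a_res, a_atom = value.split(":")
            hbonds.append((int(d_res), d_atom, h_atom, int(a_res), a_atom))
        elif key.startswith("order_param."):
            side_a, _, side_b = value.partition("|")
            order_params.append((key.split(".", 1)[1], side_a.strip(), side_b.strip()))
        else:
            kv[key] = value
    seed = int(kv.get("seed", "0"))
    synthetic = None
    if kv.get("synthetic") == "default":
        synthetic = default_fixture_spec(
            seed=seed, n_frames=int(kv.get("n_frames", "2000"))
        )
    window = None
    if "window" in kv:
        a, _, b = kv["window"].partition(":")
        window = (int(a), int(b))
    return RunConfig(
        topology_path=kv.get("topology"),
        trajectory_path=kv.get("trajectory"),
        params_path=kv.get("params"),
        synthetic=synthetic,
        stages=[s.strip() for s in kv["stages"].split(",")] if "stages" in kv else list(ALL_STAGES),
        stride=int(kv.get("stride", "1")),
        inner_cutoff=float(kv.get("inner_cutoff", sh.INNER_CUTOFF)),
        outer_cutoff=float(kv.get("outer_cutoff", sh.OUTER_CUTOFF)),
        window=window,
        energy_threshold=float(kv.get("energy_threshold", "-2.0")),
        hbonds=hbonds,
        order_params=order_params,
        seed=seed,
        out_dir=kv.get("out", "mgshells_out"),
    )


def _resolve_side(traj: Trajectory, token: str):
    idx = []
    for part in token.split("+"):
        res, _, atom = part.strip().partition(":")
        idx.append(traj.topology.atom_index(int(res), atom))
    return np.array(idx, dtype=int)


class _Writer:
    def __init__(self, out_dir: Path, config: RunConfig):
        self.out_dir = out_dir
        self.header = (
            f"# mgshells {__version__} config_hash={config.config_hash()} seed={config.seed}\n"
        )

    def table(self, df: pd.DataFrame, name: str) -> Path:
        path = self.out_dir / name
        with open(path, "w") as fh:
            fh.write(self.header)
            df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        return path

    def text(self, lines: list[str], name: str) -> Path:
        path = self.out_dir / name
        with open(path, "w") as fh:
            fh.write(self.header)
            fh.write("\n".join(lines) + "\n")
        return path


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run the configured stages and write the report bundle.

    Returns a dict of in-memory results keyed by stage (also listing the
    written files under ``"outputs"``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    writer = _Writer(out_dir, config)
    results: dict[str, object] = {"outputs": []}
    summary: list[str] = []

    def _run(stage: str, fn):
        try:
            return fn()
        except Exception as exc:  # annotate failures with their stage
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    # ---- input ----------------------------------------------------------
    truth = None
    if config.synthetic is not None:
        traj, truth = _run("simulate", lambda: generate_trajectory(config.synthetic))
        summary.append(
            f"synthetic fixture: {config.synthetic.n_nucleotides} nt, "
            f"{config.synthetic.n_ions} ions, {traj.n_frames} frames, "
            f"seed {config.synthetic.seed}"
        )
        planted_sites = sum(
            1 for p in config.synthetic.ion_plans if p.mode == "inner" and p.occupancy > 0
        )
        summary.append(f"planted inner-shell site count: {planted_sites}")
        results["truth"] = truth
    else:
        topology = _run("io", lambda: read_topology(config.topology_path, config.params_path))
        traj = _run(
            "io", lambda: read_trajectory(topology, config.trajectory_path, stride=config.stride)
        )
        summary.append(
            f"input: {config.trajectory_path} ({traj.n_frames} frames, stride {config.stride})"
        )
    results["trajectory"] = traj
    top = traj.topology
    ions = top.select(role=Role.ION)
    phosphate_oxygens = top.select(atom_name=["OP1", "OP2"])
    stages = set(config.stages)

    # ---- RDF + cutoffs --------------------------------------------------
    inner_cut, outer_cut = config.inner_cutoff, config.outer_cutoff
    if "rdf" in stages and len(ions) and len(phosphate_oxygens):
        rdf = _run(
            "rdf",
            lambda: sh.compute_rdf(
                traj, phosphate_oxygens, ions, config.rdf_bin_width, config.rdf_r_max
            ),
        )
        results["rdf"] = rdf
        results["outputs"].append(writer.table(rdf.to_frame(), "rdf.tsv"))
        suggestion = sh.suggest_cutoffs(rdf)
        results["cutoffs"] = suggestion
        summary.append(
            f"rdf cutoff suggestion: inner {suggestion.inner_cutoff:.2f} A, "
            f"outer {suggestion.outer_cutoff:.2f} A"
            + (" (fallback)" if suggestion.fallback else "")
        )

    # ---- shells ---------------------------------------------------------
    assignments = None
    if {"shells", "sites"} & stages and len(ions) and len(phosphate_oxygens):
        assignments = _run(
            "shells",
            lambda: sh.assign_shells(traj, phosphate_oxygens, ions, inner_cut, outer_cut),
        )
        results["assignments"] = assignments
    if "shells" in stages and assignments is not None:
        profile = _run(
            "shells", lambda: sh.coordination_fractions(assignments, top, traj.n_frames)
        )
        results["fractions"] = profile
        results["outputs"].append(writer.table(profile.per_residue, "fractions.tsv"))
        if any(a.shell == "inner" for a in assignments):
            pref = _run("shells", lambda: sh.op2_op1_preference(assignments, top))
            results["preference"] = pref
            results["outputs"].append(writer.table(pref.per_residue, "op_preference.tsv"))
            summary.append(
                "OP2:OP1 inner-shell preference: "
                + ("inf (no OP1 contacts)" if pref.op1_zero else f"{pref.global_ratio:.2f}")
            )

    # ---- sites + bridging waters ---------------------------------------
    if "sites" in stages and assignments is not None:
        sites = _run("sites", lambda: sh.identify_ion_sites(traj, assignments))
        results["sites"] = sites
        rows = [
            {
                "label": s.label,
                "ion_atom": s.ion,
                "dominant_residue": s.dominant_residue,
                "inner_partners": ";".join(f"{r}:{a}:{f:.4f}" for r, a, f in s.inner_partners),
                "outer_partners": ";".join(f"{r}:{a}:{f:.4f}" for r, a, f in s.outer_partners),
                "stable": int(s.stable),
                "bidentate": int(s.bidentate),
            }
            for s in sites
        ]
        results["outputs"].append(
            writer.table(
                pd.DataFrame(
                    rows,
                    columns=[
                        "label",
                        "ion_atom",
                        "dominant_residue",
                        "inner_partners",
                        "outer_partners",
                        "stable",
                        "bidentate",
                    ],
                ),
                "sites.tsv",
            )
        )
        n_stable = sum(1 for s in sites if s.stable)
        summary.append(f"recovered ion sites: {len(sites)} ({n_stable} stable)")
        waters = top.select(role=Role.WATER)
        if len(waters):
            bridge_rows = []
            for site in sites:
                adjacent = [site.dominant_residue - 1, site.dominant_residue + 1]
                adj_sel = top.select(residue=[r for r in adjacent if r >= 1], atom_name=["OP1", "OP2"])
                if not len(adj_sel):
                    continue
                report = _run(
                    "sites",
                    lambda s=site, a=adj_sel: sh.detect_bridging_waters(
                        traj, s, waters, a, inner_cutoff=inner_cut
                    ),
                )
                bridge_rows.append(
                    {
                        "label": site.label,
                        "mean_bridging": float(report["n_bridging"].mean()),
                        "frames_with_bridge": int((report["n_bridging"] > 0).sum()),
                    }
                )
            if bridge_rows:
                results["outputs"].append(
                    writer.table(pd.DataFrame(bridge_rows), "bridges.tsv")
                )

    # ---- hydrogen bonds -------------------------------------------------
    hbond_specs = list(config.hbonds)
    if config.synthetic is not None:
        for plan in config.synthetic.hbond_plans:
            hbond_specs.append(
                (plan.donor[0], plan.donor[1], plan.hydrogen, plan.acceptor[0], plan.acceptor[1])
            )
    if "hbonds" in stages and hbond_specs:
        rows = []
        series_list = []
        for d_res, d_atom, h_atom, a_res, a_atom in hbond_specs:
            hb = _run(
                "hbonds",
                lambda dr=d_res, da=d_atom, ha=h_atom, ar=a_res, aa=a_atom: geo.hbond_fraction(
                    traj,
                    top.atom_index(dr, da),
                    top.atom_index(dr, ha),
                    top.atom_index(ar, aa),
                ),
            )
            series_list.append(hb)
            rows.append(
                {
                    "donor": f"{d_res}:{d_atom}",
                    "hydrogen": f"{d_res}:{h_atom}",
                    "acceptor": f"{a_res}:{a_atom}",
                    "fraction": hb.fraction,
                }
            )
        results["hbonds"] = series_list
        results["outputs"].append(writer.table(pd.DataFrame(rows), "hbonds.tsv"))
        for row in rows:
            summary.append(
                f"hbond {row['donor']}->{row['acceptor']}: fraction {row['fraction']:.4f}"
            )

    # ---- geometry -------------------------------------------------------
    op_specs = list(config.order_params)
    if config.synthetic is not None and not op_specs:
        op_specs = [("d_P6-P14", "6:P", "14:P"), ("d_P38-P40", "38:P", "40:P")]
    if "geometry" in stages:
        series_out = []
        for name, side_a, side_b in op_specs:
            series = _run(
                "geometry",
                lambda n=name, a=side_a, b=side_b: geo.distance_series(
                    traj, _resolve_side(traj, a), _resolve_side(traj, b), name=n
                ),
            )
            series_out.append(series)
            summary.append(f"order parameter {name}: mean {series.mean:.2f} A, sd {series.sd:.2f} A")
        if (
            config.synthetic is not None
            and config.synthetic.ligand_plan is not None
            and config.synthetic.ligand_plan.carboxyl_partner_ion is not None
        ):
            lig_ox = top.select(role=Role.LIGAND, atom_name=["OC1", "OC2"])
            partner = config.synthetic.ligand_plan.carboxyl_partner_ion
            ion_atom = _ion_atom_index(config.synthetic, top, partner)
            series, frac = _run(
                "geometry",
                lambda: geo.carboxyl_ion_distance(traj, lig_ox, ion_atom, name=f"d_carboxyl-{partner}"),
            )
            series_out.append(series)
            results["carboxyl_fraction"] = frac
            summary.append(f"ligand carboxyl outer-shell fraction with {partner}: {frac:.4f}")
        results["order_params"] = series_out
        if series_out:
            merged = series_out[0].to_frame()
            for s in series_out[1:]:
                merged[s.name] = s.values
            results["outputs"].append(writer.table(merged, "order_params.tsv"))

    # ---- density --------------------------------------------------------
    if "density" in stages and len(ions):
        align = top.select(atom_name=["P", "O3'", "O5'", "C1'"], role=Role.RNA)
        if config.rmsf_exclude is not None:
            lo, hi = config.rmsf_exclude
            keep = [
                i
                for i in align.indices
                if not lo <= top.atoms[i].residue_index <= hi
            ]
            align = type(align)(keep, n_atoms=top.n_atoms)
        grid = _run("density", lambda: geo.ion_density(traj, ions, align))
        results["density"] = grid
        dx_path = out_dir / "density.dx"
        grid.to_dx(dx_path)
        results["outputs"].append(dx_path)
        summary.append(
            f"ion density grid: {grid.counts.shape} voxels, {grid.n_events} events"
        )

    # ---- energetics -----------------------------------------------------
    ligand_sel = top.select(role=Role.LIGAND)
    if "energy" in stages and len(ligand_sel):
        decomp = _run(
            "energy",
            lambda: en.per_residue_interaction(traj, ligand_sel, window=config.window),
        )
        results["energy"] = decomp
        results["outputs"].append(writer.table(decomp.per_residue, "energy.tsv"))
        major = en.call_major_nucleotides(decomp, config.energy_threshold)
        results["major_nucleotides"] = major
        summary.append(
            f"major nucleotides (< {config.energy_threshold} kcal/mol): "
            + (",".join(map(str, major)) if major else "none")
        )
        results["outputs"].append(
            writer.text(
                [
                    f"window: {decomp.window}",
                    f"threshold_kcal_mol: {config.energy_threshold}",
                ],
                "energy_meta.txt",
            )
        )

    # ---- convergence ----------------------------------------------------
    if "converge" in stages:
        target = None
        if "order_params" in results and results["order_params"]:
            target = results["order_params"][0]
        if target is not None:
            conv = _run(
                "converge", lambda: en.block_convergence(target.values, config.n_blocks)
            )
            results["convergence"] = conv
            results["outputs"].append(
                writer.table(
                    pd.DataFrame(
                        {
                            "block": np.arange(len(conv.block_means)),
                            "mean": conv.block_means,
                        }
                    ),
                    "blocks.tsv",
                )
            )
            summary.append(
                f"block convergence of {target.name}: max deviation "
                f"{conv.max_deviation:.4f} A over {config.n_blocks} blocks"
            )

    results["outputs"].append(writer.text(summary, "summary.txt"))
    results["summary"] = summary
    return results


def _ion_atom_index(spec: SyntheticSpec, topology, ion_id: str) -> int:
    """Atom index of a planted ion, matching the generator's ordering."""
    plan_ids = [p.ion_id for p in spec.ion_plans]
    ion_atoms = [i for i, a in enumerate(topology.atoms) if a.role is Role.ION]
    return ion_atoms[plan_ids.index(ion_id)]
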