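"""Pipeline orchestration: wire the analysis stages over a study directory.

A *study* is a directory with

* ``reference.pdb`` — the bound-state reference conformation,
* ``ensembles/<ligand>.pdb`` — one multi-model PDB per ligand,
* ``fep_edges.tsv`` — per-leg alchemical edge table (optional),
* ``affinity.tsv`` — ligand table with logD/pKd/MW columns (optional).

Each ``run_*`` function reads what it needs, executes the corresponding
stage and writes a JSON report (plus TSV tables) into the output directory.
Reports echo the fully materialised configuration, carry no timestamps and
format all floats explicitly, so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ensemble_io, fep_network, lipophilicity, populations, surfaces, synthetic_data, thermo
from .geometry import rmsd_series

__all__ = [
    "PipelineConfig",
    "simulate_study",
    "run_populations",
    "run_fep",
    "run_dissect",
    "run_lipo",
    "run_report",
]

# Masks written by simulate_study and expected on the reference; stored as a
# sidecar JSON because the PDB format has no mask concept.
MASKS_FILENAME = "reference_masks.json"


@dataclass
class PipelineConfig:
    """Materialised configuration for every stage; echoed into all reports."""

    study_dir: str = "."
    output_dir: str = "reports"
    reference_file: str = "reference.pdb"
    ensemble_dir: str = "ensembles"
    fep_edge_table: str = "fep_edges.tsv"
    affinity_table: str = "affinity.tsv"
    reference_ligand: str = "5"
    threshold: float = populations.DEFAULT_THRESHOLD
    bin_width: float = populations.DEFAULT_BIN_WIDTH
    n_blocks: int = populations.DEFAULT_N_BLOCKS
    temperature: float = thermo.DEFAULT_TEMPERATURE
    probe_radius: float = surfaces.DEFAULT_PROBE_RADIUS
    n_points: int = surfaces.DEFAULT_N_POINTS
    fit_selection: str = "macrocycle"
    measure_selection: str = "macrocycle"
    sasa_frame_stride: int = 25
    seed: int = 0
    # simulate-stage knobs
    n_frames: int = 2500
    n_residues: int = 8
    study_populations: dict[str, float] = field(
        default_factory=lambda: dict(synthetic_data.PAPER_POPULATIONS)
    )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def study_path(self, name: str) -> Path:
        return Path(self.study_dir) / name

    def out_path(self, name: str) -> Path:
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out / name


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _load_reference(config: PipelineConfig) -> ensemble_io.ReferenceStructure:
    ref_path = config.study_path(config.reference_file)
    if not ref_path.exists():
        raise FileNotFoundError(f"reference structure not found: {ref_path}")
    masks_path = config.study_path(MASKS_FILENAME)
    masks = json.loads(masks_path.read_text()) if masks_path.exists() else None
    return ensemble_io.read_reference(ref_path, selection_masks=masks)


def _load_ensembles(config: PipelineConfig) -> list[ensemble_io.ConformerEnsemble]:
    ens_dir = config.study_path(config.ensemble_dir)
    files = sorted(ens_dir.glob("*.pdb")) + sorted(ens_dir.glob("*.xyz"))
    if not files:
        raise FileNotFoundError(f"no ensemble files (*.pdb, *.xyz) in {ens_dir}")
    return [ensemble_io.read_ensemble(f) for f in files]


# ---------------------------------------------------------------------------
# Stages

def simulate_study(config: PipelineConfig) -> dict:
    """Generate a complete synthetic study into the study directory.

    Writes the toy reference (with its mask sidecar), one bimodal ensemble
    per ligand at the configured occupancies, a per-leg free-energy edge
    table at three restraint levels, and an affinity table carrying the
    published logD/pKd/MW panel for the ligands that have them.
    """
    study = Path(config.study_dir)
    (study / config.ensemble_dir).mkdir(parents=True, exist_ok=True)
    reference = synthetic_data.make_toy_macrocycle(config.n_residues)
    ensemble_io.write_ensemble(
        ensemble_io.ConformerEnsemble(
            ligand_id=reference.structure_id,
            atoms=reference.atoms,
            bonds=reference.bonds,
            frames=reference.coords[None, :, :],
        ),
        study / config.reference_file,
    )
    _write_json(study / MASKS_FILENAME, {k: list(v) for k, v in reference.selection_masks.items()})

    ligands = sorted(config.study_populations)
    for k, lig in enumerate(ligands):
        spec = synthetic_data.EnsembleSpec(
            ligand_id=lig,
            n_frames=config.n_frames,
            p_bioactive=config.study_populations[lig],
            seed=config.seed + 1000 + k,
        )
        ens, _labels = synthetic_data.make_bimodal_ensemble(spec, reference)
        ensemble_io.write_ensemble(ens, study / config.ensemble_dir / f"{lig}.pdb")

    # direct-interaction free energies: for the published panel use a ladder
    # following the measured trend (H/H weakest, Et substituents strongest);
    # unknown ligands fall back to an index-spaced ladder
    ref_lig = config.reference_ligand if config.reference_ligand in ligands else ligands[0]
    direct_dpkd = {"7": -2.0, "9": -1.0, "5": 0.0, "11": 0.5, "12": 0.45}
    node_dg = {
        lig: thermo.dpkd_to_ddg(direct_dpkd[lig])
        if lig in direct_dpkd
        else 0.6 * i
        for i, lig in enumerate(ligands)
    }
    node_dg = {lig: g - node_dg[ref_lig] for lig, g in node_dg.items()}
    chain = list(zip(ligands, ligands[1:]))
    star = [(ref_lig, lig) for lig in ligands if lig != ref_lig]
    edges = []
    for j, fc in enumerate((0.1, 1.0, 10.0)):
        spec = synthetic_data.NetworkSpec(
            node_dG=node_dg,
            edges=chain + star,
            noise_sigma=0.15,
            force_constant=fc,
            seed=config.seed + 2000 + j,
        )
        edges.extend(synthetic_data.make_fep_network(spec))
    fep_network.write_edge_table(edges, study / config.fep_edge_table)

    affinity = pd.DataFrame(
        {
            "ligand_id": ligands,
            "pKd": [
                {"5": 5.57, "7": 3.5, "9": 4.3, "11": 6.06, "12": 6.01}.get(l) for l in ligands
            ],
            "MW": [
                {"5": 1330.0, "7": 1302.0, "9": 1316.0, "11": 1358.0, "12": 1372.0}.get(l)
                for l in ligands
            ],
            "logD": [
                {"5": 1.26, "7": 0.63, "9": 0.95, "11": 1.30, "12": 1.35}.get(l) for l in ligands
            ],
        }
    )
    affinity.to_csv(study / config.affinity_table, sep="\t", index=False)
    return {
        "study_dir": str(study),
        "ligands": ligands,
        "reference_ligand": ref_lig,
        "config": asdict(config),
    }


def run_populations(config: PipelineConfig) -> dict:
    """Per-ligand bioactive-population occupancies with block uncertainties.

    Writes ``populations.json``, ``populations.tsv`` and one histogram TSV
    per ligand.
    """
    reference = _load_reference(config)
    ensembles = _load_ensembles(config)
    rows = []
    report: dict = {"ligands": {}, "config": asdict(config)}
    for ens in ensembles:
        series = rmsd_series(
            ens, reference,
            fit_selection=config.fit_selection,
            measure_selection=config.measure_selection,
        )
        est = populations.classify_populations(
            series, threshold=config.threshold, n_blocks=config.n_blocks
        )
        hist = populations.rmsd_histogram(series, bin_width=config.bin_width)
        conv = populations.block_convergence_report(series, n_blocks=config.n_blocks,
                                                    bin_width=config.bin_width)
        pd.DataFrame(
            {
                "bin_left": hist.bin_edges[:-1],
                "bin_right": hist.bin_edges[1:],
                "count": hist.counts,
                "density": hist.densities,
            }
        ).to_csv(config.out_path(f"hist_{ens.ligand_id}.tsv"), sep="\t", index=False,
                 float_format="%.6f")
        rows.append(
            {
                "ligand_id": ens.ligand_id,
                "p1": est.p1,
                "p2": est.p2,
                "sigma_p1": est.sigma_p1,
                "n_frames": len(series),
            }
        )
        report["ligands"][ens.ligand_id] = {
            "p1": round(est.p1, 6),
            "p2": round(est.p2, 6),
            "sigma_p1": None if est.sigma_p1 is None else round(est.sigma_p1, 6),
            "per_block_p1": [round(x, 6) for x in est.per_block_p1],
            "threshold": config.threshold,
            "n_blocks": config.n_blocks,
            "max_block_histogram_distance": round(conv["max_distance"], 6),
        }
    pd.DataFrame(rows).to_csv(config.out_path("populations.tsv"), sep="\t", index=False,
                              float_format="%.6f")
    _write_json(config.out_path("populations.json"), report)
    return report


def run_fep(config: PipelineConfig) -> dict:
    """Network diagnostics and reference-anchored ΔpKd per restraint level.

    Writes ``fep.json`` and ``fep_dpkd.tsv`` (ligand x force-constant table).
    """
    table_path = config.study_path(config.fep_edge_table)
    if not table_path.exists():
        raise FileNotFoundError(f"edge table not found: {table_path}")
    edges = fep_network.read_edge_table(table_path)
    levels = sorted({e.force_constant for e in edges})
    report: dict = {"levels": {}, "config": asdict(config)}
    dpkd_tables: dict[float, dict[str, float]] = {}
    for fc in levels:
        net = fep_network.build_network(edges, reference=config.reference_ligand, force_constant=fc)
        closure = fep_network.cycle_closure(net)
        hyst = [
            h for e in edges
            if e.force_constant == fc and (h := fep_network.edge_hysteresis(e)) is not None
        ]
        dpkd = fep_network.relative_dpkd(net, temperature=config.temperature)
        dpkd_tables[fc] = dpkd
        report["levels"][str(fc)] = {
            "n_edges": sum(1 for e in edges if e.force_constant == fc),
            "rms_cycle_closure_kcal_mol": round(closure["rms_closure_kcal_mol"], 6),
            "rms_hysteresis_kcal_mol": round(float(np.sqrt(np.mean(np.square(hyst)))), 6)
            if hyst else None,
            "dpkd_vs_reference": {lig: round(v, 6) for lig, v in sorted(dpkd.items())},
        }
    if len(dpkd_tables) >= 2:
        sens = fep_network.restraint_sensitivity(dpkd_tables)
        report["restraint_sensitivity"] = {
            row["ligand_id"]: {"spread": round(row["spread"], 6), "flagged": bool(row["flagged"])}
            for _, row in sens.iterrows()
        }
    ligands = sorted({lig for t in dpkd_tables.values() for lig in t})
    pd.DataFrame(
        [
            {"ligand_id": lig, **{f"fc_{fc}": dpkd_tables[fc].get(lig) for fc in levels}}
            for lig in ligands
        ]
    ).to_csv(config.out_path("fep_dpkd.tsv"), sep="\t", index=False, float_format="%.6f")
    _write_json(config.out_path("fep.json"), report)
    return report


def run_dissect(config: PipelineConfig) -> dict:
    """Per-ligand dissection of the affinity difference to the reference
    ligand into direct (restrained-network) and conformational (population)
    terms.  Requires ``run_populations`` and ``run_fep`` reports.
    """
    pop_path = config.out_path("populations.json")
    fep_path = config.out_path("fep.json")
    for p, stage in ((pop_path, "populations"), (fep_path, "fep")):
        if not p.exists():
            raise FileNotFoundError(f"missing {stage} report {p}; run that stage first")
    pops = json.loads(pop_path.read_text())["ligands"]
    fep = json.loads(fep_path.read_text())["levels"]
    # direct term: mean over restraint levels of the network estimate
    direct: dict[str, list[float]] = {}
    for level in fep.values():
        for lig, v in level["dpkd_vs_reference"].items():
            direct.setdefault(lig, []).append(v)
    ref = config.reference_ligand
    if ref not in pops:
        raise ValueError(f"reference ligand {ref!r} has no population estimate")
    common = sorted(set(direct) & set(pops) - {ref})
    if not common:
        raise ValueError("no ligand appears in both the network and the population report")
    rows = []
    report: dict = {"reference_ligand": ref, "pairs": {}, "config": asdict(config)}
    for lig in common:
        conf = thermo.conformational_dpkd(pops[lig]["p1"], pops[ref]["p1"])
        res = thermo.dissect(float(np.mean(direct[lig])), conf, ligand_pair=(lig, ref))
        rows.append(
            {
                "ligand_id": lig,
                "dpkd_direct": res.dpkd_direct,
                "dpkd_conformational": res.dpkd_conformational,
                "dpkd_total": res.dpkd_total,
                "fraction_conformational": res.fraction_conformational,
            }
        )
        report["pairs"][f"{lig}/{ref}"] = {
            "dpkd_direct": round(res.dpkd_direct, 6),
            "dpkd_conformational": round(res.dpkd_conformational, 6),
            "dpkd_total": round(res.dpkd_total, 6),
            "fraction_conformational": None
            if res.fraction_conformational is None
            else round(res.fraction_conformational, 6),
        }
    pd.DataFrame(rows).to_csv(config.out_path("dissect.tsv"), sep="\t", index=False,
                              float_format="%.6f")
    _write_json(config.out_path("dissect.json"), report)
    return report


def run_lipo(config: PipelineConfig) -> dict:
    """Dynamic PSA/NPSA per ligand, correlations with measured logD and, when
    at least four ligands carry logD, the multi-linear logD model."""
    import warnings as _warnings

    ensembles = _load_ensembles(config)
    rows = []
    for ens in ensembles:
        classes = ensemble_io.assign_atom_classes(ens)
        stride = max(1, config.sasa_frame_stride)
        surf = surfaces.ensemble_surface(
            ens, classes,
            probe_radius=config.probe_radius,
            n_points=config.n_points,
            n_blocks=config.n_blocks,
            frame_indices=np.arange(0, ens.n_frames, stride),
        )
        rows.append(
            {
                "ligand_id": ens.ligand_id,
                "mean_psa": surf.mean_psa,
                "mean_npsa": surf.mean_npsa,
                "mean_total": surf.mean_total,
                "sigma_psa": surf.sigma_psa,
                "sigma_npsa": surf.sigma_npsa,
            }
        )
    surf_df = pd.DataFrame(rows)
    report: dict = {
        "surfaces": {
            r["ligand_id"]: {k: round(v, 4) for k, v in r.items() if k != "ligand_id"}
            for r in rows
        },
        "config": asdict(config),
    }
    aff_path = config.study_path(config.affinity_table)
    if aff_path.exists():
        aff = pd.read_csv(aff_path, sep="\t", dtype={"ligand_id": str})
        merged = surf_df.merge(aff[["ligand_id", "logD"]].dropna(), on="ligand_id")
        if len(merged) >= 3:
            report["pearson_psa_logd"] = round(
                lipophilicity.pearson(merged["mean_psa"], merged["logD"]), 6
            )
            report["pearson_npsa_logd"] = round(
                lipophilicity.pearson(merged["mean_npsa"], merged["logD"]), 6
            )
        if len(merged) >= 4:
            model = lipophilicity.fit_logd_model(
                merged["mean_psa"], merged["mean_npsa"], merged["logD"],
                descriptor_scale="angstrom^2",
            )
            pred = lipophilicity.predict_logd(model, merged["mean_psa"], merged["mean_npsa"])
            report["model"] = {
                "coef_npsa": round(model.coef_npsa, 8),
                "coef_psa": round(model.coef_psa, 8),
                "intercept": round(model.intercept, 8),
                "pearson_r_fit": None
                if model.pearson_r_fit is None
                else round(model.pearson_r_fit, 6),
                "n": model.n,
            }
            report["predicted_logd"] = {
                lig: round(v, 6) for lig, v in zip(merged["ligand_id"], pred)
            }
        else:
            _warnings.warn("fewer than 4 ligands with logD; regression skipped", stacklevel=2)
    surf_df.to_csv(config.out_path("surfaces.tsv"), sep="\t", index=False, float_format="%.6f")
    _write_json(config.out_path("lipo.json"), report)
    return report


def run_report(config: PipelineConfig) -> dict:
    """Aggregate all stage reports present in the output directory into one
    ``report.json``."""
    combined: dict = {"config": asdict(config)}
    for stage in ("populations", "fep", "dissect", "lipo"):
        path = config.out_path(f"{stage}.json")
        if path.exists():
            payload = json.loads(path.read_text())
            payload.pop("config", None)
            combined[stage] = payload
    _write_json(config.out_path("report.json"), combined)
    return combined
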