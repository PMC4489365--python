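"""End-to-end comparison of two systems: ensembles → clustering →
per-representative mDCM → native-basin QSFR at T_m → Z-score report.

The two systems are either synthetic recipes (:class:`SyntheticSystemSpec`)
or multi-model PDB ensembles on disk.  Model parameters are fitted once on
the top-weighted representative of system A (against a target heat-capacity
curve or melting temperature, when given) and shared across representatives
and systems, mirroring the protocol of holding {u_sol, v_nat, delta_nat}
fixed within a structurally similar pair; per-representative refitting is
available as an option.  All randomness derives from one master seed, so a
rerun with the same configuration reproduces every table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import (
    classify_changes,
    delta_cc,
    flexibility_vs_mobility,
    hbond_count_difference,
    zscore,
)
from .constraint_network import HBondCriteria, hbond_propensity
from .ensemble_reduction import (
    pairwise_rmsd_matrix,
    centroid_cluster,
    select_representatives,
    tune_radius,
)
from .qsfr_metrics import (
    cooperativity_correlation,
    flexibility_index,
    structure_weighted_average,
)
from .structure_io import ConformationEnsemble, compute_rmsf, read_ensemble, write_ensemble
from .synthetic import SyntheticSystemSpec, build_peptide, perturb_ensemble
from .thermo import (
    ConstraintInventory,
    DCMParameters,
    HeatCapacityCurve,
    fit_parameters,
    free_energy_landscape,
    heat_capacity_curve,
    native_basin,
    sample_grid,
)


@dataclass
class PipelineConfig:
    """Everything one comparison run needs; YAML-loadable."""

    system_a: SyntheticSystemSpec | str
    system_b: SyntheticSystemSpec | str
    n_representatives: int = 10
    n_samples: int = 200
    stride: tuple[int, int] = (1, 1)
    target_clusters: int = 20
    thresholds: tuple[float, float] = (2.33, 3.33)
    t_range: tuple[float, float] = (250.0, 450.0)
    target_tm: float | None = None
    target_curve: str | None = None
    region_masks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    seed: int = 0
    initial_params: DCMParameters = field(default_factory=DCMParameters)
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    refit_per_representative: bool = False
    max_frames: int = 2000

    def __post_init__(self) -> None:
        lo, hi = self.thresholds
        if not 0 < lo < hi:
            raise ValueError("thresholds must be positive and ordered")
        if self.n_representatives < 1:
            raise ValueError("n_representatives must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("system_a", "system_b"):
            val = raw[key]
            if isinstance(val, dict):
                raw[key] = SyntheticSystemSpec(**{
                    **val,
                    "hbond_edits": [
                        __import__("qsfr.synthetic", fromlist=["HBondEdit"]).HBondEdit(
                            action=e["action"],
                            donor=(int(e["donor"][0]), str(e["donor"][1])),
                            acceptor=(int(e["acceptor"][0]), str(e["acceptor"][1])),
                            propensity=float(e.get("propensity", 1.0)),
                            schedule=e.get("schedule", "random"),
                        )
                        for e in val.get("hbond_edits", [])
                    ],
                })
        if "initial_params" in raw:
            raw["initial_params"] = DCMParameters(**raw["initial_params"])
        if "criteria" in raw:
            raw["criteria"] = HBondCriteria(**raw["criteria"])
        for key in ("stride", "thresholds", "t_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SystemResult:
    ensemble: ConformationEnsemble
    representatives: list
    rep_weights: np.ndarray
    coverage: float
    propensity: object
    rmsf: pd.DataFrame
    fi_per_rep: list[np.ndarray]        # per-residue FI, one array per representative
    cc_per_rep: list[np.ndarray]
    residue_index: np.ndarray


@dataclass
class PipelineResult:
    config: PipelineConfig
    params: DCMParameters
    t_m: float
    system_a: SystemResult
    system_b: SystemResult
    z: np.ndarray
    classes: np.ndarray
    class_counts: dict
    delta_hbond: pd.Series
    delta_hbond_summary: dict
    delta_cc_z: np.ndarray
    mobility_table: pd.DataFrame
    mobility_rho: float
    mobility_p: float


def _load_ensemble(source, max_frames: int) -> ConformationEnsemble:
    if isinstance(source, SyntheticSystemSpec):
        ens = perturb_ensemble(build_peptide(source), source)
    else:
        ens = read_ensemble(source)
    if len(ens) > max_frames:
        idx = np.linspace(0, len(ens) - 1, max_frames).astype(int)
        ens = ConformationEnsemble(ens.template, ens.coords[idx])
    return ens


def _analyse_system(
    ens: ConformationEnsemble, config: PipelineConfig, sys_idx: int,
    params: DCMParameters, t_m: float,
) -> SystemResult:
    matrix = pairwise_rmsd_matrix(ens)
    target = min(config.target_clusters, len(ens))
    radius = tune_radius(matrix, target_clusters=target)
    assignment = centroid_cluster(matrix, radius)
    reps = select_representatives(assignment, ens, k=config.n_representatives)
    prop = hbond_propensity(ens, config.criteria)
    rmsf = compute_rmsf(ens)

    fi_per_rep, cc_per_rep, residue_index = [], [], None
    for r, structure in enumerate(reps.structures):
        inv = ConstraintInventory.from_conformation(structure, config.criteria, params)
        grid = sample_grid(
            inv, params=params, n_samples=config.n_samples,
            seed=config.seed * 10_000 + sys_idx * 1_000 + r,
            stride=config.stride, collect_mech=True,
        )
        use_params = params
        if config.refit_per_representative and (config.target_tm or config.target_curve):
            use_params = _fit_for_grid(grid, config).params
        landscape = free_energy_landscape(grid, use_params, t_m)
        basin = native_basin(landscape)
        fi = flexibility_index(grid, basin)
        cc = cooperativity_correlation(grid, basin)
        fi_per_rep.append(fi.residue_values)
        cc_per_rep.append(cc.matrix)
        residue_index = fi.residue_index
    return SystemResult(
        ensemble=ens, representatives=reps.structures, rep_weights=reps.weights,
        coverage=reps.coverage, propensity=prop, rmsf=rmsf,
        fi_per_rep=fi_per_rep, cc_per_rep=cc_per_rep, residue_index=residue_index,
    )


def _fit_for_grid(grid, config: PipelineConfig):
    if config.target_curve:
        df = pd.read_csv(config.target_curve, sep="\t")
        target = HeatCapacityCurve(
            temperature=df.iloc[:, 0].to_numpy(), cp=df.iloc[:, 1].to_numpy()
        )
    else:
        target = float(config.target_tm)
    return fit_parameters(grid, target, initial=config.initial_params, t_range=config.t_range)


logger = logging.getLogger("qsfr.pipeline")


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute the full comparison; optionally persist artifacts to ``outdir``."""
    timings: dict[str, float] = {}
    t0 = time.time()
    logger.info("loading/generating ensembles")
    ens_a = _load_ensemble(config.system_a, config.max_frames)
    ens_b = _load_ensemble(config.system_b, config.max_frames)
    timings["ensembles"] = time.time() - t0

    # fit once on the top-weighted representative of system A
    t0 = time.time()
    logger.info("fitting model parameters on the top representative of system A")
    matrix = pairwise_rmsd_matrix(ens_a)
    radius = tune_radius(matrix, target_clusters=min(config.target_clusters, len(ens_a)))
    reps_a = select_representatives(centroid_cluster(matrix, radius), ens_a, k=config.n_representatives)
    inv0 = ConstraintInventory.from_conformation(
        reps_a.structures[0], config.criteria, config.initial_params
    )
    grid0 = sample_grid(
        inv0, params=config.initial_params, n_samples=config.n_samples,
        seed=config.seed * 10_000 + 9_999, stride=config.stride, collect_mech=False,
    )
    if config.target_tm is not None or config.target_curve:
        fit = _fit_for_grid(grid0, config)
        params = fit.params
        t_m = fit.t_m
    else:
        params = config.initial_params
        t_m = heat_capacity_curve(grid0, params, t_range=config.t_range).t_m
    timings["fit"] = time.time() - t0

    t0 = time.time()
    logger.info("per-representative QSFR at T_m = %.1f K", t_m)
    sys_a = _analyse_system(ens_a, config, 0, params, t_m)
    sys_b = _analyse_system(ens_b, config, 1, params, t_m)
    timings["qsfr"] = time.time() - t0

    if not np.array_equal(sys_a.residue_index, sys_b.residue_index):
        raise ValueError("systems do not share residue indexing; cannot compare")

    t0 = time.time()
    logger.info("comparative statistics")
    prof = zscore(
        np.stack(sys_b.fi_per_rep), np.stack(sys_a.fi_per_rep),
        sys_b.rep_weights, sys_a.rep_weights, n=config.n_representatives,
    )
    masks = {
        name: _interval_mask(sys_a.residue_index, spans)
        for name, spans in config.region_masks.items()
    }
    classes, counts = classify_changes(prof.z, config.thresholds, masks or None)
    dhb, dhb_summary = hbond_count_difference(sys_a.propensity, sys_b.propensity)
    dcc = delta_cc(
        sys_a.cc_per_rep, sys_b.cc_per_rep, sys_a.rep_weights, sys_b.rep_weights,
        n=config.n_representatives,
    )
    rmsf_a = sys_a.rmsf.set_index("residue_index")["rmsf"].reindex(sys_a.residue_index).to_numpy()
    rmsf_b = sys_b.rmsf.set_index("residue_index")["rmsf"].reindex(sys_b.residue_index).to_numpy()
    mob_table, rho, pval = flexibility_vs_mobility(
        prof.z, rmsf_a, rmsf_b, seed=config.seed
    )
    timings["compare"] = time.time() - t0

    result = PipelineResult(
        config=config, params=params, t_m=t_m,
        system_a=sys_a, system_b=sys_b,
        z=prof.z, classes=classes, class_counts=counts,
        delta_hbond=dhb, delta_hbond_summary=dhb_summary,
        delta_cc_z=dcc, mobility_table=mob_table,
        mobility_rho=rho, mobility_p=pval,
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir), timings)
    return result


def _interval_mask(residue_index: np.ndarray, spans) -> np.ndarray:
    mask = np.zeros(residue_index.shape, bool)
    for lo, hi in spans:
        mask |= (residue_index >= lo) & (residue_index <= hi)
    return mask


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_artifacts(result: PipelineResult, outdir: Path, timings: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files = []

    def save_df(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        files.append(name)

    for tag, sysres in (("a", result.system_a), ("b", result.system_b)):
        reps = ConformationEnsemble(
            sysres.representatives[0],
            np.stack([c.coords for c in sysres.representatives]),
        )
        rep_path = outdir / f"system_{tag}_representatives.pdb"
        write_ensemble(reps, rep_path)
        files.append(rep_path.name)
        (outdir / f"system_{tag}_weights.json").write_text(
            json.dumps({"weights": sysres.rep_weights.tolist(),
                        "coverage": sysres.coverage}, indent=1)
        )
        files.append(f"system_{tag}_weights.json")
        pair_df, res_df = sysres.propensity.to_frames()
        save_df(pair_df, f"system_{tag}_propensity_pairs.tsv")
        save_df(res_df, f"system_{tag}_propensity_residues.tsv")
        save_df(sysres.rmsf, f"system_{tag}_rmsf.tsv")
        fi_mean, fi_sd = structure_weighted_average(sysres.fi_per_rep, sysres.rep_weights)
        save_df(
            pd.DataFrame({"residue_index": sysres.residue_index,
                          "fi_mean": fi_mean, "fi_sd": fi_sd}),
            f"system_{tag}_fi.tsv",
        )

    save_df(
        pd.DataFrame({
            "residue_index": result.system_a.residue_index,
            "z": result.z, "class": result.classes,
        }),
        "zscore.tsv",
    )
    save_df(pd.DataFrame(result.delta_cc_z), "delta_cc_z.tsv")
    save_df(result.delta_hbond.rename_axis("residue_index").reset_index(), "delta_hbond.tsv")
    save_df(result.mobility_table.assign(residue_index=result.system_a.residue_index),
            "flexibility_vs_mobility.tsv")
    (outdir / "params.json").write_text(
        json.dumps(dataclasses.asdict(result.params) | {"t_m": result.t_m}, indent=1)
    )
    files.append("params.json")
    summary = {
        "t_m": result.t_m,
        "class_counts": result.class_counts,
        "delta_hbond_summary": result.delta_hbond_summary,
        "mobility_rank_correlation": None if np.isnan(result.mobility_rho) else result.mobility_rho,
        "mobility_permutation_p": None if np.isnan(result.mobility_p) else result.mobility_p,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    files.append("summary.json")
    manifest = {
        "version": __version__,
        "seed": result.config.seed,
        "n_representatives": result.config.n_representatives,
        "n_samples": result.config.n_samples,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "artifacts": {name: _sha256(outdir / name) for name in sorted(set(files))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
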