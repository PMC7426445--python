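"""End-to-end comparative workflow and its machine-readable report.

``run_compare`` chains the whole analysis for one ensemble or a
naïve/matured-style pair: common-frame alignment, 2D-RMSD and cluster counts
of the analyzed loop, RMSF/B-factors, occupancy mean/SD grids, Gaussian
smoothing, global and localized plasticity, difference grids, and (optionally)
the ψ-torsion tICA → k-means → Markov-state-model kinetics.  Every numeric
result, parameter and output file lands in a JSON report; logs carry no
numbers that are not also in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, flexibility, io_formats, msm, plasticity, superpose
from .io_formats import Ensemble, read_pdb_ensemble, residue_key_str

logger = logging.getLogger("voxflex")


@dataclass
class RunConfig:
    """Configuration for a comparison run; defaults mirror the standard protocol
    (clustering cutoff 1.2 Å, 150 microstates, lag in frames)."""

    inputs: list[str] = field(default_factory=list)   # one or two PDB paths
    labels: list[str] = field(default_factory=lambda: ["naive", "matured"])
    loop_selection: str = "chain H resid 95-102 name CA"
    fit_selection: str = "chain S name CA"
    cluster_cutoff: float = 1.2
    cluster_sweep: list[float] = field(default_factory=lambda: [0.8, 1.0, 1.2, 1.4, 1.6])
    grid_spacing: float = 1.0
    grid_padding: float = 4.0
    smoothing_sigma: float = 1.5
    plasticity_threshold: float = 0.05
    localize_max_dist: float = 4.0
    probe_radius: float = 0.0
    include_hydrogens: bool = False
    run_msm: bool = False
    msm_lag: int = 1
    n_microstates: int = 150
    n_macrostates: int = 2
    seed: int = 0
    output_dir: str = "voxflex_out"

    def validate(self) -> None:
        if not 1 <= len(self.inputs) <= 2:
            raise ValueError("provide one or two input ensembles")
        for name, value in [
            ("cluster_cutoff", self.cluster_cutoff),
            ("grid_spacing", self.grid_spacing),
            ("smoothing_sigma", self.smoothing_sigma),
            ("msm_lag", self.msm_lag),
            ("n_microstates", self.n_microstates),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _analyze_single(ensemble: Ensemble, label: str, config: RunConfig, outdir: Path) -> dict:
    loop = config.loop_selection
    result: dict = {"label": label, "n_frames": ensemble.n_frames}

    matrix = flexibility.rmsd_matrix(ensemble, loop, fit=True)
    cluster = clustering.average_linkage_cluster(matrix, config.cluster_cutoff)
    sweep = clustering.cluster_count_sweep(matrix, config.cluster_sweep)
    profile = flexibility.rmsf(ensemble, loop)

    result["n_clusters"] = cluster.n_clusters
    result["cluster_sweep"] = sweep.to_dict(orient="records")
    result["loop_rmsf_mean"] = float(profile.rmsf.mean())
    result["loop_rmsf_max"] = float(profile.rmsf.max())
    result["loop_bfactor_mean"] = float(profile.bfactor.mean())

    matrix_path = outdir / f"{label}_2drmsd.csv"
    pd.DataFrame(
        matrix.values, index=ensemble.frame_ids, columns=ensemble.frame_ids
    ).to_csv(matrix_path)
    rmsf_path = outdir / f"{label}_rmsf.csv"
    pd.DataFrame(
        {
            "atom_serial": [ensemble.topology.atoms[i].serial for i in profile.selection.indices],
            "residue": [
                residue_key_str(
                    (ensemble.topology.atoms[i].chain_id, ensemble.topology.atoms[i].residue_seq)
                )
                for i in profile.selection.indices
            ],
            "rmsf_A": profile.rmsf,
            "bfactor_A2": profile.bfactor,
        }
    ).to_csv(rmsf_path, index=False)
    result["files"] = {"rmsd_matrix": str(matrix_path), "rmsf": str(rmsf_path)}
    return result


def run_compare(config: RunConfig, ensembles: list[Ensemble] | None = None) -> dict:
    """Execute the full comparative workflow and return the JSON-able report.

    ``ensembles`` may be supplied directly (e.g. synthetic pairs); otherwise
    they are read from ``config.inputs``.  Stage failures are recorded in the
    report with a FAILED marker and re-raised.
    """
    if ensembles is None:
        config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if ensembles is None:
        ensembles = [read_pdb_ensemble(p) for p in config.inputs]
    labels = list(config.labels[: len(ensembles)])
    while len(labels) < len(ensembles):
        labels.append(f"ensemble{len(labels)}")

    report: dict = {"config": config.to_dict(), "stages": {}, "files": {}}
    stage = "align"
    try:
        if len(ensembles) == 2:
            a, b = superpose.pair_align(ensembles[0], ensembles[1], config.fit_selection)
            aligned = [a, b]
        else:
            aligned = [
                superpose.align_ensemble(ensembles[0], config.fit_selection, reference="mean")
            ]

        stage = "flexibility"
        per_label = [
            _analyze_single(ens, lab, config, outdir)
            for ens, lab in zip(aligned, labels)
        ]
        report["stages"]["per_ensemble"] = per_label

        stage = "plasticity"
        grid_selection = "heavy" if not config.include_hydrogens else None
        spec = plasticity.make_grid_spec(
            aligned, spacing=config.grid_spacing, padding=config.grid_padding
        )
        sd_smoothed_grids = []
        for ens, lab, res in zip(aligned, labels, per_label):
            mean_g, sd_g = plasticity.occupancy_stats(
                ens, spec, selection=grid_selection or "heavy", probe=config.probe_radius
            )
            mean_s = plasticity.gauss_filter(mean_g, config.smoothing_sigma)
            sd_s = plasticity.gauss_filter(sd_g, config.smoothing_sigma)
            sd_smoothed_grids.append(sd_s)
            res["global_plasticity_A3"] = plasticity.global_plasticity(
                sd_s, config.plasticity_threshold
            )
            profile = plasticity.localize_plasticity(
                sd_s,
                ens.topology,
                superpose.mean_structure(ens),
                max_dist=config.localize_max_dist,
                threshold=config.plasticity_threshold,
                sigma_used=config.smoothing_sigma,
            )
            loop_keys = [
                k for k in profile.per_residue if k[0] == "H"
            ]
            res["loop_plasticity_A3"] = float(
                sum(profile.per_residue[k] for k in loop_keys)
            )
            for kind, g in [("mean", mean_s), ("sd", sd_s)]:
                path = outdir / f"{lab}_{kind}_smoothed.dx"
                io_formats.write_dx_grid(g, path)
                res.setdefault("files", {})[f"{kind}_grid"] = str(path)
            prof_path = outdir / f"{lab}_plasticity.csv"
            pd.DataFrame(
                {
                    "residue": [residue_key_str(k) for k in profile.per_residue],
                    "plasticity_A3": list(profile.per_residue.values()),
                }
            ).to_csv(prof_path, index=False)
            res["files"]["plasticity_profile"] = str(prof_path)
            bf_path = outdir / f"{lab}_plasticity_bfactor.pdb"
            io_formats.write_bfactor_pdb(ens, 0, profile.per_residue, bf_path)
            res["files"]["plasticity_pdb"] = str(bf_path)

        if len(aligned) == 2:
            stage = "difference"
            diff = plasticity.plasticity_difference(sd_smoothed_grids[0], sd_smoothed_grids[1])
            diff_path = outdir / "plasticity_difference.dx"
            io_formats.write_dx_grid(diff, diff_path)
            report["files"]["difference_grid"] = str(diff_path)
            report["stages"]["difference"] = {
                "positive_sum": float(diff.values[diff.values > 0].sum()),
                "negative_sum": float(diff.values[diff.values < 0].sum()),
            }

        if config.run_msm:
            stage = "msm"
            msm_results = []
            for ens, lab in zip(aligned, labels):
                feats = flexibility.psi_features(ens, config.loop_selection.split(" name")[0])
                model_t = msm.tica(feats.features, lag=config.msm_lag)
                n_micro = min(config.n_microstates, ens.n_frames)
                labels_micro = msm.kmeans_microstates(
                    model_t.projected[:, :2], n_states=n_micro, seed=config.seed
                )
                model = msm.estimate_msm(labels_micro, lag=config.msm_lag)
                model = msm.pcca_macrostates(
                    model, min(config.n_macrostates, model.n_states), seed=config.seed
                )
                msm_results.append(
                    {
                        "label": lab,
                        "n_microstates": int(model.n_states),
                        "frame_fraction": model.frame_fraction,
                        "t2_frames": float(model.timescales[0])
                        if len(model.timescales) and np.isfinite(model.timescales[0])
                        else None,
                        "macro_populations": [float(x) for x in model.macro_populations],
                    }
                )
            report["stages"]["msm"] = msm_results

        stage = "report"
        if len(aligned) == 2:
            n0, n1 = per_label[0], per_label[1]
            report["comparison"] = {
                "cluster_count": {labels[0]: n0["n_clusters"], labels[1]: n1["n_clusters"]},
                "global_plasticity_A3": {
                    labels[0]: n0["global_plasticity_A3"],
                    labels[1]: n1["global_plasticity_A3"],
                },
                "loop_rmsf_mean_A": {
                    labels[0]: n0["loop_rmsf_mean"],
                    labels[1]: n1["loop_rmsf_mean"],
                },
            }
    except Exception as exc:
        report["stages"]["FAILED"] = {"stage": stage, "error": str(exc)}
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, default=str))
        raise

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str))
    report["files"]["report"] = str(report_path)
    return report
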