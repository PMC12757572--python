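"""Pipeline orchestration: prepare → fit → moments → mutations → ml.

A run is described by a :class:`RunConfig` (YAML-loadable).  Stages write
TSV outputs into the run directory and record themselves in a JSON manifest
keyed by a content hash of their configuration and inputs, so a rerun with
unchanged inputs skips cached stages.  Per-pore-point computations are
independent of execution order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hydropathy import (coupling_and_susceptibility, decompose, log_slopes,
                         moments, scaling_exponents)
from .ml_classify import (assemble_features, feature_importances,
                          feature_subset, global_model, local_cv,
                          make_experiment, summarize_by_median)
from .mutations import clustering_stats, entropy_midpoint, load_mutations
from .packing_model import (FitConfig, fit_packing,
                            intrinsic_dimension, packing_entropy)
from .pore_geometry import build_pore_path, build_scale_grid, radial_profile
from .structure_io import (assign_hydropathy, orient_structure,
                           read_structure, write_structure)
from .synthetic import GeneratorConfig, sample_structure, write_truth

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Defaults follow the reference protocol: 0.1 Å pore-point spacing, 800
    scale indices, moment orders k = 0..5, weight noise σ_ι = 1e-3, and 200
    permutation rounds.
    """
    structure_path: str = ""
    mutations_path: str = ""
    output_dir: str = "porescale_run"
    # pore path
    z_min: float = -10.0
    z_max: float = 10.0
    spacing: float = 0.1
    slab_half: float = 5.0
    # scale grid / fitting
    n_alpha: int = 800
    # moments
    orders_k: int = 6          # k = 0..orders_k-1
    sigma_iota: float = 1e-3
    smooth_window: int = 5
    # ml
    experiment: str = "I"
    feature_set: str = "all"   # all | inertia | conductivity
    use_absolute: bool = False
    k_folds: int = 5
    bootstrap_rounds: int = 1000
    permutation_rounds: int = 200
    run_local_cv: bool = False
    run_importances: bool = False
    # orientation / misc
    orient_mode: str = "as-is"
    keep_het: bool = False
    chain_whitelist: list | None = None
    seed: int = 0
    write_traces: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """JSON run manifest tracking stage hashes and output integrity."""

    def __init__(self, path: Path):
        self.path = path
        self.data = {"version": __version__, "stages": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def is_cached(self, stage: str, key: str) -> bool:
        """A stage is cached when its key matches and no output is missing
        or corrupted (content hash mismatch)."""
        rec = self.data["stages"].get(stage)
        if rec is None or rec.get("key") != key:
            return False
        for out, digest in rec.get("outputs", {}).items():
            if not Path(out).exists() or _file_hash(Path(out)) != digest:
                return False
        return True

    def record(self, stage: str, key: str, outputs, extra=None) -> None:
        self.data["stages"][stage] = {
            "key": key,
            "outputs": {str(o): _file_hash(Path(o)) for o in outputs},
            "extra": extra,
            "time": time.strftime("%Y-%m-%dT%H:%M:%S")}
        self.path.write_text(json.dumps(self.data, indent=2))

    def extra(self, stage: str):
        return self.data["stages"].get(stage, {}).get("extra")


def simulate(config: GeneratorConfig, out_dir) -> tuple:
    """Generate a synthetic structure (PDB + truth JSON) in ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    structure, truth = sample_structure(config)
    pdb_path = out_dir / "synthetic.pdb"
    write_structure(structure, pdb_path)
    write_truth(truth, out_dir / "synthetic_truth.json")
    return pdb_path, truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of output paths and summaries.

    Raises with the stage name (and pore-point index where relevant) on
    failure; stages with unchanged inputs are skipped via the manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out / "manifest.json")
    cfg_hash = config.content_hash()

    struct_path = Path(config.structure_path)
    if not struct_path.exists():
        raise FileNotFoundError(f"stage prepare: structure file "
                                f"{struct_path} not found")
    run_key = f"{cfg_hash}:{_file_hash(struct_path)}"
    if config.mutations_path:
        run_key += f":{_file_hash(Path(config.mutations_path))}"
    if manifest.is_cached("pipeline", run_key):
        cached = dict(manifest.extra("pipeline") or {})
        cached["cached_stages"] = ["prepare", "fit", "moments",
                                   "mutations", "ml"]
        log.info("all stages cached; skipping")
        return cached

    results = {"output_dir": str(out), "cached_stages": []}

    # ---- prepare ------------------------------------------------------
    clean_path = out / "prepared.pdb"
    try:
        structure = read_structure(struct_path.read_text(),
                                   keep_het=config.keep_het,
                                   chain_whitelist=config.chain_whitelist)
        structure, coverage = assign_hydropathy(structure)
        structure = orient_structure(structure, mode=config.orient_mode)
        write_structure(structure, clean_path)
        manifest.record("prepare", run_key, [clean_path])
        results["n_atoms"] = structure.n_total
        results["hydropathy_coverage"] = coverage.coverage
    except Exception as exc:
        raise RuntimeError(f"stage prepare failed: {exc}") from exc

    # ---- pore path + per-point fits ----------------------------------
    fits_path = out / "fits.tsv"
    path = build_pore_path(structure, config.z_min, config.z_max,
                           config.spacing, config.slab_half)
    profiles, grids, fits = [], [], []
    fit_rows = []
    for idx, p in enumerate(path.points):
        try:
            prof = radial_profile(structure, p)
            grid = build_scale_grid(prof, config.n_alpha)
            fit = fit_packing(prof, grid,
                              FitConfig(seed=config.seed))
            profiles.append(prof)
            grids.append(grid)
            fits.append(fit)
        except Exception as exc:
            raise RuntimeError(
                f"stage fit failed at pore point {idx}: {exc}") from exc
        if fit.converged:
            ent = packing_entropy(fit, grid)
            l_emp, l_theo = entropy_midpoint(prof, fit, grid)
            d_f = float(intrinsic_dimension(fit.params, fit.l_i, fit.l_i))
            fit_rows.append({
                "pore_index": idx, "p_z": p[2],
                "R_bar": prof.r_bar, "L": prof.outer_radius,
                "s": prof.radial_size,
                "zeta": fit.params.zeta, "xi": fit.params.xi,
                "K": fit.params.capacity, "nu": fit.params.nu,
                "q": fit.params.q, "l_i": fit.l_i, "l_ib": fit.l_ib,
                "l_gt": fit.l_gt, "eps_i": fit.eps_i, "d_f_at_li": d_f,
                "S": ent.S, "S_max": ent.S_max, "Xi": ent.Xi,
                "l_star_emp": l_emp, "l_star_theo": l_theo,
                "mae": fit.mae, "converged": True})
        else:
            fit_rows.append({"pore_index": idx, "p_z": p[2],
                             "mae": np.inf, "converged": False})
    pd.DataFrame(fit_rows).to_csv(fits_path, sep="\t", index=False)
    manifest.record("fit", run_key, [fits_path])
    results["fits"] = str(fits_path)

    # ---- moments ------------------------------------------------------
    exps_path = out / "exponents.tsv"
    moment_sets = {}
    exp_rows = []
    for idx, (p, prof, grid, fit) in enumerate(
            zip(path.points, profiles, grids, fits)):
        if not fit.converged:
            continue
        try:
            mset = moments(structure, p, grid,
                           orders_k=range(config.orders_k),
                           sigma_iota=config.sigma_iota, seed=config.seed)
            decompose(mset)
            for j, prof_j in mset.profiles.items():
                if prof_j.decomposable:
                    log_slopes(prof_j, grid, config.smooth_window)
                    coupling_and_susceptibility(prof_j, grid)
                trace = np.abs(prof_j.trace)
                se = scaling_exponents(trace, fit, grid)
                exp_rows.append({
                    "pore_index": idx, "j": j,
                    "eta_lt": se.eta_lt, "eta_gt": se.eta_gt,
                    "pearson_lt": se.pearson_lt,
                    "pearson_gt": se.pearson_gt,
                    "case": prof_j.case_label,
                    "l_cutoff": prof_j.l_cutoff})
            moment_sets[idx] = mset
        except Exception as exc:
            raise RuntimeError(
                f"stage moments failed at pore point {idx}: {exc}") from exc
    pd.DataFrame(exp_rows).to_csv(exps_path, sep="\t", index=False)
    manifest.record("moments", run_key, [exps_path])
    results["exponents"] = str(exps_path)
    if config.write_traces:
        traces_path = out / "traces.tsv"
        _write_traces(moment_sets, traces_path)
        results["traces"] = str(traces_path)

    # ---- mutations ----------------------------------------------------
    if config.mutations_path:
        mut_path = Path(config.mutations_path)
        try:
            muts = load_mutations(str(mut_path), structure)
            summary = clustering_stats(muts, fits, path.points)
            clus_path = out / "clustering.tsv"
            summary.per_pore.to_csv(clus_path, sep="\t", index=False)
            results["clustering"] = str(clus_path)
            results["collapsed_normal"] = (summary.collapsed_mean,
                                           summary.collapsed_sd)
        except Exception as exc:
            raise RuntimeError(f"stage mutations failed: {exc}") from exc

        # ---- ml -------------------------------------------------------
        try:
            table = assemble_features(moment_sets, path.points, muts,
                                      orders_k=range(config.orders_k),
                                      use_absolute=config.use_absolute)
            df = make_experiment(table, config.experiment)
            cols = feature_subset(table.feature_cols, config.feature_set)
            if config.run_local_cv:
                local_rows = []
                for idx, df_point in df.groupby("pore_index"):
                    res = local_cv(df_point, cols, config.k_folds,
                                   config.seed)
                    if res is not None:
                        local_rows.append({
                            "pore_index": idx, "auc": res.auc,
                            "auc_test_median": np.median(res.auc_test),
                            "f1_test_median": np.median(res.f1_test)})
                pd.DataFrame(local_rows).to_csv(out / "local_scores.tsv",
                                                sep="\t", index=False)
                results["local_scores"] = str(out / "local_scores.tsv")
            summary_df = summarize_by_median(df, cols)
            ml = global_model(summary_df, cols, config.k_folds,
                              bootstrap_rounds=config.bootstrap_rounds,
                              seed=config.seed)
            scores_path = out / "ml_scores.tsv"
            pd.DataFrame({
                "metric": ["auc_train", "auc_test", "f1_train", "f1_test",
                           "threshold"],
                "median": [ml.median_auc_train, ml.median_auc_test,
                           ml.median_f1_train, ml.median_f1_test,
                           ml.threshold]}).to_csv(scores_path, sep="\t",
                                                  index=False)
            results["ml_scores"] = str(scores_path)
            results["ml_median_auc_test"] = ml.median_auc_test
            mis_path = out / "misclassified.tsv"
            mis_rows = [{"mutation_id": i,
                         "chain": muts[i].chain,
                         "residue_seq": muts[i].residue_seq}
                        for i in ml.misclassified]
            pd.DataFrame(mis_rows).to_csv(mis_path, sep="\t", index=False)
            results["misclassified"] = str(mis_path)
            if config.run_importances:
                imp_rows = []
                for idx, df_point in df.groupby("pore_index"):
                    if df_point["y"].nunique() < 2:
                        continue
                    imp = feature_importances(
                        df_point, cols, config.permutation_rounds,
                        config.seed)
                    imp["pore_index"] = idx
                    imp_rows.append(imp)
                if imp_rows:
                    pd.concat(imp_rows).to_csv(out / "importances.tsv",
                                               sep="\t", index=False)
                    results["importances"] = str(out / "importances.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage ml failed: {exc}") from exc

    manifest.record("pipeline", run_key, [fits_path, exps_path],
                    extra={k: v for k, v in results.items()
                           if isinstance(v, (str, int, float, list, tuple))})
    return results


def _write_traces(moment_sets, path) -> None:
    rows = []
    for idx, mset in moment_sets.items():
        for j, prof in mset.profiles.items():
            if not prof.decomposable:
                continue
            for li, l in enumerate(mset.l_values):
                rows.append({
                    "pore_index": idx, "l": l, "j": j,
                    "h": prof.trace[li],
                    "h_plus": prof.plus_trace[li],
                    "h_minus": prof.minus_trace[li],
                    "psi_plus": prof.psi_plus[li],
                    "psi_minus": prof.psi_minus[li],
                    "I": prof.coupling[li],
                    "phi": prof.log_susceptibility[li]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
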