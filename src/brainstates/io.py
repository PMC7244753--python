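"""Plain-text file formats, configuration, and the end-to-end pipeline.

Everything on disk is TSV (matrices without header, tables with header) or
JSON/YAML; parcellated matrices need no neuroimaging binary formats, and
plain text keeps every artifact language-portable. Matrix writes use 17
significant digits so a write/read round-trip is lossless at double
precision.

:func:`run_pipeline` binds the stages together for a fully synthetic run:
simulate -> cluster -> assign -> dynamics -> energies -> nulls -> stats,
stamping outputs with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, control, dynamics, nulls, stats, synthetic
from .types import BoldScan, RegionParcellation, StructuralNetwork, ValidationError

logger = logging.getLogger("brainstates")

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_parcellation",
    "read_parcellation",
    "write_network",
    "read_network",
    "write_cohort",
    "read_cohort_scans",
    "PipelineConfig",
    "ConfigError",
    "PipelineError",
    "load_config",
    "run_pipeline",
]


class ConfigError(ValueError):
    """Raised when a pipeline configuration is invalid."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: np.ndarray, path: str | Path) -> None:
    """Write a 2-D numeric matrix as headerless TSV at full double precision."""
    M = np.atleast_2d(np.asarray(matrix, dtype=float))
    np.savetxt(path, M, delimiter="\t", fmt="%.17g")


def read_matrix_tsv(path: str | Path) -> np.ndarray:
    """Read a headerless numeric TSV matrix; errors name the offending line."""
    path = Path(path)
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise ValidationError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {width})"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not rows:
        raise ValidationError(f"{path}: empty matrix file")
    return np.array(rows)


# ---------------------------------------------------------------------------
# structured objects
# ---------------------------------------------------------------------------

def write_parcellation(parc: RegionParcellation, path: str | Path) -> None:
    pd.DataFrame(
        {
            "region_id": np.arange(parc.n_regions),
            "system": parc.systems,
            "x": parc.coords[:, 0],
            "y": parc.coords[:, 1],
            "z": parc.coords[:, 2],
        }
    ).to_csv(path, sep="\t", index=False)


def read_parcellation(path: str | Path) -> RegionParcellation:
    df = pd.read_csv(path, sep="\t")
    return RegionParcellation(
        systems=df["system"].to_numpy(object),
        coords=df[["x", "y", "z"]].to_numpy(float),
    )


def write_network(net: StructuralNetwork, adjacency_path: str | Path, coords_path: str | Path) -> None:
    write_matrix_tsv(net.adjacency, adjacency_path)
    write_matrix_tsv(net.coords, coords_path)


def read_network(adjacency_path: str | Path, coords_path: str | Path) -> StructuralNetwork:
    return StructuralNetwork(
        adjacency=read_matrix_tsv(adjacency_path), coords=read_matrix_tsv(coords_path)
    )


def write_cohort(cohort: "synthetic.Cohort", outdir: str | Path) -> Path:
    """Write a synthetic cohort: per-scan TSVs, manifest, covariates, truth."""
    outdir = Path(outdir)
    scandir = outdir / "scans"
    scandir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for scan in cohort.scans:
        fname = f"{scan.subject_id}_{scan.condition}.tsv"
        write_matrix_tsv(scan.data, scandir / fname)
        pd.DataFrame({"block": scan.block_labels}).to_csv(
            scandir / f"{scan.subject_id}_{scan.condition}_blocks.tsv",
            sep="\t",
            index=False,
        )
        manifest_rows.append(
            {
                "subject_id": scan.subject_id,
                "condition": scan.condition,
                "tr": scan.tr,
                "path": f"scans/{fname}",
                "blocks_path": f"scans/{scan.subject_id}_{scan.condition}_blocks.tsv",
            }
        )
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    cohort.covariates.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    write_parcellation(cohort.parcellation, outdir / "parcellation.tsv")
    truth = cohort.truth
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "planted_centroids": truth.planted_centroids.tolist(),
                "rest_tp": truth.rest_tp.tolist(),
                "task_tp": truth.task_tp.tolist(),
                "dwell": truth.dwell,
                "noise_sd": truth.noise_sd,
                "ar_coef": truth.ar_coef,
                "effect_sizes": truth.effect_sizes,
            },
            fh,
            indent=1,
        )
    return outdir


def read_cohort_scans(outdir: str | Path) -> list[BoldScan]:
    """Read the scans of a written cohort back via its manifest."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.tsv", sep="\t")
    scans = []
    for _, row in manifest.iterrows():
        blocks = pd.read_csv(outdir / row["blocks_path"], sep="\t")["block"].to_numpy(object)
        scans.append(
            BoldScan(
                subject_id=row["subject_id"],
                condition=row["condition"],
                data=read_matrix_tsv(outdir / row["path"]),
                tr=float(row["tr"]),
                block_labels=blocks,
            )
        )
    return scans


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated configuration of a full synthetic pipeline run."""

    outdir: str = "brainstates_out"
    seed: int = 0
    # synthetic cohort
    n_subjects: int = 20
    n_regions: int = 50
    n_rest_frames: int = 120
    n_task_frames: int = 225
    tr: float = 3.0
    dwell: float = 3.0
    noise_sd: float = 0.5
    ar_coef: float = 0.3
    # clustering
    k: int = 5
    n_reps: int = 20
    # dynamics
    n_perm: int = 5000
    # control
    T: float = 1.0
    c: float = 1.0
    kappa: float = 1.0
    input_mode: str = "uniform"
    # connectome + nulls
    connectome_density: float = 0.3
    connectome_decay: float = 0.5
    n_nulls: int = 20
    # stage toggles
    run_energy: bool = True
    run_nulls: bool = True
    run_stats: bool = True

    _RANGES = {
        "k": (2, 50),
        "n_subjects": (2, 100_000),
        "n_regions": (7, 10_000),
        "n_perm": (1, 10_000_000),
        "n_reps": (1, 1000),
    }

    def validate(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigError(f"{name}={v} outside [{lo}, {hi}]")
        for name in ("tr", "dwell", "T", "c", "noise_sd"):
            if getattr(self, name) <= 0 and name != "noise_sd":
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.ar_coef < 1:
            raise ConfigError("ar_coef must lie in [0, 1)")
        if not 0 < self.connectome_density <= 1:
            raise ConfigError("connectome_density must be in (0, 1]")
        if self.input_mode != "uniform" and not self.input_mode.startswith("system:"):
            raise ConfigError(f"unknown input_mode {self.input_mode!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    known = {f for f in PipelineConfig.__dataclass_fields__ if not f.startswith("_")}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(name, exc) from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return run

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic pipeline and write all outputs.

    Returns a result bundle (dict) with the in-memory objects of each stage;
    all declared TSV outputs are written under ``config.outdir``. Outputs are
    deterministic in (config, seed).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = config.seed
    provenance = {
        "config_hash": config.config_hash(),
        "seed": rng_seed,
        "config": asdict(config),
    }

    cohort_cfg = synthetic.CohortConfig(
        n_subjects=config.n_subjects,
        n_regions=config.n_regions,
        n_rest_frames=config.n_rest_frames,
        n_task_frames=config.n_task_frames,
        tr=config.tr,
        dwell=config.dwell,
        noise_sd=config.noise_sd,
        ar_coef=config.ar_coef,
    )

    cohort = _stage("simulate")(synthetic.generate_cohort)(cohort_cfg, seed=rng_seed)
    net = _stage("simulate")(synthetic.generate_connectome)(
        cohort.parcellation,
        decay=config.connectome_decay,
        density=config.connectome_density,
        seed=rng_seed + 1,
    )
    write_cohort(cohort, outdir)
    write_network(net, outdir / "adjacency.tsv", outdir / "coords.tsv")

    @_stage("cluster")
    def _cluster():
        X, index = clustering.concatenate_scans(cohort.scans)
        model = clustering.fit_kmeans(X, config.k, n_reps=config.n_reps, seed=rng_seed + 2)
        names, radar = clustering.name_states(model.centroids, cohort.parcellation)
        model.names = names
        write_matrix_tsv(model.centroids, outdir / "centroids.tsv")
        radar.to_csv(outdir / "state_alignment.tsv", sep="\t", index=False)
        return X, index, model

    X, index, model = _cluster()

    @_stage("assign")
    def _assign():
        seqs = [clustering.assign_states(model, s) for s in cohort.scans]
        rows = []
        for seq in seqs:
            for f, lab in enumerate(seq.labels):
                rows.append((seq.subject_id, seq.condition, f, int(lab)))
        pd.DataFrame(
            rows, columns=["subject_id", "condition", "frame", "state"]
        ).to_csv(outdir / "state_sequences.tsv", sep="\t", index=False)
        return seqs

    seqs = _assign()

    @_stage("dynamics")
    def _dynamics():
        metric_rows = []
        rest_tps, task_tps = [], []
        for seq in seqs:
            mets = dynamics.scan_metrics(seq)
            mets.insert(0, "subject_id", seq.subject_id)
            mets.insert(1, "scope", seq.condition)
            metric_rows.append(mets)
            tp = dynamics.transition_probability(seq)
            (rest_tps if seq.condition == "rest" else task_tps).append(tp)
        metrics = pd.concat(metric_rows, ignore_index=True)
        metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        perm = dynamics.permutation_test_tp(
            rest_tps, task_tps, n_perm=config.n_perm, seed=rng_seed + 3
        )
        perm.to_frame().to_csv(outdir / "permutation_test.tsv", sep="\t", index=False)
        mean_rest, _ = dynamics.group_average_tp(rest_tps)
        mean_task, _ = dynamics.group_average_tp(task_tps)
        write_matrix_tsv(mean_rest, outdir / "tp_rest.tsv")
        write_matrix_tsv(mean_task, outdir / "tp_task.tsv")
        return metrics, rest_tps, task_tps, perm, mean_rest, mean_task

    metrics, rest_tps, task_tps, perm, mean_rest, mean_task = _dynamics()

    results: dict = {
        "provenance": provenance,
        "cohort": cohort,
        "network": net,
        "model": model,
        "sequences": seqs,
        "metrics": metrics,
        "permutation": perm,
    }

    if config.run_energy:

        @_stage("energy")
        def _energy():
            B = control.build_input_matrix(
                cohort.parcellation, mode=config.input_mode, kappa=config.kappa
            )
            sys = control.make_control_system(net, c=config.c, T=config.T, B=B)
            E = control.transition_energy_matrix(sys, model.centroids, mode=config.input_mode)
            write_matrix_tsv(E.energies, outdir / "transition_energy.tsv")
            sweep = control.horizon_sweep(net, model.centroids, c=config.c, B=B)
            sweep.to_csv(outdir / "horizon_sweep.tsv", sep="\t", index=False)
            rho_rest, _ = control.energy_probability_correlation(E, mean_rest)
            rho_task, _ = control.energy_probability_correlation(E, mean_task)
            pd.DataFrame(
                [
                    {"condition": "rest", "spearman_rho": rho_rest},
                    {"condition": "nback", "spearman_rho": rho_task},
                ]
            ).to_csv(outdir / "energy_probability.tsv", sep="\t", index=False)
            return sys, E

        sys_, E = _energy()
        results["energy"] = E

        if config.run_nulls:

            @_stage("nulls")
            def _nulls():
                rng = np.random.default_rng(rng_seed + 4)
                null_Es = []
                for i in range(config.n_nulls):
                    nn = nulls.degree_preserving_null(net, seed=rng)
                    nsys = control.make_control_system(nn, c=config.c, T=config.T, B=sys_.B)
                    null_Es.append(control.transition_energy_matrix(nsys, model.centroids))
                p, p_corr = nulls.null_comparison_pvalues(E, null_Es)
                k = E.k
                rows = []
                null_stack = np.stack([ne.energies for ne in null_Es])
                for i in range(k):
                    for j in range(k):
                        rows.append(
                            {
                                "from_state": i + 1,
                                "to_state": j + 1,
                                "real_E": E.energies[i, j],
                                "null_mean": null_stack[:, i, j].mean(),
                                "null_sd": null_stack[:, i, j].std(ddof=1),
                                "p": p[i, j],
                                "p_corrected": p_corr[i, j],
                            }
                        )
                df = pd.DataFrame(rows)
                df.to_csv(outdir / "null_comparison.tsv", sep="\t", index=False)
                return df

            results["null_comparison"] = _nulls()

    if config.run_stats:

        @_stage("stats")
        def _stats():
            cov = cohort.covariates
            rows = []
            for state in range(1, config.k + 1):
                sub = metrics[metrics["state"] == state]
                rest = sub[sub["scope"] == "rest"].set_index("subject_id")
                task = sub[sub["scope"] == "nback"].set_index("subject_id")
                common = rest.index.intersection(task.index)
                for metric in ("fractional_occupancy", "dwell_time", "appearance_rate"):
                    r = rest.loc[common, metric].to_numpy()
                    t = task.loc[common, metric].to_numpy()
                    ok = ~np.isnan(r) & ~np.isnan(t)
                    if ok.sum() < 3:
                        continue
                    pc = stats.paired_contrast(r[ok], t[ok], m=config.k)
                    rows.append(
                        {
                            "metric": metric,
                            "state": state,
                            "mean_diff": pc.mean_diff,
                            "t": pc.t,
                            "df": pc.df,
                            "p": pc.p,
                            "p_corrected": pc.p_corrected,
                        }
                    )
                # age regression on rest fractional occupancy
                fo = rest.loc[cov["subject_id"], "fractional_occupancy"].to_numpy()
                reg = stats.fit_dynamics_regression(fo, cov, m=config.k)
                age_row = reg[reg["predictor"] == "age"].iloc[0]
                rows.append(
                    {
                        "metric": "fo_age_beta",
                        "state": state,
                        "mean_diff": age_row["beta"],
                        "t": age_row["t"],
                        "df": age_row["df"],
                        "p": age_row["p"],
                        "p_corrected": age_row["p_corrected"],
                    }
                )
            df = pd.DataFrame(rows)
            df.to_csv(outdir / "group_stats.tsv", sep="\t", index=False)
            return df

        results["group_stats"] = _stats()

    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, default=str)
    return results
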