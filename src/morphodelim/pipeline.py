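"""End-to-end orchestration: input -> clustering sweep -> selection -> validation -> characters.

A run is described by a :class:`RunConfig`, executes each stage with
stage-level logging and deterministic seeding, writes every table as
delimited text into the output directory, and records a JSON manifest from
which the entire run can be reproduced.  Candidate (gamma, K) pairs for
character analysis default to the eigengap consensus peaks, each paired with
the gamma whose profile shows the tallest gap at that K; the final
biological veto over candidates stays with the user.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .characters import MIEstimatorConfig, cluster_vs_rest_ttest, eigenvector_correlation, mi_character_cluster
from .io import CharacterMatrix, prune_correlated, ratio_transform, read_character_table, standardize
from .selection import SelectionReport, SweepConfig, SweepResult, detect_peaks, eigengap_table, sweep
from .spectral import KernelConfig, normalized_laplacian, rbf_similarity, spectral_embed
from .validation import validation_table

logger = logging.getLogger("morphodelim")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "run_from_manifest"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for error routing."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    input_path: str
    output_dir: str
    id_column: str = "individual_id"
    label_column: str | None = "taxon"
    sep: str | None = None
    ratio_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    prune: bool = False
    r2_threshold: float = 0.7
    prune_alpha: float = 0.05
    gamma_grid: list[float] = field(default_factory=lambda: [round(0.05 * i, 2) for i in range(1, 21)])
    k_min: int = 2
    k_max: int = 20
    restarts: int = 100
    exponent_scale: str = "divide"
    min_prominence: float = 2.0
    consensus_fraction: float = 0.5
    candidates: list[tuple[float, int]] | None = None
    mi_neighbors: int = 3
    seed: int = 0
    verbosity: str = "INFO"


def _stage(name: str, manifest: dict, out_dir: Path):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                (out_dir / "FAILED").write_text(f"stage {name} failed after {dt:.2f}s: {exc}\n")
                logger.error("stage %s: FAILED after %.2fs (%s)", name, dt, exc)
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = round(dt, 3)
            logger.info("stage %s: done in %.2fs", name, dt)

    return _Ctx()


def _default_candidates(sweep_result: SweepResult, report: SelectionReport) -> list[tuple[float, int]]:
    """For each consensus peak K, the gamma with the tallest gap at that K."""
    candidates = []
    for K in report.consensus_peaks:
        best = max(sweep_result.spectra, key=lambda s: s.eigengaps[K - s.k_min])
        candidates.append((best.gamma, K))
    return candidates


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and return the manifest (also written as manifest.json)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    manifest: dict = {
        "package": "morphodelim",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "outputs": {},
    }

    with _stage("read", manifest, out_dir):
        matrix = read_character_table(
            config.input_path, id_column=config.id_column, label_column=config.label_column, sep=config.sep
        )
        manifest["n_individuals"] = matrix.n_individuals

    if config.ratio_pairs:
        with _stage("ratio_transform", manifest, out_dir):
            matrix = ratio_transform(matrix, [tuple(p) for p in config.ratio_pairs])

    if config.prune:
        with _stage("prune_correlated", manifest, out_dir):
            matrix, report = prune_correlated(
                matrix, r2_threshold=config.r2_threshold, alpha=config.prune_alpha
            )
            path = out_dir / "pruning_report.csv"
            report.to_frame().to_csv(path, index=False)
            manifest["outputs"]["pruning_report"] = str(path)

    with _stage("standardize", manifest, out_dir):
        matrix = standardize(matrix)
        path = out_dir / "standardized.csv"
        matrix.to_frame(id_column=config.id_column).to_csv(path, index=False)
        manifest["outputs"]["standardized"] = str(path)
        manifest["n_characters"] = matrix.n_characters

    with _stage("sweep", manifest, out_dir):
        sweep_cfg = SweepConfig(
            gamma_grid=tuple(config.gamma_grid),
            k_min=config.k_min,
            k_max=config.k_max,
            restarts=config.restarts,
            seed=config.seed,
            exponent_scale=config.exponent_scale,  # type: ignore[arg-type]
        )
        sweep_result = sweep(matrix, sweep_cfg)
        rows = []
        for (gamma, K), a in sorted(sweep_result.assignments.items()):
            for ind, lab in zip(matrix.individual_ids, a.labels):
                rows.append({"gamma": gamma, "K": K, "individual_id": ind, "cluster": int(lab)})
        path = out_dir / "assignments.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        manifest["outputs"]["assignments"] = str(path)

    with _stage("detect_peaks", manifest, out_dir):
        report = detect_peaks(
            sweep_result.spectra,
            min_prominence=config.min_prominence,
            consensus_fraction=config.consensus_fraction,
        )
        path = out_dir / "eigengap.csv"
        eigengap_table(sweep_result.spectra, report).to_csv(path, index=False)
        manifest["outputs"]["eigengap"] = str(path)
        manifest["consensus_peaks"] = report.consensus_peaks
        manifest["excluded_gammas"] = {f"{g:.2f}": r for g, r in report.excluded.items()}

    if matrix.ground_truth is not None:
        with _stage("validate", manifest, out_dir):
            vt = validation_table(sweep_result.assignments, matrix.ground_truth)
            path = out_dir / "validation.csv"
            vt.to_csv(path, index=False)
            manifest["outputs"]["validation"] = str(path)

    candidates = config.candidates or _default_candidates(sweep_result, report)
    manifest["candidates"] = [[g, K] for g, K in candidates]
    for gamma, K in candidates:
        tag = f"gamma{gamma:.2f}_K{K}"
        with _stage(f"characters_{tag}", manifest, out_dir):
            assignment = sweep_result.assignments.get((gamma, K))
            if assignment is None:
                from .spectral import spectral_cluster

                assignment = spectral_cluster(
                    matrix, gamma, K, restarts=config.restarts, seed=config.seed,
                    exponent_scale=config.exponent_scale,  # type: ignore[arg-type]
                )
            sim = rbf_similarity(matrix, KernelConfig(gamma=gamma, exponent_scale=config.exponent_scale))  # type: ignore[arg-type]
            emb = spectral_embed(normalized_laplacian(sim), K)
            mi = mi_character_cluster(
                matrix, assignment, MIEstimatorConfig(n_neighbors=config.mi_neighbors, seed=config.seed)
            )
            corr = eigenvector_correlation(matrix, emb)
            tt = cluster_vs_rest_ttest(matrix, assignment)
            for name, df in (("mi", mi), ("eigencorr", corr), ("ttest", tt)):
                path = out_dir / f"{name}_{tag}.csv"
                df.to_csv(path, index=False)
                manifest["outputs"][f"{name}_{tag}"] = str(path)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest


def run_from_manifest(manifest_path: str | Path, output_dir: str | Path) -> dict:
    """Reproduce a run from its manifest into a fresh output directory."""
    recorded = json.loads(Path(manifest_path).read_text())
    cfg_dict = dict(recorded["config"])
    cfg_dict["output_dir"] = str(output_dir)
    cfg_dict["ratio_pairs"] = [tuple(p) for p in cfg_dict.get("ratio_pairs", [])]
    if cfg_dict.get("candidates"):
        cfg_dict["candidates"] = [(float(g), int(k)) for g, k in cfg_dict["candidates"]]
    return run_pipeline(RunConfig(**cfg_dict))
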