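"""End-to-end orchestration: simulate/load -> fit -> classify -> summarize.

``run_pipeline`` ties the stages together, writes every result table as
TSV under an output directory and records a JSON manifest with the
configuration, seed and SHA-256 content hashes, so a rerun with the same
config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import io as _io
from . import simulate as _simulate
from .circular import circular_mean_vector, wedge_histogram
from .config import AnalysisConfig
from .enrichment import enrich_gene_list
from .errors import ConfigError, DiurnalError
from .rhythms import detect_rhythms
from .simulate import GeneratorConfig

log = logging.getLogger("diurnal")

DEFAULT_PLANTING = {
    "planted_class_III": ("III", float("inf")),
    "null_set_a": ("NC", 1.0),
    "null_set_b": ("NC", 1.0),
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    expression: str | Path | None = None,
    samples: str | Path | None = None,
    gmt: str | Path | None = None,
    generator: GeneratorConfig | None = None,
    enrich: bool = True,
    enrich_class: str = "III",
) -> dict:
    """Run every stage and return the manifest dictionary.

    With no ``expression``/``samples`` paths a synthetic dataset is
    generated (and written) first; otherwise the given inputs are loaded.
    ``enrich`` requires a GMT path unless the data is simulated, in which
    case planted gene sets are generated.
    """
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "seed": config.seed, "stages": []}
    written: dict[str, Path] = {}

    def stage(name):
        def wrap(fn):
            start = time.perf_counter()
            try:
                result = fn()
            except DiurnalError:
                raise
            except Exception as exc:  # annotate with the failing stage
                raise DiurnalError(f"stage {name!r} failed: {exc}") from exc
            elapsed = time.perf_counter() - start
            log.info("stage %-12s done in %.2fs", name, elapsed)
            manifest["stages"].append(name)
            return result

        return wrap

    def emit(name: str, table: pd.DataFrame) -> None:
        path = out / name
        _io.write_table(table, path)
        written[name] = path

    if expression is None or samples is None:
        if expression is not None or samples is not None:
            raise ConfigError("provide both expression and samples, or neither")

        def simulate_stage():
            gen = generator or GeneratorConfig()
            matrix, sample_table, truth = _simulate.generate_transcriptome(
                gen, seed=config.seed
            )
            planting = dict(DEFAULT_PLANTING)
            n_target = sum(truth.genes["true_class"] == enrich_class)
            if enrich_class in truth.genes["true_class"].values and n_target >= 5:
                planting["planted_class_III"] = (
                    enrich_class,
                    float("inf"),
                    min(40, n_target),
                )
            sets = _simulate.generate_gene_sets(truth, planting, seed=config.seed)
            _io.write_expression_matrix(matrix, out / "expression.tsv")
            _io.write_sample_table(sample_table, out / "samples.tsv")
            _io.write_gmt(sets, out / "gene_sets.gmt")
            truth.to_json(out / "truth.json")
            hormones = _simulate.generate_hormone_profile(gen, seed=config.seed)
            tolerance = _simulate.generate_tolerance_test(gen, seed=config.seed)
            emit("hormones.tsv", hormones)
            emit("tolerance.tsv", tolerance)
            for name in ("expression.tsv", "samples.tsv", "gene_sets.gmt", "truth.json"):
                written[name] = out / name
            return matrix, sample_table, sets

        matrix, sample_table, collection = stage("simulate")(simulate_stage)
    else:

        def load_stage():
            mat = _io.read_expression_matrix(expression)
            tab = _io.read_sample_table(samples, period=config.period_T)
            collection = _io.read_gmt(gmt) if gmt is not None else None
            if enrich and collection is None:
                raise ConfigError("enrichment requested but no GMT path given")
            return mat, tab, collection

        matrix, sample_table, collection = stage("load")(load_stage)

    conditions = list(dict.fromkeys(sample_table["condition"]))
    if len(conditions) != 2:
        raise ConfigError(f"pipeline requires exactly 2 conditions, got {conditions}")
    cond1, cond2 = conditions

    def rhythms_stage():
        r1 = detect_rhythms(matrix, sample_table, cond1, config)
        r2 = detect_rhythms(matrix, sample_table, cond2, config)
        emit("rhythms.tsv", pd.concat([r1, r2], ignore_index=True))
        return r1, r2

    r1, r2 = stage("rhythms")(rhythms_stage)

    def classify_stage():
        base = _classify.baseline_tests(matrix, sample_table, cond1, cond2)
        table = _classify.classify_genes(r1, r2, base, config)
        emit("classes.tsv", table)
        return table

    classes = stage("classify")(classify_stage)

    def histogram_stage():
        centers = sorted(sample_table["zt"].unique())
        hists = []
        for condition, rtab in ((cond1, r1), (cond2, r2)):
            h = _classify.peak_time_histogram(rtab, centers, config.period_T)
            h.insert(0, "condition", condition)
            hists.append(h)
        emit("peak_histogram.tsv", pd.concat(hists, ignore_index=True))

    stage("histograms")(histogram_stage)

    def circular_stage():
        shifts = classes.loc[
            classes["class_label"].isin(["I", "II"]), "delta_phase"
        ].to_numpy()
        if shifts.size:
            summary = circular_mean_vector(shifts, config.period_T)
            edges, counts = wedge_histogram(shifts, config.period_T)
            emit(
                "circular_summary.tsv",
                pd.DataFrame(
                    [
                        (
                            summary.n,
                            summary.mean_direction,
                            summary.resultant_length_R,
                            summary.rayleigh_Z,
                            summary.rayleigh_p,
                        )
                    ],
                    columns=["n", "mean_direction", "resultant_length_R", "rayleigh_Z", "rayleigh_p"],
                ),
            )
            emit(
                "wedge_histogram.tsv",
                pd.DataFrame({"wedge_start_deg": edges, "count": counts}),
            )
        else:
            emit(
                "circular_summary.tsv",
                pd.DataFrame(
                    columns=["n", "mean_direction", "resultant_length_R", "rayleigh_Z", "rayleigh_p"]
                ),
            )
            edges, counts = wedge_histogram([], config.period_T)
            emit(
                "wedge_histogram.tsv",
                pd.DataFrame({"wedge_start_deg": edges, "count": counts}),
            )

    stage("circular")(circular_stage)

    if enrich:

        def enrich_stage():
            gene_list = classes.loc[
                classes["class_label"] == enrich_class, "gene"
            ].tolist()
            universe = classes["gene"].tolist()
            table = enrich_gene_list(gene_list, universe, collection, config.alpha)
            emit("enrichment.tsv", table)

        stage("enrichment")(enrich_stage)

    manifest["files"] = {
        name: _sha256(path) for name, path in sorted(written.items())
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
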