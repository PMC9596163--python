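"""Pipeline orchestration: config parsing, execution, artifact writing.

A run is described by a YAML config:

.. code-block:: yaml

    inputs:
      factor_peaks:          # label -> BED path, >= 2 factors
        factor1: factor1.bed
        factor2: factor2.bed
        factor3: factor3.bed
      replicates:            # optional: 2 replicates of the FIRST factor;
        rep1: factor1_rep1.bed   # enables the consensus filter
        rep2: factor1_rep2.bed
      mark_peaks:            # histone-mark BEDs (any subset of the 4 marks)
        H3K4me3: H3K4me3.bed
        H3K27ac: H3K27ac.bed
        H3K4me1: H3K4me1.bed
        H3K27me3: H3K27me3.bed
      gene_table: genes.tsv
      expression: expression.tsv
    screen:                  # any ScreenConfig field
      gene_window_bp: 100000
      common_mode: footprint
      gating_celltype: iOL

Relative paths resolve against the config file's directory. Outputs
(candidates.tsv, associations.tsv, common_regions.bed, elements.bed,
summary.json) are staged in a temporary directory and moved into place
only when the whole run succeeds, so a failed run leaves no partial
files.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
import tempfile
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .intervals import IntervalSet
from .io_formats import (
    read_bed,
    read_expression_table,
    read_gene_table,
    write_bed,
    write_summary,
)
from .target_screen import CandidateTable, ConfigError, ScreenConfig, screen

__all__ = ["load_config", "run_pipeline", "InputError"]

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "candidates.tsv",
    "associations.tsv",
    "common_regions.bed",
    "elements.bed",
    "summary.json",
)


class InputError(RuntimeError):
    """A referenced input file is missing or unreadable."""


def load_config(path: str | Path) -> tuple[dict, ScreenConfig]:
    """Parse the YAML run config; returns (inputs section, ScreenConfig)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    if "inputs" not in raw or "factor_peaks" not in raw.get("inputs", {}):
        raise ConfigError(f"{path}: config must define inputs.factor_peaks")
    inputs = raw["inputs"]
    base = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    inputs["factor_peaks"] = {k: resolve(v) for k, v in inputs["factor_peaks"].items()}
    if "replicates" in inputs:
        reps = inputs["replicates"]
        if set(reps) != {"rep1", "rep2"}:
            raise ConfigError(f"{path}: inputs.replicates must map rep1 and rep2")
        inputs["replicates"] = {k: resolve(v) for k, v in reps.items()}
    inputs["mark_peaks"] = {k: resolve(v) for k, v in inputs.get("mark_peaks", {}).items()}
    for key in ("gene_table", "expression"):
        if key not in inputs:
            raise ConfigError(f"{path}: inputs.{key} is required")
        inputs[key] = resolve(inputs[key])

    screen_kwargs = dict(raw.get("screen", {}))
    if "expression_gate" in screen_kwargs:
        screen_kwargs["expression_gate"] = {
            k: tuple(v) for k, v in screen_kwargs["expression_gate"].items()
        }
    known = {f.name for f in dataclasses.fields(ScreenConfig)}
    unknown = set(screen_kwargs) - known
    if unknown:
        raise ConfigError(f"{path}: unknown screen option(s) {sorted(unknown)}")
    if "factors" not in screen_kwargs:
        screen_kwargs["factors"] = list(inputs["factor_peaks"])
    try:
        config = ScreenConfig(**screen_kwargs)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return inputs, config


def _read_peaks(path: Path, normalize_chrom_names: bool) -> IntervalSet:
    if not Path(path).exists():
        raise InputError(f"peak file not found: {path}")
    return read_bed(path, normalize_chrom_names=normalize_chrom_names)


def run_pipeline(
    config_path: str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Execute the screen described by a config file; returns the summary.

    Writes candidates.tsv, associations.tsv, common_regions.bed,
    elements.bed and summary.json into ``out_dir`` atomically. ``seed``
    is recorded in the summary for provenance (the screen itself is
    deterministic).
    """
    t0 = time.monotonic()
    inputs, config = load_config(config_path)
    out_dir = Path(out_dir)

    norm = config.normalize_chrom_names
    peaks_by_factor = {
        label: _read_peaks(p, norm) for label, p in inputs["factor_peaks"].items()
    }
    for label, peaks in peaks_by_factor.items():
        logger.info("read %d peaks for factor %s", len(peaks), label)
    replicate2 = None
    if "replicates" in inputs:
        first = config.factors[0]
        peaks_by_factor[first] = _read_peaks(inputs["replicates"]["rep1"], norm)
        replicate2 = _read_peaks(inputs["replicates"]["rep2"], norm)
        logger.info(
            "replicates for %s: %d / %d peaks",
            first, len(peaks_by_factor[first]), len(replicate2),
        )
    mark_peaks = {m: _read_peaks(p, norm) for m, p in inputs["mark_peaks"].items()}
    if not Path(inputs["gene_table"]).exists():
        raise InputError(f"gene table not found: {inputs['gene_table']}")
    genes = read_gene_table(inputs["gene_table"], normalize_chrom_names=norm)
    if not Path(inputs["expression"]).exists():
        raise InputError(f"expression table not found: {inputs['expression']}")
    expression = read_expression_table(inputs["expression"])

    result = screen(
        peaks_by_factor, mark_peaks, genes, expression, config, replicate2=replicate2
    )

    summary = dict(result.summary)
    summary["tool_version"] = __version__
    summary["seed"] = seed
    summary["config"] = {
        f.name: getattr(config, f.name) for f in dataclasses.fields(config)
    }
    summary["config"]["expression_gate"] = {
        k: list(v) for k, v in config.expression_gate.items()
    }
    summary["n_peaks_per_input"] = {
        label: len(p) for label, p in peaks_by_factor.items()
    } | {m: len(p) for m, p in mark_peaks.items()}
    top = result.candidates.head(20).reset_index()
    summary["top_candidates"] = top.to_dict(orient="records")
    summary["runtime_s"] = round(time.monotonic() - t0, 3)

    _write_outputs(result, summary, out_dir)
    logger.info(
        "screen complete: %d common regions, %d at active promoters, %d candidate genes",
        summary["n_common_regions"],
        summary["n_active_promoter_regions"],
        summary["n_candidate_genes"],
    )
    return summary


def _write_outputs(result: CandidateTable, summary: dict, out_dir: Path) -> None:
    staging = Path(tempfile.mkdtemp(prefix="regscreen-", dir=out_dir.parent
                                    if out_dir.parent.exists() else None))
    try:
        result.candidates.reset_index().to_csv(
            staging / "candidates.tsv", sep="\t", index=False
        )
        assoc_rows = [
            {
                "gene_id": a.gene_id,
                "chrom": a.region.chrom,
                "start": a.region.start,
                "end": a.region.end,
                "link_kind": a.link_kind,
                "distance_bp": a.distance_bp,
                "element_state": a.element_state,
                "expression_class": a.expression_class,
                "gate_passed": a.gate_passed,
            }
            for a in result.associations
        ]
        pd.DataFrame(
            assoc_rows,
            columns=["gene_id", "chrom", "start", "end", "link_kind", "distance_bp",
                     "element_state", "expression_class", "gate_passed"],
        ).to_csv(staging / "associations.tsv", sep="\t", index=False)
        write_bed(result.common, staging / "common_regions.bed")
        with (staging / "elements.bed").open("w") as fh:
            for e in result.elements:
                fh.write(e.to_bed9() + "\n")
        write_summary(summary, staging / "summary.json")

        out_dir.mkdir(parents=True, exist_ok=True)
        for name in OUTPUT_FILES:
            shutil.move(str(staging / name), str(out_dir / name))
    finally:
        shutil.rmtree(staging, ignore_errors=True)
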