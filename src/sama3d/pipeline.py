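"""End-to-end orchestration: preprocess, segment, measure, analyze, report.

Two entry points matter to most users:

* :func:`run_pipeline` — batch-process a directory of TIFF stacks under one
  configuration, writing per-stack CSVs and (when metadata is present) the
  consolidated statistical report.
* :func:`run_validation` — the self-contained phantom validation study:
  generate the four standard conditions (six seeded stacks each), push them
  through the full pipeline, and test the designed contrasts (elongation
  C2 vs C1, lumen presence and volume C3 vs C1, complexity C4 vs C1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, dump_config
from .core import ImageStack, LabelVolume
from .imgproc import Tier1Config, run_tier1
from .io import read_stack, write_stack
from .lumen import LumenRecord, assign_lumena, lumen_metrics, lumena_to_frame, segment_lumena
from .phantom import generate_condition
from .segment import StructureRecord, label_components, measure_all, records_to_frame
from .skeleton import analyze_structure
from .stats import compare_groups, consolidate, generate_report

__all__ = ["ProcessResult", "process_stack", "run_pipeline", "run_validation"]

log = logging.getLogger(__name__)


@dataclass
class ProcessResult:
    """Everything measured on one stack."""

    labels: LabelVolume
    records: list[StructureRecord]
    lumen_records: list[LumenRecord]
    lumen_fraction: float  # image-level L
    structure_threshold: float

    @property
    def n_structures(self) -> int:
        return len(self.records)

    def structure_table(self) -> pd.DataFrame:
        df = records_to_frame(self.records)
        if not df.empty:
            df["has_lumen"] = df["n_lumena"] >= 1
        return df

    def lumen_table(self) -> pd.DataFrame:
        return lumena_to_frame(self.lumen_records)


def _drop_border_labels(labels: LabelVolume) -> LabelVolume:
    lab = labels.labels
    border = np.zeros(lab.shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        for idx in (0, -1):
            sl[ax] = idx
            border[tuple(sl)] = True
    touching = np.unique(lab[border & (lab > 0)])
    if touching.size == 0:
        return labels
    keep = np.setdiff1d(np.arange(1, labels.n_labels + 1), touching)
    remap = np.zeros(labels.n_labels + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    return LabelVolume(remap[lab], labels.spacing)


def process_stack(stack: ImageStack, config: RunConfig | None = None) -> ProcessResult:
    """Run Tier-1 preprocessing, segmentation, morphometrics, and the
    optional lumen and skeleton analyses on one stack."""
    cfg = config or RunConfig()
    t1 = run_tier1(stack, cfg.tier1)
    labels = label_components(t1.structure_mask, cfg.segment.min_voxels, stack.spacing)
    if cfg.segment.exclude_border:
        labels = _drop_border_labels(labels)
    records = measure_all(labels)
    log.info("process_stack: %d structure(s)", len(records))

    lumen_records: list[LumenRecord] = []
    L = 0.0
    if cfg.lumen.enabled:
        lum_labels = segment_lumena(
            labels.labels > 0,
            t1.for_lumen,
            cfg.lumen.threshold,
            cfg.lumen.min_lumen_voxels,
            cfg.lumen.fill_mode,
        )
        lumen_records = assign_lumena(lum_labels, labels)
        records, L = lumen_metrics(records, lumen_records)

    if cfg.skeleton.enabled:
        lab = labels.labels
        for rec in records:
            coords = np.argwhere(lab == rec.label)
            lo = coords.min(axis=0)
            hi = coords.max(axis=0) + 1
            sub = lab[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] == rec.label
            graph = analyze_structure(
                np.pad(sub, 1), stack.spacing, cfg.skeleton.prune_length
            )
            rec.has_multiple_branches = graph.has_multiple_branches
            rec.n_branches = graph.n_branches
            rec.total_length = graph.total_length

    return ProcessResult(
        labels=labels,
        records=records,
        lumen_records=lumen_records,
        lumen_fraction=L,
        structure_threshold=t1.structure_threshold,
    )


def run_pipeline(config: RunConfig) -> Path:
    """Batch-process every TIFF under ``config.input_dir``.

    Per stack: CSV of structure measurements (and of lumena when enabled).
    If a metadata CSV (columns stack, condition, replicate) is configured,
    the per-stack tables are consolidated and the statistical report is
    generated. A failing stack is logged and skipped; the run aborts only if
    every stack fails. The resolved config and a version stamp are written
    into the output directory.
    """
    config.validate()
    in_dir = Path(config.input_dir)
    paths = sorted(p for p in in_dir.glob("*.tif*") if "label" not in p.stem)
    if not paths:
        raise FileNotFoundError(f"no TIFF stacks found in {in_dir}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(config, out / "config.resolved.yaml")
    (out / "VERSION").write_text(f"sama3d {__version__}\n")

    tables: dict[str, pd.DataFrame] = {}
    failures: list[str] = []
    for path in paths:
        stack_id = path.stem
        try:
            stack = read_stack(path, spacing=config.spacing)
            result = process_stack(stack, config)
        except Exception as exc:
            log.error("stack %s failed: %s", stack_id, exc)
            failures.append(stack_id)
            continue
        df = result.structure_table()
        df.to_csv(out / f"{stack_id}_structures.csv", index=False)
        if config.lumen.enabled:
            result.lumen_table().to_csv(out / f"{stack_id}_lumena.csv", index=False)
        tables[stack_id] = df
    if not tables:
        raise RuntimeError(f"all {len(paths)} stack(s) failed: {failures}")

    if config.metadata:
        meta = pd.read_csv(config.metadata)
        study = consolidate(
            tables,
            meta,
            include_lumen=config.stats.include_lumen and config.lumen.enabled,
            include_branching=config.stats.include_branching and config.skeleton.enabled,
        )
        study.to_csv(out / "study.csv", index=False)
        generate_report(
            study, out / "report",
            parameters=config.stats.parameters, unit=config.stats.unit,
        )
    return out


#: the three per-structure complexity measures tested in the C4 contrast
COMPLEXITY_MEASURES = ["has_multiple_branches", "n_branches", "total_length"]


def run_validation(
    seed: int = 0,
    n_stacks: int = 6,
    config: RunConfig | None = None,
    conditions: tuple[str, ...] = ("C1", "C2", "C3", "C4"),
    **phantom_overrides,
) -> dict:
    """Phantom validation study: generate, process, and test all conditions.

    Returns a dict with the study table, per-stack ground truth, the
    designed contrasts' reported p-values (``p_elongation``, ``p_lumen``,
    ``p_rlv``, ``p_complexity`` = max over the three complexity measures)
    and the structure-count recovery of the first reference stack.
    """
    cfg = config or RunConfig()
    tables: dict[str, pd.DataFrame] = {}
    meta_rows = []
    truth_counts: dict[str, int] = {}
    detected_counts: dict[str, int] = {}
    for ci, cond in enumerate(conditions):
        pairs = generate_condition(
            cond, seed=seed + 1000 * ci, n_stacks=n_stacks, **phantom_overrides
        )
        for i, (stack, truth) in enumerate(pairs):
            stack_id = f"{cond}_{i}"
            result = process_stack(stack, cfg)
            tables[stack_id] = result.structure_table()
            meta_rows.append({"stack": stack_id, "condition": cond, "replicate": i})
            truth_counts[stack_id] = truth.n_structures
            detected_counts[stack_id] = result.n_structures
            log.info("validation %s: %d/%d structures, L=%.3f",
                     stack_id, result.n_structures, truth.n_structures,
                     result.lumen_fraction)
    study = consolidate(tables, pd.DataFrame(meta_rows))

    def contrast(conds: tuple[str, str], parameter: str) -> float:
        sel = study[study["condition"].isin(conds)]
        return compare_groups(sel, parameter, unit=cfg.stats.unit).reported_p

    out: dict = {
        "study": study,
        "truth_counts": truth_counts,
        "detected_counts": detected_counts,
    }
    have = set(conditions)
    if {"C1", "C2"} <= have:
        out["p_elongation"] = contrast(("C1", "C2"), "elon1")
    if {"C1", "C3"} <= have:
        out["p_lumen"] = contrast(("C1", "C3"), "has_lumen")
        out["p_rlv"] = contrast(("C1", "C3"), "rlv")
    if {"C1", "C4"} <= have:
        per_measure = {m: contrast(("C1", "C4"), m) for m in COMPLEXITY_MEASURES}
        out["p_complexity_by_measure"] = per_measure
        out["p_complexity"] = max(per_measure.values())
    first_ref = f"{conditions[0]}_0"
    out["count_recovery"] = {
        "stack": first_ref,
        "generated": truth_counts[first_ref],
        "detected": detected_counts[first_ref],
    }
    return out
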