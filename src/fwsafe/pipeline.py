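"""Subject- and cohort-level orchestration with config, logging and QA.

``run_subject`` executes the per-subject chain — gradient/grid QA, the
bi-tensor fit, safe-WM mask construction, WMH penumbra exclusion, metric
extraction — and ``run_cohort`` joins the metric table with demographics
and produces the ANOVA/Tukey report (and, when aligned FW maps are
supplied, the patient-vs-NC z-score cluster maps).  Subjects failing QA
are excluded automatically with machine-readable reason codes and never
reach the statistics.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import group_stats, metrics as metrics_mod, zscore_map
from .fw_fit import FitConfig, FreeWaterFitResult, fit_volume
from .io_core import (
    GridMismatchError,
    ScalarVolume,
    assert_same_grid,
    check_single_shell,
    read_dwi,
    read_gradients,
    read_volume,
)
from .masks import TissueMaps, build_wm_safe, expand_wmh

logger = logging.getLogger("fwsafe")


def setup_logging(level: str = "INFO",
                  log_file: Optional[Union[str, Path]] = None) -> None:
    """Log to stderr, and optionally to a per-run file; never to stdout,
    so reports and metrics stay separable from diagnostics."""
    logger.setLevel(getattr(logging, level.upper()))
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(fmt)
    logger.addHandler(h)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


@dataclass
class PipelineConfig:
    """Everything tunable in one flat, YAML-serializable structure.

    Morphology radii are in voxels of the working grid; ``r_brain``
    defaults to the full-size value (15 voxels on a 1 mm grid) and must be
    scaled down for small synthetic grids.
    """

    fit: FitConfig = field(default_factory=FitConfig)
    r_small: int = 1
    r_brain: int = 15
    wmh_dilation: int = 2
    element: str = "ball"
    threshold: float = 0.1
    z_min: float = 2.0
    min_cluster: int = 10
    connectivity: int = 26
    min_directions: int = 41
    b_tolerance: float = 50.0
    output_dir: str = "fwsafe_out"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.fit, dict):
            self.fit = FitConfig(**self.fit)
        for name in ("r_small", "r_brain", "wmh_dilation", "min_cluster"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class QACheck:
    name: str
    passed: bool
    code: str = "ok"
    message: str = ""


@dataclass
class QAReport:
    """Per-subject QA checks plus cohort-level exclusion bookkeeping."""

    subject_id: str
    checks: list[QACheck] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def reason_codes(self) -> list[str]:
        return [c.code for c in self.checks if not c.passed]


@dataclass
class SubjectInputs:
    """Paths to one subject's co-registered inputs."""

    dwi: Path
    bval: Path
    bvec: Path
    wm: Path
    gm: Path
    csf: Path
    brain: Path
    wmh: Path

    @classmethod
    def from_dir(cls, subject_dir: Union[str, Path]) -> "SubjectInputs":
        d = Path(subject_dir)
        return cls(dwi=d / "dwi.nii.gz", bval=d / "dwi.bval",
                   bvec=d / "dwi.bvec", wm=d / "wm_mask.nii.gz",
                   gm=d / "gm_mask.nii.gz", csf=d / "csf_mask.nii.gz",
                   brain=d / "brain_mask.nii.gz", wmh=d / "wmh_mask.nii.gz")


def qa_subject(inputs: SubjectInputs, config: PipelineConfig,
               subject_id: str = "") -> QAReport:
    """Programmatic QA: files present, single shell, consistent grids."""
    report = QAReport(subject_id=subject_id)
    for name in ("dwi", "bval", "bvec", "wm", "gm", "csf", "brain", "wmh"):
        p = Path(getattr(inputs, name))
        if not p.exists():
            report.checks.append(QACheck(
                name=f"exists_{name}", passed=False, code="missing_input",
                message=f"missing {name} file: {p}"))
    if not report.passed:
        return report
    gtab = read_gradients(inputs.bval, inputs.bvec)
    shell = check_single_shell(gtab, b_tolerance=config.b_tolerance,
                               min_directions=config.min_directions)
    report.checks.append(QACheck(
        name="single_shell", passed=shell.passed,
        code="ok" if shell.passed else "bad_gradients",
        message="; ".join(shell.messages)))
    try:
        vols = [read_dwi(inputs.dwi, gtab)]
        vols += [read_volume(getattr(inputs, n), as_mask=True)
                 for n in ("wm", "gm", "csf", "brain", "wmh")]
        assert_same_grid(vols)
        report.checks.append(QACheck(name="grid_consistency", passed=True))
    except (GridMismatchError, ValueError) as exc:
        report.checks.append(QACheck(
            name="grid_consistency", passed=False, code="grid_mismatch",
            message=str(exc)))
    return report


def run_subject(inputs: SubjectInputs, config: Optional[PipelineConfig] = None,
                subject_id: str = "subject",
                out_dir: Optional[Union[str, Path]] = None):
    """Fit + mask + metrics for one subject.

    Returns ``(records, fit_result, qa_report)``; ``records`` is empty and
    ``fit_result`` None when QA fails.  Deterministic given the config, so
    re-runs reproduce identical outputs.
    """
    config = config or PipelineConfig()
    qa = qa_subject(inputs, config, subject_id)
    if not qa.passed:
        logger.warning("subject %s excluded by QA: %s", subject_id,
                       ",".join(qa.reason_codes))
        return [], None, qa

    gtab = read_gradients(inputs.bval, inputs.bvec)
    dwi = read_dwi(inputs.dwi, gtab)
    tissues = TissueMaps(
        wm=read_volume(inputs.wm, as_mask=True),
        gm=read_volume(inputs.gm, as_mask=True),
        csf=read_volume(inputs.csf, as_mask=True),
        brain=read_volume(inputs.brain, as_mask=True),
        wmh=read_volume(inputs.wmh, as_mask=True),
    )
    logger.info("subject %s: fitting %d voxels", subject_id,
                tissues.brain.n_true)
    fit = fit_volume(dwi, tissues.brain, config.fit)
    wm_safe = build_wm_safe(tissues, r_small=config.r_small,
                            r_brain=config.r_brain, element=config.element)
    wmh_exp = expand_wmh(tissues.wmh, radius=config.wmh_dilation,
                         element=config.element)
    records = metrics_mod.subject_metrics(
        fit.f_map, tissues, wm_safe, wmh_exp,
        threshold=config.threshold, subject_id=subject_id)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fit.write(out, prefix=f"{subject_id}_")
        metrics_mod.write_metrics_csv(records, out / f"{subject_id}_metrics.csv")
    return records, fit, qa


def run_cohort(metrics_table: Union[pd.DataFrame, str, Path],
               demographics: Union[pd.DataFrame, str, Path],
               config: Optional[PipelineConfig] = None,
               fw_maps: Optional[dict[str, ScalarVolume]] = None,
               out_dir: Optional[Union[str, Path]] = None):
    """Cohort statistics over the per-subject metric table.

    ``metrics_table`` is the long (subject, mask) table written by
    ``run_subject``/``write_metrics_csv`` (or an equivalent DataFrame);
    ``demographics`` carries subject_id, group, age, gender.  Returns
    ``(report, cluster_maps)`` where ``cluster_maps`` maps patient group
    names to (mean z-map, ClusterMap) when ``fw_maps`` are supplied.
    """
    config = config or PipelineConfig()
    if not isinstance(metrics_table, pd.DataFrame):
        metrics_table = pd.read_csv(metrics_table)
    if not isinstance(demographics, pd.DataFrame):
        demographics = pd.read_csv(demographics)

    wide = metrics_mod.wide_metrics(metrics_table) \
        if "mask_name" in metrics_table.columns else metrics_table
    missing = set(wide["subject_id"]) - set(demographics["subject_id"])
    if missing:
        raise ValueError(f"demographics missing subject(s): {sorted(missing)[:5]}")
    table = wide.merge(demographics, on="subject_id", how="left")
    groups = set(table["group"])
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")

    metric_names = [m for m in group_stats.DEFAULT_METRICS
                    if m in table.columns]
    report = group_stats.cohort_report(table, metrics=metric_names)

    cluster_maps = {}
    if fw_maps is not None:
        by_group: dict[str, list[ScalarVolume]] = {}
        demo_idx = demographics.set_index("subject_id")["group"]
        for sid, vol in fw_maps.items():
            by_group.setdefault(str(demo_idx.get(sid)), []).append(vol)
        ref_maps = by_group.get("NC", [])
        if len(ref_maps) >= 2:
            for g, maps in by_group.items():
                if g == "NC" or not maps:
                    continue
                cluster_maps[g] = zscore_map.group_comparison(
                    maps, ref_maps, z_min=config.z_min,
                    min_size=config.min_cluster,
                    connectivity=config.connectivity)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        group_stats.write_report(report, out / "cohort_report.csv",
                                 out / "cohort_report.json")
        for g, (zbar, cmap) in cluster_maps.items():
            cmap.write(out / f"clusters_{g}_vs_NC.nii.gz",
                       out / f"clusters_{g}_vs_NC.csv")
    return report, cluster_maps
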