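"""End-to-end orchestration: correct -> denoise -> segment -> quantify -> mesh.

:func:`run_pipeline` executes the whole processing sequence on a sample
stack (plus, optionally, a bare-scaffold stack for threshold calibration),
writes every intermediate and a machine-readable run log, and returns the
results in memory.  All numeric outputs are deterministic for a given input
and configuration; re-running with the parameters stored in the run log
reproduces them exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np
from skimage.filters import threshold_multiotsu

from . import __version__
from .io import read_stack, sha256_of_file, write_mask, write_stack
from .mesh import SurfaceMesh, marching_cubes, save_mesh, taubin_smooth
from .phantom import split_into_sections
from .preprocess import correct_stack
from .quantify import (
    AnovaResult,
    SectionSummary,
    SliceQuantRecord,
    StageProjection,
    compare_sections_anova,
    quantify_stack,
    records_to_frame,
    stage_projection,
    summarize_sections,
    write_stage_projection_png,
)
from .segment import SegmentationMasks, calibrate_threshold, fit_roi, segment_scaffold, segment_tissue
from .stack import CircularROI, ImageStack

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "PipelineError"]

# fraction of ROI pixels that must be scaffold for a slice to count as
# "informative" when deriving the section split automatically
_INFORMATIVE_SCAFFOLD_FRACTION = 0.005


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass
class PipelineConfig:
    """Every tunable of the processing sequence, in one auditable record.

    Defaults follow the published parameters: background structuring-element
    radius 9 px, median radius 2 px, mask opening radius 2 px, false-positive
    tolerance 0.1% of pore pixels, reference slice = last slice.
    """

    se_radius: int = 9
    median_radius: int = 2
    opening_radius: int = 2
    reference_slice: int = -1
    roi: Union[CircularROI, str] = "auto"
    tissue_threshold: Union[float, str] = "calibrate"
    scaffold_threshold: Union[float, str] = "auto"
    fp_tolerance: float = 0.001
    section_boundaries: Union[Mapping[str, Tuple[int, int]], str] = "auto"
    taubin_lambda: float = 0.5
    taubin_mu: float = -0.53
    taubin_iterations: int = 10
    mesh_factor_scaffold: int = 1
    mesh_factor_tissue: int = 2
    seed: int = 0
    output_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        for name in ("se_radius", "median_radius", "opening_radius"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.fp_tolerance <= 1.0:
            raise ValueError("fp_tolerance must be in (0, 1]")
        if isinstance(self.section_boundaries, Mapping):
            ranges = list(self.section_boundaries.items())
            for i, (a, (lo, hi)) in enumerate(ranges):
                for b, (lo2, hi2) in ranges[i + 1 :]:
                    if lo <= hi2 and lo2 <= hi:
                        raise ValueError(f"sections {a!r} and {b!r} overlap")

    def to_jsonable(self) -> Dict:
        d = dataclasses.asdict(self)
        if isinstance(self.roi, CircularROI):
            d["roi"] = dataclasses.asdict(self.roi)
        d["output_dir"] = str(self.output_dir) if self.output_dir else None
        if isinstance(self.section_boundaries, Mapping):
            d["section_boundaries"] = {k: list(v) for k, v in self.section_boundaries.items()}
        return d


@dataclass
class PipelineResult:
    corrected: ImageStack
    masks: SegmentationMasks
    records: List[SliceQuantRecord]
    summaries: List[SectionSummary]
    anova: Optional[AnovaResult]
    projections: Dict[str, StageProjection]
    tissue_mesh: SurfaceMesh
    scaffold_mesh: SurfaceMesh
    sections: Dict[str, Tuple[int, int]]
    run_log: Dict
    output_dir: Optional[Path] = None


def _stage(tag: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{tag}] {exc}") from exc

        return wrapped

    return deco


def _auto_scaffold_threshold(stack: ImageStack, roi: CircularROI) -> float:
    """Lower multi-Otsu boundary of the mid-stack ROI histogram: separates
    the dark scaffold class from liquid."""
    mid = stack.data[stack.n_slices // 2]
    vals = mid[roi.mask(stack.shape[1:])].astype(float)
    thresholds = threshold_multiotsu(vals, classes=3)
    return float(thresholds[0])


def _auto_sections(
    scaffold_mask: np.ndarray, roi_px: int
) -> Dict[str, Tuple[int, int]]:
    per_slice = scaffold_mask.reshape(scaffold_mask.shape[0], -1).sum(axis=1)
    informative = np.flatnonzero(per_slice >= _INFORMATIVE_SCAFFOLD_FRACTION * roi_px)
    if informative.size < 3:
        raise ValueError(
            "cannot derive sections automatically: fewer than 3 slices contain scaffold"
        )
    return split_into_sections(int(informative[0]), int(informative[-1]))


def run_pipeline(
    sample_path,
    bare_path=None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full processing sequence on one sample scan.

    Stages: read -> background correction + median denoise -> scaffold and
    tissue segmentation (tissue threshold calibrated from the bare scan when
    requested) -> per-slice quantification -> section summaries + ANOVA ->
    per-section 4-stage projections -> surface meshes.  When
    ``config.output_dir`` is set, all intermediates, tables, projections,
    meshes and a JSON run log are written there.
    """
    config = config or PipelineConfig()
    sample_path = Path(sample_path)

    read = _stage("read")(lambda p: read_stack(p))
    sample = read(sample_path)
    bare = read(Path(bare_path)) if bare_path is not None else None
    if config.tissue_threshold == "calibrate" and bare is None:
        raise PipelineError("[read] tissue_threshold='calibrate' requires a bare-scaffold stack")

    roi = _stage("roi")(fit_roi)(sample, None if config.roi == "auto" else config.roi)
    roi2d = roi.mask(sample.shape[1:])

    correct = _stage("correct")(correct_stack)
    corrected, background = correct(
        sample, config.reference_slice, config.se_radius, config.median_radius
    )

    seg = _stage("segment")
    if config.scaffold_threshold == "auto":
        scaffold_thr = seg(_auto_scaffold_threshold)(sample, roi)
    else:
        scaffold_thr = float(config.scaffold_threshold)
    scaffold_mask = seg(segment_scaffold)(sample, roi, scaffold_thr)

    if config.tissue_threshold == "calibrate":
        bare_corrected, _ = correct(
            bare, config.reference_slice, config.se_radius, config.median_radius
        )
        bare_scaffold = seg(segment_scaffold)(bare, roi, scaffold_thr)
        tissue_thr = seg(calibrate_threshold)(
            bare_corrected, roi, bare_scaffold, config.fp_tolerance, config.opening_radius
        )
    else:
        tissue_thr = float(config.tissue_threshold)

    tissue_mask = seg(segment_tissue)(corrected, roi, tissue_thr, config.opening_radius)
    # tissue and scaffold are thresholded on different images; enforce the
    # disjointness contract explicitly
    tissue_mask &= ~scaffold_mask
    masks = SegmentationMasks(
        tissue_mask=tissue_mask,
        scaffold_mask=scaffold_mask,
        roi_mask=roi2d,
        tissue_threshold=tissue_thr,
        scaffold_threshold=scaffold_thr,
    )
    assert not (masks.tissue_mask & masks.scaffold_mask).any()

    quant = _stage("quantify")
    records = quant(quantify_stack)(tissue_mask, scaffold_mask, roi2d)
    if config.section_boundaries == "auto":
        sections = quant(_auto_sections)(scaffold_mask, int(roi2d.sum()))
    else:
        sections = dict(config.section_boundaries)
    summaries = quant(summarize_sections)(records, sections)
    by_id = {r.slice_id: r for r in records}
    groups = {
        name: [by_id[i].tissue_pct for i in range(lo, hi + 1) if i in by_id]
        for name, (lo, hi) in sections.items()
    }
    anova = None
    if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
        anova = quant(compare_sections_anova)(groups)
    projections = {
        name: quant(stage_projection)(tissue_mask[lo : hi + 1])
        for name, (lo, hi) in sections.items()
    }

    mesher = _stage("mesh")
    spacing = sample.spacing
    scaffold_mesh = mesher(marching_cubes)(
        scaffold_mask, config.mesh_factor_scaffold, spacing, label="scaffold"
    )
    tissue_mesh = mesher(marching_cubes)(
        tissue_mask, config.mesh_factor_tissue, spacing, label="tissue"
    )
    smooth = mesher(taubin_smooth)
    if not scaffold_mesh.is_empty:
        scaffold_mesh = smooth(
            scaffold_mesh, config.taubin_lambda, config.taubin_mu, config.taubin_iterations
        )
    if not tissue_mesh.is_empty:
        tissue_mesh = smooth(
            tissue_mesh, config.taubin_lambda, config.taubin_mu, config.taubin_iterations
        )

    run_log = {
        "scaffoldmri_version": __version__,
        "inputs": {
            "sample": {"path": str(sample_path), "sha256": sha256_of_file(sample_path)},
            "bare": (
                {"path": str(bare_path), "sha256": sha256_of_file(bare_path)}
                if bare_path is not None
                else None
            ),
        },
        "config": config.to_jsonable(),
        "roi": {"center_x": roi.center_x, "center_y": roi.center_y, "radius": roi.radius},
        "reference_slice": background.reference_slice_index,
        "tissue_threshold": tissue_thr,
        "scaffold_threshold": scaffold_thr,
        "sections": {k: list(v) for k, v in sections.items()},
        "seed": config.seed,
    }

    result = PipelineResult(
        corrected=corrected,
        masks=masks,
        records=records,
        summaries=summaries,
        anova=anova,
        projections=projections,
        tissue_mesh=tissue_mesh,
        scaffold_mesh=scaffold_mesh,
        sections=sections,
        run_log=run_log,
        output_dir=config.output_dir,
    )
    if config.output_dir is not None:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_stack(result.corrected, out / "corrected.tif")
    write_mask(result.masks.tissue_mask, out / "tissue_mask.tif")
    write_mask(result.masks.scaffold_mask, out / "scaffold_mask.tif")

    frame = records_to_frame(result.records)
    frame.to_csv(out / "slice_quant.csv", index=False, float_format="%.6f")
    rows = []
    for s in result.summaries:
        rows.append(
            {
                "section": s.section,
                "first_slice": s.slice_range[0],
                "last_slice": s.slice_range[1],
                "n_slices": s.n_slices,
                "mean_pct": s.mean_pct,
                "sd_pct": s.sd_pct,
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "section_summary.csv", index=False, float_format="%.6f")

    if result.anova is not None:
        anova_doc = {
            "f_stat": result.anova.f_stat,
            "p_value": result.anova.p_value,
            "pairwise": [dataclasses.asdict(c) for c in result.anova.comparisons],
        }
        (out / "anova.json").write_text(json.dumps(anova_doc, indent=2, sort_keys=True) + "\n")

    for name, proj in result.projections.items():
        write_stage_projection_png(proj, out / f"projection_{name}.png")

    for m, fname in ((result.tissue_mesh, "tissue.ply"), (result.scaffold_mesh, "scaffold.ply")):
        if not m.is_empty:
            save_mesh(m, out / fname)

    (out / "run_log.json").write_text(json.dumps(result.run_log, indent=2, sort_keys=True) + "\n")
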