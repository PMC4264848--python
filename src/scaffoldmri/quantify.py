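"""Quantitative outputs: per-slice records, section statistics, projections.

The central quantity is the tissue percentage per slice,

    tissue_pct = 100 * tissue_px / pore_px,      pore_px = roi_px - scaffold_px,

i.e. tissue as a share of the *available pore volume* rather than of the
whole ROI, so a denser scaffold does not dilute the number.  Slices are
grouped into top/middle/bottom sections summarized as mean +/- sample SD and
compared by one-way ANOVA with Bonferroni-adjusted pairwise t-tests.  Per
section, the binary tissue stack collapses into a 2D "4-stage" projection
counting, for every pixel, in how many slices it was classified tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SliceQuantRecord",
    "SectionSummary",
    "StageProjection",
    "AnovaResult",
    "PairwiseComparison",
    "FullyOccludedSliceError",
    "quantify_slice",
    "quantify_stack",
    "records_to_frame",
    "summarize_sections",
    "compare_sections_anova",
    "significance_stars",
    "stage_projection",
    "write_stage_projection_png",
]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class FullyOccludedSliceError(ValueError):
    """Raised when a slice has no pore pixels (ROI fully scaffold)."""


@dataclass(frozen=True)
class SliceQuantRecord:
    """One row of the per-slice table (pixel counts inside the ROI)."""

    slice_id: int
    tissue_px: int
    scaffold_px: int
    pore_px: int
    roi_px: int
    tissue_pct: float


@dataclass(frozen=True)
class SectionSummary:
    section: str
    slice_range: Tuple[int, int]
    n_slices: int
    mean_pct: float
    sd_pct: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    p_raw: float
    p_adjusted: float
    stars: str


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float
    comparisons: Tuple[PairwiseComparison, ...]


@dataclass
class StageProjection:
    counts: np.ndarray  # per-pixel number of slices classified tissue
    stages: np.ndarray  # integers 0..4
    n_slices: int
    bin_edges: Tuple[int, int, int, int]


def quantify_slice(
    tissue_slice: np.ndarray,
    scaffold_slice: np.ndarray,
    roi_mask: np.ndarray,
    slice_id: int = 0,
) -> SliceQuantRecord:
    """Count tissue/scaffold/pore pixels of one slice inside the ROI."""
    roi_px = int(roi_mask.sum())
    scaffold_px = int((scaffold_slice & roi_mask).sum())
    pore_px = roi_px - scaffold_px
    if pore_px == 0:
        raise FullyOccludedSliceError(
            f"slice {slice_id}: no pore pixels (ROI fully classified scaffold)"
        )
    tissue_px = int((tissue_slice & roi_mask & ~scaffold_slice).sum())
    return SliceQuantRecord(
        slice_id=slice_id,
        tissue_px=tissue_px,
        scaffold_px=scaffold_px,
        pore_px=pore_px,
        roi_px=roi_px,
        tissue_pct=100.0 * tissue_px / pore_px,
    )


def quantify_stack(
    tissue_mask: np.ndarray,
    scaffold_mask: np.ndarray,
    roi_mask: np.ndarray,
) -> List[SliceQuantRecord]:
    return [
        quantify_slice(tissue_mask[i], scaffold_mask[i], roi_mask, slice_id=i)
        for i in range(tissue_mask.shape[0])
    ]


def records_to_frame(records: Sequence[SliceQuantRecord]) -> pd.DataFrame:
    """Per-slice table shaped like the published supplementary table."""
    return pd.DataFrame(
        {
            "slice_id": [r.slice_id for r in records],
            "tissue_px": [r.tissue_px for r in records],
            "scaffold_px": [r.scaffold_px for r in records],
            "pore_px": [r.pore_px for r in records],
            "roi_px": [r.roi_px for r in records],
            "tissue_pct": [r.tissue_pct for r in records],
        }
    )


def summarize_sections(
    records: Sequence[SliceQuantRecord],
    boundaries: Mapping[str, Tuple[int, int]],
) -> List[SectionSummary]:
    """Mean and sample (n-1) standard deviation of tissue_pct per section."""
    by_id = {r.slice_id: r for r in records}
    ranges = list(boundaries.items())
    for i, (name, (lo, hi)) in enumerate(ranges):
        if hi < lo:
            raise ValueError(f"section {name!r}: empty slice range {lo}..{hi}")
        for other, (lo2, hi2) in ranges[i + 1 :]:
            if lo <= hi2 and lo2 <= hi:
                raise ValueError(f"sections {name!r} and {other!r} overlap")
    out = []
    for name, (lo, hi) in ranges:
        vals = [by_id[i].tissue_pct for i in range(lo, hi + 1) if i in by_id]
        if not vals:
            raise ValueError(f"section {name!r}: no quantified slices in {lo}..{hi}")
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out.append(
            SectionSummary(
                section=name,
                slice_range=(lo, hi),
                n_slices=len(vals),
                mean_pct=float(arr.mean()),
                sd_pct=sd,
            )
        )
    return out


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def compare_sections_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA across sections with Bonferroni-adjusted pairwise t-tests.

    Pairwise p-values are two-sample pooled-variance t-tests multiplied by
    the number of comparisons (capped at 1).  Degenerate all-identical input
    returns F = 0, p = 1 by convention.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    for n, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"group {n!r} needs at least 2 values")
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0.0:
        comparisons = tuple(
            PairwiseComparison(a, b, 1.0, 1.0, "ns")
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        )
        return AnovaResult(f_stat=0.0, p_value=1.0, comparisons=comparisons)
    f_stat, p_value = stats.f_oneway(*arrays)
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    m = len(pairs)
    comparisons = []
    for i, j in pairs:
        if np.ptp(np.concatenate([arrays[i], arrays[j]])) == 0.0:
            p_raw = 1.0
        else:
            p_raw = float(stats.ttest_ind(arrays[i], arrays[j], equal_var=True).pvalue)
        p_adj = min(1.0, p_raw * m)
        comparisons.append(
            PairwiseComparison(names[i], names[j], p_raw, p_adj, significance_stars(p_adj))
        )
    return AnovaResult(f_stat=float(f_stat), p_value=float(p_value), comparisons=tuple(comparisons))


def stage_projection(tissue_mask_section: np.ndarray) -> StageProjection:
    """Collapse a binary tissue stack into the 4-stage 2D projection.

    Counts of 1..n_slices are split into four equal-width bins with upper
    edges ceil(k*n/4); stage 0 is reserved for pixels never classified
    tissue, and a pixel classified tissue in every slice always reaches
    stage 4.
    """
    if tissue_mask_section.ndim != 3 or tissue_mask_section.shape[0] < 1:
        raise ValueError("need a (n_slices, ny, nx) binary stack with n_slices >= 1")
    n = tissue_mask_section.shape[0]
    counts = tissue_mask_section.astype(np.int64).sum(axis=0)
    edges = tuple(math.ceil(k * n / 4) for k in (1, 2, 3, 4))
    stages = np.searchsorted(np.asarray(edges), counts, side="left") + 1
    stages[counts == n] = 4  # degenerate small n: the full count is stage 4
    stages[counts == 0] = 0
    return StageProjection(counts=counts, stages=stages.astype(np.uint8), n_slices=n, bin_edges=edges)


# black background, then light-to-dark warm ramp for stages 1..4
_STAGE_PALETTE = [(0, 0, 0), (255, 255, 178), (254, 204, 92), (253, 141, 60), (227, 26, 28)]


def write_stage_projection_png(projection: StageProjection, path) -> None:
    """Write the stage map as an indexed-color PNG with a 5-entry palette."""
    from PIL import Image

    img = Image.fromarray(projection.stages, mode="P")
    palette: List[int] = []
    for rgb in _STAGE_PALETTE:
        palette.extend(rgb)
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(path)
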