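"""Habitat composition summaries, longitudinal comparison, Spie-chart geometry.

A habitat summary reports, per class, the voxel count, absolute volume,
volume fraction of the VOI, and the mean ADC over that class's voxels. The
fat class's mean ADC is computed but flagged non-interpretable: fat-suppressed
diffusion imaging leaves mostly noise there. The Spie chart encodes the
volume fraction as each segment's angle (fraction x 360 degrees) and the
class mean ADC as its radius; a post-treatment chart can carry the
pre-treatment radii as dashed reference arcs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifiers import HabitatMap
from .training_data import ALL_CLASS_IDS, HABITAT_CLASSES
from .volumes_io import MaskVolume, ParameterVolume, Quantity, check_alignment

__all__ = [
    "HabitatSummary",
    "LongitudinalComparison",
    "SpieSegment",
    "summarize_habitats",
    "spie_geometry",
    "compare_timepoints",
    "export_overlay",
    "plot_spie_chart",
]

#: Class whose ADC is noise-corrupted on fat-suppressed DWI.
FAT_CLASS_ID = 4


@dataclass
class HabitatSummary:
    """Per-class composition of one study's VOI."""

    voxel_counts: dict          # class id -> count
    volumes_mm3: dict           # class id -> mm^3
    fractions: dict             # class id -> fraction of VOI, sums to 1
    mean_adc: dict              # class id -> mm^2/s (NaN where class empty)
    adc_interpretable: dict     # class id -> bool (False for fat)
    total_volume_mm3: float
    total_voxels: int
    voxel_volume_mm3: float

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for c in sorted(self.voxel_counts):
            rows.append({
                "class_id": c,
                "name": HABITAT_CLASSES[c].name,
                "voxel_count": self.voxel_counts[c],
                "volume_mm3": self.volumes_mm3[c],
                "fraction": self.fractions[c],
                "mean_adc_mm2_s": self.mean_adc[c],
                "adc_interpretable": self.adc_interpretable[c],
            })
        return pd.DataFrame(rows)


@dataclass
class LongitudinalComparison:
    """Per-class and whole-tumor changes between two timepoints."""

    delta_fraction: dict        # class id -> post - pre fraction
    delta_mean_adc: dict        # class id -> mm^2/s (NaN if undefined in a timepoint)
    volume_change_pct: dict     # class id -> 100 * (V_post - V_pre) / V_pre
    total_volume_change_pct: float

    def as_frame(self) -> pd.DataFrame:
        rows = [{"class_id": c,
                 "delta_fraction": self.delta_fraction[c],
                 "delta_mean_adc_mm2_s": self.delta_mean_adc[c],
                 "volume_change_pct": self.volume_change_pct[c]}
                for c in sorted(self.delta_fraction)]
        return pd.DataFrame(rows)


@dataclass
class SpieSegment:
    class_id: int
    angle_deg: float            # 360 x volume fraction
    radius: float               # mean ADC on the chart's radial scale
    color: str
    reference_radius: float | None = None  # dashed pre-treatment arc
    adc_interpretable: bool = True


def summarize_habitats(labels: HabitatMap, adc: ParameterVolume,
                       voi: MaskVolume) -> HabitatSummary:
    """Quantify habitat composition over a VOI.

    Fractions are voxel counts over the VOI cardinality; mean ADC averages
    the valid native-unit ADC voxels of each class (voxels with invalid ADC
    still count toward volume). ADC must be in native mm^2/s.
    """
    if adc.quantity != Quantity.ADC:
        raise ValueError(f"ADC volume required (native units), got {adc.quantity!r}")
    report = check_alignment(volumes=[adc], masks=[voi])
    if not report.ok:
        raise ValueError("inputs not aligned: " + "; ".join(report.mismatches))
    sel = voi.membership & labels.valid
    n_total = int(sel.sum())
    if n_total == 0:
        raise ValueError("VOI contains no labeled voxels")
    vox_vol = labels.grid.voxel_volume_mm3

    counts, volumes, fractions, means, interp = {}, {}, {}, {}, {}
    for c in ALL_CLASS_IDS:
        in_class = sel & (labels.labels == c)
        n = int(in_class.sum())
        counts[c] = n
        volumes[c] = n * vox_vol
        fractions[c] = n / n_total
        adc_sel = in_class & adc.valid
        means[c] = float(adc.values[adc_sel].mean()) if adc_sel.any() else float("nan")
        interp[c] = c != FAT_CLASS_ID
    return HabitatSummary(voxel_counts=counts, volumes_mm3=volumes,
                          fractions=fractions, mean_adc=means,
                          adc_interpretable=interp,
                          total_volume_mm3=n_total * vox_vol,
                          total_voxels=n_total, voxel_volume_mm3=vox_vol)


def spie_geometry(summary: HabitatSummary,
                  reference: HabitatSummary | None = None) -> list[SpieSegment]:
    """Segment angles and radii for a Spie chart of a habitat summary.

    Radii are normalized by the largest interpretable class mean ADC across
    the summary and (if given) the reference, so paired pre/post charts share
    one radial scale; the reference summary's radii ride along for dashed
    overlay arcs.
    """
    pool = [summary] + ([reference] if reference is not None else [])
    scale_candidates = [
        s.mean_adc[c] for s in pool for c in s.mean_adc
        if s.adc_interpretable[c] and np.isfinite(s.mean_adc[c])
    ]
    scale = max(scale_candidates) if scale_candidates else 1.0
    if scale <= 0:
        scale = 1.0
    segments = []
    for c in sorted(summary.fractions):
        adc_c = summary.mean_adc[c]
        radius = adc_c / scale if np.isfinite(adc_c) else 0.0
        ref_radius = None
        if reference is not None:
            ref_adc = reference.mean_adc.get(c, float("nan"))
            ref_radius = ref_adc / scale if np.isfinite(ref_adc) else None
        segments.append(SpieSegment(
            class_id=c,
            angle_deg=360.0 * summary.fractions[c],
            radius=radius,
            color=HABITAT_CLASSES[c].color,
            reference_radius=ref_radius,
            adc_interpretable=summary.adc_interpretable[c],
        ))
    return segments


def compare_timepoints(pre: HabitatSummary, post: HabitatSummary) -> LongitudinalComparison:
    """Changes between two summaries of the same class taxonomy."""
    if set(pre.fractions) != set(post.fractions):
        raise ValueError("summaries cover different class taxonomies")
    if pre.total_volume_mm3 <= 0:
        raise ValueError("pre-treatment VOI volume is zero")
    delta_frac, delta_adc, vol_change = {}, {}, {}
    for c in pre.fractions:
        delta_frac[c] = post.fractions[c] - pre.fractions[c]
        delta_adc[c] = post.mean_adc[c] - pre.mean_adc[c]  # NaN-propagating
        v_pre = pre.volumes_mm3[c]
        vol_change[c] = (100.0 * (post.volumes_mm3[c] - v_pre) / v_pre
                         if v_pre > 0 else float("nan"))
    total = 100.0 * (post.total_volume_mm3 - pre.total_volume_mm3) / pre.total_volume_mm3
    return LongitudinalComparison(delta_fraction=delta_frac, delta_mean_adc=delta_adc,
                                  volume_change_pct=vol_change,
                                  total_volume_change_pct=total)


def export_overlay(labels: HabitatMap,
                   anatomical: ParameterVolume | None = None) -> tuple[ParameterVolume, dict]:
    """Label volume plus a JSON-serializable class->color legend.

    The legend always lists all five classes; classes absent from the map
    simply have no voxels in the overlay. An anatomical volume, if supplied,
    must share the grid (no resampling is performed).
    """
    if anatomical is not None:
        report = check_alignment(volumes=[anatomical],
                                 masks=[MaskVolume(grid=labels.grid,
                                                   membership=labels.valid,
                                                   label="overlay")])
        if not report.ok:
            raise ValueError("anatomical volume not aligned: "
                             + "; ".join(report.mismatches))
    overlay = ParameterVolume(grid=labels.grid,
                              values=labels.labels.astype(float),
                              quantity=Quantity.NORMALIZED,
                              valid=np.ones(labels.labels.shape, dtype=bool),
                              name="habitat-overlay")
    legend = {str(c): {"name": HABITAT_CLASSES[c].name,
                       "color": HABITAT_CLASSES[c].color}
              for c in ALL_CLASS_IDS}
    return overlay, legend


def plot_spie_chart(segments: list[SpieSegment], path=None, title: str = ""):
    """Render Spie-chart geometry with matplotlib (wedge per class; dashed
    arcs mark reference radii). Returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    theta = 0.0
    for seg in segments:
        width = np.deg2rad(seg.angle_deg)
        if seg.angle_deg > 0:
            ax.bar(theta + width / 2.0, seg.radius, width=width, bottom=0.0,
                   color=seg.color, edgecolor="black", linewidth=0.5, alpha=0.85)
            if seg.reference_radius is not None:
                arc = np.linspace(theta, theta + width, 32)
                ax.plot(arc, np.full_like(arc, seg.reference_radius),
                        linestyle="--", color="black", linewidth=1.0)
        theta += width
    ax.set_yticklabels([])
    ax.set_xticklabels([])
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def summary_to_json(summary: HabitatSummary, path=None) -> str:
    payload = {
        "total_volume_mm3": summary.total_volume_mm3,
        "total_voxels": summary.total_voxels,
        "voxel_volume_mm3": summary.voxel_volume_mm3,
        "classes": {
            str(c): {
                "name": HABITAT_CLASSES[c].name,
                "voxel_count": summary.voxel_counts[c],
                "volume_mm3": summary.volumes_mm3[c],
                "fraction": summary.fractions[c],
                "mean_adc_mm2_s": (None if not np.isfinite(summary.mean_adc[c])
                                   else summary.mean_adc[c]),
                "adc_interpretable": summary.adc_interpretable[c],
            } for c in sorted(summary.voxel_counts)
        },
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        from pathlib import Path
        Path(path).write_text(text)
    return text
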