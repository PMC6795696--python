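"""Derived parameter maps and feature normalization.

Fat fraction from the two Dixon signal volumes::

    FF = S_fat / (S_fat + S_water) * 100          (percent, in [0, 100])

Fractional enhancement from pre-/post-contrast T1-weighted volumes::

    EF = (S_post - S_pre) / (S_post + S_pre) * 100  (percent, in [-100, 100])

Each voxel's three parameters (ADC, EF, FF) are linearly rescaled to the unit
cube before classification:

    adc_n = ADC / 3e-3 mm^2/s     ef_n = (EF + 100) / 200     ff_n = FF / 100

ADC above 3e-3 mm^2/s is clipped to 1.0 so that every feature stays inside
the domain the classifiers (and the uniform novelty class) were trained on.
Voxels with a zero signal denominator or a negative raw signal are masked
invalid, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volumes_io import MaskVolume, ParameterVolume, Quantity, VoxelGrid, check_alignment

__all__ = [
    "FeatureField",
    "compute_fat_fraction",
    "compute_enhancement_fraction",
    "normalize_features",
    "normalize_adc",
    "normalize_ef",
    "normalize_ff",
    "denormalize_adc",
    "denormalize_ef",
    "denormalize_ff",
]

log = logging.getLogger(__name__)

#: Intrinsic parameter ranges; also the support of the uniform novelty class.
ADC_MAX = 3.0e-3   # mm^2/s
EF_RANGE = (-100.0, 100.0)  # percent
FF_RANGE = (0.0, 100.0)     # percent

FEATURE_NAMES = ("adc_n", "ef_n", "ff_n")


def normalize_adc(adc, clip: bool = True):
    """ADC (mm^2/s) -> unitless [0, 1]; values above 3e-3 clip to 1."""
    x = np.asarray(adc, dtype=float) / ADC_MAX
    return np.clip(x, 0.0, 1.0) if clip else x


def normalize_ef(ef):
    """EF (%) in [-100, 100] -> unitless [0, 1]."""
    return (np.asarray(ef, dtype=float) + 100.0) / 200.0


def normalize_ff(ff):
    """FF (%) in [0, 100] -> unitless [0, 1]."""
    return np.asarray(ff, dtype=float) / 100.0


def denormalize_adc(adc_n):
    return np.asarray(adc_n, dtype=float) * ADC_MAX


def denormalize_ef(ef_n):
    return np.asarray(ef_n, dtype=float) * 200.0 - 100.0


def denormalize_ff(ff_n):
    return np.asarray(ff_n, dtype=float) * 100.0


@dataclass
class FeatureField:
    """Voxel-wise normalized (adc_n, ef_n, ff_n) triples on one grid.

    A voxel is valid only where all three source maps were valid; only valid
    voxels yield feature vectors.
    """

    grid: VoxelGrid
    adc_n: np.ndarray
    ef_n: np.ndarray
    ff_n: np.ndarray
    valid: np.ndarray

    def stack(self) -> np.ndarray:
        """(nx, ny, nz, 3) array in (adc_n, ef_n, ff_n) order."""
        return np.stack([self.adc_n, self.ef_n, self.ff_n], axis=-1)

    def samples(self, mask: MaskVolume | np.ndarray | None = None):
        """Feature rows and their voxel coordinates.

        Returns ``(X, coords)`` where ``X`` is ``(n, 3)`` and ``coords`` the
        matching ``(n, 3)`` integer voxel indices, restricted to valid voxels
        (and to ``mask`` if given), in raster order.
        """
        sel = self.valid
        if mask is not None:
            member = mask.membership if isinstance(mask, MaskVolume) else np.asarray(mask, bool)
            if member.shape != self.valid.shape:
                raise ValueError("mask shape does not match feature field grid")
            sel = sel & member
        coords = np.argwhere(sel)
        X = np.stack([self.adc_n[sel], self.ef_n[sel], self.ff_n[sel]], axis=1)
        return X, coords


def _check_pair(a: ParameterVolume, b: ParameterVolume):
    report = check_alignment(volumes=[a, b])
    if not report.ok:
        raise ValueError("input volumes are not aligned: " + "; ".join(report.mismatches))


def compute_fat_fraction(s_fat: ParameterVolume, s_water: ParameterVolume) -> ParameterVolume:
    """Dixon fat fraction in percent; FF = S_fat/(S_fat+S_water) x 100.

    Voxels with negative signal in either channel, or a zero denominator, are
    masked invalid and their count logged.
    """
    _check_pair(s_fat, s_water)
    fat, water = s_fat.values, s_water.values
    valid = s_fat.valid & s_water.valid
    neg = valid & ((fat < 0) | (water < 0))
    if neg.any():
        log.warning("fat-fraction: masking %d voxels with negative signal", int(neg.sum()))
    valid &= ~neg
    denom = fat + water
    zero = valid & (denom == 0)
    valid &= ~zero
    with np.errstate(divide="ignore", invalid="ignore"):
        ff = fat / denom * 100.0
    return ParameterVolume(grid=s_fat.grid, values=np.where(valid, ff, np.nan),
                           quantity=Quantity.FF, valid=valid, name="FF")


def compute_enhancement_fraction(s_pre: ParameterVolume, s_post: ParameterVolume) -> ParameterVolume:
    """Fractional enhancement in percent; EF = (S_post-S_pre)/(S_post+S_pre) x 100."""
    _check_pair(s_pre, s_post)
    pre, post = s_pre.values, s_post.values
    valid = s_pre.valid & s_post.valid
    neg = valid & ((pre < 0) | (post < 0))
    if neg.any():
        log.warning("enhancement-fraction: masking %d voxels with negative signal",
                    int(neg.sum()))
    valid &= ~neg
    denom = pre + post
    zero = valid & (denom == 0)
    valid &= ~zero
    with np.errstate(divide="ignore", invalid="ignore"):
        ef = (post - pre) / denom * 100.0
    return ParameterVolume(grid=s_pre.grid, values=np.where(valid, ef, np.nan),
                           quantity=Quantity.EF, valid=valid, name="EF")


def normalize_features(adc: ParameterVolume, ef: ParameterVolume,
                       ff: ParameterVolume) -> FeatureField:
    """Build the normalized 3-feature field from tagged ADC/EF/FF maps.

    Raises on a wrong quantity tag: silently normalizing, say, a raw signal
    volume as ADC would corrupt every downstream class boundary.
    """
    expected = {Quantity.ADC: adc, Quantity.EF: ef, Quantity.FF: ff}
    for tag, vol in expected.items():
        if vol.quantity != tag:
            raise ValueError(f"expected a volume tagged {tag!r}, got {vol.quantity!r}")
    report = check_alignment(volumes=[adc, ef, ff])
    if not report.ok:
        raise ValueError("parameter maps are not aligned: " + "; ".join(report.mismatches))
    valid = adc.valid & ef.valid & ff.valid
    return FeatureField(
        grid=adc.grid,
        adc_n=np.where(valid, normalize_adc(adc.values), np.nan),
        ef_n=np.where(valid, normalize_ef(ef.values), np.nan),
        ff_n=np.where(valid, normalize_ff(ff.values), np.nan),
        valid=valid,
    )
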