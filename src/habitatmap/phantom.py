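"""Synthetic multi-parametric studies with known habitat ground truth.

No patient imaging ships with this package, so every pipeline stage is
exercised against phantoms: 3-D studies whose compartments (nested ellipsoids
and pockets) carry designed class-conditional parameter distributions. Each
voxel draws its ADC / EF / FF from its compartment's Gaussian (clipped to the
intrinsic parameter ranges), and the raw Dixon and T1 signal pairs are
synthesized as exact pre-images of the target FF and EF under the ratio
formulas, so the map-computation stage reproduces the designed maps exactly.

Default class settings (a design choice of this package, configurable):

    class 1 enhancing tumor       ADC 0.9e-3  EF 60  FF  5
    class 2 non-enhancing tumor   ADC 1.0e-3  EF  5  FF  5
    class 3 necrotic/cystic       ADC 2.4e-3  EF  5  FF  5
    class 4 fat                   ADC 1.5e-3 (broad/noisy)  EF 0  FF 85

with SDs 0.1e-3 mm^2/s (ADC), 8 % (EF), 4 % (FF); fat's ADC SD is 0.6e-3 to
emulate the noise-corrupted fat signal on fat-suppressed diffusion imaging.
These contrasts mirror the tissue taxonomy: cellular tumor is low-ADC and
split by enhancement, necrosis is high-ADC, fat is high-FF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import parameter_maps as pm
from .classifiers import HabitatMap
from .training_data import LabeledROI, TISSUE_CLASS_IDS, extract_roi_samples
from .volumes_io import MaskVolume, ParameterVolume, Quantity, VoxelGrid

__all__ = [
    "ClassParams",
    "Compartment",
    "PhantomSpec",
    "PhantomStudy",
    "ResponseModel",
    "generate_phantom",
    "generate_longitudinal_pair",
    "place_training_rois",
    "place_training_roi_masks",
    "export_phantom_study",
]

#: Reference total signal used when synthesizing raw pairs (arbitrary units).
_S_TOTAL = 200.0


@dataclass(frozen=True)
class ClassParams:
    """Designed parameter distribution of one tissue class."""

    adc_mean: float   # mm^2/s
    adc_sd: float
    ef_mean: float    # %
    ef_sd: float
    ff_mean: float    # %
    ff_sd: float

    def __post_init__(self):
        if not (0 <= self.adc_mean <= pm.ADC_MAX):
            raise ValueError(f"ADC mean {self.adc_mean} outside [0, {pm.ADC_MAX}]")
        if not (pm.EF_RANGE[0] <= self.ef_mean <= pm.EF_RANGE[1]):
            raise ValueError(f"EF mean {self.ef_mean} outside {pm.EF_RANGE}")
        if not (pm.FF_RANGE[0] <= self.ff_mean <= pm.FF_RANGE[1]):
            raise ValueError(f"FF mean {self.ff_mean} outside {pm.FF_RANGE}")
        if min(self.adc_sd, self.ef_sd, self.ff_sd) <= 0:
            raise ValueError("all SDs must be positive")


DEFAULT_CLASS_PARAMS: dict[int, ClassParams] = {
    1: ClassParams(0.9e-3, 0.1e-3, 60.0, 8.0, 5.0, 4.0),
    2: ClassParams(1.0e-3, 0.1e-3, 5.0, 8.0, 5.0, 4.0),
    3: ClassParams(2.4e-3, 0.1e-3, 5.0, 8.0, 5.0, 4.0),
    4: ClassParams(1.5e-3, 0.6e-3, 0.0, 8.0, 85.0, 4.0),
}

#: Background (non-tumor, outside the VOI) tissue parameters.
BACKGROUND_PARAMS = ClassParams(1.2e-3, 0.15e-3, 10.0, 6.0, 10.0, 4.0)


@dataclass(frozen=True)
class Compartment:
    """One geometric tissue compartment.

    ``kind`` is ``"ellipsoid"`` (center + radii, in voxel units) or
    ``"block"`` (inclusive lo / exclusive hi corner indices). Compartments
    are painted in list order: a later compartment overrides earlier ones
    where they overlap, which is how nested geometries are expressed.
    """

    class_id: int
    kind: str
    center: tuple = ()
    radii: tuple = ()
    lo: tuple = ()
    hi: tuple = ()

    def mask(self, shape) -> np.ndarray:
        if self.kind == "ellipsoid":
            cx, cy, cz = self.center
            rx, ry, rz = self.radii
            x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
            return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0
        if self.kind == "block":
            m = np.zeros(shape, dtype=bool)
            m[self.lo[0]:self.hi[0], self.lo[1]:self.hi[1], self.lo[2]:self.hi[2]] = True
            return m
        raise ValueError(f"unknown compartment kind {self.kind!r}")


def default_compartments(shape=(64, 64, 16)) -> list[Compartment]:
    """Nested default geometry: enhancing rim, non-enhancing mantle, necrotic
    core, plus an off-center fat pocket, all inside one ellipsoidal tumor."""
    cx, cy, cz = shape[0] / 2 - 0.5, shape[1] / 2 - 0.5, shape[2] / 2 - 0.5
    return [
        Compartment(1, "ellipsoid", center=(cx, cy, cz), radii=(26, 26, 7)),
        Compartment(2, "ellipsoid", center=(cx, cy, cz), radii=(16, 16, 5)),
        Compartment(3, "ellipsoid", center=(cx, cy, cz), radii=(8, 8, 3)),
        Compartment(4, "ellipsoid", center=(cx + 17, cy, cz), radii=(7, 7, 4)),
    ]


@dataclass
class PhantomSpec:
    """Everything needed to generate one synthetic study deterministically."""

    shape: tuple = (64, 64, 16)
    spacing: tuple = (2.0, 2.0, 2.0)
    compartments: list = None
    class_params: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PARAMS))
    blur_voxels: float = 0.0     # Gaussian blur SD applied to parameter maps
    label_noise: float = 0.0     # fraction of ground-truth labels flipped
    seed: int = 0

    def __post_init__(self):
        if self.compartments is None:
            self.compartments = default_compartments(self.shape)
        if not (0 <= self.label_noise < 1):
            raise ValueError("label_noise must be in [0, 1)")
        if self.blur_voxels < 0:
            raise ValueError("blur_voxels must be >= 0")
        for c, params in self.class_params.items():
            if not isinstance(params, ClassParams):
                self.class_params[c] = ClassParams(**params)

    def to_json(self, path=None) -> str:
        payload = {
            "shape": list(self.shape), "spacing": list(self.spacing),
            "compartments": [asdict(c) for c in self.compartments],
            "class_params": {str(k): asdict(v) for k, v in self.class_params.items()},
            "blur_voxels": self.blur_voxels, "label_noise": self.label_noise,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PhantomSpec":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        comps = [Compartment(class_id=c["class_id"], kind=c["kind"],
                             center=tuple(c.get("center", ())),
                             radii=tuple(c.get("radii", ())),
                             lo=tuple(c.get("lo", ())), hi=tuple(c.get("hi", ())))
                 for c in payload["compartments"]]
        return cls(shape=tuple(payload["shape"]), spacing=tuple(payload["spacing"]),
                   compartments=comps,
                   class_params={int(k): ClassParams(**v)
                                 for k, v in payload["class_params"].items()},
                   blur_voxels=payload["blur_voxels"],
                   label_noise=payload["label_noise"], seed=payload["seed"])


@dataclass
class PhantomStudy:
    """A generated study: parameter maps, raw signals, VOI, ground truth."""

    adc: ParameterVolume
    ef: ParameterVolume
    ff: ParameterVolume
    s_fat: ParameterVolume
    s_water: ParameterVolume
    s_pre: ParameterVolume
    s_post: ParameterVolume
    voi: MaskVolume
    truth: HabitatMap
    spec: PhantomSpec

    @property
    def grid(self) -> VoxelGrid:
        return self.adc.grid


def _sample_maps(labels, voi, class_params, rng, shape):
    adc = np.empty(shape)
    ef = np.empty(shape)
    ff = np.empty(shape)
    bg = ~voi
    for region, params in [(bg, BACKGROUND_PARAMS)] + [
        (voi & (labels == c), p) for c, p in class_params.items()
    ]:
        n = int(region.sum())
        if n == 0:
            continue
        adc[region] = rng.normal(params.adc_mean, params.adc_sd, n)
        ef[region] = rng.normal(params.ef_mean, params.ef_sd, n)
        ff[region] = rng.normal(params.ff_mean, params.ff_sd, n)
    return adc, ef, ff


def generate_phantom(spec: PhantomSpec) -> PhantomStudy:
    """Generate a study from a spec; deterministic for a fixed seed.

    Raw Dixon / T1 signal pairs are constructed with a fixed total signal so
    that the FF and EF ratio formulas recover the designed maps exactly.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    grid = VoxelGrid(shape=shape, spacing=tuple(spec.spacing))

    labels = np.zeros(shape, dtype=int)
    voi = np.zeros(shape, dtype=bool)
    for comp in spec.compartments:
        if comp.class_id not in spec.class_params:
            raise ValueError(f"compartment class {comp.class_id} has no parameters")
        m = comp.mask(shape)
        labels[m] = comp.class_id
        voi |= m

    adc, ef, ff = _sample_maps(labels, voi, spec.class_params, rng, shape)
    if spec.blur_voxels > 0:
        adc = ndimage.gaussian_filter(adc, spec.blur_voxels)
        ef = ndimage.gaussian_filter(ef, spec.blur_voxels)
        ff = ndimage.gaussian_filter(ff, spec.blur_voxels)
    adc = np.clip(adc, 0.0, pm.ADC_MAX)
    ef = np.clip(ef, *pm.EF_RANGE)
    ff = np.clip(ff, *pm.FF_RANGE)

    if spec.label_noise > 0:
        coords = np.argwhere(voi)
        n_flip = int(round(spec.label_noise * len(coords)))
        picks = rng.choice(len(coords), size=n_flip, replace=False)
        for i in picks:
            x, y, z = coords[i]
            others = [c for c in TISSUE_CLASS_IDS if c != labels[x, y, z]]
            labels[x, y, z] = int(rng.choice(others))

    # exact pre-images: FF = s_fat / (s_fat + s_water) * 100 with fixed total
    s_fat = ff / 100.0 * _S_TOTAL
    s_water = _S_TOTAL - s_fat
    # EF = (s_post - s_pre) / (s_post + s_pre) * 100 with fixed total
    s_post = (1.0 + ef / 100.0) * (_S_TOTAL / 2.0)
    s_pre = _S_TOTAL - s_post

    def vol(values, quantity, name):
        return ParameterVolume(grid=grid, values=values, quantity=quantity, name=name)

    truth = HabitatMap(grid=grid, labels=np.where(voi, labels, 0), valid=voi)
    return PhantomStudy(
        adc=vol(adc, Quantity.ADC, "ADC"),
        ef=vol(ef, Quantity.EF, "EF"),
        ff=vol(ff, Quantity.FF, "FF"),
        s_fat=vol(s_fat, Quantity.SIGNAL, "dixon-fat"),
        s_water=vol(s_water, Quantity.SIGNAL, "dixon-water"),
        s_pre=vol(s_pre, Quantity.SIGNAL, "t1-pre"),
        s_post=vol(s_post, Quantity.SIGNAL, "t1-post"),
        voi=MaskVolume(grid=grid, membership=voi, label="tumor-voi"),
        truth=truth,
        spec=spec,
    )


def place_training_roi_masks(study: PhantomStudy, n_per_class: int = 2,
                             size: int = 7, seed: int = 0,
                             margin: int = 1) -> list[tuple[MaskVolume, int]]:
    """Square in-plane ROI masks placed deep inside each class compartment.

    Candidate centers are found by 2-D erosion of each class's ground-truth
    region with a ``(size + 2*margin)`` square, so every ROI lies fully
    inside its compartment and away from boundaries — emulating how training
    ROIs are drawn far from visible tissue interfaces. Raises if a class
    cannot host the requested number of ROIs.
    """
    rng = np.random.default_rng(seed)
    half = size // 2
    foot = np.ones((size + 2 * margin, size + 2 * margin), dtype=bool)
    masks: list[tuple[MaskVolume, int]] = []
    for c in sorted(set(comp.class_id for comp in study.spec.compartments)):
        region = (study.truth.labels == c) & study.voi.membership
        candidates = []
        for z in range(region.shape[2]):
            eroded = ndimage.binary_erosion(region[:, :, z], structure=foot)
            for x, y in np.argwhere(eroded):
                candidates.append((int(x), int(y), int(z)))
        if len(candidates) < n_per_class:
            raise ValueError(
                f"class {c}: only {len(candidates)} candidate ROI centers for "
                f"{n_per_class} requested ROIs"
            )
        picks = rng.choice(len(candidates), size=n_per_class, replace=False)
        for i, k in enumerate(sorted(int(p) for p in picks)):
            x, y, z = candidates[k]
            mask = np.zeros(region.shape, dtype=bool)
            mask[x - half:x + half + 1, y - half:y + half + 1, z] = True
            masks.append((MaskVolume(grid=study.grid, membership=mask,
                                     label=f"c{c}-r{i}"), c))
    return masks


def place_training_rois(study: PhantomStudy, n_per_class: int = 2, size: int = 7,
                        seed: int = 0, margin: int = 1,
                        patient_id: str = "phantom") -> list[LabeledROI]:
    """Labeled training ROIs extracted at masks from
    :func:`place_training_roi_masks`."""
    from .parameter_maps import normalize_features

    features = normalize_features(study.adc, study.ef, study.ff)
    rois: list[LabeledROI] = []
    for mask, c in place_training_roi_masks(study, n_per_class, size, seed, margin):
        rois.append(extract_roi_samples(features, mask, class_id=c,
                                        roi_id=mask.label, patient_id=patient_id))
    return rois


def export_phantom_study(study: PhantomStudy, out_dir, n_rois_per_class: int = 2,
                         roi_seed: int = 0) -> dict:
    """Write a phantom study to disk in the layout ``run_study`` consumes.

    Emits the raw signal volumes, ADC map, VOI and ground-truth label NIfTIs,
    one mask NIfTI per training ROI, and the ROI sidecar CSV. Returns a dict
    of the written paths.
    """
    import pandas as pd

    from .volumes_io import write_mask, write_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in [("adc", study.adc), ("dixon_fat", study.s_fat),
                      ("dixon_water", study.s_water), ("t1_pre", study.s_pre),
                      ("t1_post", study.s_post), ("ef", study.ef), ("ff", study.ff)]:
        paths[name] = str(write_volume(vol, out_dir / f"{name}.nii.gz"))
    paths["voi"] = str(write_mask(study.voi, out_dir / "voi.nii.gz"))
    truth = ParameterVolume(grid=study.grid, values=study.truth.labels.astype(float),
                            quantity=Quantity.NORMALIZED,
                            valid=np.ones(study.grid.shape, bool), name="truth")
    paths["truth"] = str(write_volume(truth, out_dir / "truth_labels.nii.gz"))

    rows = []
    for mask, c in place_training_roi_masks(study, n_per_class=n_rois_per_class,
                                            seed=roi_seed):
        mask_path = out_dir / f"roi_{mask.label}.nii.gz"
        write_mask(mask, mask_path)
        rows.append({"roi_id": mask.label, "patient_id": "phantom",
                     "timepoint": "pre", "class_id": c, "mask_path": str(mask_path)})
    table_path = out_dir / "rois.csv"
    pd.DataFrame(rows).to_csv(table_path, index=False)
    paths["roi_table"] = str(table_path)
    study.spec.to_json(out_dir / "phantom_spec.json")
    return paths


@dataclass
class ResponseModel:
    """Designed treatment response: class conversions and ADC shifts.

    ``conversions`` maps ``(from_class, to_class) -> fraction`` of the source
    class's voxels that change identity after treatment (converted as one
    spatially contiguous sub-region, the way a responding sub-volume would).
    ``adc_shift`` maps class id -> additive shift of that class's designed
    mean ADC (mm^2/s) post-treatment.
    """

    conversions: dict = field(default_factory=dict)
    adc_shift: dict = field(default_factory=dict)

    def __post_init__(self):
        for (src, dst), frac in self.conversions.items():
            if not (0 <= frac <= 1):
                raise ValueError(f"conversion fraction {frac} outside [0, 1]")
            if src == dst:
                raise ValueError("conversion source and target must differ")


def generate_longitudinal_pair(spec_pre: PhantomSpec, response: ResponseModel,
                               seed: int | None = None
                               ) -> tuple[PhantomStudy, PhantomStudy, dict]:
    """Generate matched pre-/post-treatment studies with designed deltas.

    The post study reuses the pre geometry; each conversion turns the
    contiguous lowest-x sub-region of the source class into the target class,
    and per-class ADC means shift by ``adc_shift``. Returns
    ``(pre, post, designed)`` where ``designed`` records the exact fraction
    deltas and ADC shifts for recovery testing.
    """
    seed = spec_pre.seed if seed is None else seed
    import dataclasses as _dc
    pre = generate_phantom(_dc.replace(spec_pre, seed=seed))

    labels_post = pre.truth.labels.copy()
    voi = pre.voi.membership
    n_voi = int(voi.sum())
    delta_fraction = {c: 0.0 for c in pre.spec.class_params}
    for (src, dst), frac in response.conversions.items():
        coords = np.argwhere((labels_post == src) & voi)
        if len(coords) == 0:
            raise ValueError(f"conversion source class {src} has no voxels")
        n_conv = int(round(frac * len(coords)))
        # lowest-x contiguous sub-region (raster order sorts by x first)
        convert = coords[:n_conv]
        labels_post[tuple(convert.T)] = dst
        delta_fraction[src] -= n_conv / n_voi
        delta_fraction[dst] = delta_fraction.get(dst, 0.0) + n_conv / n_voi

    params_post = {}
    for c, p in pre.spec.class_params.items():
        shift = response.adc_shift.get(c, 0.0)
        shifted = p.adc_mean + shift
        if not (0 <= shifted <= pm.ADC_MAX):
            raise ValueError(f"class {c}: shifted ADC mean {shifted} out of range")
        params_post[c] = ClassParams(shifted, p.adc_sd, p.ef_mean, p.ef_sd,
                                     p.ff_mean, p.ff_sd)

    rng = np.random.default_rng(seed + 1)
    shape = tuple(spec_pre.shape)
    adc, ef, ff = _sample_maps(labels_post, voi, params_post, rng, shape)
    if spec_pre.blur_voxels > 0:
        adc = ndimage.gaussian_filter(adc, spec_pre.blur_voxels)
        ef = ndimage.gaussian_filter(ef, spec_pre.blur_voxels)
        ff = ndimage.gaussian_filter(ff, spec_pre.blur_voxels)
    adc = np.clip(adc, 0.0, pm.ADC_MAX)
    ef = np.clip(ef, *pm.EF_RANGE)
    ff = np.clip(ff, *pm.FF_RANGE)
    s_fat = ff / 100.0 * _S_TOTAL
    s_water = _S_TOTAL - s_fat
    s_post_sig = (1.0 + ef / 100.0) * (_S_TOTAL / 2.0)
    s_pre_sig = _S_TOTAL - s_post_sig

    grid = pre.grid

    def vol(values, quantity, name):
        return ParameterVolume(grid=grid, values=values, quantity=quantity, name=name)

    post = PhantomStudy(
        adc=vol(adc, Quantity.ADC, "ADC"), ef=vol(ef, Quantity.EF, "EF"),
        ff=vol(ff, Quantity.FF, "FF"),
        s_fat=vol(s_fat, Quantity.SIGNAL, "dixon-fat"),
        s_water=vol(s_water, Quantity.SIGNAL, "dixon-water"),
        s_pre=vol(s_pre_sig, Quantity.SIGNAL, "t1-pre"),
        s_post=vol(s_post_sig, Quantity.SIGNAL, "t1-post"),
        voi=MaskVolume(grid=grid, membership=voi, label="tumor-voi"),
        truth=HabitatMap(grid=grid, labels=np.where(voi, labels_post, 0), valid=voi),
        spec=_dc.replace(spec_pre, class_params=params_post, seed=seed + 1),
    )
    designed = {
        "delta_fraction": delta_fraction,
        "delta_mean_adc": {c: response.adc_shift.get(c, 0.0)
                           for c in pre.spec.class_params},
    }
    return pre, post, designed
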