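"""Markov-random-field de-noising of voxel classifications.

The classifier's per-voxel posteriors are combined with a Potts spatial prior
into the labeling energy

    E(l) = sum_v -log max(p_v(l_v), eps)  +  beta * sum_{(v,u) in N} 1[l_v != l_u]

where N is the chosen neighborhood system (8-connected within an axial slice
by default, or 6-connected in 3-D) with each pair counted once, beta >= 0 the
smoothness weight, and eps a small floor keeping the log finite. The energy
is minimized greedily by iterated conditional modes (ICM): starting from the
argmax labels, voxels are swept in fixed raster order and each label set to
the argmin of its local energy (ties toward the lowest class id). Sequential
updates make the energy non-increasing, so the sweep count is finite; the
per-sweep count of changed voxels is reported as a convergence trace.

With the default 2-D neighborhood each axial slice is an independent MRF and
is smoothed separately, matching how the habitat maps are reviewed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifiers import HabitatMap, ProbabilityVolume
from .volumes_io import MaskVolume

__all__ = [
    "MRFConfig",
    "ConvergenceTrace",
    "labeling_energy",
    "icm_denoise",
    "smooth_study",
    "discordant_pair_count",
]

_OFFSETS_2D8 = [(dx, dy, 0) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                if (dx, dy) != (0, 0)]
_OFFSETS_3D6 = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


@dataclass(frozen=True)
class MRFConfig:
    """Smoothing parameters: Potts weight, neighborhood, iteration budget."""

    beta: float = 1.0
    neighborhood: str = "2d8"   # "2d8" (axial 8-connected) or "3d6"
    max_iterations: int = 100
    eps: float = 1e-12          # probability floor inside the log

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.neighborhood not in ("2d8", "3d6"):
            raise ValueError("neighborhood must be '2d8' or '3d6'")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0 < self.eps <= 1e-3):
            raise ValueError("eps must be in (0, 1e-3]")

    @property
    def offsets(self):
        return _OFFSETS_2D8 if self.neighborhood == "2d8" else _OFFSETS_3D6


@dataclass
class ConvergenceTrace:
    """Per-sweep label-change counts; converged iff the trace ends at 0."""

    changes: list = field(default_factory=list)
    converged: bool = False
    energies: list = field(default_factory=list)  # optional per-sweep energy

    @property
    def iterations(self) -> int:
        return len(self.changes)


def _label_indices(labels, class_ids, valid):
    """Map labels to 0-based positions in class_ids; -1 outside the mask."""
    lut = {int(c): i for i, c in enumerate(class_ids)}
    idx = np.full(labels.shape, -1, dtype=int)
    for c, i in lut.items():
        idx[(labels == c) & valid] = i
    if (idx[valid] < 0).any():
        raise ValueError("labels contain a class id absent from the probability volume")
    return idx


def labeling_energy(labels: HabitatMap | np.ndarray, probs: ProbabilityVolume,
                    config: MRFConfig, voi: MaskVolume | np.ndarray | None = None) -> float:
    """Total MRF energy of a labeling: data term plus Potts pairwise term."""
    lab = labels.labels if isinstance(labels, HabitatMap) else np.asarray(labels)
    valid = probs.valid.copy()
    if voi is not None:
        member = voi.membership if isinstance(voi, MaskVolume) else np.asarray(voi, bool)
        valid &= member
    idx = _label_indices(lab, probs.class_ids, valid)
    coords = np.argwhere(valid)
    ix, iy, iz = coords.T
    p = probs.probs[ix, iy, iz, idx[ix, iy, iz]]
    data_term = float(-np.log(np.maximum(p, config.eps)).sum())

    pair_term = float(config.beta) * discordant_pair_count(lab, valid, config)
    return data_term + pair_term


def discordant_pair_count(labels: np.ndarray, valid: np.ndarray,
                          config: MRFConfig) -> int:
    """Neighbor pairs (counted once) whose labels disagree, within the mask."""
    count = 0
    # positive half of each offset pair, so every edge is counted once
    half = [o for o in config.offsets if o > (0, 0, 0)]
    nx, ny, nz = labels.shape
    for dx, dy, dz in half:
        a = labels[max(0, -dx):nx - max(0, dx), max(0, -dy):ny - max(0, dy),
                   max(0, -dz):nz - max(0, dz)]
        b = labels[max(0, dx):nx - max(0, -dx), max(0, dy):ny - max(0, -dy),
                   max(0, dz):nz - max(0, -dz)]
        va = valid[max(0, -dx):nx - max(0, dx), max(0, -dy):ny - max(0, dy),
                   max(0, -dz):nz - max(0, dz)]
        vb = valid[max(0, dx):nx - max(0, -dx), max(0, dy):ny - max(0, -dy),
                   max(0, dz):nz - max(0, -dz)]
        count += int(((a != b) & va & vb).sum())
    return count


def _icm_core(nlp_rows, neighbors, order, init_labels, beta, max_iterations):
    """Sequential ICM over flat voxel lists (pure-python inner loop).

    nlp_rows: list of per-voxel [-log p_c] lists; neighbors: list of
    neighbor-index lists; order: sweep order; init_labels: 0-based labels.
    """
    labels = list(init_labels)
    n_classes = len(nlp_rows[0]) if nlp_rows else 0
    trace = []
    for _ in range(max_iterations):
        changes = 0
        for i in order:
            counts = [0] * n_classes
            deg = 0
            for j in neighbors[i]:
                counts[labels[j]] += 1
                deg += 1
            row = nlp_rows[i]
            best_c, best_cost = 0, None
            for c in range(n_classes):
                cost = row[c] + beta * (deg - counts[c])
                if best_cost is None or cost < best_cost:
                    best_cost, best_c = cost, c
            if best_c != labels[i]:
                labels[i] = best_c
                changes += 1
        trace.append(changes)
        if changes == 0:
            break
    return labels, trace


def icm_denoise(probs: ProbabilityVolume, config: MRFConfig = MRFConfig(),
                voi=None, track_energy: bool = False) -> tuple[HabitatMap, ConvergenceTrace]:
    """Greedy MAP estimate of the MRF labeling by iterated conditional modes.

    Starts at the argmax labels; deterministic given its inputs. When
    ``track_energy`` is set, the global energy is recorded before the first
    sweep and after each sweep (useful for asserting monotonicity).
    """
    valid = probs.valid.copy()
    if voi is not None:
        member = voi.membership if isinstance(voi, MaskVolume) else np.asarray(voi, bool)
        valid &= member
    coords = np.argwhere(valid)
    if coords.shape[0] == 0:
        raise ValueError("no valid voxels to smooth")
    nlp = -np.log(np.maximum(probs.probs, config.eps))

    flat_index = -np.ones(probs.valid.shape, dtype=int)
    flat_index[tuple(coords.T)] = np.arange(coords.shape[0])
    nlp_rows = [nlp[x, y, z].tolist() for x, y, z in coords]
    shape = probs.valid.shape
    neighbors = []
    for x, y, z in coords:
        nb = []
        for dx, dy, dz in config.offsets:
            u, v, w = x + dx, y + dy, z + dz
            if 0 <= u < shape[0] and 0 <= v < shape[1] and 0 <= w < shape[2]:
                j = flat_index[u, v, w]
                if j >= 0:
                    nb.append(int(j))
        neighbors.append(nb)

    init = np.argmin(nlp[tuple(coords.T)], axis=1).tolist()
    order = list(range(coords.shape[0]))  # coords from argwhere = raster order

    energies = []

    def _energy(flat_labels):
        lab = np.zeros(shape, dtype=int)
        lab[tuple(coords.T)] = probs.class_ids[np.asarray(flat_labels)]
        return labeling_energy(lab, probs, config, voi=valid)

    if track_energy:
        energies.append(_energy(init))
        labels_flat = init
        trace_counts: list[int] = []
        for _ in range(config.max_iterations):
            labels_flat, step = _icm_core(nlp_rows, neighbors, order, labels_flat,
                                          config.beta, 1)
            trace_counts.append(step[0])
            energies.append(_energy(labels_flat))
            if step[0] == 0:
                break
    else:
        labels_flat, trace_counts = _icm_core(nlp_rows, neighbors, order, init,
                                              config.beta, config.max_iterations)

    labels = np.zeros(shape, dtype=int)
    labels[tuple(coords.T)] = probs.class_ids[np.asarray(labels_flat)]
    trace = ConvergenceTrace(changes=trace_counts,
                             converged=bool(trace_counts and trace_counts[-1] == 0),
                             energies=energies)
    return HabitatMap(grid=probs.grid, labels=labels, valid=valid), trace


def smooth_study(probs: ProbabilityVolume, voi: MaskVolume,
                 config: MRFConfig = MRFConfig()) -> tuple[HabitatMap, list, dict]:
    """Smooth a whole study; with the 2-D neighborhood each axial slice is an
    independent MRF and contributes its own convergence trace.

    Returns the smoothed map, the list of per-slice traces (one trace total
    for the 3-D neighborhood) and a summary dict with the pooled median
    iteration count and any skipped empty slices.
    """
    if voi.size == 0:
        raise ValueError("VOI mask is empty")
    if config.neighborhood == "3d6":
        habitat, trace = icm_denoise(probs, config, voi=voi)
        return habitat, [trace], {"median_iterations": float(trace.iterations),
                                  "skipped_slices": []}

    shape = probs.valid.shape
    labels = np.zeros(shape, dtype=int)
    valid = np.zeros(shape, dtype=bool)
    traces, skipped = [], []
    for z in range(shape[2]):
        slice_mask = np.zeros(shape, dtype=bool)
        slice_mask[:, :, z] = voi.membership[:, :, z]
        if not (slice_mask & probs.valid).any():
            skipped.append(z)
            continue
        habitat_z, trace_z = icm_denoise(probs, config, voi=slice_mask)
        sel = habitat_z.valid
        labels[sel] = habitat_z.labels[sel]
        valid |= sel
        traces.append(trace_z)
    summary = {
        "median_iterations": float(np.median([t.iterations for t in traces])),
        "skipped_slices": skipped,
        "all_converged": all(t.converged for t in traces),
    }
    return HabitatMap(grid=probs.grid, labels=labels, valid=valid), traces, summary
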