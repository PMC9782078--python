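"""Colon segmentation: thresholding, components, MRF graph cut, fluid growing.

The labeling problem is a two-class (colon-air vs. background) maximum a
posteriori estimate of a Markov random field: minimize

    E(f) = sum_{ij in N} V(f_i, f_j) + sum_i D(f_i)

where the data term D(f_i) is the negative log Gaussian likelihood of the
voxel intensity under the class model of label f_i and the pairwise term is
the Potts penalty lambda * [f_i != f_j] over the 6- or 26-neighborhood.
The exact global optimum of this submodular two-label energy is obtained by
an s-t minimum cut (computed with scipy's max-flow on integer-scaled
capacities).  High-intensity tagged fluid is then attached by region
growing from the air boundary in the direction of gravity, and the colon is
picked out of the air components by size and by rejecting components that
touch the lateral faces of the volume (exterior air).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .volume import CTVolume

LABEL_BACKGROUND, LABEL_AIR, LABEL_FLUID = 0, 1, 2

#: integer scale for float capacities in the max-flow graph (scipy's solver
#: works in int32: cost ceiling x scale must stay well below 2^31)
_CAP_SCALE = float(2 ** 14)
_COST_CEILING = 1e4


class SegmentationFailure(RuntimeError):
    """Raised when no colon-candidate component survives selection."""


@dataclass
class MRFConfig:
    lambda_pairwise: float = 1.0
    neighborhood: int = 6
    air_threshold_hu: float = -800.0
    fluid_threshold_hu: float = 300.0
    min_component_voxels: int = 100

    def __post_init__(self) -> None:
        if self.lambda_pairwise < 0:
            raise ValueError("lambda_pairwise must be >= 0")
        if self.neighborhood not in (6, 26):
            raise ValueError("neighborhood must be 6 or 26")
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")
        if not (np.isfinite(self.air_threshold_hu) and np.isfinite(self.fluid_threshold_hu)):
            raise ValueError("thresholds must be finite")


@dataclass
class IntensityModel:
    """Per-class Gaussian intensity model (HU)."""

    mean_air: float
    sigma_air: float
    mean_background: float
    sigma_background: float

    def __post_init__(self) -> None:
        if self.sigma_air <= 0 or self.sigma_background <= 0:
            raise ValueError("standard deviations must be positive")
        if self.mean_air == self.mean_background:
            raise ValueError("class means must be distinct")

    def data_cost(self, hu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(cost_background, cost_air): negative log Gaussian likelihoods."""
        const = 0.5 * np.log(2 * np.pi)

        def nll(mu, sig):
            return 0.5 * ((hu - mu) / sig) ** 2 + np.log(sig) + const

        return nll(self.mean_background, self.sigma_background), nll(self.mean_air, self.sigma_air)


@dataclass
class LabelVolume:
    """Per-voxel label (background / colon-air / fluid) and component ids."""

    labels: np.ndarray
    component_ids: np.ndarray | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D grid")

    @property
    def air_mask(self) -> np.ndarray:
        return self.labels == LABEL_AIR

    @property
    def fluid_mask(self) -> np.ndarray:
        return self.labels == LABEL_FLUID

    @property
    def colon_mask(self) -> np.ndarray:
        return self.labels != LABEL_BACKGROUND


def _structure(neighborhood: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if neighborhood == 6 else 3)


def threshold_air(volume: CTVolume, config: MRFConfig) -> LabelVolume:
    """Mark voxels below the air threshold as colon-air candidates."""
    labels = np.where(volume.hu < config.air_threshold_hu, LABEL_AIR, LABEL_BACKGROUND)
    return LabelVolume(labels.astype(np.uint8), spacing=volume.spacing)


def label_components(mask: LabelVolume, neighborhood: int = 6) -> LabelVolume:
    """Connected components of the air mask, ids ordered by descending size.

    Component id 0 is background; ids 1..n index components from largest to
    smallest.
    """
    binary = mask.air_mask
    lab, n = ndimage.label(binary, structure=_structure(neighborhood))
    if n == 0:
        return LabelVolume(mask.labels.copy(), np.zeros(binary.shape, dtype=np.int32),
                           mask.spacing)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    order = np.argsort(-sizes, kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1)
    return LabelVolume(mask.labels.copy(), remap[lab], mask.spacing)


def _clipped_gaussian(values: np.ndarray, sigma_floor: float,
                      clip: float = 3.0, iters: int = 10) -> tuple[float, float]:
    """Sigma-clipped mean/std: fits the dominant mode of a class sample.

    The background class mixes soft tissue with bone and tagged fluid;
    iterative 3-sigma clipping keeps the fitted Gaussian on the dominant
    (soft-tissue) mode instead of inflating sigma across all modes, which
    would skew the MRF decision boundary far into the air class.
    """
    mu, sig = float(values.mean()), float(values.std())
    for _ in range(iters):
        keep = np.abs(values - mu) <= clip * max(sig, sigma_floor)
        if keep.sum() < 2:
            break
        mu, sig = float(values[keep].mean()), float(values[keep].std())
    return mu, max(sig, sigma_floor)


def fit_intensity_models(volume: CTVolume, init_labels: LabelVolume,
                         sigma_floor: float = 1.0, pooled_sigma: bool = True) -> IntensityModel:
    """Robust (sigma-clipped) per-label Gaussian fit of HU.

    With ``pooled_sigma`` (default) both classes share the pooled standard
    deviation, putting the decision boundary at the midpoint of the class
    means.  Class-specific widths are heavily asymmetric here (air is far
    tighter than the mixed soft-tissue background), and a heteroscedastic
    boundary slides deep into the partial-volume wall band, systematically
    eroding the lumen; the homoscedastic model avoids that bias.
    """
    air = init_labels.air_mask
    bg = init_labels.labels == LABEL_BACKGROUND
    if air.sum() < 2 or bg.sum() < 2:
        raise ValueError("each label needs at least 2 voxels to fit a model")
    mean_air, sigma_air = _clipped_gaussian(volume.hu[air], sigma_floor)
    mean_bg, sigma_bg = _clipped_gaussian(volume.hu[bg], sigma_floor)
    if pooled_sigma:
        n_a, n_b = air.sum(), bg.sum()
        pooled = float(np.sqrt((n_a * sigma_air ** 2 + n_b * sigma_bg ** 2) / (n_a + n_b)))
        sigma_air = sigma_bg = max(pooled, sigma_floor)
    return IntensityModel(mean_air=mean_air, sigma_air=sigma_air,
                          mean_background=mean_bg, sigma_background=sigma_bg)


def _neighbor_offsets(neighborhood: int) -> list[tuple[int, int, int]]:
    if neighborhood == 6:
        return [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) > (0, 0, 0):
                    offs.append((dz, dy, dx))
    return offs


def _shifted_slices(shape, off):
    sl_a = tuple(slice(max(-o, 0), s - max(o, 0)) for s, o in zip(shape, off))
    sl_b = tuple(slice(max(o, 0), s - max(-o, 0)) for s, o in zip(shape, off))
    return sl_a, sl_b


def mrf_energy(volume: CTVolume, labels: LabelVolume, model: IntensityModel,
               config: MRFConfig) -> float:
    """Evaluate E(f) = Potts pairwise + negative log-likelihood data term."""
    if labels.labels.shape != volume.hu.shape:
        raise ValueError("labels and volume must be congruent")
    is_air = labels.air_mask
    cost_bg, cost_air = model.data_cost(volume.hu)
    energy = float(np.where(is_air, cost_air, cost_bg).sum())
    lam = config.lambda_pairwise
    if lam > 0:
        for off in _neighbor_offsets(config.neighborhood):
            sl_a, sl_b = _shifted_slices(is_air.shape, off)
            energy += lam * float((is_air[sl_a] != is_air[sl_b]).sum())
    return energy


def graphcut_segment(volume: CTVolume, model: IntensityModel,
                     config: MRFConfig) -> LabelVolume:
    """Globally optimal two-label MRF segmentation by s-t minimum cut.

    Voxels on the sink side of the cut take the colon-air label.  The
    terminal capacity toward a label's terminal is the data cost of the
    *other* label, and each neighbor pair gets a Potts n-link of weight
    lambda, so the cut value equals the labeling energy.
    """
    hu = volume.hu
    shape = hu.shape
    n_vox = hu.size
    cost_bg, cost_air = model.data_cost(hu)
    # ceiling keeps capacities inside int32; it binds only where the cost is
    # so large the label is never optimal, leaving the argmin unchanged
    cost_bg = np.minimum(cost_bg, _COST_CEILING)
    cost_air = np.minimum(cost_air, _COST_CEILING)
    lam = config.lambda_pairwise

    src, snk = n_vox, n_vox + 1
    idx = np.arange(n_vox).reshape(shape)
    rows = [np.full(n_vox, src), idx.ravel()]
    cols = [idx.ravel(), np.full(n_vox, snk)]
    # source side = background label: cutting s->i pays D_i(air), i->t pays D_i(bg)
    caps = [cost_air.ravel(), cost_bg.ravel()]
    if lam > 0:
        for off in _neighbor_offsets(config.neighborhood):
            sl_a, sl_b = _shifted_slices(shape, off)
            a = idx[sl_a].ravel()
            b = idx[sl_b].ravel()
            w = np.full(a.size, lam)
            rows.extend([a, b])
            cols.extend([b, a])
            caps.extend([w, w])
    cap_int = np.rint(np.concatenate(caps) * _CAP_SCALE).astype(np.int64)
    graph = sparse.csr_matrix(
        (cap_int, (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_vox + 2, n_vox + 2),
    )
    result = maximum_flow(graph, src, snk)
    residual = graph - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reachable = breadth_first_order(residual, src, directed=True, return_predecessors=False)
    on_source_side = np.zeros(n_vox + 2, dtype=bool)
    on_source_side[reachable] = True
    labels = np.where(on_source_side[:n_vox].reshape(shape), LABEL_BACKGROUND, LABEL_AIR)
    return LabelVolume(labels.astype(np.uint8), spacing=volume.spacing)


def grow_fluid(volume: CTVolume, air_labels: LabelVolume, config: MRFConfig,
               gravity_axis: str = "+y") -> LabelVolume:
    """Attach tagged fluid below air pockets by gravity-directed growing.

    Starting from high-intensity voxels immediately below colon air (in the
    gravity direction), the fluid region grows through voxels above the
    fluid threshold with steps that never move against gravity.
    """
    from .phantom import _GRAVITY_AXES

    if gravity_axis not in _GRAVITY_AXES:
        raise ValueError(f"invalid gravity axis {gravity_axis!r}")
    axis, sign = _GRAVITY_AXES[gravity_axis]
    candidates = volume.hu > config.fluid_threshold_hu
    air = air_labels.air_mask

    # seeds: candidates one step down-gravity from an air voxel
    shifted = np.roll(air, sign, axis=axis)
    edge = [slice(None)] * 3
    edge[axis] = 0 if sign > 0 else -1
    shifted[tuple(edge)] = False
    frontier = candidates & shifted
    fluid = np.zeros_like(candidates)
    lateral_axes = [a for a in range(3) if a != axis]
    while frontier.any():
        fluid |= frontier
        nxt = np.zeros_like(frontier)
        down = np.roll(frontier, sign, axis=axis)
        down[tuple(edge)] = False
        nxt |= down
        for a in lateral_axes:
            for s in (1, -1):
                lat = np.roll(frontier, s, axis=a)
                e = [slice(None)] * 3
                e[a] = 0 if s > 0 else -1
                lat[tuple(e)] = False
                nxt |= lat
        frontier = nxt & candidates & ~fluid
    labels = air_labels.labels.copy()
    labels[fluid] = LABEL_FLUID
    return LabelVolume(labels, air_labels.component_ids, air_labels.spacing)


def select_colon(components: LabelVolume, config: MRFConfig) -> LabelVolume:
    """Keep interior, large-enough air components (plus attached fluid).

    Components touching the volume's lateral faces are exterior air around
    the body and are rejected; components below the size floor are noise.
    Multiple surviving components are all kept (the colon may appear as
    disconnected segments).  Raises :class:`SegmentationFailure` when
    nothing survives.
    """
    if components.component_ids is None:
        raise ValueError("run label_components first")
    ids = components.component_ids
    n = int(ids.max())
    keep = []
    for cid in range(1, n + 1):
        comp = ids == cid
        size = int(comp.sum())
        if size < config.min_component_voxels:
            continue
        touches = (comp[:, 0, :].any() or comp[:, -1, :].any() or
                   comp[:, :, 0].any() or comp[:, :, -1].any())
        if touches:
            continue
        keep.append(cid)
    if not keep:
        raise SegmentationFailure(
            "segmentation failed: no interior air component above the size floor")
    kept_mask = np.isin(ids, keep)
    labels = components.labels.copy()
    labels[(labels == LABEL_AIR) & ~kept_mask] = LABEL_BACKGROUND
    new_ids = np.where(kept_mask, ids, 0).astype(np.int32)
    return LabelVolume(labels, new_ids, components.spacing)


def iou(ground: np.ndarray, predicted: np.ndarray) -> float:
    """Intersection over union |G∩S| / |G∪S|; 1.0 when both masks are empty."""
    ground = np.asarray(ground).astype(bool)
    predicted = np.asarray(predicted).astype(bool)
    if ground.shape != predicted.shape:
        raise ValueError("mask shapes differ")
    union = np.logical_or(ground, predicted).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(ground, predicted).sum() / union)


def segment_colon(volume: CTVolume, config: MRFConfig | None = None,
                  gravity_axis: str = "+y", grow_tagged_fluid: bool = True) -> LabelVolume:
    """Full segmentation pipeline: threshold -> models -> graph cut ->
    components -> colon selection -> gravity fluid growing."""
    config = config or MRFConfig()
    init = threshold_air(volume, config)
    if init.air_mask.sum() < 2 or (~init.air_mask).sum() < 2:
        raise SegmentationFailure("threshold initialization found no usable air region")
    model = fit_intensity_models(volume, init)
    refined = graphcut_segment(volume, model, config)
    comps = label_components(refined, config.neighborhood)
    selected = select_colon(comps, config)
    if grow_tagged_fluid:
        selected = grow_fluid(volume, selected, config, gravity_axis)
    return selected
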