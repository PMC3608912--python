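"""Whole-volume searchlight decoding and second-level group statistics.

A spherical aperture (default radius 9 mm on a 2.5 x 2.5 x 4 mm grid) is
centred on every gray-matter voxel; the radial-vs-concentric decoder runs
inside each aperture with leave-one-run-out cross-validation, and each
voxel's map value is the mean accuracy over all apertures containing it —
equivalent to smoothing the aperture accuracies with a spherical kernel.
Group-level significance is a one-sample t-test of the subject maps against
chance (0.5) with a cluster-extent threshold; the extent threshold is by
default *estimated* from a sign-flip permutation null of the maximum
cluster size, controlling the family-wise rate of spurious clusters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.svm import SVC

from .mvpa import TrialDataset

logger = logging.getLogger(__name__)

__all__ = ["SearchlightMap", "aperture_offsets", "aperture_members",
           "run_searchlight", "group_map", "extract_rois",
           "GroupMapResult"]


def aperture_offsets(radius_mm: float,
                     voxel_size_mm=(2.5, 2.5, 4.0)) -> np.ndarray:
    """Integer voxel offsets whose physical centre distance is <= radius."""
    vs = np.asarray(voxel_size_mm, float)
    ranges = [np.arange(-int(np.floor(radius_mm / v)),
                        int(np.floor(radius_mm / v)) + 1) for v in vs]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    d2 = np.sum((grid * vs) ** 2, axis=1)
    return grid[d2 <= radius_mm ** 2 + 1e-9]


def aperture_members(center, radius_mm: float, voxel_size_mm,
                     mask: np.ndarray) -> np.ndarray:
    """In-mask voxel indices (K, 3) within radius of the centre voxel."""
    center = np.asarray(center, int)
    if not mask[tuple(center)]:
        raise ValueError("aperture centre outside mask")
    pts = center + aperture_offsets(radius_mm, voxel_size_mm)
    ok = np.all((pts >= 0) & (pts < np.array(mask.shape)), axis=1)
    pts = pts[ok]
    return pts[mask[tuple(pts.T)]]


@dataclass
class SearchlightMap:
    """Per-voxel mean decoding accuracy plus aperture bookkeeping."""

    accuracy: np.ndarray               # (X, Y, Z), NaN outside mask
    n_apertures: np.ndarray            # count volume
    mask: np.ndarray
    aperture_radius_mm: float = 9.0
    voxel_size_mm: tuple = (2.5, 2.5, 4.0)
    aperture_accuracy: dict = field(default_factory=dict, repr=False)

    def values(self) -> np.ndarray:
        return self.accuracy[self.mask]

    def to_nifti(self):
        import nibabel as nib

        return nib.Nifti1Image(np.nan_to_num(self.accuracy, nan=0.0),
                               np.diag(list(self.voxel_size_mm) + [1.0]))


def _loro_accuracy(X: np.ndarray, y: np.ndarray, run_id: np.ndarray,
                   C: float = 1.0) -> float:
    """Leave-one-run-out linear-SVM accuracy over all trials."""
    hits = 0
    total = 0
    for r in np.unique(run_id):
        test = run_id == r
        y_train = y[~test]
        if len(set(y_train)) < 2:
            continue
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[~test], y_train)
        hits += int(np.sum(clf.predict(X[test]) == y[test]))
        total += int(test.sum())
    if total == 0:
        raise ValueError("no testable fold")
    return hits / total


def run_searchlight(data: TrialDataset, mask: np.ndarray | None = None,
                    radius_mm: float = 9.0,
                    voxel_size_mm=(2.5, 2.5, 4.0),
                    C: float = 1.0) -> SearchlightMap:
    """Map local category information across the volume.

    ``data`` must carry ``voxel_coords`` (grid indices per pattern column)
    and ``grid_shape``.  No top-N voxel selection is applied inside
    apertures.  Apertures with fewer than 2 voxels are skipped and logged.
    The per-voxel value is the mean over all apertures that include the
    voxel, so the result is independent of the aperture visiting order.
    """
    if data.voxel_coords is None or data.grid_shape is None:
        raise ValueError("dataset lacks voxel coordinates / grid shape")
    if mask is None:
        mask = np.zeros(data.grid_shape, bool)
        mask[tuple(data.voxel_coords.T)] = True
    col_of = {tuple(c): i for i, c in enumerate(map(tuple, data.voxel_coords))}
    stim = data.stimulus_mask()
    y = data.labels[stim].astype(str)
    runs = data.run_id[stim]
    P = data.patterns[stim]
    acc_sum = np.zeros(mask.shape)
    acc_n = np.zeros(mask.shape, int)
    offsets = aperture_offsets(radius_mm, voxel_size_mm)
    shape = np.array(mask.shape)
    n_skipped = 0
    ap_acc = {}
    for center in np.argwhere(mask):
        pts = center + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        pts = pts[mask[tuple(pts.T)]]
        cols = [col_of[tuple(p)] for p in map(tuple, pts) if tuple(p) in col_of]
        if len(cols) < 2:
            n_skipped += 1
            continue
        a = _loro_accuracy(P[:, cols], y, runs, C)
        ap_acc[tuple(center)] = a
        acc_sum[tuple(pts.T)] += a
        acc_n[tuple(pts.T)] += 1
    if n_skipped:
        logger.info("%d aperture(s) skipped (<2 voxels)", n_skipped)
    with np.errstate(invalid="ignore"):
        acc = np.where(acc_n > 0, acc_sum / np.maximum(acc_n, 1), np.nan)
    acc[~mask] = np.nan
    return SearchlightMap(acc, acc_n, mask, radius_mm, tuple(voxel_size_mm),
                          aperture_accuracy=ap_acc)


@dataclass
class GroupMapResult:
    """Second-level t-map, surviving-cluster mask and cluster table."""

    t_map: np.ndarray
    p_map: np.ndarray
    sig_mask: np.ndarray
    clusters: pd.DataFrame
    cluster_threshold: int
    alpha: float


def _cluster_sizes(binary: np.ndarray) -> tuple[np.ndarray, int]:
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n = ndimage.label(binary, structure=structure)
    return labels, n


def _max_cluster(binary: np.ndarray) -> int:
    labels, n = _cluster_sizes(binary)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def group_map(subject_maps, alpha: float = 0.05,
              cluster_min: int | str = "auto", chance: float = 0.5,
              n_permutations: int = 500,
              seed: int | None = None) -> GroupMapResult:
    """One-sample t-test of subject accuracy maps against chance, clustered.

    ``cluster_min='auto'`` estimates the cluster-extent threshold from a
    sign-flip permutation null (flipping each subject's map about chance),
    taking the smallest extent whose family-wise null rate is <= alpha; an
    integer keeps the classical fixed-extent behaviour.  An empty surviving
    set is a valid outcome.
    """
    maps = [m.accuracy if isinstance(m, SearchlightMap) else np.asarray(m)
            for m in subject_maps]
    if len(maps) < 2:
        raise ValueError("need at least 2 subjects")
    mask = np.all([np.isfinite(m) for m in maps], axis=0)
    data = np.stack(maps)                      # (S, X, Y, Z)
    dev = data - chance

    def t_and_p(d):
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(len(d)))
        p = stats.t.sf(t, df=len(d) - 1)       # one-sided: accuracy > chance
        return t, p

    t_map, p_map = t_and_p(dev)
    supra = mask & (p_map < alpha)

    if cluster_min == "auto":
        S = len(maps)
        rng = np.random.default_rng(seed)
        if 2 ** S <= n_permutations:
            signs = np.array(list(itertools.product([1, -1], repeat=S)))
        else:
            signs = rng.choice([1, -1], size=(n_permutations, S))
        null_max = []
        for sv in signs:
            tp, pp = t_and_p(dev * sv[:, None, None, None])
            null_max.append(_max_cluster(mask & (pp < alpha)))
        null_max = np.sort(null_max)
        # smallest extent c with P(max cluster >= c) <= alpha under the null
        cthr = int(np.quantile(null_max, 1 - alpha, method="higher")) + 1
    else:
        cthr = int(cluster_min)

    labels, n = _cluster_sizes(supra)
    rows = []
    sig = np.zeros_like(supra)
    mean_acc = data.mean(axis=0)
    keep = 0
    for lab in range(1, n + 1):
        m = labels == lab
        size = int(m.sum())
        if size < cthr:
            continue
        keep += 1
        sig |= m
        peak_idx = np.unravel_index(np.nanargmax(np.where(m, t_map, -np.inf)),
                                    t_map.shape)
        rows.append({
            "label": keep, "size_voxels": size,
            "peak_x": peak_idx[0], "peak_y": peak_idx[1], "peak_z": peak_idx[2],
            "peak_t": float(t_map[peak_idx]),
            "mean_accuracy": float(mean_acc[m].mean()),
        })
    clusters = pd.DataFrame(
        rows, columns=["label", "size_voxels", "peak_x", "peak_y", "peak_z",
                       "peak_t", "mean_accuracy"])
    return GroupMapResult(t_map, p_map, sig, clusters, cthr, alpha)


def extract_rois(source, mask: np.ndarray | None = None,
                 radius_mm: float = 9.0,
                 voxel_size_mm=(2.5, 2.5, 4.0)) -> list[np.ndarray]:
    """ROI masks from a group result's clusters or a list of coordinates.

    Given a :class:`GroupMapResult`, each surviving cluster becomes one ROI
    (identical voxel sets).  Given a list of voxel coordinates, each ROI is
    the sphere of ``radius_mm`` around the coordinate, restricted to
    ``mask``; a coordinate outside the mask is an error.
    """
    if isinstance(source, GroupMapResult):
        labels, n = _cluster_sizes(source.sig_mask)
        sizes = np.bincount(labels.ravel())[1:] if n else []
        order = np.argsort(sizes)[::-1] if n else []
        return [labels == (int(i) + 1) for i in order]
    if mask is None:
        raise ValueError("coordinate mode requires a mask")
    rois = []
    for coord in source:
        members = aperture_members(coord, radius_mm, voxel_size_mm, mask)
        roi = np.zeros(mask.shape, bool)
        roi[tuple(members.T)] = True
        rois.append(roi)
    return rois
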