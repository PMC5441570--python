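"""Functional-network feature extraction.

Two feature families are extracted per run:

* voxel-level (log-)degrees of a thresholded Pearson correlation graph —
  a link joins two voxels when their correlation strictly exceeds the cutoff
  ``c`` (default 0.7);
* supervoxel-level link weights — all pairwise Pearson correlations between
  block-aggregated time series, used directly as features.

Features may then be z-scored within each acquisition site (``ss_`` types) to
mitigate multi-site batch effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np

from .cohort import CohortSample, RunTimeSeries

__all__ = [
    "FunctionalNetwork",
    "FeatureMatrix",
    "FEATURE_TYPES",
    "correlation_matrix",
    "threshold_network",
    "degrees",
    "log_degree",
    "degrees_thresholded",
    "build_supervoxels",
    "link_weight_features",
    "link_descriptors",
    "n_link_features",
    "site_standardize",
    "extract_features",
]

FEATURE_TYPES = ("degree", "log_degree", "ss_log_degree", "link_weight", "ss_link_weight")
DEFAULT_THRESHOLD = 0.7


def correlation_matrix(ts: np.ndarray, return_flags: bool = False):
    """Pairwise Pearson correlations among the rows of ``ts``.

    Constant rows get correlation 0 with everything (and are flagged); the
    diagonal is forced to 1. Requires at least 3 time points.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a 2-D node x time matrix with >= 3 time points")
    centered = ts - ts.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    if return_flags:
        return corr, constant
    return corr


@dataclass
class FunctionalNetwork:
    """Thresholded correlation graph over a set of grid nodes."""

    node_coords: np.ndarray
    corr: np.ndarray
    threshold: float
    adjacency: np.ndarray

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum()) // 2


def threshold_network(
    corr: np.ndarray,
    c: float = DEFAULT_THRESHOLD,
    node_coords: np.ndarray | None = None,
    absolute: bool = False,
) -> FunctionalNetwork:
    """Binary adjacency: a link where the (signed) correlation strictly exceeds ``c``.

    With ``absolute=True`` the magnitude is compared instead.
    """
    if not -1.0 <= c <= 1.0:
        raise ValueError("threshold must lie in [-1, 1]")
    corr = np.asarray(corr, dtype=float)
    vals = np.abs(corr) if absolute else corr
    adjacency = (vals > c).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    if node_coords is None:
        node_coords = np.arange(corr.shape[0])[:, None]
    return FunctionalNetwork(
        node_coords=np.asarray(node_coords), corr=corr, threshold=float(c), adjacency=adjacency
    )


def degrees(net: FunctionalNetwork) -> np.ndarray:
    """Per-node link counts (adjacency row sums)."""
    return net.adjacency.sum(axis=1).astype(int)


def log_degree(d) -> np.ndarray | float:
    """log10(degree + 1); defined for non-negative integer degrees."""
    arr = np.asarray(d)
    if np.any(arr < 0):
        raise ValueError("degrees must be non-negative")
    out = np.log10(arr + 1.0)
    return float(out) if np.isscalar(d) else out


def degrees_thresholded(
    ts: np.ndarray, c: float = DEFAULT_THRESHOLD, absolute: bool = False, tile: int = 1024
) -> np.ndarray:
    """Node degrees of the thresholded correlation graph, by tiled accumulation.

    Never materializes the full node x node correlation matrix: correlations
    are computed tile-by-tile against the standardized series, so the working
    set is one tile of rows. Equivalent to thresholding the full matrix.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.shape[1] < 3:
        raise ValueError("need >= 3 time points")
    centered = ts - ts.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    constant = norms == 0
    unit = centered / np.where(constant, 1.0, norms)[:, None]
    n = unit.shape[0]
    deg = np.zeros(n, dtype=np.int64)
    for start in range(0, n, tile):
        stop = min(start + tile, n)
        block = unit[start:stop] @ unit.T  # (tile, n)
        if absolute:
            np.abs(block, out=block)
        hits = block > c
        # remove self-correlation and any constant-row artifacts
        idx = np.arange(start, stop)
        hits[np.arange(stop - start), idx] = False
        hits[:, constant] = False
        hits[constant[start:stop], :] = False
        deg[start:stop] += hits.sum(axis=1)
    return deg


def build_supervoxels(
    run: RunTimeSeries, block_dims: Sequence[int], min_fill: float = 0.5
) -> RunTimeSeries:
    """Aggregate the voxel grid into non-overlapping blocks ("supervoxels").

    Blocks tile from grid index (0, 0, 0) and are half-open
    ``[origin, origin + block_dims)``; a supervoxel's series is the mean of its
    in-mask member voxels' series; blocks whose in-mask fraction is below
    ``min_fill`` are dropped. The supervoxel coordinate is the block index
    triple, and the returned mask lives on the block grid.
    """
    if run.mask.sum() == 0:
        raise ValueError("empty mask")
    block_dims = np.asarray(block_dims, dtype=int)
    if block_dims.shape != (3,) or np.any(block_dims < 1):
        raise ValueError("block_dims must be a positive integer triple")
    grid = np.asarray(run.mask.shape)
    sup_dims = tuple(int(x) for x in -(-grid // block_dims))  # ceil division
    block_of_node = run.node_coords // block_dims
    block_flat = np.ravel_multi_index(block_of_node.T, sup_dims)
    n_blocks = int(np.prod(sup_dims))

    sums = np.zeros((n_blocks, run.T))
    counts = np.bincount(block_flat, minlength=n_blocks)
    np.add.at(sums, block_flat, run.series)

    # capacity of each block = number of grid voxels it covers (partial edge
    # blocks have smaller capacity)
    all_coords = np.argwhere(np.ones(tuple(grid), dtype=bool))
    cap = np.bincount(
        np.ravel_multi_index((all_coords // block_dims).T, sup_dims), minlength=n_blocks
    )
    keep = counts / np.maximum(cap, 1) >= min_fill
    keep &= counts > 0
    kept = np.flatnonzero(keep)
    series = sums[kept] / counts[kept, None]
    coords = np.stack(np.unravel_index(kept, sup_dims), axis=1)
    sup_mask = np.zeros(sup_dims, dtype=bool)
    sup_mask[tuple(coords.T)] = True
    return RunTimeSeries(node_coords=coords, series=series, mask=sup_mask)


def n_link_features(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def link_descriptors(n_nodes: int) -> list[tuple[int, int]]:
    """Canonical upper-triangle pair order: lexicographic by (i, j), i < j."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def link_weight_features(corr: np.ndarray) -> np.ndarray:
    """Upper-triangle correlations in canonical (i, j) i<j order."""
    corr = np.asarray(corr)
    if corr.shape[0] < 2:
        raise ValueError("need at least 2 nodes for link features")
    iu, ju = np.triu_indices(corr.shape[0], k=1)
    return corr[iu, ju]


@dataclass
class FeatureMatrix:
    """Samples x features with typed descriptors and sample metadata.

    ``descriptors`` holds, per feature, either a voxel/supervoxel coordinate
    triple (degree-type features) or an unordered node-index pair stored with
    the lower index first (link-type features).
    """

    values: np.ndarray
    feature_type: str
    descriptors: list[tuple]
    samples: list[CohortSample]
    constant_flags: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature_type {self.feature_type!r}")
        if self.values.shape != (len(self.samples), len(self.descriptors)):
            raise ValueError("values shape must be (n_samples, n_features)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def sites(self) -> np.ndarray:
        return np.array([s.site_id for s in self.samples])

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.samples])

    @property
    def is_patient(self) -> np.ndarray:
        return self.groups == "patient"

    @property
    def subject_ids(self) -> np.ndarray:
        return np.array([s.subject_id for s in self.samples])

    def subset_rows(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureMatrix(
            values=self.values[idx],
            feature_type=self.feature_type,
            descriptors=self.descriptors,
            samples=[self.samples[i] for i in idx],
            constant_flags=self.constant_flags,
        )

    def patients_only(self) -> "FeatureMatrix":
        return self.subset_rows(self.is_patient)


def site_standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-score every feature within each site (sample SD, ddof=1).

    Features constant within a site are set to 0 there and flagged. A site
    with a single sample is an error.
    """
    values = fm.values.copy()
    sites = fm.sites
    constant = np.zeros(fm.n_features, dtype=bool)
    for site in np.unique(sites):
        rows = sites == site
        n = int(rows.sum())
        if n < 2:
            raise ValueError(f"site {site!r} has fewer than 2 samples")
        block = values[rows]
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        zero = sd == 0
        constant |= zero
        sd_safe = np.where(zero, 1.0, sd)
        z = (block - mean) / sd_safe
        z[:, zero] = 0.0
        values[rows] = z
    new_type = fm.feature_type if fm.feature_type.startswith("ss_") else "ss_" + fm.feature_type
    if new_type not in FEATURE_TYPES:
        # degree has no ss_ variant in the published feature set; standardize in place
        new_type = fm.feature_type
    return FeatureMatrix(
        values=values,
        feature_type=new_type,
        descriptors=fm.descriptors,
        samples=fm.samples,
        constant_flags=constant,
    )


def _check_consistent_nodes(runs: Sequence[RunTimeSeries]) -> None:
    ref = runs[0].node_coords
    for run in runs[1:]:
        if run.node_coords.shape != ref.shape or not np.array_equal(run.node_coords, ref):
            raise ValueError("inconsistent node sets across runs")


def extract_features(
    runs: Sequence[RunTimeSeries],
    samples: Sequence[CohortSample],
    feature_type: str,
    c: float = DEFAULT_THRESHOLD,
    block_dims: Sequence[int] = (4, 4, 3),
    min_fill: float = 0.5,
    absolute: bool = False,
) -> FeatureMatrix:
    """One feature-matrix row per run sample.

    degree / log_degree / ss_log_degree: thresholded-graph degrees per voxel
    (tiled accumulation); link_weight / ss_link_weight: supervoxel pairwise
    correlations. ``ss_`` types apply within-site standardization.
    """
    if feature_type not in FEATURE_TYPES:
        raise ValueError(f"unknown feature_type {feature_type!r}")
    if len(runs) != len(samples):
        raise ValueError("runs and samples must be aligned")
    runs = list(runs)
    if feature_type in ("degree", "log_degree", "ss_log_degree"):
        _check_consistent_nodes(runs)
        rows = [degrees_thresholded(r.series, c=c, absolute=absolute) for r in runs]
        values = np.asarray(rows, dtype=float)
        if feature_type != "degree":
            values = np.log10(values + 1.0)
        descriptors = [tuple(xyz) for xyz in runs[0].node_coords.tolist()]
        base = "degree" if feature_type == "degree" else "log_degree"
        fm = FeatureMatrix(values, base, descriptors, list(samples))
    else:
        sups = [build_supervoxels(r, block_dims, min_fill=min_fill) for r in runs]
        _check_consistent_nodes(sups)
        rows = [link_weight_features(correlation_matrix(s.series)) for s in sups]
        values = np.asarray(rows, dtype=float)
        descriptors = link_descriptors(sups[0].n_nodes)
        fm = FeatureMatrix(values, "link_weight", descriptors, list(samples))
    if feature_type.startswith("ss_"):
        fm = site_standardize(fm)
    return fm
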