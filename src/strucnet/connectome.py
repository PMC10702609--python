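"""Adjacency-matrix construction from streamline-count connectomes.

One subject's connectome is a symmetric 72×72 matrix of nonnegative integer
streamline counts (zero diagonal).  Analyses run on four scopes, named for
where the tracking seeds sit:

- ``ipsi-L`` / ``ipsi-R``: the 36×36 within-hemisphere submatrix;
- ``contra-L`` / ``contra-R``: the full 72×72 matrix is retained (seeding one
  hemisphere still tracks its within-hemisphere connections), with the 36×36
  cross-hemisphere block extractable for pairwise comparison and display.

Graph construction normalizes weights so the maximum entry is 1 and then
zeroes every weight below the extraction threshold (default 0.001 of the
maximum).  Thresholding after max-normalization is the only order under
which a 0.001 threshold is non-vacuous for integer counts; applying
normalize→threshold twice is a no-op.

Composite seed ROIs (e.g. hippocampus = CA1+CA2+CA3+DG) restrict the graph
to edges incident to the seed regions.  By default the members are collapsed
to a single node whose edge weights are the member row sums; with
``collapse=False`` the full node set is kept (the convention under which
seeded tracts are still mapped to all 36 ipsilateral regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import CompositeROI, RegionAtlas

__all__ = [
    "SCOPES",
    "SubjectConnectome",
    "ConnectomeConfig",
    "AdjacencyMatrix",
    "build_adjacency",
    "seed_restricted_adjacency",
    "total_connections",
    "scope_pairs",
    "scope_count_matrix",
]

SCOPES = ("ipsi-L", "ipsi-R", "contra-L", "contra-R")

GROUPS = ("WT", "KO")


@dataclass(frozen=True)
class SubjectConnectome:
    """One subject's symmetric streamline-count matrix plus group label."""

    subject_id: str
    group: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"counts must be square, got shape {c.shape}")
        if np.any(c < 0):
            raise ValueError("streamline counts must be nonnegative")
        if not np.array_equal(c, c.T):
            raise ValueError("streamline-count matrix must be symmetric")
        if np.any(np.diag(c) != 0):
            raise ValueError("streamline-count matrix must have a zero diagonal")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class ConnectomeConfig:
    """Graph-construction parameters.

    extraction_threshold is a fraction of the maximum weight; weights below
    it (after max-normalization) are removed.
    """

    extraction_threshold: float = 0.001
    normalization: str = "max_one"

    def __post_init__(self) -> None:
        if not 0.0 <= self.extraction_threshold < 1.0:
            raise ValueError("extraction_threshold must be in [0, 1)")
        if self.normalization != "max_one":
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Thresholded, max-normalized weighted undirected graph."""

    weights: np.ndarray
    labels: tuple[str, ...]
    scope: str
    seed_hemisphere: str | None = field(default=None)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.labels), len(self.labels)):
            raise ValueError("weights shape does not match labels")
        object.__setattr__(self, "weights", w)

    def cross_block(self, atlas: RegionAtlas) -> tuple[np.ndarray, list[str], list[str]]:
        """The 36×36 seed-hemisphere × contralateral block of a contra scope.

        Returns (block, row_labels, col_labels); rows are seed-side regions.
        """
        if self.seed_hemisphere is None or len(self.labels) != len(atlas):
            raise ValueError("cross_block is defined for full-atlas contra scopes")
        seed = atlas.hemisphere_indices(self.seed_hemisphere)
        other = atlas.hemisphere_indices("R" if self.seed_hemisphere == "L" else "L")
        block = self.weights[np.ix_(seed, other)]
        names = atlas.abbreviations
        return block, [names[i] for i in seed], [names[j] for j in other]


def _normalize_threshold(weights: np.ndarray, config: ConnectomeConfig) -> np.ndarray:
    w = np.asarray(weights, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    mx = w.max()
    if mx > 0:
        w /= mx
    w[w < config.extraction_threshold] = 0.0
    return w


def _scope_sides(scope: str) -> tuple[str, str]:
    """(laterality, seed hemisphere) for a scope string."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    lat, side = scope.split("-")
    return lat, side


def build_adjacency(
    subject: SubjectConnectome,
    scope: str,
    config: ConnectomeConfig,
    atlas: RegionAtlas,
) -> AdjacencyMatrix:
    """Scope-restricted, max-normalized, thresholded adjacency matrix."""
    lat, side = _scope_sides(scope)
    if subject.counts.shape[0] != len(atlas):
        raise ValueError(
            f"matrix dimension {subject.counts.shape[0]} does not match "
            f"atlas size {len(atlas)}"
        )
    names = atlas.abbreviations
    if lat == "ipsi":
        idx = atlas.hemisphere_indices(side)
        w = subject.counts[np.ix_(idx, idx)].astype(float)
        labels = tuple(names[i] for i in idx)
        seed_hemi = None
    else:  # contra: full graph retained for network analysis
        w = subject.counts.astype(float)
        labels = tuple(names)
        seed_hemi = side
    return AdjacencyMatrix(
        weights=_normalize_threshold(w, config),
        labels=labels,
        scope=scope,
        seed_hemisphere=seed_hemi,
    )


def seed_restricted_adjacency(
    subject: SubjectConnectome,
    roi: CompositeROI,
    laterality: str,
    config: ConnectomeConfig,
    atlas: RegionAtlas,
    collapse: bool = True,
) -> AdjacencyMatrix:
    """Adjacency for tracts seeded in a composite ROI.

    Keeps only edges incident to the ROI's member regions, restricted to the
    ROI's hemisphere (``laterality="ipsi"``) or spanning all 72 regions
    (``"contra"``).  With ``collapse=True`` the member regions are summed
    into a single node; with ``collapse=False`` the scope's full node set is
    kept and only non-incident edges are zeroed.
    """
    if laterality not in ("ipsi", "contra"):
        raise ValueError(f"laterality must be 'ipsi' or 'contra', got {laterality!r}")
    if subject.counts.shape[0] != len(atlas):
        raise ValueError("matrix dimension does not match atlas size")
    names = atlas.abbreviations
    if laterality == "ipsi":
        scope_idx = atlas.hemisphere_indices(roi.hemisphere)
    else:
        scope_idx = list(range(len(atlas)))
    member_idx = sorted(atlas.index_of(m) for m in roi.members)
    counts = subject.counts[np.ix_(scope_idx, scope_idx)].astype(float)
    local = {g: i for i, g in enumerate(scope_idx)}
    mem_local = [local[i] for i in member_idx]
    scope_name = f"composite:{roi.name}:{laterality}"

    if collapse:
        other_local = [i for i in range(len(scope_idx)) if i not in set(mem_local)]
        labels = (roi.name,) + tuple(names[scope_idx[i]] for i in other_local)
        n = len(labels)
        w = np.zeros((n, n))
        # composite ↔ other edges: member row sums (internal edges excluded
        # by the zero diagonal; they are summed once in total_connections)
        col = counts[np.ix_(mem_local, other_local)].sum(axis=0)
        w[0, 1:] = col
        w[1:, 0] = col
    else:
        incident = np.zeros(counts.shape, dtype=bool)
        incident[mem_local, :] = True
        incident[:, mem_local] = True
        w = np.where(incident, counts, 0.0)
        labels = tuple(names[i] for i in scope_idx)

    return AdjacencyMatrix(
        weights=_normalize_threshold(w, config),
        labels=labels,
        scope=scope_name,
        seed_hemisphere=roi.hemisphere if laterality == "contra" else None,
    )


def _scope_pair_mask(scope: str, atlas: RegionAtlas,
                     roi: CompositeROI | None = None) -> np.ndarray:
    """Boolean upper-triangle mask over the full matrix of the pairs a scope
    counts: within-hemisphere pairs for ipsi scopes; for contra scopes every
    pair touching the seed hemisphere (within-seed plus cross-hemisphere,
    since ipsilateral connections still track when seeding one side).  With a
    seed ROI, only pairs incident to its members are kept."""
    lat, side = _scope_sides(scope)
    n = len(atlas)
    in_hemi = np.zeros(n, dtype=bool)
    in_hemi[atlas.hemisphere_indices(side)] = True
    if lat == "ipsi":
        pair = np.outer(in_hemi, in_hemi)
    else:
        pair = np.outer(in_hemi, in_hemi) | np.outer(in_hemi, ~in_hemi) | np.outer(~in_hemi, in_hemi)
    if roi is not None:
        mem = np.zeros(n, dtype=bool)
        mem[[atlas.index_of(m) for m in roi.members]] = True
        pair &= np.outer(mem, np.ones(n, bool)) | np.outer(np.ones(n, bool), mem)
    return np.triu(pair, k=1)


def total_connections(
    subject: SubjectConnectome,
    scope: str,
    atlas: RegionAtlas,
    roi: CompositeROI | None = None,
) -> int:
    """Total streamline count in a scope: the sum of upper-triangle raw
    counts over the scope's region pairs, before any normalization or
    thresholding.  With a composite ROI, only pairs incident to the ROI
    members are summed (internal member pairs counted once)."""
    lat, _ = _scope_sides(scope)
    if roi is not None and lat == "ipsi":
        _, side = _scope_sides(scope)
        if roi.hemisphere != side:
            raise ValueError(
                f"ROI hemisphere {roi.hemisphere} inconsistent with scope {scope}"
            )
    mask = _scope_pair_mask(scope, atlas, roi)
    return int(subject.counts[mask].sum())


def scope_pairs(scope: str, atlas: RegionAtlas) -> list[tuple[int, int]]:
    """The distinct region pairs a scope compares edgewise.

    Ipsilateral scopes enumerate the 36·35/2 = 630 unordered within-
    hemisphere pairs; contralateral scopes enumerate the 36×36 cross-
    hemisphere pairs (seed-side region × contralateral region)."""
    lat, side = _scope_sides(scope)
    if lat == "ipsi":
        idx = atlas.hemisphere_indices(side)
        return [(idx[a], idx[b]) for a in range(len(idx)) for b in range(a + 1, len(idx))]
    seed = atlas.hemisphere_indices(side)
    other = atlas.hemisphere_indices("R" if side == "L" else "L")
    return [(i, j) for i in seed for j in other]


def scope_count_matrix(subjects, scope: str, atlas: RegionAtlas) -> np.ndarray:
    """Stack of raw counts, shape (n_subjects, n_pairs), aligned with
    :func:`scope_pairs`."""
    pairs = scope_pairs(scope, atlas)
    rows = np.array([p[0] for p in pairs])
    cols = np.array([p[1] for p in pairs])
    return np.stack([s.counts[rows, cols] for s in subjects])
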