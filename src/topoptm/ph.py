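"""Persistent homology of element-labeled atomic point clouds.

Two filtrations are provided:

* Vietoris-Rips (:func:`vr_barcodes`) on the pairwise-distance scale — a
  simplex enters the filtration when its largest pairwise distance reaches
  the filtration value.  Simplices are enumerated up to dimension 3 below a
  cap ``r_f``; homology classes still alive at ``r_f`` are right-censored
  (reported as dying at ``r_f`` and flagged).
* Alpha (:func:`alpha_barcodes`) on the ball-radius scale — the nerve of
  Voronoi-restricted balls, computed from the Delaunay triangulation with
  the standard Gabriel-face value propagation.  Its persistence diagram
  coincides with that of the Čech filtration.

Small brute-force oracles (:func:`brute_force_vr`, :func:`brute_force_cech`)
enumerate every simplex and reduce the full boundary matrix over GF(2);
they are intended for testing the production paths on tiny clouds.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial import Delaunay, QhullError, distance_matrix

from ._reduction import (
    _count_tets,
    _count_triangles,
    _fill_tets,
    _fill_triangles,
    _kruskal,
    _reduce_csr,
)

INF = math.inf

#: seed of the deterministic jitter applied to degenerate Alpha inputs
_JITTER_SEED = 20230930
#: jitter amplitude in Å — far below any feature bin width
_JITTER_SD = 1e-6


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointCloud:
    """3D coordinates (Å) with a parallel list of chemical element symbols."""

    points: np.ndarray
    elements: tuple[str, ...]

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "elements", tuple(self.elements))
        if pts.shape[0] != len(self.elements):
            raise ValueError(
                f"{pts.shape[0]} points but {len(self.elements)} element labels"
            )
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class FiltrationSpec:
    """Filtration configuration.

    complex : ``"vr"`` or ``"alpha"``.
    scale : filtration-value convention; ``"distance"`` (default for VR:
        a pair connects at its interpoint distance) or ``"radius"`` (half
        of that; always the convention for Alpha).
    r_f : ending value of the filtration in Å (ignored by Alpha, whose
        complex is finite).
    max_hom_dim : highest homology dimension computed (0, 1 or 2).
    """

    complex: str = "vr"
    scale: str = "distance"
    r_f: float = 7.0
    max_hom_dim: int = 2

    def __post_init__(self):
        if self.complex not in ("vr", "alpha"):
            raise ValueError(f"unknown complex {self.complex!r}")
        if self.scale not in ("distance", "radius"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not self.r_f > 0:
            raise ValueError("r_f must be positive")
        if self.max_hom_dim not in (0, 1, 2):
            raise ValueError("max_hom_dim must be 0, 1 or 2")


@dataclass(frozen=True)
class Bar:
    """A persistence interval. ``censored`` marks a class still alive at r_f."""

    dim: int
    birth: float
    death: float
    censored: bool = False

    @property
    def length(self) -> float:
        return self.death - self.birth

    @property
    def finite(self) -> bool:
        return math.isfinite(self.death)


@dataclass(frozen=True)
class Barcode:
    bars: tuple[Bar, ...]
    spec: FiltrationSpec = field(default_factory=FiltrationSpec)

    def __post_init__(self):
        object.__setattr__(self, "bars", tuple(self.bars))

    def finite_bars(self, dim: int) -> list[Bar]:
        return [b for b in self.bars if b.dim == dim and b.finite]

    def n_infinite(self, dim: int = 0) -> int:
        return sum(1 for b in self.bars if b.dim == dim and not b.finite)

    def births(self, dim: int) -> np.ndarray:
        return np.array([b.birth for b in self.finite_bars(dim)], dtype=float)

    def deaths(self, dim: int) -> np.ndarray:
        return np.array([b.death for b in self.finite_bars(dim)], dtype=float)

    def lengths(self, dim: int) -> np.ndarray:
        return np.array([b.length for b in self.finite_bars(dim)], dtype=float)


def element_filter(cloud: PointCloud, elements: Iterable[str]) -> PointCloud:
    """Sub-cloud of the atoms whose element is in ``elements`` (order kept)."""
    wanted = {e.upper() for e in elements}
    mask = np.array([e.upper() in wanted for e in cloud.elements], dtype=bool)
    return PointCloud(cloud.points[mask], tuple(np.array(cloud.elements)[mask]))


# ---------------------------------------------------------------------------
# shared pairing machinery
# ---------------------------------------------------------------------------

def _sort_simplices(verts: np.ndarray, values: np.ndarray):
    """Order simplices by (filtration value, lexicographic vertices)."""
    keys = tuple(verts[:, c] for c in reversed(range(verts.shape[1]))) + (values,)
    order = np.lexsort(keys)
    return verts[order], values[order]

def _face_ranks(face_verts: np.ndarray, facet_verts: np.ndarray, n: int) -> np.ndarray:
    """Row indices (positions in the facet dimension's order) of each face.

    ``face_verts`` has one row per column and ``w`` faces encoded per row.
    """
    k = facet_verts.shape[1]
    weights = np.array([n ** (k - 1 - i) for i in range(k)], dtype=np.int64)
    codes = facet_verts.astype(np.int64) @ weights
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]

    w = face_verts.shape[1]
    m = face_verts.shape[0]
    faces = np.empty((m, w, k), dtype=np.int64)
    for drop in range(w):
        cols = [c for c in range(w) if c != drop]
        faces[:, drop, :] = face_verts[:, cols]
    face_codes = faces.reshape(m * w, k) @ weights
    pos = np.searchsorted(sorted_codes, face_codes)
    ranks = order[pos].reshape(m, w)
    ranks.sort(axis=1)
    return ranks


def _pairs_to_bars(
    n_points: int,
    edges: np.ndarray,
    edge_vals: np.ndarray,
    tris: np.ndarray,
    tri_vals: np.ndarray,
    tets: np.ndarray,
    tet_vals: np.ndarray,
    max_hom_dim: int,
    censor_value: float | None,
    min_length: float = 0.0,
) -> list[Bar]:
    """Persistence pairs of a flag-like complex given per-dimension simplex
    lists already in filtration order.  ``censor_value`` is the right-censor
    death for classes alive at the end of the filtration (``None`` → such
    classes must not exist and raise).  Pairs whose persistence is at
    most ``min_length`` are discarded as numerically zero-length."""
    bars: list[Bar] = []

    # dimension 0: union-find over edges in filtration order
    is_tree, n_comp = _kruskal(edges.astype(np.int64), n_points)
    for v in edge_vals[is_tree]:
        if v > min_length:
            bars.append(Bar(0, 0.0, float(v)))
    bars.extend(Bar(0, 0.0, INF) for _ in range(n_comp))

    cleared_tris = np.zeros(len(tris), dtype=bool)
    if max_hom_dim >= 2 and len(tets):
        nq = len(tets)
        tet_rows = _face_ranks(tets, tris, n_points)  # (nq, 4) triangle ranks
        piv_t = _reduce_csr(
            tet_rows.ravel(),
            np.arange(nq + 1, dtype=np.int64) * 4,
            np.zeros(nq, dtype=bool),
            len(tris),
        )
        for j in np.nonzero(piv_t >= 0)[0]:
            p = piv_t[j]
            cleared_tris[p] = True
            if tet_vals[j] > tri_vals[p] + min_length:
                bars.append(Bar(2, float(tri_vals[p]), float(tet_vals[j])))

    if max_hom_dim >= 1 and len(tris):
        tri_rows = _face_ranks(tris, edges, n_points)
        piv_tri = _reduce_csr(
            tri_rows.ravel(),
            np.arange(len(tris) + 1, dtype=np.int64) * 3,
            cleared_tris,
            len(edges),
        )
    else:
        piv_tri = np.full(len(tris), -1, dtype=np.int64)

    paired_edges = set()
    for j, p in enumerate(piv_tri):
        if p >= 0:
            paired_edges.add(int(p))
            if tri_vals[j] > edge_vals[p] + min_length:
                bars.append(Bar(1, float(edge_vals[p]), float(tri_vals[j])))

    if max_hom_dim >= 1:
        # creator edges never killed: censored dim-1 classes
        for e in np.nonzero(~is_tree)[0]:
            if int(e) not in paired_edges:
                if censor_value is None:
                    raise RuntimeError("unpaired 1-cycle in a complete filtration")
                if censor_value > edge_vals[e] + min_length:
                    bars.append(Bar(1, float(edge_vals[e]), float(censor_value), True))
    if max_hom_dim >= 2:
        for j in np.nonzero((piv_tri < 0) & ~cleared_tris)[0]:
            if censor_value is None:
                raise RuntimeError("unpaired 2-cycle in a complete filtration")
            if censor_value > tri_vals[j] + min_length:
                bars.append(Bar(2, float(tri_vals[j]), float(censor_value), True))

    bars.sort(key=lambda b: (b.dim, b.birth, b.death))
    return bars


# ---------------------------------------------------------------------------
# Vietoris-Rips
# ---------------------------------------------------------------------------

def vr_barcodes(cloud: PointCloud, spec: FiltrationSpec | None = None) -> Barcode:
    """Vietoris-Rips persistence barcode of a point cloud.

    A simplex's filtration value is the largest pairwise distance among its
    vertices (halved under the ``radius`` scale convention).  Classes alive
    at ``spec.r_f`` are right-censored there, except dimension-0 classes,
    which stay infinite (one per connected component of the final complex).
    """
    if spec is None:
        spec = FiltrationSpec(complex="vr")
    if spec.complex != "vr":
        raise ValueError("spec.complex must be 'vr'")
    if len(cloud) == 0:
        raise ValueError("cannot compute persistence of an empty cloud")

    factor = 0.5 if spec.scale == "radius" else 1.0
    n = len(cloud)
    D = distance_matrix(cloud.points, cloud.points) * factor
    cutoff = spec.r_f

    adj = (D <= cutoff) & ~np.eye(n, dtype=bool)
    nbr_lists = [np.nonzero(adj[i])[0] for i in range(n)]
    nbr_off = np.zeros(n + 1, dtype=np.int64)
    nbr_off[1:] = np.cumsum([len(x) for x in nbr_lists])
    nbr_flat = (
        np.concatenate(nbr_lists).astype(np.int64)
        if n > 1
        else np.empty(0, dtype=np.int64)
    )

    iu, ju = np.nonzero(np.triu(adj))
    edges = np.column_stack([iu, ju]).astype(np.int64)
    edge_vals = D[iu, ju]
    edges, edge_vals = _sort_simplices(edges, edge_vals)

    tris = np.empty((0, 3), dtype=np.int64)
    tri_vals = np.empty(0)
    tets = np.empty((0, 4), dtype=np.int64)
    tet_vals = np.empty(0)
    if spec.max_hom_dim >= 1 and len(edges):
        nt = _count_triangles(nbr_flat, nbr_off, adj)
        tris = np.empty((nt, 3), dtype=np.int64)
        _fill_triangles(nbr_flat, nbr_off, adj, tris)
        tri_vals = np.maximum(
            D[tris[:, 0], tris[:, 1]],
            np.maximum(D[tris[:, 0], tris[:, 2]], D[tris[:, 1], tris[:, 2]]),
        )
        tris, tri_vals = _sort_simplices(tris, tri_vals)
    if spec.max_hom_dim >= 2 and len(tris):
        nq = _count_tets(tris, nbr_flat, nbr_off, adj)
        tets = np.empty((nq, 4), dtype=np.int64)
        _fill_tets(tris, nbr_flat, nbr_off, adj, tets)
        if len(tets):
            pts_d = [D[tets[:, a], tets[:, b]] for a, b in combinations(range(4), 2)]
            tet_vals = np.max(np.stack(pts_d), axis=0)
            tets, tet_vals = _sort_simplices(tets, tet_vals)

    bars = _pairs_to_bars(
        n, edges, edge_vals, tris, tri_vals, tets, tet_vals,
        spec.max_hom_dim, censor_value=cutoff,
    )
    return Barcode(tuple(bars), spec)


# ---------------------------------------------------------------------------
# Alpha
# ---------------------------------------------------------------------------

class _DegenerateCloud(Exception):
    """A (near-)degenerate simplex was met; the cloud needs jittering."""


#: Alpha bars shorter than this (Å) are treated as numerically zero-length
#: artifacts of degenerate configurations and discarded; far below any
#: physically meaningful persistence at atomic scale.
MIN_ALPHA_BAR = 1e-4


def _circumradius2(pts: np.ndarray, strict: bool = False) -> tuple[np.ndarray, float]:
    """Circumcenter and squared circumradius of k+1 affinely independent
    points (center constrained to their affine hull).

    With ``strict``, a nearly affinely dependent vertex set raises
    :class:`_DegenerateCloud` instead of returning an ill-conditioned
    solution."""
    p0 = pts[0]
    V = pts[1:] - p0
    if V.shape[0] == 0:
        return p0, 0.0
    G = 2.0 * V @ V.T
    b = np.einsum("ij,ij->i", V, V)
    # thin ("sliver") simplices are legitimate in a 3D Delaunay complex;
    # only catastrophic near-singularity warrants a jitter-and-retry
    if strict and (G.shape[0] > 1 and np.linalg.cond(G) > 1e13):
        raise _DegenerateCloud
    try:
        y = np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        if strict:
            raise _DegenerateCloud from None
        y, *_ = np.linalg.lstsq(G, b, rcond=None)
    c = p0 + y @ V
    r2 = float(np.dot(y @ V, y @ V))
    return c, r2


def _alpha_complex(coords: np.ndarray):
    """Delaunay simplices of every dimension with squared alpha values."""
    dim = coords.shape[1]
    if dim == 1:
        order = np.argsort(coords[:, 0], kind="stable")
        tops = [tuple(sorted((int(order[i]), int(order[i + 1]))))
                for i in range(len(order) - 1)]
    else:
        tri = Delaunay(coords)
        tops = [tuple(sorted(int(v) for v in s)) for s in tri.simplices]

    by_dim: list[dict[tuple, float | None]] = [dict() for _ in range(dim + 1)]
    for s in tops:
        by_dim[dim][s] = None
        for k in range(dim):
            for f in combinations(s, k + 1):
                by_dim[k][f] = None
    for v in by_dim[0]:
        by_dim[0][v] = 0.0

    for k in range(dim, 0, -1):
        simplices = by_dim[k]
        facets = by_dim[k - 1]
        for s in simplices:
            if simplices[s] is None:
                _, r2 = _circumradius2(coords[list(s)], strict=True)
                simplices[s] = r2
            sval = simplices[s]
            for drop in range(len(s)):
                tau = s[:drop] + s[drop + 1:]
                opposite = s[drop]
                tval = facets[tau]
                if tval is not None:
                    facets[tau] = min(tval, sval)
                else:
                    c, r2 = _circumradius2(coords[list(tau)], strict=True)
                    d2 = float(np.dot(coords[opposite] - c, coords[opposite] - c))
                    if d2 < r2 * (1.0 - 1e-12):  # not Gabriel w.r.t. this cofacet
                        facets[tau] = sval
    return by_dim


def _project_to_rank(points: np.ndarray) -> np.ndarray:
    """Isometric projection of the cloud onto its affine hull."""
    centered = points - points.mean(axis=0)
    if len(points) == 1:
        return np.zeros((1, 1))
    _, s, Vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > 1e-9 * max(s[0], 1.0)))
    rank = max(rank, 1)
    return centered @ Vt[:rank].T


def alpha_barcodes(cloud: PointCloud, spec: FiltrationSpec | None = None) -> Barcode:
    """Alpha-complex persistence barcode, filtration value = ball radius in Å.

    Degenerate configurations (collinear/coplanar subsets, duplicates) are
    perturbed by a deterministic 1e-6 Å jitter before the Delaunay
    construction; the perturbation is far below any feature bin width.
    """
    if spec is None:
        spec = FiltrationSpec(complex="alpha")
    if spec.complex != "alpha":
        raise ValueError("spec.complex must be 'alpha'")
    n = len(cloud)
    if n == 0:
        raise ValueError("cannot compute persistence of an empty cloud")
    if n == 1:
        return Barcode((Bar(0, 0.0, INF),), spec)

    # canonical point order: the barcode must not depend on how the atoms
    # were listed, and the deterministic jitter must see a fixed order
    points = cloud.points[np.lexsort(cloud.points.T)]
    coords = _project_to_rank(points)
    by_dim = None
    rng = np.random.default_rng(_JITTER_SEED)
    for attempt in range(4):
        try:
            by_dim = _alpha_complex(coords)
            break
        except (QhullError, ValueError, _DegenerateCloud):
            jitter = rng.normal(0.0, _JITTER_SD * 10 ** attempt, points.shape)
            coords = _project_to_rank(points + jitter)
    if by_dim is None:
        raise RuntimeError("Delaunay triangulation failed after jitter attempts")

    def _dim_arrays(k: int):
        if k >= len(by_dim) or not by_dim[k]:
            return np.empty((0, k + 1), dtype=np.int64), np.empty(0)
        items = sorted(by_dim[k].items())
        verts = np.array([v for v, _ in items], dtype=np.int64)
        vals = np.sqrt(np.maximum(np.array([x for _, x in items], dtype=float), 0.0))
        return _sort_simplices(verts, vals)

    edges, edge_vals = _dim_arrays(1)
    tris, tri_vals = _dim_arrays(2)
    tets, tet_vals = _dim_arrays(3)

    bars = _pairs_to_bars(
        n, edges, edge_vals, tris, tri_vals, tets, tet_vals,
        spec.max_hom_dim, censor_value=None, min_length=MIN_ALPHA_BAR,
    )
    return Barcode(tuple(bars), spec)


# ---------------------------------------------------------------------------
# brute-force oracles (testing only)
# ---------------------------------------------------------------------------

def _min_enclosing_ball_r(pts: np.ndarray) -> float:
    """Radius of the smallest ball containing ≤ 4 points (exact search over
    boundary subsets)."""
    m = len(pts)
    if m == 1:
        return 0.0
    best = None
    for k in range(2, m + 1):
        for sub in combinations(range(m), k):
            P = pts[list(sub)]
            # require affine independence for a well-posed circumball
            if np.linalg.matrix_rank(P[1:] - P[0], tol=1e-10) < k - 1:
                continue
            c, r2 = _circumradius2(P)
            r = math.sqrt(max(r2, 0.0))
            if all(np.linalg.norm(p - c) <= r + 1e-9 for p in pts):
                if best is None or r < best:
                    best = r
    if best is None:  # fully degenerate; fall back to half-diameter
        best = 0.5 * max(
            np.linalg.norm(pts[a] - pts[b]) for a, b in combinations(range(m), 2)
        )
    return best


def _brute_force(cloud, spec, value_fn, cap, censor_value, min_length=0.0) -> Barcode:
    n = len(cloud)
    if n == 0:
        raise ValueError("cannot compute persistence of an empty cloud")
    if n > cap:
        raise ValueError(f"brute-force oracle limited to {cap} points, got {n}")
    pts = cloud.points

    simplices = []
    for k in range(min(3, n - 1) + 1):
        for vs in combinations(range(n), k + 1):
            v = value_fn(pts, vs)
            if censor_value is None or v <= censor_value:
                simplices.append((v, k, vs))
    simplices.sort(key=lambda t: (t[0], t[1], t[2]))
    index = {s[2]: i for i, s in enumerate(simplices)}

    columns = []
    for v, k, vs in simplices:
        if k == 0:
            columns.append(set())
        else:
            columns.append({index[vs[:d] + vs[d + 1:]] for d in range(len(vs))})

    low_owner: dict[int, int] = {}
    for j in range(len(columns)):
        col = columns[j]
        while col:
            p = max(col)
            if p not in low_owner:
                low_owner[p] = j
                break
            col = col ^ columns[low_owner[p]]
        columns[j] = col

    bars = []
    paired = set(low_owner).union(low_owner.values())
    for p, j in low_owner.items():
        birth, dim = simplices[p][0], simplices[p][1]
        death = simplices[j][0]
        if death > birth + min_length:
            bars.append(Bar(dim, float(birth), float(death)))
    for i, (v, k, vs) in enumerate(simplices):
        if i in paired or columns[i]:
            continue  # destroyer or already-paired creator
        if k == 0:
            bars.append(Bar(0, 0.0, INF))
        elif censor_value is not None and censor_value > v:
            bars.append(Bar(k, float(v), float(censor_value), True))
    bars = [b for b in bars if b.dim <= spec.max_hom_dim]
    bars.sort(key=lambda b: (b.dim, b.birth, b.death))
    return Barcode(tuple(bars), spec)


def brute_force_vr(cloud: PointCloud, spec: FiltrationSpec | None = None) -> Barcode:
    """Enumerative VR persistence for ≤ 10 points (test oracle)."""
    if spec is None:
        spec = FiltrationSpec(complex="vr")
    factor = 0.5 if spec.scale == "radius" else 1.0

    def value(pts, vs):
        if len(vs) == 1:
            return 0.0
        return factor * max(
            np.linalg.norm(pts[a] - pts[b]) for a, b in combinations(vs, 2)
        )

    return _brute_force(cloud, spec, value, cap=10, censor_value=spec.r_f)


def brute_force_cech(cloud: PointCloud, spec: FiltrationSpec | None = None) -> Barcode:
    """Enumerative Čech persistence (min-enclosing-ball radii) for ≤ 8 points.

    Serves as the oracle for :func:`alpha_barcodes`, whose persistence it
    matches on general-position inputs.
    """
    if spec is None:
        spec = FiltrationSpec(complex="alpha")

    def value(pts, vs):
        return _min_enclosing_ball_r(pts[list(vs)])

    return _brute_force(cloud, spec, value, cap=8, censor_value=None,
                        min_length=MIN_ALPHA_BAR)


# ---------------------------------------------------------------------------
# barcode CSV round-trip
# ---------------------------------------------------------------------------

def write_barcode_csv(barcode: Barcode, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["dim", "birth", "death"])
        for b in barcode.bars:
            w.writerow([b.dim, repr(b.birth), "inf" if not b.finite else repr(b.death)])


def read_barcode_csv(path: str | Path, spec: FiltrationSpec | None = None) -> Barcode:
    bars = []
    with open(path, newline="") as fh:
        rd = csv.reader(fh)
        header = next(rd)
        if header[:3] != ["dim", "birth", "death"]:
            raise ValueError(f"unexpected barcode header {header!r}")
        for row in rd:
            death = INF if row[2] == "inf" else float(row[2])
            bars.append(Bar(int(row[0]), float(row[1]), death))
    return Barcode(tuple(bars), spec or FiltrationSpec())
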