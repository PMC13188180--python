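"""Sublevel-set cubical persistent homology on voxel grids.

A 2D/3D image is modeled as a cubical complex in the "T-construction":
every voxel is a top-dimensional cube and contributes its faces, edges and
vertices, each lower cell inheriting the minimum value over the voxels that
contain it.  Sweeping a threshold t from low to high and keeping cells with
value <= t produces a nested family of complexes; persistent homology
tracks connected components (H0), loops (H1) and enclosed cavities (H2)
across the sweep, recording for each class the threshold where it appears
(birth) and where it disappears (death).

The complex is stored on the interleaved "cell grid" of shape
``(2*n0+1, 2*n1+1, ...)``: a lattice point with k odd coordinates is a
k-cell, and the two facets of a cell along each spanned axis sit at +/-1
along that (odd) coordinate.  Pair computation uses GF(2) boundary-matrix
column reduction with the twist/clearing optimization, processing cell
dimensions from high to low; H0 is paired by the equivalent elder-rule
union-find over edges.  An independent brute-force oracle
(:func:`betti_at_threshold`, GF(2) ranks by Gaussian elimination) and the
Euler-curve identity are provided for cross-checking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numba import njit
from numba.typed import List as NumbaList

from .preprocess import DegenerateROIError

#: Sentinel filtration value for voxels excluded from the complex (outside the
#: ROI): strictly above the 0-255 scale so they never enter any sublevel set.
EXCLUDED = np.inf
SENTINEL = 256.0


@dataclass(frozen=True)
class CubicalCell:
    """A single cell of the cubical complex (for inspection on small grids)."""

    dim: int
    anchor: tuple        # cell-grid lattice coordinates
    extent: tuple        # axes along which the cell spans (odd coordinates)
    value: float


@dataclass
class PersistencePair:
    dim: int
    birth: float
    death: float
    essential: bool = False

    @property
    def lifetime(self) -> float:
        return self.death - self.birth


@dataclass
class PersistenceDiagram:
    """Multiset of (birth, death) pairs per homology dimension, on [0, 255]."""

    pairs: list
    filtration_range: tuple = (0.0, 255.0)

    def by_dim(self, dim: int) -> np.ndarray:
        """(n, 2) array of (birth, death) for one homology dimension."""
        pts = [(p.birth, p.death) for p in self.pairs if p.dim == dim]
        return np.array(pts, dtype=float).reshape(-1, 2)

    def betti_at(self, t: float) -> tuple:
        """Counts #{pairs: birth <= t < death} per dim, essential classes
        counted as alive for all t >= birth."""
        out = [0, 0, 0]
        for p in self.pairs:
            alive = p.birth <= t and (t < p.death or p.essential)
            if alive and p.dim <= 2:
                out[p.dim] += 1
        return tuple(out)

    def to_json(self, path=None):
        recs = [
            {"dim": p.dim, "birth": p.birth, "death": p.death, "essential": p.essential}
            for p in self.pairs
        ]
        obj = {"filtration_range": list(self.filtration_range), "pairs": recs}
        if path is None:
            return json.dumps(obj)
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, source):
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        pairs = [
            PersistencePair(r["dim"], r["birth"], r["death"], r.get("essential", False))
            for r in obj["pairs"]
        ]
        return cls(pairs=pairs, filtration_range=tuple(obj["filtration_range"]))


class FiltrationComplex:
    """Sublevel cubical filtration of a (masked) voxel grid.

    Cells live on the interleaved lattice of shape ``2*n+1`` per axis; a
    cell's dimension is its number of odd coordinates and its value is the
    minimum over incident voxels (+inf marks cells excluded by the ROI mask).
    The filtration order sorts included cells by (value, dim, lexicographic
    anchor).
    """

    def __init__(self, values: np.ndarray):
        self.cell_shape = values.shape
        self.values = values
        flat = values.ravel()
        self._finite = np.isfinite(flat)
        if not self._finite.any():
            raise DegenerateROIError("no voxels inside the ROI")
        self.ndim = values.ndim
        # cell dimension = number of odd coordinates
        parities = np.meshgrid(
            *[np.arange(n) % 2 for n in self.cell_shape], indexing="ij"
        )
        self.dims = sum(parities).astype(np.int8).ravel()
        idx = np.nonzero(self._finite)[0]
        order = np.lexsort((idx, self.dims[idx], flat[idx]))
        #: flat cell indices in filtration order
        self.order = idx[order].astype(np.int64)
        #: flat cell index -> filtration position (-1 if excluded)
        self.rank_of = np.full(flat.size, -1, dtype=np.int64)
        self.rank_of[self.order] = np.arange(self.order.size)
        self.max_finite = float(flat[self._finite].max())

    @property
    def n_cells(self) -> int:
        return int(self.order.size)

    def cell_values(self) -> np.ndarray:
        """Values of included cells in filtration order."""
        return self.values.ravel()[self.order]

    def cells(self):
        """Yield :class:`CubicalCell` objects in filtration order (small grids)."""
        flat_vals = self.values.ravel()
        for f in self.order:
            anchor = np.unravel_index(f, self.cell_shape)
            extent = tuple(a for a, c in enumerate(anchor) if c % 2 == 1)
            yield CubicalCell(len(extent), tuple(int(c) for c in anchor),
                              extent, float(flat_vals[f]))

    def boundary_of(self, flat_index: int) -> list:
        """Flat indices of the facets of one cell (2 per spanned axis)."""
        coords = list(np.unravel_index(flat_index, self.cell_shape))
        strides = _strides(self.cell_shape)
        out = []
        for a, c in enumerate(coords):
            if c % 2 == 1:
                out.append(flat_index - strides[a])
                out.append(flat_index + strides[a])
        return out


def _strides(shape):
    st = [1] * len(shape)
    for a in range(len(shape) - 2, -1, -1):
        st[a] = st[a + 1] * shape[a + 1]
    return st


def build_filtration(grid) -> FiltrationComplex:
    """Build the sublevel T-construction filtration of a voxel grid.

    ``grid`` may be a :class:`~topovox.preprocess.VoxelGrid` or a bare 2D/3D
    array.  When a mask is present only in-mask voxels become top cells; all
    other voxels are excluded outright (so no spurious merging can occur
    through non-ROI tissue) and any lower cell incident only to excluded
    voxels is excluded too.
    """
    data = np.asarray(getattr(grid, "data", grid), dtype=float)
    mask = getattr(grid, "mask", None)
    if data.ndim not in (2, 3):
        raise ValueError(f"expected 2D or 3D data, got ndim={data.ndim}")
    vox = data.copy()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise DegenerateROIError("ROI mask is empty")
        vox[~mask] = EXCLUDED
    cell_shape = tuple(2 * n + 1 for n in data.shape)
    vals = np.full(cell_shape, EXCLUDED)
    vals[tuple(slice(1, None, 2) for _ in data.shape)] = vox
    # Separable min: a cell's value is the min over the voxels containing it.
    for a in range(data.ndim):
        v = np.moveaxis(vals, a, 0)
        lo = np.full_like(v, EXCLUDED)
        hi = np.full_like(v, EXCLUDED)
        lo[:-1] = v[1:]
        hi[1:] = v[:-1]
        v[::2] = np.minimum(lo, hi)[::2]
    return FiltrationComplex(vals)


# ---------------------------------------------------------------------------
# GF(2) column reduction (twist/clearing), numba-compiled

@njit(cache=True)
def _symdiff(a, b):
    out = np.empty(a.size + b.size, dtype=np.int64)
    i = j = k = 0
    while i < a.size and j < b.size:
        if a[i] < b[j]:
            out[k] = a[i]; i += 1; k += 1
        elif a[i] > b[j]:
            out[k] = b[j]; j += 1; k += 1
        else:
            i += 1; j += 1
    while i < a.size:
        out[k] = a[i]; i += 1; k += 1
    while j < b.size:
        out[k] = b[j]; j += 1; k += 1
    return out[:k].copy()


@njit(cache=True)
def _reduce_columns(col_pos, rows, width, n_cells):
    """Reduce boundary columns in filtration order.

    col_pos : filtration positions of the columns, ascending.
    rows    : (n_cols * width) facet positions, sorted ascending per column.
    Returns the pivot row per column (-1 for columns reducing to zero).
    """
    n_cols = col_pos.size
    pivot = np.full(n_cols, -1, dtype=np.int64)
    owner = np.full(n_cells, -1, dtype=np.int64)
    stored = NumbaList()
    stored.append(np.empty(0, dtype=np.int64))  # slot 0 placeholder
    for ci in range(n_cols):
        col = rows[ci * width:(ci + 1) * width].copy()
        while col.size > 0:
            low = col[col.size - 1]
            slot = owner[low]
            if slot == -1:
                owner[low] = len(stored)
                stored.append(col)
                pivot[ci] = low
                break
            col = _symdiff(col, stored[slot])
    return pivot


@njit(cache=True)
def _find(parent, x):
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:
        nxt = parent[x]
        parent[x] = root
        x = nxt
    return root


@njit(cache=True)
def _h0_union_find(edge_pos, endpoints, n_cells):
    """Elder-rule H0 pairing over edges in filtration order.

    endpoints : (n_edges, 2) vertex filtration positions per edge.
    Returns (deaths, births) arrays aligned with edges: for a merging edge,
    births[i] = the dying component's creator-vertex position; for a cycle
    edge births[i] = -1.  parent array is returned for essential-class
    extraction.
    """
    parent = np.arange(n_cells, dtype=np.int64)
    comp_birth = np.arange(n_cells, dtype=np.int64)
    births = np.full(edge_pos.size, -1, dtype=np.int64)
    for i in range(edge_pos.size):
        u = _find(parent, endpoints[i, 0])
        v = _find(parent, endpoints[i, 1])
        if u == v:
            continue
        bu, bv = comp_birth[u], comp_birth[v]
        if bu < bv:  # v's component is younger: it dies
            parent[v] = u
            births[i] = bv
        else:
            parent[u] = v
            comp_birth[v] = min(bu, bv)
            births[i] = bu
    return births, parent


def _cells_of_dim(cx: FiltrationComplex, d: int):
    """Filtration positions (ascending) and flat indices of dim-d cells."""
    flat = cx.order
    sel = cx.dims[flat] == d
    return np.nonzero(sel)[0].astype(np.int64), flat[sel]


def _facet_positions(cx: FiltrationComplex, flat_idx: np.ndarray, d: int):
    """(n, 2d) facet filtration positions, sorted ascending per row."""
    coords = np.array(np.unravel_index(flat_idx, cx.cell_shape))
    strides = _strides(cx.cell_shape)
    n = flat_idx.size
    out = np.empty((n, 2 * d), dtype=np.int64)
    fill = np.zeros(n, dtype=np.int64)
    for a in range(cx.ndim):
        odd = coords[a] % 2 == 1
        idx = np.nonzero(odd)[0]
        if idx.size == 0:
            continue
        lo = flat_idx[idx] - strides[a]
        hi = flat_idx[idx] + strides[a]
        out[idx, fill[idx]] = cx.rank_of[lo]
        out[idx, fill[idx] + 1] = cx.rank_of[hi]
        fill[idx] += 2
    assert (fill == 2 * d).all()
    out.sort(axis=1)
    return out


def compute_persistence(cx: FiltrationComplex) -> PersistenceDiagram:
    """Persistence pairs of the sublevel filtration, homology dims 0-2.

    Standard GF(2) boundary-matrix column reduction in filtration order,
    processed from the top cell dimension downward with clearing: a cell
    paired as the pivot of a higher-dimensional column is a known class
    birth whose own column would reduce to zero, so it is skipped.  H0 is
    paired by elder-rule union-find over the edges (equivalent to reducing
    the dim-1 columns).  Zero-persistence pairs are discarded; classes that
    never die are closed at the maximum finite filtration value and flagged
    essential.
    """
    vals = cx.values.ravel()
    order_vals = vals[cx.order]
    top = cx.ndim
    pairs: list[PersistencePair] = []
    cleared = np.zeros(cx.n_cells, dtype=bool)

    for d in range(top, 1, -1):
        pos, flat = _cells_of_dim(cx, d)
        keep = ~cleared[pos]
        pos_k, flat_k = pos[keep], flat[keep]
        if pos_k.size:
            facets = _facet_positions(cx, flat_k, d)
            pivot = _reduce_columns(pos_k, facets.ravel(), 2 * d, cx.n_cells)
        else:
            pivot = np.empty(0, dtype=np.int64)
        paired = pivot >= 0
        # paired columns kill a (d-1)-class
        for p, c in zip(pivot[paired], pos_k[paired]):
            b, dd = order_vals[p], order_vals[c]
            if b != dd:
                pairs.append(PersistencePair(d - 1, float(b), float(dd)))
            cleared[p] = True
        # unpaired, uncleared d-columns: essential d-classes (d < top only;
        # a top-dimensional cycle cannot exist in a complex embedded in R^top)
        if d < top:
            for c in pos_k[~paired]:
                pairs.append(
                    PersistencePair(d, float(order_vals[c]), cx.max_finite, essential=True)
                )

    # H0 via union-find over edges; H1 births = cycle edges
    pos1, flat1 = _cells_of_dim(cx, 1)
    if pos1.size:
        endpoints = _facet_positions(cx, flat1, 1)
        births, parent = _h0_union_find(pos1, endpoints, cx.n_cells)
    else:
        births = np.empty(0, dtype=np.int64)
        parent = np.arange(cx.n_cells, dtype=np.int64)
    merging = births >= 0
    for bpos, epos in zip(births[merging], pos1[merging]):
        b, dd = order_vals[bpos], order_vals[epos]
        if b != dd:
            pairs.append(PersistencePair(0, float(b), float(dd)))
    if top >= 2:
        # cycle edges not cleared by the dim-2 reduction are essential H1
        for epos in pos1[~merging]:
            if not cleared[epos]:
                pairs.append(
                    PersistencePair(1, float(order_vals[epos]), cx.max_finite, essential=True)
                )
    # essential H0: one per final component among the vertices
    pos0, _ = _cells_of_dim(cx, 0)
    roots = {}
    parent_arr = np.asarray(parent)
    for vp in pos0:
        r = int(_find_py(parent_arr, int(vp)))
        if r not in roots or vp < roots[r]:
            roots[r] = int(vp)
    for vp in roots.values():
        pairs.append(PersistencePair(0, float(order_vals[vp]), cx.max_finite, essential=True))

    pairs.sort(key=lambda p: (p.dim, p.birth, p.death))
    lo = float(min(0.0, order_vals.min()))
    hi = float(max(255.0, cx.max_finite))
    return PersistenceDiagram(pairs=pairs, filtration_range=(0.0, 255.0) if hi <= 255.0 and lo >= 0.0 else (lo, hi))


def _find_py(parent, x):
    while parent[x] != x:
        x = parent[x]
    return x


# ---------------------------------------------------------------------------
# Independent oracle: Betti numbers by GF(2) ranks

def _gf2_rank(rows):
    """Rank over GF(2) of a matrix whose rows are Python-int bitsets."""
    pivots = {}
    rank = 0
    for row in rows:
        while row:
            b = row.bit_length() - 1
            if b in pivots:
                row ^= pivots[b]
            else:
                pivots[b] = row
                rank += 1
                break
    return rank


def betti_at_threshold(cx: FiltrationComplex, t: float) -> tuple:
    """Betti numbers (β0, β1, β2) of the sublevel complex at threshold t.

    Brute-force oracle: builds the full GF(2) boundary matrices of the cells
    with value <= t and computes βk = dim ker ∂k − rank ∂k+1 by Gaussian
    elimination on bitset rows.  Independent of the column-reduction pairing
    path; intended for small grids.
    """
    vals = cx.values.ravel()
    included = {}
    for d in range(cx.ndim + 1):
        _, flat = _cells_of_dim(cx, d)
        sel = vals[flat] <= t
        included[d] = {int(f): i for i, f in enumerate(flat[sel])}
    n = {d: len(included[d]) for d in included}
    ranks = {}
    for d in range(1, cx.ndim + 1):
        rows = []
        for f in included[d]:
            bits = 0
            for g in FiltrationComplex.boundary_of(cx, f):
                bits |= 1 << included[d - 1][int(g)]
            rows.append(bits)
        ranks[d] = _gf2_rank(rows)
    ranks[cx.ndim + 1] = 0
    betti = []
    for k in range(3):
        if k > cx.ndim:
            betti.append(0)
            continue
        nk = n.get(k, 0)
        betti.append(nk - ranks.get(k, 0) - ranks.get(k + 1, 0))
    return tuple(betti)


def euler_curve(cx: FiltrationComplex, thresholds) -> np.ndarray:
    """Euler characteristic χ(t) = Σ_d (−1)^d #{d-cells with value <= t}."""
    vals = cx.values.ravel()[cx.order]
    dims = cx.dims[cx.order]
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    out = np.zeros(thresholds.size)
    for d in range(cx.ndim + 1):
        v = np.sort(vals[dims == d])
        counts = np.searchsorted(v, thresholds, side="right")
        out += ((-1) ** d) * counts
    return out
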