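"""Contact sequence reconstruction: projecting junction counts onto the
protein-protected sequence that generated them.

MNase cannot cut under a bound protein, so a protein-mediated contact
appears in raw data as a quartet of junction pixels at the corners
surrounding the true contact point. The direction flag of each junction end
says on which side of the cut the protected fragment lies; smearing each
directional channel over a footprint-sized window toward the protected side
collapses the corner quartet onto the contact point between the two
footprints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .junctions import LigationJunction
from .matrix import ContactMatrix
from .synthetic import TOWARD_DOWNSTREAM, TOWARD_UPSTREAM

_DIR_IDX = {TOWARD_UPSTREAM: 0, TOWARD_DOWNSTREAM: 1}


@dataclass
class DirectionalMatrix:
    """Four orientation-resolved count channels over one pixel grid.

    ``channels[da, db]`` holds junctions whose row-end fragment lies
    upstream (da=0) or downstream (da=1) of its cut, likewise ``db`` for the
    column end. The channel sum equals the raw contact matrix.
    """

    row_region: tuple[str, int, int]
    pixel_size: int
    channels: np.ndarray  # shape (2, 2, n, n)

    @property
    def channel_sum(self) -> np.ndarray:
        return self.channels.sum(axis=(0, 1))


def build_directional_matrix(
    junctions: list[LigationJunction],
    region: tuple[str, int, int],
    pixel_size: int = 1,
) -> DirectionalMatrix:
    """Bin junctions into four (dir_a, dir_b) channels.

    Each junction increments exactly one channel at its (pos_a, pos_b)
    pixel; the mirrored pixel gets the transposed channel so that the
    channel sum reproduces the symmetric raw matrix.
    """
    chrom, start, end = region
    if pixel_size < 1:
        raise ValueError("pixel_size must be >= 1")
    n = math.ceil((end - start) / pixel_size)
    ch = np.zeros((2, 2, n, n), dtype=np.float32)
    for j in junctions:
        if j.dir_a not in _DIR_IDX or j.dir_b not in _DIR_IDX:
            raise ValueError(f"junction {j} lacks direction flags")
        if j.chrom != chrom or not (start <= j.pos_a < end and start <= j.pos_b < end):
            continue
        ia = (j.pos_a - start) // pixel_size
        ib = (j.pos_b - start) // pixel_size
        da, db = _DIR_IDX[j.dir_a], _DIR_IDX[j.dir_b]
        ch[da, db, ia, ib] += 1
        if ia != ib:
            ch[db, da, ib, ia] += 1
    return DirectionalMatrix(region, pixel_size, ch)


def _directional_kernel(footprint: int, direction: int, kernel: str) -> tuple[np.ndarray, int]:
    """Weights and offset such that output[x] = sum_t w[t] * ch[x + off + t].

    A cut at pixel i spreads toward the protected side: upstream (dir 0)
    over [i-f+1, i], downstream (dir 1) over [i, i+f-1].
    """
    if kernel == "uniform":
        v = np.full(footprint, 1.0 / footprint)
    elif kernel == "triangular":
        # weight decreasing with distance from the cut
        v = np.arange(footprint, 0, -1, dtype=float)
        v /= v.sum()
    else:
        raise ValueError("kernel must be 'uniform' or 'triangular'")
    if direction == 0:  # signal at i lands on [i-f+1 .. i]
        return v, 0  # output[x] = sum_t v[t] * ch[x + t]
    return v[::-1], -(footprint - 1)  # lands on [i .. i+f-1]


def _smear_axis(grid: np.ndarray, axis: int, footprint: int, direction: int, kernel: str) -> np.ndarray:
    w, off = _directional_kernel(footprint, direction, kernel)
    g = np.moveaxis(grid, axis, 0)
    n = g.shape[0]
    if kernel == "uniform":
        # sliding-window sum via cumulative sums: out[x] = mean g[x+off .. x+off+f)
        c = np.zeros((n + 1,) + g.shape[1:], dtype=float)
        np.cumsum(g, axis=0, out=c[1:])
        lo = np.clip(np.arange(n) + off, 0, n)
        hi = np.clip(np.arange(n) + off + footprint, 0, n)
        out = (c[hi] - c[lo]) / footprint
    else:
        out = np.zeros_like(g, dtype=float)
        for t, wt in enumerate(w):
            src = off + t
            lo_dst = max(0, -src)
            hi_dst = min(n, n - src)
            if hi_dst > lo_dst:
                out[lo_dst:hi_dst] += wt * g[lo_dst + src : hi_dst + src]
    return np.moveaxis(out, 0, axis)


def reconstruct_contact_sequences(
    dmat: DirectionalMatrix,
    footprint: int = 20,
    kernel: str = "uniform",
) -> np.ndarray:
    """Smear each directional channel over a footprint-length window toward
    the protected side along both axes, then sum the four channels.

    Total signal is conserved except for truncation at the region edges; a
    corner quartet of junctions around a protected contact collapses onto
    the contact point. ``footprint`` is in pixels of the grid.
    """
    if footprint < 1:
        raise ValueError("footprint must be >= 1")
    n = dmat.channels.shape[-1]
    if footprint > n:
        raise ValueError("footprint larger than the matrix")
    out = np.zeros((n, n))
    for da in (0, 1):
        for db in (0, 1):
            g = _smear_axis(dmat.channels[da, db], 0, footprint, da, kernel)
            g = _smear_axis(g, 1, footprint, db, kernel)
            out += g
    return out


def reconstructed_matrix(
    dmat: DirectionalMatrix, footprint: int = 20, kernel: str = "uniform"
) -> ContactMatrix:
    grid = reconstruct_contact_sequences(dmat, footprint, kernel)
    return ContactMatrix(
        dmat.row_region,
        dmat.row_region,
        dmat.pixel_size,
        dmat.pixel_size,
        grid,
        "raw",
    )
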