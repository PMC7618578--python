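"""Contact matrices at arbitrary pixel sizes down to 1 bp, with ICE and
cis normalization, plus the inter-junction distance spectrum.

Square cis matrices are symmetric in raw counts: a junction (a, b)
increments pixel (i, j) and its transpose, with the upper-triangle-plus-
diagonal sum equal to the number of in-region junctions. Extended maps use
fine rows over the viewpoint region against coarse genome-wide columns,
a hybrid between a viewpoint profile and an all-vs-all map.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .junctions import LigationJunction


@dataclass
class ContactMatrix:
    row_region: tuple[str, int, int]
    col_region: tuple[str, int, int]
    pixel_size: int
    col_pixel_size: int
    counts: np.ndarray
    normalization: str = "raw"
    replicate_ids: tuple = ()
    bias: np.ndarray | None = None
    converged: bool = True

    @property
    def extended(self) -> bool:
        return self.pixel_size != self.col_pixel_size or self.row_region != self.col_region


def _bin_index(pos: int, start: int, px: int) -> int:
    return (pos - start) // px


def build_contact_matrix(
    junctions: list[LigationJunction],
    row_region: tuple[str, int, int],
    pixel_size: int = 1,
    extended: int | None = None,
    genome_length: int | None = None,
) -> ContactMatrix:
    """Bin deduplicated junctions into a square (or extended) count matrix.

    Square mode drops junctions with either end outside the region; extended
    mode keeps any junction with one end in the region, binning the partner
    end into genome-wide columns of ``extended`` bp.
    """
    chrom, start, end = row_region
    if pixel_size < 1:
        raise ValueError("pixel_size must be >= 1")
    if end <= start:
        raise ValueError("empty region")
    n = math.ceil((end - start) / pixel_size)
    if extended is None:
        counts = np.zeros((n, n))
        for j in junctions:
            if j.chrom != chrom or not (start <= j.pos_a < end and start <= j.pos_b < end):
                continue
            ia = _bin_index(j.pos_a, start, pixel_size)
            ib = _bin_index(j.pos_b, start, pixel_size)
            counts[ia, ib] += 1
            if ia != ib:
                counts[ib, ia] += 1
        return ContactMatrix(row_region, row_region, pixel_size, pixel_size, counts)
    if genome_length is None:
        raise ValueError("extended mode requires genome_length")
    m = math.ceil(genome_length / extended)
    counts = np.zeros((n, m))
    for j in junctions:
        if j.chrom != chrom:
            continue
        for p, q in ((j.pos_a, j.pos_b), (j.pos_b, j.pos_a)):
            if start <= p < end:
                counts[_bin_index(p, start, pixel_size), q // extended] += 1
    return ContactMatrix(
        row_region, (chrom, 0, genome_length), pixel_size, extended, counts
    )


def coarsen(matrix: ContactMatrix, factor: int) -> ContactMatrix:
    """Aggregate pixels in ``factor`` x ``factor`` blocks.

    Reproduces ``build_contact_matrix`` at the coarser pixel size exactly:
    in symmetric single-count-diagonal storage, a fine off-diagonal pair
    falling into a coarse diagonal block contributes its two mirrored
    entries to one coarse pixel, so diagonal blocks are corrected back to
    single counts."""
    c = matrix.counts
    n = math.ceil(c.shape[0] / factor)
    m = math.ceil(c.shape[1] / factor)
    pad = np.zeros((n * factor, m * factor))
    pad[: c.shape[0], : c.shape[1]] = c
    out = pad.reshape(n, factor, m, factor).sum(axis=(1, 3))
    if c.shape[0] == c.shape[1] and matrix.row_region == matrix.col_region:
        diag_fine = np.diag(pad)
        d = diag_fine.reshape(n, factor).sum(axis=1)
        idx = np.arange(n)
        out[idx, idx] = (out[idx, idx] + d) / 2
    return ContactMatrix(
        matrix.row_region,
        matrix.col_region,
        matrix.pixel_size * factor,
        matrix.col_pixel_size * factor,
        out,
        matrix.normalization,
        matrix.replicate_ids,
    )


# ---------------------------------------------------------------------------
# normalization


def ice_normalize(
    matrix: ContactMatrix | np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 200,
    low_coverage_quantile: float = 0.02,
) -> tuple[ContactMatrix, np.ndarray]:
    """Iterative correction (matrix balancing) of a square contact matrix.

    Rows whose coverage falls below the ``low_coverage_quantile`` of row
    sums (or is zero) are masked and returned as NaN. The bias vector b
    satisfies raw = b_i * b_j * balanced on unmasked entries.
    """
    was_array = isinstance(matrix, np.ndarray)
    m = np.asarray(matrix if was_array else matrix.counts, dtype=float).copy()
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("ICE requires a square matrix")
    if m.sum() <= 0:
        raise ValueError("cannot balance an all-zero matrix")
    rowsum = m.sum(axis=1)
    thr = np.quantile(rowsum, low_coverage_quantile)
    mask = (rowsum <= 0) | (rowsum < thr)
    keep = ~mask
    bias = np.ones(m.shape[0])
    sub = m[np.ix_(keep, keep)]
    converged = False
    for _ in range(max_iter):
        s = sub.sum(axis=1)
        s = s / s.mean()
        bias[keep] *= s
        sub /= np.outer(s, s)
        if np.max(np.abs(s - 1)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("ICE balancing did not converge within max_iter", RuntimeWarning)
    out = np.full(m.shape, np.nan)
    out[np.ix_(keep, keep)] = sub
    bias[mask] = np.nan
    if was_array:
        cm = ContactMatrix(
            ("", 0, m.shape[0]), ("", 0, m.shape[0]), 1, 1, out, "ice",
        )
    else:
        cm = ContactMatrix(
            matrix.row_region,
            matrix.col_region,
            matrix.pixel_size,
            matrix.col_pixel_size,
            out,
            "ice",
            matrix.replicate_ids,
        )
    cm.bias = bias
    cm.converged = converged
    return cm, bias


def cis_normalize(
    matrix: ContactMatrix,
    cis_totals: np.ndarray,
    mode: str = "single",
    scale: float = 1e5,
) -> ContactMatrix:
    """Scale each viewpoint row to counts per ``scale`` cis-unique junctions
    of that viewpoint (capture-efficiency correction).

    ``tiled`` mode additionally symmetrizes by averaging with the transpose.
    Rows with zero cis total are masked (NaN), never divided.
    """
    if mode not in ("single", "tiled"):
        raise ValueError("mode must be 'single' or 'tiled'")
    cis_totals = np.asarray(cis_totals, dtype=float)
    c = matrix.counts.astype(float).copy()
    if cis_totals.shape[0] != c.shape[0]:
        raise ValueError("cis_totals must have one entry per matrix row")
    factors = np.full(c.shape[0], np.nan)
    nz = cis_totals > 0
    factors[nz] = scale / cis_totals[nz]
    c = c * factors[:, None]
    if mode == "tiled":
        if c.shape[0] != c.shape[1]:
            raise ValueError("tiled normalization requires a square matrix")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            c = np.nanmean(np.stack([c, c.T]), axis=0)
    return ContactMatrix(
        matrix.row_region,
        matrix.col_region,
        matrix.pixel_size,
        matrix.col_pixel_size,
        c,
        "cis_single" if mode == "single" else "cis_tiled",
        matrix.replicate_ids,
    )


def cis_totals_per_row(
    junctions: list[LigationJunction],
    row_region: tuple[str, int, int],
    pixel_size: int = 1,
) -> np.ndarray:
    """Cis-unique junction total per viewpoint row (both ends counted)."""
    chrom, start, end = row_region
    n = math.ceil((end - start) / pixel_size)
    tot = np.zeros(n)
    for j in junctions:
        if j.chrom != chrom or not j.cis:
            continue
        for p in (j.pos_a, j.pos_b):
            if start <= p < end:
                tot[(p - start) // pixel_size] += 1
    return tot


# ---------------------------------------------------------------------------
# periodicity


def junction_distance_spectrum(
    junctions: list[LigationJunction],
    region: tuple[str, int, int] | None = None,
    d_range: tuple[int, int] = (50, 1000),
    smooth_window: int = 11,
    min_period: int = 100,
):
    """Histogram of inter-junction distances and the dominant period.

    The dominant period is the location of the largest smoothed local
    maximum beyond ``min_period`` bp; nucleosome-spaced chromatin shows it
    at about one repeat length. Requires >= 100 junctions.
    """
    from scipy.signal import find_peaks

    if region is not None:
        chrom, start, end = region
        junctions = [
            j
            for j in junctions
            if j.chrom == chrom and start <= j.pos_a < end and start <= j.pos_b < end
        ]
    if len(junctions) < 100:
        raise ValueError(f"need >= 100 junctions in region, got {len(junctions)}")
    lo, hi = d_range
    dists = np.array([j.distance for j in junctions])
    hist = np.bincount(
        dists[(dists >= lo) & (dists <= hi)] - lo, minlength=hi - lo + 1
    ).astype(float)
    kernel = np.ones(smooth_window) / smooth_window
    smooth = np.convolve(hist, kernel, mode="same")
    peaks, props = find_peaks(smooth, height=0)
    cand = [(int(p) + lo, smooth[p]) for p in peaks if p + lo > min_period]
    if not cand:
        raise ValueError("no local maximum beyond min_period")
    cand.sort(key=lambda t: -t[1])
    return {
        "distances": np.arange(lo, hi + 1),
        "histogram": hist,
        "smoothed": smooth,
        "dominant_period": cand[0][0],
        "secondary_maxima": [c[0] for c in cand[1:6]],
    }
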