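"""Viewpoint-profile peak comparison between conditions.

Peaks (called from a 1D junction-density profile by local enrichment, or
supplied as BED) are filtered on width and distance from the viewpoint;
per-replicate junction counts in each peak are scaled to counts per 1e5
cis-unique junctions of the viewpoint (capture-efficiency normalization),
compared by Welch's t-test with Benjamini-Hochberg correction, and flagged
as significantly skewed when q < alpha and |log2 fold change| exceeds the
threshold. Annotation enrichment contrasts the intersection rate of
significant vs non-significant peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CIS_SCALE = 1e5


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    viewpoint_id: str = ""
    distance_from_viewpoint: int = 0
    counts_control: np.ndarray | None = None
    counts_treated: np.ndarray | None = None
    norm_control: np.ndarray | None = None
    norm_treated: np.ndarray | None = None
    log2fc: float = np.nan
    skew: float = np.nan
    p_value: float = np.nan
    q_value: float = np.nan
    significant: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start


def call_and_filter_peaks(
    profile: np.ndarray | None,
    viewpoint: tuple[str, int],
    min_width: int,
    max_width: int,
    min_distance: int,
    chrom: str | None = None,
    peaks: list[tuple[str, int, int]] | None = None,
    enrichment_factor: float = 3.0,
    median_window: int = 2001,
) -> list[Peak]:
    """Call candidate peaks from a per-bp profile (runs above the local
    median times ``enrichment_factor``) or ingest BED peaks, then filter on
    width in [min_width, max_width] and distance from the viewpoint.
    """
    vchrom, vpos = viewpoint
    cands: list[tuple[str, int, int]] = []
    if peaks is not None:
        for c, s, e, *_ in peaks:
            cands.append((c, int(s), int(e)))
    else:
        if profile is None:
            raise ValueError("either a profile or explicit peaks are required")
        chrom = chrom or vchrom
        if chrom != vchrom:
            raise ValueError(
                f"viewpoint chromosome {vchrom!r} does not match profile chromosome {chrom!r}"
            )
        prof = np.asarray(profile, dtype=float)
        from scipy.ndimage import median_filter

        local_med = median_filter(prof, size=min(median_window, prof.size), mode="nearest")
        thr = np.maximum(local_med * enrichment_factor, 1e-12)
        above = prof > thr
        edges = np.flatnonzero(np.diff(np.r_[0, above.view(np.int8), 0]))
        for s, e in zip(edges[::2], edges[1::2]):
            cands.append((chrom, int(s), int(e)))
    out = []
    for c, s, e in cands:
        if c != vchrom:
            continue
        w = e - s
        if not (min_width <= w <= max_width):
            continue
        dist = 0 if s <= vpos < e else min(abs(s - vpos), abs(e - 1 - vpos))
        if dist < min_distance:
            continue
        out.append(Peak(c, s, e, distance_from_viewpoint=dist))
    return out


def count_junctions_in_peaks(
    peaks: list[Peak], junction_positions_by_rep: list[np.ndarray]
) -> np.ndarray:
    """(n_peaks, n_reps) unique-junction endpoint counts per peak."""
    mat = np.zeros((len(peaks), len(junction_positions_by_rep)))
    for r, pos in enumerate(junction_positions_by_rep):
        pos = np.sort(np.asarray(pos))
        for i, p in enumerate(peaks):
            mat[i, r] = np.searchsorted(pos, p.end) - np.searchsorted(pos, p.start)
    return mat


def compare_peak_counts(
    peaks: list[Peak],
    counts_control: np.ndarray,
    counts_treated: np.ndarray,
    cis_totals_control: np.ndarray,
    cis_totals_treated: np.ndarray,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> list[Peak]:
    """Normalize per-replicate peak counts to per-1e5 cis-unique junctions,
    Welch t-test per peak, BH q-values, and the significant-skew flag
    (q < alpha and |log2FC| > fc_threshold).

    Skew = log2((mean_treated + pc) / (mean_control + pc)). Replicates with
    zero cis total are masked for that peak rather than divided.
    """
    from scipy import stats
    from statsmodels.stats.multitest import multipletests

    counts_control = np.asarray(counts_control, dtype=float)
    counts_treated = np.asarray(counts_treated, dtype=float)
    if counts_control.shape[1] < 2 or counts_treated.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    fc_c = np.where(cis_totals_control > 0, CIS_SCALE / np.maximum(cis_totals_control, 1), np.nan)
    fc_t = np.where(cis_totals_treated > 0, CIS_SCALE / np.maximum(cis_totals_treated, 1), np.nan)
    norm_c = counts_control * fc_c[None, :]
    norm_t = counts_treated * fc_t[None, :]

    ps = np.full(len(peaks), np.nan)
    for i, p in enumerate(peaks):
        a = norm_c[i][np.isfinite(norm_c[i])]
        b = norm_t[i][np.isfinite(norm_t[i])]
        p.counts_control = counts_control[i]
        p.counts_treated = counts_treated[i]
        p.norm_control = norm_c[i]
        p.norm_treated = norm_t[i]
        ma, mb = a.mean() if a.size else np.nan, b.mean() if b.size else np.nan
        p.skew = float(np.log2((mb + pseudocount) / (ma + pseudocount)))
        p.log2fc = p.skew
        if a.size >= 2 and b.size >= 2:
            if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(ma, mb):
                ps[i] = 1.0
            else:
                ps[i] = stats.ttest_ind(a, b, equal_var=False).pvalue
        if not np.isfinite(ps[i]):
            ps[i] = 1.0 if np.isclose(ma, mb) else np.nan
        p.p_value = ps[i]
    ok = np.isfinite(ps)
    if ok.any():
        _, qs, _, _ = multipletests(ps[ok], alpha=alpha, method="fdr_bh")
        it = iter(qs)
        for p, good in zip(peaks, ok):
            p.q_value = float(next(it)) if good else np.nan
            p.significant = bool(
                good and p.q_value < alpha and abs(p.log2fc) > fc_threshold
            )
    return peaks


def annotation_enrichment(
    significant: list[Peak],
    nonsignificant: list[Peak],
    annotation: list[tuple[str, int, int]],
) -> dict:
    """log2 of (fraction of significant peaks intersecting the annotation) /
    (same fraction for non-significant peaks); >= 1 bp overlap counts.

    A zero fraction gets a Haldane (add 0.5 to counts) correction and the
    result is flagged as corrected.
    """
    if not significant:
        raise ValueError("significant peak set is empty")
    if not nonsignificant:
        raise ValueError("non-significant peak set is empty")

    ann = sorted((c, int(s), int(e)) for c, s, e, *_ in annotation)

    def hits(peaks: list[Peak]) -> int:
        n = 0
        for p in peaks:
            if any(c == p.chrom and s < p.end and p.start < e for c, s, e in ann):
                n += 1
        return n

    ks, kn = hits(significant), hits(nonsignificant)
    ns, nn = len(significant), len(nonsignificant)
    corrected = ks == 0 or kn == 0 or ks == ns or kn == nn
    if corrected:
        fs = (ks + 0.5) / (ns + 1.0)
        fn = (kn + 0.5) / (nn + 1.0)
    else:
        fs, fn = ks / ns, kn / nn
    return {
        "log2_enrichment": float(np.log2(fs / fn)),
        "significant_hits": ks,
        "significant_total": ns,
        "nonsignificant_hits": kn,
        "nonsignificant_total": nn,
        "haldane_corrected": corrected,
    }
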