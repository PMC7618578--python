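"""Fragment reconstruction from paired reads and genome-collinear sub-read
splitting.

Sonicated 3C fragments average ~200 bp and are sequenced with 150-bp paired
ends, so most pairs overlap in the middle and the full fragment sequence can
be reconstructed by overlap merging. Reconstructed reads are chimeric:
proximity ligation concatenates pieces from distant loci, so each read is
split into genome-collinear sub-reads by seeded exact matching with bounded
mismatch extension. Breakpoint micro-homology (bases consistent with both
flanking alignments) is assigned to the upstream (left-in-read) sub-read,
which makes junction coordinates canonical and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq import encode, revcomp, revcomp_arr


@dataclass
class MergedRead:
    id: str
    sequence: str
    qualities: str
    merged: bool
    source: tuple[int, int, int]  # (r1_len, r2_len, overlap_len)


@dataclass
class SubRead:
    read_id: str
    read_interval: tuple[int, int]  # within the reconstructed read
    genome_interval: tuple[str, int, int]
    strand: str
    edit_distance: int


# ---------------------------------------------------------------------------
# pair merging


def _best_overlap(r1: str, rc2: str, min_overlap: int, max_mismatch_rate: float):
    """Longest suffix(r1)/prefix(rc2) overlap with tolerable mismatch rate.

    Returns (overlap_len, n_mismatches) or None. Exact overlaps are found by
    string search; a seed-probe scan handles sequencing errors.
    """
    L1, L2 = len(r1), len(rc2)
    lim = min(L1, L2)
    # exact path: every occurrence of the rc2 seed in r1 is a candidate
    seed = rc2[:min_overlap]
    start = 0
    best_exact = None
    while True:
        i = r1.find(seed, start)
        if i < 0:
            break
        o = L1 - i
        if o <= lim and r1[i:] == rc2[: L1 - i]:
            best_exact = (o, 0)
            break  # leftmost hit = longest exact overlap
        start = i + 1
    if best_exact:
        return best_exact
    # noisy path: probe several seeds to propose offsets, verify with numpy
    a1 = encode(r1)
    a2 = encode(rc2)
    cands = set()
    for j in range(0, max(1, L2 - min_overlap), 16):
        i = -1
        while True:
            i = r1.find(rc2[j : j + min_overlap], i + 1)
            if i < 0:
                break
            o = L1 - (i - j)
            if min_overlap <= o <= lim and i - j >= 0:
                cands.add(o)
    best = None
    for o in sorted(cands, reverse=True):
        mm = int(np.count_nonzero(a1[L1 - o :] != a2[:o]))
        if mm / o <= max_mismatch_rate:
            best = (o, mm)
            break
    return best


def merge_read_pairs(
    r1_reads,
    r2_reads,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.25,
) -> tuple[list[MergedRead], dict]:
    """Reconstruct full fragment sequences by overlapping R1 with the
    reverse complement of R2 (FLASH-style).

    Unmergeable pairs are passed through as two reads flagged unmerged.
    Disagreeing overlap bases are resolved to the higher-quality call.
    """
    if len(r1_reads) != len(r2_reads):
        raise ValueError("R1 and R2 files contain different read counts")
    out: list[MergedRead] = []
    n_merged = 0
    for (id1, s1, q1), (id2, s2, q2) in zip(r1_reads, r2_reads):
        b1 = id1.rsplit("/", 1)[0]
        b2 = id2.rsplit("/", 1)[0]
        if b1 != b2:
            raise ValueError(f"read id mismatch between pair files: {id1!r} vs {id2!r}")
        rc2 = revcomp(s2)
        qc2 = q2[::-1]
        hit = _best_overlap(s1, rc2, min_overlap, max_mismatch_rate)
        if hit is None:
            out.append(MergedRead(b1 + "/1", s1, q1, False, (len(s1), len(s2), 0)))
            out.append(MergedRead(b1 + "/2", s2, q2, False, (len(s1), len(s2), 0)))
            continue
        o, _ = hit
        i0 = len(s1) - o
        merged = list(s1[:i0])
        qual = list(q1[:i0])
        for k in range(o):
            c1, c2 = s1[i0 + k], rc2[k]
            if c1 == c2 or q1[i0 + k] >= qc2[k]:
                merged.append(c1)
                qual.append(q1[i0 + k])
            else:
                merged.append(c2)
                qual.append(qc2[k])
        merged.extend(rc2[o:])
        qual.extend(qc2[o:])
        out.append(
            MergedRead(b1, "".join(merged), "".join(qual), True, (len(s1), len(s2), o))
        )
        n_merged += 1
    stats = {
        "pairs": len(r1_reads),
        "merged": n_merged,
        "merged_fraction": n_merged / len(r1_reads) if r1_reads else 0.0,
    }
    return out, stats


# ---------------------------------------------------------------------------
# capture-region pre-filter


def prefilter_capture_reads(
    reads: list[MergedRead],
    capture_regions: list[tuple[str, int, int]],
    reference: dict[str, str],
    flank: int = 800,
    seed_length: int = 20,
) -> list[MergedRead]:
    """Retain reads sharing any exact ``seed_length``-mer (either strand)
    with a capture region extended by ``flank`` bp on both sides."""
    if not capture_regions:
        raise ValueError("capture_regions must be non-empty")
    kmers: set[str] = set()
    for chrom, s, e in capture_regions:
        if chrom not in reference:
            raise ValueError(f"capture region chromosome {chrom!r} not in reference")
        ref = reference[chrom]
        if not (0 <= s < e <= len(ref)):
            raise ValueError(f"capture region {(chrom, s, e)} outside reference bounds")
        sub = ref[max(0, s - flank) : min(len(ref), e + flank)]
        for i in range(len(sub) - seed_length + 1):
            k = sub[i : i + seed_length]
            kmers.add(k)
            kmers.add(revcomp(k))
    kept = []
    for r in reads:
        s = r.sequence
        if any(s[i : i + seed_length] in kmers for i in range(len(s) - seed_length + 1)):
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# seeded sub-read mapping


class ReferenceIndex:
    """Exact k-mer index over one reference sequence plus its reverse
    complement, supporting bounded-mismatch extension."""

    def __init__(self, reference: dict[str, str] | str, k: int = 20, chrom: str | None = None):
        if isinstance(reference, str):
            reference = {chrom or "chrS": reference}
        if len(reference) != 1:
            raise ValueError("single-chromosome references only")
        ((self.chrom, seq),) = reference.items()
        self.k = k
        self.fwd = encode(seq)
        self.rev = revcomp_arr(self.fwd).copy()
        self.length = len(seq)
        self.index: dict[bytes, list[tuple[int, int]]] = {}
        for strand, arr in ((0, self.fwd), (1, self.rev)):
            data = arr.tobytes()
            for i in range(len(data) - k + 1):
                self.index.setdefault(data[i : i + k], []).append((strand, i))

    def lookup(self, kmer: bytes) -> list[tuple[int, int]]:
        return self.index.get(kmer, [])


def _extend_match(
    read: np.ndarray, i: int, garr: np.ndarray, p: int, max_mismatches: int, guard: int = 4
) -> tuple[int, int]:
    """Maximal extension length of read[i:] against garr[p:] allowing up to
    ``max_mismatches`` substitutions, each followed by >= ``guard`` matches;
    the extension always ends on a match. Returns (length, mismatches)."""
    n = min(read.size - i, garr.size - p)
    if n <= 0:
        return 0, 0
    eq = read[i : i + n] == garr[p : p + n]
    mis = np.flatnonzero(~eq)
    if mis.size == 0:
        return n, 0
    length = int(mis[0])
    used = 0
    j = 0
    while used < max_mismatches and j < mis.size:
        m = int(mis[j])
        nxt = int(mis[j + 1]) if j + 1 < mis.size else n
        if nxt - m - 1 >= guard or (nxt == n and n - m - 1 >= 1):
            used += 1
            length = nxt
            j += 1
        else:
            break
    return length, used


def split_and_map_subreads(
    read: MergedRead,
    index: ReferenceIndex,
    min_subread: int = 20,
    max_mismatches: int = 2,
) -> list[SubRead]:
    """Split a reconstructed read into genome-collinear sub-reads.

    Greedy left-to-right chaining of maximal seeded matches; alignment
    breakpoints partition the read, ambiguous (micro-homologous) bases go to
    the upstream sub-read, and leftovers shorter than ``min_subread`` are
    discarded. An unmappable read yields an empty list.
    """
    r = encode(read.sequence)
    k = index.k
    L = index.length
    subs: list[SubRead] = []
    i = 0
    while i + min_subread <= r.size:
        seed = r[i : i + k].tobytes()
        best = None
        for strand, p in index.lookup(seed):
            garr = index.fwd if strand == 0 else index.rev
            length, mm = _extend_match(r, i, garr, p, max_mismatches)
            if best is None or length > best[0]:
                best = (length, mm, strand, p)
        if best is None or best[0] < min_subread:
            i += 1
            continue
        length, mm, strand, p = best
        if strand == 0:
            gi = (index.chrom, p, p + length)
            st = "+"
        else:
            gi = (index.chrom, L - p - length, L - p)
            st = "-"
        subs.append(SubRead(read.id, (i, i + length), gi, st, mm))
        i += length
    return subs


# ---------------------------------------------------------------------------
# SAM interchange


def subreads_to_sam(subreads: list[SubRead], index: ReferenceIndex) -> str:
    """One SAM record per sub-read; query name is read_id/segment-index."""
    lines = [
        "@HD\tVN:1.6\tSO:unknown",
        f"@SQ\tSN:{index.chrom}\tLN:{index.length}",
    ]
    by_read: dict[str, int] = {}
    for s in subreads:
        seg = by_read.get(s.read_id, 0)
        by_read[s.read_id] = seg + 1
        flag = 16 if s.strand == "-" else 0
        chrom, gs, ge = s.genome_interval
        ln = ge - gs
        lines.append(
            "\t".join(
                [
                    f"{s.read_id}:{seg}",
                    str(flag),
                    chrom,
                    str(gs + 1),
                    "255",
                    f"{ln}M",
                    "*",
                    "0",
                    "0",
                    "*",
                    "*",
                    f"NM:i:{s.edit_distance}",
                    f"XR:Z:{s.read_interval[0]}-{s.read_interval[1]}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def subreads_from_sam(path) -> list[SubRead]:
    """Ingest externally aligned sub-reads (query name read_id:segment,
    read-interval in the XR tag when present)."""
    import pysam

    subs = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            qn = rec.query_name
            rid = qn.rsplit(":", 1)[0] if ":" in qn else qn
            xr = None
            if rec.has_tag("XR"):
                a, b = rec.get_tag("XR").split("-")
                xr = (int(a), int(b))
            length = rec.reference_end - rec.reference_start
            subs.append(
                SubRead(
                    rid,
                    xr or (0, length),
                    (rec.reference_name, rec.reference_start, rec.reference_end),
                    "-" if rec.is_reverse else "+",
                    int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                )
            )
    return subs
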