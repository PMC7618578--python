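"""Ligation-junction calling from ordered sub-reads, with PCR deduplication.

A junction joins each adjacent pair of sub-reads of one reconstructed read.
Its coordinates are the two cut-adjacent bases: the genomic base under the
3' (in read orientation) end of the left sub-read and the base under the 5'
start of the right sub-read, 0-based. The direction flag of each side
records where the sequenced fragment -- and therefore the protein footprint
protecting it from MNase -- lies relative to the cut: 'U' (toward_upstream)
when the fragment extends to lower coordinates, 'D' (toward_downstream)
when it extends to higher coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reconstruct import SubRead
from .synthetic import TOWARD_DOWNSTREAM, TOWARD_UPSTREAM

SHORT_RANGE_THRESHOLD = 1000


@dataclass(frozen=True)
class LigationJunction:
    chrom: str
    pos_a: int
    pos_b: int
    dir_a: str
    dir_b: str
    fragment_ends: tuple[int, int]
    read_id: str
    cis: bool = True

    @property
    def range_class(self) -> str:
        return "short" if abs(self.pos_b - self.pos_a) < SHORT_RANGE_THRESHOLD else "long"

    @property
    def distance(self) -> int:
        return abs(self.pos_b - self.pos_a)


def _junction_end(sub: SubRead, side: str) -> tuple[int, str]:
    """Genomic base and direction flag of a sub-read end.

    ``side='right'`` is the 3'-in-read end (left member of a junction),
    ``side='left'`` the 5'-in-read end (right member).
    """
    chrom, gs, ge = sub.genome_interval
    if side == "right":
        if sub.strand == "+":
            return ge - 1, TOWARD_UPSTREAM
        return gs, TOWARD_DOWNSTREAM
    if sub.strand == "+":
        return gs, TOWARD_DOWNSTREAM
    return ge - 1, TOWARD_UPSTREAM


def _outer_end(sub: SubRead, side: str) -> int:
    """Outermost genomic coordinate of the first/last aligned read base."""
    _, gs, ge = sub.genome_interval
    if side == "start":  # read 5' end
        return gs if sub.strand == "+" else ge - 1
    return ge - 1 if sub.strand == "+" else gs


def call_junctions(subreads: list[SubRead]) -> list[LigationJunction]:
    """One canonically sorted junction per adjacent sub-read pair of a read.

    Non-adjacent pairs from 3-way ligations are not emitted. A single
    sub-read yields no junctions.
    """
    if len(subreads) < 2:
        return []
    subs = sorted(subreads, key=lambda s: s.read_interval)
    frag = (_outer_end(subs[0], "start"), _outer_end(subs[-1], "end"))
    frag = (min(frag), max(frag))
    out = []
    for left, right in zip(subs, subs[1:]):
        pos_a, dir_a = _junction_end(left, "right")
        pos_b, dir_b = _junction_end(right, "left")
        chrom = left.genome_interval[0]
        cis = chrom == right.genome_interval[0]
        if pos_a > pos_b:
            pos_a, pos_b, dir_a, dir_b = pos_b, pos_a, dir_b, dir_a
        out.append(
            LigationJunction(chrom, pos_a, pos_b, dir_a, dir_b, frag, left.read_id, cis)
        )
    return out


def call_junctions_for_reads(
    subreads_by_read: dict[str, list[SubRead]]
) -> list[LigationJunction]:
    out = []
    for subs in subreads_by_read.values():
        out.extend(call_junctions(subs))
    return out


def deduplicate_junctions(junctions: list[LigationJunction]) -> list[LigationJunction]:
    """Collapse PCR duplicates on (pos_a, pos_b, dir_a, dir_b, fragment_ends).

    Two molecules ligated in opposite orientations at the same coordinates
    are distinct events, so direction flags are part of the key; sonication
    fragment ends differing by a single base keep junctions distinct.
    Output is stably sorted by (pos_a, pos_b); the operation is idempotent.
    """
    seen = {}
    for j in junctions:
        key = (j.chrom, j.pos_a, j.pos_b, j.dir_a, j.dir_b, j.fragment_ends)
        if key not in seen:
            seen[key] = j
    return sorted(seen.values(), key=lambda j: (j.chrom, j.pos_a, j.pos_b))


def junction_table(junctions: list[LigationJunction]) -> "pandas.DataFrame":
    """Tab-separable junction table (0-based coordinates)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chrom": j.chrom,
                "pos_a": j.pos_a,
                "pos_b": j.pos_b,
                "dir_a": j.dir_a,
                "dir_b": j.dir_b,
                "frag_start": j.fragment_ends[0],
                "frag_end": j.fragment_ends[1],
                "read_id": j.read_id,
            }
            for j in junctions
        ],
        columns=[
            "chrom",
            "pos_a",
            "pos_b",
            "dir_a",
            "dir_b",
            "frag_start",
            "frag_end",
            "read_id",
        ],
    )


def junctions_to_bedpe(junctions: list[LigationJunction]) -> str:
    lines = []
    for j in junctions:
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    j.chrom,
                    j.pos_a,
                    j.pos_a + 1,
                    j.chrom,
                    j.pos_b,
                    j.pos_b + 1,
                    j.read_id,
                    ".",
                    "+" if j.dir_a == TOWARD_DOWNSTREAM else "-",
                    "+" if j.dir_b == TOWARD_DOWNSTREAM else "-",
                )
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
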