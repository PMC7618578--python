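"""Capture oligonucleotide tiling design.

Target regions are tiled with fixed-length oligos (default 120 bp) at a
fixed overlap fraction (default 50%, i.e. a 60-bp step); a final oligo is
right-anchored at the region end when the regular tiling would leave more
than half a step uncovered.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class CaptureDesign:
    region: tuple[str, int, int]
    oligo_length: int
    overlap: float
    oligos: list[tuple[str, int, int]]


def design_capture_tiling(
    region: tuple[str, int, int],
    oligo_length: int = 120,
    overlap: float = 0.5,
) -> CaptureDesign:
    chrom, start, end = region
    L = end - start
    if L < oligo_length:
        raise ValueError(f"region length {L} shorter than oligo length {oligo_length}")
    if not (0 <= overlap < 1):
        raise ValueError("overlap fraction must be in [0, 1)")
    step = round(oligo_length * (1 - overlap))
    if step < 1:
        raise ValueError("overlap too large: step would be zero")
    oligos = []
    k = 0
    while start + k * step + oligo_length <= end:
        s = start + k * step
        oligos.append((chrom, s, s + oligo_length))
        k += 1
    covered_to = oligos[-1][2]
    if end - covered_to > step / 2:
        oligos.append((chrom, end - oligo_length, end))
    return CaptureDesign(region, oligo_length, overlap, oligos)
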