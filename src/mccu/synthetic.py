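"""Ground-truthed simulator for MNase-based 3C (MCC-style) sequencing libraries.

The generator emulates the physical steps that produce a Micro Capture-C
library: MNase digestion of chromatin in which nucleosome cores and
transcription-factor footprints are protected and cutting is enhanced in the
few base pairs flanking a footprint; proximity ligation whose pair
frequencies follow a contact model (power-law distance decay modulated by
nanoscale-domain, NDR-pair and CTCF-pair enrichment factors); sonication of
the ligated molecules to ~200-bp fragments; and 150-bp paired-end
sequencing. Every simulated molecule carries a truth record with the exact
ligation-junction coordinates and read directions, so junction calling can
be scored base-exactly.

Coordinates are 0-based half-open. A "cut" at position c separates bases
c-1 and c; a fragment lying upstream (left) of its cut therefore ends at
base c-1 and a fragment lying downstream starts at base c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq import random_dna, revcomp

CORE_HALF = 73  # nucleosome core = 147 bp around the dyad
MIN_REPEAT = 157  # core + minimal linker
FOOTPRINT_FLANK = 5  # bp of enhanced cutting at each footprint edge
FLANK_WEIGHT = 4.0

# directionality flags: the side of the cut on which the sequenced
# (protein-protected) fragment lies
TOWARD_UPSTREAM = "U"
TOWARD_DOWNSTREAM = "D"


@dataclass(frozen=True)
class Nucleosome:
    dyad: int
    fixed: bool = False
    acetylated: bool = False


@dataclass
class GenomeFixture:
    """Synthetic reference with annotated chromatin architecture."""

    sequence: str
    nucleosomes: list[Nucleosome]
    repeat_length: int
    ndrs: list[tuple[int, int]]
    tf_footprints: list[tuple[tuple[int, int], str]]
    ctcf_sites: list[tuple[int, str]]
    phase_mode: str
    seed: int
    chrom: str = "chrS"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ContactModel:
    """Pairwise contact propensities between candidate cut sites.

    All enrichment factors are >= 1 and multiply a power-law distance decay
    ``(1 + d) ** -decay_exponent``.
    """

    background_rate: float = 1.0
    domain_boundaries: list[int] | None = None  # defaults to NDR centres
    within_domain_factor: float = 3.0
    ndr_pair_factor: float = 10.0
    ctcf_pair_factor: float = 10.0
    tf_pair_factor: float = 1.0
    linker_periodic_factor: float = 1.0
    decay_exponent: float = 1.0

    def validate(self) -> None:
        facs = [
            self.within_domain_factor,
            self.ndr_pair_factor,
            self.ctcf_pair_factor,
            self.tf_pair_factor,
            self.linker_periodic_factor,
        ]
        if not all(np.isfinite(f) and f >= 1 for f in facs):
            raise ValueError("contact model factors must be finite and >= 1")
        if not (np.isfinite(self.background_rate) and self.background_rate >= 0):
            raise ValueError("background_rate must be finite and nonnegative")


@dataclass
class TruthJunction:
    pos_a: int
    pos_b: int
    dir_a: str
    dir_b: str
    read_offset: int  # boundary offset within the molecule sequence


@dataclass
class SimulatedMolecule:
    """One chimeric proximity-ligation product plus its truth record."""

    id: int
    sequence: str
    # (genome_start, genome_end, strand) per fragment, in molecule order
    pieces: list[tuple[int, int, str]]
    junctions: list[TruthJunction]

    @property
    def fragment_ends(self) -> tuple[int, int]:
        return (min(p[0] for p in self.pieces), max(p[1] for p in self.pieces))


# TruthRecord in the external sense: one SimulatedMolecule per chimeric
# molecule, carrying read id, true junctions and fragment ends.
TruthRecord = SimulatedMolecule


# ---------------------------------------------------------------------------
# fixture construction


def layout_nucleosome_array(n_nucleosomes: int, repeat_length: int) -> tuple[list[int], int]:
    """Regular nucleosome array: dyads at repeat/2 + i*repeat, span n*repeat."""
    if n_nucleosomes < 1:
        raise ValueError("n_nucleosomes must be >= 1")
    if repeat_length < MIN_REPEAT:
        raise ValueError(f"repeat_length must be >= {MIN_REPEAT}")
    dyads = [repeat_length // 2 + i * repeat_length for i in range(n_nucleosomes)]
    return dyads, n_nucleosomes * repeat_length


def _segments(length: int, ndrs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    segs, prev = [], 0
    for s, e in ndrs:
        if s > prev:
            segs.append((prev, s))
        prev = e
    if prev < length:
        segs.append((prev, length))
    return segs


def _tile_dyads(seg: tuple[int, int], repeat: int, phase: int = 0) -> list[int]:
    s, e = seg
    first = s + (repeat // 2 + phase) % repeat
    out = []
    d = first
    while d + CORE_HALF + 1 <= e:
        if d - CORE_HALF >= s:
            out.append(d)
        d += repeat
    return out


def build_fixture(
    length: int,
    repeat_length: int = 190,
    ndrs: list[tuple[int, int]] | None = None,
    tf_footprints: list[tuple[tuple[int, int], str]] | None = None,
    ctcf_sites: list[tuple[int, str]] | None = None,
    phase_mode: str = "fixed",
    seed: int = 0,
) -> GenomeFixture:
    """Build a synthetic reference with nucleosomes tiled at ``repeat_length``
    over all non-NDR sequence.

    ``phase_mode='random'`` keeps the annotated (phase-0) nucleosomes but
    marks the fixture so that the ligation simulator redraws one global phase
    offset per molecule: individual positions vary, spacing stays fixed.
    """
    if length < 1000:
        raise ValueError("fixture length must be >= 1000 bp")
    if repeat_length < MIN_REPEAT:
        raise ValueError(
            f"repeat_length must be >= {MIN_REPEAT} bp (147-bp core + minimal linker)"
        )
    if phase_mode not in ("fixed", "random"):
        raise ValueError("phase_mode must be 'fixed' or 'random'")
    ndrs = sorted(tuple(x) for x in (ndrs or []))
    for i, (s, e) in enumerate(ndrs):
        if not (0 <= s < e <= length):
            raise ValueError(f"NDR {(s, e)} outside [0, {length})")
        if i and s < ndrs[i - 1][1]:
            raise ValueError(f"overlapping NDRs: {ndrs[i - 1]} and {(s, e)}")
    tf_footprints = [(tuple(iv), lab) for iv, lab in (tf_footprints or [])]
    for (s, e), _ in tf_footprints:
        if not (0 <= s < e <= length):
            raise ValueError(f"footprint {(s, e)} outside [0, {length})")
    ctcf_sites = list(ctcf_sites or [])
    for pos, _ in ctcf_sites:
        if not (0 <= pos < length):
            raise ValueError(f"CTCF site {pos} outside [0, {length})")

    rng = np.random.default_rng(seed)
    sequence = random_dna(length, rng)

    fp_ivs = [iv for iv, _ in tf_footprints]
    nucleosomes = []
    for seg in _segments(length, ndrs):
        for d in _tile_dyads(seg, repeat_length):
            core = (d - CORE_HALF, d + CORE_HALF + 1)
            if any(core[0] < fe and fs < core[1] for fs, fe in fp_ivs):
                continue
            fixed = any(abs(d - p) <= 2 * repeat_length for p, _ in ctcf_sites)
            nucleosomes.append(Nucleosome(d, fixed=fixed))
    return GenomeFixture(
        sequence=sequence,
        nucleosomes=nucleosomes,
        repeat_length=repeat_length,
        ndrs=ndrs,
        tf_footprints=tf_footprints,
        ctcf_sites=ctcf_sites,
        phase_mode=phase_mode,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cut-site model

# per-bp cut-site classes used by the pair-factor model
CLS_LINKER, CLS_NDR, CLS_CTCF, CLS_TF_FLANK = 0, 1, 2, 3


def cut_weights(fixture: GenomeFixture, phase: int = 0) -> np.ndarray:
    """Per-bp MNase cut weight: 0 in 147-bp cores and inside footprints,
    1 in linkers and NDR interiors, enhanced in the 5 bp flanking each
    footprint edge."""
    L = len(fixture)
    w = np.ones(L)
    for (fs, fe), _ in fixture.tf_footprints:
        w[max(0, fs - FOOTPRINT_FLANK) : fs] = FLANK_WEIGHT
        w[fe : min(L, fe + FOOTPRINT_FLANK)] = FLANK_WEIGHT
    for seg in _segments(L, fixture.ndrs):
        for d in _tile_dyads(seg, fixture.repeat_length, phase):
            w[max(0, d - CORE_HALF) : min(L, d + CORE_HALF + 1)] = 0.0
    for (fs, fe), _ in fixture.tf_footprints:
        w[fs:fe] = 0.0
    return w


def _site_classes(fixture: GenomeFixture) -> tuple[np.ndarray, np.ndarray]:
    """Per-bp class label and domain id (domains bounded by NDR centres)."""
    L = len(fixture)
    cls = np.full(L, CLS_LINKER, dtype=np.int8)
    for s, e in fixture.ndrs:
        cls[s:e] = CLS_NDR
    for pos, _ in fixture.ctcf_sites:
        cls[max(0, pos - 20) : min(L, pos + 21)] = CLS_CTCF
    for (fs, fe), _ in fixture.tf_footprints:
        cls[max(0, fs - FOOTPRINT_FLANK) : min(L, fe + FOOTPRINT_FLANK)] = CLS_TF_FLANK
    boundaries = [(s + e) // 2 for s, e in fixture.ndrs]
    dom = np.searchsorted(boundaries, np.arange(L)).astype(np.int32)
    return cls, dom


def _footprint_side(fixture: GenomeFixture) -> np.ndarray:
    """-1 outside flanks; 0 if the footprint lies to the right of this
    position (left flank); 1 if it lies to the left (right flank)."""
    L = len(fixture)
    side = np.full(L, -1, dtype=np.int8)
    for (fs, fe), _ in fixture.tf_footprints:
        side[max(0, fs - FOOTPRINT_FLANK) : fs] = 0
        side[fe : min(L, fe + FOOTPRINT_FLANK)] = 1
    return side


def _pair_factor_rows(
    idx: np.ndarray,
    positions: np.ndarray,
    cls: np.ndarray,
    dom: np.ndarray,
    model: ContactModel,
) -> np.ndarray:
    """Rows of the (factors x decay) pair-weight matrix for anchor indices
    ``idx`` against all candidate positions."""
    pa = positions[idx][:, None]
    pb = positions[None, :]
    d = np.abs(pa - pb).astype(float)
    decay = (1.0 + d) ** (-model.decay_exponent)
    flat = (
        model.within_domain_factor == 1.0
        and model.ndr_pair_factor == 1.0
        and model.ctcf_pair_factor == 1.0
        and model.tf_pair_factor == 1.0
        and model.linker_periodic_factor == 1.0
    )
    if flat:
        return decay
    ca = cls[positions[idx]][:, None]
    da = dom[positions[idx]][:, None]
    cb = cls[positions][None, :]
    db = dom[positions][None, :]
    F = np.where(da == db, model.within_domain_factor, 1.0)
    F = F * np.where((ca == CLS_NDR) & (cb == CLS_NDR), model.ndr_pair_factor, 1.0)
    F = F * np.where((ca == CLS_CTCF) & (cb == CLS_CTCF), model.ctcf_pair_factor, 1.0)
    F = F * np.where(
        (ca == CLS_TF_FLANK) & (cb == CLS_TF_FLANK), model.tf_pair_factor, 1.0
    )
    F = F * np.where(
        (ca == CLS_LINKER) & (cb == CLS_LINKER), model.linker_periodic_factor, 1.0
    )
    return F * decay


def pair_weight_marginal(
    fixture: GenomeFixture, model: ContactModel, phase: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate cut positions and the exact marginal sampling weight of each
    as a junction endpoint (oracle for goodness-of-fit tests)."""
    model.validate()
    w = cut_weights(fixture, phase)
    positions = np.flatnonzero(w)
    wv = w[positions]
    cls, dom = _site_classes(fixture)
    S = np.empty(len(positions))
    for i0 in range(0, len(positions), 256):
        blk = np.arange(i0, min(i0 + 256, len(positions)))
        rows = _pair_factor_rows(blk, positions, cls, dom, model)
        np.fill_diagonal(rows[:, i0 : i0 + len(blk)], 0.0)
        S[blk] = rows @ wv
    marg = wv * S
    return positions, marg / marg.sum()


# ---------------------------------------------------------------------------
# ligation-event simulation

N_PHASES = 32  # discretisation of the per-molecule random phase offset
THIRD_FRAGMENT_PROB = 0.1
FOOTPRINT_SIDE_BIAS = 0.9  # P(fragment extends across the protected footprint)
EDGE_MARGIN = 350
MIN_FRAGMENT = 40


def _sample_pairs_for_phase(
    fixture: GenomeFixture,
    model: ContactModel,
    phase: int,
    n: int,
    rng: np.random.Generator,
    cls: np.ndarray,
    dom: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample n junction cut-position pairs; returns (cut_a, cut_b, positions)."""
    w = cut_weights(fixture, phase)
    positions = np.flatnonzero(w)
    if positions.size < 2:
        raise ValueError("no candidate cut sites in fixture")
    wv = w[positions]

    # marginal over anchors: p(a) ~ w[a] * sum_b w[b] F(a,b) decay(|a-b|)
    S = np.empty(len(positions))
    for i0 in range(0, len(positions), 256):
        blk = np.arange(i0, min(i0 + 256, len(positions)))
        rows = _pair_factor_rows(blk, positions, cls, dom, model)
        np.fill_diagonal(rows[:, i0 : i0 + len(blk)], 0.0)
        S[blk] = rows @ wv
    pa = model.background_rate * wv * S
    total = pa.sum()
    if not (np.isfinite(total) and total > 0):
        raise ValueError("contact model weights are all zero")
    a_idx = np.searchsorted(np.cumsum(pa / total), rng.random(n))

    # conditional for the partner, one row per distinct anchor
    b_idx = np.empty(n, dtype=np.int64)
    uniq, inv = np.unique(a_idx, return_inverse=True)
    for u_pos in range(0, len(uniq), 128):
        blk = uniq[u_pos : u_pos + 128]
        rows = _pair_factor_rows(blk, positions, cls, dom, model) * wv[None, :]
        for k, u in enumerate(blk):
            row = rows[k]
            row[u] = 0.0
            cs = np.cumsum(row)
            sel = np.flatnonzero(inv == (u_pos + k))
            b_idx[sel] = np.searchsorted(cs, rng.random(sel.size) * cs[-1])
    return positions[a_idx], positions[b_idx], positions


def _choose_sides(
    cuts: np.ndarray, fp_side: np.ndarray, L: int, rng: np.random.Generator
) -> np.ndarray:
    """0 = fragment extends left (upstream) of each cut, 1 = right.

    Cuts in a footprint flank extend across the protected footprint with
    probability FOOTPRINT_SIDE_BIAS; cuts near an edge point inward."""
    side = rng.integers(0, 2, size=cuts.size).astype(np.int8)
    fp = fp_side[np.clip(cuts, 0, L - 1)]
    biased = (fp >= 0) & (rng.random(cuts.size) < FOOTPRINT_SIDE_BIAS)
    # fp == 0 means the footprint lies to the RIGHT, so the protected
    # fragment extends rightward (side 1), and vice versa
    side[biased] = 1 - fp[biased]
    side[cuts < EDGE_MARGIN] = 1
    side[cuts > L - EDGE_MARGIN] = 0
    return side


def _outer_ends(
    cuts: np.ndarray,
    sides: np.ndarray,
    positions: np.ndarray,
    L: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Other (non-junction) MNase cut of each fragment: a target distance is
    drawn and snapped to the nearest candidate cut site on the chosen side,
    at least MIN_FRAGMENT bp from the junction cut."""
    n = cuts.size
    npos = len(positions)
    delta = np.clip(rng.normal(250.0, 80.0, size=n), 80, 500).astype(np.int64)
    raw = np.clip(np.where(sides == 0, cuts - delta, cuts + delta), 0, L)
    i = np.searchsorted(positions, raw)
    lo = positions[np.clip(i - 1, 0, npos - 1)]
    hi = positions[np.clip(i, 0, npos - 1)]
    snapped = np.where(np.abs(raw - lo) <= np.abs(hi - raw), lo, hi)

    left = sides == 0
    lim_l = cuts - MIN_FRAGMENT
    jl = np.searchsorted(positions, lim_l, side="right") - 1
    cand_l = np.where(jl >= 0, positions[np.clip(jl, 0, npos - 1)], -1)
    bad_l = left & (snapped > lim_l)
    snapped = np.where(
        bad_l, np.where(cand_l >= 0, cand_l, np.maximum(0, lim_l)), snapped
    )
    lim_r = cuts + MIN_FRAGMENT
    jr = np.searchsorted(positions, lim_r, side="left")
    cand_r = np.where(jr < npos, positions[np.clip(jr, 0, npos - 1)], -1)
    bad_r = (~left) & (snapped < lim_r)
    snapped = np.where(
        bad_r, np.where(cand_r >= 0, cand_r, np.minimum(L, lim_r)), snapped
    )
    return snapped


def _piece_from_cut(cut: int, side: int, outer: int) -> tuple[int, int, str, int, str]:
    """Fragment interval, junction base and direction for a cut boundary.

    Returns (genome_start, genome_end, junction_dir, junction_pos, strand
    placeholder) -- orientation in the molecule is decided by the caller.
    """
    if side == 0:  # fragment upstream of the cut
        return outer, cut, TOWARD_UPSTREAM, cut - 1, "+"
    return cut, outer, TOWARD_DOWNSTREAM, cut, "+"


def _canonical_shift(
    seq: str, mol: str, t: int, piece_a: tuple[int, int, str], max_h: int
) -> int:
    """Micro-homology length at a junction: how far the upstream fragment's
    genomic continuation keeps matching the molecule past the junction.
    Both truth records and the sub-read splitter assign these ambiguous
    bases to the upstream fragment, making junction coordinates canonical."""
    gs, ge, strand = piece_a
    L = len(seq)
    h = 0
    while h < max_h and t + h < len(mol):
        if strand == "+":
            g = ge + h
            if g >= L:
                break
            exp = seq[g]
        else:
            g = gs - 1 - h
            if g < 0:
                break
            exp = revcomp(seq[g])
        if mol[t + h] != exp:
            break
        h += 1
    return h


def simulate_ligation_events(
    fixture: GenomeFixture,
    model: ContactModel,
    n_events: int,
    seed: int = 0,
    third_fragment_prob: float = THIRD_FRAGMENT_PROB,
) -> list[SimulatedMolecule]:
    """Simulate chimeric proximity-ligation molecules with exact truth.

    Each molecule concatenates 2 (with probability ``third_fragment_prob``,
    3) genomic fragments whose ends are MNase cut sites; junction pair
    frequencies follow the contact model times power-law distance decay.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    model.validate()
    rng = np.random.default_rng(seed)
    L = len(fixture)
    seq = fixture.sequence
    cls, dom = _site_classes(fixture)
    fp_side = _footprint_side(fixture)

    if fixture.phase_mode == "random":
        phases = rng.integers(0, fixture.repeat_length, size=N_PHASES)
        phase_of_event = rng.integers(0, N_PHASES, size=n_events)
    else:
        phases = np.array([0])
        phase_of_event = np.zeros(n_events, dtype=int)

    cut_a = np.empty(n_events, dtype=np.int64)
    cut_b = np.empty(n_events, dtype=np.int64)
    outer_a = np.empty(n_events, dtype=np.int64)
    outer_b = np.empty(n_events, dtype=np.int64)
    side_a = np.empty(n_events, dtype=np.int8)
    side_b = np.empty(n_events, dtype=np.int8)
    has_third = rng.random(n_events) < third_fragment_prob
    cut_c = np.full(n_events, -1, dtype=np.int64)
    outer_c = np.empty(n_events, dtype=np.int64)
    side_c = np.empty(n_events, dtype=np.int8)

    for pi in range(len(phases)):
        sel = np.flatnonzero(phase_of_event == pi)
        if sel.size == 0:
            continue
        ca, cb, positions = _sample_pairs_for_phase(
            fixture, model, int(phases[pi]), sel.size, rng, cls, dom
        )
        cut_a[sel], cut_b[sel] = ca, cb
        side_a[sel] = _choose_sides(ca, fp_side, L, rng)
        side_b[sel] = _choose_sides(cb, fp_side, L, rng)
        outer_a[sel] = _outer_ends(ca, side_a[sel], positions, L, rng)
        outer_b[sel] = _outer_ends(cb, side_b[sel], positions, L, rng)

        # third fragments ligate at fragment B's other MNase cut (= outer_b)
        t3 = sel[has_third[sel]]
        if t3.size:
            wv = cut_weights(fixture, int(phases[pi]))[positions]
            anchors = np.clip(
                np.searchsorted(positions, outer_b[t3]), 0, len(positions) - 1
            )
            cc = np.empty(t3.size, dtype=np.int64)
            for b0 in range(0, t3.size, 128):
                blk = slice(b0, min(b0 + 128, t3.size))
                rows = (
                    _pair_factor_rows(anchors[blk], positions, cls, dom, model)
                    * wv[None, :]
                )
                rows[np.arange(rows.shape[0]), anchors[blk]] = 0.0
                cs = np.cumsum(rows, axis=1)
                u = rng.random(rows.shape[0]) * cs[:, -1]
                cc[blk] = positions[
                    np.array([np.searchsorted(cs[k], u[k]) for k in range(rows.shape[0])])
                ]
            cut_c[t3] = cc
            side_c[t3] = _choose_sides(cc, fp_side, L, rng)
            outer_c[t3] = _outer_ends(cc, side_c[t3], positions, L, rng)

    molecules: list[SimulatedMolecule] = []
    for ev in range(n_events):
        ca, cb = int(cut_a[ev]), int(cut_b[ev])
        gs_a, ge_a, dir_a, jpos_a, _ = _piece_from_cut(ca, int(side_a[ev]), int(outer_a[ev]))
        gs_b, ge_b, dir_b, jpos_b, _ = _piece_from_cut(cb, int(side_b[ev]), int(outer_b[ev]))
        # orientation: fragment A's junction base sits at the molecule-3' end
        # of piece A, fragment B's at the molecule-5' start of piece B
        strand_a = "+" if side_a[ev] == 0 else "-"
        strand_b = "+" if side_b[ev] == 1 else "-"

        pieces = [(gs_a, ge_a, strand_a), (gs_b, ge_b, strand_b)]
        junction_dirs = [(dir_a, dir_b)]
        junction_raw = [(jpos_a, jpos_b)]

        if cut_c[ev] >= 0:
            # second junction at fragment B's other MNase cut (boundary outer_b)
            cut2 = int(outer_b[ev])
            j2_a = cut2 - 1 if strand_b == "+" else cut2
            d2_a = TOWARD_UPSTREAM if strand_b == "+" else TOWARD_DOWNSTREAM
            gs_c, ge_c, dir_c, jpos_c, _ = _piece_from_cut(
                int(cut_c[ev]), int(side_c[ev]), int(outer_c[ev])
            )
            strand_c = "+" if side_c[ev] == 1 else "-"
            pieces.append((gs_c, ge_c, strand_c))
            junction_dirs.append((d2_a, dir_c))
            junction_raw.append((j2_a, jpos_c))

        parts = [
            seq[gs:ge] if st == "+" else revcomp(seq[gs:ge])
            for gs, ge, st in pieces
        ]
        mol = "".join(parts)
        offsets = np.cumsum([len(p) for p in parts])

        junctions = []
        for k, ((pa, pb), (da, db)) in enumerate(zip(junction_raw, junction_dirs)):
            t = int(offsets[k])
            h = _canonical_shift(
                seq, mol, t, pieces[k], max_h=len(parts[k + 1]) - 1
            )
            gs_u, ge_u, st_u = pieces[k]
            gs_d, ge_d, st_d = pieces[k + 1]
            pa_c = pa + h if st_u == "+" else pa - h
            pb_c = pb + h if st_d == "+" else pb - h
            if pa_c > pb_c:
                pa_c, pb_c, da, db = pb_c, pa_c, db, da
            junctions.append(TruthJunction(pa_c, pb_c, da, db, t + h))
        molecules.append(SimulatedMolecule(ev, mol, pieces, junctions))
    return molecules


# ---------------------------------------------------------------------------
# sequencing library


def paired_reads_from_fragment(frag: str, read_length: int) -> tuple[str, str]:
    """R1 from the fragment start, R2 the reverse complement of its end."""
    return frag[:read_length], revcomp(frag)[:read_length]


def simulate_fragment_library(
    sequence: str,
    n_fragments: int,
    mean_fragment: int = 200,
    fragment_sd: int = 40,
    read_length: int = 150,
    seed: int = 0,
):
    """Plain (non-chimeric) sonicated fragment library: lengths drawn from
    Normal(mean, sd) truncated to [100, 320] bp at uniform-random positions,
    each fragment sequenced as one error-free read pair.

    Returns (r1_reads, r2_reads) as (id, sequence, quality) triples. This is
    the benchmark input for read-pair overlap merging.
    """
    rng = np.random.default_rng(seed)
    L = len(sequence)
    lengths = np.clip(
        rng.normal(mean_fragment, fragment_sd, size=n_fragments), 100, 320
    ).astype(int)
    starts = rng.integers(0, L - lengths.max(), size=n_fragments)
    r1, r2 = [], []
    for i, (s, fl) in enumerate(zip(starts, lengths)):
        frag = sequence[s : s + fl]
        a, b = paired_reads_from_fragment(frag, read_length)
        r1.append((f"F{i}", a, "I" * len(a)))
        r2.append((f"F{i}", b, "I" * len(b)))
    return r1, r2


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < error_rate)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def render_sequencing_library(
    molecules: list[SimulatedMolecule],
    mean_fragment: int = 200,
    fragment_sd: int = 40,
    read_length: int = 150,
    error_rate: float = 0.0,
    duplication_rate: float = 0.0,
    seed: int = 0,
    min_flank: int = 20,
):
    """Sonicate molecules and sequence each fragment as a 150-bp read pair.

    Returns (r1_reads, r2_reads, truth_table) where reads are
    (id, sequence, quality) triples and the truth table is a pandas
    DataFrame with one row per read pair linking it to surviving junctions.
    A junction is flagged destroyed when sonication leaves fewer than
    ``min_flank`` bp on either side of it, which makes the junction
    unrecoverable by sub-read mapping.
    """
    import pandas as pd

    if not (0.0 <= error_rate <= 0.1):
        raise ValueError("error_rate must be in [0, 0.1]")
    if read_length < 50:
        raise ValueError("read_length must be >= 50")
    if mean_fragment < read_length / 2:
        raise ValueError("mean_fragment must be >= read_length/2")
    rng = np.random.default_rng(seed)
    err_rng = np.random.default_rng((seed, 1))  # separate stream: error
    # draws must not perturb fragmentation
    r1, r2, rows = [], [], []

    for mol in molecules:
        n = len(mol.sequence)
        frags = []
        off = 0
        while off < n:
            fl = int(np.clip(rng.normal(mean_fragment, fragment_sd), 100, 320))
            if n - off - fl < 100:
                fl = n - off
            frags.append((off, off + fl))
            off += fl
        for k, (s, e) in enumerate(frags):
            copies = 1 + (1 if rng.random() < duplication_rate else 0)
            for c in range(copies):
                rid = f"M{mol.id}F{k}" + (f"D{c}" if c else "")
                frag = mol.sequence[s:e]
                a, b = paired_reads_from_fragment(frag, read_length)
                a = _mutate(a, error_rate, err_rng)
                b = _mutate(b, error_rate, err_rng)
                r1.append((rid, a, "I" * len(a)))
                r2.append((rid, b, "I" * len(b)))
                juncs = []
                for j in mol.junctions:
                    t = j.read_offset
                    if s < t < e:
                        survived = (t - s) >= min_flank and (e - t) >= min_flank
                        juncs.append(
                            f"{j.pos_a}|{j.pos_b}|{j.dir_a}|{j.dir_b}|"
                            f"{int(survived)}"
                        )
                rows.append(
                    {
                        "read_id": rid,
                        "molecule_id": mol.id,
                        "mol_start": s,
                        "mol_end": e,
                        "fragment_length": e - s,
                        "junctions": ";".join(juncs),
                    }
                )
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "molecule_id",
            "mol_start",
            "mol_end",
            "fragment_length",
            "junctions",
        ],
    )
    return r1, r2, truth


def truth_junction_set(truth_table, survived_only: bool = True) -> set[tuple]:
    """Unique (pos_a, pos_b, dir_a, dir_b) truth junctions from a truth table."""
    out = set()
    for s in truth_table["junctions"]:
        if not s:
            continue
        for item in s.split(";"):
            pa, pb, da, db, surv = item.split("|")
            if survived_only and surv != "1":
                continue
            out.add((int(pa), int(pb), da, db))
    return out
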