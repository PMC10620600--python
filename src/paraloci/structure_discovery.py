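"""Internal-duplication detection and identity tables.

A fused gene annotation hiding a tandem duplication betrays itself by
self-similarity: a k-mer-seeded scan finds long, highly identical segment
pairs within one locus, and projecting the annotated exons through the
duplication mapping yields the two-gene proposal (here: two 9-exon genes
separated by an intergenic spacer, where the original annotation fused
exons 1–7 of the first copy to exons 8–9 of the second).

Identity conventions (both fixed, both needed to reproduce the published
tables): per-exon identities are *truncated* to integer percent
(floor(100·matches/columns)); gene-level identities are rounded half-up to
one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .locus_model import GeneModel, InputError, build_coordinate_map, make_aligner

DEFAULT_WORD_SIZE = 12
DEFAULT_MIN_LEN = 300
DEFAULT_MIN_IDENTITY = 85.0
_MAX_KMER_OCCURRENCES = 12   # skip low-complexity seeds
_DIAGONAL_BAND = 120         # indel drift tolerated within one chained match
_MAX_SEED_GAP = 600          # chain break threshold along the query


class ParameterError(ValueError):
    pass


class ProposalError(RuntimeError):
    pass


def round_half_up(value: float, ndigits: int) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SegmentMatch:
    """A pair of similar forward-orientation segments (1-based, inclusive)."""

    span_a: tuple[int, int]
    span_b: tuple[int, int]
    identity_pct: float

    @property
    def length(self) -> int:
        return self.span_a[1] - self.span_a[0] + 1


@dataclass
class DuplicateProposal:
    gene_a_span: tuple[int, int]
    gene_b_span: tuple[int, int]
    intergenic_span: tuple[int, int]
    exon_count_a: int
    exon_count_b: int


def self_similarity_scan(
    seq: str,
    k: int = DEFAULT_WORD_SIZE,
    min_len: int = DEFAULT_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[SegmentMatch]:
    """Find internal forward duplications by k-mer seeding and chaining.

    Exact k-mer hits off the main diagonal are chained within a diagonal
    band; chains long enough are refined by global alignment of the two
    segments, and reported when identity and length clear the thresholds.
    """
    seq = seq.upper()
    if k < 4 or k >= len(seq):
        raise ParameterError(f"word size {k} degenerate for sequence of length {len(seq)}")
    if len(seq) <= 2 * min_len:
        raise ParameterError("sequence shorter than twice the minimum segment length")

    kmers: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmers.setdefault(seq[i : i + k], []).append(i)

    # seeds: (posA, posB) with posA < posB, kept as (diagonal, posA)
    seeds: list[tuple[int, int]] = []
    for positions in kmers.values():
        if len(positions) < 2 or len(positions) > _MAX_KMER_OCCURRENCES:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                seeds.append((positions[bi] - positions[ai], positions[ai]))
    seeds.sort()

    # cluster by diagonal band, then chain along the query
    chains: list[list[tuple[int, int]]] = []
    for diag, pos in seeds:
        placed = False
        for chain in reversed(chains):
            last_diag, last_pos = chain[-1]
            if diag - last_diag > _DIAGONAL_BAND:
                break
            if abs(diag - last_diag) <= _DIAGONAL_BAND and 0 <= pos - last_pos <= _MAX_SEED_GAP:
                chain.append((diag, pos))
                placed = True
                break
        if not placed:
            chains.append([(diag, pos)])

    matches: list[SegmentMatch] = []
    for chain in chains:
        a_start = min(p for _, p in chain)
        a_end = max(p for _, p in chain) + k - 1
        if a_end - a_start + 1 < min_len:
            continue
        diag0 = chain[0][0]
        b_start = a_start + diag0
        b_end = max(p + d for d, p in chain) + k - 1
        if b_start <= a_end:  # overlapping copies: near-diagonal self hit
            continue
        cmap = build_coordinate_map(seq[a_start : a_end + 1], seq[b_start : b_end + 1])
        identity = cmap.identity_pct()
        if identity >= min_identity:
            matches.append(
                SegmentMatch((a_start + 1, a_end + 1), (b_start + 1, b_end + 1), identity)
            )
    matches.sort(key=lambda m: -m.length)
    return _drop_contained(matches)


def _drop_contained(matches: list[SegmentMatch]) -> list[SegmentMatch]:
    kept: list[SegmentMatch] = []
    for m in matches:
        if not any(
            _contains(k.span_a, m.span_a) and _contains(k.span_b, m.span_b) for k in kept
        ):
            kept.append(m)
    return kept


def _contains(outer: tuple[int, int], inner: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def propose_duplicate_structure(
    fused: GeneModel, matches: list[SegmentMatch]
) -> DuplicateProposal:
    """Partition a fused locus into two genes via the duplication mapping.

    The fused annotation's exons are projected through the best segment
    match: exons landing in copy A keep their coordinates and gain projected
    mates in copy B, and vice versa, so each proposed gene carries the full
    exon complement.
    """
    if not matches:
        raise ProposalError("no duplicate structure detectable")
    match = max(matches, key=lambda m: m.length)
    a0, a1 = match.span_a
    b0, b1 = match.span_b
    cmap = build_coordinate_map(
        fused.sequence[a0 - 1 : a1], fused.sequence[b0 - 1 : b1]
    )

    _EDGE_TOL = 200  # seeding may start a few bases inside the true copy

    def _project(mapping: dict[int, int], pos: int, src0: int, dst0: int) -> int | None:
        rel = pos - src0 + 1
        if rel in mapping:
            return mapping[rel] + dst0 - 1
        # extrapolate from the nearest mapped position (edge of the match)
        for delta in range(1, _EDGE_TOL + 1):
            for cand in (rel + delta, rel - delta):
                if cand in mapping:
                    return mapping[cand] - (cand - rel) + dst0 - 1
        return None

    def a_to_b(pos: int) -> int | None:
        return _project(cmap.a_to_b, pos, a0, b0)

    def b_to_a(pos: int) -> int | None:
        return _project(cmap.b_to_a, pos, b0, a0)

    gene_a_pts: list[int] = []
    gene_b_pts: list[int] = []
    for exon in fused.exons:
        in_a = a0 - _EDGE_TOL <= exon.start and exon.end <= a1 + _EDGE_TOL and exon.end < b0
        in_b = b0 - _EDGE_TOL <= exon.start and exon.end <= b1 + _EDGE_TOL and exon.start > a1
        if in_a:
            gene_a_pts.extend((exon.start, exon.end))
            proj = [a_to_b(exon.start), a_to_b(exon.end)]
        elif in_b:
            gene_b_pts.extend((exon.start, exon.end))
            proj = [b_to_a(exon.start), b_to_a(exon.end)]
        else:
            raise ProposalError(
                f"exon {exon.index} is covered by neither copy of the duplication"
            )
        if None in proj:
            raise ProposalError(
                f"exon {exon.index} does not project through the duplication"
            )
        (gene_b_pts if in_a else gene_a_pts).extend(proj)  # type: ignore[arg-type]
    span_a = (min(gene_a_pts), max(gene_a_pts))
    span_b = (min(gene_b_pts), max(gene_b_pts))
    if span_a[1] >= span_b[0]:
        raise ProposalError("projected genes overlap; duplication mapping inconsistent")
    n = len(fused.exons)
    return DuplicateProposal(
        gene_a_span=span_a,
        gene_b_span=span_b,
        intergenic_span=(span_a[1] + 1, span_b[0] - 1),
        exon_count_a=n,
        exon_count_b=n,
    )


def exon_identity_table(gene_a: GeneModel, gene_b: GeneModel) -> pd.DataFrame:
    """Per-exon lengths and truncated integer identity between two paralogs."""
    if len(gene_a.exons) != len(gene_b.exons):
        raise InputError("exon count mismatch")
    aligner = make_aligner()
    rows = []
    for ea, eb in zip(gene_a.exons, gene_b.exons):
        sub_a = gene_a.sequence[ea.start - 1 : ea.end]
        sub_b = gene_b.sequence[eb.start - 1 : eb.end]
        matches, columns = _count_alignment(aligner.align(sub_a, sub_b)[0], sub_a, sub_b)
        rows.append({
            "exon": ea.index,
            "len_a": ea.length,
            "len_b": eb.length,
            "identity_pct": int(np.floor(100.0 * matches / columns)),
        })
    return pd.DataFrame(rows)


def gene_identity_matrix(genes: list[GeneModel]) -> pd.DataFrame:
    """Pairwise gene-level identity (ATG-to-stop), half-up to one decimal."""
    if len(genes) < 2:
        raise InputError("need at least two genes")
    aligner = make_aligner()
    names = [g.name for g in genes]
    out = pd.DataFrame(100.0, index=names, columns=names)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            matches, columns = _count_alignment(
                aligner.align(genes[i].sequence, genes[j].sequence)[0],
                genes[i].sequence, genes[j].sequence,
            )
            ident = round_half_up(100.0 * matches / columns, 1)
            out.iloc[i, j] = out.iloc[j, i] = ident
    return out


def _count_alignment(alignment, seq_a: str, seq_b: str) -> tuple[int, int]:
    blocks_a, blocks_b = alignment.aligned
    matches = 0
    aligned_cols = 0
    for (a_start, a_end), (b_start, b_end) in zip(blocks_a, blocks_b):
        aligned_cols += a_end - a_start
        matches += sum(
            seq_a[a_start + o] == seq_b[b_start + o] for o in range(a_end - a_start)
        )
    gap_cols = (len(seq_a) - aligned_cols) + (len(seq_b) - aligned_cols)
    return matches, aligned_cols + gap_cols
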