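"""Assign sequenced transcripts to their source paralog.

A transcript amplified from diploid cDNA carries a pattern of polymorphisms
(heterozygous positions appear as mixed peaks).  The source gene is the one
candidate whose own CDS genotype — obtained from the same animal's gDNA —
replicates that pattern *exactly*, genotype for genotype: a heterozygous
transcript position against a homozygous gene position excludes the
candidate even when the alleles overlap.  This exact-replication rule is
what separates the two-gene model from the fused annotation, whose CDS
disagrees with the transcript precisely in the exon 8–9 region.

Expressed-locus inference adds the indirect argument: an assay whose primers
co-amplify several loci, yet only ever yields transcripts assigned to one of
them, is evidence the others are not expressed (or not detectable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .locus_model import GeneModel, GenotypeCall, InputError, build_coordinate_map
from .synthetic_data import IUPAC_DECODE

__all__ = [
    "PatternTable",
    "AssignmentResult",
    "genotype_pattern",
    "assign_transcript",
    "assign_transcript_sequence",
    "detect_expressed_loci",
]

_BASES = set("ACGT")


@dataclass
class PatternTable:
    """Genotype calls of one entity (transcript or gene CDS) in c. coordinates.

    ``refs`` records the reference base at every assayed position so that a
    candidate lacking a call can be defaulted to homozygous reference.
    """

    entity: str
    calls: tuple[GenotypeCall, ...]
    refs: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        positions = [c.position for c in self.calls]
        if positions != sorted(set(positions)):
            raise InputError(f"{self.entity}: pattern positions must be strictly increasing")

    def genotype_at(self, c_position: int) -> tuple[str, str] | None:
        for call in self.calls:
            if call.position == c_position:
                return call.alleles
        ref = self.refs.get(c_position)
        if ref is not None:
            return (ref, ref)
        return None


@dataclass
class AssignmentResult:
    transcript_id: str
    verdict: str                     # "assigned" | "ambiguous" | "unassigned"
    genes: tuple[str, ...]           # the single source, or all consistent ones
    mismatches: dict[str, list[int]]  # candidate → c. positions that disagree

    @property
    def assigned_gene(self) -> str | None:
        return self.genes[0] if self.verdict == "assigned" else None


def genotype_pattern(consensus_cds: str, reference_cds: str, entity: str = "sample") -> PatternTable:
    """Diff a diploid IUPAC consensus CDS against a reference CDS."""
    if len(consensus_cds) != len(reference_cds):
        raise InputError("consensus and reference CDS lengths differ")
    consensus_cds = consensus_cds.upper()
    reference_cds = reference_cds.upper()
    calls = []
    refs: dict[int, str] = {}
    for i, sym in enumerate(consensus_cds):
        ref = reference_cds[i]
        if sym == ref:
            continue
        if sym in _BASES:
            alleles: tuple[str, str] = (sym, sym)
        elif sym in IUPAC_DECODE:
            alleles = IUPAC_DECODE[sym]
        else:
            raise InputError(f"invalid IUPAC symbol {sym!r} at c.{i + 1}")
        calls.append(GenotypeCall.from_alleles(i + 1, "c", alleles, ref))
        refs[i + 1] = ref
    return PatternTable(entity, tuple(calls), refs)


def assign_transcript(
    transcript_pattern: PatternTable,
    candidates: Mapping[str, PatternTable],
) -> AssignmentResult:
    """Exact genotype-replication assignment.

    A candidate is consistent iff at every assayed transcript position its
    genotype (unordered allele pair) is identical to the transcript's; a
    candidate without a call at some position is homozygous reference there.
    """
    mismatches: dict[str, list[int]] = {}
    for name, candidate in candidates.items():
        bad: list[int] = []
        for call in transcript_pattern.calls:
            cand_gt = candidate.genotype_at(call.position)
            if cand_gt is None:
                ref = transcript_pattern.refs.get(call.position)
                cand_gt = (ref, ref) if ref is not None else None
            if cand_gt != call.alleles:
                bad.append(call.position)
        mismatches[name] = bad
    consistent = tuple(sorted(n for n, bad in mismatches.items() if not bad))
    if len(consistent) == 1:
        verdict = "assigned"
    elif consistent:
        verdict = "ambiguous"
    else:
        verdict = "unassigned"
    return AssignmentResult(transcript_pattern.entity, verdict,
                            consistent or tuple(sorted(candidates)), mismatches)


def assign_transcript_sequence(
    transcript_id: str,
    transcript_seq: str,
    candidates: Mapping[str, GeneModel],
) -> AssignmentResult:
    """Sequence-level assignment for transcripts of possibly different length.

    Each candidate's spliced CDS is aligned to the transcript; a candidate is
    consistent iff every aligned column matches (IUPAC consensus symbols
    match when the candidate base is one of the encoded alleles) and there
    are no gap columns.  Length differences between paralogs (the exon-4
    3-bp indel) are handled by the alignment, never by raw position equality.
    """
    mismatches: dict[str, list[int]] = {}
    for name, gene in candidates.items():
        cds = gene.cds()
        cmap = build_coordinate_map(transcript_seq, cds, name_a=transcript_id, name_b=name)
        bad: list[int] = []
        for a_pos, b_pos, match in cmap.columns:
            if a_pos is None or b_pos is None:
                bad.append(a_pos if a_pos is not None else -(b_pos or 0))
                continue
            if match:
                continue
            sym = transcript_seq[a_pos - 1].upper()
            alleles = IUPAC_DECODE.get(sym, (sym, sym))
            if cds[b_pos - 1] not in alleles:
                bad.append(a_pos)
        mismatches[name] = bad
    consistent = tuple(sorted(n for n, bad in mismatches.items() if not bad))
    if len(consistent) == 1:
        verdict = "assigned"
    elif consistent:
        verdict = "ambiguous"
    else:
        verdict = "unassigned"
    return AssignmentResult(transcript_id, verdict,
                            consistent or tuple(sorted(candidates)), mismatches)


def load_printed_patterns() -> dict[str, tuple[PatternTable, dict[str, PatternTable]]]:
    """The bundled four-animal transcript/CDS genotype table.

    Returns, per animal, the transcript pattern and the three candidate
    patterns (the two proposed paralogs and the fused annotation), all in
    the shared CDS coordinate frame of the published comparison.
    """
    import pandas as pd
    from importlib import resources

    with resources.files("paraloci.data").joinpath("transcript_genotypes.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    candidates = [c for c in frame.columns if c not in ("horse", "c_pos", "ref", "transcript")]
    out: dict[str, tuple[PatternTable, dict[str, PatternTable]]] = {}
    for horse, group in frame.groupby("horse"):
        refs = {int(row["c_pos"]): str(row["ref"]) for _, row in group.iterrows()}

        def _table(entity: str, column: str) -> PatternTable:
            calls = tuple(
                GenotypeCall.from_alleles(
                    int(row["c_pos"]), "c", str(row[column]).split("/"), str(row["ref"])
                )
                for _, row in group.iterrows()
            )
            return PatternTable(entity, calls, dict(refs))

        transcript = _table(f"horse{horse}.transcript", "transcript")
        cand = {name: _table(f"horse{horse}.{name}", name) for name in candidates}
        out[f"horse{horse}"] = (transcript, cand)
    return out


def detect_expressed_loci(
    assignments: Iterable[tuple[AssignmentResult, str]],
    assays: Mapping[str, frozenset[str] | set[str]],
    loci: Iterable[str] | None = None,
) -> dict[str, str]:
    """Per-locus expression status from assay-tagged assignments.

    detected — at least one transcript assigned to the locus;
    not_detected — some assay could have amplified the locus, but no
    transcript was ever assigned to it (the indirect non-expression
    argument); untested — no assay covers the locus.
    """
    covered: set[str] = set()
    for amplifiable in assays.values():
        covered |= set(amplifiable)
    detected: set[str] = set()
    for result, assay_id in assignments:
        if assay_id not in assays:
            raise InputError(f"assignment references unknown assay {assay_id!r}")
        gene = result.assigned_gene
        if gene is None:
            continue
        if gene not in assays[assay_id]:
            raise InputError(
                f"transcript {result.transcript_id} assigned to {gene}, which "
                f"assay {assay_id!r} cannot amplify"
            )
        detected.add(gene)
    universe = set(loci) if loci is not None else covered | detected
    status = {}
    for locus in sorted(universe | covered | detected):
        if locus in detected:
            status[locus] = "detected"
        elif locus in covered:
            status[locus] = "not_detected"
        else:
            status[locus] = "untested"
    return status
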