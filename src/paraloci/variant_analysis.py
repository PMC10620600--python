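"""Variant calling from diploid IUPAC consensus sequences.

Sanger sequencing of diploid gDNA reports heterozygous positions as mixed
peaks, i.e. IUPAC two-base ambiguity codes in the consensus.  Calling a
sample against its paralog reference therefore decodes:

* an ambiguity code containing the reference base → heterozygous (HET);
* a plain non-reference base → homozygous alternate (MUT);
* recorded indel events → deletion records;

and annotates each call with its region (exon/intron index), its protein
effect through the splice map, its cohort allele frequency, and its novelty
against a table of known rs identifiers.

Adjacent substitutions inside one codon with the same zygosity are merged
into a single multi-nucleotide variant so that, e.g., an AAG>GGA codon
change is reported as one K→G event rather than three point mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from Bio.Seq import Seq

from .locus_model import GeneModel, InputError, Intronic, SpliceMap
from .synthetic_data import IUPAC_DECODE, SangerConsensus

__all__ = [
    "VariantRecord",
    "KnownVariantTable",
    "call_variants",
    "classify_region",
    "annotate_effect",
    "allele_frequency",
    "aggregate_cohort",
    "annotate_novelty",
]

_BASES = set("ACGT")


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class VariantRecord:
    """One called variant (per sample, or aggregated over a cohort)."""

    gene: str
    g_start: int
    g_end: int
    ref: str
    alt: str           # "-" for a deletion
    region: str        # "exon k" | "intron k"
    effect: str        # "synonymous" | "R31H" | "378 fs" | "intronic" | ...
    genotype: str | None = None      # HET | MUT (per-sample calls)
    frequency_pct: float | None = None
    rs_id: str | None = None

    @property
    def is_deletion(self) -> bool:
        return self.alt == "-"

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.g_start, self.ref, self.alt)

    def location_label(self) -> str:
        if self.g_start == self.g_end:
            return f"g.{self.g_start}"
        return f"g.{self.g_start}-{self.g_end}"


@dataclass
class KnownVariantTable:
    """(gene, g_position, ref, alt) → rs identifier, unique keys."""

    entries: dict[tuple[str, int, str, str], str] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "KnownVariantTable":
        table = cls()
        for _, row in frame.iterrows():
            key = (str(row.gene), int(row.g_position), str(row.ref), str(row.alt))
            if key in table.entries:
                raise InputError(f"duplicate known-variant key {key}")
            table.entries[key] = str(row.rs_id)
        return table

    def lookup(self, gene: str, g_position: int, ref: str, alt: str) -> str | None:
        return self.entries.get((gene, g_position, ref, alt))


# ---------------------------------------------------------------------------
# Region and effect annotation
# ---------------------------------------------------------------------------

def classify_region(gene: GeneModel, g_position: int) -> str:
    if not 1 <= g_position <= len(gene.sequence):
        raise InputError(f"g.{g_position} outside {gene.name}")
    exon = gene.exon_of(g_position)
    if exon is not None:
        return f"exon {exon.index}"
    preceding = max(e.index for e in gene.exons if e.end < g_position)
    return f"intron {preceding}"


def annotate_effect(gene: GeneModel, g_start: int, ref: str, alt: str) -> str:
    """Protein effect of a substitution, in-codon MNV, or deletion.

    Substitutions and in-codon MNVs mutate the spliced CDS and translate the
    affected codon; frameshifts are reported as "<codon> fs" with the codon
    index of the first deleted coding base.  Intronic changes return
    "intronic".
    """
    smap = gene.splice_map
    g_end = g_start + len(ref) - 1
    c_positions = [smap.g_to_c(g) for g in range(g_start, g_end + 1)]
    exonic = [c for c in c_positions if isinstance(c, int)]
    if not exonic:
        return "intronic"

    cds = gene.cds()
    if alt == "-":  # deletion
        if len(exonic) % 3 != 0:
            codon_index = (exonic[0] - 1) // 3 + 1
            return f"{codon_index} fs"
        codon_index = (exonic[0] - 1) // 3 + 1
        return f"{codon_index}del"

    if len(alt) != len(ref):
        raise InputError("substitution alleles must be equal length")
    if len(exonic) != len(c_positions):
        raise InputError(
            f"variant g.{g_start} spans a splice junction; unsupported"
        )
    first_codon = (exonic[0] - 1) // 3
    last_codon = (exonic[-1] - 1) // 3
    if first_codon != last_codon:
        raise InputError("multi-nucleotide variant spans a codon boundary")
    mutated = list(cds)
    for c, base in zip(exonic, alt):
        if cds[c - 1] != ref[c - exonic[0]]:
            raise InputError(f"reference mismatch at c.{c}")
        mutated[c - 1] = base
    codon_index = first_codon + 1
    ref_aa = str(Seq(cds[3 * first_codon : 3 * first_codon + 3]).translate())
    alt_aa = str(Seq("".join(mutated[3 * first_codon : 3 * first_codon + 3])).translate())
    if ref_aa == alt_aa:
        return "synonymous"
    return f"{ref_aa}{codon_index}{alt_aa}"


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def call_variants(
    consensus: SangerConsensus | str,
    reference: GeneModel,
    merge_mnv: bool = True,
) -> list[VariantRecord]:
    """Call one sample's variants against its paralog reference."""
    if isinstance(consensus, str):
        consensus = SangerConsensus(consensus)
    seq = consensus.sequence.upper()
    if len(seq) != len(reference.sequence):
        raise InputError(
            "consensus and reference lengths differ; align or record indels first"
        )
    smap = reference.splice_map
    deleted = set()
    for ev in consensus.indels:
        deleted.update(range(ev.g_start, ev.g_end + 1))

    raw: list[tuple[int, str, str, str]] = []  # (g, ref, alt, genotype)
    for i, sym in enumerate(seq):
        g = i + 1
        if g in deleted:
            continue
        ref_base = reference.sequence[i]
        if sym == ref_base:
            continue
        if sym in _BASES:
            raw.append((g, ref_base, sym, "MUT"))
        elif sym in IUPAC_DECODE:
            alleles = IUPAC_DECODE[sym]
            if ref_base not in alleles:
                # both alleles non-reference: report the pair as two HET calls
                for alt in alleles:
                    raw.append((g, ref_base, alt, "HET"))
                continue
            alt = alleles[0] if alleles[1] == ref_base else alleles[1]
            raw.append((g, ref_base, alt, "HET"))
        elif sym == "-":
            continue  # covered by a recorded indel event
        else:
            raise InputError(f"invalid IUPAC symbol {sym!r} at g.{g}")

    records: list[VariantRecord] = []
    groups = _merge_same_codon(raw, smap) if merge_mnv else [[r] for r in raw]
    for group in groups:
        g_start = group[0][0]
        ref = "".join(r[1] for r in group)
        alt = "".join(r[2] for r in group)
        genotype = group[0][3]
        records.append(VariantRecord(
            gene=reference.name,
            g_start=g_start,
            g_end=g_start + len(ref) - 1,
            ref=ref,
            alt=alt,
            region=classify_region(reference, g_start),
            effect=annotate_effect(reference, g_start, ref, alt),
            genotype=genotype,
        ))

    for ev in consensus.indels:
        ref = reference.sequence[ev.g_start - 1 : ev.g_end]
        records.append(VariantRecord(
            gene=reference.name,
            g_start=ev.g_start,
            g_end=ev.g_end,
            ref=ref,
            alt="-",
            region=classify_region(reference, ev.g_start),
            effect=annotate_effect(reference, ev.g_start, ref, "-"),
            genotype=ev.zygosity,
        ))
    records.sort(key=lambda r: r.g_start)
    return records


def _merge_same_codon(
    raw: list[tuple[int, str, str, str]], smap: SpliceMap
) -> list[list[tuple[int, str, str, str]]]:
    """Group adjacent same-codon, same-zygosity substitutions into MNVs."""
    groups: list[list[tuple[int, str, str, str]]] = []
    for item in raw:
        g, _ref, _alt, genotype = item
        c = smap.g_to_c(g)
        if groups and not isinstance(c, Intronic):
            prev = groups[-1][-1]
            pg, _, _, pgt = prev
            pc = smap.g_to_c(pg)
            if (
                g == pg + 1
                and genotype == pgt
                and not isinstance(pc, Intronic)
                and (c - 1) // 3 == (pc - 1) // 3
            ):
                groups[-1].append(item)
                continue
        groups.append([item])
    return groups


# ---------------------------------------------------------------------------
# Cohort aggregation
# ---------------------------------------------------------------------------

def allele_frequency(n_het: int, n_mut: int, n_genotyped: int) -> float:
    """Percent of alleles carrying the variant, half-up to 2 decimals."""
    if n_genotyped <= 0:
        raise InputError("no genotyped samples; frequency undefined")
    return _round2(100.0 * (n_het + 2 * n_mut) / (2 * n_genotyped))


def aggregate_cohort(
    per_sample_calls: list[list[VariantRecord]],
    n_samples: int | None = None,
) -> list[VariantRecord]:
    """Collapse per-sample calls into distinct variants with frequencies.

    Samples absent from ``per_sample_calls`` are not imputed; the denominator
    is the number of genotyped samples.
    """
    n = n_samples if n_samples is not None else len(per_sample_calls)
    if n <= 0:
        raise InputError("no genotyped samples")
    counts: dict[tuple[int, str, str], dict] = {}
    for calls in per_sample_calls:
        for rec in calls:
            slot = counts.setdefault(rec.key, {"rec": rec, "het": 0, "mut": 0})
            slot["het" if rec.genotype == "HET" else "mut"] += 1
    out = []
    for slot in counts.values():
        rec: VariantRecord = slot["rec"]
        out.append(replace(
            rec,
            genotype=None,
            frequency_pct=allele_frequency(slot["het"], slot["mut"], n),
        ))
    out.sort(key=lambda r: r.g_start)
    return out


def annotate_novelty(
    variants: list[VariantRecord], known: KnownVariantTable
) -> list[VariantRecord]:
    """Attach rs identifiers by exact key lookup; absent keys are novel."""
    out = []
    for rec in variants:
        rs = known.lookup(rec.gene, rec.g_start, rec.ref, rec.alt)
        out.append(replace(rec, rs_id=rs if rs is not None else "novel"))
    return out


def variants_to_frame(variants: list[VariantRecord]) -> pd.DataFrame:
    rows = [{
        "gene": v.gene, "g_start": v.g_start, "g_end": v.g_end,
        "ref": v.ref, "alt": v.alt, "region": v.region, "effect": v.effect,
        "genotype": v.genotype, "frequency_pct": v.frequency_pct, "rs_id": v.rs_id,
    } for v in variants]
    return pd.DataFrame(rows, columns=[
        "gene", "g_start", "g_end", "ref", "alt", "region", "effect",
        "genotype", "frequency_pct", "rs_id",
    ])
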