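"""Gene-conversion hybrid detection between two paralogs.

Diagnostic sites — positions where acceptor and donor paralogs carry
different bases — let each allele be attributed base by base.  A run of
consecutive donor-matching states on an acceptor allele is a conversion
tract; when the run extends to the end of the gene it is a hybrid allele
(5′ acceptor, 3′ donor), and the conversion boundary lies in the open
interval between the last acceptor-matching site and the first
donor-matching one.

A diagnostic site can be confounded: if the donor population itself is
polymorphic at the corresponding donor position (here, a fixed T>C in the
donor at the position matching acceptor g.3805), conversion transfers the
donor's *observed* allele and the site never looks converted.  Such sites
are masked (informative = False) and excluded from tract logic; leaving
them in would split the tract and misplace the breakpoint.

Diploid (unphased Sanger) calling rests on one phase assumption, flagged in
reports: an uninterrupted run of heterozygous diagnostic sites is one hybrid
haplotype, not two reciprocal recombinants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .locus_model import CoordinateMap, GeneModel, InputError, build_coordinate_map
from .synthetic_data import IUPAC_DECODE

__all__ = [
    "DiagnosticSite",
    "ConversionCall",
    "find_diagnostic_sites",
    "mask_confounded_sites",
    "classify_allele_at_sites",
    "detect_conversion_tract",
    "call_hybrids_diploid",
    "hybrid_frequency",
]

DEFAULT_MIN_RUN = 2  # an isolated donor-matching site is just a point mutation

ACCEPTOR = "acceptor"
DONOR = "donor"
OTHER = "other"


@dataclass(frozen=True)
class DiagnosticSite:
    pos_a: int
    pos_b: int
    base_a: str
    base_b: str
    informative: bool = True
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.base_a == self.base_b:
            raise InputError(f"g.{self.pos_a}: not a diagnostic site (equal bases)")
        if not self.informative and not self.reason:
            raise InputError(f"g.{self.pos_a}: masking requires a recorded reason")


@dataclass
class ConversionCall:
    allele_id: str
    site_states: tuple[str, ...]
    tract: tuple[int, int] | None
    switching_interval: tuple[int, int] | None
    is_hybrid: bool
    label: str  # "hybrid" | "conversion_segment" | "none"


def find_diagnostic_sites(
    gene_a: GeneModel, gene_b: GeneModel, cmap: CoordinateMap | None = None
) -> list[DiagnosticSite]:
    """Every substitution column of the paralog alignment, ordered by pos_a."""
    if cmap is None:
        cmap = build_coordinate_map(
            gene_a.sequence, gene_b.sequence, name_a=gene_a.name, name_b=gene_b.name
        )
    sites = []
    for a_pos, b_pos, match in cmap.columns:
        if a_pos is None or b_pos is None or match:
            continue
        sites.append(DiagnosticSite(
            pos_a=a_pos, pos_b=b_pos,
            base_a=gene_a.sequence[a_pos - 1],
            base_b=gene_b.sequence[b_pos - 1],
        ))
    sites.sort(key=lambda s: s.pos_a)
    return sites


def mask_confounded_sites(
    sites: Sequence[DiagnosticSite], donor_variants: pd.DataFrame
) -> list[DiagnosticSite]:
    """Mark sites whose donor position carries a known donor polymorphism.

    ``donor_variants`` is keyed in donor coordinates (columns g_position,
    ref, alt).  A polymorphic donor position makes the acceptor site
    uninformative for conversion scoring.
    """
    donor_positions = {
        int(row.g_position): f"donor polymorphism {row.ref}>{row.alt} at donor g.{int(row.g_position)}"
        for _, row in donor_variants.iterrows()
    }
    out = []
    for site in sites:
        reason = donor_positions.get(site.pos_b)
        if reason is not None:
            out.append(replace(site, informative=False, reason=reason))
        else:
            out.append(site)
    return out


def _informative(sites: Iterable[DiagnosticSite]) -> list[DiagnosticSite]:
    return [s for s in sites if s.informative]


def classify_allele_at_sites(
    allele_seq: str, sites: Sequence[DiagnosticSite]
) -> tuple[str, ...]:
    """Per informative site: acceptor / donor / other (acceptor coordinates)."""
    states = []
    for site in _informative(sites):
        if site.pos_a > len(allele_seq):
            raise InputError(f"allele does not cover site g.{site.pos_a}")
        base = allele_seq[site.pos_a - 1].upper()
        if base == site.base_a:
            states.append(ACCEPTOR)
        elif base == site.base_b:
            states.append(DONOR)
        else:
            if base not in "ACGT":
                warnings.warn(f"ambiguous base {base!r} at diagnostic site g.{site.pos_a}")
            states.append(OTHER)
    return tuple(states)


def detect_conversion_tract(
    state_vector: Sequence[str],
    sites: Sequence[DiagnosticSite],
    min_run: int = DEFAULT_MIN_RUN,
    allele_id: str = "allele",
    upstream_boundary: int = 1,
) -> ConversionCall:
    """Locate the maximal donor-state run and the switching interval.

    The tract is the longest run of consecutive donor states (ties: the
    first).  A tract of length ≥ ``min_run`` reaching the last informative
    site is a hybrid (tail conversion); an interior tract is reported as a
    conversion segment without the hybrid label.  The switching interval is
    open: (position of the last non-donor informative site before the
    tract — or ``upstream_boundary`` if the tract starts at the first
    site — , position of the first converted site).
    """
    informative = _informative(sites)
    if len(state_vector) != len(informative):
        raise InputError("state vector length does not match informative sites")
    if not state_vector:
        return ConversionCall(allele_id, (), None, None, False, "none")

    best_start, best_len = None, 0
    i = 0
    while i < len(state_vector):
        if state_vector[i] == DONOR:
            j = i
            while j < len(state_vector) and state_vector[j] == DONOR:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1

    if best_start is None or best_len < min_run:
        return ConversionCall(allele_id, tuple(state_vector), None, None, False, "none")

    first = informative[best_start]
    last = informative[best_start + best_len - 1]
    lower = (
        informative[best_start - 1].pos_a if best_start > 0 else upstream_boundary
    )
    interval = (lower, first.pos_a)
    is_tail = best_start + best_len == len(state_vector)
    return ConversionCall(
        allele_id,
        tuple(state_vector),
        tract=(first.pos_a, last.pos_a),
        switching_interval=interval,
        is_hybrid=is_tail,
        label="hybrid" if is_tail else "conversion_segment",
    )


def call_hybrids_diploid(
    consensus: str, sites: Sequence[DiagnosticSite], min_run: int = DEFAULT_MIN_RUN
) -> int:
    """Count hybrid alleles (0, 1 or 2) in one unphased diploid consensus.

    Per informative site the diploid genotype is decoded from the IUPAC
    symbol; a tail run (≥ min_run, ending at the last informative site) of
    sites all heterozygous acceptor/donor is one hybrid allele, all
    homozygous donor is two; a mixed run is flagged complex and counted
    conservatively as one.
    """
    informative = _informative(sites)
    if not informative:
        return 0
    states = []
    for site in informative:
        sym = consensus[site.pos_a - 1].upper()
        alleles = IUPAC_DECODE.get(sym, (sym, sym))
        pair = frozenset(alleles)
        if pair == frozenset((site.base_a, site.base_b)):
            states.append("het")
        elif pair == frozenset((site.base_b,)):
            states.append("hom_donor")
        elif pair == frozenset((site.base_a,)):
            states.append("hom_acceptor")
        else:
            states.append("other")

    # maximal suffix run of donor-carrying genotypes
    run = 0
    for state in reversed(states):
        if state in ("het", "hom_donor"):
            run += 1
        else:
            break
    if run < min_run:
        return 0
    tail = states[len(states) - run:]
    if all(s == "het" for s in tail):
        return 1
    if all(s == "hom_donor" for s in tail):
        return 2
    warnings.warn(
        "mixed heterozygous/homozygous-donor run; complex genotype counted as 1 hybrid allele"
    )
    return 1


def hybrid_frequency(counts: Iterable[int], n_samples: int) -> float:
    """Percent of alleles that are hybrid, half-up to 2 decimals."""
    counts = list(counts)
    if any(c not in (0, 1, 2) for c in counts):
        raise InputError("per-sample hybrid counts must be 0, 1 or 2")
    total = sum(counts)
    pct = 100.0 * total / (2 * n_samples)
    return float(Decimal(repr(float(pct))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
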