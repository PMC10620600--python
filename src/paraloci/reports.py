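"""Report rendering in the layouts of the published tables.

All reports are TSV (tab-separated, UTF-8, Unix newlines); frequencies are
printed with 2 decimals, per-exon identities as truncated integers, and
gene-level identities with 1 decimal.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .effect_expression import ExpressionResult
from .hybrid_detection import DiagnosticSite
from .transcript_assignment import AssignmentResult
from .variant_analysis import VariantRecord

VARIANT_REPORT_COLUMNS = [
    "Location", "SNP identified", "Aminoacidic change",
    "Frequency alleles containing the SNP (%)", "rs number",
    "PROVEAN result", "SIFT results",
]


def exon_identity_report(table: pd.DataFrame, name_a: str, name_b: str) -> pd.DataFrame:
    return pd.DataFrame({
        "Exon": table["exon"],
        f"bps {name_a}": table["len_a"],
        f"bps {name_b}": table["len_b"],
        f"% of identity between {name_a} and {name_b}": table["identity_pct"],
    })


def variant_report(
    variants: Sequence[VariantRecord], scores: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Cohort variant table in the published column layout.

    ``scores`` (optional) supplies PROVEAN/SIFT values joined on the
    amino-acid change.
    """
    lookup = {}
    if scores is not None:
        for _, row in scores.iterrows():
            lookup[(row["gene"], row["aa_change"])] = (row["provean"], row["sift"])
    rows = []
    for v in variants:
        provean, sift = lookup.get((v.gene, v.effect), (None, None))
        snp = f"{v.ref} > {v.alt}" if v.alt != "-" else f"{v.ref} del"
        rows.append({
            "Location": v.location_label(),
            "SNP identified": snp,
            "Aminoacidic change": "" if v.effect in ("intronic", "synonymous") else v.effect,
            "Frequency alleles containing the SNP (%)":
                "" if v.frequency_pct is None else f"{v.frequency_pct:.2f}",
            "rs number": "" if v.rs_id in (None, "novel") else v.rs_id,
            "PROVEAN result": "" if provean is None or pd.isna(provean) else provean,
            "SIFT results": "" if sift is None or pd.isna(sift) else sift,
        })
    return pd.DataFrame(rows, columns=VARIANT_REPORT_COLUMNS)


def conversion_site_report(
    sites: Sequence[DiagnosticSite], acceptor: str, donor: str
) -> pd.DataFrame:
    rows = [{
        f"Location (on gDNA {acceptor})": f"g.{s.pos_a}",
        "SNP identified": f"{s.base_a} > {s.base_b}",
        f"Nucleotide on corresponding {donor} location": s.base_b,
        "Informative": "yes" if s.informative else f"no ({s.reason})",
    } for s in sites]
    return pd.DataFrame(rows)


def assignment_report(
    results: Iterable[AssignmentResult],
) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "transcript": r.transcript_id,
            "verdict": r.verdict,
            "assigned_gene": r.assigned_gene or "",
        }
        for name, bad in sorted(r.mismatches.items()):
            row[f"mismatches:{name}"] = ";".join(str(p) for p in bad)
        rows.append(row)
    return pd.DataFrame(rows)


def hybrid_report(counts: Sequence[int], frequency_pct: float,
                  switching_interval: tuple[int, int] | None) -> pd.DataFrame:
    rows = [{"sample": i, "hybrid_alleles": c} for i, c in enumerate(counts)]
    frame = pd.DataFrame(rows)
    frame.attrs["summary"] = {
        "hybrid_allele_frequency_pct": frequency_pct,
        "switching_interval": (
            f"between g.{switching_interval[0]} and g.{switching_interval[1] - 1}"
            if switching_interval else ""
        ),
        "phasing_assumption": (
            "an uninterrupted run of heterozygous diagnostic sites is "
            "attributed to one hybrid haplotype"
        ),
    }
    return frame


def expression_report(result: ExpressionResult) -> pd.DataFrame:
    frame = result.normalized.copy()
    frame.attrs["summary"] = {
        "fold_change": result.fold_change,
        "comparison": f"{result.target_a} vs {result.target_b}",
        "welch_t": result.t_statistic,
        "welch_df": result.df,
        "welch_p": result.p_value,
    }
    return frame


def write_tsv(frame: pd.DataFrame, path) -> None:
    with open(path, "w", newline="\n") as fh:
        summary = frame.attrs.get("summary")
        if summary:
            for key, value in summary.items():
                fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep="\t", index=False)
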