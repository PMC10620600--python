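"""End-to-end pipeline orchestration on synthetic inputs.

Stages run in method order — simulate, discover-structure, diagnostics,
call-variants, assign-transcripts, detect-hybrids, classify-effects,
quantify-expression, report — each consuming the previous stage's outputs.
Every run is a pure function of its configuration (seeds included), and the
manifest written alongside the reports records exactly what is needed to
reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import effect_expression as ee
from . import hybrid_detection as hd
from . import reports
from . import structure_discovery as sdisc
from . import synthetic_data as sd
from . import transcript_assignment as ta
from . import variant_analysis as va
from .locus_model import InputError

STAGES = (
    "simulate",
    "discover_structure",
    "diagnostics",
    "call_variants",
    "assign_transcripts",
    "detect_hybrids",
    "classify_effects",
    "quantify_expression",
    "report",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_samples: int = 72
    hybrid_allele_count: int = 42
    expressed_loci: tuple[str, ...] = tuple(sorted(sd.EXPRESSED_DEFAULT))
    min_identity: float = sdisc.DEFAULT_MIN_IDENTITY
    min_run: int = hd.DEFAULT_MIN_RUN
    sift_cutoff: float = ee.SIFT_CUTOFF
    provean_cutoff: float = ee.PROVEAN_CUTOFF
    qpcr_true_ratio: float = 7.5
    qpcr_noise_sd: float = 0.0
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise InputError(f"unknown pipeline stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown configuration keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("expressed_loci", "stages"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["expressed_loci"] = list(out["expressed_loci"])
        out["stages"] = list(out["stages"])
        return out

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    config: PipelineConfig
    artifacts: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None,
                 log=lambda stage, msg: None) -> PipelineResult:
    cfg = config or PipelineConfig()
    result = PipelineResult(cfg)
    art = result.artifacts
    enabled = set(cfg.stages)
    skipped = [s for s in STAGES if s not in enabled]

    def stage_enabled(name: str) -> bool:
        return name in enabled

    # -- simulate ----------------------------------------------------------
    if not stage_enabled("simulate"):
        raise InputError("the simulate stage cannot be skipped: it provides all inputs")
    log("simulate", "generating family, cohort, transcripts, qPCR plate")
    family = sd.simulate_family(sd.FamilyConfig(seed=cfg.seed))
    cohort = sd.simulate_cohort(family, sd.default_cohort_spec(
        n_samples=cfg.n_samples, hybrid_allele_count=cfg.hybrid_allele_count,
        seed=cfg.seed + 1))
    transcripts = sd.simulate_transcripts(family, cfg.expressed_loci)
    plate = sd.simulate_qpcr(sd.QpcrSpec(
        true_ratio=cfg.qpcr_true_ratio, ct_noise_sd=cfg.qpcr_noise_sd,
        seed=cfg.seed + 2))
    fused = sd.simulate_fused_locus(family, seed=cfg.seed + 3)
    art.update(family=family, cohort=cohort, transcripts=transcripts,
               plate=plate, fused=fused)
    consensi = [cohort.consensus(s) for s in range(cfg.n_samples)]

    # -- discover-structure ------------------------------------------------
    if stage_enabled("discover_structure"):
        log("discover_structure", "self-similarity scan of the fused locus")
        matches = sdisc.self_similarity_scan(
            fused.model.sequence, min_identity=cfg.min_identity)
        proposal = sdisc.propose_duplicate_structure(fused.model, matches)
        exon_table = sdisc.exon_identity_table(family.acceptor_gene, family.donor_gene)
        art.update(matches=matches, proposal=proposal, exon_identity=exon_table)

    # -- diagnostics -------------------------------------------------------
    sites = None
    if stage_enabled("diagnostics") or stage_enabled("detect_hybrids"):
        log("diagnostics", "diagnostic sites between the focal paralogs")
        sites = hd.find_diagnostic_sites(family.acceptor_gene, family.donor_gene)
        sites = hd.mask_confounded_sites(sites, family.donor_variants)
        art["diagnostic_sites"] = sites

    # -- call-variants -----------------------------------------------------
    if stage_enabled("call_variants"):
        log("call_variants", f"calling {cfg.n_samples} samples")
        per_sample = [va.call_variants(c, family.acceptor_gene) for c in consensi]
        aggregated = va.aggregate_cohort(per_sample, cfg.n_samples)
        known = va.KnownVariantTable.from_frame(_load_known_variants())
        aggregated = va.annotate_novelty(aggregated, known)
        art.update(per_sample_calls=per_sample, cohort_variants=aggregated)

    # -- assign-transcripts ------------------------------------------------
    if stage_enabled("assign_transcripts"):
        log("assign_transcripts", "printed patterns + synthetic transcripts")
        printed = [
            ta.assign_transcript(tpat, cands)
            for tpat, cands in ta.load_printed_patterns().values()
        ]
        synthetic = [
            ta.assign_transcript_sequence(tid, seq, family.genes)
            for tid, seq in transcripts
        ]
        assay = {"liver_panel": set(family.genes)}
        status = ta.detect_expressed_loci(
            [(r, "liver_panel") for r in synthetic], assay)
        art.update(printed_assignments=printed, transcript_assignments=synthetic,
                   expressed_status=status)

    # -- detect-hybrids ----------------------------------------------------
    if stage_enabled("detect_hybrids"):
        log("detect_hybrids", "per-sample hybrid calling")
        counts = [
            hd.call_hybrids_diploid(c.sequence, sites, min_run=cfg.min_run)
            for c in consensi
        ]
        freq = hd.hybrid_frequency(counts, cfg.n_samples)
        interval = None
        for s, c in enumerate(counts):
            if c > 0:
                hap = _hybrid_haplotype(cohort, s)
                states = hd.classify_allele_at_sites(hap, sites)
                call = hd.detect_conversion_tract(states, sites, min_run=cfg.min_run)
                interval = call.switching_interval
                break
        art.update(hybrid_counts=counts, hybrid_frequency=freq,
                   switching_interval=interval)

    # -- classify-effects --------------------------------------------------
    if stage_enabled("classify_effects"):
        log("classify_effects", "threshold classification of predictor scores")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            classified = ee.classify_deleterious(
                ee.load_effect_scores(),
                sift_cutoff=cfg.sift_cutoff, provean_cutoff=cfg.provean_cutoff)
        art["effect_classification"] = classified
        art["novel_deleterious"] = {
            gene: ee.count_novel_deleterious(classified, gene)
            for gene in sorted(classified["gene"].unique())
        }

    # -- quantify-expression -----------------------------------------------
    if stage_enabled("quantify_expression"):
        log("quantify_expression", "relative standard curve quantification")
        art["expression"] = ee.quantify_expression(plate)

    # -- report ------------------------------------------------------------
    result.manifest = {
        "package": "paraloci",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages_run": [s for s in STAGES if s in enabled],
        "stages_skipped": skipped,
    }
    if stage_enabled("report") and out_dir is not None:
        log("report", f"writing reports to {out_dir}")
        _write_reports(result, Path(out_dir))
    return result


def _hybrid_haplotype(cohort: sd.Cohort, sample: int) -> str:
    flags = cohort.hybrid_flags[sample]
    idx = 0 if flags[0] else 1
    return cohort.haplotypes[sample][idx]


def _load_known_variants():
    import pandas as pd
    from importlib import resources

    with resources.files("paraloci.data").joinpath("known_variants.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def _write_reports(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    art = result.artifacts
    family: sd.Family = art["family"]
    if "exon_identity" in art:
        reports.write_tsv(
            reports.exon_identity_report(
                art["exon_identity"], family.acceptor, family.donor),
            out_dir / "exon_identity.tsv")
    if "proposal" in art:
        p = art["proposal"]
        (out_dir / "proposal.json").write_text(json.dumps({
            "gene_a_span": list(map(int, p.gene_a_span)),
            "gene_b_span": list(map(int, p.gene_b_span)),
            "intergenic_span": list(map(int, p.intergenic_span)),
            "exon_count_a": p.exon_count_a,
            "exon_count_b": p.exon_count_b,
        }, indent=2) + "\n")
    if "diagnostic_sites" in art:
        reports.write_tsv(
            reports.conversion_site_report(
                art["diagnostic_sites"], family.acceptor, family.donor),
            out_dir / "diagnostic_sites.tsv")
    if "cohort_variants" in art:
        reports.write_tsv(
            reports.variant_report(art["cohort_variants"], ee.load_effect_scores()),
            out_dir / "variants.tsv")
    if "printed_assignments" in art:
        reports.write_tsv(
            reports.assignment_report(
                art["printed_assignments"] + art["transcript_assignments"]),
            out_dir / "assignments.tsv")
        (out_dir / "expressed_loci.json").write_text(
            json.dumps(art["expressed_status"], indent=2) + "\n")
    if "hybrid_counts" in art:
        reports.write_tsv(
            reports.hybrid_report(art["hybrid_counts"], art["hybrid_frequency"],
                                  art["switching_interval"]),
            out_dir / "hybrids.tsv")
    if "effect_classification" in art:
        reports.write_tsv(art["effect_classification"], out_dir / "effect_verdicts.tsv")
    if "expression" in art:
        reports.write_tsv(reports.expression_report(art["expression"]),
                          out_dir / "expression.tsv")
    (out_dir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")
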