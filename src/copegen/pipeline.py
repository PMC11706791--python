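"""Stage orchestration: genome -> CpG -> tails -> enrichment -> clustering ->
duplication screens -> machine-readable report.

The report is a pydantic model (JSON schema shipped in
``copegen/schemas/run_report.schema.json``) fully determined by inputs,
config, and seed; stage timings are logged to stderr but never influence a
result.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from pydantic import BaseModel

from . import __version__
from . import cpg_metrics, duplication_signals, spatial_clustering, term_enrichment
from .genome_io import extract_cds, load_genome, read_labels

logger = logging.getLogger("copegen.pipeline")


class PipelineConfig(BaseModel):
    fasta: str
    gff3: str
    labels: str | None = None
    centromeres: str | None = None  # TSV chrom <tab> position
    depth_table: str | None = None  # TSV gene_id <tab> depth
    pairs_fasta: str | None = None  # paired CDS FASTA (<id>_a / <id>_b)
    term_map: str | None = None  # TSV gene_id <tab> term
    subset_label: str = "ion_transport"
    cpg_threshold: float = 1.0
    tail_q: float = 0.05
    null_mode: str = "montecarlo"
    centromere_window_bp: int = 100_000
    iqr_k: float = 1.5
    stages: list[str] = ["cpg", "enrichment", "clustering", "depth", "ks"]
    seed: int = 0
    outdir: str = "copegen_out"


class CpGStageReport(BaseModel):
    n_genes: int
    n_undefined: int
    mean: float
    sd: float
    min: float
    max: float
    percent_below_threshold: float
    threshold: float
    n_modes: int
    tail_size: int


class KSStageReport(BaseModel):
    D: float
    p_value: float
    n: int
    null_mode: str


class ChiSquareStageReport(BaseModel):
    chi2: float
    df: int
    p_value: float


class ClusteringStageReport(BaseModel):
    subset: str
    n_genes: int
    per_chromosome_counts: dict[str, int]
    ks: KSStageReport
    chisq_vs_high_cpg: ChiSquareStageReport | None = None
    centromere_proximal: dict[str, int | None] | None = None
    centromere_window_bp: int | None = None


class EnrichmentStageReport(BaseModel):
    n_terms_tested: int
    n_significant: int
    alpha: float
    top_terms: list[str]


class DepthStageReport(BaseModel):
    n_genes: int
    n_outliers_high: int
    percent_outliers: float
    q1: float
    q3: float


class KsStageReport(BaseModel):
    n_pairs: int
    n_saturated: int
    mean_ks: float
    window_fractions: dict[str, float]


class RunReport(BaseModel):
    version: str
    seed: int
    input_hashes: dict[str, str]
    parameters: dict
    cpg: CpGStageReport | None = None
    enrichment: EnrichmentStageReport | None = None
    clustering: ClusteringStageReport | None = None
    depth: DepthStageReport | None = None
    ks: KsStageReport | None = None
    skipped: list[str] = []


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_centromeres(path: str) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 2 and parts[1].isdigit():
                out[parts[0]] = int(parts[1])
    return out


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the enabled stages in dependency order and return the report.

    Hard errors (missing required inputs, broken files) raise; an optional
    stage whose input is absent is skipped with a warning and listed in
    ``report.skipped``.
    """
    for required in (config.fasta, config.gff3):
        if not Path(required).exists():
            raise FileNotFoundError(f"required input missing: {required}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hashes = {}
    for key in ("fasta", "gff3", "labels", "centromeres", "depth_table",
                "pairs_fasta", "term_map"):
        val = getattr(config, key)
        if val and Path(val).exists():
            hashes[key] = _sha256(val)

    report = RunReport(
        version=__version__,
        seed=config.seed,
        input_hashes=hashes,
        parameters=config.model_dump(),
    )
    if not config.stages:
        return report

    centromeres = (
        _read_centromeres(config.centromeres) if config.centromeres else None
    )
    bundle = load_genome(config.fasta, config.gff3, config.labels, centromeres)

    records = None
    if "cpg" in config.stages:
        records, report.cpg = _run_cpg(bundle, config, outdir)
    if "enrichment" in config.stages:
        if config.term_map and records:
            report.enrichment = _run_enrichment(bundle, records, config, outdir)
        else:
            logger.warning("enrichment stage skipped: no term map / cpg records")
            report.skipped.append("enrichment")
    if "clustering" in config.stages:
        report.clustering = _run_clustering(bundle, records, config, outdir)
    if "depth" in config.stages:
        if config.depth_table:
            report.depth = _run_depth(config, outdir)
        else:
            logger.warning("depth stage skipped: no depth table")
            report.skipped.append("depth")
    if "ks" in config.stages:
        if config.pairs_fasta:
            report.ks = _run_ks(config, outdir)
        else:
            logger.warning("ks stage skipped: no paralog FASTA")
            report.skipped.append("ks")

    (outdir / "report.json").write_text(report.model_dump_json(indent=1))
    return report


@_stage("cpg")
def _run_cpg(bundle, config, outdir):
    records = []
    for g in bundle.genes:
        if not g.has_cds:
            continue
        records.append(cpg_metrics.compute_cpg_oe(extract_cds(bundle, g.gene_id),
                                                  g.gene_id))
    summary = cpg_metrics.summarize(records, config.cpg_threshold)
    low, high = cpg_metrics.tail_sets(records, config.tail_q)
    with open(outdir / "cpg_oe.tsv", "w") as fh:
        fh.write("gene_id\tL\tn_C\tn_G\tn_CpG\tcpg_oe\tdefined\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.L}\t{r.n_C}\t{r.n_G}\t{r.n_CpG}"
                f"\t{r.cpg_oe:.6g}\t{int(r.defined)}\n"
            )
    for name, tail in (("cpg_low_tail.txt", low), ("cpg_high_tail.txt", high)):
        (outdir / name).write_text("".join(r.gene_id + "\n" for r in tail))
    stage = CpGStageReport(
        n_genes=summary.n_genes,
        n_undefined=summary.n_undefined,
        mean=summary.mean,
        sd=summary.sd,
        min=summary.min,
        max=summary.max,
        percent_below_threshold=summary.percent_below,
        threshold=summary.threshold,
        n_modes=summary.n_modes,
        tail_size=len(low),
    )
    return records, stage


@_stage("enrichment")
def _run_enrichment(bundle, records, config, outdir, alpha: float = 0.05):
    term_map = {
        g: set(terms) for g, terms in read_labels(config.term_map).items()
    }
    low, _high = cpg_metrics.tail_sets(records, config.tail_q)
    study = {r.gene_id for r in low}
    population = {r.gene_id for r in records if r.defined}
    results = term_enrichment.enrich(study, population, term_map)
    with open(outdir / "enrichment.tsv", "w") as fh:
        fh.write("term_id\tk\tn\tK\tN\tp_value\tq_value\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.k}\t{r.n}\t{r.K}\t{r.N}"
                f"\t{r.p_value:.6g}\t{r.q_value:.6g}\n"
            )
    sig = [r for r in results if r.q_value < alpha]
    return EnrichmentStageReport(
        n_terms_tested=len(results),
        n_significant=len(sig),
        alpha=alpha,
        top_terms=[r.term_id for r in results[:10]],
    )


@_stage("clustering")
def _run_clustering(bundle, records, config, outdir):
    sset = spatial_clustering.spacings(bundle, config.subset_label)
    ks = spatial_clustering.ks_clustering_test(
        sset, config.null_mode, rng_seed=config.seed
    )
    counts = spatial_clustering.per_chromosome_counts(bundle, config.subset_label)
    chisq_report = None
    if records:
        # reference = same number of highest-CpG_o/e ("functionally
        # conserved", housekeeping-like) genes
        n_subset = sum(counts.values())
        defined = sorted(
            (r for r in records if r.defined),
            key=lambda r: (-r.cpg_oe, r.gene_id),
        )
        ref_ids = {r.gene_id for r in defined[:n_subset]}
        ref_genes = [g for g in bundle.genes if g.gene_id in ref_ids]
        import numpy as np

        ref_per_chrom = {}
        for chrom in sorted({g.chrom for g in ref_genes}):
            mids = np.sort([g.midpoint for g in ref_genes if g.chrom == chrom])
            ref_per_chrom[chrom] = (bundle.chrom_map[chrom].length, mids)
        ref_set = spatial_clustering.SpacingSet(ref_per_chrom)
        try:
            chi = spatial_clustering.chisq_vs_reference(sset, ref_set)
            chisq_report = ChiSquareStageReport(
                chi2=chi.chi2, df=chi.df, p_value=chi.p_value
            )
        except ValueError as exc:
            logger.warning("chi-square comparison skipped: %s", exc)
    prox = None
    if any(c.centromere_pos is not None for c in bundle.chromosomes):
        prox = spatial_clustering.centromere_proximity(
            bundle, config.subset_label, config.centromere_window_bp
        )
    with open(outdir / "spacings.tsv", "w") as fh:
        fh.write("spacing_bp\n")
        for s in sset.pooled:
            fh.write(f"{s:.0f}\n")
    return ClusteringStageReport(
        subset=config.subset_label,
        n_genes=sset.n_genes,
        per_chromosome_counts=counts,
        ks=KSStageReport(D=ks.D, p_value=ks.p_value, n=ks.n, null_mode=ks.null_mode),
        chisq_vs_high_cpg=chisq_report,
        centromere_proximal=prox,
        centromere_window_bp=config.centromere_window_bp if prox else None,
    )


@_stage("depth")
def _run_depth(config, outdir):
    table = {}
    with open(config.depth_table) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "gene_id")):
                continue
            gene_id, depth = line.split("\t")[:2]
            table[gene_id] = float(depth)
    recs = duplication_signals.depth_outliers(table, k=config.iqr_k)
    n_out = sum(r.outlier_high for r in recs)
    with open(outdir / "depth_outliers.tsv", "w") as fh:
        fh.write("gene_id\tdepth\toutlier_high\tlow_side\n")
        for r in recs:
            fh.write(f"{r.gene_id}\t{r.depth:.3g}\t{int(r.outlier_high)}"
                     f"\t{int(r.low_side)}\n")
    return DepthStageReport(
        n_genes=len(recs),
        n_outliers_high=n_out,
        percent_outliers=cpg_metrics.round_percent(n_out, len(recs)),
        q1=recs[0].q1,
        q3=recs[0].q3,
    )


@_stage("ks")
def _run_ks(config, outdir):
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(config.pairs_fasta, "fasta")}
    pair_ids = sorted({i[:-2] for i in seqs if i.endswith("_a")})
    pairs = [
        duplication_signals.ng86_ks(seqs[p + "_a"], seqs[p + "_b"],
                                    p + "_a", p + "_b")
        for p in pair_ids
        if p + "_b" in seqs
    ]
    hist = duplication_signals.ks_histogram(pairs)
    import math

    finite = [p.ks for p in pairs if math.isfinite(p.ks)]
    with open(outdir / "ks_pairs.tsv", "w") as fh:
        fh.write("id_a\tid_b\tS\tN\tsd\tnd\tps\tks\n")
        for p in pairs:
            fh.write(
                f"{p.id_a}\t{p.id_b}\t{p.S:.2f}\t{p.N:.2f}\t{p.sd:.2f}"
                f"\t{p.nd:.2f}\t{p.ps:.5f}\t{p.ks:.5f}\n"
            )
    return KsStageReport(
        n_pairs=hist["n_pairs"],
        n_saturated=hist["n_saturated"],
        mean_ks=sum(finite) / len(finite),
        window_fractions={
            f"{lo:g}-{hi:g}": frac
            for (lo, hi), frac in hist["window_fractions"].items()
        },
    )
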