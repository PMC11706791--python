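"""Synthetic genomes, depth tables, paralog pairs, and reads.

Every analysis stage in this package is exercised against data generated
here, with known truth written alongside.  The generators emulate the
statistical structure the analyses assume in a small AT-rich multichromosome
genome (GC 33%, four chromosomes — the karyotype scale of the copepod
genomes these analyses were designed around):

* gene placement — uniform midpoints, or Gaussian clusters around uniform
  cluster centers, with non-overlap enforced by resampling;
* coding sequences — a first-order Markov chain whose stationary base
  composition is fixed and whose C->G transition is scaled by a CpG-odds
  parameter ``w`` so the expected CpG_o/e of generated CDS equals ``w``
  (the mechanistic cause of depletion in real genomes is deamination of
  methylated cytosines; the Markov chain reproduces the resulting
  dinucleotide statistics without simulating mutation history);
* per-gene read depths — negative binomial, with a chosen fraction of
  "duplicated" genes multiplied up;
* paralog pairs — an ancestral codon sequence whose two copies accumulate
  Poisson numbers of strictly synonymous single-nucleotide changes to a
  target Ks;
* reads — error-free (or uniformly erroneous) fixed-length reads from
  uniform start positions on both strands.

All randomness flows from one integer seed; identical seeds reproduce every
output byte-for-byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .duplication_signals import _CODON_TABLE

__all__ = [
    "PlacementSpec",
    "DepthModel",
    "ParalogModel",
    "ReadModel",
    "SyntheticGenomeSpec",
    "markov_transition_matrix",
    "gen_cds",
    "place_genes",
    "gen_genome",
    "gen_depths",
    "gen_paralogs",
    "gen_reads",
    "gen_trait_table",
]

# stationary base composition, GC = 33%: (A, C, G, T)
BASE_COMPOSITION = {"A": 0.335, "C": 0.165, "G": 0.165, "T": 0.335}
_BASES = "ACGT"


@dataclass(frozen=True)
class PlacementSpec:
    mode: str = "uniform"  # "uniform" | "clustered"
    n_clusters: int = 10  # per chromosome, clustered mode
    cluster_sd_bp: int | None = None  # default 0.5% of chromosome length


@dataclass(frozen=True)
class DepthModel:
    mean: float = 100.0
    dispersion: float = 200.0  # NB size; variance = mean + mean^2/dispersion
    duplicated_fraction: float = 0.05
    duplication_multiplier: float = 10.0
    n_genes: int = 2000


@dataclass(frozen=True)
class ParalogModel:
    n_pairs: int = 200
    codons: int = 300
    # scalar Ks, or mixture as a tuple of (ks, weight) pairs
    target_ks: float | tuple[tuple[float, float], ...] = 0.05


@dataclass(frozen=True)
class ReadModel:
    coverage: float = 30.0
    read_length: int = 125
    error_rate: float = 0.0


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    n_chromosomes: int = 4
    chrom_length: int = 2_000_000
    n_genes_per_chrom: int = 125
    placement: PlacementSpec = field(default_factory=PlacementSpec)
    cds_length: int = 1500
    cpg_odds: float = 0.5  # target CpG_o/e of generated CDS
    # optional lower CpG-odds for ion_transport-labeled genes, emulating the
    # deeper historical methylation of ion-transport gene bodies
    ion_transport_cpg_odds: float | None = None
    ion_transport_fraction: float = 0.16
    housekeeping_fraction: float = 0.16
    depth_model: DepthModel = field(default_factory=DepthModel)
    paralog_model: ParalogModel = field(default_factory=ParalogModel)
    read_model: ReadModel = field(default_factory=ReadModel)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cpg_odds <= 0:
            raise ValueError("cpg_odds must be > 0")
        if self.n_genes_per_chrom * self.cds_length > 0.9 * self.chrom_length:
            raise ValueError(
                "infeasible gene density: genes would cover >90% of the chromosome"
            )


# ------------------------------------------------------------- sequences --


def markov_transition_matrix(w: float, comp: dict[str, float] | None = None) -> np.ndarray:
    """First-order transition matrix with stationary distribution equal to
    the base composition and P(G|C) = w*p_G.

    The remaining entries are scaled so that (a) each row sums to 1 and
    (b) the stationary distribution is exactly the target composition, which
    makes the expected CpG_o/e of emitted sequence equal to ``w``:
    f_CpG -> p_C*(w*p_G) while f_C*f_G -> p_C*p_G.
    """
    comp = comp or BASE_COMPOSITION
    p = np.array([comp[b] for b in _BASES])
    pC, pG = comp["C"], comp["G"]
    if w * pG >= 1 or w * pC >= 1:
        raise ValueError(f"cpg_odds {w} too large for composition")
    iC, iG = _BASES.index("C"), _BASES.index("G")
    T = np.zeros((4, 4))
    # row C: G gets w*pG, the rest share 1 - w*pG in stationary proportion
    T[iC, iG] = w * pG
    for j, b in enumerate(_BASES):
        if j != iG:
            T[iC, j] = (1 - w * pG) * p[j] / (1 - pG)
    # other rows: G compensated so the stationary G frequency stays pG
    g_other = pG * (1 - w * pC) / (1 - pC)
    for i in range(4):
        if i == iC:
            continue
        T[i, iG] = g_other
        for j in range(4):
            if j != iG:
                T[i, j] = (1 - g_other) * p[j] / (1 - pG)
    return T


def gen_cds(rng: np.random.Generator, length: int, w: float) -> str:
    """One CDS of ``length`` nt from the CpG-odds Markov chain."""
    T = markov_transition_matrix(w)
    p = np.array([BASE_COMPOSITION[b] for b in _BASES])
    # draw the whole state path via inverse-CDF on per-state cumulative rows
    cum = np.cumsum(T, axis=1)
    u = rng.random(length)
    states = np.empty(length, dtype=np.int64)
    states[0] = np.searchsorted(np.cumsum(p), u[0])
    for i in range(1, length):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i])
    return "".join(_BASES[s] for s in states)


def _background(rng: np.random.Generator, length: int) -> np.ndarray:
    p = np.array([BASE_COMPOSITION[b] for b in _BASES])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)


# ------------------------------------------------------------- placement --


def place_genes(
    rng: np.random.Generator,
    chrom_length: int,
    n_genes: int,
    gene_length: int,
    placement: PlacementSpec,
) -> np.ndarray:
    """Sorted non-overlapping gene start positions on one chromosome.

    Uniform mode draws midpoints uniformly; clustered mode draws cluster
    centers uniformly, then gene midpoints Normal(center, cluster_sd_bp)
    truncated to the chromosome.  Colliding genes are resampled; a gene
    whose cluster is saturated (no room after 1000 draws) falls back to a
    uniform draw so dense clustered specs remain feasible.
    """
    if n_genes * gene_length > 0.9 * chrom_length:
        raise ValueError("infeasible gene density")
    half = gene_length / 2
    lo, hi = half, chrom_length - half
    sd = placement.cluster_sd_bp or max(1, int(0.005 * chrom_length))
    if placement.mode == "clustered":
        centers = rng.uniform(lo, hi, size=placement.n_clusters)
        assignment = rng.integers(0, placement.n_clusters, size=n_genes)
    elif placement.mode == "uniform":
        centers = assignment = None
    else:
        raise ValueError(f"unknown placement mode {placement.mode!r}")

    def draw_one(idx: int) -> float:
        if centers is None:
            return rng.uniform(lo, hi)
        m = rng.normal(centers[assignment[idx]], sd)
        return min(max(m, lo), hi)

    accepted: list[tuple[float, float]] = []  # (start, end), kept sorted
    for idx in range(n_genes):
        placed = False
        for attempt in range(2000):
            # fall back to uniform placement once the cluster is saturated
            if centers is None or attempt >= 1000:
                mid = rng.uniform(lo, hi)
            else:
                mid = draw_one(idx)
            start, end = mid - half, mid + half
            if all(end <= s or start >= e for s, e in accepted):
                accepted.append((start, end))
                accepted.sort()
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place gene without overlap")
    return np.array(sorted(int(round(s)) for s, _ in accepted))


# ------------------------------------------------------------- generators --


def gen_genome(spec: SyntheticGenomeSpec, outdir: str | Path) -> dict:
    """Write genome.fasta, genes.gff3, labels.tsv and truth.json.

    Genes are intronless (one CDS segment spanning the gene), placed per the
    spec, with random strands; centromeres sit at each chromosome midpoint
    and are recorded in the truth file and in centromeres.tsv.
    Returns the truth dict (which also lists the file paths).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)

    fasta = outdir / "genome.fasta"
    gff3 = outdir / "genes.gff3"
    labels_tsv = outdir / "labels.tsv"
    cent_tsv = outdir / "centromeres.tsv"
    truth_json = outdir / "truth.json"

    genes_truth = []
    gff_lines = ["##gff-version 3"]
    label_lines = []
    cent_lines = ["chrom\tcentromere_pos"]

    n_genes_total = spec.n_chromosomes * spec.n_genes_per_chrom
    n_ion = int(round(spec.ion_transport_fraction * n_genes_total))
    n_hk = int(round(spec.housekeeping_fraction * n_genes_total))
    perm = rng.permutation(n_genes_total)
    ion_ids = set(perm[:n_ion])
    hk_ids = set(perm[n_ion : n_ion + n_hk])

    with open(fasta, "w") as fa:
        gene_counter = 0
        for ci in range(spec.n_chromosomes):
            chrom = f"chr{ci + 1}"
            seq = _background(rng, spec.chrom_length)
            starts = place_genes(
                rng, spec.chrom_length, spec.n_genes_per_chrom,
                spec.cds_length, spec.placement,
            )
            for start in starts:
                gene_id = f"g{gene_counter + 1:05d}"
                strand = "+" if rng.random() < 0.5 else "-"
                w = spec.cpg_odds
                if gene_counter in ion_ids and spec.ion_transport_cpg_odds:
                    w = spec.ion_transport_cpg_odds
                cds = gen_cds(rng, spec.cds_length, w)
                genomic = cds if strand == "+" else _revcomp(cds)
                seq[start : start + spec.cds_length] = np.frombuffer(
                    genomic.encode(), dtype="S1"
                )
                end1 = start + spec.cds_length  # GFF3 1-based inclusive end
                gff_lines.append(
                    f"{chrom}\tcopegen\tgene\t{start + 1}\t{end1}\t.\t{strand}\t."
                    f"\tID={gene_id}"
                )
                gff_lines.append(
                    f"{chrom}\tcopegen\tmRNA\t{start + 1}\t{end1}\t.\t{strand}\t."
                    f"\tID={gene_id}.t1;Parent={gene_id}"
                )
                gff_lines.append(
                    f"{chrom}\tcopegen\tCDS\t{start + 1}\t{end1}\t.\t{strand}\t0"
                    f"\tID={gene_id}.cds;Parent={gene_id}.t1"
                )
                gene_labels = []
                if gene_counter in ion_ids:
                    gene_labels.append("ion_transport")
                if gene_counter in hk_ids:
                    gene_labels.append("housekeeping")
                for lab in gene_labels:
                    label_lines.append(f"{gene_id}\t{lab}")
                genes_truth.append(
                    {
                        "gene_id": gene_id,
                        "chrom": chrom,
                        "start": int(start),
                        "end": int(start + spec.cds_length),
                        "strand": strand,
                        "cds": cds,
                        "labels": gene_labels,
                    }
                )
                gene_counter += 1
            fa.write(f">{chrom}\n")
            raw = seq.tobytes().decode()
            for i in range(0, len(raw), 80):
                fa.write(raw[i : i + 80] + "\n")
            cent_lines.append(f"{chrom}\t{spec.chrom_length // 2}")

    gff3.write_text("\n".join(gff_lines) + "\n")
    labels_tsv.write_text("".join(line + "\n" for line in label_lines))
    cent_tsv.write_text("\n".join(cent_lines) + "\n")

    truth = {
        "spec": asdict(spec),
        "files": {
            "fasta": str(fasta),
            "gff3": str(gff3),
            "labels": str(labels_tsv),
            "centromeres": str(cent_tsv),
        },
        "centromeres": {
            f"chr{ci + 1}": spec.chrom_length // 2
            for ci in range(spec.n_chromosomes)
        },
        "genes": genes_truth,
    }
    truth_json.write_text(json.dumps(truth, indent=1))
    return truth


def gen_depths(spec: SyntheticGenomeSpec, outdir: str | Path) -> dict:
    """Write depths.tsv (gene_id <tab> depth) and depth_truth.json.

    Depths ~ NegBin(mean, dispersion); a ``duplicated_fraction`` of genes is
    multiplied by ``duplication_multiplier``; truth lists the duplicated ids.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dm = spec.depth_model
    rng = np.random.default_rng(spec.rng_seed)
    n = dm.n_genes
    p = dm.dispersion / (dm.dispersion + dm.mean)
    depths = rng.negative_binomial(dm.dispersion, p, size=n).astype(float)
    n_dup = int(round(dm.duplicated_fraction * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False)
    depths[dup_idx] *= dm.duplication_multiplier
    ids = [f"g{i + 1:05d}" for i in range(n)]
    tsv = Path(outdir) / "depths.tsv"
    tsv.write_text(
        "".join(f"{g}\t{d:.0f}\n" for g, d in zip(ids, depths))
    )
    truth = {
        "model": asdict(dm),
        "file": str(tsv),
        "duplicated": sorted(ids[i] for i in dup_idx),
    }
    (Path(outdir) / "depth_truth.json").write_text(json.dumps(truth, indent=1))
    return truth


# synonymous single-nt change options per codon, cached
_SYN_OPTIONS: dict[str, list[tuple[int, str]]] = {}


def _syn_options(codon: str) -> list[tuple[int, str]]:
    if codon not in _SYN_OPTIONS:
        aa = _CODON_TABLE[codon]
        opts = []
        for pos in range(3):
            for alt in _BASES:
                if alt == codon[pos]:
                    continue
                alt_codon = codon[:pos] + alt + codon[pos + 1 :]
                if _CODON_TABLE[alt_codon] == aa:
                    opts.append((pos, alt))
        _SYN_OPTIONS[codon] = opts
    return _SYN_OPTIONS[codon]


_SENSE_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")


def _mutate_synonymously(
    rng: np.random.Generator, codons: list[str], n_events: int
) -> list[str]:
    """Apply n_events substitutions, each drawn uniformly from the current
    sequence's synonymous single-nucleotide change set."""
    codons = list(codons)
    opts_per = [len(_syn_options(c)) for c in codons]
    for _ in range(n_events):
        total = sum(opts_per)
        if total == 0:
            break
        r = int(rng.integers(total))
        for i, cnt in enumerate(opts_per):
            if r < cnt:
                pos, alt = _syn_options(codons[i])[r]
                codons[i] = codons[i][:pos] + alt + codons[i][pos + 1 :]
                opts_per[i] = len(_syn_options(codons[i]))
                break
            r -= cnt
    return codons


def _ancestral_codons(rng: np.random.Generator, n_codons: int) -> list[str]:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return [_SENSE_CODONS[i] for i in idx]


def _syn_sites(codons: list[str]) -> float:
    # synonymous changes / 3 == NG86 synonymous site count
    return sum(len(_syn_options(c)) for c in codons) / 3


def gen_paralogs(spec: SyntheticGenomeSpec, outdir: str | Path) -> dict:
    """Write paralog pair FASTAs (pairs.fasta, ids <pair>_a / <pair>_b) and
    paralog_truth.json with each pair's target Ks.

    Each pair descends from a random sense-codon ancestor; each copy
    receives Poisson(target_ks/2 * S_ancestor) strictly synonymous changes,
    so the pair's expected synonymous divergence is the target Ks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pm = spec.paralog_model
    rng = np.random.default_rng(spec.rng_seed)
    if isinstance(pm.target_ks, (int, float)):
        mixture = ((float(pm.target_ks), 1.0),)
    else:
        mixture = tuple((float(k), float(w)) for k, w in pm.target_ks)
    weights = np.array([w for _, w in mixture])
    weights = weights / weights.sum()
    comp_idx = rng.choice(len(mixture), size=pm.n_pairs, p=weights)

    fasta = Path(outdir) / "pairs.fasta"
    pairs_truth = []
    with open(fasta, "w") as fh:
        for i in range(pm.n_pairs):
            target = mixture[comp_idx[i]][0]
            anc = _ancestral_codons(rng, pm.codons)
            S = _syn_sites(anc)
            copies = []
            for _copy in range(2):
                n_events = int(rng.poisson(target / 2 * S))
                copies.append("".join(_mutate_synonymously(rng, anc, n_events)))
            pid = f"pair{i + 1:04d}"
            fh.write(f">{pid}_a\n{copies[0]}\n>{pid}_b\n{copies[1]}\n")
            pairs_truth.append({"pair_id": pid, "target_ks": target})
    truth = {
        "model": {
            "n_pairs": pm.n_pairs,
            "codons": pm.codons,
            "mixture": [list(m) for m in mixture],
        },
        "file": str(fasta),
        "pairs": pairs_truth,
    }
    (Path(outdir) / "paralog_truth.json").write_text(json.dumps(truth, indent=1))
    return truth


def gen_trait_table(
    groups: dict[str, tuple[int, float]],
    cv: float = 0.5,
    seed: int = 0,
    out_tsv: str | Path | None = None,
):
    """Order-labeled species trait table with group shifts.

    ``groups`` maps group name -> (n_species, median value); each species
    value is lognormal around the group median with coefficient of
    variation ``cv``.  Returns a TraitTable; optionally writes TSV.
    """
    from .comparative_stats import TraitTable

    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1 + cv**2))
    rows = []
    for group in sorted(groups):
        n, median = groups[group]
        vals = median * np.exp(rng.normal(0, sigma, size=n))
        rows += [(f"{group}_sp{i + 1}", group, float(v))
                 for i, v in enumerate(vals)]
    table = TraitTable.from_records(rows)
    if out_tsv:
        table.df.to_csv(out_tsv, sep="\t", index=False)
    return table


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def gen_reads(
    genome_fasta: str | Path,
    out_fastq: str | Path,
    coverage: float = 30.0,
    read_length: int = 125,
    error_rate: float = 0.0,
    seed: int = 0,
) -> int:
    """Write fixed-length reads at the given coverage: uniform start
    positions, both strands, optional uniform substitution errors.
    Returns the number of reads written (0 with a warning at coverage 0).
    """
    from Bio import SeqIO

    rng = np.random.default_rng(seed)
    n_total = 0
    with open(out_fastq, "w") as out:
        for rec in SeqIO.parse(str(genome_fasta), "fasta"):
            seq = str(rec.seq).upper()
            L = len(seq)
            if L < read_length:
                continue
            n_reads = int(round(coverage * L / read_length))
            if n_reads == 0:
                continue
            starts = rng.integers(0, L - read_length + 1, size=n_reads)
            strands = rng.random(n_reads) < 0.5
            qual = "I" * read_length
            for j, (s, fwd) in enumerate(zip(starts, strands)):
                read = seq[s : s + read_length]
                if not fwd:
                    read = _revcomp(read)
                if error_rate > 0:
                    arr = list(read)
                    for pos in np.flatnonzero(rng.random(read_length) < error_rate):
                        arr[pos] = "ACGT"[
                            (("ACGT".index(arr[pos])) + int(rng.integers(1, 4))) % 4
                        ]
                    read = "".join(arr)
                out.write(f"@{rec.id}_{j}\n{read}\n+\n{qual}\n")
                n_total += 1
    if n_total == 0:
        import logging

        logging.getLogger(__name__).warning(
            "gen_reads produced no reads (coverage or genome too small)"
        )
    return n_total
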