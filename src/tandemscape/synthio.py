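"""Synthetic genomes, homology tables, term assignments and expression designs.

Every input the pipeline consumes can be generated here with a known
ground truth, so each downstream stage is testable without any downloads.
The generator emulates the study conditions of a grass-genome tandem
duplication survey: chromosomes of ordered genes carrying planted tandem
arrays of size 2–9, codon sequence pairs diverged to specified Ka and Ks,
term assignments with planted over-represented terms, and a
two-tissue × five-timepoint × three-replicate salt-stress design
(treatment vs control) with planted leaf-specific, root-specific and
co-expressed up-regulation patterns.

The codon substitution simulator is deliberately independent of the NG86
estimator it is used to test: substitutions are per-site uniform
nucleotide proposals, accepted when they realise the requested synonymous
or nonsynonymous event and do not create a stop codon, with event numbers
calibrated by the expected NG86 site counts of the ancestor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import BASES, GENETIC_CODE, STOP, random_cds, synonymous_site_count, translate
from .tandem_finder import GeneModel

INTERGENIC_GAP_BP = 500
MEDIAN_GENE_CODONS = 300
MIN_GENE_CODONS = 100
LENGTH_SIGMA = 0.3

#: Planted per-contrast effect for responsive genes: log2 fold change 2 (4x).
PLANTED_LOG2FC = 2.0
NB_DISPERSION = 0.05

CLASS_LABELS = ("leaf_specific", "root_specific", "co_expressed")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class PlantedCluster:
    """A tandem array to plant: ``size`` consecutive ranks on one chromosome."""

    chromosome: int  # 0-based chromosome index
    start_rank: int
    size: int
    true_ks: float = 0.65
    true_kaks: float = 0.2


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic data generator.

    Defaults mirror the emulated experiment: two tissues (leaf, root),
    five salt-stress timepoints (8 h, 12 h, 24 h, 48 h, 5 d; 400 mM NaCl
    vs water control), three biological replicates, tandem arrays of
    2–9 genes.
    """

    n_chromosomes: int = 2
    genes_per_chromosome: int = 200
    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    background_homology_noise: float = 0.0
    n_timepoints: int = 5
    n_replicates: int = 3
    tissues: tuple[str, ...] = ("leaf", "root")
    timepoints: tuple[str, ...] = ("8h", "12h", "24h", "48h", "5d")
    planted_class_counts: dict[str, int] = field(default_factory=dict)
    planted_terms: list[tuple[str, int, int]] = field(default_factory=list)
    n_null_terms: int = 20
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.background_homology_noise <= 1:
            raise ConfigurationError("noise probability must lie in [0, 1]")
        occupied: dict[int, set[int]] = {}
        for pc in self.planted_clusters:
            if not 2 <= pc.size <= 9:
                raise ConfigurationError(f"cluster size {pc.size} outside [2, 9]")
            if pc.chromosome >= self.n_chromosomes or pc.chromosome < 0:
                raise ConfigurationError(f"cluster chromosome {pc.chromosome} out of range")
            ranks = set(range(pc.start_rank, pc.start_rank + pc.size))
            if pc.start_rank < 0 or pc.start_rank + pc.size > self.genes_per_chromosome:
                raise ConfigurationError(
                    f"cluster at ranks {pc.start_rank}..{pc.start_rank + pc.size - 1} "
                    f"exceeds chromosome of {self.genes_per_chromosome} genes"
                )
            taken = occupied.setdefault(pc.chromosome, set())
            if taken & ranks:
                raise ConfigurationError(
                    f"planted clusters overlap on chromosome {pc.chromosome}"
                )
            taken |= ranks
        unknown = set(self.planted_class_counts) - set(CLASS_LABELS)
        if unknown:
            raise ConfigurationError(f"unknown class labels {sorted(unknown)}")
        if len(self.timepoints) != self.n_timepoints:
            self.timepoints = tuple(f"t{i}" for i in range(self.n_timepoints))


@dataclass
class TruthManifest:
    """Ground truth of one simulated dataset.

    ``clusters`` lists member ids per planted array; ``pair_truth`` the
    (true Ks, true Ka/Ks) for every within-cluster pair; ``gene_classes``
    the planted tissue-specificity label per responsive gene;
    ``enriched_terms`` the term ids planted as over-represented;
    ``gene_lengths`` CDS length in bp per gene (for FPKM).
    """

    clusters: list[dict] = field(default_factory=list)
    pair_truth: dict[str, tuple[float, float]] = field(default_factory=dict)
    gene_classes: dict[str, str] = field(default_factory=dict)
    enriched_terms: list[str] = field(default_factory=list)
    gene_lengths: dict[str, int] = field(default_factory=dict)

    def cluster_of(self) -> dict[str, int]:
        return {
            gid: i for i, c in enumerate(self.clusters) for gid in c["members"]
        }

    def to_json(self, path) -> None:
        data = {
            "clusters": self.clusters,
            "pair_truth": {k: list(v) for k, v in self.pair_truth.items()},
            "gene_classes": self.gene_classes,
            "enriched_terms": self.enriched_terms,
            "gene_lengths": self.gene_lengths,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            clusters=data["clusters"],
            pair_truth={k: tuple(v) for k, v in data["pair_truth"].items()},
            gene_classes=data["gene_classes"],
            enriched_terms=data["enriched_terms"],
            gene_lengths={k: int(v) for k, v in data["gene_lengths"].items()},
        )


def _pair_key(a: str, b: str) -> str:
    return "|".join(sorted((a, b)))


# ---------------------------------------------------------------------------
# codon-pair evolution


def _site_counts(cds: str) -> tuple[float, float]:
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    S = sum(synonymous_site_count(c) for c in codons)
    return S, 3.0 * len(codons) - S


def _evolve_branch(cds: str, d_syn: float, d_nonsyn: float, rng) -> str:
    """Apply Poisson numbers of synonymous/nonsynonymous substitutions.

    Event counts are d·(expected NG86 site count of the ancestor); each
    event proposes a uniform (codon, position, base) change and is
    accepted when it has the requested synonymy and creates no stop,
    so events land uniformly over the corresponding NG86 opportunities.
    """
    seq = list(cds)
    n_codons = len(cds) // 3
    S, N = _site_counts(cds)
    events = ["syn"] * rng.poisson(d_syn * S) + ["nonsyn"] * rng.poisson(d_nonsyn * N)
    rng.shuffle(events)
    for kind in events:
        for _attempt in range(100_000):
            ci = int(rng.integers(n_codons))
            pos = int(rng.integers(3))
            base = BASES[int(rng.integers(4))]
            codon = "".join(seq[3 * ci : 3 * ci + 3])
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == STOP:
                continue
            synonymous = GENETIC_CODE[mutant] == GENETIC_CODE[codon]
            if (kind == "syn") == synonymous:
                seq[3 * ci + pos] = base
                break
        else:  # pragma: no cover - only reachable on degenerate sequences
            raise RuntimeError("could not place a substitution event")
    return "".join(seq)


def evolve_codon_pair(
    ancestor_cds: str,
    target_ks: float,
    target_kaks: float,
    rng,
) -> tuple[str, str]:
    """Two descendants of an ancestor with expected pairwise NG86 Ks/Ka.

    Each branch receives half the requested divergence, so the distance
    *between* the descendants has expectation ``target_ks`` (synonymous)
    and ``target_ks * target_kaks`` (nonsynonymous).  ``rng`` is a
    ``numpy.random.Generator`` (pass ``np.random.default_rng(seed)``).
    """
    if target_ks < 0:
        raise ValueError("target_ks must be non-negative")
    if target_kaks < 0:
        raise ValueError("target_kaks must be non-negative")
    translate(ancestor_cds, "ancestor")  # validates frame/alphabet/stops
    if target_ks == 0 and target_kaks == 0:
        return ancestor_cds, ancestor_cds
    d_syn = target_ks / 2.0
    d_nonsyn = target_ks * target_kaks / 2.0
    a = _evolve_branch(ancestor_cds, d_syn, d_nonsyn, rng)
    b = _evolve_branch(ancestor_cds, d_syn, d_nonsyn, rng)
    return a, b


# ---------------------------------------------------------------------------
# genome


def _gene_lengths_codons(rng, n: int) -> np.ndarray:
    raw = rng.lognormal(mean=np.log(MEDIAN_GENE_CODONS), sigma=LENGTH_SIGMA, size=n)
    return np.maximum(raw.astype(int), MIN_GENE_CODONS)


def chromosome_name(i: int) -> str:
    return f"chr{i + 1:02d}"


def generate_genome(
    config: SimConfig,
) -> tuple[list[GeneModel], dict[str, str], dict[str, str], TruthManifest]:
    """Lay out ordered genes per chromosome and plant tandem arrays.

    Planted-cluster members descend from one random ancestor, each branch
    carrying half the configured Ks (so any member pair meets the target
    in expectation); background genes are independent random CDS with no
    homology.  Returns (annotation, cds, proteins, manifest); coordinates
    are strictly increasing and non-overlapping within a chromosome.
    """
    rng = np.random.default_rng(config.rng_seed)
    cluster_at: dict[tuple[int, int], tuple[int, PlantedCluster]] = {}
    for idx, pc in enumerate(config.planted_clusters):
        for r in range(pc.start_rank, pc.start_rank + pc.size):
            cluster_at[(pc.chromosome, r)] = (idx, pc)

    manifest = TruthManifest()
    manifest.clusters = [
        {
            "cluster_id": i,
            "chromosome": chromosome_name(pc.chromosome),
            "members": [],
            "true_ks": pc.true_ks,
            "true_kaks": pc.true_kaks,
        }
        for i, pc in enumerate(config.planted_clusters)
    ]

    genes: list[GeneModel] = []
    cds: dict[str, str] = {}
    proteins: dict[str, str] = {}
    cluster_seqs: dict[int, dict[int, str]] = {}

    for ci, pc in enumerate(config.planted_clusters):
        n_codons = int(_gene_lengths_codons(rng, 1)[0])
        ancestor = random_cds(rng, n_codons)
        d_syn = pc.true_ks / 2.0
        d_nonsyn = pc.true_ks * pc.true_kaks / 2.0
        cluster_seqs[ci] = {
            r: _evolve_branch(ancestor, d_syn, d_nonsyn, rng)
            for r in range(pc.start_rank, pc.start_rank + pc.size)
        }

    for chrom_idx in range(config.n_chromosomes):
        chrom = chromosome_name(chrom_idx)
        lengths = _gene_lengths_codons(rng, config.genes_per_chromosome)
        pos = 1
        for rank in range(config.genes_per_chromosome):
            gene_id = f"{chrom}g{rank + 1:04d}"
            planted = cluster_at.get((chrom_idx, rank))
            if planted is not None:
                ci, pc = planted
                seq = cluster_seqs[ci][rank]
                manifest.clusters[ci]["members"].append(gene_id)
            else:
                seq = random_cds(rng, int(lengths[rank]))
            strand = "+" if rng.random() < 0.5 else "-"
            start = pos
            end = start + len(seq) - 1
            pos = end + 1 + INTERGENIC_GAP_BP
            genes.append(GeneModel(gene_id, chrom, start, end, strand))
            cds[gene_id] = seq
            proteins[gene_id] = translate(seq, gene_id)
            manifest.gene_lengths[gene_id] = len(seq)

    for c in manifest.clusters:
        members = c["members"]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                manifest.pair_truth[_pair_key(a, b)] = (c["true_ks"], c["true_kaks"])

    _assign_classes(config, manifest, rng)
    return genes, cds, proteins, manifest


def _assign_classes(config: SimConfig, manifest: TruthManifest, rng) -> None:
    """Plant tissue-class labels, preferring tandem genes (the study set)."""
    total = sum(config.planted_class_counts.values())
    if total == 0:
        return
    tdgs = [gid for c in manifest.clusters for gid in c["members"]]
    others = sorted(set(manifest.gene_lengths) - set(tdgs))
    pool = tdgs + list(rng.permutation(others))
    if total > len(pool):
        raise ConfigurationError(
            f"{total} planted class labels exceed {len(pool)} genes"
        )
    it = iter(pool)
    for label in CLASS_LABELS:
        for _ in range(config.planted_class_counts.get(label, 0)):
            manifest.gene_classes[next(it)] = label


# ---------------------------------------------------------------------------
# homology


def generate_homology_table(
    genes: list[GeneModel],
    manifest: TruthManifest,
    noise: float = 0.0,
    rng=None,
    max_gap_guard: int = 5,
) -> pd.DataFrame:
    """Emulated all-vs-all protein search output (12-column outfmt 6).

    Every within-cluster pair appears in both directions with E-value far
    below 1e-10, plus self-hits.  Spurious extra pairs (probability
    ``noise`` per gene) are constrained to rank gaps > ``max_gap_guard``
    or different chromosomes, so noise can never create a tandem pair or
    bridge two planted arrays.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    by_id = {g.gene_id: g for g in genes}
    order: dict[str, dict[str, int]] = {}
    for g in genes:
        order.setdefault(g.chromosome, {})
    for chrom in order:
        chrom_genes = sorted(
            (g for g in genes if g.chromosome == chrom), key=lambda g: g.start
        )
        order[chrom] = {g.gene_id: i for i, g in enumerate(chrom_genes)}

    rows = []

    def add_pair(a: str, b: str, pident: float, evalue: float, bits: float):
        la = by_id[a].end - by_id[a].start + 1
        rows.append((a, b, round(pident, 2), la // 3, 0, 0, 1, la, 1, la, evalue, bits))

    for g in genes:
        la = g.end - g.start + 1
        rows.append((g.gene_id, g.gene_id, 100.0, la // 3, 0, 0, 1, la, 1, la, 0.0, 2000.0))

    for c in manifest.clusters:
        members = c["members"]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                pident = float(np.clip(100 - 25 * c["true_ks"] + rng.normal(0, 2), 30, 99.9))
                evalue = 10.0 ** float(rng.uniform(-180, -50))
                bits = float(rng.uniform(300, 1500))
                add_pair(a, b, pident, evalue, bits)
                add_pair(b, a, pident, evalue, bits)

    if noise > 0:
        gene_ids = [g.gene_id for g in genes]
        for g in genes:
            if rng.random() >= noise:
                continue
            for _attempt in range(200):
                partner = gene_ids[int(rng.integers(len(gene_ids)))]
                if partner == g.gene_id:
                    continue
                other = by_id[partner]
                if other.chromosome == g.chromosome:
                    gap = abs(order[g.chromosome][g.gene_id] - order[g.chromosome][partner])
                    if gap <= max_gap_guard:
                        continue
                evalue = 10.0 ** float(rng.uniform(-60, -15))
                bits = float(rng.uniform(80, 300))
                pident = float(rng.uniform(30, 60))
                add_pair(g.gene_id, partner, pident, evalue, bits)
                add_pair(partner, g.gene_id, pident, evalue, bits)
                break

    from .tandem_finder import HOMOLOGY_COLUMNS

    return pd.DataFrame(rows, columns=HOMOLOGY_COLUMNS)


# ---------------------------------------------------------------------------
# term assignments


def generate_term_table(
    config: SimConfig,
    manifest: TruthManifest,
    rng=None,
) -> pd.DataFrame:
    """Gene->term assignments with planted over-represented terms.

    Planted terms (term_id, term_size, study_overlap) draw their study
    overlap from the tandem-gene set; null terms draw uniformly from all
    genes.  The truly enriched term ids are recorded in the manifest.
    """
    rng = np.random.default_rng(config.rng_seed + 1) if rng is None else rng
    all_genes = sorted(manifest.gene_lengths)
    study = sorted({gid for c in manifest.clusters for gid in c["members"]})
    non_study = sorted(set(all_genes) - set(study))
    rows = []
    manifest.enriched_terms = []
    for term_id, term_size, overlap in config.planted_terms:
        if overlap > len(study) or term_size - overlap > len(non_study):
            raise ConfigurationError(f"term {term_id} larger than available gene pools")
        chosen = list(rng.choice(study, size=overlap, replace=False)) + list(
            rng.choice(non_study, size=term_size - overlap, replace=False)
        )
        manifest.enriched_terms.append(term_id)
        for gid in chosen:
            rows.append((gid, term_id, f"planted term {term_id}", "biological_process"))
    for i in range(config.n_null_terms):
        term_id = f"NULL:{i:04d}"
        size = int(rng.integers(10, 51))
        for gid in rng.choice(all_genes, size=size, replace=False):
            rows.append((gid, term_id, f"background term {i}", "biological_process"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name", "namespace"])


# ---------------------------------------------------------------------------
# expression


def _planted_events(label: str, tissues: tuple[str, ...], n_tp: int, rng) -> dict[str, set[int]]:
    """Timepoint indices with an up event per tissue, realising the label."""
    first, second = tissues[0], tissues[1]
    if label == "leaf_specific":
        n1 = int(rng.integers(4, n_tp + 1))
        n2 = int(rng.integers(0, 2))
    elif label == "root_specific":
        n2 = int(rng.integers(4, n_tp + 1))
        n1 = int(rng.integers(0, 2))
    elif label == "co_expressed":
        while True:
            n1 = int(rng.integers(3, n_tp + 1))
            n2 = int(rng.integers(3, n_tp + 1))
            if n1 + n2 >= 7:
                break
    else:
        n1 = n2 = 0
    return {
        first: set(map(int, rng.choice(n_tp, size=n1, replace=False))),
        second: set(map(int, rng.choice(n_tp, size=n2, replace=False))),
    }


def generate_expression(
    config: SimConfig,
    manifest: TruthManifest,
    rng=None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.DataFrame]:
    """Counts, design, gene lengths and high-signal DE tables.

    Returns ``(counts, design, gene_lengths_bp, de_table)``.  The DE table
    is the primary synthetic product: planted up events get log2FC near
    +2 at tiny FDR, everything else is null (small |log2FC|, FDR >= 0.2).
    Counts are negative binomial around a per-gene log-normal baseline
    with the planted fold changes applied to treatment libraries, for
    exercising FPKM and the stand-in DE test.
    """
    if len(config.tissues) != 2:
        raise ConfigurationError("expression design requires exactly two tissues")
    rng = np.random.default_rng(config.rng_seed + 2) if rng is None else rng
    genes = sorted(manifest.gene_lengths)
    n_tp = config.n_timepoints
    timepoints = list(config.timepoints)[:n_tp]

    events: dict[str, dict[str, set[int]]] = {}
    for gid, label in manifest.gene_classes.items():
        events[gid] = _planted_events(label, config.tissues, n_tp, rng)

    design_rows = []
    samples = []
    for tissue in config.tissues:
        for cond in ("control", "treatment"):
            for ti, tp in enumerate(timepoints):
                for rep in range(1, config.n_replicates + 1):
                    sample = f"{tissue}_{cond}_{tp}_r{rep}"
                    samples.append((sample, tissue, cond, ti))
                    design_rows.append(
                        {"sample": sample, "tissue": tissue, "timepoint": tp,
                         "condition": cond, "replicate": rep}
                    )
    design = pd.DataFrame(design_rows)

    baseline = rng.lognormal(mean=np.log(200), sigma=1.0, size=len(genes))
    r = 1.0 / NB_DISPERSION
    counts = np.zeros((len(genes), len(samples)), dtype=int)
    fold = 2.0 ** PLANTED_LOG2FC
    for si, (sample, tissue, cond, ti) in enumerate(samples):
        mu = baseline.copy()
        if cond == "treatment":
            for gi, gid in enumerate(genes):
                ev = events.get(gid)
                if ev is not None and ti in ev[tissue]:
                    mu[gi] *= fold
        counts[:, si] = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=[s[0] for s in samples])

    de_rows = []
    for tissue in config.tissues:
        for ti, tp in enumerate(timepoints):
            for gid in genes:
                ev = events.get(gid)
                if ev is not None and ti in ev[tissue]:
                    log2fc = float(rng.normal(PLANTED_LOG2FC, 0.15))
                    fdr = 10.0 ** float(rng.uniform(-6, -3))
                else:
                    log2fc = float(rng.normal(0.0, 0.2))
                    fdr = float(rng.uniform(0.2, 1.0))
                de_rows.append((gid, tissue, tp, log2fc, fdr, fdr))
    de = pd.DataFrame(
        de_rows, columns=["gene_id", "tissue", "timepoint", "log2fc", "pvalue", "fdr"]
    )
    lengths = pd.Series(
        {g: manifest.gene_lengths[g] for g in genes}, name="length_bp"
    )
    return counts_df, design, lengths, de


def default_study_config(seed: int = 0) -> SimConfig:
    """The default synthetic study: 2 × 500-gene chromosomes, 60 arrays.

    Planted cluster sizes cycle over 2–9; Ks values alternate around the
    young genome-wide duplication signal (0.65) with a minority of old
    (2.45) arrays; tissue classes 48/116/138 as in the emulated survey.
    """
    rng = np.random.default_rng(seed)
    clusters = []
    sizes = [2, 3, 4, 5, 6, 7, 8, 9]
    per_chrom = 30
    genes_per_chrom = 500
    for chrom in range(2):
        spacing = genes_per_chrom // per_chrom
        for i in range(per_chrom):
            size = sizes[(chrom * per_chrom + i) % len(sizes)]
            start = i * spacing
            old = (chrom * per_chrom + i) % 5 == 4
            clusters.append(
                PlantedCluster(
                    chromosome=chrom,
                    start_rank=start,
                    size=size,
                    true_ks=2.45 if old else 0.65,
                    true_kaks=0.2,
                )
            )
    return SimConfig(
        n_chromosomes=2,
        genes_per_chromosome=genes_per_chrom,
        planted_clusters=clusters,
        background_homology_noise=0.0,
        planted_class_counts={"leaf_specific": 48, "root_specific": 116, "co_expressed": 138},
        planted_terms=[("GO:PLANT01", 40, 30), ("GO:PLANT02", 60, 35), ("GO:PLANT03", 25, 20)],
        rng_seed=seed,
    )
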