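"""End-to-end orchestration: simulate → detect → kaks → date → enrich → classify.

All randomness flows from one seed through named per-stage substreams, so
a run is deterministic and every intermediate is a plain text file (GFF3,
FASTA, TSV, JSON) that external tools' real outputs can replace.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import io, ks_landscape, salt_response, synthio, tandem_finder
from .enrichment import hypergeom_enrich, read_term_table, records_to_frame
from .molevo import ClockParams, KaKsResult, divergence_time_ma, kaks_pair, round_half_up
from .synthio import SimConfig, TruthManifest, default_study_config

logger = logging.getLogger("tandemscape")

STAGE_SEEDS = {"genome": 11, "homology": 23, "terms": 37, "expression": 41}


@dataclass
class RunConfig:
    """All stage parameters in one place, with the study defaults."""

    out_dir: str = "tandemscape_out"
    rng_seed: int = 0
    evalue_max: float = 1e-10
    top_n: int = 10
    max_gap: int = 1
    lam: float = 1.5e-8
    bin_width: float = 0.1
    ks_cap: float = 3.5
    fdr_max: float = 0.05
    lfc_min: float = 1.0
    spec_min: int = 4
    other_max: int = 1
    co_min: int = 7
    q_max: float = 0.05
    noise: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _stage_rng(seed: int, stage: str):
    return np.random.default_rng([seed, STAGE_SEEDS[stage]])


def simulate(config: RunConfig, sim: SimConfig | None = None) -> Path:
    """Generate the full synthetic input bundle under ``out_dir``."""
    out = io.ensure_dir(config.out_dir)
    if sim is None:
        sim = default_study_config(config.rng_seed)
        sim.background_homology_noise = config.noise
    genes, cds, proteins, manifest = synthio.generate_genome(sim)
    hits = synthio.generate_homology_table(
        genes, manifest, noise=sim.background_homology_noise,
        rng=_stage_rng(sim.rng_seed, "homology"), max_gap_guard=max(5, config.max_gap),
    )
    terms = synthio.generate_term_table(sim, manifest, rng=_stage_rng(sim.rng_seed, "terms"))
    counts, design, lengths, de = synthio.generate_expression(
        sim, manifest, rng=_stage_rng(sim.rng_seed, "expression")
    )
    io.write_gff3(genes, out / "genes.gff3")
    io.write_fasta(cds, out / "cds.fasta")
    io.write_fasta(proteins, out / "proteins.fasta")
    hits.to_csv(out / "homology.tsv", sep="\t", header=False, index=False)
    io.write_tsv(terms, out / "terms.tsv")
    io.write_counts(counts, out / "counts.tsv")
    io.write_tsv(design, out / "design.tsv")
    lengths.rename_axis("gene_id").reset_index().to_csv(
        out / "gene_lengths.tsv", sep="\t", index=False
    )
    io.write_tsv(de, out / "de_table.tsv")
    manifest.to_json(out / "manifest.json")
    logger.info("simulated %d genes, %d clusters", len(genes), len(manifest.clusters))
    return out


def detect_stage(config: RunConfig, out: Path) -> tuple[list, list, set]:
    genes = io.read_gff3(out / "genes.gff3")
    hits = tandem_finder.read_homology_table(out / "homology.tsv")
    clusters, pairs = tandem_finder.detect(
        genes, hits, evalue_max=config.evalue_max, top_n=config.top_n,
        max_gap=config.max_gap,
    )
    tdgs = tandem_finder.tdg_genes(clusters)
    ranked = tandem_finder.assign_ranks(genes)
    cluster_rows = [
        {"cluster_id": i, "chromosome": c.chromosome, "size": c.size,
         "members": ",".join(c.members)}
        for i, c in enumerate(clusters)
    ]
    io.write_tsv(pd.DataFrame(cluster_rows), out / "clusters.tsv")
    io.write_tsv(
        tandem_finder.chromosome_distribution(tdgs, ranked), out / "distribution.tsv"
    )
    io.write_tsv(tandem_finder.cluster_size_table(clusters), out / "cluster_sizes.tsv")
    return clusters, ranked, tdgs


def consecutive_cluster_pairs(clusters) -> list[tuple[str, str]]:
    """The designated Ka/Ks pairs: consecutive-rank members within each cluster."""
    pairs = []
    for c in clusters:
        pairs.extend(zip(c.members, c.members[1:]))
    return pairs


def kaks_stage(config: RunConfig, out: Path, clusters) -> list[KaKsResult]:
    cds = io.read_fasta(out / "cds.fasta")
    clock = ClockParams(config.lam)
    results = []
    rows = []
    for a, b in consecutive_cluster_pairs(clusters):
        r = kaks_pair(cds[a], cds[b], a, b)
        results.append(r)
        rows.append({
            "gene1": a, "gene2": b,
            "Ka": round_half_up(r.Ka, 4) if np.isfinite(r.Ka) else float("nan"),
            "Ks": round_half_up(r.Ks, 4) if np.isfinite(r.Ks) else float("nan"),
            "Ka_Ks": round_half_up(r.ratio, 2) if np.isfinite(r.ratio) else float("nan"),
            "S": round(r.S, 2), "N": round(r.N, 2),
            "Sd": round(r.Sd, 2), "Nd": round(r.Nd, 2),
            "selection": r.selection,
            "T_ma": divergence_time_ma(r.Ks, clock) if np.isfinite(r.Ks) else float("nan"),
        })
    df = pd.DataFrame(rows)
    io.write_tsv(df, out / "kaks.tsv")
    with open(out / "kaks_meta.json", "w") as fh:
        json.dump({"pair_rule": "consecutive-rank members within each cluster",
                   "lambda": config.lam}, fh, indent=1)
    return results


def date_stage(config: RunConfig, out: Path, results, gene_classes) -> pd.DataFrame:
    clock = ClockParams(config.lam)
    dists, peak_table = ks_landscape.class_ks_compare(
        results, gene_classes, ks_cap=config.ks_cap, bin_width=config.bin_width,
        clock=clock,
    )
    for label, d in dists.items():
        if d.counts is None or len(d.counts) == 0:
            continue
        hist = pd.DataFrame({
            "bin_lo": d.edges[:-1], "bin_hi": d.edges[1:], "count": d.counts,
        })
        io.write_tsv(hist, out / f"ks_hist_{label}.tsv")
    io.write_tsv(peak_table, out / "ks_peaks.tsv")
    return peak_table


def enrich_stage(config: RunConfig, out: Path, tdgs: set, all_genes: set) -> pd.DataFrame:
    assignments = read_term_table(out / "terms.tsv")
    annotated = set().union(*(t.genes for t in assignments)) if assignments else set()
    background = annotated & all_genes
    study = tdgs & background
    records = hypergeom_enrich(study, assignments, background, q_max=config.q_max)
    df = records_to_frame(records)
    io.write_tsv(df, out / "enrichment.tsv")
    return df


def classify_stage(config: RunConfig, out: Path, tdgs: set) -> tuple[pd.DataFrame, pd.DataFrame]:
    de = io.read_tsv(out / "de_table.tsv")
    calls = salt_response.call_up(de, fdr_max=config.fdr_max, lfc_min=config.lfc_min)
    counts = salt_response.count_up_events(calls)
    labels = salt_response.classify_genes(
        counts, spec_min=config.spec_min, other_max=config.other_max, co_min=config.co_min
    )
    summary = salt_response.summarize_classes(labels, tdg_set=tdgs)
    io.write_tsv(labels, out / "tissue_classes.tsv")
    io.write_tsv(summary, out / "class_summary.tsv")
    return labels, summary


def recovery_summary(out: Path, clusters) -> dict:
    """Planted-vs-detected cluster agreement (adjusted Rand index)."""
    manifest = TruthManifest.from_json(out / "manifest.json")
    truth = manifest.cluster_of()
    detected = {gid: i for i, c in enumerate(clusters) for gid in c.members}
    genes = sorted(manifest.gene_lengths)
    t_labels = [truth.get(g, -1 - i) for i, g in enumerate(genes)]
    d_labels = [detected.get(g, -100000 - i) for i, g in enumerate(genes)]
    # singletons get unique labels on both sides so only cluster structure matters
    ari = float(adjusted_rand_score(t_labels, d_labels))
    planted_sets = sorted(tuple(sorted(c["members"])) for c in manifest.clusters)
    detected_sets = sorted(tuple(sorted(c.members)) for c in clusters)
    exact = planted_sets == detected_sets
    return {
        "adjusted_rand_index": ari,
        "n_planted_clusters": len(manifest.clusters),
        "n_detected_clusters": len(clusters),
        "exact_recovery": bool(exact),
    }


def run(config: RunConfig, sim: SimConfig | None = None) -> dict:
    """Run every stage on a (by default simulated) dataset; returns the report."""
    out = simulate(config, sim)
    try:
        clusters, ranked, tdgs = detect_stage(config, out)
        results = kaks_stage(config, out, clusters)
        manifest = TruthManifest.from_json(out / "manifest.json")
        peaks = date_stage(config, out, results, manifest.gene_classes)
        enrich = enrich_stage(config, out, tdgs, {g.gene_id for g in ranked})
        labels, class_summary = classify_stage(config, out, tdgs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    report = {
        "n_genes": len(ranked),
        "n_tdgs": len(tdgs),
        "tdg_pct_of_genes": tandem_finder.tdg_fraction(tdgs, ranked),
        "n_clusters": len(clusters),
        "cluster_sizes": tandem_finder.cluster_size_table(clusters).to_dict("records"),
        "chromosome_distribution": tandem_finder.chromosome_distribution(
            tdgs, ranked
        ).to_dict("records"),
        "n_kaks_pairs": len(results),
        "ks_peaks": peaks.to_dict("records"),
        "n_significant_terms": int(enrich["significant"].sum()) if len(enrich) else 0,
        "class_summary": class_summary.to_dict("records"),
        "recovery": recovery_summary(out, clusters),
        "parameters": dataclasses.asdict(config),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    config.to_json(out / "run_config.json")
    return report
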