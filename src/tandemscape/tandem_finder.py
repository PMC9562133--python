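"""Tandem duplicated gene (TDG) detection from gene order plus homology.

A tandem pair is a homologous gene pair sitting within ``max_gap`` ordinal
positions (ranks) of each other on the same chromosome; a tandem cluster
is a connected component of the tandem-pair graph.  Homology comes from an
all-vs-all protein search table (BLAST outfmt 6) filtered at E < 1e-10,
top 10 matches per query, matching the common MCScanX-style workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import pandas as pd

from .molevo import round_half_up

HOMOLOGY_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene: 1-based inclusive coordinates plus chromosome-local rank."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class TandemCluster:
    """Maximal chained set of tandem duplicates on one chromosome."""

    chromosome: str
    members: tuple[str, ...]  # ordered by rank

    @property
    def size(self) -> int:
        return len(self.members)


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def read_homology_table(path) -> pd.DataFrame:
    """Read a 12-column BLAST outfmt-6 TSV; errors carry the line number."""
    try:
        df = pd.read_csv(
            path, sep="\t", names=HOMOLOGY_COLUMNS, header=None, comment="#",
            dtype={"qseqid": str, "sseqid": str},
        )
    except Exception as exc:  # pragma: no cover - pandas error paths
        raise DataError(f"cannot parse homology table {path}: {exc}") from exc
    bad = df["evalue"].isna() | df["bitscore"].isna()
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise DataError(f"malformed homology row at line {line} of {path}")
    return df


def filter_hits(
    hits: pd.DataFrame, evalue_max: float = 1e-10, top_n: int = 10
) -> pd.DataFrame:
    """Apply the E-value cutoff and per-query best-N rule, then close symmetrically.

    Self-hits are dropped; E-values must be strictly below ``evalue_max``
    (an "E < 1e-10" search setting).  Per query the ``top_n`` best distinct
    subjects are kept, ranked by bitscore, ties broken by E-value then
    subject id, reproducing a -max_target_seqs-style cap deterministically.
    A pair survives if either direction survives; the result contains one
    row per surviving unordered pair with both orientations materialised.
    """
    df = hits.loc[hits["qseqid"] != hits["sseqid"]]
    df = df.loc[df["evalue"] < evalue_max]
    if df.empty:
        return df.reindex(columns=hits.columns)
    # best HSP per (query, subject), then best top_n subjects per query
    df = df.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    df = df.drop_duplicates(["qseqid", "sseqid"], keep="first")
    df = df.groupby("qseqid", sort=False).head(top_n)
    mirrored = df.rename(columns={"qseqid": "sseqid", "sseqid": "qseqid"})
    out = pd.concat([df, mirrored], ignore_index=True)
    out = out.sort_values(
        ["qseqid", "sseqid", "bitscore"], ascending=[True, True, False], kind="mergesort"
    )
    return out.drop_duplicates(["qseqid", "sseqid"], keep="first").reset_index(drop=True)


def homologous_pairs(filtered: pd.DataFrame) -> set[frozenset]:
    """Unordered homologous pairs surviving `filter_hits`."""
    return {
        frozenset((q, s))
        for q, s in zip(filtered["qseqid"], filtered["sseqid"])
        if q != s
    }


def assign_ranks(genes: list[GeneModel]) -> list[GeneModel]:
    """Set each gene's rank to its index in start-sorted order per chromosome.

    Ties in start are broken by end then gene id so ranks are deterministic.
    """
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise DataError(f"duplicate gene id {g.gene_id!r}")
        seen.add(g.gene_id)
    ranked: list[GeneModel] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        ranked.extend(
            replace(g, rank=i) for i, g in enumerate(chrom_genes)
        )
    return ranked


def find_tandem_pairs(
    genes: list[GeneModel],
    filtered_hits: pd.DataFrame,
    max_gap: int = 1,
) -> list[tuple[str, str]]:
    """Homologous pairs on one chromosome within ``max_gap`` ranks.

    Each unordered pair is emitted once, members ordered by rank.
    """
    index = {g.gene_id: g for g in genes}
    if any(g.rank is None for g in index.values()):
        raise DataError("ranks not assigned; call assign_ranks first")
    pairs = []
    for pair in homologous_pairs(filtered_hits):
        a, b = sorted(pair)
        if a not in index or b not in index:
            missing = a if a not in index else b
            raise DataError(f"homology hit references unknown gene {missing!r}")
        ga, gb = index[a], index[b]
        if ga.chromosome != gb.chromosome:
            continue
        if abs(ga.rank - gb.rank) <= max_gap:
            pairs.append((a, b) if ga.rank < gb.rank else (b, a))
    return sorted(pairs)


def build_clusters(
    tandem_pairs: list[tuple[str, str]], genes: list[GeneModel]
) -> list[TandemCluster]:
    """Connected components of the tandem-pair graph, members rank-sorted.

    Cluster order (and hence cluster ids downstream) is deterministic:
    by chromosome, then first member's rank.
    """
    index = {g.gene_id: g for g in genes}
    graph = nx.Graph()
    graph.add_edges_from(tandem_pairs)
    clusters = []
    for component in nx.connected_components(graph):
        members = sorted(component, key=lambda gid: index[gid].rank)
        clusters.append(
            TandemCluster(chromosome=index[members[0]].chromosome, members=tuple(members))
        )
    clusters.sort(key=lambda c: (c.chromosome, index[c.members[0]].rank))
    return clusters


def tdg_genes(clusters: list[TandemCluster]) -> set[str]:
    return {gid for c in clusters for gid in c.members}


def chromosome_distribution(
    tdgs: set[str], genes: list[GeneModel]
) -> pd.DataFrame:
    """Per-chromosome TDG counts and percentages of the total TDG set.

    Percentages are 100·count/total rounded half-up to 2 decimals, so e.g.
    428 of 2,542 TDGs on one chromosome reports as 16.84%.  An empty TDG
    set yields an empty table.
    """
    if not tdgs:
        return pd.DataFrame(columns=["chromosome", "n_tdgs", "pct_of_tdgs"])
    index = {g.gene_id: g for g in genes}
    counts: dict[str, int] = {}
    for gid in tdgs:
        counts[index[gid].chromosome] = counts.get(index[gid].chromosome, 0) + 1
    total = sum(counts.values())
    rows = [
        {
            "chromosome": chrom,
            "n_tdgs": n,
            "pct_of_tdgs": round_half_up(100.0 * n / total, 2),
        }
        for chrom, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def tdg_fraction(tdgs: set[str], genes: list[GeneModel]) -> float:
    """TDGs as a percentage of the annotated gene set, 2 decimals."""
    if not genes:
        raise DataError("annotation is empty")
    return round_half_up(100.0 * len(tdgs) / len(genes), 2)


def cluster_size_table(clusters: list[TandemCluster]) -> pd.DataFrame:
    """Counts of clusters by size (the shape of a cluster-size report table)."""
    sizes: dict[int, int] = {}
    for c in clusters:
        sizes[c.size] = sizes.get(c.size, 0) + 1
    return pd.DataFrame(
        [{"cluster_size": s, "n_clusters": n} for s, n in sorted(sizes.items())]
    )


def detect(
    genes: list[GeneModel],
    hits: pd.DataFrame,
    evalue_max: float = 1e-10,
    top_n: int = 10,
    max_gap: int = 1,
) -> tuple[list[TandemCluster], list[tuple[str, str]]]:
    """Full detection pass: filter hits, rank genes, pair, cluster."""
    ranked = assign_ranks(genes)
    filtered = filter_hits(hits, evalue_max=evalue_max, top_n=top_n)
    pairs = find_tandem_pairs(ranked, filtered, max_gap=max_gap)
    return build_clusters(pairs, ranked), pairs
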