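"""Over-representation analysis (ORA) with rich factors and set comparison.

For a study set of m genes drawn from a background of N annotated genes,
a term annotating n background genes and k study genes is scored with the
hypergeometric upper tail P[X >= k], X ~ Hypergeom(N, n, m), corrected
across tested terms by Benjamini–Hochberg.  The rich factor k/n is the
effect-size companion to the p-value.  Multi-species comparisons partition
enriched-term sets into shared/unique regions (Venn-style).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TermAssignment:
    term_id: str
    name: str
    namespace: str
    genes: frozenset


@dataclass
class EnrichmentRecord:
    term_id: str
    name: str
    namespace: str
    k: int  # study genes in term
    n: int  # background genes in term
    m: int  # study size
    N: int  # background size
    p: float
    q: float = float("nan")
    rich_factor: float = float("nan")
    significant: bool = False


def read_term_table(path) -> list[TermAssignment]:
    """Read a gene->term TSV (gene_id, term_id, term_name, namespace)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id", "term_name", "namespace"}
    if not required.issubset(df.columns):
        raise ValueError(f"term table {path} missing columns {required - set(df.columns)}")
    out = []
    for (term_id, name, ns), grp in df.groupby(
        ["term_id", "term_name", "namespace"], sort=True
    ):
        out.append(TermAssignment(term_id, name, ns, frozenset(grp["gene_id"])))
    return out


def rich_factor(k: int, n: int) -> float:
    """Study genes in the term over all genes in the term."""
    if n < 1:
        raise ValueError("term size n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    return k / n


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    study: set[str],
    assignments: list[TermAssignment],
    background: set[str],
    q_max: float = 0.05,
) -> list[EnrichmentRecord]:
    """Hypergeometric ORA over every term hit by the study set.

    Terms with k = 0 are not tested (and do not enter the BH denominator).
    Study genes must be drawn from the background; term genes outside the
    background are ignored for counting but flag nothing.
    """
    stray = sorted(study - background)
    if stray:
        raise ValueError(f"study genes absent from background: {stray}")
    m, N = len(study), len(background)
    records = []
    for term in sorted(assignments, key=lambda t: t.term_id):
        term_bg = term.genes & background
        n = len(term_bg)
        k = len(term_bg & study)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, N, n, m))
        records.append(
            EnrichmentRecord(
                term.term_id, term.name, term.namespace,
                k=k, n=n, m=m, N=N, p=min(p, 1.0),
                rich_factor=rich_factor(k, n),
            )
        )
    qs = bh_adjust([r.p for r in records])
    for r, q in zip(records, qs):
        r.q = float(q)
        r.significant = r.q <= q_max
    return records


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        return pd.DataFrame(columns=[
            "term_id", "name", "namespace", "k", "n", "m", "N",
            "p", "q", "rich_factor", "significant",
        ])
    return df.sort_values(["q", "p", "term_id"], kind="mergesort").reset_index(drop=True)


def set_comparison(named_sets: dict[str, set]) -> dict[frozenset, set]:
    """Partition the union of named sets into Venn regions.

    Every element lands in exactly one region keyed by the frozenset of
    set names containing it; region sizes therefore sum to the union size.
    """
    if len(named_sets) < 2:
        raise ValueError("set comparison needs at least two named sets")
    regions: dict[frozenset, set] = {}
    for element in set().union(*named_sets.values()):
        key = frozenset(name for name, s in named_sets.items() if element in s)
        regions.setdefault(key, set()).add(element)
    return regions


def region_size_table(regions: dict[frozenset, set]) -> pd.DataFrame:
    rows = [
        {"region": "&".join(sorted(key)), "n_terms": len(terms)}
        for key, terms in regions.items()
    ]
    rows.sort(key=lambda r: r["region"])
    return pd.DataFrame(rows, columns=["region", "n_terms"])
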