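"""Salt-stress expression response: FPKM, up-regulation calls, tissue classes.

The design is a two-tissue (leaf, root) time course: treatment vs control
contrasts at several timepoints with replicated libraries.  A gene is
called up-regulated in a contrast when FDR <= 0.05 and log2FC >= 1
(one-sided: up only).  Counting up events per tissue across timepoints
classifies genes as tissue-specifically expressed (>= 4 events in one
tissue, <= 1 in the other), co-expressed (>= 7 events across both), or
unclassified.  With five timepoints per tissue ">= 7 in both" can only be
read as a total across tissues, which is the rule implemented.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust

LABELS = ("leaf_specific", "root_specific", "co_expressed", "unclassified")

DE_COLUMNS = ["gene_id", "tissue", "timepoint", "log2fc", "pvalue", "fdr"]


def fpkm(
    counts: pd.DataFrame,
    gene_lengths_bp: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM[g, s] = counts[g, s] * 1e9 / (library_size[s] * length[g]).
    Library sizes default to column sums of the count matrix.
    """
    lengths = gene_lengths_bp.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    else:
        library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.mul(1e9).div(library_sizes, axis=1).div(lengths, axis=0)


def simple_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Stand-in differential-expression test for treatment-vs-control contrasts.

    Per (tissue, timepoint): counts are CPM-normalised, the log2 fold
    change is computed from mean normalised counts with a pseudo-count,
    and the p-value is a Welch t-test on log2 CPM across replicates, with
    BH correction across genes within the contrast.  This deliberately
    simple test exists so the classifier can be driven from raw counts; it
    is not a negative-binomial GLM and makes no dispersion shrinkage.
    """
    required = {"sample", "tissue", "timepoint", "condition", "replicate"}
    if not required.issubset(design.columns):
        raise ValueError(f"design is missing columns {required - set(design.columns)}")
    design = design.set_index("sample")
    cpm = counts.div(counts.sum(axis=0), axis=1) * 1e6
    rows = []
    for (tissue, timepoint), grp in design.groupby(["tissue", "timepoint"], sort=True):
        treated = grp.index[grp["condition"] == "treatment"]
        control = grp.index[grp["condition"] == "control"]
        if len(treated) < 2 or len(control) < 2:
            raise ValueError(
                f"contrast {tissue}/{timepoint} needs >= 2 replicates per condition"
            )
        mean_t = cpm[treated].mean(axis=1)
        mean_c = cpm[control].mean(axis=1)
        log2fc = np.log2((mean_t + pseudo_count) / (mean_c + pseudo_count))
        log_t = np.log2(cpm[treated] + pseudo_count)
        log_c = np.log2(cpm[control] + pseudo_count)
        p = stats.ttest_ind(log_t, log_c, axis=1, equal_var=False).pvalue
        p = np.nan_to_num(p, nan=1.0)  # zero-variance identical groups
        fdr = bh_adjust(p)
        rows.append(pd.DataFrame({
            "gene_id": counts.index,
            "tissue": tissue,
            "timepoint": timepoint,
            "log2fc": log2fc.to_numpy(),
            "pvalue": p,
            "fdr": fdr,
        }))
    return pd.concat(rows, ignore_index=True)


def call_up(
    de: pd.DataFrame, fdr_max: float = 0.05, lfc_min: float = 1.0
) -> pd.DataFrame:
    """Boolean up-regulation call per row: fdr <= fdr_max and log2fc >= lfc_min."""
    out = de.copy()
    out["up"] = (out["fdr"] <= fdr_max) & (out["log2fc"] >= lfc_min)
    return out


def count_up_events(calls: pd.DataFrame) -> pd.DataFrame:
    """Up-event counts per (gene, tissue); duplicated contrasts are an error."""
    dup = calls.duplicated(["gene_id", "tissue", "timepoint"])
    if dup.any():
        row = calls.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate contrast for gene {row['gene_id']} "
            f"({row['tissue']}, {row['timepoint']})"
        )
    counts = (
        calls.groupby(["gene_id", "tissue"], sort=True)["up"].sum().unstack(fill_value=0)
    )
    return counts.astype(int)


def classify(
    leaf_count: int,
    root_count: int,
    spec_min: int = 4,
    other_max: int = 1,
    co_min: int = 7,
) -> str:
    """Tissue-specificity label from per-tissue up-event counts.

    Specificity (>= spec_min in one tissue, <= other_max in the other) is
    checked before co-expression (total >= co_min across both tissues).
    """
    if leaf_count < 0 or root_count < 0:
        raise ValueError("event counts cannot be negative")
    if leaf_count >= spec_min and root_count <= other_max:
        return "leaf_specific"
    if root_count >= spec_min and leaf_count <= other_max:
        return "root_specific"
    if leaf_count + root_count >= co_min:
        return "co_expressed"
    return "unclassified"


def classify_genes(
    up_counts: pd.DataFrame,
    tissues: tuple[str, str] = ("leaf", "root"),
    spec_min: int = 4,
    other_max: int = 1,
    co_min: int = 7,
) -> pd.DataFrame:
    """Apply `classify` to an up-event count table (genes × tissues)."""
    first, second = tissues
    for t in tissues:
        if t not in up_counts.columns:
            up_counts = up_counts.assign(**{t: 0})
    labels = [
        classify(l, r, spec_min, other_max, co_min)
        for l, r in zip(up_counts[first], up_counts[second])
    ]
    return pd.DataFrame(
        {
            "gene_id": up_counts.index,
            f"up_{first}": up_counts[first].to_numpy(),
            f"up_{second}": up_counts[second].to_numpy(),
            "label": labels,
        }
    ).reset_index(drop=True)


def summarize_classes(
    labels: pd.DataFrame, tdg_set: set[str] | None = None
) -> pd.DataFrame:
    """Per-class counts (optionally restricted to TDGs) plus the responsive total."""
    df = labels
    if tdg_set is not None:
        df = df[df["gene_id"].isin(tdg_set)]
    counts = {label: int((df["label"] == label).sum()) for label in LABELS}
    responsive = sum(counts[l] for l in LABELS if l != "unclassified")
    rows = [{"class": l, "n_genes": counts[l]} for l in LABELS]
    rows.append({"class": "total_responsive", "n_genes": responsive})
    return pd.DataFrame(rows)
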