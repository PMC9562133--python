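"""Reading and writing the pipeline's on-disk formats.

Everything is plain text so any stage can be driven by real external
outputs (a genuine GFF3 annotation, a genuine BLAST table) in place of the
simulator's files: GFF3 for gene models, FASTA for CDS/proteins, 12-column
outfmt-6 TSV for homology, TSV with headers for counts/design/DE tables,
JSON for the truth manifest.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tandem_finder import GeneModel


def write_gff3(genes: list[GeneModel], path) -> None:
    """Minimal gene-only GFF3 (1-based inclusive, ID attribute)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            fh.write(
                f"{g.chromosome}\ttandemscape\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_gff3(path) -> list[GeneModel]:
    """Load gene features from GFF3 via gffutils (in-memory db)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
            )
        )
    return genes


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def read_counts(path) -> pd.DataFrame:
    """Count matrix TSV: first column gene_id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").reset_index().to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
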