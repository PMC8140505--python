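"""Readers and writers for the plain-text formats the package exchanges.

FASTA goes through Biopython; tables are plain TSV via pandas. Study
abundance tables are samples-as-rows, taxa-as-columns, fractions not
percents, with the sample id in the first column.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import ProteinCatalog
from .genome import AssemblyQC, GenomeAssembly
from .prevalence import StudyTable


def read_fasta(path) -> list[tuple[str, str]]:
    """Multi-FASTA -> list of (id, sequence)."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_genome(path, name: str | None = None) -> GenomeAssembly:
    records = read_fasta(path)
    if not records:
        raise ValueError(f"{path}: no sequences")
    return GenomeAssembly(
        name=name or Path(str(path)).stem, contigs=[seq for _, seq in records]
    )


def write_genome(genome: GenomeAssembly, path) -> None:
    write_fasta(
        ((f"{genome.name}_contig{i}", c) for i, c in enumerate(genome.contigs)),
        path,
    )


def read_study_table(path, study_id: str, read_counts_path=None) -> StudyTable:
    """TSV abundance table (first column = sample id) -> StudyTable.

    ``read_counts_path`` optionally points to a two-column TSV
    (sample, reads)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = None
    if read_counts_path is not None:
        counts = pd.read_csv(
            read_counts_path, sep="\t", index_col=0
        ).iloc[:, 0].reindex(df.index)
    return StudyTable(study_id=study_id, abundances=df, read_counts=counts)


def write_study_table(table: StudyTable, path) -> None:
    table.abundances.rename_axis("sample").to_csv(path, sep="\t")


def write_qc_table(qcs: list[AssemblyQC], path) -> None:
    """Assembly QC TSV: name, n_contigs, N50, completeness, contamination,
    quality_score."""
    pd.DataFrame(
        [
            {
                "name": q.name,
                "n_contigs": q.n_contigs,
                "n50": q.n50,
                "completeness": q.completeness,
                "contamination": q.contamination,
                "quality_score": q.quality_score,
            }
            for q in qcs
        ]
    ).to_csv(path, sep="\t", index=False)


def write_catalog(catalog: ProteinCatalog, fasta_path, cluster_tsv_path=None) -> None:
    write_fasta(catalog.entries, fasta_path)
    if cluster_tsv_path is not None:
        pd.DataFrame(
            [
                {"member": m, "representative": r}
                for m, r in sorted(catalog.cluster_map.items())
            ]
        ).to_csv(cluster_tsv_path, sep="\t", index=False)
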