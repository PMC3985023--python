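"""Annotated gene collections: data model, I/O and the gene-fragment filter.

Single amplified genomes are riddled with truncated open reading frames, so a
reliability filter removes genes shorter than 300 nucleotides or not
annotated as complete before any descriptor evidence is trusted.  The
annotation table is a plain TSV (one row per gene) optionally joined with a
protein FASTA for scan-mode pattern matching; a minimal GFF3 reader extracts
IDs, lengths and the ``partial`` attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GeneRecord",
    "GeneCollection",
    "MIN_NT_LENGTH",
    "load_collection",
    "load_gff3",
    "gene_fragment_filter",
]

log = logging.getLogger(__name__)

#: Minimal nucleotide length for a gene to be considered functional.
MIN_NT_LENGTH = 300

REQUIRED_COLUMNS = (
    "gene_id",
    "genome_id",
    "taxon",
    "nt_length",
    "complete",
    "product",
    "go_terms",
    "prosite_ids",
)

_TRUE_TOKENS = {"true", "1", "yes", "y", "complete"}


@dataclass
class GeneRecord:
    """One annotated gene.

    At least one of ``nt_length`` / ``aa_length`` / ``protein_seq`` must be
    present; when only protein information exists the nucleotide length is
    derived as ``3 × aa_length + 3`` (codons plus stop).  An absent
    completeness annotation counts as incomplete — the conservative reading.
    """

    gene_id: str
    genome_id: str = ""
    taxon: str = ""
    nt_length: Optional[int] = None
    aa_length: Optional[int] = None
    complete: bool = False
    product: str = ""
    go_terms: frozenset[str] = frozenset()
    prosite_ids: frozenset[str] = frozenset()
    protein_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.protein_seq is not None:
            if self.aa_length is None:
                self.aa_length = len(self.protein_seq)
            elif self.aa_length != len(self.protein_seq):
                raise ValueError(
                    f"{self.gene_id}: aa_length {self.aa_length} != "
                    f"sequence length {len(self.protein_seq)}"
                )
        if self.nt_length is None and self.aa_length is None:
            raise ValueError(
                f"{self.gene_id}: need nt_length, aa_length or protein_seq"
            )
        self.go_terms = frozenset(self.go_terms)
        self.prosite_ids = frozenset(self.prosite_ids)

    @property
    def resolved_nt_length(self) -> int:
        if self.nt_length is not None:
            return self.nt_length
        return 3 * self.aa_length + 3  # type: ignore[operator]


class GeneCollection:
    """Ordered, id-unique list of gene records with provenance metadata."""

    def __init__(
        self, genes: Iterable[GeneRecord], provenance: Optional[dict] = None
    ) -> None:
        self.genes: list[GeneRecord] = list(genes)
        self._index: dict[str, GeneRecord] = {}
        for g in self.genes:
            if g.gene_id in self._index:
                raise ValueError(f"duplicate gene_id: {g.gene_id}")
            self._index[g.gene_id] = g
        self.provenance: dict = provenance or {}

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def get(self, gene_id: str) -> GeneRecord:
        return self._index[gene_id]

    def ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def subset(self, gene_ids: Sequence[str]) -> "GeneCollection":
        wanted = set(gene_ids)
        return GeneCollection(
            (g for g in self.genes if g.gene_id in wanted),
            provenance=dict(self.provenance),
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g.gene_id,
                "genome_id": g.genome_id,
                "taxon": g.taxon,
                "nt_length": g.nt_length if g.nt_length is not None else "",
                "complete": str(g.complete).lower(),
                "product": g.product,
                "go_terms": ";".join(sorted(g.go_terms)),
                "prosite_ids": ";".join(sorted(g.prosite_ids)),
            }
            for g in self.genes
        ]
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _split_cell(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(p.strip() for p in text.split(";") if p.strip())


def _parse_bool(cell) -> bool:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return False
    return str(cell).strip().lower() in _TRUE_TOKENS


def load_collection(
    annotation_table: str | Path, fasta: Optional[str | Path] = None
) -> GeneCollection:
    """Build a collection from an annotation TSV, optionally joined to FASTA.

    Multi-valued descriptor cells are split on ``;`` and de-duplicated.
    Genes present only in the FASTA are appended with empty descriptor sets.
    Duplicate gene ids and missing mandatory columns are errors.
    """
    df = pd.read_csv(annotation_table, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing column(s): {missing}")

    sequences: dict[str, str] = {}
    if fasta is not None:
        sequences = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }

    genes: list[GeneRecord] = []
    for row in df.itertuples(index=False):
        nt = str(row.nt_length).strip()
        genes.append(
            GeneRecord(
                gene_id=row.gene_id,
                genome_id=row.genome_id,
                taxon=row.taxon,
                nt_length=int(nt) if nt else None,
                complete=_parse_bool(row.complete),
                product=row.product,
                go_terms=_split_cell(row.go_terms),
                prosite_ids=_split_cell(row.prosite_ids),
                protein_seq=sequences.get(row.gene_id),
            )
        )
    table_ids = {g.gene_id for g in genes}
    for gene_id, seq in sequences.items():
        if gene_id not in table_ids:
            genes.append(GeneRecord(gene_id=gene_id, protein_seq=seq))

    provenance = {
        "annotation_table": str(annotation_table),
        "fasta": str(fasta) if fasta else None,
        "n_genes": len(genes),
    }
    return GeneCollection(genes, provenance)


def load_gff3(path: str | Path) -> GeneCollection:
    """Minimal GFF3 ingestion: ID, feature length and ``partial`` → complete.

    Only gene/CDS features carrying an ``ID`` attribute are read; a feature
    is complete iff it has no truthy ``partial`` attribute.
    """
    genes: list[GeneRecord] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {line[:60]!r}")
        ftype = cols[2].lower()
        if ftype not in ("gene", "cds"):
            continue
        attrs = dict(
            kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
        )
        if "ID" not in attrs:
            continue
        start, end = int(cols[3]), int(cols[4])
        partial = attrs.get("partial", "").lower() in ("1", "true", "yes", "10", "01", "11")
        genes.append(
            GeneRecord(
                gene_id=attrs["ID"],
                genome_id=cols[0],
                nt_length=end - start + 1,
                complete=not partial,
                product=attrs.get("product", ""),
            )
        )
    return GeneCollection(genes, {"gff3": str(path), "n_genes": len(genes)})


def gene_fragment_filter(
    collection: GeneCollection, min_nt: int = MIN_NT_LENGTH
) -> GeneCollection:
    """Remove unreliable gene fragments.

    Keeps genes with a resolved nucleotide length of at least *min_nt* AND an
    explicit complete annotation; input order is preserved.  Removal counts
    per reason are logged and recorded in the output provenance.  The filter
    is idempotent and commutes with descriptor filtering.
    """
    kept: list[GeneRecord] = []
    removed_short = removed_incomplete = 0
    for g in collection:
        if g.resolved_nt_length < min_nt:
            removed_short += 1
        elif not g.complete:
            removed_incomplete += 1
        else:
            kept.append(g)
    log.info(
        "gene fragment filter: kept %d, removed %d short (<%d nt), %d incomplete",
        len(kept),
        removed_short,
        min_nt,
        removed_incomplete,
    )
    provenance = dict(collection.provenance)
    provenance["fragment_filter"] = {
        "min_nt": min_nt,
        "kept": len(kept),
        "removed_short": removed_short,
        "removed_incomplete": removed_incomplete,
    }
    return GeneCollection(kept, provenance)
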