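"""Readers and writers for the pipeline's standard input formats.

Genome annotations arrive as GFF3 (CDS features, 1-based inclusive
coordinates), profile-HMM evidence as HMMER3 per-domain tabular output
("domtblout", as written by ``hmmscan --domtblout``), and taxonomy /
count-table inputs as plain TSV.  Everything is validated into a small
data model (:class:`Gene`, :class:`GenomeAnnotation`, :class:`DomainHit`,
:class:`SpeciesMap`) that the downstream neighborhood analysis consumes.

Gene order on a contig is defined by start coordinate (ties broken by end,
then gene id), irrespective of strand; the resulting rank is stored as the
gene's ``ordinal`` and is the distance unit of the neighborhood rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SearchIO
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed input violates a data-model invariant."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene with 1-based inclusive coordinates."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    ordinal: int
    protein_id: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: invalid strand {self.strand!r}")


@dataclass
class GenomeAnnotation:
    """All genes of one genome, grouped by contig and sorted by ordinal."""

    genome_id: str
    genes_by_contig: dict[str, list[Gene]] = field(default_factory=dict)

    @classmethod
    def from_records(cls, genome_id: str, records: Iterable[dict]) -> "GenomeAnnotation":
        """Build an annotation from unordered gene records, assigning ordinals.

        Each record is a mapping with keys gene_id, contig_id, start, end,
        strand and (optionally) protein_id; ordinals are assigned per contig
        by sorting on (start, end, gene_id).
        """
        by_contig: dict[str, list[dict]] = {}
        for rec in records:
            by_contig.setdefault(rec["contig_id"], []).append(rec)
        genes_by_contig: dict[str, list[Gene]] = {}
        for contig_id, recs in sorted(by_contig.items()):
            recs.sort(key=lambda r: (r["start"], r["end"], r["gene_id"]))
            seen: set[tuple] = set()
            genes = []
            for ordinal, rec in enumerate(recs):
                key = (rec["start"], rec["end"], rec["gene_id"])
                if key in seen:
                    raise ValidationError(
                        f"{genome_id}/{contig_id}: duplicate gene {key}"
                    )
                seen.add(key)
                genes.append(
                    Gene(
                        gene_id=rec["gene_id"],
                        genome_id=genome_id,
                        contig_id=contig_id,
                        start=int(rec["start"]),
                        end=int(rec["end"]),
                        strand=rec["strand"],
                        ordinal=ordinal,
                        protein_id=rec.get("protein_id") or rec["gene_id"],
                    )
                )
            genes_by_contig[contig_id] = genes
        return cls(genome_id=genome_id, genes_by_contig=genes_by_contig)

    def iter_genes(self) -> Iterable[Gene]:
        for genes in self.genes_by_contig.values():
            yield from genes

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.genes_by_contig.values())


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM hit row (full-sequence e-value and bit score)."""

    protein_id: str
    profile_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"hit {self.protein_id}/{self.profile_id}: e-value < 0")


@dataclass
class SpeciesMap:
    """Genome -> (species, lineage) lookup; each genome maps to one species."""

    mapping: dict[str, tuple[str, tuple[str, ...]]]

    def species_of(self, genome_id: str) -> str:
        return self.mapping[genome_id][0]

    def lineage_of(self, genome_id: str) -> tuple[str, ...]:
        return self.mapping[genome_id][1]

    def species_ids(self) -> list[str]:
        return sorted({sp for sp, _ in self.mapping.values()})

    def genomes_of(self, species_id: str) -> list[str]:
        return sorted(g for g, (sp, _) in self.mapping.items() if sp == species_id)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(
    path: str | Path,
    feature_types: Sequence[str] = ("CDS",),
    default_genome_id: str | None = None,
) -> list[GenomeAnnotation]:
    """Read CDS features from a GFF3 file into genome annotations.

    The genome a feature belongs to is taken from a ``genome_id`` attribute
    when present, otherwise from *default_genome_id* (defaulting to the file
    stem), so one file may hold one or many genomes.  Coordinates stay
    1-based inclusive.  Ordinals are assigned per contig by the
    sort-by-start rule and are therefore independent of line order.
    """
    path = Path(path)
    if default_genome_id is None:
        default_genome_id = path.stem
    records: dict[str, list[dict]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            if len(line.split("\t")) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted exceptions
                raise ParseError(f"{path}:{lineno}: malformed GFF3 line ({exc})") from exc
            if feat.featuretype not in feature_types:
                continue
            if feat.end < feat.start:
                raise ValidationError(f"{path}:{lineno}: end < start")
            attrs = feat.attributes
            gene_id = (attrs.get("ID") or attrs.get("locus_tag") or [None])[0]
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: feature lacks ID/locus_tag attribute")
            genome_id = (attrs.get("genome_id") or [default_genome_id])[0]
            protein_id = (attrs.get("protein_id") or [gene_id])[0]
            records.setdefault(genome_id, []).append(
                dict(
                    gene_id=gene_id,
                    contig_id=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in ("+", "-") else "+",
                    protein_id=protein_id,
                )
            )
    return [
        GenomeAnnotation.from_records(genome_id, recs)
        for genome_id, recs in sorted(records.items())
    ]


def write_gff3(annotations: Iterable[GenomeAnnotation], path: str | Path) -> None:
    """Write annotations as GFF3 CDS features (round-trips with read_gff3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            for gene in ann.iter_genes():
                attrs = (
                    f"ID={gene.gene_id};protein_id={gene.protein_id};"
                    f"genome_id={gene.genome_id}"
                )
                fh.write(
                    "\t".join(
                        [
                            gene.contig_id,
                            "hdcminer",
                            "CDS",
                            str(gene.start),
                            str(gene.end),
                            ".",
                            gene.strand,
                            "0",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# HMMER3 domtblout
# ---------------------------------------------------------------------------

def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Read hmmscan per-domain tabular output into domain hits.

    One :class:`DomainHit` is produced per domain row, carrying the
    full-sequence e-value (hmmscan's headline e-value) of its target
    profile; multiple rows per protein are retained.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    try:
        for qresult in SearchIO.parse(str(path), "hmmscan3-domtab"):
            for hit in qresult.hits:
                n_rows = max(1, len(hit.hsps))
                for _ in range(n_rows):
                    hits.append(
                        DomainHit(
                            protein_id=qresult.id,
                            profile_id=hit.id,
                            evalue=float(hit.evalue),
                            bitscore=float(hit.bitscore),
                        )
                    )
    except ValueError as exc:
        raise ParseError(f"{path}: malformed domtblout ({exc})") from exc
    return hits


def write_domtblout(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the hmmscan --domtblout dialect (23 columns + comments)."""
    header = (
        "#                                                                            "
        "--- full sequence --- -------------- this domain -------------   hmm coord   "
        "ali coord   env coord\n"
        "# target name        accession   tlen query name           accession   qlen   "
        "E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  "
        "from    to  from    to  acc description of target\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for h in hits:
            fields = [
                h.profile_id,
                "-",
                "300",
                h.protein_id,
                "-",
                "310",
                f"{h.evalue:.6g}",
                f"{h.bitscore:.1f}",
                "0.1",
                "1",
                "1",
                f"{h.evalue:.6g}",
                f"{h.evalue:.6g}",
                f"{h.bitscore:.1f}",
                "0.1",
                "1",
                "300",
                "1",
                "300",
                "1",
                "300",
                "0.98",
                "-",
            ]
            fh.write(" ".join(fields) + "\n")
        fh.write("#\n")


# ---------------------------------------------------------------------------
# TSV inputs
# ---------------------------------------------------------------------------

def read_species_map(path: str | Path) -> SpeciesMap:
    """Read a genome->species TSV (columns genome_id, species_id, lineage)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "species_id"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: species map needs columns {sorted(required)}")
    mapping: dict[str, tuple[str, tuple[str, ...]]] = {}
    for row in df.itertuples(index=False):
        lineage_raw = getattr(row, "lineage", "") or ""
        if isinstance(lineage_raw, float):  # NaN
            lineage_raw = ""
        lineage = tuple(t for t in str(lineage_raw).split(";") if t)
        entry = (row.species_id, lineage)
        previous = mapping.get(row.genome_id)
        if previous is not None and previous[0] != row.species_id:
            raise ValidationError(
                f"{path}: genome {row.genome_id} mapped to both "
                f"{previous[0]} and {row.species_id}"
            )
        mapping[row.genome_id] = entry
    return SpeciesMap(mapping=mapping)


def write_species_map(species_map: SpeciesMap, path: str | Path) -> None:
    rows = [
        {"genome_id": g, "species_id": sp, "lineage": ";".join(lin)}
        for g, (sp, lin) in sorted(species_map.mapping.items())
    ]
    pd.DataFrame(rows, columns=["genome_id", "species_id", "lineage"]).to_csv(
        path, sep="\t", index=False
    )


def read_count_table(counts_path: str | Path, meta_path: str | Path):
    """Read a species x sample count TSV plus sample metadata TSV.

    The counts file has species ids in the first column and one column per
    sample; the metadata file has columns sample_id, study, condition.
    Returns an :class:`hdcminer.enrichment.CountTable`.
    """
    from hdcminer.enrichment import CountTable  # local import avoids a cycle

    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample_id")
    return CountTable(counts=counts, sample_meta=meta)


def read_da_table(path: str | Path) -> list:
    """Read differential-abundance results (species_id, method, effect, qvalue, direction)."""
    from hdcminer.enrichment import DAResult

    df = pd.read_csv(path, sep="\t")
    return [
        DAResult(
            species_id=str(r.species_id),
            method=str(r.method),
            effect=float(r.effect),
            qvalue=float(r.qvalue),
            direction=str(r.direction),
        )
        for r in df.itertuples(index=False)
    ]


def read_operon_counts(path: str | Path) -> list:
    """Read per-sample operon/total mapped-read counts."""
    from hdcminer.operon_abundance import OperonReadCounts

    df = pd.read_csv(path, sep="\t")
    return [
        OperonReadCounts(
            sample_id=str(r.sample_id),
            condition=str(r.condition),
            reads_on_operon=int(r.reads_on_operon),
            total_mapped=int(r.total_mapped),
        )
        for r in df.itertuples(index=False)
    ]
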