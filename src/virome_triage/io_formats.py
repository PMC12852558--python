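"""Readers and writers for the external file formats the pipeline touches.

Sequences arrive as FASTA, similarity hits as 12-column BLAST/DIAMOND
tabular text (outfmt-6 column order), quantification as Salmon-style
``quant.sf`` tables, and the small annotation tables (viral-subject
flags, conserved-domain calls, library metadata) as headered TSV.

Conventions applied at the boundary:

* residues are uppercased and RNA ``U`` is normalised to ``T`` on
  ingest, so downstream codon/k-mer arithmetic runs on a DNA alphabet;
* a FASTA record id is the header token up to the first whitespace and
  the full header is retained as the description;
* all coordinates internal to the package are 0-based half-open on the
  forward strand; BLAST tabular coordinates stay 1-based inclusive as
  read and are converted where consumed.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "NucleotideSequence",
    "TabularHit",
    "ViralSubjectSet",
    "DomainAnnotation",
    "QuantRow",
    "LibraryMetadata",
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "read_quant_table",
    "read_viral_flags",
    "read_domain_annotations",
    "read_library_metadata",
]

#: IUPAC nucleotide one-letter codes (after U->T normalisation).
IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")

BLAST_TAB_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class NucleotideSequence:
    """An identified contig or coding sequence.

    ``residues`` is stored uppercase with ``U`` normalised to ``T`` and
    may contain IUPAC ambiguity codes.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        self.residues = self.residues.upper().replace("U", "T")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} has an empty body")
        bad = set(self.residues) - IUPAC_NUCLEOTIDES
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-IUPAC symbols: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TabularHit:
    """One row of 12-column BLAST/DIAMOND tabular output."""

    qseqid: str
    sseqid: str
    pident: float
    aln_length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise FormatError(f"pident {self.pident} outside [0, 100]")
        if self.evalue < 0:
            raise FormatError(f"negative evalue {self.evalue}")
        if self.qstart < 1 or self.qend < 1:
            raise FormatError("query coordinates must be >= 1 (1-based inclusive)")


@dataclass
class ViralSubjectSet:
    """Subject accessions flagged as viral.

    Stands in for a reference database: membership is an exact string
    match on ``sseqid``.
    """

    members: frozenset[str]

    def __contains__(self, sseqid: str) -> bool:
        return sseqid in self.members


@dataclass(frozen=True)
class DomainAnnotation:
    """A conserved-domain call for one query sequence."""

    qseqid: str
    domain_accession: str
    is_viral_domain: bool


@dataclass
class QuantRow:
    """Per-feature quantification for one library (quant.sf-style)."""

    name: str
    length: int
    num_reads: float
    effective_length: float | None = None
    tpm: float | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise FormatError(f"feature {self.name!r}: length must be >= 1")
        if self.num_reads < 0:
            raise FormatError(f"feature {self.name!r}: num_reads must be >= 0")


@dataclass(frozen=True)
class LibraryMetadata:
    """Grouping information for one sequencing library."""

    library_id: str
    project_id: str
    treatment: str


def _as_text_handle(path_or_text) -> io.StringIO | io.TextIOBase:
    """Accept a filesystem path, a file handle, or raw text."""
    if hasattr(path_or_text, "read"):
        return path_or_text
    text = str(path_or_text)
    if "\n" not in text and os.path.exists(text):
        return open(text)
    return io.StringIO(text)


def read_fasta(path_or_text) -> list[NucleotideSequence]:
    """Parse FASTA into :class:`NucleotideSequence` records.

    Empty input yields an empty list; a header with no sequence body is
    a :class:`FormatError` naming the offending record.
    """
    handle = _as_text_handle(path_or_text)
    records = []
    for rec in SeqIO.parse(handle, "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append(
            NucleotideSequence(
                id=rec.id, residues=str(rec.seq), description=rec.description
            )
        )
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise FormatError(f"duplicate FASTA id {r.id!r}")
        seen.add(r.id)
    return records


def write_fasta(seqs: list[NucleotideSequence], path_or_handle, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=_strip_id(s.description, s.id))
        for s in seqs
    ]
    if hasattr(path_or_handle, "write"):
        SeqIO.write(records, path_or_handle, "fasta")
    else:
        with open(path_or_handle, "w") as fh:
            SeqIO.write(records, fh, "fasta")


def _strip_id(description: str, seq_id: str) -> str:
    # Biopython writes "id description"; avoid doubling the id token.
    if description == seq_id:
        return ""
    if description.startswith(seq_id + " "):
        return description[len(seq_id) + 1 :]
    return description


def read_blast_tab(path_or_text) -> dict[str, list[TabularHit]]:
    """Parse 12-column tabular hits, grouped by query, file order kept.

    Within-query row order is preserved exactly: rank semantics
    downstream (``top 30``, ``top 10``) depend on it.
    """
    handle = _as_text_handle(path_or_text)
    by_query: dict[str, list[TabularHit]] = {}
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise FormatError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            hit = TabularHit(
                qseqid=fields[0],
                sseqid=fields[1],
                pident=float(fields[2]),
                aln_length=int(fields[3]),
                mismatch=int(fields[4]),
                gapopen=int(fields[5]),
                qstart=int(fields[6]),
                qend=int(fields[7]),
                sstart=int(fields[8]),
                send=int(fields[9]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
            )
        except ValueError as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"line {lineno}: {exc}") from exc
        by_query.setdefault(hit.qseqid, []).append(hit)
    return by_query


_QUANT_ALIASES = {
    "name": "name",
    "length": "length",
    "effectivelength": "effective_length",
    "effective_length": "effective_length",
    "tpm": "tpm",
    "numreads": "num_reads",
    "num_reads": "num_reads",
}


def read_quant_table(path_or_text) -> list[QuantRow]:
    """Parse a per-library quantification table.

    Accepts Salmon ``quant.sf`` headers (Name, Length, EffectiveLength,
    TPM, NumReads) or any headered TSV providing at least name, length
    and num_reads; optional columns are left unset when absent.
    """
    handle = _as_text_handle(path_or_text)
    df = pd.read_csv(handle, sep="\t")
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _QUANT_ALIASES:
            rename[col] = _QUANT_ALIASES[key]
    df = df.rename(columns=rename)
    for mandatory in ("name", "length", "num_reads"):
        if mandatory not in df.columns:
            raise FormatError(f"quant table missing mandatory column {mandatory!r}")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            QuantRow(
                name=str(rec.name),
                length=int(rec.length),
                num_reads=float(rec.num_reads),
                effective_length=(
                    float(rec.effective_length)
                    if "effective_length" in df.columns
                    else None
                ),
                tpm=float(rec.tpm) if "tpm" in df.columns else None,
            )
        )
    return rows


def read_viral_flags(path_or_text) -> ViralSubjectSet:
    """Read a headered TSV of (sseqid, is_viral) into a subject set."""
    df = pd.read_csv(_as_text_handle(path_or_text), sep="\t")
    for col in ("sseqid", "is_viral"):
        if col not in df.columns:
            raise FormatError(f"viral-flag table missing column {col!r}")
    flagged = df.loc[df["is_viral"].map(_parse_bool), "sseqid"].astype(str)
    return ViralSubjectSet(members=frozenset(flagged))


def read_domain_annotations(path_or_text) -> list[DomainAnnotation]:
    """Read a headered TSV of (qseqid, domain_accession, is_viral_domain)."""
    df = pd.read_csv(_as_text_handle(path_or_text), sep="\t")
    for col in ("qseqid", "domain_accession", "is_viral_domain"):
        if col not in df.columns:
            raise FormatError(f"domain table missing column {col!r}")
    seen = set()
    out = []
    for rec in df.itertuples(index=False):
        key = (str(rec.qseqid), str(rec.domain_accession))
        if key in seen:
            raise FormatError(f"duplicate domain row for {key}")
        seen.add(key)
        out.append(
            DomainAnnotation(
                qseqid=str(rec.qseqid),
                domain_accession=str(rec.domain_accession),
                is_viral_domain=_parse_bool(rec.is_viral_domain),
            )
        )
    return out


def read_library_metadata(path_or_text) -> dict[str, LibraryMetadata]:
    """Read a headered TSV of (library_id, project_id, treatment)."""
    df = pd.read_csv(_as_text_handle(path_or_text), sep="\t")
    for col in ("library_id", "project_id", "treatment"):
        if col not in df.columns:
            raise FormatError(f"metadata table missing column {col!r}")
    out: dict[str, LibraryMetadata] = {}
    for rec in df.itertuples(index=False):
        lib = str(rec.library_id)
        if lib in out:
            raise FormatError(f"duplicate library_id {lib!r}")
        out[lib] = LibraryMetadata(
            library_id=lib, project_id=str(rec.project_id), treatment=str(rec.treatment)
        )
    return out


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "t"}:
        return True
    if text in {"false", "0", "no", "f"}:
        return False
    raise FormatError(f"cannot interpret {value!r} as a boolean flag")
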