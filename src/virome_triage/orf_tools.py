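"""ORF prediction and translation.

Two prediction modes mirror the two screening styles used in virome
triage:

* ``complete`` — ATG-to-in-frame-stop spans (ORFfinder-like contig
  characterisation). The stop codon is included in the span and counts
  toward the reported length.
* ``region`` — maximal stop-free translated regions between stops
  (getorf-like genome screening); the flanking stops are excluded.

All coordinates are 0-based half-open on the forward strand; minus
strand ORFs carry forward-strand coordinates and the reverse-complement
sequence. The standard genetic code (table 1) is the default; the mold
mitochondrial code (table 4, TGA=Trp) is exposed because capsidless
mitochondria-associated RNA viruses are translated by the organelle.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.Seq import Seq

from virome_triage.io_formats import NucleotideSequence

__all__ = ["OrfRecord", "find_orfs", "translate", "reverse_complement"]

SUPPORTED_CODES = (1, 4)

START_CODON = "ATG"


def _stop_codons(genetic_code: int) -> frozenset[str]:
    if genetic_code not in SUPPORTED_CODES:
        raise ValueError(
            f"unsupported genetic code {genetic_code}; supported: {SUPPORTED_CODES}"
        )
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    return frozenset(table.stop_codons)


def reverse_complement(residues: str) -> str:
    return str(Seq(residues).reverse_complement())


@dataclass(frozen=True)
class OrfRecord:
    """A predicted open reading frame.

    ``start``/``end`` are 0-based half-open forward-strand coordinates
    on the parent sequence; ``nt_sequence`` equals the parent
    subsequence, reverse-complemented when ``strand`` is ``-``.
    """

    parent_id: str
    start: int
    end: int
    strand: str
    has_start_codon: bool
    has_stop_codon: bool
    nt_sequence: str
    genetic_code: int = 1

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        span = self.end - self.start
        if span <= 0 or span % 3 != 0:
            raise ValueError(
                f"ORF span {self.start}..{self.end} is not a positive multiple of 3"
            )
        if len(self.nt_sequence) != span:
            raise ValueError("nt_sequence length does not match coordinates")
        if self.has_start_codon and self.nt_sequence[:3] != START_CODON:
            raise ValueError("has_start_codon set but first codon is not ATG")
        if self.has_stop_codon and self.nt_sequence[-3:] not in _stop_codons(
            self.genetic_code
        ):
            raise ValueError("has_stop_codon set but last codon is not a stop")

    def __len__(self) -> int:
        return self.end - self.start


def translate(nt: str, genetic_code: int = 1, ambiguous: str = "error") -> str:
    """Translate an in-frame nucleotide string; stops become ``*``.

    ``ambiguous`` controls codons containing non-ACGT symbols:
    ``"error"`` (default) raises, ``"X"`` emits an X residue.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} is not divisible by 3")
    if ambiguous not in {"error", "X"}:
        raise ValueError("ambiguous must be 'error' or 'X'")
    stops = _stop_codons(genetic_code)
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    nt = nt.upper().replace("U", "T")
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon in stops:
            out.append("*")
        elif codon in table.forward_table:
            out.append(table.forward_table[codon])
        elif ambiguous == "X":
            out.append("X")
        else:
            raise ValueError(f"ambiguous codon {codon!r} at position {i}")
    return "".join(out)


def find_orfs(
    seq: NucleotideSequence,
    mode: str = "complete",
    min_len: int = 3,
    max_len: int | None = None,
    genetic_code: int = 1,
    strands: str = "both",
    all_starts: bool = False,
) -> list[OrfRecord]:
    """Predict ORFs on a nucleotide sequence.

    Parameters
    ----------
    mode
        ``"complete"`` for ATG-to-stop spans (stop included in length)
        or ``"region"`` for maximal stop-free regions between stops
        (stops excluded).
    min_len, max_len
        Inclusive bounds on ORF length in nucleotides. ``max_len=None``
        means unbounded.
    strands
        ``"both"`` scans all six frames, ``"forward"`` only three.
    all_starts
        In complete mode, report every internal ATG sharing a stop; the
        default reports only the longest ORF per (frame, stop).

    Returns
    -------
    list of :class:`OrfRecord`, sorted by (start, strand, end). ORFs
    whose sequence contains a non-ACGT symbol are excluded.
    """
    if mode not in {"complete", "region"}:
        raise ValueError(f"unknown mode {mode!r}")
    if strands not in {"both", "forward"}:
        raise ValueError(f"unknown strands option {strands!r}")
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    if max_len is not None and max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    stops = _stop_codons(genetic_code)

    residues = seq.residues
    n = len(residues)
    if n < 3:
        return []

    orfs: list[OrfRecord] = []
    strand_seqs = [("+", residues)]
    if strands == "both":
        strand_seqs.append(("-", reverse_complement(residues)))

    for strand, s in strand_seqs:
        for frame in range(3):
            spans = (
                _complete_spans(s, frame, stops, all_starts)
                if mode == "complete"
                else _region_spans(s, frame, stops)
            )
            for lo, hi, has_start, has_stop in spans:
                length = hi - lo
                if length < min_len or (max_len is not None and length > max_len):
                    continue
                nt = s[lo:hi]
                if set(nt) - set("ACGT"):
                    continue
                if strand == "+":
                    start, end = lo, hi
                else:
                    start, end = n - hi, n - lo
                orfs.append(
                    OrfRecord(
                        parent_id=seq.id,
                        start=start,
                        end=end,
                        strand=strand,
                        has_start_codon=has_start,
                        has_stop_codon=has_stop,
                        nt_sequence=nt,
                        genetic_code=genetic_code,
                    )
                )
    orfs.sort(key=lambda o: (o.start, o.strand, o.end))
    return orfs


def _complete_spans(s, frame, stops, all_starts):
    """ATG..stop spans in one frame (coordinates on the given strand)."""
    spans = []
    pending: list[int] = []  # ATG offsets since last stop
    for i in range(frame, len(s) - 2, 3):
        codon = s[i : i + 3]
        if codon in stops:
            if pending:
                starts = pending if all_starts else pending[:1]
                for a in starts:
                    spans.append((a, i + 3, True, True))
            pending = []
        elif codon == START_CODON:
            pending.append(i)
    return spans


def _region_spans(s, frame, stops):
    """Maximal stop-free codon runs in one frame, stops excluded.

    has_stop_codon is always False here: the flanking stop is not part
    of the span, so no region record ends with a stop codon.
    """
    spans = []
    run_start = frame
    last_full = frame + ((len(s) - frame) // 3) * 3
    for i in range(frame, last_full, 3):
        if s[i : i + 3] in stops:
            if i > run_start:
                first = s[run_start : run_start + 3]
                spans.append((run_start, i, first == START_CODON, False))
            run_start = i + 3
    if last_full > run_start:
        first = s[run_start : run_start + 3]
        spans.append((run_start, last_full, first == START_CODON, False))
    return spans
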