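"""CDS FASTA / expression-table I/O, quality control and codon tokenization.

The QC policy mirrors common codon-usage practice: coding sequences shorter
than 300 bp are removed outright (short CDS give unstable indices); kept
sequences whose length is not a multiple of three have the trailing 1-2
bases trimmed (flagged, not removed); sequences with an in-frame internal
stop codon are flagged but retained by default, since stop codons never
enter any downstream statistic anyway.  ``strict=True`` turns both flags
into rejections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import STOP_CODONS

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class ExpressionTableError(ValueError):
    """Malformed or invalid expression table."""


@dataclass(frozen=True)
class CodingSequence:
    """One protein-coding sequence after normalization (uppercase, U->T)."""

    id: str
    seq: str
    genome: str = ""
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class QCReport:
    """Summary of a :func:`qc_filter` pass."""

    n_input: int
    n_kept: int
    n_removed_short: int
    n_trimmed_frame: int
    n_with_internal_stop: int
    min_len: int
    n_rejected_strict: int = 0
    per_sequence: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.n_kept + self.n_removed_short + self.n_rejected_strict != self.n_input:
            raise ValueError("inconsistent QC report totals")

    def to_tsv(self, path: str | Path) -> None:
        self.per_sequence.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CodonSeq:
    """A CDS tokenized into non-overlapping codons (ambiguous ones skipped)."""

    gene_id: str
    codons: tuple[str, ...]
    n_skipped_ambiguous: int = 0
    genome: str = ""


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_cds_fasta(path: str | Path, genome_label: str = "") -> list[CodingSequence]:
    """Read a (multi-)FASTA of coding sequences.

    Record ids are the header token up to the first whitespace; the full
    header is kept as ``description``.  Sequences are case-folded to
    uppercase and RNA ``U`` is normalized to ``T``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    # Biopython silently ignores junk before the first '>'; reject it here
    # so truncated/concatenated files fail loudly.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            CodingSequence(
                id=rec.id,
                seq=_normalize(str(rec.seq)),
                genome=genome_label,
                description=rec.description,
            )
        )
    return records


def write_cds_fasta(seqs: Iterable[CodingSequence], path: str | Path) -> None:
    """Write sequences as unwrapped FASTA (id + description header)."""
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description=s.description or s.id)
        for s in seqs
    ]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.description}\n{rec.seq}\n")


def qc_filter(
    seqs: Sequence[CodingSequence],
    min_len: int = 300,
    strict: bool = False,
) -> tuple[list[CodingSequence], QCReport]:
    """Apply the length filter and frame/stop checks.

    The length threshold applies to the raw sequence length *before* frame
    trimming; exactly ``min_len`` bp is kept (strictly shorter is removed).
    """
    if not seqs:
        raise ValueError("no sequences")
    if min_len < 3:
        raise ValueError("min_len must be >= 3")

    kept: list[CodingSequence] = []
    rows = []
    n_removed_short = n_trimmed = n_internal_stop = n_rejected = 0
    for s in seqs:
        raw_len = len(s.seq)
        if raw_len < min_len:
            n_removed_short += 1
            rows.append((s.id, s.genome, raw_len, "removed_short", False, False))
            continue
        remainder = raw_len % 3
        seq = s.seq[: raw_len - remainder] if remainder else s.seq
        trimmed = remainder != 0
        if trimmed:
            n_trimmed += 1
            logger.warning("trimmed %d trailing base(s) from %s", remainder, s.id)
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        internal_stop = any(c in STOP_CODONS for c in codons[:-1])
        if internal_stop:
            n_internal_stop += 1
        if strict and (trimmed or internal_stop):
            n_rejected += 1
            rows.append((s.id, s.genome, raw_len, "rejected_strict", trimmed, internal_stop))
            continue
        kept.append(CodingSequence(s.id, seq, s.genome, s.description))
        rows.append((s.id, s.genome, raw_len, "kept", trimmed, internal_stop))

    per_seq = pd.DataFrame(
        rows,
        columns=["gene_id", "genome", "raw_length", "status", "trimmed_frame", "internal_stop"],
    )
    report = QCReport(
        n_input=len(seqs),
        n_kept=len(kept),
        n_removed_short=n_removed_short,
        n_trimmed_frame=n_trimmed,
        n_with_internal_stop=n_internal_stop,
        min_len=min_len,
        n_rejected_strict=n_rejected,
        per_sequence=per_seq,
    )
    return kept, report


def tokenize(seq: CodingSequence | str, gene_id: str | None = None) -> CodonSeq:
    """Split a CDS into non-overlapping 3-mers from position 1.

    Codons containing any non-ACGT symbol are skipped and counted in
    ``n_skipped_ambiguous``; a trailing partial codon is ignored.
    """
    if isinstance(seq, CodingSequence):
        s, gid, genome = seq.seq, seq.id, seq.genome
    else:
        s, gid, genome = _normalize(seq), gene_id or "", ""
    if len(s) < 3:
        raise ValueError(f"sequence shorter than one codon: {gid!r}")
    codons = []
    skipped = 0
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        if set(codon) <= _ACGT:
            codons.append(codon)
        else:
            skipped += 1
    return CodonSeq(gene_id=gid, codons=tuple(codons), n_skipped_ambiguous=skipped, genome=genome)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x tissue RPKM matrix (TSV, header row, first column ids).

    Returns a DataFrame indexed by gene id with one numeric column per
    tissue.  Negative values and duplicated gene ids are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression table not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ExpressionTableError(f"cannot parse expression TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ExpressionTableError(f"{path}: no tissue columns found")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ExpressionTableError(
            f"{path}: non-numeric RPKM values (is the header row present?)"
        ) from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ExpressionTableError(f"{path}: duplicate gene ids: {dups[:5]}")
    if (df.values < 0).any():
        raise ExpressionTableError(f"{path}: negative RPKM values")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", float_format="%.6g")
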