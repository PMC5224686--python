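"""Readers and writers for the external formats the pipeline touches.

All sequence data is held internally as DNA over {A,C,G,T(,N)}; RNA input
(``U``) is mapped to ``T`` at every read boundary.  Coordinates are 1-based
inclusive throughout, matching the convention of tRNA databases and genome
browsers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "TAXONOMY_IDS",
    "REQUIRED_TRIO",
    "REFERENCE_SPECIES",
    "FormatError",
    "DataError",
    "AlignmentError",
    "EmptyInputError",
    "SourceDB",
    "MatchType",
    "MatureTRNA",
    "CollapsedRead",
    "UTRBlock",
    "ExpressionTable",
    "SiteRecord",
    "read_trna_fasta",
    "read_small_rna",
    "write_collapsed_fasta",
    "read_utr_alignments",
    "write_utr_alignments",
    "write_site_records",
    "read_site_records",
    "read_expression_table",
    "write_expression_table",
    "read_genome_fasta",
    "revcomp",
]

#: The 23 vertebrate taxonomy IDs used for conserved-site counting.
TAXONOMY_IDS: tuple[int, ...] = (
    8364, 9031, 9258, 9361, 9365, 9371, 9544, 9598, 9606, 9615, 9685,
    9785, 9796, 9913, 9986, 10090, 10116, 10141, 13616, 28377, 30611,
    37347, 42254,
)

#: Human, mouse, rat — every conserved site must be present in all three.
REQUIRED_TRIO: frozenset[int] = frozenset({9606, 10090, 10116})

#: Rat: the species whose ungapped UTR coordinates anchor every site call.
REFERENCE_SPECIES: int = 10116


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class DataError(ValueError):
    """A file parses but violates a content invariant."""


class AlignmentError(DataError):
    """Rows of one alignment block disagree in gapped length."""


class EmptyInputError(FormatError):
    """An input file contains no records."""


class SourceDB(str, Enum):
    GTRNADB = "gtrnadb"
    TRNADB = "trnadb"


class MatchType(str, Enum):
    """Canonical target-site categories (as used for miRNA seed sites)."""

    M7_M8 = "7mer-m8"
    M7_1A = "7mer-1a"
    M8_1A = "8mer-1a"


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class MatureTRNA:
    """A mature tRNA gene sequence used as a mapping reference.

    ``sequence`` is the molecule reads are matched against: when
    ``cca_appended`` is true it ends with the post-transcriptional CCA.
    ``body`` recovers the encoded gene body (CCA stripped) for genome
    searches.
    """

    id: str
    anticodon: str
    amino_acid: str
    sequence: str
    is_mitochondrial: bool = False
    source_db: SourceDB = SourceDB.GTRNADB
    genomic_locus: tuple[str, int, int, str] | None = None
    cca_appended: bool = False
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"tRNA {self.id}: empty sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise DataError(f"tRNA {self.id}: non-ACGT characters {sorted(bad)}")

    @property
    def body(self) -> str:
        """Sequence without the 3' CCA (the genome-encoded part)."""
        if self.cca_appended and self.sequence.endswith("CCA"):
            return self.sequence[:-3]
        return self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence with its multiplicity in the raw library."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise DataError(f"collapsed read count must be >= 1, got {self.count}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise DataError(f"read contains non-ACGTN characters {sorted(bad)}")


@dataclass
class UTRBlock:
    """One gene's 3'UTR alignment across species.

    ``rows`` maps taxonomy ID to the gapped sequence; all rows share the
    same column count.
    """

    gene_id: str
    rows: dict[int, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise DataError(f"UTR block {self.gene_id}: no rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"UTR block {self.gene_id}: unequal gapped lengths {sorted(lengths)}"
            )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def ungapped(self, taxonomy_id: int) -> str:
        return self.rows[taxonomy_id].replace("-", "")


@dataclass
class ExpressionTable:
    """Per-transcript expression values over (timepoint, replicate) columns.

    ``data`` is indexed by transcript id with a 2-level column MultiIndex
    (timepoint, replicate); ``timepoints`` fixes the age ordering.
    """

    data: pd.DataFrame
    timepoints: tuple[str, ...]

    def __post_init__(self) -> None:
        if list(self.data.columns.names) != ["timepoint", "replicate"]:
            raise DataError("expression columns must be (timepoint, replicate)")
        present = list(dict.fromkeys(self.data.columns.get_level_values(0)))
        if set(present) != set(self.timepoints):
            raise DataError(
                f"timepoints {self.timepoints} do not match columns {present}"
            )
        reps = {
            tp: tuple(self.data[tp].columns) for tp in self.timepoints
        }
        counts = {len(r) for r in reps.values()}
        if len(counts) != 1:
            raise DataError(f"unequal replicate structure per timepoint: {reps}")
        if (self.data.values < 0).any():
            raise DataError("negative expression values")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise DataError(f"duplicated transcript ids: {list(dupes[:5])}")

    @property
    def transcripts(self) -> pd.Index:
        return self.data.index

    def replicate_means(self) -> pd.DataFrame:
        """Average replicates within each timepoint (columns = timepoints)."""
        return self.data.T.groupby(level="timepoint").mean().T[list(self.timepoints)]


@dataclass(frozen=True)
class SiteRecord:
    """One conserved target-site occurrence, in the 8-column deposited layout."""

    gene_name: str
    window_offset: int  # 1-based start of the 7-mer on the tRF
    msa_start: int
    msa_end: int
    utr_start: int
    utr_end: int
    match_type: MatchType
    species: frozenset[int]

    def __post_init__(self) -> None:
        if self.msa_start > self.msa_end or self.utr_start > self.utr_end:
            raise DataError(f"site record {self.gene_name}: inverted coordinates")
        if not self.species:
            raise DataError(f"site record {self.gene_name}: empty species set")


# ---------------------------------------------------------------------------
# tRNA FASTA

# Header dialects: the id token first, then optional amino-acid and anticodon
# labels, e.g. ">trna3690 Phe GAA" or ">tdbD00000658 Glu CTC mitochondrial".
_DEFAULT_HEADER_RE = re.compile(
    r"^(?P<id>\S+)(?:\s+(?P<aa>[A-Za-z]{2,4})\s+(?P<anticodon>[ACGTUacgtu]{3}))?"
)


def read_trna_fasta(
    path: str | Path,
    source_db: SourceDB = SourceDB.GTRNADB,
    append_cca: bool = True,
    header_pattern: re.Pattern | str = _DEFAULT_HEADER_RE,
) -> list[MatureTRNA]:
    """Read mature tRNA sequences, optionally appending the CCA tail.

    ``append_cca`` adds "CCA" only when the sequence does not already end
    with it (idempotent).  Duplicate mature sequences are kept but flagged
    via ``is_duplicate``.
    """
    path = Path(path)
    if isinstance(header_pattern, str):
        header_pattern = re.compile(header_pattern)
    _validate_fasta_layout(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records")
    out: list[MatureTRNA] = []
    seen: dict[str, int] = {}
    ids: set[str] = set()
    for rec in records:
        m = header_pattern.match(rec.description)
        if m is None or not m.group("id"):
            raise FormatError(f"{path}: unparseable header {rec.description!r}")
        rid = m.group("id")
        if rid in ids:
            raise DataError(f"{path}: duplicate tRNA id {rid}")
        ids.add(rid)
        aa = m.groupdict().get("aa")
        anticodon = m.groupdict().get("anticodon")
        if aa is None or anticodon is None:
            warnings.warn(
                f"{path}: header {rec.description!r} lacks amino-acid/anticodon "
                "labels; using fallback",
                stacklevel=2,
            )
            aa = aa or "Xaa"
            anticodon = anticodon or "NNN"
        seq = _normalize_dna(str(rec.seq))
        if append_cca and not seq.endswith("CCA"):
            seq = seq + "CCA"
        trna = MatureTRNA(
            id=rid,
            anticodon=_normalize_dna(anticodon),
            amino_acid=aa,
            sequence=seq,
            is_mitochondrial="mito" in rec.description.lower()
            or rid.startswith("Mtdb"),
            source_db=source_db,
            cca_appended=append_cca or seq.endswith("CCA"),
        )
        if seq in seen:
            trna.is_duplicate = True
            out[seen[seq]].is_duplicate = True
        else:
            seen[seq] = len(out)
        out.append(trna)
    return out


def _validate_fasta_layout(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}:{lineno}: expected FASTA header, got {line.strip()!r}"
                    )
                return
    raise EmptyInputError(f"{path}: empty file")


# ---------------------------------------------------------------------------
# Small-RNA reads

_COLLAPSED_HEADER_RE = re.compile(r"^(\d+)-(\d+)$")


def read_small_rna(path: str | Path) -> list[CollapsedRead]:
    """Read a small-RNA library as collapsed reads.

    Accepts FASTQ, plain FASTA (collapsed on read: identical sequences
    summed) or collapsed-FASTA with ">serial-count" headers (the
    fastx-collapser convention).  Total raw read count is conserved.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line[0]
                break
    if not first:
        raise EmptyInputError(f"{path}: empty file")
    if first == "@":
        return _collapse_sequences(_iter_fastq(path))
    if first != ">":
        raise FormatError(f"{path}: neither FASTA nor FASTQ")

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"{path}: no records")
    headers = [rec.id for rec in records]
    if all(_COLLAPSED_HEADER_RE.match(h) for h in headers):
        out = []
        for rec in records:
            m = _COLLAPSED_HEADER_RE.match(rec.id)
            out.append(
                CollapsedRead(_normalize_dna(str(rec.seq)), int(m.group(2)))
            )
        return out
    if any(re.match(r"^\d+-", h) for h in headers):
        bad = next(h for h in headers if re.match(r"^\d+-", h))
        raise FormatError(
            f"{path}: header {bad!r} looks collapsed but count is non-numeric"
        )
    return _collapse_sequences(_normalize_dna(str(rec.seq)) for rec in records)


def _iter_fastq(path: Path) -> Iterable[str]:
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield _normalize_dna(str(rec.seq))
    except ValueError as exc:  # quality/sequence length mismatch etc.
        raise FormatError(f"{path}: {exc}") from exc


def _collapse_sequences(seqs: Iterable[str]) -> list[CollapsedRead]:
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    return [CollapsedRead(s, c) for s, c in counts.items()]


def write_collapsed_fasta(reads: Sequence[CollapsedRead], path: str | Path) -> None:
    """Write collapsed reads using the ">serial-count" header dialect."""
    with open(path, "w") as fh:
        for serial, read in enumerate(reads, start=1):
            fh.write(f">{serial}-{read.count}\n{read.sequence}\n")


def total_raw_reads(reads: Iterable[CollapsedRead]) -> int:
    return sum(r.count for r in reads)


# ---------------------------------------------------------------------------
# UTR alignment blocks


def read_utr_alignments(
    path: str | Path, dialect: str = "simple"
) -> list[UTRBlock]:
    """Read multi-species 3'UTR alignment blocks from TSV.

    ``simple``: three columns (gene_id, taxonomy_id, gapped_sequence), with
    or without a header line.  ``targetscan``: the TargetScan UTR download
    layout (gene id, gene symbol, species id, gapped UTR sequence); the
    symbol column is dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.empty:
        raise EmptyInputError(f"{path}: no rows")
    if dialect == "simple":
        if df.shape[1] < 3:
            raise FormatError(f"{path}: expected 3 columns, got {df.shape[1]}")
        df = df.iloc[:, :3]
    elif dialect == "targetscan":
        if df.shape[1] < 4:
            raise FormatError(f"{path}: expected 4 TargetScan columns")
        df = df.iloc[:, [0, 2, 3]]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.columns = ["gene_id", "taxonomy_id", "gapped_sequence"]
    # tolerate a header line
    if not df.iloc[0]["taxonomy_id"].strip().isdigit():
        df = df.iloc[1:]
        if df.empty:
            raise EmptyInputError(f"{path}: header only")

    blocks: list[UTRBlock] = []
    order: dict[str, dict[int, str]] = {}
    for gene, tax, seq in df.itertuples(index=False):
        try:
            tax_id = int(tax)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric taxonomy id {tax!r}") from exc
        if tax_id not in TAXONOMY_IDS:
            warnings.warn(
                f"{path}: unknown taxonomy ID {tax_id} in gene {gene} (row kept)",
                stacklevel=2,
            )
        seq = _normalize_dna(seq.strip())
        bad = set(seq) - set("ACGTN-")
        if bad:
            raise FormatError(
                f"{path}: gene {gene} species {tax_id}: bad characters {sorted(bad)}"
            )
        rows = order.setdefault(gene, {})
        if tax_id in rows:
            raise DataError(f"{path}: gene {gene}: duplicate taxonomy ID {tax_id}")
        rows[tax_id] = seq
    for gene, rows in order.items():
        blocks.append(UTRBlock(gene_id=gene, rows=rows))
    return blocks


def write_utr_alignments(blocks: Sequence[UTRBlock], path: str | Path) -> None:
    """Write blocks in the simple 3-column TSV dialect."""
    with open(path, "w") as fh:
        for block in blocks:
            for tax_id, seq in block.rows.items():
                fh.write(f"{block.gene_id}\t{tax_id}\t{seq}\n")


# ---------------------------------------------------------------------------
# Site records (the deposited 8-column layout)


def write_site_records(
    records: Sequence[SiteRecord], path: str | Path, header: str | None = None
) -> None:
    """Write sites in the deposited 8-column tab-separated layout.

    Columns: gene name; 7-mer location on the tRF; MSA start; MSA end;
    3'UTR start; 3'UTR end; match type; comma-joined taxonomy IDs
    (ascending, for deterministic diffs).
    """
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for r in records:
            species = ",".join(str(t) for t in sorted(r.species))
            fh.write(
                f"{r.gene_name}\t{r.window_offset}\t{r.msa_start}\t{r.msa_end}\t"
                f"{r.utr_start}\t{r.utr_end}\t{r.match_type.value}\t{species}\n"
            )


def read_site_records(path: str | Path) -> list[SiteRecord]:
    """Read the 8-column site layout written by :func:`write_site_records`."""
    out: list[SiteRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 8:
                raise FormatError(f"{path}:{lineno}: expected 8 fields, got {len(parts)}")
            gene, off, ms, me, us, ue, mt, species = parts
            try:
                record = SiteRecord(
                    gene_name=gene,
                    window_offset=int(off),
                    msa_start=int(ms),
                    msa_end=int(me),
                    utr_start=int(us),
                    utr_end=int(ue),
                    match_type=MatchType(mt),
                    species=frozenset(int(t) for t in species.split(",")),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(record)
    return out


# ---------------------------------------------------------------------------
# Expression tables

_EXPR_COL_RE = re.compile(r"^(?P<tp>.+)_(?P<rep>[^_]+)$")


def read_expression_table(
    path: str | Path, timepoints: Sequence[str] | None = None
) -> ExpressionTable:
    """Read a transcript expression TSV with ``<timepoint>_<replicate>`` columns.

    Values are kept raw; normalization happens downstream.  ``timepoints``
    fixes the age order (default: column appearance order).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise EmptyInputError(f"{path}: no rows")
    cols = []
    for c in df.columns:
        m = _EXPR_COL_RE.match(str(c))
        if m is None:
            raise FormatError(f"{path}: column {c!r} not <timepoint>_<replicate>")
        cols.append((m.group("tp"), m.group("rep")))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["timepoint", "replicate"])
    if timepoints is None:
        timepoints = tuple(dict.fromkeys(tp for tp, _ in cols))
    return ExpressionTable(data=df, timepoints=tuple(timepoints))


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    flat = table.data.copy()
    flat.columns = [f"{tp}_{rep}" for tp, rep in table.data.columns]
    flat.to_csv(path, sep="\t", index_label="transcript_id")


# ---------------------------------------------------------------------------
# Genome FASTA


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a {chrom: sequence} dict (DNA-normalized)."""
    path = Path(path)
    _validate_fasta_layout(path)
    genome = {
        rec.id: _normalize_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }
    if not genome:
        raise EmptyInputError(f"{path}: no FASTA records")
    return genome
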