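"""tRF discovery, classification, normalization and age-pattern calling.

A tRF (tRNA-derived fragment) is a short (~16-24 nt) RNA cleaved from a
mature tRNA.  Reads are matched as exact, full-length, sense-strand
substrings of CCA-appended mature tRNAs; fragments anchored at position 1
are 5' tRFs, fragments ending at the CCA terminus are 3'CCA tRFs, and the
rest map internally.  Fragment abundance is normalized to reads per
million (RPM) and a fragment is only reported when its read count exceeds
a configurable fraction (default 0.1%) of total reads in *every*
replicate library.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import CollapsedRead, DataError, MatureTRNA, revcomp

__all__ = [
    "TRFClass",
    "AgePatternKind",
    "Match",
    "TRFRecord",
    "AgePattern",
    "LibraryStats",
    "clip_adapter",
    "filter_by_length",
    "map_reads",
    "classify_match",
    "normalize_counts",
    "call_trfs",
    "classify_age_pattern",
    "length_distribution",
    "length_variance",
    "library_stats",
    "locate_gene_in_genome",
]

LibraryKey = tuple[str, int]  # (timepoint label, replicate number)


class TRFClass(str, Enum):
    FIVE_PRIME = "5p"
    THREE_PRIME_CCA = "3p-CCA"
    THREE_PRIME_U = "3p-U"
    INTERNAL = "internal"
    FULL_LENGTH_EXCLUDED = "full-length"


class AgePatternKind(str, Enum):
    MONO_UP = "mono-up"
    MONO_DOWN = "mono-down"
    DIP = "dip"
    PEAK = "peak"
    FLAT = "flat"


@dataclass(frozen=True)
class Match:
    """An exact full-length placement of a read on one mature tRNA."""

    trna_id: str
    start: int  # 1-based inclusive, CCA included in coordinates
    end: int
    trf_class: TRFClass


@dataclass
class AgePattern:
    pattern: AgePatternKind
    means: dict[str, float]  # timepoint -> replicate-averaged RPM
    ranges: dict[str, tuple[float, float]]  # timepoint -> (min, max) RPM


@dataclass
class TRFRecord:
    """A called tRF: representative fragment plus per-library abundance."""

    trf_id: str
    trna_ids: tuple[str, ...]
    trf_class: TRFClass
    start: int
    end: int
    sequence: str
    abundance_rpm: dict[LibraryKey, float]
    age_pattern: AgePattern | None = None

    @property
    def trna_id(self) -> str:
        return self.trna_ids[0]

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class LibraryStats:
    library: LibraryKey
    total_reads: int
    mapped_reads: int
    class_fractions: dict[TRFClass, float]  # fractions of mapped reads

    @property
    def mapped_fraction(self) -> float:
        return self.mapped_reads / self.total_reads if self.total_reads else 0.0


# ---------------------------------------------------------------------------
# Read preprocessing


def clip_adapter(
    reads: Sequence[CollapsedRead], adapter: str, min_overlap: int = 7
) -> list[CollapsedRead]:
    """Remove the 3' adapter (and everything after it) from each read.

    The leftmost exact occurrence of an adapter prefix of length
    >= ``min_overlap`` is clipped; a terminal partial adapter shorter than
    ``min_overlap`` is left in place.  Empty ``adapter`` is a no-op.
    Fully-adapter reads become empty and are dropped.
    """
    if not adapter:
        return list(reads)
    adapter = adapter.upper().replace("U", "T")
    probe = adapter[: max(min_overlap, 1)]
    out: list[CollapsedRead] = []
    for read in reads:
        idx = read.sequence.find(probe)
        clipped = read.sequence[:idx] if idx >= 0 else read.sequence
        if clipped:
            out.append(CollapsedRead(clipped, read.count))
    return out


def filter_by_length(
    reads: Iterable[CollapsedRead], min_len: int = 17
) -> list[CollapsedRead]:
    """Keep reads of length >= ``min_len`` (default: longer than 16 nt)."""
    return [r for r in reads if len(r.sequence) >= min_len]


# ---------------------------------------------------------------------------
# Exact matching and classification


def classify_match(start: int, end: int, trna_length: int) -> TRFClass:
    """Classify a placement by its anchoring on the mature molecule."""
    if start == 1 and end == trna_length:
        return TRFClass.FULL_LENGTH_EXCLUDED
    if start == 1:
        return TRFClass.FIVE_PRIME
    if end == trna_length:
        return TRFClass.THREE_PRIME_CCA
    return TRFClass.INTERNAL


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i >= 0:
        yield i
        i = haystack.find(needle, i + 1)


def map_reads(
    reads: Sequence[CollapsedRead], trnas: Sequence[MatureTRNA]
) -> dict[str, list[Match]]:
    """Locate each distinct read as an exact substring of mature tRNAs.

    Sense strand only; all placements on all tRNA gene copies are
    reported.  Reads with no placement map to an empty list.
    """
    out: dict[str, list[Match]] = {}
    for read in reads:
        seq = read.sequence
        if seq in out:
            continue
        matches: list[Match] = []
        for trna in trnas:
            for i in _find_all(trna.sequence, seq):
                start, end = i + 1, i + len(seq)
                matches.append(
                    Match(trna.id, start, end, classify_match(start, end, len(trna)))
                )
        out[seq] = matches
    return out


def normalize_counts(counts: Mapping[str, int], total_reads: int) -> dict[str, float]:
    """Scale raw counts to reads per million of ``total_reads``."""
    if total_reads <= 0:
        raise DataError("cannot normalize: total_reads is zero")
    scale = 1e6 / total_reads
    return {k: v * scale for k, v in counts.items()}


# ---------------------------------------------------------------------------
# tRF calling


def call_trfs(
    libraries: Mapping[LibraryKey, Sequence[CollapsedRead]],
    trnas: Sequence[MatureTRNA],
    abundance_filter: float = 0.001,
    timepoints: Sequence[str] = ("Y", "M", "O"),
    n_replicates: int = 3,
    denominator: str = "all",
    pattern_epsilon: float = 0.05,
    require_full_grid: bool = True,
) -> list[TRFRecord]:
    """Aggregate mapped reads into filtered, age-annotated tRF records.

    Candidates are accumulated per (tRNA gene, fragment class); the
    representative fragment is the modal distinct read (highest count
    summed across libraries).  A candidate is retained only when its read
    count strictly exceeds ``abundance_filter`` of total reads in every
    library.  ``denominator`` selects the filter/normalization total:
    ``"all"`` (every read in the library, the default) or ``"mapped"``.
    Records over tRNA genes with identical mature sequences are merged.
    """
    expected = [(tp, rep) for tp in timepoints for rep in range(1, n_replicates + 1)]
    if require_full_grid and sorted(libraries) != sorted(expected):
        raise DataError(
            f"expected {len(expected)} libraries {expected}, got {sorted(libraries)}"
        )
    if denominator not in ("all", "mapped"):
        raise ValueError(f"unknown denominator {denominator!r}")

    all_reads = {r.sequence for lib in libraries.values() for r in lib}
    placements = map_reads(
        [CollapsedRead(s, 1) for s in sorted(all_reads)], trnas
    )
    trna_by_id = {t.id: t for t in trnas}

    # per-(trna, class): per-library count and per-distinct-read total count
    lib_counts: dict[tuple[str, TRFClass], dict[LibraryKey, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    read_totals: dict[tuple[str, TRFClass], dict[str, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    totals: dict[LibraryKey, int] = {}
    for key, lib in libraries.items():
        total_all = sum(r.count for r in lib)
        total_mapped = 0
        for read in lib:
            matches = placements[read.sequence]
            if matches:
                total_mapped += read.count
            for m in matches:
                if m.trf_class is TRFClass.FULL_LENGTH_EXCLUDED:
                    continue
                k = (m.trna_id, m.trf_class)
                lib_counts[k][key] += read.count
                read_totals[k][read.sequence] += read.count
        totals[key] = total_all if denominator == "all" else total_mapped
        if totals[key] <= 0:
            raise DataError(f"library {key}: zero total reads")

    # abundance filter: strictly above threshold in every library
    kept: list[tuple[str, TRFClass]] = []
    for k, counts in lib_counts.items():
        if all(
            counts.get(lib, 0) > abundance_filter * totals[lib] for lib in libraries
        ):
            kept.append(k)

    # merge gene copies with identical mature sequences
    groups: dict[tuple[str, TRFClass], list[str]] = defaultdict(list)
    for trna_id, trf_class in sorted(kept, key=lambda k: (k[1].value, k[0])):
        groups[(trna_by_id[trna_id].sequence, trf_class)].append(trna_id)

    records: list[TRFRecord] = []
    for (trna_seq, trf_class), trna_ids in groups.items():
        k = (trna_ids[0], trf_class)
        # modal distinct read; ties broken deterministically by sequence
        rep_seq = max(read_totals[k].items(), key=lambda kv: (kv[1], kv[0]))[0]
        pos = trna_seq.find(rep_seq)
        start, end = pos + 1, pos + len(rep_seq)
        rpm = {
            lib: lib_counts[k].get(lib, 0) * 1e6 / totals[lib] for lib in libraries
        }
        record = TRFRecord(
            trf_id=f"{trf_class.value}:{'+'.join(sorted(trna_ids))}",
            trna_ids=tuple(sorted(trna_ids)),
            trf_class=trf_class,
            start=start,
            end=end,
            sequence=rep_seq,
            abundance_rpm=rpm,
        )
        record.age_pattern = classify_age_pattern(
            rpm, timepoints=timepoints, epsilon=pattern_epsilon
        )
        records.append(record)
    records.sort(key=lambda r: r.trf_id)
    return records


# ---------------------------------------------------------------------------
# Age patterns


def classify_age_pattern(
    abundance_rpm: Mapping[LibraryKey, float],
    timepoints: Sequence[str] = ("Y", "M", "O"),
    epsilon: float = 0.05,
) -> AgePattern:
    """Label the trajectory of replicate-averaged abundance over age.

    With per-timepoint means (y, m, o) and tolerance band
    eps = ``epsilon`` * grand mean: monotone up/down require every step to
    exceed eps; a dip (m below both ends, the "M < Y < O" shape) or a peak
    require m to clear both ends by eps; anything else is flat.
    """
    by_tp: dict[str, list[float]] = {tp: [] for tp in timepoints}
    for (tp, _rep), value in abundance_rpm.items():
        by_tp[tp].append(value)
    means = {tp: float(np.mean(v)) if v else 0.0 for tp, v in by_tp.items()}
    ranges = {
        tp: (float(min(v)), float(max(v))) if v else (0.0, 0.0)
        for tp, v in by_tp.items()
    }
    if len(timepoints) != 3:
        return AgePattern(AgePatternKind.FLAT, means, ranges)
    y, m, o = (means[tp] for tp in timepoints)
    eps = epsilon * float(np.mean([y, m, o]))
    if m - y > eps and o - m > eps:
        kind = AgePatternKind.MONO_UP
    elif y - m > eps and m - o > eps:
        kind = AgePatternKind.MONO_DOWN
    elif min(y, o) - m > eps:
        kind = AgePatternKind.DIP
    elif m - max(y, o) > eps:
        kind = AgePatternKind.PEAK
    else:
        kind = AgePatternKind.FLAT
    return AgePattern(kind, means, ranges)


# ---------------------------------------------------------------------------
# Distributions and stats


def length_distribution(
    reads: Mapping[str, int],
    placements: Mapping[str, list[Match]],
    trf_class: TRFClass,
) -> dict[int, float]:
    """Abundance-weighted fragment-length frequencies for one class.

    ``reads`` maps distinct read sequence to its summed count; a read
    contributes when any placement carries the class.  Frequencies sum
    to 1 (empty class: empty dict).
    """
    weights: dict[int, float] = defaultdict(float)
    for seq, count in reads.items():
        if any(m.trf_class is trf_class for m in placements.get(seq, [])):
            weights[len(seq)] += count
    total = sum(weights.values())
    return {ln: w / total for ln, w in sorted(weights.items())} if total else {}


def length_variance(distribution: Mapping[int, float]) -> float:
    """Variance of fragment length under a frequency distribution."""
    if not distribution:
        return float("nan")
    lengths = np.array(list(distribution.keys()), dtype=float)
    freqs = np.array(list(distribution.values()), dtype=float)
    mean = float(lengths @ freqs)
    return float(((lengths - mean) ** 2) @ freqs)


def library_stats(
    library_key: LibraryKey,
    reads: Sequence[CollapsedRead],
    placements: Mapping[str, list[Match]],
) -> LibraryStats:
    """Totals and per-class fractions of tRNA-mapped reads for one library.

    A multi-mapping read contributes its count once, to the class of its
    first placement in a fixed class-priority order (5', 3'CCA, internal);
    fractions are over mapped reads and sum to 1.
    """
    priority = [TRFClass.FIVE_PRIME, TRFClass.THREE_PRIME_CCA, TRFClass.INTERNAL]
    total = sum(r.count for r in reads)
    mapped = 0
    class_counts: dict[TRFClass, int] = {c: 0 for c in priority}
    for read in reads:
        matches = placements.get(read.sequence, [])
        classes = {m.trf_class for m in matches}
        chosen = next((c for c in priority if c in classes), None)
        if chosen is not None:
            mapped += read.count
            class_counts[chosen] += read.count
    fractions = {
        c: (n / mapped if mapped else 0.0) for c, n in class_counts.items()
    }
    return LibraryStats(library_key, total, mapped, fractions)


# ---------------------------------------------------------------------------
# tRF table TSV


def write_trf_table(records: Sequence[TRFRecord], path, header: str | None = None) -> None:
    """TSV: id, gene copies, class, coordinates, sequence, per-library RPM, pattern."""
    if not records:
        raise DataError("no tRF records to write")
    libs = sorted(records[0].abundance_rpm)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        cols = ["trf_id", "trna_ids", "class", "start", "end", "sequence"]
        cols += [f"rpm_{tp}_{rep}" for tp, rep in libs]
        cols.append("pattern")
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [
                r.trf_id,
                "+".join(r.trna_ids),
                r.trf_class.value,
                str(r.start),
                str(r.end),
                r.sequence,
            ]
            row += [f"{r.abundance_rpm[lib]:.6g}" for lib in libs]
            row.append(r.age_pattern.pattern.value if r.age_pattern else "")
            fh.write("\t".join(row) + "\n")


def read_trf_table(path) -> list[TRFRecord]:
    """Read the TSV written by :func:`write_trf_table`."""
    records: list[TRFRecord] = []
    with open(path) as fh:
        cols: list[str] | None = None
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if cols is None:
                cols = parts
                continue
            row = dict(zip(cols, parts))
            rpm: dict[LibraryKey, float] = {}
            for c in cols:
                if c.startswith("rpm_"):
                    _, tp, rep = c.split("_")
                    rpm[(tp, int(rep))] = float(row[c])
            records.append(
                TRFRecord(
                    trf_id=row["trf_id"],
                    trna_ids=tuple(row["trna_ids"].split("+")),
                    trf_class=TRFClass(row["class"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    sequence=row["sequence"],
                    abundance_rpm=rpm,
                    age_pattern=classify_age_pattern(rpm) if rpm else None,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Genome annotation helper


def locate_gene_in_genome(
    trna_sequence: str, genome: Mapping[str, str]
) -> list[tuple[str, int, int, str]]:
    """Find all exact genomic placements of a tRNA body, both strands.

    ``trna_sequence`` should be the gene body (CCA removed).  Returns
    1-based inclusive (chrom, start, end, strand) tuples; minus-strand
    hits are reported in plus-strand coordinates.
    """
    query = trna_sequence.upper().replace("U", "T")
    hits: list[tuple[str, int, int, str]] = []
    rc = revcomp(query)
    for chrom, seq in genome.items():
        for i in _find_all(seq, query):
            hits.append((chrom, i + 1, i + len(query), "+"))
        for i in _find_all(seq, rc):
            hits.append((chrom, i + 1, i + len(query), "-"))
    hits.sort()
    return hits
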