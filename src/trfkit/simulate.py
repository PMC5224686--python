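"""Synthetic data generators with planted, recoverable ground truth.

Every generator emulates the statistical structure the downstream
analysis assumes: tRNA gene sets with CCA tails; nine collapsed-read
libraries (3 ages x 3 replicates) with class-specific cleavage-site
jitter (3' fragments end exactly at the CCA terminus with small start
jitter; 5' fragments start at position 1 with larger end jitter) and
per-fragment age trajectories; 23-species 3'UTR alignment blocks with
sites planted at shared columns in a controlled number of species; and
expression tables with a controlled down-regulation of planted targets.

Randomness is hierarchical: one integer seed feeds named child streams
(one per emitted artifact), so regenerating one file never perturbs the
others.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    REQUIRED_TRIO,
    TAXONOMY_IDS,
    CollapsedRead,
    DataError,
    ExpressionTable,
    MatchType,
    MatureTRNA,
    SourceDB,
    UTRBlock,
    revcomp,
)
from .pipeline import AgePatternKind, LibraryKey, TRFClass
from .seeds import site_variants

__all__ = [
    "SimulationConfig",
    "PlantedTRF",
    "PlantedWindow",
    "GroundTruth",
    "make_trna_set",
    "simulate_read_libraries",
    "choose_planted_windows",
    "simulate_utr_alignments",
    "simulate_expression",
    "simulate_background",
]

_BASES = np.array(list("ACGT"))

# amino acid / anticodon pairs sampled for synthetic tRNA labels
_ISOTYPES = [
    ("Phe", "GAA"), ("Gly", "GCC"), ("Val", "CAC"), ("Ser", "AGA"),
    ("Pro", "TGG"), ("Ala", "TGC"), ("Leu", "CAG"), ("Lys", "CTT"),
    ("Glu", "CTC"), ("His", "GTG"), ("Cys", "GCA"), ("Gln", "CTG"),
    ("Arg", "ACG"), ("Trp", "CCA"), ("Ile", "AAT"), ("Met", "CAT"),
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the study's defaults."""

    seed: int = 0
    # tRNA set
    n_trnas: int = 30
    trna_length_range: tuple[int, int] = (70, 90)  # gene body, before CCA
    n_mitochondrial: int = 2
    n_duplicate_trnas: int = 0
    # libraries
    timepoints: tuple[str, ...] = ("Y", "M", "O")
    n_replicates: int = 3
    library_depth: int = 1_000_000
    noise_cv: float = 0.2
    three_prime_start_jitter_sd: float = 0.5
    five_prime_end_jitter_sd: float = 3.0
    n_three_prime_trfs: int = 8
    n_five_prime_trfs: int = 8
    three_prime_trajectories: tuple[str, ...] = ("mono-up",)
    five_prime_trajectories: tuple[str, ...] = ("dip", "mono-up", "dip", "flat")
    trf_base_fraction: float = 0.004
    effect_size: float = 2.0
    internal_fraction: float = 0.05  # of tRNA-mapped reads
    n_internal_fragments: int = 150
    n_decoys: int = 400
    # UTR alignments
    n_genes: int = 300
    n_species: int = 23
    utr_length: int = 500
    gap_rate: float = 0.02
    gc_content: float = 0.4
    conservation_k: int = 16
    genes_per_window: int = 40
    # expression
    n_transcripts: int = 2000
    target_downregulation: float = 0.15
    expression_noise_cv: float = 0.2
    ratio_sigma: float = 0.15
    expression_timepoints: tuple[str, ...] = ("Y", "M", "O")

    def __post_init__(self) -> None:
        if self.conservation_k > self.n_species:
            raise DataError("conservation_k exceeds the species count")
        if self.n_species != len(TAXONOMY_IDS):
            raise DataError(f"species universe is fixed at {len(TAXONOMY_IDS)} taxa")
        if min(
            self.n_trnas, self.library_depth, self.n_genes, self.n_transcripts
        ) <= 0:
            raise DataError("all counts must be positive")
        valid = {k.value for k in AgePatternKind}
        bad = (set(self.three_prime_trajectories) | set(self.five_prime_trajectories)) - valid
        if bad:
            raise DataError(f"unknown trajectory labels {sorted(bad)}")


@dataclass(frozen=True)
class PlantedTRF:
    trf_id: str
    trna_id: str
    trf_class: TRFClass
    start: int
    end: int
    sequence: str
    trajectory: AgePatternKind
    base_fraction: float
    effect: float


@dataclass(frozen=True)
class PlantedWindow:
    """A 7-mer window planted as conserved sites in a set of genes."""

    trf_id: str
    offset: int
    kmer: str
    genes: tuple[str, ...] = ()
    conservation_k: int | None = None


@dataclass
class GroundTruth:
    """What was planted, in a JSON-serializable form."""

    trfs: list[PlantedTRF] = field(default_factory=list)
    windows: list[PlantedWindow] = field(default_factory=list)
    site_species: dict[str, list[int]] = field(default_factory=dict)  # gene -> carriers
    target_sets: dict[str, list[str]] = field(default_factory=dict)
    target_downregulation: float = 0.0
    duplicate_trna_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        def default(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            if isinstance(obj, (TRFClass, AgePatternKind, MatchType)):
                return obj.value
            raise TypeError(f"not serializable: {obj!r}")

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=default)


def _stream(config: SimulationConfig, *key: int) -> np.random.Generator:
    """Named child RNG stream derived from the master seed."""
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *key])


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


# ---------------------------------------------------------------------------
# tRNA set


def make_trna_set(config: SimulationConfig) -> tuple[list[MatureTRNA], GroundTruth]:
    """Random tRNA-like genes with anticodon labels and appended CCA."""
    rng = _stream(config, 0)
    lo, hi = config.trna_length_range
    trnas: list[MatureTRNA] = []
    bodies: list[str] = []
    truth = GroundTruth()
    for i in range(config.n_trnas):
        aa, anticodon = _ISOTYPES[i % len(_ISOTYPES)]
        is_mito = i < config.n_mitochondrial
        if config.n_duplicate_trnas and 0 < i <= config.n_duplicate_trnas:
            body = bodies[0]  # configured duplicates copy the first gene
        else:
            body = _random_dna(rng, int(rng.integers(lo, hi + 1)))
            while body in bodies:
                body = _random_dna(rng, int(rng.integers(lo, hi + 1)))
        bodies.append(body)
        rid = f"MtdbD{7000 + i:07d}" if is_mito else f"trna{1000 + i}"
        trnas.append(
            MatureTRNA(
                id=rid,
                anticodon=anticodon,
                amino_acid=aa,
                sequence=body + "CCA",
                is_mitochondrial=is_mito,
                source_db=SourceDB.TRNADB if is_mito else SourceDB.GTRNADB,
                cca_appended=True,
            )
        )
    seen: dict[str, list[int]] = {}
    for idx, t in enumerate(trnas):
        seen.setdefault(t.sequence, []).append(idx)
    for indices in seen.values():
        if len(indices) > 1:
            for idx in indices:
                trnas[idx].is_duplicate = True
                truth.duplicate_trna_ids.append(trnas[idx].id)
    return trnas, truth


# ---------------------------------------------------------------------------
# Read libraries

_TRAJ_MULTIPLIERS = {
    AgePatternKind.MONO_UP: lambda e, i: e**i,
    AgePatternKind.MONO_DOWN: lambda e, i: e**-i,
    AgePatternKind.DIP: lambda e, i: (1.0, 1.0 / e, e)[i],
    AgePatternKind.PEAK: lambda e, i: (1.0, e, 1.0)[i],
    AgePatternKind.FLAT: lambda e, i: 1.0,
}


def _plan_trfs(
    trnas: Sequence[MatureTRNA], config: SimulationConfig, rng: np.random.Generator
) -> list[PlantedTRF]:
    hosts = [t for t in trnas if not t.is_duplicate]
    needed = config.n_three_prime_trfs + config.n_five_prime_trfs
    if len(hosts) < needed:
        raise DataError(f"need {needed} distinct tRNAs, have {len(hosts)}")
    planted: list[PlantedTRF] = []
    for j in range(config.n_three_prime_trfs):
        trna = hosts[j]
        flen = int(rng.integers(17, 23))
        start, end = len(trna) - flen + 1, len(trna)
        traj = AgePatternKind(
            config.three_prime_trajectories[j % len(config.three_prime_trajectories)]
        )
        planted.append(
            PlantedTRF(
                trf_id=f"{TRFClass.THREE_PRIME_CCA.value}:{trna.id}",
                trna_id=trna.id,
                trf_class=TRFClass.THREE_PRIME_CCA,
                start=start,
                end=end,
                sequence=trna.sequence[start - 1 : end],
                trajectory=traj,
                base_fraction=config.trf_base_fraction,
                effect=config.effect_size,
            )
        )
    for j in range(config.n_five_prime_trfs):
        trna = hosts[config.n_three_prime_trfs + j]
        flen = int(rng.integers(18, 34))
        traj = AgePatternKind(
            config.five_prime_trajectories[j % len(config.five_prime_trajectories)]
        )
        planted.append(
            PlantedTRF(
                trf_id=f"{TRFClass.FIVE_PRIME.value}:{trna.id}",
                trna_id=trna.id,
                trf_class=TRFClass.FIVE_PRIME,
                start=1,
                end=flen,
                sequence=trna.sequence[:flen],
                trajectory=traj,
                base_fraction=config.trf_base_fraction,
                effect=config.effect_size,
            )
        )
    return planted


def _jitter_pmf(sd: float, half_width: int) -> tuple[np.ndarray, np.ndarray]:
    offsets = np.arange(-half_width, half_width + 1)
    if sd <= 0:
        p = (offsets == 0).astype(float)
    else:
        p = np.exp(-0.5 * (offsets / sd) ** 2)
    return offsets, p / p.sum()


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1 + cv**2))
    return float(rng.lognormal(-(sigma**2) / 2, sigma))


def _make_decoys(
    trnas: Sequence[MatureTRNA], config: SimulationConfig, rng: np.random.Generator
) -> list[str]:
    """Non-mapping reads: random sequences plus single-mismatch tRNA
    fragments exercising the perfect-match requirement."""
    decoys: list[str] = []
    seen: set[str] = set()
    references = [t.sequence for t in trnas]
    while len(decoys) < config.n_decoys:
        if rng.random() < 0.5 and references:
            ref = references[int(rng.integers(len(references)))]
            flen = int(rng.integers(17, 26))
            if len(ref) <= flen:
                continue
            start = int(rng.integers(0, len(ref) - flen + 1))
            frag = list(ref[start : start + flen])
            pos = int(rng.integers(flen))
            frag[pos] = rng.choice([b for b in "ACGT" if b != frag[pos]])
            cand = "".join(frag)
        else:
            cand = _random_dna(rng, int(rng.integers(17, 25)))
        if cand in seen or any(cand in ref for ref in references):
            continue
        seen.add(cand)
        decoys.append(cand)
    return decoys


def simulate_read_libraries(
    trnas: Sequence[MatureTRNA], config: SimulationConfig
) -> tuple[dict[LibraryKey, list[CollapsedRead]], GroundTruth]:
    """Nine collapsed-read libraries with planted tRFs and backgrounds.

    Per library, each planted tRF's expected count is its base fraction
    of the depth scaled by the age-trajectory multiplier, with
    multiplicative log-normal replicate noise; reads are spread over
    cleavage-site jitter offsets (class-specific sd).  An internal-read
    background (a configurable fraction of mapped reads) and non-mapping
    decoys filling the library to depth are added.
    """
    plan_rng = _stream(config, 1)
    planted = _plan_trfs(trnas, config, plan_rng)
    decoy_pool = _make_decoys(trnas, config, plan_rng)
    trna_by_id = {t.id: t for t in trnas}

    # internal fragment pool (never touching either end)
    internal_pool: list[str] = []
    hosts = [t for t in trnas if not t.is_duplicate]
    guard = 0
    while len(internal_pool) < config.n_internal_fragments and guard < 100000:
        guard += 1
        trna = hosts[int(plan_rng.integers(len(hosts)))]
        flen = int(plan_rng.integers(17, 26))
        if len(trna) < flen + 4:
            continue
        start = int(plan_rng.integers(2, len(trna) - flen))  # 1-based start >= 2
        frag = trna.sequence[start - 1 : start - 1 + flen]
        # reject fragments that happen to anchor at an end of any gene copy
        if any(
            frag == t.sequence[: len(frag)] or frag == t.sequence[-len(frag) :]
            for t in trnas
        ):
            continue
        internal_pool.append(frag)

    libraries: dict[LibraryKey, list[CollapsedRead]] = {}
    for tp_idx, tp in enumerate(config.timepoints):
        for rep in range(1, config.n_replicates + 1):
            rng = _stream(config, 1, tp_idx, rep)
            counts: dict[str, int] = {}

            def add(seq: str, n: int) -> None:
                if n > 0:
                    counts[seq] = counts.get(seq, 0) + int(n)

            mapped_total = 0
            for trf in planted:
                mult = _TRAJ_MULTIPLIERS[trf.trajectory](trf.effect, tp_idx)
                expected = trf.base_fraction * config.library_depth * mult
                n = int(round(expected * _lognormal_factor(rng, config.noise_cv)))
                if n <= 0:
                    continue
                trna = trna_by_id[trf.trna_id]
                if trf.trf_class is TRFClass.THREE_PRIME_CCA:
                    offsets, p = _jitter_pmf(config.three_prime_start_jitter_sd, 3)
                    split = rng.multinomial(n, p)
                    for off, k in zip(offsets, split):
                        start = min(max(trf.start + int(off), 2), len(trna) - 16)
                        add(trna.sequence[start - 1 :], k)
                else:
                    offsets, p = _jitter_pmf(config.five_prime_end_jitter_sd, 6)
                    split = rng.multinomial(n, p)
                    for off, k in zip(offsets, split):
                        end = min(max(trf.end + int(off), 17), len(trna) - 1)
                        add(trna.sequence[:end], k)
                mapped_total += n

            f = config.internal_fraction
            n_internal = int(round(mapped_total * f / (1 - f))) if f > 0 else 0
            if n_internal > 0 and internal_pool:
                split = rng.multinomial(
                    n_internal, np.full(len(internal_pool), 1 / len(internal_pool))
                )
                for frag, k in zip(internal_pool, split):
                    add(frag, k)
            n_decoy = config.library_depth - mapped_total - n_internal
            if n_decoy > 0 and decoy_pool:
                split = rng.multinomial(
                    n_decoy, np.full(len(decoy_pool), 1 / len(decoy_pool))
                )
                for seq, k in zip(decoy_pool, split):
                    add(seq, k)
            libraries[(tp, rep)] = [
                CollapsedRead(s, c) for s, c in sorted(counts.items())
            ]
    truth = GroundTruth(trfs=planted)
    return libraries, truth


# ---------------------------------------------------------------------------
# Planted seed windows and UTR alignments


def choose_planted_windows(
    planted_trfs: Sequence[PlantedTRF],
    config: SimulationConfig,
    n_windows: int = 3,
    offset: int | None = None,
) -> list[PlantedWindow]:
    """Pick one 7-mer window per planted 3' tRF to plant as a seed.

    Offsets whose window starts with T, or whose 5'-flanking base is T,
    are avoided: there the 7mer-m8 / 7mer-1a site of the neighbouring
    offset coincides with a planted site (an A on the target side can
    read as either the 1a-position or a complementary base), which would
    blur single-offset recovery.
    """
    rng = _stream(config, 2, 0)
    out = []
    three = [t for t in planted_trfs if t.trf_class is TRFClass.THREE_PRIME_CCA]
    for trf in three[:n_windows]:
        seq = trf.sequence
        max_offset = len(seq) - 6
        if offset is not None:
            off = min(offset, max_offset)
        else:
            valid = [
                o
                for o in range(1, max_offset + 1)
                if seq[o - 1] != "T" and (o == 1 or seq[o - 2] != "T")
            ]
            pool = valid or list(range(1, max_offset + 1))
            off = int(pool[int(rng.integers(len(pool)))])
        out.append(
            PlantedWindow(
                trf_id=trf.trf_id,
                offset=off,
                kmer=seq[off - 1 : off + 6],
            )
        )
    return out


_PLANT_CYCLE = (MatchType.M7_M8, MatchType.M7_1A, MatchType.M8_1A)


def simulate_utr_alignments(
    config: SimulationConfig, windows_to_plant: Sequence[PlantedWindow]
) -> tuple[list[UTRBlock], GroundTruth]:
    """Alignment blocks over the 23 taxa with planted conserved sites.

    Each planted window is inserted (as its target-site sequence,
    cycling through the three match types) at one shared column span in
    exactly ``conservation_k`` species — always including human, mouse
    and rat — of ``genes_per_window`` genes.  Everything else is i.i.d.
    background with the configured GC and gap rate.
    """
    taxa = list(TAXONOMY_IDS)
    gene_ids = [f"G{g + 1:04d}" for g in range(config.n_genes)]
    # assign planted windows to disjoint gene groups
    assignments: dict[str, list[tuple[PlantedWindow, MatchType]]] = {g: [] for g in gene_ids}
    cursor = 0
    planted_windows: list[PlantedWindow] = []
    truth = GroundTruth()
    for w_idx, window in enumerate(windows_to_plant):
        n_genes = config.genes_per_window
        if cursor + n_genes > len(gene_ids):
            raise DataError(
                f"not enough genes ({config.n_genes}) to plant "
                f"{len(windows_to_plant)} windows x {n_genes} genes"
            )
        chosen = gene_ids[cursor : cursor + n_genes]
        cursor += n_genes
        for g_idx, gene in enumerate(chosen):
            assignments[gene].append((window, _PLANT_CYCLE[g_idx % len(_PLANT_CYCLE)]))
        planted_windows.append(
            PlantedWindow(
                trf_id=window.trf_id,
                offset=window.offset,
                kmer=window.kmer,
                genes=tuple(chosen),
                conservation_k=window.conservation_k or config.conservation_k,
            )
        )
    truth.windows = planted_windows
    window_by_id = {(w.trf_id, w.offset): w for w in planted_windows}

    blocks: list[UTRBlock] = []
    for g_idx, gene in enumerate(gene_ids):
        rng = _stream(config, 2, 1, g_idx)
        n_cols = config.utr_length
        rows: dict[int, np.ndarray] = {}
        for tax in taxa:
            chars = rng.choice(_BASES, size=n_cols, p=_gc_p(config.gc_content))
            gaps = rng.random(n_cols) < config.gap_rate
            chars[gaps] = "-"
            rows[tax] = chars
        used: list[tuple[int, int]] = []
        for window, match_type in assignments[gene]:
            spec = window_by_id[(window.trf_id, window.offset)]
            site = site_variants(window.kmer)[match_type]
            span = _place_site(rng, n_cols, len(site), used)
            used.append(span)
            k = spec.conservation_k or config.conservation_k
            carriers = _pick_carriers(rng, taxa, k)
            for tax in taxa:
                segment = rows[tax][span[0] : span[1] + 1]
                if tax in carriers:
                    segment[:] = list(site)
                else:
                    # make sure non-carriers do not accidentally carry the site
                    if "".join(segment[segment != "-"]) == site:
                        pos = int(rng.integers(len(site)))
                        segment[pos] = rng.choice(
                            [b for b in "ACGT" if b != site[pos]]
                        )
            truth.site_species[gene] = sorted(carriers)
        blocks.append(
            UTRBlock(gene_id=gene, rows={t: "".join(rows[t]) for t in taxa})
        )
    return blocks, truth


def _gc_p(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _place_site(
    rng: np.random.Generator,
    n_cols: int,
    width: int,
    used: Sequence[tuple[int, int]],
    max_tries: int = 100,
) -> tuple[int, int]:
    for _ in range(max_tries):
        start = int(rng.integers(0, n_cols - width + 1))
        span = (start, start + width - 1)
        if all(span[1] < lo or span[0] > hi for lo, hi in used):
            return span
    raise DataError("could not place a site without collision")


def _pick_carriers(
    rng: np.random.Generator, taxa: Sequence[int], k: int
) -> frozenset[int]:
    trio = sorted(REQUIRED_TRIO)
    others = [t for t in taxa if t not in REQUIRED_TRIO]
    if k < len(trio):
        raise DataError(f"conservation_k={k} below the required trio size")
    extra = rng.choice(len(others), size=k - len(trio), replace=False)
    return frozenset(trio) | frozenset(others[i] for i in extra)


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    config: SimulationConfig,
    target_sets: Mapping[str, Sequence[str]],
    transcript_ids: Sequence[str] | None = None,
) -> tuple[ExpressionTable, GroundTruth]:
    """Expression table with planted target down-regulation.

    Background transcripts get an old/young ratio log-normal around 1
    (sigma ``ratio_sigma``); transcripts in any target set have the
    ratio scaled down by ``target_downregulation``.  Replicate noise is
    multiplicative log-normal with ``expression_noise_cv``.
    """
    rng = _stream(config, 3)
    if transcript_ids is None:
        ids = [f"T{i + 1:06d}" for i in range(config.n_transcripts)]
    else:
        ids = list(transcript_ids)
        if len(ids) != config.n_transcripts:
            raise DataError(
                f"transcript_ids length {len(ids)} != n_transcripts {config.n_transcripts}"
            )
    unknown = {
        t for ids_ in target_sets.values() for t in ids_ if t not in set(ids)
    }
    if unknown:
        raise DataError(f"target ids outside the transcriptome: {sorted(unknown)[:5]}")
    is_target = np.zeros(config.n_transcripts, dtype=bool)
    index = {t: i for i, t in enumerate(ids)}
    for members in target_sets.values():
        for t in members:
            is_target[index[t]] = True

    baseline = rng.lognormal(math.log(100.0), 1.0, size=config.n_transcripts)
    ratio = rng.lognormal(0.0, config.ratio_sigma, size=config.n_transcripts)
    ratio[is_target] *= 1.0 - config.target_downregulation

    tps = config.expression_timepoints
    cv = config.expression_noise_cv
    sigma = math.sqrt(math.log(1 + cv**2)) if cv > 0 else 0.0
    cols = {}
    for i, tp in enumerate(tps):
        frac = i / (len(tps) - 1) if len(tps) > 1 else 1.0
        tp_mean = baseline * ratio**frac  # geometric interpolation Y -> O
        for rep in range(1, config.n_replicates + 1):
            noise = (
                rng.lognormal(-(sigma**2) / 2, sigma, size=config.n_transcripts)
                if sigma > 0
                else 1.0
            )
            cols[(tp, str(rep))] = tp_mean * noise
    df = pd.DataFrame(cols, index=pd.Index(ids, name="transcript_id"))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["timepoint", "replicate"])
    table = ExpressionTable(data=df, timepoints=tuple(tps))
    truth = GroundTruth(
        target_sets={k: list(v) for k, v in target_sets.items()},
        target_downregulation=config.target_downregulation,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Background corpus for the genomic-frequency null


def simulate_background(
    config: SimulationConfig, n_sequences: int = 50, length: int = 2000
) -> list[str]:
    """Uniform-composition background sequences for the k-mer null."""
    rng = _stream(config, 4)
    return [_random_dna(rng, length) for _ in range(n_sequences)]
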