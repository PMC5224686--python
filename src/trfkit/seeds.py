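"""Conserved 7-mer seed discovery on tRFs against multi-species 3'UTRs.

Every 7-nt window of a tRF (slid 5'->3' by one nt) is turned into the
three canonical target-site variants used for miRNA seeds — 7mer-m8 (full
7-mer site), 7mer-1a (site for the first six window nucleotides followed
by an A on the target) and 8mer-1a (full 7-mer site followed by an A).
Under the default COMPLEMENTARY orientation the site is the reverse
complement of the window, i.e. the subsequence a transcript must carry to
base-pair with the tRF; a DIRECT orientation (literal window match) is
available since deposited pipelines differ on this point.

A site occurrence, anchored on the reference species (rat), counts as
conserved when the same sequence occupies the same alignment columns in
at least ``min_species`` of the 23 aligned vertebrates, always including
human, mouse and rat.  Observed per-gene counts are compared with two
nulls: the expectation from the site's background k-mer frequency, and
the mean count over all other 7-mers with the same nucleotide
composition.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sympy.utilities.iterables import multiset_permutations

from .io import (
    REFERENCE_SPECIES,
    REQUIRED_TRIO,
    TAXONOMY_IDS,
    DataError,
    MatchType,
    SiteRecord,
    UTRBlock,
    revcomp,
)

__all__ = [
    "SeedWindow",
    "ConservationRule",
    "SeedCallResult",
    "TargetSet",
    "ConservationIndex",
    "sliding_windows",
    "site_variants",
    "find_sites_in_block",
    "observed_count",
    "expected_genomic_count",
    "composition_null",
    "call_seed",
    "predict_targets",
    "seed_profile",
]


@dataclass(frozen=True)
class SeedWindow:
    """A 7-mer window on a tRF, 1-based ``offset`` from the 5' end."""

    trf_id: str
    offset: int
    kmer: str

    def __post_init__(self) -> None:
        if len(self.kmer) != 7:
            raise DataError(f"seed window must be 7 nt, got {self.kmer!r}")
        if self.offset < 1:
            raise DataError(f"window offset must be >= 1, got {self.offset}")


@dataclass(frozen=True)
class ConservationRule:
    """When does a site occurrence count as conserved?

    ``aligned_columns=True`` (default) requires the site to occupy the
    same alignment columns in each carrying species; ``False`` accepts a
    match anywhere in a species' ungapped UTR.
    """

    min_species: int = 15
    universe: tuple[int, ...] = TAXONOMY_IDS
    required: frozenset[int] = REQUIRED_TRIO
    aligned_columns: bool = True
    reference: int = REFERENCE_SPECIES

    def __post_init__(self) -> None:
        if not self.required <= set(self.universe):
            raise DataError("required species must be within the universe")
        if self.min_species > len(self.universe):
            raise DataError("min_species exceeds the species universe")


@dataclass
class SeedCallResult:
    """Observed conserved-site gene count for one window vs the two nulls."""

    window: SeedWindow
    observed: int
    expected_genomic: float
    composition_mean: float
    called: bool = False

    @property
    def enrichment_vs_expected(self) -> float:
        return self.observed / self.expected_genomic if self.expected_genomic else math.inf

    @property
    def enrichment_vs_composition(self) -> float:
        return self.observed / self.composition_mean if self.composition_mean else math.inf


@dataclass
class TargetSet:
    """Predicted target genes of a tRF, with every supporting site."""

    trf_id: str
    genes: frozenset[str]
    sites: tuple[SiteRecord, ...]


# ---------------------------------------------------------------------------
# Windows and site variants


def sliding_windows(trf_id: str, sequence: str) -> list[SeedWindow]:
    """All L-6 consecutive 7-mers of a tRF, 5'->3', offsets 1..L-6."""
    sequence = sequence.upper().replace("U", "T")
    if len(sequence) < 7:
        raise DataError(f"tRF {trf_id}: sequence shorter than 7 nt")
    return [
        SeedWindow(trf_id, i + 1, sequence[i : i + 7])
        for i in range(len(sequence) - 6)
    ]


def site_variants(kmer: str, orientation: str = "complementary") -> dict[MatchType, str]:
    """Target-site strings for one window under the chosen orientation.

    COMPLEMENTARY (default): 7mer-m8 = revcomp(window); 7mer-1a =
    revcomp(first 6 nt) + "A"; 8mer-1a = revcomp(window) + "A".  DIRECT
    replaces each reverse complement by the literal subsequence.
    """
    kmer = kmer.upper().replace("U", "T")
    if len(kmer) != 7 or set(kmer) - set("ACGT"):
        raise DataError(f"invalid 7-mer {kmer!r}")
    if orientation == "complementary":
        core7, core6 = revcomp(kmer), revcomp(kmer[:6])
    elif orientation == "direct":
        core7, core6 = kmer, kmer[:6]
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return {
        MatchType.M7_M8: core7,
        MatchType.M7_1A: core6 + "A",
        MatchType.M8_1A: core7 + "A",
    }


# ---------------------------------------------------------------------------
# Per-block site search


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i >= 0:
        yield i
        i = haystack.find(needle, i + 1)


def _column_map(gapped: str) -> list[int]:
    return [c for c, ch in enumerate(gapped) if ch != "-"]


def _carriers(
    block: UTRBlock, col_start: int, col_end: int, site: str, rule: ConservationRule
) -> frozenset[int]:
    """Species whose UTR carries ``site`` for this occurrence."""
    carriers = set()
    for tax_id, gapped in block.rows.items():
        if rule.aligned_columns:
            if gapped[col_start : col_end + 1].replace("-", "") == site:
                carriers.add(tax_id)
        else:
            if site in gapped.replace("-", ""):
                carriers.add(tax_id)
    return frozenset(carriers)


def find_sites_in_block(
    variants: Mapping[MatchType, str],
    block: UTRBlock,
    rule: ConservationRule,
    window_offset: int = 0,
) -> list[SiteRecord]:
    """Locate and conservation-score every variant occurrence in one block.

    Occurrences are anchored on the reference species' ungapped sequence;
    one record is emitted per conserved occurrence per variant, with both
    alignment-column (MSA) and ungapped UTR coordinates (1-based).
    """
    if rule.reference not in block.rows:
        warnings.warn(
            f"block {block.gene_id}: reference species {rule.reference} absent; skipped",
            stacklevel=2,
        )
        return []
    ref_gapped = block.rows[rule.reference]
    ref = ref_gapped.replace("-", "")
    colmap = _column_map(ref_gapped)
    records: list[SiteRecord] = []
    for match_type, site in variants.items():
        for i in _find_all(ref, site):
            c1, c2 = colmap[i], colmap[i + len(site) - 1]
            carriers = _carriers(block, c1, c2, site, rule)
            if len(carriers) >= rule.min_species and rule.required <= carriers:
                records.append(
                    SiteRecord(
                        gene_name=block.gene_id,
                        window_offset=window_offset,
                        msa_start=c1 + 1,
                        msa_end=c2 + 1,
                        utr_start=i + 1,
                        utr_end=i + len(site),
                        match_type=match_type,
                        species=carriers,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Fast conserved 7-mer index

_GAP = ord("-")


class ConservationIndex:
    """Precomputed map from 7-mer site sequence to genes carrying it conserved.

    Scans every reference-anchored 7-mer occurrence of every block once,
    so that per-window observed counts (and the thousands of counts a
    composition null needs) become dictionary lookups.  Column-anchored
    conservation reduces to per-column agreement with the reference row
    (a gap column must be a gap, a base column the same base), which
    vectorizes as a windowed all-equal over a byte matrix.
    """

    def __init__(self, blocks: Sequence[UTRBlock], rule: ConservationRule):
        self.rule = rule
        self.n_reference_positions = 0  # total 7-mer positions scanned
        self._genes: dict[str, set[str]] = defaultdict(set)
        for block in blocks:
            self._scan_block(block)

    def _scan_block(self, block: UTRBlock) -> None:
        rule = self.rule
        if rule.reference not in block.rows:
            warnings.warn(
                f"block {block.gene_id}: reference species {rule.reference} absent; skipped",
                stacklevel=2,
            )
            return
        ref_gapped = block.rows[rule.reference]
        ref = ref_gapped.replace("-", "")
        if len(ref) < 7:
            return
        self.n_reference_positions += len(ref) - 6
        colmap = np.array(_column_map(ref_gapped), dtype=np.intp)
        taxa = list(block.rows)
        required_idx = [taxa.index(t) for t in rule.required if t in block.rows]
        if len(required_idx) < len(rule.required):
            return  # a required species missing: nothing can be conserved
        if rule.aligned_columns:
            mat = np.frombuffer(
                "".join(block.rows[t] for t in taxa).encode(), dtype=np.uint8
            ).reshape(len(taxa), block.n_columns)
            ref_row = mat[taxa.index(rule.reference)]
            eq = np.cumsum(
                np.concatenate(
                    [np.zeros((len(taxa), 1), dtype=np.int64), (mat == ref_row).astype(np.int64)],
                    axis=1,
                ),
                axis=1,
            )
            c1 = colmap[:-6]
            c2 = colmap[6:]
            width = c2 - c1 + 1
            spans = eq[:, c2 + 1] - eq[:, c1]  # (n_species, n_positions)
            ok = spans == width
            n_carriers = ok.sum(axis=0)
            required_ok = ok[required_idx].all(axis=0)
            hit = (n_carriers >= rule.min_species) & required_ok
            for i in np.flatnonzero(hit):
                self._genes[ref[i : i + 7]].add(block.gene_id)
        else:
            kmer_sets = {
                t: {
                    s[j : j + 7]
                    for s in [block.rows[t].replace("-", "")]
                    for j in range(len(s) - 6)
                }
                for t in taxa
            }
            for i in range(len(ref) - 6):
                site = ref[i : i + 7]
                carriers = {t for t in taxa if site in kmer_sets[t]}
                if len(carriers) >= rule.min_species and rule.required <= carriers:
                    self._genes[site].add(block.gene_id)

    def genes_with_site(self, site7: str) -> frozenset[str]:
        """Genes with >=1 conserved occurrence of a 7-mer site sequence."""
        return frozenset(self._genes.get(site7, ()))


# ---------------------------------------------------------------------------
# Observed count and the two nulls


def observed_count(
    window: SeedWindow | str,
    blocks: Sequence[UTRBlock] | None,
    rule: ConservationRule,
    index: ConservationIndex | None = None,
    orientation: str = "complementary",
) -> int:
    """Distinct genes with >=1 conserved 7mer-m8 or 7mer-1a site.

    8mer-1a occurrences contain both 7-mer site types and are therefore
    covered automatically.  Supply a prebuilt :class:`ConservationIndex`
    to avoid rescanning blocks per window.
    """
    kmer = window.kmer if isinstance(window, SeedWindow) else window
    variants = site_variants(kmer, orientation)
    sites7 = (variants[MatchType.M7_M8], variants[MatchType.M7_1A])
    if index is None:
        if blocks is None:
            raise ValueError("either blocks or a ConservationIndex is required")
        index = ConservationIndex(blocks, rule)
    return len(index.genes_with_site(sites7[0]) | index.genes_with_site(sites7[1]))


def expected_genomic_count(
    window: SeedWindow | str,
    background: Sequence[str],
    blocks: Sequence[UTRBlock] | None,
    rule: ConservationRule,
    index: ConservationIndex | None = None,
    orientation: str = "complementary",
) -> float:
    """Chance expectation from the site's background k-mer frequency.

    f = per-position frequency of the 7mer-m8 site in ``background``;
    N = 7-mer positions scanned across reference UTRs; expectation = f*N.
    """
    if not background:
        raise DataError("empty background sequence set")
    kmer = window.kmer if isinstance(window, SeedWindow) else window
    site = site_variants(kmer, orientation)[MatchType.M7_M8]
    occurrences = 0
    positions = 0
    for seq in background:
        seq = seq.upper().replace("U", "T")
        positions += max(len(seq) - 6, 0)
        occurrences += sum(1 for _ in _find_all(seq, site))
    if positions == 0:
        raise DataError("background contains no 7-mer positions")
    if occurrences == 0:
        warnings.warn(
            f"site {site} absent from background; expectation floored at 0",
            stacklevel=2,
        )
    if index is None:
        if blocks is None:
            raise ValueError("either blocks or a ConservationIndex is required")
        index = ConservationIndex(blocks, rule)
    return occurrences / positions * index.n_reference_positions


def composition_null(
    window: SeedWindow | str,
    blocks: Sequence[UTRBlock] | None,
    rule: ConservationRule,
    index: ConservationIndex | None = None,
    orientation: str = "complementary",
    exclude_self: bool = True,
) -> float:
    """Mean observed count over all other same-composition 7-mers.

    Enumerates every distinct permutation of the window's nucleotide
    multiset (<= 5040).  The observed window itself is excluded by
    default; a single-permutation composition falls back to including it,
    with a warning.
    """
    kmer = window.kmer if isinstance(window, SeedWindow) else window
    if index is None:
        if blocks is None:
            raise ValueError("either blocks or a ConservationIndex is required")
        index = ConservationIndex(blocks, rule)
    perms = ["".join(p) for p in multiset_permutations(sorted(kmer))]
    pool = [p for p in perms if p != kmer] if exclude_self else perms
    if not pool:
        warnings.warn(
            f"window {kmer}: single-permutation composition; including self in null",
            stacklevel=2,
        )
        pool = perms
    counts = [
        observed_count(p, None, rule, index=index, orientation=orientation)
        for p in pool
    ]
    return float(np.mean(counts))


def call_seed(
    result: SeedCallResult, call_ratio: float = 2.0, min_genes: int = 25
) -> bool:
    """Call a window a candidate seed when the observed count clears both
    nulls by ``call_ratio``-fold and reaches ``min_genes`` genes."""
    return (
        result.observed >= min_genes
        and result.observed >= call_ratio * result.expected_genomic
        and result.observed >= call_ratio * result.composition_mean
    )


# ---------------------------------------------------------------------------
# Profiles and target prediction


def seed_profile(
    trf_id: str,
    trf_sequence: str,
    blocks: Sequence[UTRBlock],
    background: Sequence[str],
    rule: ConservationRule | None = None,
    orientation: str = "complementary",
    call_ratio: float = 2.0,
    min_genes: int = 25,
    index: ConservationIndex | None = None,
) -> list[SeedCallResult]:
    """Per-offset (observed, expected, composition-null) triples for a tRF."""
    rule = rule or ConservationRule()
    if index is None:
        index = ConservationIndex(blocks, rule)
    results = []
    for window in sliding_windows(trf_id, trf_sequence):
        obs = observed_count(window, None, rule, index=index, orientation=orientation)
        exp = expected_genomic_count(
            window, background, None, rule, index=index, orientation=orientation
        )
        comp = composition_null(
            window, None, rule, index=index, orientation=orientation
        )
        res = SeedCallResult(window, obs, exp, comp)
        res.called = call_seed(res, call_ratio, min_genes)
        results.append(res)
    return results


def predict_targets(
    called_windows: Sequence[SeedWindow],
    blocks: Sequence[UTRBlock],
    rule: ConservationRule | None = None,
    orientation: str = "complementary",
    trf_id: str | None = None,
) -> TargetSet:
    """Union of genes with a conserved 7mer-m8 or 7mer-1a site for any
    called window, with the full site-record list (8mer-1a included)."""
    rule = rule or ConservationRule()
    if not called_windows:
        raise DataError("no called windows")
    trf_id = trf_id or called_windows[0].trf_id
    sites: list[SiteRecord] = []
    genes: set[str] = set()
    for window in called_windows:
        variants = site_variants(window.kmer, orientation)
        for block in blocks:
            recs = find_sites_in_block(variants, block, rule, window.offset)
            sites.extend(recs)
            genes.update(
                r.gene_name
                for r in recs
                if r.match_type in (MatchType.M7_M8, MatchType.M7_1A)
            )
    sites.sort(key=lambda r: (r.gene_name, r.window_offset, r.utr_start, r.match_type.value))
    return TargetSet(trf_id=trf_id, genes=frozenset(genes), sites=tuple(sites))
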