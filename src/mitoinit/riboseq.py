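"""Mitoribosome-profiling footprint quantification.

Counting rules for mitochondrial ribosome-protected fragments (mt-RPFs):
footprints of 30-35 nt (inclusive) are assigned to a gene by their 5' end
only, when that end lies in the positive-sense orientation inside the
gene's counting window — from the first nucleotide of the start codon to
30 nt 5' of the stop codon, half-open. Regions where ORFs overlap in the
bicistronic ATP8/ATP6 (46 nt) and ND4L/ND4 (7 nt) transcripts are excluded
from all gene counts because assignment there is ambiguous; such reads are
tallied separately so that counted + excluded + unassigned always equals
the input size. Per-gene counts are expressed as percent of total counted
mt-RPFs in the library, and libraries are compared as per-gene percent
ratios (knockout over wild type).

A synthetic footprint generator draws reads from per-gene weights
(multinomial occupancy profile), with a preset emulating the mtIF3
knockout in which ATP6 occupancy collapses and ATP8 occupancy rises.
All coordinates are 0-based, intervals half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousAnnotationError,
    InvalidConfigError,
    InvalidInputError,
    UndefinedResultError,
)

__all__ = [
    "MitoGeneModel",
    "OverlapRegion",
    "AlignedFootprint",
    "RpfTable",
    "filter_by_length",
    "counting_window",
    "assign_footprints",
    "percent_of_total",
    "compare_libraries",
    "simulate_footprints",
    "human_mt_genes",
    "human_mt_overlaps",
    "wt_weights",
    "mtif3_ko_weights",
    "MIN_FOOTPRINT_LEN",
    "MAX_FOOTPRINT_LEN",
    "STOP_STANDOFF_NT",
]

MIN_FOOTPRINT_LEN = 30
MAX_FOOTPRINT_LEN = 35
#: Counting windows end this many nt 5' of the stop codon.
STOP_STANDOFF_NT = 30


@dataclass(frozen=True)
class MitoGeneModel:
    """One mitochondrial ORF.

    ``start`` is the 0-based position of the first nucleotide of the start
    codon, ``stop_first`` that of the stop codon; on the minus strand the
    gene runs toward decreasing coordinates so ``start > stop_first``.
    """

    gene: str
    start: int
    stop_first: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvalidInputError(f"strand must be +/-, got {self.strand!r}")
        s, e = self.window
        if s >= e:
            raise InvalidInputError(
                f"gene {self.gene}: counting window empty "
                f"(start={self.start}, stop_first={self.stop_first})")

    @property
    def window(self) -> tuple[int, int]:
        """Genomic half-open counting window [start codon, stop - 30 nt)."""
        return counting_window(self.start, self.stop_first, self.strand)

    @property
    def orf_interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.start, self.stop_first + 3
        return self.stop_first - 2, self.start + 1


def counting_window(start: int, stop_first: int, strand: str
                    ) -> tuple[int, int]:
    """The half-open genomic interval of 5'-end positions counted for a
    gene: from the first nucleotide of the start codon up to (excluding)
    30 nt 5' of the stop codon, in the gene's reading direction.

    The far-boundary convention (exclusive) is isolated here.
    """
    if strand == "+":
        return start, stop_first - STOP_STANDOFF_NT
    # minus strand: reading direction is decreasing genomic coordinates
    return stop_first + STOP_STANDOFF_NT + 1, start + 1


@dataclass(frozen=True)
class OverlapRegion:
    """An interval shared by two overlapping ORFs, excluded from counting."""

    gene_pair: tuple[str, str]
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InvalidInputError("overlap interval must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedFootprint:
    """One aligned mt-RPF, reduced to the fields the counting rules use."""

    five_prime_pos: int
    length: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InvalidInputError("footprint length must be > 0")
        if self.strand not in ("+", "-"):
            raise InvalidInputError(f"strand must be +/-, got {self.strand!r}")


@dataclass
class RpfTable:
    """Per-gene footprint counts and derived percentages.

    ``excluded`` tallies reads whose 5' end fell in an overlap region;
    ``unassigned`` everything matching no counting window. Percentages are
    over counted genes only and sum to 100 when the total is positive.
    """

    counts: dict[str, int]
    excluded: int = 0
    unassigned: int = 0
    percent: dict[str, float] | None = None
    ratio_to_reference: dict[str, float] | None = None
    flagged_genes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def total_counted(self) -> int:
        return sum(self.counts.values())

    @property
    def total_input(self) -> int:
        return self.total_counted + self.excluded + self.unassigned

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.counts:
            rows.append({
                "gene": gene,
                "count": self.counts[gene],
                "percent": self.percent.get(gene) if self.percent else np.nan,
                "ratio_to_reference": (self.ratio_to_reference.get(gene)
                                       if self.ratio_to_reference else np.nan),
            })
        return pd.DataFrame(rows)


def filter_by_length(footprints, min_len: int = MIN_FOOTPRINT_LEN,
                     max_len: int = MAX_FOOTPRINT_LEN) -> list[AlignedFootprint]:
    """Keep footprints with min_len <= length <= max_len (both inclusive),
    preserving order."""
    if min_len > max_len:
        raise InvalidConfigError(
            f"min_len {min_len} exceeds max_len {max_len}")
    return [fp for fp in footprints if min_len <= fp.length <= max_len]


def _effective_segments(gene: MitoGeneModel,
                        overlaps: list[OverlapRegion]) -> list[tuple[int, int]]:
    """The gene's counting window minus all overlap intervals."""
    s, e = gene.window
    segments = [(s, e)]
    for ov in overlaps:
        out = []
        for a, b in segments:
            if ov.end <= a or ov.start >= b:
                out.append((a, b))
                continue
            if a < ov.start:
                out.append((a, ov.start))
            if ov.end < b:
                out.append((ov.end, b))
        segments = out
    return [(a, b) for a, b in segments if b > a]


def _validate_disjoint(genes, overlaps) -> None:
    per_strand: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        for a, b in _effective_segments(g, overlaps):
            per_strand.setdefault(g.strand, []).append((a, b, g.gene))
    for strand, segs in per_strand.items():
        segs.sort()
        for (a1, b1, g1), (a2, b2, g2) in zip(segs, segs[1:]):
            if a2 < b1:
                raise AmbiguousAnnotationError(
                    f"counting windows of {g1} and {g2} overlap on strand "
                    f"{strand} in [{a2}, {min(b1, b2)}) without a declared "
                    "overlap region")


def assign_footprints(footprints, genes, overlaps=()) -> RpfTable:
    """Count footprints per gene by the 5'-end rule.

    A footprint is counted for gene g iff its strand matches g and its 5'
    end lies in g's counting window minus all overlap intervals. A 5' end
    inside a declared overlap interval (on the overlapping genes' strand)
    goes to the ``excluded`` tally; anything else is ``unassigned``.
    counted + excluded + unassigned equals the input size.
    """
    genes = list(genes)
    overlaps = list(overlaps)
    _validate_disjoint(genes, overlaps)

    gene_strands = {g.gene: g.strand for g in genes}
    counts = {g.gene: 0 for g in genes}
    # lookup tables: per strand, sorted segment boundaries -> gene index
    lookup: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for strand in set(g.strand for g in genes):
        segs = []
        for g in genes:
            if g.strand != strand:
                continue
            for a, b in _effective_segments(g, overlaps):
                segs.append((a, b, g.gene))
        segs.sort()
        lookup[strand] = (np.array([s[0] for s in segs], dtype=np.int64),
                          np.array([s[1] for s in segs], dtype=np.int64),
                          [s[2] for s in segs])

    excl: list[tuple[int, int, str]] = []
    for ov in overlaps:
        strands = {gene_strands.get(g) for g in ov.gene_pair}
        strands.discard(None)
        strand = strands.pop() if len(strands) == 1 else "+"
        excl.append((ov.start, ov.end, strand))

    excluded = 0
    unassigned = 0
    for fp in footprints:
        pos = fp.five_prime_pos
        if any(a <= pos < b and fp.strand == s for a, b, s in excl):
            excluded += 1
            continue
        hit = None
        tab = lookup.get(fp.strand)
        if tab is not None:
            starts, ends, names = tab
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and pos < ends[i]:
                hit = names[i]
        if hit is None:
            unassigned += 1
        else:
            counts[hit] += 1
    return RpfTable(counts=counts, excluded=excluded, unassigned=unassigned)


def percent_of_total(table: RpfTable) -> RpfTable:
    """Express per-gene counts as percent of total counted mt-RPFs in the
    library; excluded and unassigned reads are not in the denominator."""
    total = table.total_counted
    if total == 0:
        raise UndefinedResultError("empty library: no counted footprints")
    percent = {g: 100.0 * c / total for g, c in table.counts.items()}
    return replace(table, percent=percent)


def compare_libraries(test: RpfTable, reference: RpfTable) -> RpfTable:
    """Per-gene ratio of percentages, test over reference (e.g. knockout
    over wild type). Genes with zero reference percent are flagged and get
    a NaN ratio rather than a division."""
    if set(test.counts) != set(reference.counts):
        raise InvalidInputError(
            "libraries cover different gene sets: "
            f"{sorted(set(test.counts) ^ set(reference.counts))}")
    t = test if test.percent is not None else percent_of_total(test)
    r = reference if reference.percent is not None else percent_of_total(reference)
    ratios: dict[str, float] = {}
    flagged: list[str] = []
    for gene in t.counts:
        if r.percent[gene] == 0:
            ratios[gene] = float("nan")
            flagged.append(gene)
        else:
            ratios[gene] = t.percent[gene] / r.percent[gene]
    return replace(t, ratio_to_reference=ratios, flagged_genes=tuple(flagged))


def simulate_footprints(genes, overlaps, per_gene_weights: dict[str, float],
                        n: int, seed: int = 0,
                        overlap_leak_prob: float = 0.0
                        ) -> list[AlignedFootprint]:
    """Draw ``n`` synthetic footprints from a multinomial occupancy profile.

    The gene of each footprint is sampled from the normalized weights, the
    5' position uniformly over that gene's counting window (overlap
    intervals re-included with probability ``overlap_leak_prob``), the
    length uniformly in {30..35}; strand follows the gene. Deterministic
    for a given seed.
    """
    genes = list(genes)
    overlaps = list(overlaps)
    by_name = {g.gene: g for g in genes}
    names = [g for g in per_gene_weights if per_gene_weights[g] > 0]
    w = np.array([per_gene_weights[g] for g in names], dtype=float)
    if (np.array(list(per_gene_weights.values())) < 0).any():
        raise InvalidConfigError("weights must be >= 0")
    if len(names) == 0 or w.sum() == 0:
        raise InvalidConfigError("weights must not be all zero")
    unknown = set(names) - set(by_name)
    if unknown:
        raise InvalidInputError(f"weights name unknown genes: {sorted(unknown)}")

    segments: dict[str, list[tuple[int, int]]] = {}
    full_windows: dict[str, list[tuple[int, int]]] = {}
    for name in names:
        g = by_name[name]
        segments[name] = _effective_segments(g, overlaps)
        full_windows[name] = [g.window]
        if not segments[name]:
            raise InvalidConfigError(
                f"gene {name}: counting window empty after overlap removal")

    rng = np.random.default_rng(seed)
    gene_idx = rng.choice(len(names), size=n, p=w / w.sum())
    lengths = rng.integers(MIN_FOOTPRINT_LEN, MAX_FOOTPRINT_LEN + 1, size=n)
    leak = (rng.random(n) < overlap_leak_prob if overlap_leak_prob > 0
            else np.zeros(n, dtype=bool))

    footprints: list[AlignedFootprint] = []
    for i in range(n):
        name = names[gene_idx[i]]
        segs = full_windows[name] if leak[i] else segments[name]
        seg_lens = np.array([b - a for a, b in segs], dtype=float)
        j = rng.choice(len(segs), p=seg_lens / seg_lens.sum()) if len(segs) > 1 else 0
        a, b = segs[j]
        pos = int(rng.integers(a, b))
        footprints.append(AlignedFootprint(pos, int(lengths[i]),
                                           by_name[name].strand))
    return footprints


def _read_packaged_tsv(name: str) -> pd.DataFrame:
    with resources.files("mitoinit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def human_mt_genes() -> list[MitoGeneModel]:
    """The 13 protein-coding ORFs of the human mitochondrial genome
    (rCRS coordinates), packaged as a text fixture."""
    df = _read_packaged_tsv("human_mt_annotation.tsv")
    return [MitoGeneModel(r.gene, int(r.start), int(r.stop_first), r.strand)
            for r in df.itertuples()]


def human_mt_overlaps() -> list[OverlapRegion]:
    """The ATP8/ATP6 (46 nt) and ND4L/ND4 (7 nt) bicistronic overlaps."""
    df = _read_packaged_tsv("human_mt_overlaps.tsv")
    return [OverlapRegion((r.gene_a, r.gene_b), int(r.start), int(r.end))
            for r in df.itertuples()]


def wt_weights(genes=None, overlaps=None) -> dict[str, float]:
    """Wild-type occupancy preset: uniform footprint density, so each
    gene's weight is its effective counting-window length."""
    genes = list(genes) if genes is not None else human_mt_genes()
    overlaps = list(overlaps) if overlaps is not None else human_mt_overlaps()
    return {g.gene: float(sum(b - a for a, b in
                              _effective_segments(g, overlaps)))
            for g in genes}


def mtif3_ko_weights(genes=None, overlaps=None,
                     atp6_factor: float = 0.1,
                     atp8_factor: float = 1.6) -> dict[str, float]:
    """mtIF3-knockout occupancy preset: ATP6 occupancy collapses while
    ribosomes accumulate on the upstream ATP8 ORF."""
    w = wt_weights(genes, overlaps)
    if "ATP6" in w:
        w["ATP6"] *= atp6_factor
    if "ATP8" in w:
        w["ATP8"] *= atp8_factor
    return w
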