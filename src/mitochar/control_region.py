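"""Scanners for conserved control-region elements and spacer motifs: fixed
motifs, homopolymer stretches, perfect microsatellites and tandem repeats.

Only perfect repeats are detected.  A repeat array is reported for a unit of
size k when the region has period k over a maximal stretch, the unit is
primitive (not itself a repetition), and the copy number (stretch length / k,
possibly fractional for a partial final unit) reaches the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

from .genome_model import AnnotatedGenome, SequenceUnavailableError, reverse_complement
from .gene_topology import pair_ledger

_CONTEXT_WIDTH = 5


@dataclass(frozen=True)
class MotifHit:
    motif: str
    strand: str  # "F" | "R"
    start: int  # 1-based inclusive, F-strand coordinates of the region
    end: int
    context: str = ""


@dataclass(frozen=True)
class RepeatHit:
    unit: str
    copies: float
    start: int  # 1-based inclusive
    end: int
    kind: str  # "homopolymer" | "microsatellite" | "tandem"
    strand: str = "F"


@dataclass(frozen=True)
class MotifPolyTHit:
    """An anchor motif followed (within a small offset) by a poly-T stretch."""

    motif_hit: MotifHit
    poly_t: Optional[RepeatHit]
    poly_t_len: int


def _canonical_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return False
    return True


def find_motif(region: str, motif: str, both_strands: bool = False) -> list[MotifHit]:
    """All (possibly overlapping) exact occurrences of ``motif``.

    F-strand hits first; R-strand hit coordinates are mapped back to the
    F strand, so slicing the region at [start, end] and reverse-complementing
    recovers the motif.
    """
    motif = motif.upper()
    if len(motif) < 3:
        raise ValueError("motif must be at least 3 bp")
    if set(motif) - set("ACGT"):
        raise ValueError(f"ambiguous characters in motif {motif!r}")
    region = region.upper()
    n = len(region)
    hits: list[MotifHit] = []

    def scan(s: str) -> list[int]:
        found, i = [], s.find(motif)
        while i != -1:
            found.append(i)
            i = s.find(motif, i + 1)
        return found

    for i in scan(region):
        hits.append(
            MotifHit(
                motif=motif,
                strand="F",
                start=i + 1,
                end=i + len(motif),
                context=region[max(0, i - _CONTEXT_WIDTH) : i + len(motif) + _CONTEXT_WIDTH],
            )
        )
    if both_strands:
        rc = reverse_complement(region)
        for i in scan(rc):
            start = n - (i + len(motif)) + 1
            hits.append(
                MotifHit(
                    motif=motif,
                    strand="R",
                    start=start,
                    end=n - i,
                    context=rc[max(0, i - _CONTEXT_WIDTH) : i + len(motif) + _CONTEXT_WIDTH],
                )
            )
    return hits


def _run_length(s: str, pos: int, base: str) -> int:
    j = pos
    while j < len(s) and s[j] == base:
        j += 1
    return j - pos


def find_motif_poly_t(
    region: str,
    motif: str = "ATAGA",
    threshold: int = 10,
    max_offset: int = 2,
    both_strands: bool = True,
) -> Optional[MotifPolyTHit]:
    """First occurrence of ``motif`` whose downstream T-run (allowing a
    0..max_offset bp gap) reaches ``threshold``; None when absent.

    The F strand is scanned first, then the reverse strand; reverse-strand
    coordinates are mapped back to F-strand positions.
    """
    region = region.upper()
    n = len(region)
    strands = ["F", "R"] if both_strands else ["F"]
    for strand in strands:
        s = region if strand == "F" else reverse_complement(region)
        i = s.find(motif)
        while i != -1:
            tail = i + len(motif)
            best_off, best_len = 0, -1
            for off in range(0, max_offset + 1):
                run = _run_length(s, tail + off, "T")
                if run > best_len:
                    best_off, best_len = off, run
            if best_len >= threshold:
                local_m = (i + 1, i + len(motif))
                local_t = (tail + best_off + 1, tail + best_off + best_len)

                def map_back(lo: int, hi: int) -> tuple[int, int]:
                    if strand == "F":
                        return lo, hi
                    return n - hi + 1, n - lo + 1

                m_start, m_end = map_back(*local_m)
                motif_hit = MotifHit(motif, strand, m_start, m_end)
                poly_t = None
                if best_len > 0:
                    t_start, t_end = map_back(*local_t)
                    poly_t = RepeatHit("T", float(best_len), t_start, t_end, "homopolymer", strand)
                return MotifPolyTHit(motif_hit, poly_t, best_len)
            i = s.find(motif, i + 1)
    return None


def longest_homopolymer(region: str, base: str) -> Optional[RepeatHit]:
    """Maximal run of ``base``; ties broken by first occurrence; None if absent."""
    region = region.upper()
    base = base.upper()
    best_start, best_len = -1, 0
    i = 0
    while i < len(region):
        if region[i] == base:
            run = _run_length(region, i, base)
            if run > best_len:
                best_start, best_len = i, run
            i += run
        else:
            i += 1
    if best_len == 0:
        return None
    return RepeatHit(base, float(best_len), best_start + 1, best_start + best_len, "homopolymer")


def _maximal_periodic_runs(region: str, k: int) -> list[tuple[int, int]]:
    """(start0, length) of maximal stretches with period k (0-based)."""
    n = len(region)
    runs = []
    i = 0
    while i + k < n:
        if region[i] == region[i + k]:
            j = i
            while j + k < n and region[j] == region[j + k]:
                j += 1
            # matched pairs i..j-1, so the periodic stretch covers i..j+k-1
            length = (j + k) - i
            # left-maximality: the scan only lands here when pair i-1 failed
            if i == 0 or region[i - 1] != region[i - 1 + k]:
                runs.append((i, length))
            i = j + 1
        else:
            i += 1
    return runs


def _repeat_hits(region: str, k: int, min_copies: float, kind: str) -> list[RepeatHit]:
    hits = []
    for start0, length in _maximal_periodic_runs(region, k):
        unit = region[start0 : start0 + k]
        if not _is_primitive(unit):
            continue
        copies = length / k
        if copies < min_copies:
            continue
        hits.append(
            RepeatHit(
                unit=_canonical_rotation(unit),
                copies=copies,
                start=start0 + 1,
                end=start0 + length,
                kind=kind if k > 1 else "homopolymer",
            )
        )
    return hits


def find_microsatellites(
    region: str, unit_sizes: Iterable[int] = (1, 2, 3), min_copies: int = 3
) -> list[RepeatHit]:
    """Maximal perfect tandem arrays of any unit of the given sizes.

    Homopolymers are reported only under unit size 1 (larger units must be
    primitive).  The reported unit is the lexicographically least rotation.
    """
    region = region.upper()
    if min_copies < 1:
        raise ValueError("min_copies must be >= 1")
    hits: list[RepeatHit] = []
    for k in sorted(set(unit_sizes)):
        if k < 1:
            raise ValueError("unit sizes must be >= 1")
        hits.extend(_repeat_hits(region, k, min_copies, "microsatellite"))
    hits.sort(key=lambda h: (h.start, len(h.unit)))
    return hits


def find_tandem_repeats(
    region: str, min_unit: int = 2, max_unit: int = 6, min_copies: int = 3
) -> list[RepeatHit]:
    """Perfect tandem arrays for unit lengths in [min_unit, max_unit].

    Nested reports are suppressed: a hit whose span lies inside the span of a
    kept hit with a longer unit is dropped (longest unit wins, then leftmost).
    """
    region = region.upper()
    if max_unit > len(region):
        warnings.warn(
            f"max_unit {max_unit} exceeds region length {len(region)}; clamped"
        )
        max_unit = len(region)
    candidates: list[RepeatHit] = []
    for k in range(min_unit, max_unit + 1):
        candidates.extend(_repeat_hits(region, k, min_copies, "tandem"))
    candidates.sort(key=lambda h: (-len(h.unit), h.start))
    kept: list[RepeatHit] = []
    for hit in candidates:
        if any(o.start <= hit.start and hit.end <= o.end for o in kept):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (h.start, len(h.unit)))
    return kept


def _to_genome_coords(region_start: int, local: int, genome_length: int) -> int:
    """Map a 1-based position inside a region starting at ``region_start``
    (1-based, circular) to a genome coordinate."""
    return (region_start - 1 + local - 1) % genome_length + 1


def spacer_motif_report(
    genome: AnnotatedGenome,
    motifs: Iterable[str] = ("ATACTAA", "ATGATAA"),
    min_spacer: int = 5,
    poly_t_threshold: int = 10,
    microsat_min_copies: int = 5,
):
    """Scan spacers for fixed motifs and the A+T-rich region for its
    conserved elements; one row per hit, genome F-strand coordinates."""
    import pandas as pd

    if genome.sequence is None:
        raise SequenceUnavailableError("spacer_motif_report requires a sequence")
    rows = []
    motifs = list(motifs)

    def add(region_label, region_start, kind, label, copies, hit_strand, s, e):
        rows.append(
            {
                "Region": region_label,
                "Kind": kind,
                "Motif": label,
                "Copies": copies,
                "Strand": hit_strand,
                "Start": _to_genome_coords(region_start, s, genome.length),
                "End": _to_genome_coords(region_start, e, genome.length),
            }
        )

    for entry in pair_ledger(genome, source="coordinates"):
        if entry.gap < min_spacer:
            continue
        up = genome.record(entry.upstream_gene)
        spacer_start = up.end % genome.length + 1
        region = "".join(
            genome.sequence[(up.end + i) % genome.length] for i in range(entry.gap)
        )
        label = f"spacer:{entry.upstream_gene}-{entry.downstream_gene}"
        for motif in motifs:
            for hit in find_motif(region, motif, both_strands=True):
                add(label, spacer_start, "motif", motif, None, hit.strand, hit.start, hit.end)

    for rec in genome.records_of_class("control_region"):
        region = genome.sequence[rec.start - 1 : rec.end] if not rec.wraps else (
            genome.sequence[rec.start - 1 :] + genome.sequence[: rec.end]
        )
        label = f"control_region:{rec.name}"
        composite = find_motif_poly_t(region, threshold=poly_t_threshold)
        if composite is not None:
            mh = composite.motif_hit
            add(label, rec.start, "motif", mh.motif, None, mh.strand, mh.start, mh.end)
            if composite.poly_t is not None:
                pt = composite.poly_t
                add(label, rec.start, "homopolymer", "T", pt.copies, pt.strand, pt.start, pt.end)
        for hit in find_microsatellites(region, unit_sizes=(2,), min_copies=microsat_min_copies):
            add(label, rec.start, hit.kind, hit.unit, hit.copies, hit.strand, hit.start, hit.end)
        poly_a = longest_homopolymer(region, "A")
        if poly_a is not None:
            add(label, rec.start, "homopolymer", "A", poly_a.copies, "F", poly_a.start, poly_a.end)
    return pd.DataFrame(
        rows, columns=["Region", "Kind", "Motif", "Copies", "Strand", "Start", "End"]
    )
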