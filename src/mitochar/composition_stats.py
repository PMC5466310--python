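"""Base composition, A+T content, and strand-skew statistics per region class.

AT skew = (A - T) / (A + T); GC skew = (G - C) / (G + C), computed on the
majority (F) strand.  Percentages use unambiguous bases only; ambiguous
bases are counted separately.  Rounding (2 decimals for percentages,
3 for skews) happens only in the report layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome_model import AnnotatedGenome, SequenceUnavailableError

PANELS = ["Whole genome", "PCG", "tRNA", "rRNA", "A+T-rich region"]
_PANEL_CLASS = {
    "PCG": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "A+T-rich region": "control_region",
}

REPORT_COLUMNS = [
    "Species",
    "Panel",
    "Size",
    "A",
    "G",
    "T",
    "C",
    "AT",
    "ATskew",
    "GCskew",
]


@dataclass(frozen=True)
class Composition:
    """Counts and derived statistics for one sequence (class)."""

    n: int  # total length including ambiguous bases
    count_a: int
    count_t: int
    count_g: int
    count_c: int
    n_ambiguous: int = 0

    @property
    def n_unambiguous(self) -> int:
        return self.count_a + self.count_t + self.count_g + self.count_c

    @property
    def pct_a(self) -> float:
        return 100.0 * self.count_a / self.n_unambiguous

    @property
    def pct_t(self) -> float:
        return 100.0 * self.count_t / self.n_unambiguous

    @property
    def pct_g(self) -> float:
        return 100.0 * self.count_g / self.n_unambiguous

    @property
    def pct_c(self) -> float:
        return 100.0 * self.count_c / self.n_unambiguous

    @property
    def pct_at(self) -> float:
        return self.pct_a + self.pct_t

    @property
    def at_skew(self) -> float:
        return skew(self.count_a, self.count_t)

    @property
    def gc_skew(self) -> float:
        return skew(self.count_g, self.count_c)


def skew(x: float, y: float) -> float:
    """Strand skew (x - y) / (x + y); also applicable to printed percentages."""
    if x + y == 0:
        raise ValueError("skew undefined: x + y = 0")
    return (x - y) / (x + y)


def base_composition(seq: str) -> Composition:
    """Composition of a nucleotide string (case-insensitive)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    a = seq.count("A")
    t = seq.count("T")
    g = seq.count("G")
    c = seq.count("C")
    unambiguous = a + t + g + c
    if unambiguous == 0:
        raise ValueError("all-ambiguous sequence: skews undefined")
    return Composition(
        n=len(seq),
        count_a=a,
        count_t=t,
        count_g=g,
        count_c=c,
        n_ambiguous=len(seq) - unambiguous,
    )


def region_composition(genome: AnnotatedGenome, region_class: str) -> Composition:
    """Composition of the whole F strand or of one feature class.

    Class slices are taken on the F strand regardless of gene strand, and
    overlapping coverage is counted once per feature, so class length sums
    match per-class totals of printed comparison tables.
    """
    if genome.sequence is None:
        raise SequenceUnavailableError(
            f"region_composition requires a sequence for {genome.identifier}"
        )
    if region_class == "whole":
        return base_composition(genome.sequence)
    records = genome.records_of_class(region_class)
    if not records:
        raise ValueError(f"genome {genome.identifier} has no features of class {region_class!r}")
    seq = genome.sequence
    pieces = []
    for rec in records:
        if rec.wraps:
            pieces.append(seq[rec.start - 1 :] + seq[: rec.end])
        else:
            pieces.append(seq[rec.start - 1 : rec.end])
    return base_composition("".join(pieces))


def class_length_summary(genome: AnnotatedGenome) -> dict[str, int]:
    """Summed feature lengths per class from coordinates (table-only safe)."""
    from .genome_model import gene_length

    out: dict[str, int] = {}
    for rec in genome.records:
        out[rec.feature_class] = out.get(rec.feature_class, 0) + gene_length(
            rec, genome.length
        )
    return out


def composition_row(identifier: str, panel: str, comp: Composition) -> dict:
    return {
        "Species": identifier,
        "Panel": panel,
        "Size": comp.n,
        "A": round(comp.pct_a, 2),
        "G": round(comp.pct_g, 2),
        "T": round(comp.pct_t, 2),
        "C": round(comp.pct_c, 2),
        "AT": round(comp.pct_at, 2),
        "ATskew": round(comp.at_skew, 3),
        "GCskew": round(comp.gc_skew, 3),
    }


def composition_report(genomes) -> pd.DataFrame:
    """One row per genome per panel, in the printed comparison-table layout."""
    rows = []
    for genome in genomes:
        for panel in PANELS:
            region = _PANEL_CLASS.get(panel, "whole")
            try:
                comp = region_composition(genome, region)
            except ValueError:
                continue  # class absent in this genome
            rows.append(composition_row(genome.identifier, panel, comp))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
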