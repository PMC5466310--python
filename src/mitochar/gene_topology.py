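"""Adjacent-gene ledger (overlaps and intergenic spacers), summary statistics,
and circular gene-order comparison by breakpoint counting.

Gap sign convention: negative = overlap, positive = spacer, zero = abutting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .genome_model import AnnotatedGenome, GeneRecord, SequenceUnavailableError


@dataclass(frozen=True)
class PairLedgerEntry:
    upstream_gene: str
    downstream_gene: str
    gap: int
    source: str  # "printed" | "coordinates"


@dataclass
class TopologySummary:
    n_overlaps: int
    overlap_total_bp: int
    overlap_max_bp: int
    overlap_max_pair: Optional[tuple[str, str]]
    n_spacers: int
    spacer_total_bp: int
    spacer_max_bp: int
    spacer_max_pair: Optional[tuple[str, str]]
    n_major_spacers: int  # spacers >= major_cutoff bp
    major_cutoff: int = 10


def pair_ledger(
    genome: AnnotatedGenome,
    source: str = "printed",
    include_closing: bool = True,
) -> list[PairLedgerEntry]:
    """One entry per adjacent feature pair in genome order.

    printed mode: copies the intergenic-nucleotides column, attributed to the
    row's gene as the upstream member; rows whose printed cell is absent
    (typically the closing control-region row) yield no entry.
    coordinates mode: gap = start(downstream) - end(upstream) - 1, with the
    circular closing pair computed modulo genome length and included when
    ``include_closing`` is set.
    """
    if source not in ("printed", "coordinates"):
        raise ValueError(f"unknown ledger source {source!r}")
    recs = genome.records
    if len(recs) < 2:
        raise ValueError("pair ledger needs at least two records")
    entries: list[PairLedgerEntry] = []
    n = len(recs)
    if source == "printed":
        if all(r.intergenic_printed is None for r in recs):
            raise ValueError("printed mode requires the intergenic-nucleotides column")
        for i, rec in enumerate(recs):
            if rec.intergenic_printed is None:
                continue
            nxt = recs[(i + 1) % n]
            entries.append(
                PairLedgerEntry(rec.name, nxt.name, rec.intergenic_printed, "printed")
            )
        return entries
    for i, rec in enumerate(recs):
        nxt = recs[(i + 1) % n]
        if i + 1 < n:
            gap = nxt.start - rec.end - 1
        else:
            if not include_closing:
                continue
            gap = (nxt.start - 1) + (genome.length - rec.end)
        entries.append(PairLedgerEntry(rec.name, nxt.name, gap, "coordinates"))
    return entries


def summarize_topology(
    ledger: list[PairLedgerEntry], major_cutoff: int = 10
) -> TopologySummary:
    """Counts, totals and extrema over a pair ledger.

    Ties on extrema are broken by first occurrence in genome order.
    """
    if not ledger:
        raise ValueError("empty ledger")
    overlaps = [e for e in ledger if e.gap < 0]
    spacers = [e for e in ledger if e.gap > 0]
    max_overlap = max(overlaps, key=lambda e: -e.gap, default=None)
    max_spacer = max(spacers, key=lambda e: e.gap, default=None)
    return TopologySummary(
        n_overlaps=len(overlaps),
        overlap_total_bp=sum(-e.gap for e in overlaps),
        overlap_max_bp=-max_overlap.gap if max_overlap else 0,
        overlap_max_pair=(
            (max_overlap.upstream_gene, max_overlap.downstream_gene)
            if max_overlap
            else None
        ),
        n_spacers=len(spacers),
        spacer_total_bp=sum(e.gap for e in spacers),
        spacer_max_bp=max_spacer.gap if max_spacer else 0,
        spacer_max_pair=(
            (max_spacer.upstream_gene, max_spacer.downstream_gene)
            if max_spacer
            else None
        ),
        n_major_spacers=sum(1 for e in spacers if e.gap >= major_cutoff),
        major_cutoff=major_cutoff,
    )


def motif_at_overlap(genome: AnnotatedGenome, pair: tuple[str, str]) -> str:
    """F-strand sequence shared by an overlapping adjacent pair."""
    if genome.sequence is None:
        raise SequenceUnavailableError("motif_at_overlap requires a sequence")
    up = genome.record(pair[0])
    down = genome.record(pair[1])
    # overlap on the F strand between consecutive features
    start = down.start
    end = up.end
    if start > end:
        raise ValueError(f"pair {pair} does not overlap")
    return genome.sequence[start - 1 : end]


def gene_order_signature(
    genome: AnnotatedGenome, anchor: str = "cox1"
) -> tuple[str, ...]:
    """Signed circular gene order, rotation-normalized to start at ``anchor``.

    R-strand genes carry a '-' prefix.
    """
    names = [("-" if r.strand == "R" else "") + r.name for r in genome.records]
    plain = [r.name for r in genome.records]
    if anchor not in plain:
        raise ValueError(f"anchor gene {anchor!r} not present")
    i = plain.index(anchor)
    return tuple(names[i:] + names[:i])


def _adjacencies(signature: tuple[str, ...]) -> set[tuple[str, str]]:
    """Signed circular adjacencies; (x, y) is equivalent to (-y, -x)."""

    def flip(g: str) -> str:
        return g[1:] if g.startswith("-") else "-" + g

    adj = set()
    n = len(signature)
    for i in range(n):
        x, y = signature[i], signature[(i + 1) % n]
        adj.add(min((x, y), (flip(y), flip(x))))
    return adj


def compare_order(a: tuple[str, ...], b: tuple[str, ...]) -> dict:
    """Compare two signed circular gene orders.

    Returns {"identical": bool, "breakpoints": int} where breakpoints counts
    the adjacencies of ``a`` not conserved in ``b``.
    """
    strip = lambda g: g.lstrip("-")
    set_a = {strip(g) for g in a}
    set_b = {strip(g) for g in b}
    if set_a != set_b:
        diff = sorted(set_a ^ set_b)
        raise ValueError(f"gene-name alphabets differ: {diff}")
    adj_a = _adjacencies(a)
    adj_b = _adjacencies(b)
    breakpoints = len(adj_a - adj_b)
    return {"identical": breakpoints == 0, "breakpoints": breakpoints}


def ancestral_insect_signature(genome: AnnotatedGenome) -> tuple[str, ...]:
    """The ancestral insect arrangement derived from a lepidopteran-order
    genome by restoring the ancestral trnI-trnQ-trnM block (lepidopterans
    carry the derived trnM-trnI-trnQ order)."""
    sig = list(gene_order_signature(genome))
    try:
        m = sig.index("trnM")
    except ValueError:
        raise ValueError("genome lacks trnM; cannot derive ancestral order")
    if sig[m + 1 : m + 3] != ["trnI", "-trnQ"]:
        raise ValueError("genome does not show the trnM-trnI-trnQ block")
    sig[m : m + 3] = ["trnI", "-trnQ", "trnM"]
    return tuple(sig)


def ledger_table(ledger: list[PairLedgerEntry]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "Upstream": e.upstream_gene,
                "Downstream": e.downstream_gene,
                "Gap": e.gap,
                "Source": e.source,
            }
            for e in ledger
        ]
    )
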