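"""Translation under the invertebrate mitochondrial code (NCBI table 5),
start/stop classification including incomplete stops, codon usage and RSCU."""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.Data import CodonTable

from . import genome_model as gm

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]

#: DNA codon -> amino acid (one letter), invertebrate mitochondrial code.
CODON_TO_AA = dict(_TABLE5.forward_table)
STOP_CODONS = frozenset(_TABLE5.stop_codons)  # {"TAA", "TAG"}
ALL_CODONS = tuple("".join(c) for c in itertools.product("ACGT", repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

ATN_STARTS = frozenset({"ATA", "ATT", "ATC", "ATG"})


def _family_label(codon: str) -> str:
    """Synonymous-family label; Leu and Ser are split by codon family
    (Leu1 = CTN, Leu2 = TTR; Ser1 = AGN, Ser2 = TCN)."""
    aa = CODON_TO_AA[codon]
    if aa == "L":
        return "Leu1" if codon.startswith("CT") else "Leu2"
    if aa == "S":
        return "Ser1" if codon.startswith("AG") else "Ser2"
    return aa


#: family label -> tuple of member codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    FAMILIES.setdefault(_family_label(_codon), ())
    FAMILIES[_family_label(_codon)] += (_codon,)


class TranslationError(ValueError):
    pass


@dataclass
class StartStopCall:
    gene: str
    start_codon: str
    start_class: str  # "ATN" | "nonstandard"
    stop_codon: str
    stop_class: str  # "complete" | "incomplete_T" | "incomplete_TA"


@dataclass
class CodonUsage:
    counts: dict[str, int]
    n_codons: int
    per_thousand: dict[str, float] = field(default_factory=dict)
    rscu: dict[str, float] = field(default_factory=dict)
    missing: set[str] = field(default_factory=set)


def translate_mt(cds: str, complete_stop: bool = False) -> str:
    """Translate a CDS under the invertebrate mitochondrial code.

    The first codon is read as Met when it is a recognised ATN initiator.
    A terminal stop codon is dropped.  With ``complete_stop`` a trailing
    partial codon of 1-2 bases is completed with A's (polyadenylation of an
    incomplete T / TA stop) and must then form a stop.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise TranslationError(f"CDS too short ({len(cds)} bp)")
    remainder = len(cds) % 3
    if remainder:
        if not complete_stop:
            raise TranslationError(
                f"CDS length {len(cds)} not a multiple of 3 (set complete_stop "
                "to allow an incomplete terminal stop codon)"
            )
        tail = cds[-remainder:] + "A" * (3 - remainder)
        if tail not in STOP_CODONS:
            raise TranslationError(
                f"trailing partial codon {cds[-remainder:]!r} does not complete to a stop"
            )
        cds = cds[:-remainder]
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    protein = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise TranslationError(f"internal stop codon {codon} at codon {i + 1}")
        if i == 0 and codon in ATN_STARTS:
            protein.append("M")
        else:
            try:
                protein.append(CODON_TO_AA[codon])
            except KeyError as exc:
                raise TranslationError(f"unknown codon {codon!r} at codon {i + 1}") from exc
    return "".join(protein)


def _classify_stop(stop: str) -> str:
    if stop in ("TAA", "TAG"):
        return "complete"
    if stop == "T":
        return "incomplete_T"
    if stop == "TA":
        return "incomplete_TA"
    raise ValueError(f"unrecognised stop codon {stop!r}")


def classify_start_stop(
    genome: gm.AnnotatedGenome, record: gm.GeneRecord
) -> StartStopCall:
    """Classify one PCG's start and stop.

    With a sequence present, codons are read off the extracted CDS (an
    incomplete stop is the trailing 1-2 bases left over after whole codons).
    In table-only mode the printed codon columns are used verbatim.
    """
    if record.feature_class != "PCG":
        raise ValueError(f"{record.name} is not a protein-coding gene")
    if genome.has_sequence:
        cds = gm.extract_feature_sequence(genome, record)
        start = cds[:3]
        remainder = len(cds) % 3
        stop = cds[-remainder:] if remainder else cds[-3:]
    else:
        if record.start_codon is None or record.stop_codon is None:
            raise ValueError(f"{record.name}: printed codon columns missing")
        start, stop = record.start_codon, record.stop_codon
    return StartStopCall(
        gene=record.name,
        start_codon=start,
        start_class="ATN" if start in ATN_STARTS else "nonstandard",
        stop_codon=stop,
        stop_class=_classify_stop(stop),
    )


def start_stop_tally(genome: gm.AnnotatedGenome) -> tuple[Counter, Counter]:
    """(start-codon counts, stop-class counts) over all PCGs."""
    starts: Counter = Counter()
    stops: Counter = Counter()
    for rec in genome.records_of_class("PCG"):
        call = classify_start_stop(genome, rec)
        starts[call.start_codon] += 1
        stops[call.stop_class] += 1
    return starts, stops


def incomplete_stop_genes(genome: gm.AnnotatedGenome) -> list[str]:
    """Names of PCGs terminating with an incomplete (T or TA) stop."""
    out = []
    for rec in genome.records_of_class("PCG"):
        call = classify_start_stop(genome, rec)
        if call.stop_class.startswith("incomplete"):
            out.append(rec.name)
    return out


def _strip_stop(cds: str) -> str:
    """Drop the incomplete trailing codon and/or terminal stop for counting."""
    remainder = len(cds) % 3
    if remainder:
        cds = cds[:-remainder]
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    return cds


def codon_usage(cds_collection: Iterable[str]) -> CodonUsage:
    """Codon counts and per-thousand rates over a CDS collection.

    Stop codons and incomplete terminal codons are excluded from counting.
    Every CDS must translate cleanly (internal stops are rejected).
    """
    counts: Counter = Counter()
    n_cds = 0
    for cds in cds_collection:
        cds = cds.upper()
        translate_mt(cds, complete_stop=True)  # validation
        body = _strip_stop(cds)
        for i in range(0, len(body), 3):
            counts[body[i : i + 3]] += 1
        n_cds += 1
    if n_cds == 0:
        raise ValueError("empty CDS collection")
    n_codons = sum(counts.values())
    usage = CodonUsage(
        counts={c: counts.get(c, 0) for c in ALL_CODONS},
        n_codons=n_codons,
        per_thousand={
            c: 1000.0 * counts.get(c, 0) / n_codons for c in SENSE_CODONS
        },
        missing={c for c in SENSE_CODONS if counts.get(c, 0) == 0},
    )
    return rscu(usage)


def rscu(usage: CodonUsage) -> CodonUsage:
    """Fill RSCU values: count x family size / family total.

    Families with zero total are omitted from the mapping; the mean RSCU
    within each populated family is 1 by construction.
    """
    values: dict[str, float] = {}
    for members in FAMILIES.values():
        total = sum(usage.counts.get(c, 0) for c in members)
        if total == 0:
            continue
        size = len(members)
        for c in members:
            values[c] = usage.counts.get(c, 0) * size / total
    usage.rscu = values
    usage.missing = {c for c in SENSE_CODONS if usage.counts.get(c, 0) == 0}
    return usage


def usage_table(usage: CodonUsage):
    """Tidy per-codon table (family, amino acid, count, CDspT, RSCU)."""
    import pandas as pd

    rows = []
    for fam, members in sorted(FAMILIES.items()):
        for codon in sorted(members):
            rows.append(
                {
                    "Family": fam,
                    "Codon": codon,
                    "Count": usage.counts.get(codon, 0),
                    "CDspT": round(usage.per_thousand.get(codon, 0.0), 2),
                    "RSCU": round(usage.rscu[codon], 3) if codon in usage.rscu else None,
                    "Missing": codon in usage.missing,
                }
            )
    return pd.DataFrame(rows)


def genome_codon_usage(genome: gm.AnnotatedGenome) -> CodonUsage:
    """Codon usage over all 13 PCGs of one genome (sequence mode)."""
    cds_list = [
        gm.extract_feature_sequence(genome, rec)
        for rec in genome.records_of_class("PCG")
    ]
    return codon_usage(cds_list)
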