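"""Seeded generators: circular annotated mitogenomes with planted features
(motifs, overlaps, control-region elements) and aligned clades evolved under
a K2P substitution model, so every analysis stage is testable offline.

Every generator takes an explicit seed; a spec plus its seed fully
determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import genome_model as gm
from .codon_analysis import SENSE_CODONS, STOP_CODONS
from .phylogeny import DistanceMatrix, Node, Tree, parse_newick

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# specs


@dataclass
class GenePlan:
    name: str
    feature_class: str
    strand: str
    length: int
    gap_after: int = 0  # to the next feature in circular order
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    spacer_motif: Optional[str] = None  # planted centered in the following spacer
    junction_motif: Optional[str] = None  # content of the overlap with the next feature


@dataclass
class ControlRegionPlan:
    motif: str = "ATAGA"
    motif_offset: int = 20  # 0-based offset of the motif inside the region
    poly_t_len: int = 17  # immediately after the motif
    at_copies: int = 9
    at_offset: int = 150
    poly_a_len: int = 10  # flush with the region end
    pct_at: float = 95.16


@dataclass
class GenomeSpec:
    identifier: str
    gene_plans: list[GenePlan]
    control_region: ControlRegionPlan = field(default_factory=ControlRegionPlan)
    pct_at: float = 80.29
    at_skew: float = 0.017
    gc_skew: float = -0.231
    length_target: Optional[int] = None  # when set, the plans must tile exactly
    seed: int = 0

    @property
    def genome_length(self) -> int:
        return sum(p.length + p.gap_after for p in self.gene_plans)


@dataclass
class CladeSpec:
    tree: str | Tree  # newick string or Tree with branch lengths
    kappa: float = 2.0
    gene_lengths: Optional[dict[str, int]] = None
    pct_at: float = 80.0
    seed: int = 0


class PlanError(ValueError):
    """Raised before any sampling when a genome plan does not tile."""


# ---------------------------------------------------------------------------
# base / codon probabilities


def base_probabilities(pct_at: float, at_skew: float = 0.0, gc_skew: float = 0.0):
    """Per-base probabilities (A, C, G, T order) from composition targets via
    the closed-form inversion pA = AT(1 + at_skew)/2 etc."""
    at = pct_at / 100.0
    gc = 1.0 - at
    p = np.array(
        [
            at * (1 + at_skew) / 2,  # A
            gc * (1 - gc_skew) / 2,  # C
            gc * (1 + gc_skew) / 2,  # G
            at * (1 - at_skew) / 2,  # T
        ]
    )
    if (p < 0).any():
        raise ValueError("composition targets imply negative base probabilities")
    return p / p.sum()


def _codon_probabilities(pct_at: float, at_skew: float, gc_skew: float) -> np.ndarray:
    """Codon sampling distribution over the sense codons, calibrated so that
    the expected A+T fraction matches the target despite stop exclusion."""
    target = pct_at / 100.0
    base = base_probabilities(pct_at, at_skew, gc_skew)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    at_frac = np.array([sum(ch in "AT" for ch in c) / 3 for c in SENSE_CODONS])

    def expected(theta: float) -> tuple[float, np.ndarray]:
        p = base.copy()
        p[idx["A"]] *= theta
        p[idx["T"]] *= theta
        p /= p.sum()
        q = np.array([p[idx[c[0]]] * p[idx[c[1]]] * p[idx[c[2]]] for c in SENSE_CODONS])
        q /= q.sum()
        return float((q * at_frac).sum()), q

    lo, hi = 0.5, 3.0
    for _ in range(60):
        mid = (lo + hi) / 2
        value, q = expected(mid)
        if value < target:
            lo = mid
        else:
            hi = mid
    return expected((lo + hi) / 2)[1]


# ---------------------------------------------------------------------------
# mitogenome generator


class _Assembly:
    """Mutable circular sequence with first-writer-wins laying and
    protected positions for planted features."""

    def __init__(self, length: int):
        self.length = length
        self.seq: list[Optional[str]] = [None] * length
        self.protected = [False] * length

    def lay(self, pos0: int, content: str) -> None:
        """Write content at 0-based circular position, keeping existing bases."""
        for i, ch in enumerate(content):
            p = (pos0 + i) % self.length
            if self.seq[p] is None:
                self.seq[p] = ch

    def force(self, pos0: int, content: str, protect: bool = True) -> None:
        """Overwrite content; error on a protected position holding a
        different base (an inconsistent plan)."""
        for i, ch in enumerate(content):
            p = (pos0 + i) % self.length
            if self.protected[p] and self.seq[p] != ch:
                raise PlanError(
                    f"planted features conflict at position {p + 1}: "
                    f"{self.seq[p]} vs {ch}"
                )
            self.seq[p] = ch
            if protect:
                self.protected[p] = True

    def read(self, pos0: int, length: int) -> str:
        return "".join(self.seq[(pos0 + i) % self.length] or "N" for i in range(length))

    def string(self) -> str:
        if any(b is None for b in self.seq):
            raise RuntimeError("assembly has unfilled positions")
        return "".join(self.seq)


def _validate_spec(spec: GenomeSpec) -> None:
    length = spec.genome_length
    if length <= 0:
        raise PlanError("plans do not tile a positive genome length")
    if spec.length_target is not None and length != spec.length_target:
        raise PlanError(
            f"plans tile {length} bp but the genome length target is {spec.length_target} bp"
        )
    for plan in spec.gene_plans:
        if plan.length < 1:
            raise PlanError(f"{plan.name}: non-positive length")
        if plan.junction_motif is not None:
            if plan.gap_after >= 0:
                raise PlanError(f"{plan.name}: junction motif without an overlap")
            if len(plan.junction_motif) != -plan.gap_after:
                raise PlanError(
                    f"{plan.name}: junction motif length {len(plan.junction_motif)} "
                    f"!= overlap {-plan.gap_after}"
                )
        if plan.spacer_motif is not None and len(plan.spacer_motif) > plan.gap_after:
            raise PlanError(f"{plan.name}: spacer motif longer than the spacer")
        if plan.feature_class == "PCG":
            if plan.start_codon is None or plan.stop_codon is None:
                raise PlanError(f"{plan.name}: PCG plan needs start and stop codons")
            body = plan.length - 3 - len(plan.stop_codon)
            if body < 0 or body % 3:
                raise PlanError(
                    f"{plan.name}: length {plan.length} incompatible with stop "
                    f"{plan.stop_codon!r}"
                )
    cr = spec.control_region
    cr_plans = [p for p in spec.gene_plans if p.feature_class == "control_region"]
    if cr_plans:
        cr_len = cr_plans[0].length
        end_of_polyt = cr.motif_offset + len(cr.motif) + cr.poly_t_len
        if end_of_polyt + 1 > cr.at_offset:
            raise PlanError("control region: poly-T stretch collides with (AT)n")
        if cr.at_offset + 2 * cr.at_copies + 1 > cr_len - cr.poly_a_len - 1:
            raise PlanError("control region: (AT)n collides with the poly-A tail")


def _cds_pos(plan_start0: int, plan_len: int, strand: str, idx: int, length: int) -> int:
    """0-based genome position of CDS index ``idx``."""
    if strand == "F":
        return (plan_start0 + idx) % length
    return (plan_start0 + plan_len - 1 - idx) % length


def _force_cds(
    asm: _Assembly, plan_start0: int, plan_len: int, strand: str, idx: int, codon: str
) -> None:
    for k, ch in enumerate(codon):
        base = ch if strand == "F" else _COMPLEMENT[ch]
        asm.force(_cds_pos(plan_start0, plan_len, strand, idx + k, asm.length), base)


def _sample_bases(rng, probs: np.ndarray, n: int) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=probs)])


def _build_control_region(rng, cr: ControlRegionPlan, length: int) -> tuple[str, list[dict]]:
    """Control-region string (local coordinates) plus its truth entries."""
    probs = base_probabilities(cr.pct_at, -0.126, -0.413)
    s = list(_sample_bases(rng, probs, length))
    protected = [False] * length
    truth: list[dict] = []

    def plant(pos0: int, content: str) -> None:
        for i, ch in enumerate(content):
            s[pos0 + i] = ch
            protected[pos0 + i] = True

    m0 = cr.motif_offset
    plant(m0, cr.motif)
    truth.append({"kind": "cr_motif", "motif": cr.motif, "start": m0 + 1, "end": m0 + len(cr.motif)})

    t0 = m0 + len(cr.motif)
    plant(t0, "T" * cr.poly_t_len)
    truth.append({"kind": "poly_t", "unit": "T", "copies": cr.poly_t_len,
                  "start": t0 + 1, "end": t0 + cr.poly_t_len})
    if s[t0 + cr.poly_t_len] == "T":  # break the run so the planted length is exact
        plant(t0 + cr.poly_t_len, "A")

    a0 = cr.at_offset
    plant(a0, "AT" * cr.at_copies)
    truth.append({"kind": "microsatellite", "unit": "AT", "copies": float(cr.at_copies),
                  "start": a0 + 1, "end": a0 + 2 * cr.at_copies})
    # block single-base period-2 extensions on either side
    if s[a0 - 1] == s[a0 + 1]:
        plant(a0 - 1, "A" if s[a0 + 1] != "A" else "T")
    tail = a0 + 2 * cr.at_copies
    if s[tail] == s[tail - 2]:
        plant(tail, "T" if s[tail - 2] != "T" else "A")

    p0 = length - cr.poly_a_len
    plant(p0, "A" * cr.poly_a_len)
    truth.append({"kind": "poly_a", "unit": "A", "copies": cr.poly_a_len,
                  "start": p0 + 1, "end": p0 + cr.poly_a_len})
    if s[p0 - 1] == "A":
        plant(p0 - 1, "T")
    # keep the planted poly-A the longest A-run in the region
    i = 0
    while i < length:
        if s[i] == "A" and not protected[i]:
            j = i
            while j < length and s[j] == "A":
                j += 1
            if j - i >= cr.poly_a_len and not all(protected[i:j]):
                for k in range(i, j):
                    if not protected[k]:
                        s[k] = "T"
                        break
            i = j
        else:
            i += 1
    # likewise keep the planted poly-T the longest T-run
    i = 0
    while i < length:
        if s[i] == "T" and not protected[i]:
            j = i
            while j < length and s[j] == "T":
                j += 1
            if j - i >= cr.poly_t_len and not all(protected[i:j]):
                for k in range(i, j):
                    if not protected[k]:
                        s[k] = "A"
                        break
            i = j
        else:
            i += 1
    # remove accidental copies of the anchor motif (keep the planted one)
    for _ in range(20):
        region = "".join(s)
        extra = [
            i
            for i in range(length - len(cr.motif) + 1)
            if region.startswith(cr.motif, i) and i != m0
        ]
        rc = gm.reverse_complement(region)
        extra_rc = [
            length - (i + len(cr.motif))
            for i in range(length - len(cr.motif) + 1)
            if rc.startswith(cr.motif, i)
        ]
        extra += [i for i in extra_rc if i != m0]
        if not extra:
            break
        for i in extra:
            for k in range(i, i + len(cr.motif)):
                if not protected[k]:
                    s[k] = "T" if s[k] != "T" else "A"
                    break
            else:
                raise PlanError("cannot disambiguate the control-region motif")
    return "".join(s), truth


def generate_mitogenome(spec: GenomeSpec) -> tuple[gm.AnnotatedGenome, list[dict]]:
    """Generate a circular annotated genome satisfying the spec.

    Returns the genome (sequence present) and a truth record listing every
    planted feature with exact genome coordinates, for plant-and-recover
    tests of the scanners.
    """
    _validate_spec(spec)
    length = spec.genome_length
    rng = np.random.default_rng(spec.seed)
    # recenter the non-control-region sampling so the genome-wide A+T
    # expectation hits the target despite the AT-richer control region
    cr_len = sum(
        p.length for p in spec.gene_plans if p.feature_class == "control_region"
    )
    other_at = 100.0 * (
        spec.pct_at / 100.0 * length - spec.control_region.pct_at / 100.0 * cr_len
    ) / (length - cr_len)
    probs = base_probabilities(other_at, spec.at_skew, spec.gc_skew)
    codon_probs = _codon_probabilities(other_at, spec.at_skew, spec.gc_skew)
    asm = _Assembly(length)
    truth: list[dict] = []

    # coordinates
    starts: list[int] = []
    cursor = 1
    for plan in spec.gene_plans:
        starts.append(cursor)
        cursor += plan.length + plan.gap_after
    if cursor != length + 1:
        raise PlanError("plans do not close the circle")

    records: list[gm.GeneRecord] = []
    pcg_layout: list[tuple[GenePlan, int]] = []

    for plan, start in zip(spec.gene_plans, starts):
        start0 = start - 1
        end = start + plan.length - 1  # may exceed length only for the last (never here)
        if plan.feature_class == "PCG":
            body_n = (plan.length - 3 - len(plan.stop_codon)) // 3
            codons = [SENSE_CODONS[i] for i in rng.choice(len(SENSE_CODONS), size=body_n, p=codon_probs)]
            cds = plan.start_codon + "".join(codons) + plan.stop_codon
            content = cds if plan.strand == "F" else gm.reverse_complement(cds)
            asm.lay(start0, content)
            _force_cds(asm, start0, plan.length, plan.strand, 0, plan.start_codon)
            _force_cds(
                asm,
                start0,
                plan.length,
                plan.strand,
                plan.length - len(plan.stop_codon),
                plan.stop_codon,
            )
            pcg_layout.append((plan, start0))
        elif plan.feature_class == "control_region":
            region, local_truth = _build_control_region(rng, spec.control_region, plan.length)
            asm.lay(start0, region)
            for entry in local_truth:
                entry = dict(entry)
                entry["start"] = (start0 + entry["start"] - 1) % length + 1
                entry["end"] = (start0 + entry["end"] - 1) % length + 1
                truth.append(entry)
        else:  # tRNA / rRNA: unconstrained content
            asm.lay(start0, _sample_bases(rng, probs, plan.length))
        truth.append(
            {
                "kind": "gene",
                "name": plan.name,
                "class": plan.feature_class,
                "strand": plan.strand,
                "start": start,
                "end": end,
            }
        )
        if plan.junction_motif is not None:
            ov_start0 = (start0 + plan.length + plan.gap_after) % length
            asm.force(ov_start0, plan.junction_motif)
            truth.append(
                {
                    "kind": "junction_motif",
                    "motif": plan.junction_motif,
                    "upstream": plan.name,
                    "start": ov_start0 + 1,
                    "end": ov_start0 + len(plan.junction_motif),
                }
            )
        if plan.gap_after > 0:
            gap_start0 = (start0 + plan.length) % length
            asm.lay(gap_start0, _sample_bases(rng, probs, plan.gap_after))
            if plan.spacer_motif is not None:
                offset = (plan.gap_after - len(plan.spacer_motif)) // 2
                m_start0 = (gap_start0 + offset) % length
                asm.force(m_start0, plan.spacer_motif)
                truth.append(
                    {
                        "kind": "spacer_motif",
                        "motif": plan.spacer_motif,
                        "upstream": plan.name,
                        "start": m_start0 + 1,
                        "end": m_start0 + len(plan.spacer_motif),
                    }
                )
        records.append(
            gm.GeneRecord(
                name=plan.name,
                feature_class=plan.feature_class,
                strand=plan.strand,
                start=start,
                end=end,
                anticodon=plan.anticodon,
                start_codon=plan.start_codon,
                stop_codon=plan.stop_codon,
                intergenic_printed=plan.gap_after,
                size_printed=plan.length,
            )
        )

    _repair_internal_stops(asm, pcg_layout)
    genome = gm.AnnotatedGenome(
        identifier=spec.identifier,
        length=length,
        records=records,
        sequence=asm.string(),
    )
    return genome, truth


def _repair_internal_stops(asm: _Assembly, pcg_layout: list[tuple[GenePlan, int]]) -> None:
    """Mutate unprotected bases until no PCG carries an internal stop codon.

    Boundary overwrites (overlaps, junction motifs) can create stops inside a
    neighbouring frame; each is broken by a single deterministic substitution.
    """
    for _ in range(30):
        dirty = False
        for plan, start0 in pcg_layout:
            raw = asm.read(start0, plan.length)
            cds = raw if plan.strand == "F" else gm.reverse_complement(raw)
            for i in range(plan.length // 3 - (1 if len(plan.stop_codon) == 3 else 0)):
                codon = cds[3 * i : 3 * i + 3]
                if i == 0 or codon not in STOP_CODONS:
                    continue
                dirty = True
                for k, new in ((1, "C"), (0, "C"), (2, "T")):
                    pos = _cds_pos(start0, plan.length, plan.strand, 3 * i + k, asm.length)
                    if not asm.protected[pos]:
                        base = new if plan.strand == "F" else _COMPLEMENT[new]
                        asm.seq[pos] = base
                        break
                else:
                    raise PlanError(
                        f"{plan.name}: internal stop at codon {i + 1} is fully protected"
                    )
                break
        if not dirty:
            return
    raise PlanError("internal-stop repair did not converge")


# ---------------------------------------------------------------------------
# default genome spec (emulates the printed reference annotation)


def default_genome_spec(seed: int = 0, identifier: str = "synthetic_mitogenome") -> GenomeSpec:
    """A ~15.2 kb plan mirroring the reference annotation table: same gene
    order, strands and coordinates, lepidopteran composition targets, the
    7 bp ATGATAA junction at atp8/atp6, an ATACTAA spacer motif upstream of
    nad1, and the standard control-region elements.

    Stop-codon assignments are derived from each gene's length modulo 3
    (complete TAA, incomplete TA or T) so that every frame closes exactly at
    the printed coordinates; cytb is initiated with TTG so its first base is
    compatible with the 1 bp nad6 overlap.
    """
    ref = gm.load_reference_annotation()
    plans: list[GenePlan] = []
    n = len(ref.records)
    for i, rec in enumerate(ref.records):
        nxt = ref.records[(i + 1) % n]
        if i + 1 < n:
            gap = nxt.start - rec.end - 1
        else:
            gap = (nxt.start - 1) + (ref.length - rec.end)
        length = gm.gene_length(rec, ref.length)
        start_codon = stop_codon = None
        if rec.feature_class == "PCG":
            start_codon = rec.start_codon
            stop_codon = {0: "TAA", 1: "T", 2: "TA"}[length % 3]
            if rec.name == "cytb":
                start_codon = "TTG"  # first base must match nad6's incomplete T
        plans.append(
            GenePlan(
                name=rec.name,
                feature_class=rec.feature_class,
                strand=rec.strand,
                length=length,
                gap_after=gap,
                anticodon=rec.anticodon,
                start_codon=start_codon,
                stop_codon=stop_codon,
                junction_motif="ATGATAA" if rec.name == "atp8" else None,
                spacer_motif="ATACTAA" if rec.name == "trnS2(UCN)" else None,
            )
        )
    return GenomeSpec(
        identifier=identifier, gene_plans=plans, length_target=ref.length, seed=seed
    )


# ---------------------------------------------------------------------------
# clade generator


def _k2p_probs(t: float, kappa: float) -> tuple[float, float]:
    """(transition prob, per-target transversion prob) after branch length t
    (expected substitutions/site) under K2P with ts/tv rate ratio kappa."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    p_ts = 0.25 + 0.25 * math.exp(-4 * beta * t) - 0.5 * math.exp(-2 * (alpha + beta) * t)
    p_tv = 0.25 - 0.25 * math.exp(-4 * beta * t)
    return p_ts, p_tv


_TRANSITION = np.array([2, 3, 0, 1])  # A<->G, C<->T in ACGT coding
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def _evolve(parent: np.ndarray, t: float, kappa: float, rng) -> np.ndarray:
    p_ts, p_tv = _k2p_probs(max(t, 0.0), kappa)
    u = rng.random(parent.size)
    pick = rng.integers(0, 2, size=parent.size)
    child = parent.copy()
    ts_mask = u < p_ts
    tv_mask = (u >= p_ts) & (u < p_ts + 2 * p_tv)
    child[ts_mask] = _TRANSITION[parent[ts_mask]]
    child[tv_mask] = _TRANSVERSIONS[parent[tv_mask], pick[tv_mask]]
    return child


DEFAULT_CLADE_GENES = {f"pcg{i:02d}": 120 for i in range(1, 14)}


def generate_clade(spec: CladeSpec) -> tuple[list[gm.AnnotatedGenome], Tree]:
    """Evolve aligned per-gene sequences down the spec tree (no indels).

    Returns one AnnotatedGenome per leaf (PCG records only, concatenated
    without gaps) and the generating tree as truth.
    """
    tree = parse_newick(spec.tree) if isinstance(spec.tree, str) else spec.tree
    genes = (
        spec.gene_lengths if spec.gene_lengths is not None else dict(DEFAULT_CLADE_GENES)
    )
    total = sum(genes.values())
    if total == 0:
        raise ValueError("zero-length alignment")
    rng = np.random.default_rng(spec.seed)
    probs = base_probabilities(spec.pct_at)
    root_seq = rng.choice(4, size=total, p=probs)
    leaf_seqs: dict[str, np.ndarray] = {}

    def walk(node: Node, seq: np.ndarray) -> None:
        if node.is_leaf:
            leaf_seqs[node.name] = seq
            return
        for child in node.children:
            walk(child, _evolve(seq, child.length or 0.0, spec.kappa, rng))

    walk(tree.root, root_seq)

    genomes: list[gm.AnnotatedGenome] = []
    for taxon in sorted(leaf_seqs):
        seq = "".join(_BASES[leaf_seqs[taxon]])
        records = []
        offset = 0
        for gene, width in genes.items():
            records.append(
                gm.GeneRecord(
                    name=gene,
                    feature_class="PCG",
                    strand="F",
                    start=offset + 1,
                    end=offset + width,
                    start_codon=seq[offset : offset + 3],
                )
            )
            offset += width
        genomes.append(
            gm.AnnotatedGenome(
                identifier=taxon, length=total, records=records, sequence=seq
            )
        )
    return genomes, tree


# ---------------------------------------------------------------------------
# random trees and additive distances (oracles for tree inference)


def random_tree(taxa: list[str], rng, min_branch: float = 0.05, max_branch: float = 0.3) -> Tree:
    """Random unrooted binary topology with uniform branch lengths."""
    if len(taxa) < 3:
        raise ValueError("need at least three taxa")

    def bl() -> float:
        return float(rng.uniform(min_branch, max_branch))

    nodes = [Node(name=t, length=bl()) for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = Node(children=[nodes[i], nodes[j]], length=bl())
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return Tree(Node(children=nodes))


def tree_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Additive (path-length) distances between the leaves of a tree."""
    taxa = sorted(tree.leaf_names())
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    out = np.zeros((n, n))

    def walk(node: Node) -> dict[str, float]:
        if node.is_leaf:
            below = {node.name: 0.0}
        else:
            below = {}
            child_maps = []
            for child in node.children:
                cmap = {t: d + (child.length or 0.0) for t, d in walk(child).items()}
                child_maps.append(cmap)
            for a_idx in range(len(child_maps)):
                for b_idx in range(a_idx + 1, len(child_maps)):
                    for ta, da in child_maps[a_idx].items():
                        for tb, db in child_maps[b_idx].items():
                            out[index[ta], index[tb]] = out[index[tb], index[ta]] = da + db
            for cmap in child_maps:
                below.update(cmap)
        return below

    walk(tree.root)
    return DistanceMatrix(taxa, out)
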