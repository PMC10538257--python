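"""Effect classification of highly differentiated variants on gene
models, and per-gene summaries of effect counts and callable coverage.

Candidate variants are SNPs and short indels with between-mode F_ST
strictly above 0.5 and depth >= 20 in every population. Each is placed
against the longest-transcript CDS chain of its gene: coding SNPs are
translated on the correct strand and frame (standard genetic code);
indels are frameshift unless their net length change is a multiple of
3. Impact follows the usual convention: frameshift and premature stops
are high; missense and in-frame indels moderate; synonymous low;
non-coding modifier.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .divergence_dating import _CODON_AA, reverse_complement
from .io_formats import GeneModel

__all__ = [
    "Variant",
    "EffectCall",
    "IMPACT",
    "select_candidate_variants",
    "classify_variant",
    "classify_variants",
    "per_gene_summary",
]

IMPACT = {
    "frameshift": "high",
    "nonsense": "high",
    "stop_lost": "high",
    "missense": "moderate",
    "inframe_deletion": "moderate",
    "inframe_insertion": "moderate",
    "synonymous": "low",
    "splice_adjacent": "modifier",
    "intronic": "modifier",
    "intergenic": "modifier",
    "modifier": "modifier",
}

#: bases of intron flanking a CDS edge flagged as splice-adjacent
SPLICE_REGION = 2


@dataclasses.dataclass
class Variant:
    """A SNP or short indel in VCF-style representation (``ref``/``alt``
    share their first base for indels). ``pos`` is 0-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    fst: float = float("nan")
    depths: np.ndarray | None = None  # per-population depth
    freq_op: float = float("nan")
    freq_cp: float = float("nan")

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if max(len(self.ref), len(self.alt)) - 1 >= 50:
            raise ValueError("indel length must be < 50 bp")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


@dataclasses.dataclass
class EffectCall:
    gene_id: str | None
    effect: str
    impact: str
    codon_change: str | None = None
    aa_change: str | None = None


class ReferenceMismatchError(ValueError):
    pass


def select_candidate_variants(
    variants: list[Variant], fst_min: float = 0.5, depth_min: int = 20
) -> list[Variant]:
    """Strictly F_ST > fst_min and depth >= depth_min in every population."""
    out = []
    for v in variants:
        if not (v.fst > fst_min):
            continue
        if v.depths is None or np.any(np.asarray(v.depths) < depth_min):
            continue
        out.append(v)
    return out


def _coding_offset(gene: GeneModel, pos: int) -> int | None:
    """Offset of a genomic position within the spliced CDS (coding
    orientation, phase-adjusted); None when the position is intronic."""
    total = gene.cds_length
    acc = 0
    offset = None
    for s, e in gene.cds:
        if s <= pos < e:
            offset = acc + (pos - s)
            break
        acc += e - s
    if offset is None:
        return None
    if gene.strand == "-":
        offset = total - 1 - offset
    offset -= gene.phase
    return offset if offset >= 0 else None


def _splice_adjacent(gene: GeneModel, pos: int) -> bool:
    for i, (s, e) in enumerate(gene.cds):
        if i > 0 and gene.cds[i - 1][1] <= pos < s and pos >= s - SPLICE_REGION:
            return True
        if i < len(gene.cds) - 1 and e <= pos < gene.cds[i + 1][0] and pos < e + SPLICE_REGION:
            return True
    return False


def _codon_at(gene: GeneModel, reference: dict[str, str], codon_index: int) -> str:
    """Codon ``codon_index`` of the spliced, strand-oriented CDS."""
    chrom_seq = reference[gene.chrom]
    cds = "".join(chrom_seq[s:e] for s, e in gene.cds)
    if gene.strand == "-":
        cds = reverse_complement(cds)
    cds = cds[gene.phase :]
    return cds[3 * codon_index : 3 * codon_index + 3]


def classify_variant(
    v: Variant, genes: list[GeneModel], reference: dict[str, str]
) -> EffectCall:
    """Classify one variant against gene models and the reference.

    The reference base(s) at the variant position must match ``v.ref``;
    a mismatch raises :class:`ReferenceMismatchError` naming the
    position.
    """
    ref_here = reference[v.chrom][v.pos : v.pos + len(v.ref)]
    if ref_here.upper() != v.ref.upper():
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos + 1}: reference has {ref_here!r}, variant claims {v.ref!r}"
        )
    gene = None
    for g in genes:
        s, e = g.span
        if g.chrom == v.chrom and s <= v.pos < e:
            gene = g
            break
    if gene is None:
        return EffectCall(gene_id=None, effect="intergenic", impact="modifier")
    if not gene.usable:
        warnings.warn(f"{gene.gene_id}: broken reading frame; variant left unclassified")
        return EffectCall(gene_id=gene.gene_id, effect="modifier", impact="modifier")

    offset = _coding_offset(gene, v.pos)
    if offset is None:
        effect = "splice_adjacent" if _splice_adjacent(gene, v.pos) else "intronic"
        return EffectCall(gene_id=gene.gene_id, effect=effect, impact="modifier")

    if not v.is_snp:
        delta = len(v.alt) - len(v.ref)
        if delta % 3 != 0:
            effect = "frameshift"
        elif delta < 0:
            effect = "inframe_deletion"
        else:
            effect = "inframe_insertion"
        return EffectCall(gene_id=gene.gene_id, effect=effect, impact=IMPACT[effect])

    codon_index, codon_pos = divmod(offset, 3)
    codon = _codon_at(gene, reference, codon_index)
    if len(codon) < 3:
        return EffectCall(gene_id=gene.gene_id, effect="modifier", impact="modifier")
    alt_base = v.alt if gene.strand == "+" else reverse_complement(v.alt)
    alt_codon = codon[:codon_pos] + alt_base + codon[codon_pos + 1 :]
    aa_ref = _CODON_AA.get(codon.upper())
    aa_alt = _CODON_AA.get(alt_codon.upper())
    if aa_ref is None or aa_alt is None:
        return EffectCall(gene_id=gene.gene_id, effect="modifier", impact="modifier")
    if aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "nonsense"
    elif aa_ref == "*":
        effect = "stop_lost"
    else:
        effect = "missense"
    return EffectCall(
        gene_id=gene.gene_id,
        effect=effect,
        impact=IMPACT[effect],
        codon_change=f"{codon}>{alt_codon}",
        aa_change=f"{aa_ref}{codon_index + 1}{aa_alt}",
    )


def classify_variants(
    variants: list[Variant], genes: list[GeneModel], reference: dict[str, str]
) -> list[EffectCall]:
    return [classify_variant(v, genes, reference) for v in variants]


def per_gene_summary(
    calls: list[EffectCall],
    genes: list[GeneModel],
    depth_by_pop: np.ndarray | None = None,
    depth_positions: np.ndarray | None = None,
    pop_modes: list[str] | None = None,
    depth_min: int = 20,
) -> pd.DataFrame:
    """Per-gene effect-category counts and callable coverage per mode.

    ``depth_by_pop`` is a (n_positions, n_pops) per-population depth
    track at ``depth_positions`` (genomic, 0-based) with population
    modes in ``pop_modes``. A position counts as covered for a mode only
    when every population of that mode reaches ``depth_min``. Coverage
    is the percentage of the gene span covered; NaN when the track does
    not include the gene.
    """
    categories = [
        "nonsense", "frameshift", "missense",
        "inframe_deletion", "inframe_insertion", "synonymous",
    ]
    rows = []
    for gene in genes:
        row: dict = {"gene_id": gene.gene_id}
        for cat in categories:
            row[cat] = sum(
                1 for c in calls if c.gene_id == gene.gene_id and c.effect == cat
            )
        for mode in ("CP", "OP"):
            key = f"pct_depth{depth_min}_{mode}"
            row[key] = float("nan")
            if depth_by_pop is None or depth_positions is None or pop_modes is None:
                continue
            s, e = gene.span
            sel = (depth_positions >= s) & (depth_positions < e)
            if sel.sum() < e - s:  # track does not span the gene
                continue
            cols = [j for j, m in enumerate(pop_modes) if m == mode]
            if not cols:
                continue
            covered = (depth_by_pop[np.ix_(sel, cols)] >= depth_min).all(axis=1)
            row[key] = 100.0 * float(covered.mean())
        rows.append(row)
    return pd.DataFrame(rows)
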