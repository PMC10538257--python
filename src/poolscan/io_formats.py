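"""Readers and writers for Pool-seq ``sync`` files, FASTA, GFF3 and the
pipeline's tabular outputs, plus replicate merging and mode-level pooling.

The sync format (PoPoolation2) is tab-separated: chromosome, 1-based
position, reference base, then one ``A:T:C:G:N:del`` colon-separated count
field per sequencing library.

Coordinates are 0-based half-open everywhere inside this package; file
readers and writers convert to and from each format's native convention
(sync and GFF3 are 1-based inclusive).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: column order of a sync count field
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")
BASE_TO_COL = {"A": 0, "T": 1, "C": 2, "G": 3, "N": 4}
#: columns counting real nucleotides (depth excludes N and deletions)
NUC_COLS = slice(0, 4)

MODES = ("CP", "OP")


class SyncFormatError(ValueError):
    """Raised when a sync line does not conform to the format."""


class MetadataError(ValueError):
    """Raised when pool metadata and sync columns disagree."""


@dataclasses.dataclass
class AlleleCountRecord:
    """One genomic position with per-library A/T/C/G/N/del read counts."""

    chrom: str
    pos: int  # 1-based, as in the file
    ref: str
    counts: np.ndarray  # (n_libraries, 6) non-negative ints

    def depth(self) -> np.ndarray:
        """Per-library depth, counting A/T/C/G only."""
        return self.counts[:, NUC_COLS].sum(axis=1)


class PoolMetadata:
    """Pool-seq library metadata: which sync column is which library.

    One row per library, in sync column order. Each library belongs to a
    population; each population has a reproductive mode (CP = cyclical
    parthenogen, OP = obligate parthenogen) and a number of clonal
    lineages contributing to the DNA pool.
    """

    REQUIRED = ("library_id", "population_id", "mode", "n_lineages")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise MetadataError(f"metadata missing columns: {missing}")
        bad = set(df["mode"]) - set(MODES)
        if bad:
            raise MetadataError(f"unknown reproductive mode(s): {sorted(bad)}")
        if df["library_id"].duplicated().any():
            raise MetadataError("duplicated library_id in metadata")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def library_ids(self) -> list[str]:
        return list(self.df["library_id"])

    @property
    def populations(self) -> list[str]:
        """Population ids in order of first appearance."""
        return list(dict.fromkeys(self.df["population_id"]))

    def libraries_of(self, population: str) -> list[int]:
        """Sync column indices of a population's libraries."""
        return list(np.flatnonzero(self.df["population_id"] == population))

    def mode_of(self, population: str) -> str:
        rows = self.df[self.df["population_id"] == population]
        if rows.empty:
            raise MetadataError(f"unknown population {population!r}")
        return rows["mode"].iloc[0]

    def chromosomes_in_pool(self, population: str) -> int:
        """Haploid pool size: 2 x summed lineages of the population."""
        rows = self.df[self.df["population_id"] == population]
        # lineages are shared by replicate libraries of one DNA pool
        return int(2 * rows["n_lineages"].iloc[0])

    def population_level(self) -> "PoolMetadata":
        """Metadata with one (merged) entry per population."""
        rows = []
        for pop in self.populations:
            sub = self.df[self.df["population_id"] == pop]
            rows.append(
                {
                    "library_id": pop,
                    "population_id": pop,
                    "mode": sub["mode"].iloc[0],
                    "n_lineages": int(sub["n_lineages"].iloc[0]),
                }
            )
        return PoolMetadata(pd.DataFrame(rows))

    def mode_level(self) -> "PoolMetadata":
        """Metadata with one entry per reproductive mode (CP, OP)."""
        rows = []
        for mode in MODES:
            pops = [p for p in self.populations if self.mode_of(p) == mode]
            if not pops:
                continue
            n_lin = sum(
                int(self.df[self.df["population_id"] == p]["n_lineages"].iloc[0])
                for p in pops
            )
            rows.append(
                {
                    "library_id": mode,
                    "population_id": mode,
                    "mode": mode,
                    "n_lineages": n_lin,
                }
            )
        return PoolMetadata(pd.DataFrame(rows))

    @classmethod
    def read(cls, path: str | Path) -> "PoolMetadata":
        return cls(pd.read_csv(path, sep="\t", dtype={"library_id": str, "population_id": str}))

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sync reading / writing


def _parse_count_field(field: str, lineno: int) -> list[int]:
    parts = field.split(":")
    if len(parts) != 6:
        raise SyncFormatError(
            f"line {lineno}: count field {field!r} has {len(parts)} values, expected 6"
        )
    try:
        return [int(p) for p in parts]
    except ValueError as exc:
        raise SyncFormatError(f"line {lineno}: non-integer count in {field!r}") from exc


def read_sync(
    path: str | Path, metadata: PoolMetadata | None = None
) -> Iterator[AlleleCountRecord]:
    """Stream AlleleCountRecords from a sync file.

    If ``metadata`` is given, the number of count columns must equal the
    number of libraries.
    """
    n_expected = len(metadata) if metadata is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncFormatError(f"line {lineno}: fewer than 4 columns")
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            if n_expected is not None and len(fields) - 3 != n_expected:
                raise MetadataError(
                    f"line {lineno}: {len(fields) - 3} count columns but metadata "
                    f"describes {n_expected} libraries"
                )
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise SyncFormatError(f"line {lineno}: bad position {pos_s!r}") from exc
            counts = np.array(
                [_parse_count_field(f, lineno) for f in fields[3:]], dtype=np.int64
            )
            yield AlleleCountRecord(chrom=chrom, pos=pos, ref=ref, counts=counts)


def write_sync(records: Iterable[AlleleCountRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fields = [rec.chrom, str(rec.pos), rec.ref]
            fields += [":".join(str(int(c)) for c in row) for row in rec.counts]
            fh.write("\t".join(fields) + "\n")


@dataclasses.dataclass
class SyncData:
    """Column-oriented in-memory sync table.

    ``counts`` has shape (n_sites, n_groups, 6) where groups are libraries,
    populations or modes depending on the pooling level applied.
    """

    chrom: np.ndarray  # (n_sites,) str
    pos: np.ndarray  # (n_sites,) int, 0-based
    ref: np.ndarray  # (n_sites,) str
    counts: np.ndarray  # (n_sites, n_groups, 6) int
    metadata: PoolMetadata

    def __len__(self) -> int:
        return self.chrom.shape[0]

    @property
    def group_ids(self) -> list[str]:
        return self.metadata.library_ids

    def depth(self) -> np.ndarray:
        """(n_sites, n_groups) depth over A/T/C/G."""
        return self.counts[:, :, NUC_COLS].sum(axis=2)

    def restrict(self, chrom: str, start: int, end: int) -> "SyncData":
        """Subset to a 0-based half-open interval."""
        mask = (self.chrom == chrom) & (self.pos >= start) & (self.pos < end)
        return SyncData(
            self.chrom[mask], self.pos[mask], self.ref[mask], self.counts[mask], self.metadata
        )

    def to_records(self) -> Iterator[AlleleCountRecord]:
        for i in range(len(self)):
            yield AlleleCountRecord(
                chrom=str(self.chrom[i]),
                pos=int(self.pos[i]) + 1,
                ref=str(self.ref[i]),
                counts=self.counts[i],
            )


def load_sync(path: str | Path, metadata: PoolMetadata) -> SyncData:
    """Read a whole sync file into a SyncData (positions become 0-based)."""
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    counts: list[np.ndarray] = []
    for rec in read_sync(path, metadata):
        chroms.append(rec.chrom)
        poss.append(rec.pos - 1)
        refs.append(rec.ref)
        counts.append(rec.counts)
    n_lib = len(metadata)
    return SyncData(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        counts=(
            np.stack(counts) if counts else np.empty((0, n_lib, 6), dtype=np.int64)
        ),
        metadata=metadata,
    )


def _group_counts(
    sync: SyncData, groups: Sequence[Sequence[int]], grouped_meta: PoolMetadata
) -> SyncData:
    out = np.zeros((len(sync), len(groups), 6), dtype=np.int64)
    for g, cols in enumerate(groups):
        out[:, g, :] = sync.counts[:, list(cols), :].sum(axis=1)
    return SyncData(sync.chrom, sync.pos, sync.ref, out, grouped_meta)


def merge_replicate_libraries(sync: SyncData) -> SyncData:
    """Sum replicate libraries of each population into one count vector.

    Replicates are technical libraries of a single DNA pool, so their
    counts are summed as if they were one library; total depth is
    preserved.
    """
    meta = sync.metadata
    groups = [meta.libraries_of(pop) for pop in meta.populations]
    return _group_counts(sync, groups, meta.population_level())


def pool_by_mode(sync: SyncData) -> SyncData:
    """Sum population-level counts into one vector per reproductive mode."""
    meta = sync.metadata
    mode_meta = meta.mode_level()
    groups = []
    for mode in mode_meta.populations:
        cols = [
            i for i, pop in enumerate(meta.populations) if meta.mode_of(pop) == mode
        ]
        groups.append(cols)
    return _group_counts(sync, groups, mode_meta)


def merge_replicate_records(
    records: Iterable[AlleleCountRecord], metadata: PoolMetadata
) -> Iterator[AlleleCountRecord]:
    """Streaming variant of :func:`merge_replicate_libraries`."""
    groups = [metadata.libraries_of(pop) for pop in metadata.populations]
    for rec in records:
        merged = np.stack([rec.counts[g].sum(axis=0) for g in groups])
        yield AlleleCountRecord(rec.chrom, rec.pos, rec.ref, merged)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 gene models


@dataclasses.dataclass
class GeneModel:
    """One gene reduced to its longest transcript's CDS chain.

    ``cds`` holds 0-based half-open intervals in genomic order. ``phase``
    is the GFF3 phase of the 5'-most CDS segment (number of bases to skip
    before the first complete codon). ``usable`` is False when the summed
    CDS length is not a multiple of 3 after phase adjustment.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds: list[tuple[int, int]]
    phase: int = 0
    usable: bool = True

    @property
    def span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


def read_gff_cds(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3, keeping the longest transcript per gene.

    Transcript length is summed CDS length. Genes whose CDS chain is not a
    multiple of 3 after phase adjustment are flagged unusable but kept.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: tuple[int, list, str] | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            cds_feats = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
            if not cds_feats:
                continue
            length = sum(f.end - f.start + 1 for f in cds_feats)
            if best is None or length > best[0]:
                best = (length, cds_feats, mrna.id)
        if best is None:
            continue
        _, cds_feats, _ = best
        strand = cds_feats[0].strand
        # GFF3 phase is on the 5'-most CDS: first for '+', last for '-'
        first = cds_feats[0] if strand == "+" else cds_feats[-1]
        phase = int(first.frame) if first.frame not in (None, ".") else 0
        intervals = [(f.start - 1, f.end) for f in cds_feats]
        total = sum(e - s for s, e in intervals)
        usable = (total - phase) % 3 == 0
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=strand,
                cds=intervals,
                phase=phase,
                usable=usable,
            )
        )
    return genes


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as gene/mRNA/CDS features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = g.span
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tpoolscan\tgene\t{start + 1}\t{end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tpoolscan\tmRNA\t{start + 1}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            # phase chain along the coding direction
            order = g.cds if g.strand == "+" else g.cds[::-1]
            phase = g.phase
            phases = {}
            for s, e in order:
                phases[(s, e)] = phase
                phase = (3 - ((e - s) - phase) % 3) % 3
            for i, (s, e) in enumerate(g.cds):
                fh.write(
                    f"{g.chrom}\tpoolscan\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f"{phases[(s, e)]}\tID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )
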