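"""Reading, writing and preprocessing of coding sequences.

Genes are grouped into virus families (one FASTA per family, or a single
FASTA plus a ``gene_id<TAB>family`` map).  Before any statistics are
collected the family is reduced to cluster representatives at a given
identity level, emulating the usual redundancy-reduction step.  A
sliding-window segmenter supports single-genome mode, where windows of a
genome rather than annotated genes are ranked.

Conventions
-----------
* Sequences are uppercased on ingest; ``U`` is mapped to ``T``.  IUPAC
  ambiguity codes are tolerated; downstream word counting skips words
  containing non-ACGT characters.
* Coordinates are 0-based, half-open.  Sequences are taken as given (the
  coding strand of the CDS); there is no reverse-complement
  canonicalisation, because strand asymmetries of single-stranded viral
  genomes are themselves informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio import SeqIO

from .errors import ParameterError, ValidationError

__all__ = [
    "GeneRecord",
    "FamilyDataset",
    "Segment",
    "read_family_fasta",
    "read_family_map",
    "read_families",
    "write_family_fasta",
    "write_cluster_table",
    "greedy_clusters",
    "reduce_redundancy",
    "select_representatives",
    "sliding_window",
]

#: IUPAC nucleotide one-letter codes accepted on ingest.
IUPAC_NT = frozenset("ACGTRYSWKMBDHVN")


def _clean_seq(seq: str) -> str:
    s = str(seq).strip().upper().replace("U", "T")
    if not s:
        raise ValidationError("empty sequence")
    bad = set(s) - IUPAC_NT
    if bad:
        raise ValidationError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class GeneRecord:
    """One coding nucleotide sequence with its family membership."""

    gene_id: str
    family: str
    seq: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        object.__setattr__(self, "seq", _clean_seq(self.seq))

    @property
    def length_nt(self) -> int:
        return len(self.seq)


@dataclass
class FamilyDataset:
    """An ordered collection of genes attributed to one virus family.

    Gene order is the stable ingest order; ties elsewhere in the pipeline
    (equal distances, equal GC deviations) break on this order.
    """

    family: str
    genes: list[GeneRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValidationError(f"duplicate gene_id {i!r} in family {self.family!r}")
                seen.add(i)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def require_analyzable(self) -> None:
        """Families with more than three genes are analyzable."""
        from .errors import DatasetTooSmallError

        if len(self.genes) <= 3:
            raise DatasetTooSmallError(
                f"family {self.family!r} has {len(self.genes)} genes; more than 3 required"
            )


@dataclass(frozen=True)
class Segment:
    """A window of a genome, 0-based half-open coordinates."""

    segment_id: str
    source_genome: str
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError("segment requires 0 <= start < end")
        if self.end - self.start != len(self.seq):
            raise ValidationError("segment length does not match coordinates")


# ---------------------------------------------------------------------------
# FASTA / TSV input and output
# ---------------------------------------------------------------------------

def read_family_fasta(path, family: str) -> FamilyDataset:
    """Read one family FASTA; headers are parsed to the first token."""
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gid = rec.id
        if gid in seen:
            raise ValidationError(f"duplicate gene_id {gid!r} in {path}")
        seen.add(gid)
        genes.append(GeneRecord(gene_id=gid, family=family, seq=str(rec.seq)))
    if not genes:
        raise ValidationError(f"no FASTA records found in {path}")
    return FamilyDataset(family=family, genes=genes, provenance=f"fasta:{path}")


def read_family_map(path) -> dict[str, str]:
    """Read a two-column ``gene_id<TAB>family`` table."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected gene_id<TAB>family")
            gid, fam = parts
            if gid in mapping:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            mapping[gid] = fam
    if not mapping:
        raise ValidationError(f"empty family map {path}")
    return mapping


def read_families(fasta_path, map_path) -> list[FamilyDataset]:
    """Single-file mode: split one FASTA into families using a TSV map.

    Families are returned in order of first appearance in the FASTA; genes
    keep their FASTA order within each family.
    """
    mapping = read_family_map(map_path)
    by_family: dict[str, list[GeneRecord]] = {}
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        gid = rec.id
        if gid in seen:
            raise ValidationError(f"duplicate gene_id {gid!r} in {fasta_path}")
        seen.add(gid)
        if gid not in mapping:
            raise ValidationError(f"gene {gid!r} missing from family map")
        fam = mapping[gid]
        by_family.setdefault(fam, []).append(GeneRecord(gene_id=gid, family=fam, seq=str(rec.seq)))
    if not by_family:
        raise ValidationError(f"no FASTA records found in {fasta_path}")
    return [
        FamilyDataset(family=f, genes=gs, provenance=f"fasta:{fasta_path} map:{map_path}")
        for f, gs in by_family.items()
    ]


def write_family_fasta(ds: FamilyDataset, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for g in ds.genes:
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


def write_cluster_table(assignments: dict[str, str], path) -> None:
    """Write a ``gene_id<TAB>representative_id`` table in ingest order."""
    with open(path, "w") as fh:
        fh.write("gene_id\trepresentative_id\n")
        for gid, rep in assignments.items():
            fh.write(f"{gid}\t{rep}\n")


# ---------------------------------------------------------------------------
# Redundancy reduction
# ---------------------------------------------------------------------------

def _kmer_set(seq: str, k: int) -> frozenset[str]:
    acgt = frozenset("ACGT")
    return frozenset(
        seq[i : i + k] for i in range(len(seq) - k + 1) if set(seq[i : i + k]) <= acgt
    )


def greedy_clusters(ds: FamilyDataset, identity: float = 0.95, k: int = 5) -> dict[str, str]:
    """Greedy incremental clustering; returns gene_id -> representative_id.

    Genes are processed in order of decreasing length (ties keep ingest
    order).  A gene joins the first existing cluster whose representative
    shares at least ``identity`` of the gene's k-mers (containment over the
    shorter sequence, which is always the incoming gene); otherwise it
    founds a new cluster.  Representatives are cluster founders.

    This is a deliberately lightweight stand-in for alignment-based
    clustering: the downstream method only needs redundancy reduction, not
    exact identity values.
    """
    if not (0.0 < identity <= 1.0):
        raise ParameterError(f"identity must be in (0, 1], got {identity}")
    if not ds.genes:
        raise ValidationError("cannot cluster an empty dataset")
    order = sorted(range(len(ds.genes)), key=lambda i: -ds.genes[i].length_nt)
    reps: list[tuple[int, frozenset[str]]] = []  # (gene index, k-mer set)
    assignment_by_index: dict[int, int] = {}
    for idx in order:
        g = ds.genes[idx]
        km = _kmer_set(g.seq, k)
        joined = False
        for rep_idx, rep_km in reps:
            if km:
                frac = len(km & rep_km) / len(km)
            else:  # too short for k-mers: merge only on exact sequence match
                frac = 1.0 if g.seq == ds.genes[rep_idx].seq else 0.0
            if frac >= identity:
                assignment_by_index[idx] = rep_idx
                joined = True
                break
        if not joined:
            reps.append((idx, km))
            assignment_by_index[idx] = idx
    # report in ingest order
    return {
        ds.genes[i].gene_id: ds.genes[assignment_by_index[i]].gene_id
        for i in range(len(ds.genes))
    }


def reduce_redundancy(ds: FamilyDataset, identity: float = 0.95, k: int = 5) -> FamilyDataset:
    """Collapse near-identical genes to cluster representatives.

    Representatives are returned in ingest order.  Applying the operation a
    second time is a no-op (founders are pairwise below the identity
    threshold by construction).
    """
    assignments = greedy_clusters(ds, identity=identity, k=k)
    rep_ids = {rep for rep in assignments.values()}
    genes = [g for g in ds.genes if g.gene_id in rep_ids]
    prov = (ds.provenance + "; " if ds.provenance else "") + (
        f"greedy-cluster identity={identity} k={k} ({len(ds.genes)}->{len(genes)})"
    )
    return FamilyDataset(family=ds.family, genes=genes, provenance=prov)


def select_representatives(ds: FamilyDataset, rep_ids) -> FamilyDataset:
    """Keep a user-supplied representative list (e.g. from external CD-HIT)."""
    keep = set(rep_ids)
    unknown = keep - set(ds.gene_ids)
    if unknown:
        raise ValidationError(f"representative ids not in dataset: {sorted(unknown)[:5]}")
    genes = [g for g in ds.genes if g.gene_id in keep]
    return replace(ds, genes=genes, provenance=ds.provenance + "; external representatives")


# ---------------------------------------------------------------------------
# Sliding-window segmentation
# ---------------------------------------------------------------------------

def sliding_window(
    genome_seq: str, window: int, step: int, source_genome: str = "genome"
) -> list[Segment]:
    """Cut a genome into windows at starts 0, step, 2*step, ...

    The trailing segment is truncated at the genome end; it is kept iff its
    length is at least half the window, otherwise dropped.
    """
    seq = _clean_seq(genome_seq)
    if window < 1 or step < 1:
        raise ParameterError("window and step must be >= 1")
    if window > len(seq):
        raise ValidationError(f"window {window} exceeds genome length {len(seq)}")
    segments: list[Segment] = []
    for start in range(0, len(seq), step):
        end = min(start + window, len(seq))
        length = end - start
        if length < window and length < window / 2:
            continue
        segments.append(
            Segment(
                segment_id=f"{source_genome}:{start}-{end}",
                source_genome=source_genome,
                start=start,
                end=end,
                seq=seq[start:end],
            )
        )
    return segments
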