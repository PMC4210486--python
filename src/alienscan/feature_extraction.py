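"""Compositional signatures of coding sequences.

Nine feature sets are supported, each turning a gene into a fixed-length
real vector:

================  ====  =============================================
name              dim   description
================  ====  =============================================
mono                 4  mononucleotide frequencies
di                  16  dinucleotide frequencies (overlapping words)
tri                 64  trinucleotide frequencies (overlapping words)
tetra              256  tetranucleotide frequencies (overlapping words)
codon_usage         64  codon frequencies (frame 0, stops included)
relative_codon_usage 64 codon frequencies within synonymous families
amino_acid          20  amino-acid frequencies of the translation
position_nt         12  nucleotide frequencies per codon position
gc_content           1  fraction of G+C among unambiguous bases
================  ====  =============================================

Word counting uses overlapping windows; any window containing a non-ACGT
character is skipped rather than guessed at.  Codon-based sets read frame 0
of the provided CDS and drop a trailing partial codon with a logged
warning.  Translation uses the standard genetic code by default
(configurable NCBI table id).

Feature matrices are standardized column-wise to zero mean and unit
variance (population standard deviation) before being passed to the SVM;
constant columns map to all-zeros.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .errors import DatasetTooSmallError, ParameterError, UnencodableError, ValidationError
from .sequence_io import FamilyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "ALL_SPECS",
    "DEFAULT_SPEC",
    "get_spec",
    "feature_names",
    "encode",
    "oligo_freqs",
    "gc_content",
    "codon_usage",
    "relative_codon_usage",
    "amino_acid_freqs",
    "position_nt_freqs",
    "build_feature_matrix",
    "standardize",
    "apply_standardization",
    "regress_out_gc",
]

BASES = "ACGT"
CODONS = ["".join(p) for p in itertools.product(BASES, repeat=3)]
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical one-letter codes

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i


def _codes(seq: str) -> np.ndarray:
    """Map a sequence to integer codes; -1 marks non-ACGT characters."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class FeatureSpec:
    """A named gene encoding and its dimensionality."""

    name: str
    k: int | None
    dimension: int


ALL_SPECS: tuple[FeatureSpec, ...] = (
    FeatureSpec("mono", 1, 4),
    FeatureSpec("di", 2, 16),
    FeatureSpec("tri", 3, 64),
    FeatureSpec("tetra", 4, 256),
    FeatureSpec("codon_usage", None, 64),
    FeatureSpec("relative_codon_usage", None, 64),
    FeatureSpec("amino_acid", None, 20),
    FeatureSpec("position_nt", None, 12),
    FeatureSpec("gc_content", None, 1),
)

#: Tetranucleotide frequencies: the best-performing signature and the default.
DEFAULT_SPEC = ALL_SPECS[3]

_BY_NAME = {s.name: s for s in ALL_SPECS}
_ALIASES = {
    "codon": "codon_usage",
    "relcodon": "relative_codon_usage",
    "aa": "amino_acid",
    "posnt": "position_nt",
    "gc": "gc_content",
}


def get_spec(name: str) -> FeatureSpec:
    key = _ALIASES.get(name, name)
    try:
        return _BY_NAME[key]
    except KeyError:
        raise ParameterError(
            f"unknown feature set {name!r}; choose from "
            f"{sorted(_BY_NAME) + sorted(_ALIASES)}"
        ) from None


def feature_names(spec: FeatureSpec) -> list[str]:
    """Column labels for TSV output."""
    if spec.name in ("mono", "di", "tri", "tetra"):
        return ["".join(p) for p in itertools.product(BASES, repeat=spec.k)]
    if spec.name == "codon_usage":
        return list(CODONS)
    if spec.name == "relative_codon_usage":
        return [f"rcu_{c}" for c in CODONS]
    if spec.name == "amino_acid":
        return [f"aa_{a}" for a in AA_ORDER]
    if spec.name == "position_nt":
        return [f"p{p}_{b}" for p in (1, 2, 3) for b in BASES]
    if spec.name == "gc_content":
        return ["GC"]
    raise ParameterError(f"unknown spec {spec.name!r}")


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

def _code_tables(table_id: int = 1) -> tuple[dict[str, str], tuple[str, ...]]:
    """(codon -> one-letter amino acid, stop codons) for an NCBI table id."""
    try:
        table = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError:
        raise ParameterError(f"unknown genetic code table id {table_id}") from None
    return dict(table.forward_table), tuple(table.stop_codons)


def _synonymous_families(table_id: int = 1) -> list[list[int]]:
    """Codon indices grouped by encoded amino acid; stops form one family."""
    fwd, stops = _code_tables(table_id)
    groups: dict[str, list[int]] = {}
    for i, codon in enumerate(CODONS):
        aa = fwd.get(codon, "*" if codon in stops else None)
        if aa is None:  # pragma: no cover - complete tables only
            raise ParameterError(f"codon {codon} missing from table {table_id}")
        groups.setdefault(aa, []).append(i)
    return list(groups.values())


# ---------------------------------------------------------------------------
# Per-sequence encoders
# ---------------------------------------------------------------------------

def oligo_freqs(seq: str, k: int) -> np.ndarray:
    """Overlapping k-mer frequencies in lexicographic order (k in 1..4)."""
    if not 1 <= k <= 4:
        raise ParameterError(f"k must be in 1..4, got {k}")
    c = _codes(seq)
    n_win = len(c) - k + 1
    if n_win < 1:
        raise UnencodableError(f"sequence shorter than k={k}")
    idx = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        w = c[j : j + n_win]
        valid &= w >= 0
        idx = idx * 4 + np.where(w >= 0, w, 0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise UnencodableError(f"no ACGT-only window of length {k}")
    return np.bincount(idx[valid], minlength=4**k).astype(float) / n_valid


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); ambiguity codes excluded from both sides."""
    c = _codes(seq)
    n = int((c >= 0).sum())
    if n == 0:
        raise UnencodableError("no unambiguous nucleotides")
    gc = int(((c == 1) | (c == 2)).sum())
    return gc / n


def _codon_counts(seq: str) -> np.ndarray:
    """Counts of the 64 codons in frame 0; ambiguous codons are skipped."""
    c = _codes(seq)
    n_codons = len(c) // 3
    if n_codons < 1:
        raise UnencodableError("sequence shorter than one codon")
    if len(c) % 3:
        logger.warning("trailing partial codon (%d nt) dropped", len(c) % 3)
    cod = c[: 3 * n_codons].reshape(n_codons, 3)
    valid = (cod >= 0).all(axis=1)
    if not valid.any():
        raise UnencodableError("no ACGT-only codon in frame 0")
    idx = cod[valid] @ np.array([16, 4, 1])
    return np.bincount(idx, minlength=64).astype(float)


def codon_usage(seq: str) -> np.ndarray:
    counts = _codon_counts(seq)
    return counts / counts.sum()


def relative_codon_usage(seq: str, table_id: int = 1) -> np.ndarray:
    """Codon frequency within its synonymous family (stops are one family).

    A family never observed in the gene is assigned the uniform value
    1/len(family): this keeps rows free of 0/0 artefacts and comparable
    across genes.
    """
    counts = _codon_counts(seq)
    out = np.empty(64)
    for fam in _synonymous_families(table_id):
        tot = counts[fam].sum()
        if tot > 0:
            out[fam] = counts[fam] / tot
        else:
            out[fam] = 1.0 / len(fam)
    return out


def amino_acid_freqs(seq: str, table_id: int = 1) -> np.ndarray:
    """Frequencies of the 20 amino acids of the translation, stops excluded."""
    counts = _codon_counts(seq)
    fwd, _ = _code_tables(table_id)
    aa_counts = np.zeros(20)
    aa_index = {a: i for i, a in enumerate(AA_ORDER)}
    for i, codon in enumerate(CODONS):
        aa = fwd.get(codon)
        if aa is not None:
            aa_counts[aa_index[aa]] += counts[i]
    tot = aa_counts.sum()
    if tot == 0:
        raise UnencodableError("no sense codon in frame 0")
    return aa_counts / tot


def position_nt_freqs(seq: str) -> np.ndarray:
    """A/C/G/T frequencies at codon positions 1..3; each triplet sums to 1."""
    counts = _codon_counts(seq)
    idx = np.arange(64)
    out = np.empty(12)
    for p, div in enumerate((16, 4, 1)):
        base_of = (idx // div) % 4
        for b in range(4):
            out[4 * p + b] = counts[base_of == b].sum()
        out[4 * p : 4 * p + 4] /= counts.sum()
    return out


def encode(seq: str, spec: FeatureSpec, table_id: int = 1) -> np.ndarray:
    """Encode one sequence under a feature spec; raises UnencodableError."""
    if spec.name in ("mono", "di", "tri", "tetra"):
        return oligo_freqs(seq, spec.k)
    if spec.name == "codon_usage":
        return codon_usage(seq)
    if spec.name == "relative_codon_usage":
        return relative_codon_usage(seq, table_id)
    if spec.name == "amino_acid":
        return amino_acid_freqs(seq, table_id)
    if spec.name == "position_nt":
        return position_nt_freqs(seq)
    if spec.name == "gc_content":
        return np.array([gc_content(seq)])
    raise ParameterError(f"unknown spec {spec.name!r}")


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Genes x dimensions matrix under one feature spec.

    ``excluded`` lists (gene_id, reason) pairs for genes that could not be
    encoded.  After :func:`standardize`, ``center`` and ``scale`` hold the
    column statistics (scale 0 marks a constant column) so that new rows —
    e.g. genome segments scored against a family background — can be
    transformed consistently.
    """

    spec: FeatureSpec
    gene_ids: list[str]
    values: np.ndarray
    standardized: bool = False
    excluded: list[tuple[str, str]] = field(default_factory=list)
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.gene_ids), self.spec.dimension):
            raise ValidationError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {self.spec.dimension} dims"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=feature_names(self.spec))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, spec: FeatureSpec, standardized: bool = False) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        if list(df.columns) != feature_names(spec):
            raise ValidationError(f"column header does not match spec {spec.name!r}")
        return cls(spec=spec, gene_ids=[str(i) for i in df.index],
                   values=df.to_numpy(), standardized=standardized)


def build_feature_matrix(ds: FamilyDataset, spec: FeatureSpec, table_id: int = 1) -> FeatureMatrix:
    """Encode every gene of a family; unencodable genes are excluded and reported."""
    ds.require_analyzable()
    rows, ids, excluded = [], [], []
    for g in ds.genes:
        try:
            rows.append(encode(g.seq, spec, table_id))
            ids.append(g.gene_id)
        except UnencodableError as e:
            excluded.append((g.gene_id, str(e)))
    if len(rows) < 4:
        raise DatasetTooSmallError(
            f"family {ds.family!r}: only {len(rows)} encodable genes under "
            f"{spec.name!r}; at least 4 required"
        )
    return FeatureMatrix(spec=spec, gene_ids=ids, values=np.vstack(rows), excluded=excluded)


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Column-wise z-scores (population sd); constant columns become zeros.

    Idempotent: standardizing an already standardized matrix returns the
    same values to within floating tolerance.
    """
    if fm.n_genes < 2:
        raise ValidationError("standardization requires at least 2 rows")
    center = fm.values.mean(axis=0)
    scale = fm.values.std(axis=0)  # population (ddof=0)
    scale = np.where(scale > 1e-12, scale, 0.0)
    return FeatureMatrix(
        spec=fm.spec,
        gene_ids=list(fm.gene_ids),
        values=apply_standardization(fm.values, center, scale),
        standardized=True,
        excluded=list(fm.excluded),
        center=center,
        scale=scale,
    )


def apply_standardization(values: np.ndarray, center: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Apply stored column statistics to (possibly new) rows."""
    safe = np.where(scale > 0, scale, 1.0)
    out = (np.asarray(values, dtype=float) - center) / safe
    out[:, scale == 0] = 0.0
    return out


def regress_out_gc(fm: FeatureMatrix, gc_values: np.ndarray) -> FeatureMatrix:
    """EXPERIMENTAL: replace each column by its residual after OLS on GC.

    After standardization this variant collapses onto essentially the same
    solution as the raw features, and it is excluded from the default nine
    feature sets; it is retained only behind an explicit flag.
    """
    if fm.standardized:
        raise ValidationError("regress_out_gc expects an unstandardized matrix")
    gc = np.asarray(gc_values, dtype=float)
    if gc.shape != (fm.n_genes,):
        raise ValidationError("gc_values must have one entry per gene")
    X = np.column_stack([np.ones_like(gc), gc])
    beta, *_ = np.linalg.lstsq(X, fm.values, rcond=None)
    resid = fm.values - X @ beta
    return FeatureMatrix(spec=fm.spec, gene_ids=list(fm.gene_ids), values=resid,
                         excluded=list(fm.excluded))
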