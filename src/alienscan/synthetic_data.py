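"""Synthetic virus families with controlled compositional divergence.

Real viral gene corpora are large and uncurated; this module generates
families whose genes carry a family-specific *codon-level* signature, the
statistical structure the detection method assumes.  Each gene is an
in-frame CDS: ATG, then L codons drawn i.i.d. from a family codon
distribution (internal stops excluded), then exactly one stop codon.

Drawing whole codons — rather than nucleotides from a Markov chain — means
one parameter set simultaneously shapes codon usage, relative codon usage,
amino-acid, position-wise and oligonucleotide signatures, so every feature
set inherits family structure from the same source model.

`generate_benchmark` creates several families whose codon distributions
interpolate between a shared base distribution (divergence d = 0: families
statistically identical, no signal) and family-unique distributions
(d = 1: maximally distinct).  An optional GC-matching mode exponentially
tilts each family distribution so all families share the base expected GC,
isolating codon-usage signal from the one-dimensional GC baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterError
from .feature_extraction import CODONS
from .sequence_io import FamilyDataset, GeneRecord

__all__ = [
    "STOP_CODONS",
    "SENSE_CODONS",
    "FamilyGeneratorConfig",
    "generate_family",
    "generate_benchmark",
    "random_codon_distribution",
    "expected_gc",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
STOP_INDICES = tuple(CODONS.index(c) for c in STOP_CODONS)
SENSE_CODONS = tuple(c for c in CODONS if c not in STOP_CODONS)
_SENSE_INDICES = np.array([i for i in range(64) if i not in STOP_INDICES])
#: GC fraction of each sense codon.
_SENSE_GC = np.array([sum(b in "GC" for b in c) / 3.0 for c in SENSE_CODONS])

#: Dirichlet concentrations: the base distribution is moderately even, the
#: family-unique distributions are skewed (strong codon bias).
BASE_CONCENTRATION = 5.0
UNIQUE_CONCENTRATION = 0.5

#: Realistic viral CDS length range, in codons (~300-1200 nt).
DEFAULT_LENGTH_CODONS = (100, 400)


@dataclass
class FamilyGeneratorConfig:
    """Source model of one synthetic family.

    ``codon_weights`` has 64 entries in lexicographic codon order; stop
    codon weights are forced to zero for internal positions (genes end with
    exactly one terminal stop instead).
    """

    family_id: str
    n_genes: int
    codon_weights: np.ndarray
    length_codons: tuple[int, int] = DEFAULT_LENGTH_CODONS
    seed: int = 0
    divergence: float | None = None  # provenance only; mixing happens upstream

    def __post_init__(self) -> None:
        if self.n_genes < 4:
            raise ParameterError("n_genes must be >= 4")
        lo, hi = self.length_codons
        if not (1 <= lo <= hi):
            raise ParameterError(f"invalid length range {self.length_codons}")
        w = np.asarray(self.codon_weights, dtype=float)
        if w.shape != (64,):
            raise ParameterError("codon_weights must have 64 entries")
        if (w < 0).any() or not np.isfinite(w).all():
            raise ParameterError("codon_weights must be finite and non-negative")
        w = w.copy()
        w[list(STOP_INDICES)] = 0.0
        if w.sum() <= 0:
            raise ParameterError("codon_weights are all zero after removing stops")
        self.codon_weights = w / w.sum()


def generate_family(cfg: FamilyGeneratorConfig) -> FamilyDataset:
    """Draw n_genes i.i.d. CDS sequences; byte-deterministic given the seed."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_codons
    genes = []
    for i in range(cfg.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        idx = rng.choice(64, size=n_codons, p=cfg.codon_weights)
        stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
        seq = "ATG" + "".join(CODONS[j] for j in idx) + stop
        genes.append(GeneRecord(gene_id=f"{cfg.family_id}_g{i:04d}", family=cfg.family_id,
                                seq=seq))
    return FamilyDataset(
        family=cfg.family_id,
        genes=genes,
        provenance=f"synthetic seed={cfg.seed} length_codons={cfg.length_codons}"
        + (f" divergence={cfg.divergence}" if cfg.divergence is not None else ""),
    )


def random_codon_distribution(rng: np.random.Generator,
                              concentration: float) -> np.ndarray:
    """Dirichlet draw over the 61 sense codons, embedded into 64 dims."""
    w61 = rng.dirichlet(np.full(len(SENSE_CODONS), concentration))
    w = np.zeros(64)
    w[_SENSE_INDICES] = w61
    return w


def expected_gc(codon_weights: np.ndarray) -> float:
    """Expected per-nucleotide GC of internal codons under the source model."""
    w = np.asarray(codon_weights, dtype=float)[_SENSE_INDICES]
    return float(w @ _SENSE_GC / w.sum())


def _tilt_to_gc(codon_weights: np.ndarray, target_gc: float) -> np.ndarray:
    """Exponentially tilt a codon distribution to a target expected GC.

    Reweights codon c by exp(lambda * gc(c)) and solves for lambda; this is
    the minimal (KL-closest) adjustment achieving the GC constraint, so the
    family's codon-usage character is preserved.
    """
    w = np.asarray(codon_weights, dtype=float)[_SENSE_INDICES]
    w = w / w.sum()

    def gap(lam: float) -> float:
        z = lam * (_SENSE_GC - _SENSE_GC.mean())
        t = w * np.exp(z - z.max())
        return float(t @ _SENSE_GC / t.sum()) - target_gc

    if abs(gap(0.0)) < 1e-12:
        lam = 0.0
    else:
        lam = brentq(gap, -200.0, 200.0, xtol=1e-12)
    z = lam * (_SENSE_GC - _SENSE_GC.mean())
    t = w * np.exp(z - z.max())
    out = np.zeros(64)
    out[_SENSE_INDICES] = t / t.sum()
    return out


def generate_benchmark(
    n_families: int,
    divergence: float,
    per_family_n: int,
    seed: int = 0,
    length_codons: tuple[int, int] = DEFAULT_LENGTH_CODONS,
    match_gc: bool = False,
) -> list[FamilyDataset]:
    """Families sharing a base codon distribution, perturbed by divergence d.

    Family f draws codons from (1-d)*base + d*unique_f.  With
    ``match_gc=True`` every family distribution is tilted to the base
    expected GC, so families differ in codon usage but not in GC.
    """
    if n_families < 2:
        raise ParameterError("n_families must be >= 2")
    if not (0.0 <= divergence <= 1.0):
        raise ParameterError(f"divergence must be in [0, 1], got {divergence}")
    ss = np.random.SeedSequence(seed)
    dist_seed, *family_seeds = ss.spawn(n_families + 1)
    rng = np.random.default_rng(dist_seed)
    base = random_codon_distribution(rng, BASE_CONCENTRATION)
    target_gc = expected_gc(base)
    families = []
    for f in range(n_families):
        unique = random_codon_distribution(rng, UNIQUE_CONCENTRATION)
        weights = (1.0 - divergence) * base + divergence * unique
        if match_gc:
            weights = _tilt_to_gc(weights, target_gc)
        cfg = FamilyGeneratorConfig(
            family_id=f"synthfam{f:02d}",
            n_genes=per_family_n,
            codon_weights=weights,
            length_codons=length_codons,
            seed=int(family_seeds[f].generate_state(1)[0] % (2**31)),
            divergence=divergence,
        )
        families.append(generate_family(cfg))
    return families
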