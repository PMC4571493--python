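"""Domain containers and marker-level preprocessing.

A :class:`GenotypeMatrix` holds biallelic SNP genotypes as additive dosage
codes (0 and 2 the two homozygotes, 1 the heterozygote), with a reserved
out-of-band sentinel for missing calls.  Code 2 counts the ALT/minor allele
twice (VCF dosage convention); which homozygote carries 0 vs 2 is a labelling
choice the data-driven encodings are invariant to.

The sentinel is -9, never -1: -1 is a legal encoded value under the
{-1, 0, 1} scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Reserved sentinel for a missing genotype call.
MISSING: int = -9

_VALID_CODES = frozenset({0, 1, 2, MISSING})


class TraitPredError(Exception):
    """Base class for all errors raised by this package."""


class AlignmentError(TraitPredError):
    """Genotype and phenotype sample ids cannot be aligned."""


class ImputationError(TraitPredError):
    """A marker has no observed genotypes to impute from."""


class ParseError(TraitPredError):
    """A genotype or phenotype file could not be parsed."""


@dataclass
class GenotypeMatrix:
    """n samples x m markers of integer genotype codes {0, 1, 2, MISSING}."""

    sample_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.marker_ids = list(self.marker_ids)
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D array")
        n, m = self.codes.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {n} genotype rows"
            )
        if m != len(self.marker_ids):
            raise ValueError(
                f"{len(self.marker_ids)} marker ids but {m} genotype columns"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        bad = set(np.unique(self.codes)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        if not np.issubdtype(self.codes.dtype, np.integer):
            self.codes = self.codes.astype(np.int16)

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def has_missing(self) -> bool:
        return bool((self.codes == MISSING).any())


@dataclass
class TraitVector:
    """Real-valued phenotype, one value per sample."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.sample_ids) != self.values.size:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {self.values.size} trait values"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class MarkerFilterSpec:
    """Marker QC thresholds.

    A marker is kept when its missing fraction is <= ``max_missing_rate``,
    its minor-allele frequency is >= ``min_maf``, and its heterozygote
    fraction is <= ``max_heterozygosity`` (all boundaries inclusive for
    keeping).
    """

    max_missing_rate: float = 0.10
    min_maf: float = 0.001
    max_heterozygosity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must lie in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")
        if not 0.0 <= self.max_heterozygosity <= 1.0:
            raise ValueError("max_heterozygosity must lie in [0, 1]")


@dataclass
class FilterReport:
    """Which markers were dropped and the first rule each one failed."""

    dropped: list[tuple[str, str]] = field(default_factory=list)
    n_kept: int = 0
    all_dropped: bool = False


def validate_alignment(
    g: GenotypeMatrix, t: TraitVector
) -> tuple[GenotypeMatrix, TraitVector]:
    """Restrict genotypes and traits to their shared samples, in one order.

    The canonical order is the genotype matrix's sample order restricted to
    the intersection; marker order is unchanged.
    """
    if g.n_samples == 0 or t.n_samples == 0:
        raise AlignmentError("cannot align empty inputs")
    t_index = {s: i for i, s in enumerate(t.sample_ids)}
    shared = [s for s in g.sample_ids if s in t_index]
    if not shared:
        raise AlignmentError(
            f"no shared sample ids between genotypes ({g.n_samples} samples) "
            f"and traits ({t.n_samples} samples)"
        )
    if shared == g.sample_ids == t.sample_ids:
        return g, t
    g_index = {s: i for i, s in enumerate(g.sample_ids)}
    g_rows = [g_index[s] for s in shared]
    t_rows = [t_index[s] for s in shared]
    g_out = GenotypeMatrix(shared, g.marker_ids, g.codes[g_rows, :])
    t_out = TraitVector(shared, t.values[t_rows])
    return g_out, t_out


def filter_markers(
    g: GenotypeMatrix, spec: MarkerFilterSpec
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop markers failing missing-rate, MAF or heterozygosity thresholds.

    MAF is min(p, 1-p) with p = (2*n_hom2 + n_het) / (2*n_called).  Each
    dropped marker is reported once with the first failing rule, checked in
    the order missing, maf, het.
    """
    if g.n_samples == 0 or g.n_markers == 0:
        raise ValueError("cannot filter an empty genotype matrix")
    codes = g.codes
    n = g.n_samples
    miss = (codes == MISSING).sum(axis=0)
    called = n - miss
    n_het = (codes == 1).sum(axis=0)
    n_hom2 = (codes == 2).sum(axis=0)

    miss_rate = miss / n
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, (2 * n_hom2 + n_het) / (2 * np.maximum(called, 1)), 0.0)
        het_rate = np.where(called > 0, n_het / np.maximum(called, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)

    report = FilterReport()
    keep = np.ones(g.n_markers, dtype=bool)
    for j, marker in enumerate(g.marker_ids):
        if miss_rate[j] > spec.max_missing_rate:
            keep[j] = False
            report.dropped.append((marker, "missing"))
        elif called[j] == 0 or maf[j] < spec.min_maf:
            keep[j] = False
            report.dropped.append((marker, "maf"))
        elif het_rate[j] > spec.max_heterozygosity:
            keep[j] = False
            report.dropped.append((marker, "het"))
    kept_ids = [m for m, k in zip(g.marker_ids, keep) if k]
    report.n_kept = len(kept_ids)
    report.all_dropped = not kept_ids
    out = GenotypeMatrix(g.sample_ids, kept_ids, codes[:, keep])
    return out, report


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace MISSING by the per-marker modal code (ties toward smaller)."""
    if not g.has_missing():
        return g
    codes = g.codes.copy()
    for j in range(g.n_markers):
        col = codes[:, j]
        mask = col == MISSING
        if not mask.any():
            continue
        observed = col[~mask]
        if observed.size == 0:
            raise ImputationError(
                f"marker {g.marker_ids[j]!r} has no observed genotypes"
            )
        counts = np.bincount(observed, minlength=3)
        # argmax returns the first (smallest) code on ties
        col[mask] = int(np.argmax(counts))
    return GenotypeMatrix(g.sample_ids, g.marker_ids, codes)
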