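"""Genotype encodings: fixed schemes, data-driven, and pairwise grids.

A linear genomic-prediction model needs real numbers for the three genotype
classes.  The traditional schemes ({0,1,2} or {-1,0,1}) use one map for every
marker.  The data-driven encodings instead use the training phenotype:

* pure     — E(i, c) is the mean trait of training samples with code c at
             marker i, for all three codes;
* hybrid   — E(i, 0) and E(i, 2) as in pure, but E(i, 1) is the grand mean
             of all training traits, preserving the traditional idea that
             the heterozygote sits "between" the homozygotes;
* pairwise — a 3x3 grid per marker pair: corner cells are conditional means
             given both codes, edge cells (one code = 1) are marginal means
             given the other marker's code, and the centre cell (1, 1) is
             the training grand mean.

Genotype classes unseen in training fall back to the training grand mean.
Tables are fitted on training samples only and applied read-only elsewhere;
fitting on test traits would leak the prediction target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from traitpred.core import GenotypeMatrix, TraitVector, TraitPredError

_SCHEMES: dict[str, tuple[float, float, float]] = {
    "{0,1,2}": (0.0, 1.0, 2.0),
    "{-1,0,1}": (-1.0, 0.0, 1.0),
}


class EncodingError(TraitPredError):
    """Raised when an encoding cannot be fitted or applied."""


@dataclass
class EncodingTable:
    """Per-marker map {0,1,2} -> real value.

    ``marker_ids is None`` marks a universal table (a fixed scheme) that
    applies the same map to any marker.
    """

    marker_ids: list[str] | None
    values: np.ndarray  # (m, 3) or (1, 3) if universal
    fallback: float
    provenance: str  # traditional | shifted | pure | hybrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError("values must have shape (m, 3)")
        if self.marker_ids is not None:
            self.marker_ids = list(self.marker_ids)
            if len(self.marker_ids) != self.values.shape[0]:
                raise ValueError("marker_ids and values length mismatch")
        if not np.all(np.isfinite(self.values)) or not np.isfinite(self.fallback):
            raise ValueError("encoding values must be finite")

    @property
    def is_universal(self) -> bool:
        return self.marker_ids is None

    def values_for(self, marker_ids: list[str]) -> np.ndarray:
        """Return the (len(marker_ids), 3) value block for the given markers."""
        if self.is_universal:
            return np.tile(self.values[0], (len(marker_ids), 1))
        index = {m: i for i, m in enumerate(self.marker_ids)}
        try:
            rows = [index[m] for m in marker_ids]
        except KeyError as exc:
            raise EncodingError(f"marker {exc.args[0]!r} absent from encoding table")
        return self.values[rows]

    def to_tsv(self, path: str) -> None:
        """Serialize as (marker id, E0, E1, E2, fallback) for audit."""
        with open(path, "w") as fh:
            fh.write("marker_id\tE0\tE1\tE2\tfallback\n")
            ids = self.marker_ids if self.marker_ids is not None else ["*"]
            for mid, row in zip(ids, self.values):
                cells = "\t".join(f"{v:.17g}" for v in row)
                fh.write(f"{mid}\t{cells}\t{self.fallback:.17g}\n")


@dataclass
class PairEncodingTable:
    """Per marker-pair 3x3 grid of real values, indexed (code_i, code_j)."""

    pairs: list[tuple[str, str]]
    grids: np.ndarray  # (n_pairs, 3, 3)
    fallback: float
    grand_mean: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.pairs = [tuple(p) for p in self.pairs]
        self.grids = np.asarray(self.grids, dtype=float)
        if self.grids.shape != (len(self.pairs), 3, 3):
            raise ValueError("grids must have shape (n_pairs, 3, 3)")
        if not np.all(np.isfinite(self.grids)):
            raise ValueError("grid values must be finite")
        if np.isnan(self.grand_mean):
            self.grand_mean = self.fallback

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            header = "\t".join(
                f"E{a}{b}" for a in (0, 1, 2) for b in (0, 1, 2)
            )
            fh.write(f"marker_i\tmarker_j\t{header}\n")
            for (mi, mj), grid in zip(self.pairs, self.grids):
                cells = "\t".join(f"{v:.17g}" for v in grid.ravel())
                fh.write(f"{mi}\t{mj}\t{cells}\n")


def traditional_encoding(scheme: str) -> EncodingTable:
    """A fixed scheme applied uniformly to every marker.

    ``scheme`` is ``"{0,1,2}"`` (additive dosage) or ``"{-1,0,1}"`` (shifted:
    -1 and 1 for the homozygotes, 0 for the heterozygote).
    """
    key = scheme.replace(" ", "").replace("−", "-")
    if key not in _SCHEMES:
        raise EncodingError(
            f"unknown scheme {scheme!r}; expected one of {sorted(_SCHEMES)}"
        )
    vals = np.array([_SCHEMES[key]])
    provenance = "traditional" if key == "{0,1,2}" else "shifted"
    return EncodingTable(None, vals, fallback=vals[0, 1], provenance=provenance)


def _check_fit_inputs(g: GenotypeMatrix, t: TraitVector) -> None:
    if g.sample_ids != t.sample_ids:
        raise EncodingError("genotypes and traits are not aligned; "
                            "call validate_alignment first")
    if g.n_samples == 0:
        raise EncodingError("cannot fit an encoding on zero samples")
    if g.has_missing():
        raise EncodingError("genotypes contain missing values; impute first")


def _class_means(codes_col: np.ndarray, y: np.ndarray, grand: float) -> np.ndarray:
    out = np.empty(3)
    for c in (0, 1, 2):
        mask = codes_col == c
        out[c] = y[mask].mean() if mask.any() else grand
    return out


def fit_pure(g: GenotypeMatrix, t: TraitVector) -> EncodingTable:
    """Pure data-driven encoding: E(i, c) = mean trait of the class (i, c)."""
    _check_fit_inputs(g, t)
    y = t.values
    grand = float(y.mean())
    values = np.empty((g.n_markers, 3))
    for j in range(g.n_markers):
        values[j] = _class_means(g.codes[:, j], y, grand)
    return EncodingTable(g.marker_ids, values, fallback=grand, provenance="pure")


def fit_hybrid(g: GenotypeMatrix, t: TraitVector) -> EncodingTable:
    """Hybrid encoding: homozygote classes as in pure, heterozygote = grand mean."""
    table = fit_pure(g, t)
    values = table.values
    values[:, 1] = table.fallback
    return EncodingTable(g.marker_ids, values, fallback=table.fallback,
                         provenance="hybrid")


def fit_pairwise_hybrid(
    g: GenotypeMatrix, t: TraitVector, pairs: list[tuple[str, str]]
) -> PairEncodingTable:
    """Fit the 3x3 data-driven grid for each requested marker pair.

    Grid orientation: row = code at marker i, column = code at marker j.
    Corners condition on both codes; the edge cell (1, c_j) is the marginal
    mean over samples with code c_j at marker j (and likewise for (c_i, 1));
    the centre (1, 1) is the grand mean.  Empty cells fall back to the grand
    mean.
    """
    _check_fit_inputs(g, t)
    y = t.values
    grand = float(y.mean())
    index = {m: i for i, m in enumerate(g.marker_ids)}
    grids = np.empty((len(pairs), 3, 3))
    canonical: list[tuple[str, str]] = []
    for k, (mi, mj) in enumerate(pairs):
        if mi == mj:
            raise EncodingError(f"pair ({mi!r}, {mj!r}) references one marker twice")
        if mi not in index or mj not in index:
            missing = mi if mi not in index else mj
            raise EncodingError(f"pair marker {missing!r} not in genotype matrix")
        ci = g.codes[:, index[mi]]
        cj = g.codes[:, index[mj]]
        grid = np.full((3, 3), grand)
        for a in (0, 2):
            for b in (0, 2):
                mask = (ci == a) & (cj == b)
                if mask.any():
                    grid[a, b] = y[mask].mean()
        for b in (0, 2):  # edge (1, b): marginal on marker j
            mask = cj == b
            if mask.any():
                grid[1, b] = y[mask].mean()
        for a in (0, 2):  # edge (a, 1): marginal on marker i
            mask = ci == a
            if mask.any():
                grid[a, 1] = y[mask].mean()
        grid[1, 1] = grand
        grids[k] = grid
        canonical.append((mi, mj))
    return PairEncodingTable(canonical, grids, fallback=grand, grand_mean=grand)


def apply_encoding(g: GenotypeMatrix, table: EncodingTable):
    """Replace each genotype code with its encoded value.

    Returns an :class:`~traitpred.io_formats.EncodedMatrix` whose feature ids
    are the marker ids, sample order preserved.
    """
    from traitpred.io_formats import EncodedMatrix

    if g.has_missing():
        raise EncodingError("genotypes contain missing values; impute first")
    block = table.values_for(g.marker_ids)  # (m, 3)
    codes = g.codes
    values = block[np.arange(g.n_markers)[None, :], codes]
    return EncodedMatrix(g.sample_ids, g.marker_ids, values)


def apply_pair_encoding(g: GenotypeMatrix, table: PairEncodingTable):
    """Build one feature per pair: value = grid(code_i, code_j), id ``"i:j"``."""
    from traitpred.io_formats import EncodedMatrix

    if g.has_missing():
        raise EncodingError("genotypes contain missing values; impute first")
    index = {m: i for i, m in enumerate(g.marker_ids)}
    n = g.n_samples
    values = np.empty((n, len(table.pairs)))
    feature_ids = []
    for k, (mi, mj) in enumerate(table.pairs):
        if mi not in index or mj not in index:
            missing = mi if mi not in index else mj
            raise EncodingError(f"pair marker {missing!r} not in genotype matrix")
        ci = g.codes[:, index[mi]]
        cj = g.codes[:, index[mj]]
        values[:, k] = table.grids[k][ci, cj]
        feature_ids.append(f"{mi}:{mj}")
    return EncodedMatrix(g.sample_ids, feature_ids, values)


def product_epistasis(g_encoded, pairs: list[tuple[str, str]]):
    """Multiplicative interaction features on an already-encoded matrix.

    This is the classical epistasis construction the data-driven grid is an
    alternative to: the feature for pair (i, j) is the elementwise product of
    the two encoded marker columns.
    """
    from traitpred.io_formats import EncodedMatrix

    index = {f: i for i, f in enumerate(g_encoded.feature_ids)}
    values = np.empty((g_encoded.n_samples, len(pairs)))
    feature_ids = []
    for k, (fi, fj) in enumerate(pairs):
        if fi not in index or fj not in index:
            missing = fi if fi not in index else fj
            raise EncodingError(f"unknown feature id {missing!r}")
        values[:, k] = g_encoded.values[:, index[fi]] * g_encoded.values[:, index[fj]]
        feature_ids.append(f"{fi}:{fj}")
    return EncodedMatrix(g_encoded.sample_ids, feature_ids, values)
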