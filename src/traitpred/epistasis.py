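"""Pairwise-epistasis feature ranking by mutual information.

The interaction feature of a marker pair under a fixed encoding scheme is
the product of the two encoded values.  Distinct genotype combinations can
collapse onto one product (e.g. under {0,1,2}, the pairs (0,1) and (0,2)
both give 0), so the choice of scheme changes the category partition and
hence the ranking.  Four scheme combinations are examined for a pair
(SNP1, SNP2):

    E1 = ({0,1,2}, {0,1,2})    E2 = ({0,1,2}, {2,1,0})
    E3 = ({2,1,0}, {0,1,2})    E4 = ({2,1,0}, {2,1,0})

Mutual information is a plug-in estimate in bits between the product
categories and the phenotype discretized into equal-frequency bins.  Ranked
lists from different schemes are compared by average overlap: the mean,
over prefix depths 1..K, of the fraction of shared pairs in the two
top-k prefixes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from traitpred.core import GenotypeMatrix, TraitVector, TraitPredError

DEFAULT_MI_BINS = 10


class RankingError(TraitPredError):
    """Raised for unusable ranking inputs."""


@dataclass(frozen=True)
class EncodingCombo:
    """A pair of fixed per-marker schemes, each (v0, v1, v2)."""

    scheme_1: tuple[float, float, float]
    scheme_2: tuple[float, float, float]
    name: str = ""


_FWD = (0.0, 1.0, 2.0)
_REV = (2.0, 1.0, 0.0)
E1 = EncodingCombo(_FWD, _FWD, "E1")
E2 = EncodingCombo(_FWD, _REV, "E2")
E3 = EncodingCombo(_REV, _FWD, "E3")
E4 = EncodingCombo(_REV, _REV, "E4")
ALL_COMBOS = (E1, E2, E3, E4)


@dataclass
class RankedPairList:
    """Marker pairs sorted by MI to the trait, descending; ties by (i, j)."""

    entries: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        scores = [s for _, _, s in self.entries]
        if any(s < -1e-12 for s in scores):
            raise ValueError("MI scores must be nonnegative")
        if any(a > b + 1e-12 for a, b in zip(scores[1:], scores[:-1])):
            raise ValueError("scores must be nonincreasing")

    def __len__(self) -> int:
        return len(self.entries)

    def pair_ids(self) -> list[tuple[str, str]]:
        return [(i, j) for i, j, _ in self.entries]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("marker_i\tmarker_j\tMI_bits\trank\n")
            for rank, (mi, mj, s) in enumerate(self.entries, start=1):
                fh.write(f"{mi}\t{mj}\t{s:.17g}\t{rank}\n")


def _discretize_trait(y: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency (quantile) bin labels; a constant trait gets one bin."""
    if bins < 2:
        raise RankingError("bins must be >= 2")
    if np.allclose(y, y[0]):
        return np.zeros(y.size, dtype=int)
    labels = pd.qcut(y, q=bins, labels=False, duplicates="drop")
    return np.asarray(labels, dtype=int)


def _plugin_mi_bits(x: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI in bits between two integer-labelled samples (0 log 0 = 0)."""
    n = x.size
    joint = pd.crosstab(x, b).to_numpy(dtype=float) / n
    px = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (px @ pb)
        terms = np.where(joint > 0, joint * np.log2(ratio), 0.0)
    return float(max(terms.sum(), 0.0))


def mutual_information(
    pair_feature: np.ndarray, t: TraitVector, bins: int = DEFAULT_MI_BINS
) -> float:
    """MI in bits between a categorical feature and the binned trait.

    The trait is discretized into ``bins`` equal-frequency bins; MI is the
    plug-in estimate over observed (category, bin) cells.  A constant trait
    has zero entropy, so MI is 0.
    """
    feat = np.asarray(pair_feature)
    if feat.size != t.n_samples:
        raise RankingError("feature and trait lengths differ")
    if feat.size < 2:
        raise RankingError("need at least 2 samples")
    y_binned = _discretize_trait(t.values, bins)
    _, x = np.unique(feat, return_inverse=True)
    return _plugin_mi_bits(x, y_binned)


def rank_pairs(
    g: GenotypeMatrix,
    t: TraitVector,
    combo: EncodingCombo = E1,
    bins: int = DEFAULT_MI_BINS,
) -> RankedPairList:
    """Score every unordered marker pair by MI of its product feature.

    The pair category is the product of the two scheme-encoded genotype
    values (the interaction term of the epistasis regression under that
    combo).  Pairs are streamed; no m^2 feature matrix is materialized.
    Ties are broken by lexicographic (marker_i, marker_j) order.
    """
    if g.n_markers < 2:
        raise RankingError("need at least 2 markers to form pairs")
    if g.sample_ids != t.sample_ids:
        raise RankingError("genotypes and traits are not aligned")
    if g.has_missing():
        raise RankingError("genotypes contain missing values; impute first")
    y_binned = _discretize_trait(t.values, bins)
    s1 = np.asarray(combo.scheme_1)
    s2 = np.asarray(combo.scheme_2)
    enc1 = s1[g.codes]
    enc2 = s2[g.codes]
    scored: list[tuple[float, str, str]] = []
    for a, b in combinations(range(g.n_markers), 2):
        prod = enc1[:, a] * enc2[:, b]
        _, x = np.unique(prod, return_inverse=True)
        mi = _plugin_mi_bits(x, y_binned)
        scored.append((mi, g.marker_ids[a], g.marker_ids[b]))
    scored.sort(key=lambda e: (-e[0], e[1], e[2]))
    return RankedPairList([(i, j, s) for s, i, j in scored])


def top_k(ranked: RankedPairList, k: int) -> RankedPairList:
    """First min(k, length) entries of a ranked list."""
    if k < 1:
        raise RankingError("k must be >= 1")
    return RankedPairList(ranked.entries[:k])


def average_overlap(a: RankedPairList, b: RankedPairList, depth: int | None = None) -> float:
    """Average overlap of two ranked pair lists down to ``depth``.

    (1/K) * sum_{k=1..K} |top_k(a) & top_k(b)| / k, treating pairs as
    unordered identities.  ``depth`` defaults to the shorter list length.
    Symmetric in its arguments; 1.0 for identical lists, 0.0 for disjoint.
    """
    if depth is None:
        depth = min(len(a), len(b))
    if depth < 1:
        raise RankingError("depth must be >= 1")
    if len(a) < depth or len(b) < depth:
        raise RankingError(
            f"lists of length {len(a)}, {len(b)} are shorter than depth {depth}"
        )
    ids_a = [frozenset(p) for p in a.pair_ids()]
    ids_b = [frozenset(p) for p in b.pair_ids()]
    seen_a: set[frozenset] = set()
    seen_b: set[frozenset] = set()
    total = 0.0
    for k in range(1, depth + 1):
        seen_a.add(ids_a[k - 1])
        seen_b.add(ids_b[k - 1])
        total += len(seen_a & seen_b) / k
    return total / depth


def combo_correlation_matrix(
    g: GenotypeMatrix,
    t: TraitVector,
    bins: int = DEFAULT_MI_BINS,
    depth: int | None = None,
) -> pd.DataFrame:
    """4x4 average-overlap matrix between the rankings under E1..E4."""
    lists = {c.name: rank_pairs(g, t, c, bins) for c in ALL_COMBOS}
    names = [c.name for c in ALL_COMBOS]
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for i in names:
        for j in names:
            mat.loc[i, j] = average_overlap(lists[i], lists[j], depth)
    return mat
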