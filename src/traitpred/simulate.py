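"""Synthetic genotype/trait generator for oligogenic and polygenic traits.

Genotypes are drawn per marker from Hardy-Weinberg class frequencies with a
minor-allele frequency drawn uniformly on [0.05, 0.5] per marker (no linkage
disequilibrium, no population structure).  The trait is additive on the raw
dosage codes:

    Y = sum_i beta_i X_i + e,   beta_1..beta_s ~ N(0, sigma_beta^2),
                                beta_{s+1..m} = 0,  e ~ N(0, sigma_e^2)

so ``s`` controls the architecture: small s gives an oligogenic trait,
large s a polygenic one.  Defaults: 100 samples x 500 markers,
sigma_beta = sigma_e = 1.  The generator returns a truth record (the drawn
beta and residuals) for parameter-recovery tests and is fully reproducible
from its seed.

An optional epistatic hook adds multiplicative pair terms
``gamma * X_i X_j`` for planted pairs; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from traitpred.core import GenotypeMatrix, TraitVector
from traitpred.evaluation import CVConfig, cross_validate, make_folds


@dataclass
class SimulationConfig:
    """Design of one simulated dataset."""

    n: int = 100
    m: int = 500
    s: int = 5
    sigma_beta: float = 1.0
    sigma_e: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: planted multiplicative pairs [(marker index i, marker index j, gamma)]
    epistatic_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be positive")
        if not 0 <= self.s <= self.m:
            raise ValueError(f"s must lie in [0, m]; got s={self.s}, m={self.m}")
        if self.sigma_e < 0 or self.sigma_beta < 0:
            raise ValueError("sigma_beta and sigma_e must be nonnegative")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for i, j, _ in self.epistatic_pairs:
            if not (0 <= i < self.m and 0 <= j < self.m and i != j):
                raise ValueError(f"invalid epistatic pair indices ({i}, {j})")


@dataclass
class TruthRecord:
    """The draws behind one dataset, for recovery tests."""

    beta: np.ndarray
    residuals: np.ndarray
    maf: np.ndarray

    def to_tsv(self, path: str, marker_ids: list[str]) -> None:
        with open(path, "w") as fh:
            fh.write("marker_id\tbeta\tmaf\n")
            for mid, b, f in zip(marker_ids, self.beta, self.maf):
                fh.write(f"{mid}\t{b:.17g}\t{f:.17g}\n")


def generate(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, TraitVector, TruthRecord]:
    """Draw one genotype matrix and additive trait under ``config``."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=config.m)
    # Hardy-Weinberg class probabilities for dosage of the minor allele
    probs = np.stack([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2], axis=1)
    u = rng.random((config.n, config.m))
    cum = np.cumsum(probs, axis=1)  # (m, 3)
    codes = (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.int16)

    beta = np.zeros(config.m)
    if config.s > 0:
        beta[: config.s] = rng.normal(0.0, config.sigma_beta, size=config.s)
    e = rng.normal(0.0, config.sigma_e, size=config.n) if config.sigma_e > 0 else (
        np.zeros(config.n)
    )
    y = codes @ beta + e
    for i, j, gamma in config.epistatic_pairs:
        y = y + gamma * codes[:, i] * codes[:, j]

    sample_ids = [f"S{i:04d}" for i in range(config.n)]
    marker_ids = [f"M{j:04d}" for j in range(config.m)]
    g = GenotypeMatrix(sample_ids, marker_ids, codes)
    t = TraitVector(sample_ids, y)
    return g, t, TruthRecord(beta, e, maf)


def replicate_study(
    s_values: list[int],
    n_datasets: int = 10,
    cv_folds: int = 10,
    seed: int = 0,
    n: int = 100,
    m: int = 500,
    encodings: tuple[str, ...] = ("traditional012", "pure", "hybrid"),
) -> pd.DataFrame:
    """Mean cross-validated r^2 per (s, encoding) over replicate datasets.

    For each ``s``, ``n_datasets`` datasets are generated; each is scored by
    ``cv_folds``-fold CV under every encoding with folds shared across
    encodings (a paired comparison).  The result has one row per s and one
    column per encoding, each cell the mean over datasets of the per-dataset
    mean r^2.
    """
    if not s_values:
        raise ValueError("s_values must be nonempty")
    rng = np.random.default_rng(seed)
    rows = {}
    for s in s_values:
        sums = {enc: [] for enc in encodings}
        for _ in range(n_datasets):
            ds_seed = int(rng.integers(0, 2**31 - 1))
            g, t, _ = generate(SimulationConfig(n=n, m=m, s=s, seed=ds_seed))
            folds = make_folds(g.sample_ids, cv_folds, ds_seed)
            for enc in encodings:
                cfg = CVConfig(encoding=enc, model="reml", k=cv_folds,
                               seed=ds_seed)
                report = cross_validate(g, t, cfg, fold_assignment=folds)
                sums[enc].append(report.mean_r2)
        rows[s] = {enc: float(np.mean(v)) for enc, v in sums.items()}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "s"
    return table
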