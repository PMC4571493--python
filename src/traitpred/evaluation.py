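"""Leakage-safe k-fold cross-validation scored by squared Pearson correlation.

Every fitted quantity — encoding tables, epistasis-pair rankings, variance
components and coefficients — is computed from the training split of each
fold only and applied read-only to the held-out split.  The reported mean is
the arithmetic mean of per-fold r^2 (not a pooled-prediction r^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from traitpred.core import GenotypeMatrix, TraitVector, TraitPredError
from traitpred.encoding import (
    traditional_encoding,
    fit_pure,
    fit_hybrid,
    fit_pairwise_hybrid,
    apply_encoding,
    apply_pair_encoding,
    product_epistasis,
)
from traitpred.epistasis import E1, rank_pairs, top_k
from traitpred.rrblup import solve_fixed_lambda, reml_fit, predict

ENCODINGS = ("traditional012", "traditional-101", "pure", "hybrid")
EPISTASIS_MODES = ("off", "product", "datadriven")


class EvaluationError(TraitPredError):
    """Raised for invalid cross-validation configurations or folds."""


@dataclass
class CVConfig:
    """Cross-validation arm: encoding, model policy, optional epistasis."""

    encoding: str = "traditional012"
    model: str = "reml"  # "reml" or "fixed"
    lam: float | None = None  # required when model == "fixed"
    epistasis: str = "off"
    top_k: int = 2000
    mi_bins: int = 10
    rank_once: bool = False  # global (leaky) ranking protocol, off by default
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoding not in ENCODINGS:
            raise EvaluationError(
                f"unknown encoding {self.encoding!r}; expected one of {ENCODINGS}"
            )
        if self.model not in ("reml", "fixed"):
            raise EvaluationError("model must be 'reml' or 'fixed'")
        if self.model == "fixed" and (self.lam is None or self.lam <= 0):
            raise EvaluationError("fixed-lambda model needs lam > 0")
        if self.epistasis not in EPISTASIS_MODES:
            raise EvaluationError(
                f"unknown epistasis mode {self.epistasis!r}; "
                f"expected one of {EPISTASIS_MODES}"
            )


@dataclass
class CVReport:
    """Per-fold and mean r^2, the fold assignment and the configuration."""

    fold_r2: list[float]
    mean_r2: float
    fold_assignment: dict[str, int]
    seed: int
    config: dict = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("fold\tr2\n")
            for i, r2 in enumerate(self.fold_r2):
                fh.write(f"{i}\t{r2:.17g}\n")
            fh.write(f"mean\t{self.mean_r2:.17g}\n")

    def config_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "fold_assignment": self.fold_assignment,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def r_squared(observed: TraitVector, predicted: TraitVector) -> float:
    """Square of the Pearson correlation; 0 when either side is constant."""
    yo = observed.values
    yp = predicted.values
    if yo.size != yp.size:
        raise EvaluationError("observed and predicted lengths differ")
    if yo.size < 2:
        raise EvaluationError("need at least 2 samples to correlate")
    so = yo - yo.mean()
    sp = yp - yp.mean()
    denom = np.sqrt((so**2).sum() * (sp**2).sum())
    if denom == 0.0:
        return 0.0
    r = float((so * sp).sum() / denom)
    return min(r * r, 1.0)


def make_folds(sample_ids: list[str], k: int, seed: int) -> dict[str, int]:
    """Seeded uniform partition into k folds with sizes differing by <= 1."""
    n = len(sample_ids)
    if k < 2:
        raise EvaluationError("k must be >= 2")
    if n < k:
        raise EvaluationError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment: dict[str, int] = {}
    for fold, chunk in enumerate(np.array_split(order, k)):
        for idx in chunk:
            assignment[sample_ids[idx]] = fold
    return assignment


def _fit_encoding_table(name: str, g: GenotypeMatrix, t: TraitVector):
    if name == "traditional012":
        return traditional_encoding("{0,1,2}")
    if name == "traditional-101":
        return traditional_encoding("{-1,0,1}")
    if name == "pure":
        return fit_pure(g, t)
    return fit_hybrid(g, t)


def _subset(g: GenotypeMatrix, t: TraitVector, rows: np.ndarray):
    ids = [g.sample_ids[i] for i in rows]
    return (
        GenotypeMatrix(ids, g.marker_ids, g.codes[rows, :]),
        TraitVector(ids, t.values[rows]),
    )


def _fit_fold(g_tr, t_tr, config: CVConfig, fixed_pairs=None):
    """Fit all per-fold state (tables, pairs, model) on the training split."""
    table = _fit_encoding_table(config.encoding, g_tr, t_tr)
    state = {"table": table, "pairs": None, "pair_table": None}
    if config.epistasis != "off":
        if fixed_pairs is not None:
            pairs = fixed_pairs
        else:
            ranked = rank_pairs(g_tr, t_tr, E1, config.mi_bins)
            pairs = top_k(ranked, config.top_k).pair_ids()
        state["pairs"] = pairs
        if config.epistasis == "datadriven":
            state["pair_table"] = fit_pairwise_hybrid(g_tr, t_tr, pairs)
    X_tr = _design(g_tr, state, config)
    if config.model == "reml":
        _, model = reml_fit(X_tr, t_tr)
    else:
        model = solve_fixed_lambda(X_tr, t_tr, config.lam)
    state["model"] = model
    return state


def _design(g: GenotypeMatrix, state: dict, config: CVConfig):
    X = apply_encoding(g, state["table"])
    if config.epistasis == "off" or not state["pairs"]:
        return X
    if config.epistasis == "product":
        X_pairs = product_epistasis(X, state["pairs"])
    else:
        X_pairs = apply_pair_encoding(g, state["pair_table"])
    return X.hstack(X_pairs)


def cross_validate(
    g: GenotypeMatrix,
    t: TraitVector,
    config: CVConfig,
    fold_assignment: dict[str, int] | None = None,
    return_state: bool = False,
) -> CVReport:
    """k-fold cross-validation of one (encoding, model, epistasis) arm.

    A precomputed ``fold_assignment`` lets several arms share folds for a
    paired comparison; otherwise folds are drawn from ``config.seed``.
    With ``return_state`` the report carries the per-fold fitted state
    (encoding tables, selected pairs, models) for audit, e.g. to verify
    that nothing fitted depends on held-out trait values.
    """
    if g.sample_ids != t.sample_ids:
        raise EvaluationError("genotypes and traits are not aligned; "
                              "call validate_alignment first")
    if fold_assignment is None:
        fold_assignment = make_folds(g.sample_ids, config.k, config.seed)
    folds = sorted(set(fold_assignment.values()))
    labels = np.array([fold_assignment[s] for s in g.sample_ids])

    fixed_pairs = None
    if config.epistasis != "off" and config.rank_once:
        ranked = rank_pairs(g, t, E1, config.mi_bins)
        fixed_pairs = top_k(ranked, config.top_k).pair_ids()

    fold_r2: list[float] = []
    fold_states: list[dict] = []
    for fold in folds:
        tr = np.where(labels != fold)[0]
        te = np.where(labels == fold)[0]
        g_tr, t_tr = _subset(g, t, tr)
        g_te, t_te = _subset(g, t, te)
        if np.unique(t_tr.values).size < 2:
            raise EvaluationError(
                f"fold {fold}: training split has fewer than 2 distinct "
                "trait values"
            )
        state = _fit_fold(g_tr, t_tr, config, fixed_pairs)
        X_te = _design(g_te, state, config)
        yhat = predict(state["model"], X_te)
        fold_r2.append(r_squared(t_te, yhat))
        if return_state:
            fold_states.append(state)

    report = CVReport(
        fold_r2=fold_r2,
        mean_r2=float(np.mean(fold_r2)),
        fold_assignment=dict(fold_assignment),
        seed=config.seed,
        config=asdict(config),
    )
    if return_state:
        report.fold_states = fold_states  # audit attribute, not serialized
    return report
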