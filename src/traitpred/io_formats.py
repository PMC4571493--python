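"""Readers and writers for genotype, phenotype and encoded-feature files.

Supported genotype inputs: VCF 4.x (via cyvcf2, biallelic sites only), a
plain sample-by-marker integer TSV, and the PLINK ``--recode A`` .raw
dialect.  Phenotypes are two-column TSV.  Encoded (real-valued) design
matrices round-trip through TSV at 17 significant digits, i.e. bit-faithfully
for doubles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from traitpred.core import MISSING, GenotypeMatrix, TraitVector, ParseError

_NA_STRINGS = {"na", "nan", ""}


@dataclass
class EncodedMatrix:
    """n samples x p real-valued regression features.

    Feature ids are marker ids for main effects and ``"i:j"`` for pair
    features.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("encoded values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def hstack(self, other: "EncodedMatrix") -> "EncodedMatrix":
        """Column-concatenate two encoded matrices over the same samples."""
        if self.sample_ids != other.sample_ids:
            raise ValueError("sample ids differ; align before stacking")
        return EncodedMatrix(
            self.sample_ids,
            self.feature_ids + other.feature_ids,
            np.hstack([self.values, other.values]),
        )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic GT calls from a VCF into additive dosage codes.

    0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2; any genotype containing a missing
    allele (including half-calls) -> MISSING.  Phased separators are treated
    like unphased.  Sites with more than one ALT allele are skipped with a
    warning.  Marker id is the ID column, or CHROM:POS (1-based POS as
    printed) when ID is ".".
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise ParseError(f"cannot open VCF {path!r}: {exc}") from exc
    sample_ids = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    try:
        for line_no, variant in enumerate(vcf, start=1):
            if len(variant.ALT) != 1:
                warnings.warn(
                    f"skipping multi-allelic site {variant.CHROM}:{variant.POS}"
                )
                continue
            mid = variant.ID if variant.ID not in (None, ".") else (
                f"{variant.CHROM}:{variant.POS}"
            )
            gt = np.asarray(variant.genotype.array())  # (n, ploidy+1)
            alleles = gt[:, :2]
            col = alleles.sum(axis=1).astype(np.int16)
            col[(alleles < 0).any(axis=1)] = MISSING
            marker_ids.append(mid)
            columns.append(col)
    except Exception as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(
            f"error parsing VCF {path!r} at record {len(marker_ids) + 1}: {exc}"
        ) from exc
    finally:
        vcf.close()
    if len(set(marker_ids)) != len(marker_ids):
        raise ParseError(f"duplicate marker ids in VCF {path!r}")
    if not marker_ids:
        codes = np.zeros((len(sample_ids), 0), dtype=np.int16)
    else:
        codes = np.column_stack(columns)
    return GenotypeMatrix(sample_ids, marker_ids, codes)


def _parse_code_frame(df: pd.DataFrame, path: str) -> np.ndarray:
    """Map a string/number dataframe of {0,1,2,NA} cells to integer codes."""
    codes = np.empty(df.shape, dtype=np.int16)
    raw = df.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            text = "" if cell is None else str(cell).strip()
            if text.lower() in _NA_STRINGS or (
                isinstance(cell, float) and np.isnan(cell)
            ):
                codes[i, j] = MISSING
                continue
            try:
                value = int(float(text))
            except ValueError:
                value = -1
            if value not in (0, 1, 2) or float(text) != value:
                raise ParseError(
                    f"{path}: invalid genotype cell {text!r} at data row "
                    f"{i + 1}, column {j + 1} (expected 0, 1, 2 or NA)"
                )
            codes[i, j] = value
    return codes


def read_genotype_tsv(path: str) -> GenotypeMatrix:
    """Read a sample-by-marker TSV: header of marker ids, first column sample ids."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot read genotype TSV {path!r}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty genotype table")
    codes = _parse_code_frame(df, path)
    return GenotypeMatrix(
        [str(s) for s in df.index], [str(m) for m in df.columns], codes
    )


_RAW_MANDATORY = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_plink_raw(path: str) -> GenotypeMatrix:
    """Read a PLINK .raw (``--recode A``) file; sample id is IID.

    The PHENOTYPE column is ignored: phenotypes come from read_phenotype.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot read .raw file {path!r}: {exc}") from exc
    missing_cols = [c for c in _RAW_MANDATORY if c not in df.columns[:6].tolist()]
    if list(df.columns[:6]) != _RAW_MANDATORY:
        raise ParseError(
            f"{path}: .raw header must start with {' '.join(_RAW_MANDATORY)}; "
            f"missing or misplaced: {missing_cols or list(df.columns[:6])}"
        )
    sample_ids = [str(s) for s in df["IID"]]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate IID values")
    geno = df.iloc[:, 6:]
    if geno.shape[1] == 0:
        raise ParseError(f"{path}: no marker columns after the six mandatory columns")
    codes = _parse_code_frame(geno, path)
    return GenotypeMatrix(sample_ids, [str(m) for m in geno.columns], codes)


def read_phenotype(path: str) -> TraitVector:
    """Read a two-column (sample id, trait) TSV; an optional header is detected.

    Rows whose trait field is non-numeric are rejected with a parse error,
    except a single leading header row which is skipped.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot read phenotype file {path!r}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns")
    start = 0
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        start = 1  # header row
    ids: list[str] = []
    values: list[float] = []
    for i in range(start, df.shape[0]):
        sid = str(df.iloc[i, 0]).strip()
        raw = df.iloc[i, 1]
        try:
            values.append(float(raw))
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-numeric trait value {raw!r} for sample {sid!r} "
                f"(row {i + 1})"
            ) from None
        ids.append(sid)
    if not ids:
        raise ParseError(f"{path}: no parseable phenotype rows")
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample ids {dupes}")
    return TraitVector(ids, np.asarray(values))


def write_encoded(matrix: EncodedMatrix, path: str) -> None:
    """Write an encoded matrix as TSV (17 significant digits)."""
    if matrix.n_samples == 0 or matrix.n_features == 0:
        raise ValueError("refusing to write an empty encoded matrix")
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(matrix.feature_ids) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.values):
            cells = "\t".join(f"{v:.17g}" for v in row)
            fh.write(f"{sid}\t{cells}\n")


def read_encoded(path: str) -> EncodedMatrix:
    """Read a TSV written by :func:`write_encoded`."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return EncodedMatrix(
        [str(s) for s in df.index],
        [str(f) for f in df.columns],
        df.to_numpy(dtype=float),
    )


def write_genotype_tsv(g: GenotypeMatrix, path: str) -> None:
    """Write a genotype matrix in the sample-by-marker TSV dialect."""
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(g.marker_ids) + "\n")
        for sid, row in zip(g.sample_ids, g.codes):
            cells = "\t".join("NA" if c == MISSING else str(int(c)) for c in row)
            fh.write(f"{sid}\t{cells}\n")


def write_phenotype(t: TraitVector, path: str) -> None:
    """Write a trait vector as two-column TSV with header."""
    with open(path, "w") as fh:
        fh.write("sample_id\ttrait\n")
        for sid, v in zip(t.sample_ids, t.values):
            fh.write(f"{sid}\t{v:.17g}\n")
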