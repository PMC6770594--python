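"""Expression matrix container, median-ratio normalization, gene filtering.

The universal input is a non-negative gene x sample matrix (raw counts,
MRN-normalized values, or TPM). Median-ratio normalization (MRN, the
DESeq-style size-factor scheme) divides each sample by

    factor_j = median_g ( counts_gj / geomean_over_samples(counts_g.) )

computed over the genes that are strictly positive in every sample, with
factors rescaled so their geometric mean is 1 (only ratios between factors
matter downstream). TPM inputs are used as-is and bypass MRN.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import NormalizationError

__all__ = [
    "VALUE_KINDS",
    "ExpressionMatrix",
    "mrn_size_factors",
    "normalize",
    "filter_genes",
]

VALUE_KINDS = ("raw_count", "normalized", "tpm")


@dataclass(frozen=True, eq=False)
class ExpressionMatrix:
    """Non-negative genes x samples expression values with identifiers.

    Parameters
    ----------
    values
        DataFrame with unique gene ids as the index and unique sample ids
        as the columns; entries must be finite and >= 0.
    value_kind
        One of ``raw_count``, ``normalized``, ``tpm`` — recorded so every
        downstream score can state which kind of value fed it (first-digit
        distributions are not invariant under normalization in general).
    """

    values: pd.DataFrame
    value_kind: str = "raw_count"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}")
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate gene ids: {dup}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate sample ids: {dup}")
        arr = v.to_numpy(dtype=float, copy=False)
        if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
            raise ValueError("expression values must be finite and non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def mrn_size_factors(m: ExpressionMatrix) -> pd.Series:
    """Median-ratio (MRN) size factors, geometric-mean-1 convention.

    The per-gene reference is the geometric mean across samples, computed
    over genes strictly positive in all samples; each sample's factor is
    the median of its ratios to the reference.

    Raises
    ------
    NormalizationError
        If no gene is positive in every sample (the reference geometric
        mean would be zero everywhere) — filter genes or use a different
        normalization in that case.
    """
    if m.value_kind != "raw_count":
        raise ValueError(
            f"MRN size factors are defined on raw counts, got {m.value_kind!r}"
        )
    arr = m.values.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise NormalizationError(
            "MRN undefined: no gene has strictly positive counts in every "
            "sample; consider filter_genes(...) or supplying deeper data"
        )
    sub = arr[all_pos]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1
    return pd.Series(factors, index=m.sample_ids, name="size_factor")


def normalize(m: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """Divide each sample column by its size factor; zeros stay zeros."""
    if m.value_kind != "raw_count":
        raise ValueError(f"normalize expects raw counts, got {m.value_kind!r}")
    missing = m.sample_ids.difference(factors.index)
    if len(missing):
        raise KeyError(f"no size factor for samples: {missing.tolist()[:5]}")
    f = factors.reindex(m.sample_ids).to_numpy(dtype=float)
    if (f <= 0).any() or not np.isfinite(f).all():
        raise ValueError("size factors must be finite and > 0")
    out = m.values / f
    return ExpressionMatrix(values=out, value_kind="normalized")


def mrn_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """MRN in one step: ``normalize(m, mrn_size_factors(m))``."""
    return normalize(m, mrn_size_factors(m))


def filter_genes(m: ExpressionMatrix, min_nonzero_fraction: float = 0.0) -> ExpressionMatrix:
    """Keep genes expressed (> 0) in at least the given fraction of samples.

    ``min_nonzero_fraction=0`` is the identity (no silent filtering);
    gene order is preserved. May return an empty matrix.
    """
    if not 0.0 <= min_nonzero_fraction <= 1.0:
        raise ValueError("min_nonzero_fraction must be in [0, 1]")
    if min_nonzero_fraction == 0.0:
        return m
    frac = (m.values > 0).mean(axis=1)
    keep = frac >= min_nonzero_fraction
    return replace(m, values=m.values.loc[keep])
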