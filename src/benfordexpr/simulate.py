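"""Synthetic expression matrices with planted, ground-truth structure.

The generator emulates the statistical skeleton the Benford method relies
on in real single-cell data:

* **background genes** — values spanning several orders of magnitude.
  They are drawn as ``floor(10^U)`` with ``U ~ Uniform[lo, hi]``; for
  integer spans this construction gives integer counts whose first digits
  follow Benford's law *exactly* (flooring never moves a value across a
  leading-digit boundary), so the background calibrates the GOF test.
* **marker genes** (one disjoint set per group) — in their own group:
  narrow, low-expression rounded lognormals (the empirically observed
  profile of Benford-deviant genes); in other groups: the background law
  scaled down by ``off_marker_scale``, i.e. broad, Benford-adherent and
  moderately expressed. Own-group markers are therefore simultaneously
  the most Benford-deviant and the lowest-expressed genes of their group.
* **DE genes** (one set per group) — broad lognormals shifted strongly up
  in the focus group: the classical highly expressed, differentially
  expressed markers that dominate a t-test ranking without being
  Benford-deviant. They keep the DE selection route honest: it should
  find these, not the Benford-deviant set.

Bernoulli dropout zeros are overlaid on marker genes; all counts are
integers; a single seed drives deterministic per-block substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import ExpressionMatrix

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "default_scenario"]

#: Group sizes of the six-cell-type single-cell scenario the defaults mirror.
_DEFAULT_GROUP_SIZES = (374, 173, 138, 105, 69, 159)
_DEFAULT_GROUP_NAMES = ("hESC", "NPC", "DEP", "EC", "TB", "HFF")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic world (all counts per matrix, not rates).

    ``marker_location`` is the lognormal median of a marker gene in its
    own group (counts); ``marker_cv`` is the lognormal shape (log-scale
    sd, approximately the coefficient of variation for small values) —
    small means narrow. ``off_marker_scale`` scales the background law
    for marker genes outside their own group. ``de_high``/``de_low`` are
    the focus/other lognormal medians of the planted DE genes and
    ``de_sigma`` their (broad) shape.
    """

    n_groups: int = 6
    cells_per_group: tuple[int, ...] = _DEFAULT_GROUP_SIZES
    group_names: tuple[str, ...] = _DEFAULT_GROUP_NAMES
    n_background_genes: int = 5000
    n_markers_per_group: int = 200
    background_log10_range: tuple[float, float] = (0.0, 4.0)
    marker_location: float | tuple[float, ...] = 7.0
    marker_cv: float = 0.1
    off_marker_scale: float = 0.2
    n_de_genes_per_group: int = 200
    de_high: float = 5000.0
    de_low: float = 500.0
    de_sigma: float = 0.5
    dropout_rate: float = 0.3
    seed: int = 1004

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if len(self.cells_per_group) != self.n_groups:
            raise ValueError("cells_per_group must have n_groups entries")
        if len(self.group_names) != self.n_groups:
            raise ValueError("group_names must have n_groups entries")
        if any(c < 1 for c in self.cells_per_group):
            raise ValueError("cells_per_group entries must be positive")
        if self.n_background_genes < 1 or self.n_markers_per_group < 0:
            raise ValueError("gene counts must be positive")
        lo, hi = self.background_log10_range
        if not lo < hi:
            raise ValueError("background_log10_range must satisfy lo < hi")
        if self.marker_cv <= 0:
            raise ValueError("marker_cv must be > 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if np.min(self.marker_locations) <= 0:
            raise ValueError("marker_location must be positive")

    @property
    def marker_locations(self) -> np.ndarray:
        loc = self.marker_location
        if np.isscalar(loc):
            return np.full(self.n_groups, float(loc))
        arr = np.asarray(loc, dtype=float)
        if arr.shape != (self.n_groups,):
            raise ValueError("marker_location must be scalar or one per group")
        return arr

    @property
    def n_cells(self) -> int:
        return int(sum(self.cells_per_group))


@dataclass(frozen=True, eq=False)
class SyntheticTruth:
    """Ground truth echoed by the generator, for recovery tests."""

    labels: pd.Series  # sample_id -> group
    marker_genes: dict[str, tuple[str, ...]]
    de_genes: dict[str, tuple[str, ...]]
    spec: SyntheticSpec = field(repr=False, default=None)


def _background_block(rng: np.random.Generator, shape, lo: float, hi: float) -> np.ndarray:
    """Integer counts with exactly-Benford first digits over [10^lo, 10^hi)."""
    return np.floor(10.0 ** rng.uniform(lo, hi, size=shape))


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one synthetic raw-count matrix plus its ground truth."""
    ss = np.random.SeedSequence(spec.seed)
    rng_bg, rng_mk, rng_de, rng_drop = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    lo, hi = spec.background_log10_range
    groups = list(spec.group_names)
    n_cells = spec.n_cells
    cell_group = np.repeat(np.arange(spec.n_groups), spec.cells_per_group)
    sample_ids = [
        f"{groups[g]}_c{i:04d}"
        for g in range(spec.n_groups)
        for i in range(spec.cells_per_group[g])
    ]
    labels = pd.Series([groups[g] for g in cell_group], index=sample_ids, name="group")

    blocks, gene_ids = [], []

    bg = _background_block(rng_bg, (spec.n_background_genes, n_cells), lo, hi)
    blocks.append(bg)
    gene_ids += [f"BG{i:05d}" for i in range(spec.n_background_genes)]

    marker_genes: dict[str, tuple[str, ...]] = {}
    locations = spec.marker_locations
    for g, group in enumerate(groups):
        n_mk = spec.n_markers_per_group
        if n_mk == 0:
            marker_genes[group] = ()
            continue
        own = cell_group == g
        block = _background_block(rng_mk, (n_mk, n_cells), lo, hi) * spec.off_marker_scale
        block = np.floor(block)
        n_own = int(own.sum())
        narrow = locations[g] * np.exp(
            spec.marker_cv * rng_mk.standard_normal((n_mk, n_own))
        )
        block[:, own] = np.round(narrow)
        if spec.dropout_rate > 0:
            block[rng_drop.random(block.shape) < spec.dropout_rate] = 0.0
        ids = tuple(f"MK_{group}_{i:04d}" for i in range(n_mk))
        marker_genes[group] = ids
        gene_ids += list(ids)
        blocks.append(block)

    de_genes: dict[str, tuple[str, ...]] = {}
    for g, group in enumerate(groups):
        n_de = spec.n_de_genes_per_group
        if n_de == 0:
            de_genes[group] = ()
            continue
        own = cell_group == g
        median = np.where(own, spec.de_high, spec.de_low)
        block = np.round(
            median * np.exp(spec.de_sigma * rng_de.standard_normal((n_de, n_cells)))
        )
        ids = tuple(f"DE_{group}_{i:04d}" for i in range(n_de))
        de_genes[group] = ids
        gene_ids += list(ids)
        blocks.append(block)

    values = pd.DataFrame(
        np.concatenate(blocks, axis=0), index=gene_ids, columns=sample_ids
    )
    matrix = ExpressionMatrix(values=values, value_kind="raw_count")
    truth = SyntheticTruth(
        labels=labels, marker_genes=marker_genes, de_genes=de_genes, spec=spec
    )
    return matrix, truth


def default_scenario() -> SyntheticSpec:
    """The reference scenario: 6 groups, 1,018 cells, 200 markers per group.

    Group sizes (374, 173, 138, 105, 69, 159) mirror a published
    six-cell-type single-cell dataset; 5,000 background genes span four
    orders of magnitude; dropout 0.3; seed 1004.
    """
    return SyntheticSpec()
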