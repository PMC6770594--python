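"""Gene panels and per-cell scores: the Benford, mean-expression and DE routes.

For each group (cell type / tissue) three families of gene panels are built:

* ``high_mae`` / ``low_mae`` — the k genes with the highest / lowest
  *gene-centered* MAE, i.e. the MAE of each gene's first-digit
  distribution across the cells of that group;
* ``high_exp`` / ``low_exp`` — the k genes with the highest / lowest mean
  expression within the group (zeros included);
* ``de`` — the k most differentially expressed genes (Welch t-test, focus
  group vs all other groups combined, p <= alpha), each carrying a sign
  s_i in {-1, +1} for the direction of regulation.

Each cell is then summarized per panel by a *cell-centered* score: the MAE
of its first-digit distribution over the panel genes, its mean expression
over them, or the polygenic score PS = sum_i s_i * e_i over the signed DE
panel. One score per group panel yields the samples x groups ScoreMatrix
that feeds the classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .benford import MAX_MAE, benford_expected, digit_codes
from .errors import EmptyPanelError
from .preprocessing import ExpressionMatrix

__all__ = [
    "PANEL_MODES",
    "GenePanel",
    "check_labels",
    "gene_centered_mae",
    "gene_centered_mean_exp",
    "select_top_k",
    "de_ttest",
    "select_de",
    "cell_centered_mae",
    "cell_centered_mean_exp",
    "polygenic_score",
    "build_score_matrix",
    "build_group_panels",
    "panel_overlap",
]

logger = logging.getLogger(__name__)

PANEL_MODES = ("high_mae", "low_mae", "high_exp", "low_exp", "de")

#: Cell-centered score kind implied by each panel mode.
MODE_SCORE_KIND = {
    "high_mae": "mae",
    "low_mae": "mae",
    "high_exp": "mean_exp",
    "low_exp": "mean_exp",
    "de": "ps",
}

#: Default eligibility floor: a gene needs at least this many nonzero
#: values within the group for its MAE to be trusted (an MAE estimated
#: from one or two digits would otherwise dominate the extremes).
DEFAULT_MIN_NONZERO = 10


@dataclass(frozen=True, eq=False)
class GenePanel:
    """Ordered gene list selected for one focus group.

    ``signs`` (one +1/-1 per gene) is present exactly for DE panels, where
    it records the direction of regulation used by the polygenic score.
    """

    group: str
    genes: tuple[str, ...]
    mode: str
    k_requested: int
    signs: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in PANEL_MODES:
            raise ValueError(f"mode must be one of {PANEL_MODES}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel genes must be unique")
        if len(self.genes) > self.k_requested:
            raise ValueError("panel larger than k_requested")
        if (self.signs is not None) != (self.mode == "de"):
            raise ValueError("signs are present iff mode == 'de'")
        if self.signs is not None:
            if len(self.signs) != len(self.genes):
                raise ValueError("signs must align with genes")
            if any(s not in (-1, 1) for s in self.signs):
                raise ValueError("signs must be -1 or +1")


def check_labels(labels: pd.Series, sample_ids: Iterable[str] | None = None) -> pd.Series:
    """Validate a sample -> group labeling (every sample exactly one label)."""
    if labels.index.has_duplicates:
        dup = labels.index[labels.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate sample ids in labels: {dup}")
    if labels.isna().any():
        raise ValueError("labels contain missing values")
    if sample_ids is not None:
        sample_ids = pd.Index(sample_ids)
        missing = sample_ids.difference(labels.index)
        extra = labels.index.difference(sample_ids)
        if len(missing) or len(extra):
            raise ValueError(
                f"labels/matrix mismatch: {len(missing)} samples unlabeled "
                f"(e.g. {missing.tolist()[:3]}), {len(extra)} labels without a "
                f"sample (e.g. {extra.tolist()[:3]})"
            )
        labels = labels.reindex(sample_ids)
    return labels.astype(str)


def _group_columns(m: ExpressionMatrix, labels: pd.Series, group: str) -> pd.Index:
    labels = check_labels(labels, m.sample_ids)
    cols = labels.index[labels == group]
    if len(cols) == 0:
        raise ValueError(f"group {group!r} has no samples")
    return cols


def _mae_rows(values: np.ndarray, min_nonzero: int) -> np.ndarray:
    """Row-wise MAE of first-digit distributions; NaN when < min_nonzero digits."""
    codes = digit_codes(values)
    counts = np.stack([(codes == d).sum(axis=1) for d in range(1, 10)], axis=1)
    n_used = counts.sum(axis=1)
    E = benford_expected().E
    with np.errstate(invalid="ignore", divide="ignore"):
        A = counts / n_used[:, None]
        out = np.abs(A - E).mean(axis=1)
    out[n_used < min_nonzero] = np.nan
    return out


def gene_centered_mae(
    m: ExpressionMatrix,
    labels: pd.Series,
    group: str,
    min_nonzero: int = DEFAULT_MIN_NONZERO,
) -> pd.Series:
    """Per-gene MAE across the cells of one group (zeros excluded).

    Genes with fewer than ``min_nonzero`` positive values in the group are
    ineligible and returned as NaN.
    """
    if min_nonzero < 1:
        raise ValueError("min_nonzero must be >= 1")
    cols = _group_columns(m, labels, group)
    values = m.values[cols].to_numpy(dtype=float)
    return pd.Series(_mae_rows(values, min_nonzero), index=m.gene_ids, name="mae")


def gene_centered_mean_exp(m: ExpressionMatrix, labels: pd.Series, group: str) -> pd.Series:
    """Per-gene arithmetic mean expression within the group (zeros included)."""
    cols = _group_columns(m, labels, group)
    return m.values[cols].mean(axis=1).rename("mean_exp")


def select_top_k(
    scores: pd.Series,
    k: int,
    direction: str,
    group: str = "",
    mode: str | None = None,
) -> GenePanel:
    """Take the k highest or lowest scoring genes, deterministically.

    Missing (NaN) scores are ineligible. Ties are broken by gene id
    ascending so identical inputs always give byte-identical panels.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction not in ("highest", "lowest"):
        raise ValueError("direction must be 'highest' or 'lowest'")
    eligible = scores.dropna()
    if eligible.empty:
        raise EmptyPanelError(f"no eligible genes for group {group!r}")
    frame = eligible.rename("score").rename_axis("gene").reset_index()
    frame = frame.sort_values(
        ["score", "gene"], ascending=[direction == "lowest", True]
    )
    genes = tuple(frame["gene"].head(k))
    if mode is None:
        mode = {"highest": "high_mae", "lowest": "low_mae"}[direction]
    return GenePanel(group=group, genes=genes, mode=mode, k_requested=k)


def de_ttest(m: ExpressionMatrix, labels: pd.Series, group: str) -> pd.DataFrame:
    """Welch two-sample t-test per gene: focus group vs all others combined.

    Returns a DataFrame indexed by gene with ``t_stat``, ``p_value`` and
    ``sign`` (+1 when the focus mean is >= the rest mean, else -1; equal
    means get +1). Genes with zero variance on both sides and equal means
    have no defined statistic and are returned as NaN.
    """
    labels = check_labels(labels, m.sample_ids)
    in_focus = (labels == group).to_numpy()
    n_focus, n_rest = int(in_focus.sum()), int((~in_focus).sum())
    if n_focus < 2 or n_rest < 2:
        raise ValueError(
            f"t-test needs >= 2 samples on each side; group {group!r} has "
            f"{n_focus}, rest has {n_rest}"
        )
    arr = m.values.to_numpy(dtype=float)
    focus, rest = arr[:, in_focus], arr[:, ~in_focus]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_value = stats.ttest_ind(focus, rest, axis=1, equal_var=False)
    sign = np.where(focus.mean(axis=1) >= rest.mean(axis=1), 1, -1)
    return pd.DataFrame(
        {"t_stat": t_stat, "p_value": p_value, "sign": sign}, index=m.gene_ids
    )


def select_de(de: pd.DataFrame, k: int, alpha: float = 0.05, group: str = "") -> GenePanel:
    """Top-k most differentially expressed genes with p <= alpha, signed.

    Ranking: p ascending, then |t| descending, then gene id ascending.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    passing = de[de["p_value"].notna() & (de["p_value"] <= alpha)]
    if passing.empty:
        raise EmptyPanelError(f"no gene passes p <= {alpha} for group {group!r}")
    frame = passing.rename_axis("gene").reset_index()
    frame["abs_t"] = frame["t_stat"].abs()
    frame = frame.sort_values(
        ["p_value", "abs_t", "gene"], ascending=[True, False, True]
    ).head(k)
    return GenePanel(
        group=group,
        genes=tuple(frame["gene"]),
        mode="de",
        k_requested=k,
        signs=tuple(int(s) for s in frame["sign"]),
    )


def _panel_values(m: ExpressionMatrix, panel: GenePanel) -> np.ndarray:
    missing = [g for g in panel.genes if g not in m.gene_ids]
    if missing:
        raise KeyError(f"panel genes absent from matrix: {missing[:10]}")
    return m.values.loc[list(panel.genes)].to_numpy(dtype=float)


def cell_centered_mae(m: ExpressionMatrix, panel: GenePanel) -> pd.Series:
    """Per-sample MAE over the panel genes (zeros excluded).

    A sample expressing none of the panel genes is maximally non-Benford
    on that panel and receives the theoretical maximum MAE
    (:data:`~benfordexpr.benford.MAX_MAE`), with a logged warning; this
    keeps the classifier's feature table complete.
    """
    values = _panel_values(m, panel)
    out = _mae_rows(values.T, min_nonzero=1)
    empty = np.isnan(out)
    if empty.any():
        logger.warning(
            "%d sample(s) express no gene of the %s panel for group %r; "
            "assigning the maximum MAE %.7f",
            int(empty.sum()), panel.mode, panel.group, MAX_MAE,
        )
        out[empty] = MAX_MAE
    return pd.Series(out, index=m.sample_ids, name=panel.group)


def cell_centered_mean_exp(m: ExpressionMatrix, panel: GenePanel) -> pd.Series:
    """Per-sample mean expression over the panel genes (zeros included)."""
    values = _panel_values(m, panel)
    return pd.Series(values.mean(axis=0), index=m.sample_ids, name=panel.group)


def polygenic_score(m: ExpressionMatrix, panel: GenePanel) -> pd.Series:
    """Polygenic score PS = sum_i s_i * e_i over the signed DE panel.

    ``e_i`` are normalized (or TPM) expression values; no log transform.
    """
    if panel.mode != "de" or panel.signs is None:
        raise ValueError("polygenic_score requires a DE panel with signs")
    values = _panel_values(m, panel)
    signs = np.asarray(panel.signs, dtype=float)
    return pd.Series(signs @ values, index=m.sample_ids, name=panel.group)


_SCORE_FUNCS = {
    "mae": cell_centered_mae,
    "mean_exp": cell_centered_mean_exp,
    "ps": polygenic_score,
}


def build_score_matrix(
    m: ExpressionMatrix,
    panels: Mapping[str, GenePanel],
    score_kind: str | None = None,
) -> pd.DataFrame:
    """Samples x groups matrix of cell-centered panel scores.

    One column per group panel (group-name order), scored for *every*
    sample, including samples of other groups. All panels must share one
    mode; the score kind is implied by it (mae / mean_exp / ps) unless
    given explicitly.
    """
    if not panels:
        raise ValueError("panels is empty")
    modes = {p.mode for p in panels.values()}
    if len(modes) > 1:
        raise ValueError(f"panels mix modes: {sorted(modes)}")
    implied = MODE_SCORE_KIND[modes.pop()]
    if score_kind is None:
        score_kind = implied
    elif score_kind != implied:
        raise ValueError(f"score_kind {score_kind!r} incompatible with panel mode")
    func = _SCORE_FUNCS[score_kind]
    columns = {g: func(m, panels[g]) for g in sorted(panels)}
    out = pd.DataFrame(columns)
    out.index.name = "sample_id"
    out.attrs["score_kind"] = score_kind
    return out


def build_group_panels(
    m: ExpressionMatrix,
    labels: pd.Series,
    mode: str,
    k: int = 200,
    alpha: float = 0.05,
    min_nonzero: int = DEFAULT_MIN_NONZERO,
) -> dict[str, GenePanel]:
    """One panel per group under the given mode (the full selection step)."""
    if mode not in PANEL_MODES:
        raise ValueError(f"mode must be one of {PANEL_MODES}")
    labels = check_labels(labels, m.sample_ids)
    panels: dict[str, GenePanel] = {}
    for group in sorted(labels.unique()):
        if mode in ("high_mae", "low_mae"):
            scores = gene_centered_mae(m, labels, group, min_nonzero=min_nonzero)
            direction = "highest" if mode == "high_mae" else "lowest"
            panels[group] = select_top_k(scores, k, direction, group=group, mode=mode)
        elif mode in ("high_exp", "low_exp"):
            scores = gene_centered_mean_exp(m, labels, group)
            direction = "highest" if mode == "high_exp" else "lowest"
            panels[group] = select_top_k(scores, k, direction, group=group, mode=mode)
        else:
            panels[group] = select_de(de_ttest(m, labels, group), k, alpha, group=group)
    return panels


def panel_overlap(panels_by_mode: Mapping[str, Mapping[str, GenePanel]]) -> pd.DataFrame:
    """Pairwise gene overlap between panel modes, per group.

    Returns a long-format DataFrame (group, mode_a, mode_b, n_overlap)
    comparing every unordered pair of modes within each group — the
    standard report for asking which selection routes pick the same genes.
    """
    modes = sorted(panels_by_mode)
    rows = []
    groups = sorted({g for m in panels_by_mode.values() for g in m})
    for group in groups:
        for i, a in enumerate(modes):
            for b in modes[i + 1:]:
                pa, pb = panels_by_mode[a].get(group), panels_by_mode[b].get(group)
                if pa is None or pb is None:
                    continue
                rows.append(
                    {
                        "group": group,
                        "mode_a": a,
                        "mode_b": b,
                        "n_overlap": len(set(pa.genes) & set(pb.genes)),
                    }
                )
    return pd.DataFrame(rows, columns=["group", "mode_a", "mode_b", "n_overlap"])
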