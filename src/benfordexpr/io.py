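"""Readers and writers for expression matrices, labels, panels and reports.

Supported matrix formats, genes x samples orientation enforced:

* ``dense_csv`` / ``dense_tsv`` — header row of sample ids, first column
  of gene ids, UTF-8, '.' decimal separator (fixed dialect, not sniffed);
* ``mtx_triplet`` — MatrixMarket coordinate file plus ``features.tsv``
  (genes, rows) and ``barcodes.tsv`` (samples, columns) sidecars in the
  same directory;
* ``gct`` — the ``#1.2`` dialect: version line, "nrow ncol" line, then a
  table with Name and Description columns; Description is preserved in
  ``attrs`` but unused.

Labels are a two-column TSV (sample_id, group). Panels serialize as a
two-column TSV (gene_id, sign-or-blank) under a ``# mode=, group=, k=``
comment header; score matrices as CSV with a sample_id index.
"""

from __future__ import annotations

import json
import numbers
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .classify import ALGORITHMS, RepeatSummary
from .errors import MatrixParseError
from .features import GenePanel, PANEL_MODES
from .preprocessing import VALUE_KINDS, ExpressionMatrix

__all__ = [
    "MATRIX_FORMATS",
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_panel",
    "write_panel",
    "read_scores",
    "write_scores",
    "summary_to_dict",
    "write_report",
]

MATRIX_FORMATS = ("dense_csv", "dense_tsv", "mtx_triplet", "gct")


@dataclass
class RunConfig:
    """Configuration of a full run; YAML/JSON-loadable, unknown keys rejected."""

    matrix: str = ""
    labels: str = ""
    format: str = "dense_csv"
    value_kind: str = "raw_count"
    mode: str = "high_mae"
    k: int = 200
    alpha: float = 0.05
    min_nonzero: int = 10
    min_nonzero_fraction: float = 0.0
    fraction: float = 0.8
    n_repeats: int = 10
    algorithms: tuple[str, ...] = ("svm_radial",)
    cv_folds: int = 10
    seed: int = 0
    outdir: str = "benfordexpr_out"

    def __post_init__(self) -> None:
        if self.format not in MATRIX_FORMATS:
            raise ValueError(f"format must be one of {MATRIX_FORMATS}")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}")
        if self.mode not in PANEL_MODES:
            raise ValueError(f"mode must be one of {PANEL_MODES}")
        if isinstance(self.algorithms, (list, str)):
            self.algorithms = (
                tuple(self.algorithms.split(","))
                if isinstance(self.algorithms, str)
                else tuple(self.algorithms)
            )
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms {sorted(unknown)}; pick from {ALGORITHMS}")
        if self.k < 1 or self.cv_folds < 2 or self.n_repeats < 1:
            raise ValueError("k >= 1, cv_folds >= 2 and n_repeats >= 1 required")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load YAML/JSON config; keyword overrides (CLI flags) win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _validated(values: pd.DataFrame, value_kind: str, source: str) -> ExpressionMatrix:
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as err:
        raise MatrixParseError(f"{source}: non-numeric expression value ({err})") from err
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    try:
        return ExpressionMatrix(values=values, value_kind=value_kind)
    except (TypeError, ValueError) as err:
        raise MatrixParseError(f"{source}: {err}") from err


def _read_dense(path: Path, sep: str, value_kind: str) -> ExpressionMatrix:
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as err:  # pandas raises many flavors; unify
        raise MatrixParseError(f"{path}: cannot parse dense matrix ({err})") from err
    if frame.shape[1] == 0:
        raise MatrixParseError(f"{path}: no sample columns found")
    return _validated(frame, value_kind, str(path))


def _mtx_paths(path: Path) -> tuple[Path, Path, Path]:
    directory = path if path.is_dir() else path.parent
    matrix = path if path.suffix == ".mtx" else directory / "matrix.mtx"
    return matrix, directory / "features.tsv", directory / "barcodes.tsv"


def _read_mtx(path: Path, value_kind: str) -> ExpressionMatrix:
    matrix_path, features_path, barcodes_path = _mtx_paths(path)
    for p in (matrix_path, features_path, barcodes_path):
        if not p.exists():
            raise MatrixParseError(f"missing MTX component: {p}")
    genes = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str)
    samples = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    try:
        mat = spio.mmread(matrix_path)
    except Exception as err:
        raise MatrixParseError(f"{matrix_path}: invalid MatrixMarket file ({err})") from err
    mat = sparse.coo_matrix(mat).toarray()
    if mat.shape != (len(genes), len(samples)):
        raise MatrixParseError(
            f"{matrix_path}: shape {mat.shape} does not match sidecars "
            f"({len(genes)} features x {len(samples)} barcodes)"
        )
    frame = pd.DataFrame(mat, index=genes, columns=samples)
    return _validated(frame, value_kind, str(matrix_path))


def _read_gct(path: Path, value_kind: str) -> ExpressionMatrix:
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise MatrixParseError(f"{path}:1: expected GCT version '#1.2', got {version!r}")
        dims = fh.readline().split()
        try:
            nrow, ncol = int(dims[0]), int(dims[1])
        except (IndexError, ValueError) as err:
            raise MatrixParseError(f"{path}:2: malformed dimension line") from err
        frame = pd.read_csv(fh, sep="\t")
    if frame.columns[:2].tolist() != ["Name", "Description"]:
        raise MatrixParseError(f"{path}:3: first columns must be Name, Description")
    frame = frame.set_index("Name")
    description = frame.pop("Description")
    if frame.shape != (nrow, ncol):
        raise MatrixParseError(
            f"{path}: table is {frame.shape}, header line 2 declared ({nrow}, {ncol})"
        )
    m = _validated(frame, value_kind, str(path))
    m.values.attrs["description"] = description.to_dict()
    return m


def read_matrix(path: str | Path, format: str = "dense_csv", value_kind: str = "raw_count") -> ExpressionMatrix:
    """Read a genes x samples expression matrix in any supported format."""
    if format not in MATRIX_FORMATS:
        raise ValueError(f"format must be one of {MATRIX_FORMATS}")
    path = Path(path)
    if format == "dense_csv":
        return _read_dense(path, ",", value_kind)
    if format == "dense_tsv":
        return _read_dense(path, "\t", value_kind)
    if format == "mtx_triplet":
        return _read_mtx(path, value_kind)
    return _read_gct(path, value_kind)


def write_matrix(m: ExpressionMatrix, path: str | Path, format: str = "dense_csv") -> None:
    """Write a matrix in any supported format (round-trips with read_matrix)."""
    path = Path(path)
    if format == "dense_csv":
        m.values.to_csv(path)
    elif format == "dense_tsv":
        m.values.to_csv(path, sep="\t")
    elif format == "mtx_triplet":
        directory = path if path.suffix != ".mtx" else path.parent
        directory.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(directory / "matrix.mtx", sparse.coo_matrix(m.values.to_numpy()))
        pd.Series(m.gene_ids).to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(m.sample_ids).to_csv(directory / "barcodes.tsv", sep="\t", header=False, index=False)
    elif format == "gct":
        desc = m.values.attrs.get("description", {})
        table = m.values.copy()
        table.insert(0, "Description", [desc.get(g, "na") for g in m.gene_ids])
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.shape[0]}\t{m.shape[1]}\n")
            table.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"format must be one of {MATRIX_FORMATS}")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (sample_id, group) TSV into a labeling Series."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except Exception as err:
        raise MatrixParseError(f"{path}: cannot parse labels ({err})") from err
    if frame.shape[1] != 2:
        raise MatrixParseError(f"{path}: expected 2 columns, found {frame.shape[1]}")
    if list(frame.iloc[0]) == ["sample_id", "group"]:
        frame = frame.iloc[1:]
    if frame[0].duplicated().any():
        dup = frame[0][frame[0].duplicated()].tolist()[:5]
        raise MatrixParseError(f"{path}: duplicate sample id(s): {dup}")
    labels = pd.Series(frame[1].to_numpy(), index=frame[0].to_numpy(), name="group")
    labels.index.name = "sample_id"
    return labels


def write_labels(labels: pd.Series, path: str | Path) -> None:
    frame = labels.rename("group").rename_axis("sample_id").reset_index()
    frame.to_csv(path, sep="\t", header=True, index=False)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# mode={panel.mode}, group={panel.group}, k={panel.k_requested}\n")
        signs = panel.signs or ("",) * len(panel.genes)
        for gene, sign in zip(panel.genes, signs):
            fh.write(f"{gene}\t{sign}\n")


def read_panel(path: str | Path) -> GenePanel:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("# "):
            raise MatrixParseError(f"{path}:1: missing '# mode=, group=, k=' header")
        meta = dict(
            item.strip().split("=", 1) for item in header[2:].split(",") if "=" in item
        )
        genes, signs = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            genes.append(parts[0])
            signs.append(parts[1] if len(parts) > 1 else "")
    has_signs = any(s != "" for s in signs)
    return GenePanel(
        group=meta["group"],
        genes=tuple(genes),
        mode=meta["mode"],
        k_requested=int(meta["k"]),
        signs=tuple(int(s) for s in signs) if has_signs else None,
    )


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def _json_scalar(value):
    """numpy scalars -> plain Python for JSON serialization."""
    if isinstance(value, numbers.Integral):
        return int(value)
    if isinstance(value, numbers.Real):
        return float(value)
    return value


def summary_to_dict(summary: RepeatSummary) -> dict:
    """JSON-ready view of a repeat evaluation (AUCs, params, seeds)."""
    out = {
        "mode": summary.mode,
        "base_seed": summary.base_seed,
        "median_auc": summary.median_auc.round(6).to_dict(),
        "iqr_auc": summary.iqr_auc.round(6).to_dict(),
        "auc_per_repeat": summary.aucs.round(6).to_dict(orient="list"),
        "repeats": [],
    }
    for report in summary.reports:
        out["repeats"].append(
            {
                "seed": report.seed,
                "results": {
                    name: {
                        "auc": round(res.auc, 6),
                        "best_params": {
                            k: _json_scalar(v) for k, v in res.best_params.items()
                        },
                    }
                    for name, res in report.results.items()
                },
            }
        )
    return out


def write_report(summary: RepeatSummary, outdir: str | Path) -> None:
    """Write the JSON report, flat AUC CSV and per-repeat confusion CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(summary_to_dict(summary), indent=2))
    summary.aucs.to_csv(outdir / "auc.csv")
    for r, report in enumerate(summary.reports):
        for name, res in report.results.items():
            res.confusion.to_csv(outdir / f"confusion_rep{r}_{name}.csv")
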