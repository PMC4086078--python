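"""Tab-delimited table I/O for profiles, kernels and interaction edge lists.

Three plain-text formats are supported, all TAB-separated, UTF-8, with
``#`` comment lines skipped:

* **profile matrix** — header row of feature ids, first column of object
  ids, real-valued cells (binary profiles are just 0/1-valued);
* **kernel matrix** — square table whose header ids equal the first-column
  ids in the same order; symmetrized on load;
* **edge list** — two columns ``drug_id TAB protein_id``, one edge per line.

Parsing is deliberately strict: duplicate ids, non-numeric cells, ragged
rows and header/row mismatches are hard errors with located messages,
because a silently mangled similarity matrix corrupts everything
downstream.  Ids are matched case-sensitively after stripping surrounding
whitespace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "KernelMatrix",
    "InteractionNetwork",
    "read_profile",
    "write_profile",
    "read_kernel",
    "write_kernel",
    "read_interactions",
    "write_edges",
    "read_edges",
    "restrict_to_intersection",
]

SIDES = ("drug", "protein")

#: number of significant digits preserved by the writers (round-trip contract)
_FLOAT_FMT = "%.12g"


def _check_side(side: str) -> str:
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    return side


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if not x:
            raise ValueError(f"empty {what} id")
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ProfileMatrix:
    """Objects x features data table for one view of drugs or proteins."""

    object_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    side: str

    def __post_init__(self) -> None:
        self.object_ids = [str(x).strip() for x in self.object_ids]
        self.feature_ids = [str(x).strip() for x in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_side(self.side)
        _check_unique(self.object_ids, "object")
        _check_unique(self.feature_ids, "feature")
        if self.values.shape != (len(self.object_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.object_ids)} objects x {len(self.feature_ids)} features"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("profile contains non-finite values")

    @property
    def n_objects(self) -> int:
        return len(self.object_ids)

    def reorder(self, ids: Sequence[str]) -> "ProfileMatrix":
        """Return a copy restricted/permuted to ``ids`` (all must be present)."""
        index = {x: i for i, x in enumerate(self.object_ids)}
        try:
            rows = [index[str(x).strip()] for x in ids]
        except KeyError as e:
            raise KeyError(f"object id {e.args[0]!r} not present in profile") from None
        return ProfileMatrix(list(ids), list(self.feature_ids), self.values[rows], self.side)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.object_ids, columns=self.feature_ids)


@dataclass
class KernelMatrix:
    """Symmetric object x object similarity matrix for one side."""

    object_ids: list[str]
    values: np.ndarray
    side: str
    provenance: str = ""

    def __post_init__(self) -> None:
        self.object_ids = [str(x).strip() for x in self.object_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_side(self.side)
        _check_unique(self.object_ids, "object")
        n = len(self.object_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kernel shape {self.values.shape} does not match {n} ids")
        if not np.isfinite(self.values).all():
            raise ValueError("kernel contains non-finite values")
        asym = float(np.max(np.abs(self.values - self.values.T))) if n else 0.0
        if asym > 1e-8:
            raise ValueError(
                f"kernel not symmetric (max |K - K^T| = {asym:.3g}); "
                "symmetrize explicitly or load through read_kernel"
            )
        # exact symmetry internally
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n_objects(self) -> int:
        return len(self.object_ids)

    def reorder(self, ids: Sequence[str]) -> "KernelMatrix":
        index = {x: i for i, x in enumerate(self.object_ids)}
        try:
            idx = [index[str(x).strip()] for x in ids]
        except KeyError as e:
            raise KeyError(f"object id {e.args[0]!r} not present in kernel") from None
        return KernelMatrix(list(ids), self.values[np.ix_(idx, idx)], self.side, self.provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.object_ids, columns=self.object_ids)


@dataclass
class InteractionNetwork:
    """Bipartite 0/1 adjacency between labeled drugs and proteins."""

    drug_ids: list[str]
    protein_ids: list[str]
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = [str(x).strip() for x in self.drug_ids]
        self.protein_ids = [str(x).strip() for x in self.protein_ids]
        self.Y = np.asarray(self.Y, dtype=float)
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.protein_ids, "protein")
        if self.Y.shape != (len(self.drug_ids), len(self.protein_ids)):
            raise ValueError(
                f"Y shape {self.Y.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.protein_ids)} proteins"
            )
        if not np.isin(self.Y, (0.0, 1.0)).all():
            raise ValueError("Y entries must be 0 or 1")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_edges(self) -> int:
        return int(self.Y.sum())

    def edges(self) -> list[tuple[str, str]]:
        di, pi = np.nonzero(self.Y)
        return [(self.drug_ids[i], self.protein_ids[j]) for i, j in zip(di, pi)]


# ---------------------------------------------------------------------------
# low-level parsing


def _read_rows(path: str | Path) -> list[list[str]]:
    """Read TAB-split rows, skipping blank lines and '#' comments."""
    rows: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            rows.append([cell.strip() for cell in line.split("\t")])
    return rows


def _parse_cell(cell: str, row_id: str, col_id: str) -> float:
    if cell == "" or cell.upper() in ("NA", "NAN"):
        raise ValueError(f"missing value at row {row_id!r}, column {col_id!r}")
    try:
        return float(cell)
    except ValueError:
        raise ValueError(
            f"non-numeric cell {cell!r} at row {row_id!r}, column {col_id!r}"
        ) from None


def _parse_table(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Parse header + id-column table into (row_ids, col_ids, values)."""
    rows = _read_rows(path)
    if len(rows) < 2:
        raise ValueError(f"{path}: expected a header line and at least one data row")
    header, data = rows[0], rows[1:]
    width = len(data[0])
    for i, r in enumerate(data):
        if len(r) != width:
            raise ValueError(
                f"{path}: ragged row {i + 2} ({len(r)} cells, expected {width})"
            )
    if len(header) == width:
        col_ids = header[1:]  # first header cell is a corner label
    elif len(header) == width - 1:
        col_ids = header
    else:
        raise ValueError(
            f"{path}: header has {len(header)} cells but data rows have {width}"
        )
    row_ids = [r[0] for r in data]
    _check_unique(row_ids, "object")
    values = np.empty((len(data), len(col_ids)))
    for i, r in enumerate(data):
        for j, cell in enumerate(r[1:]):
            values[i, j] = _parse_cell(cell, row_ids[i], col_ids[j])
    return row_ids, col_ids, values


# ---------------------------------------------------------------------------
# public readers / writers


def read_profile(path: str | Path, side: str, fill_missing: float | None = None) -> ProfileMatrix:
    """Read a tab-delimited profile matrix.

    ``fill_missing`` — value substituted for empty/NA cells; by default a
    missing cell is a hard error (silent imputation corrupts kernels).
    """
    _check_side(side)
    if fill_missing is None:
        row_ids, col_ids, values = _parse_table(path)
    else:
        rows = _read_rows(path)
        patched: list[list[str]] = []
        for r in rows:
            patched.append(
                [c if (c != "" and c.upper() not in ("NA", "NAN")) else repr(float(fill_missing)) for c in r]
            )
        # re-serialize through the strict parser for the shape checks
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False, encoding="utf-8") as tmp:
            for r in patched:
                tmp.write("\t".join(r) + "\n")
            tmp_path = tmp.name
        try:
            row_ids, col_ids, values = _parse_table(tmp_path)
        finally:
            Path(tmp_path).unlink(missing_ok=True)
    _check_unique(col_ids, "feature")
    return ProfileMatrix(row_ids, col_ids, values, side)


def write_profile(profile: ProfileMatrix, path: str | Path, header_comment: str | None = None) -> None:
    _write_labeled(profile.to_frame(), path, header_comment)


def read_kernel(path: str | Path, side: str, provenance: str | None = None) -> KernelMatrix:
    """Read a square similarity matrix; symmetrized as ``(K + K^T)/2``.

    Asymmetry above 1e-6 before symmetrization triggers a warning (the
    matrix is still loaded); a non-square table or a header whose ids do
    not equal the row ids in order is a hard error.
    """
    _check_side(side)
    row_ids, col_ids, values = _parse_table(path)
    if len(row_ids) != len(col_ids):
        raise ValueError(
            f"{path}: kernel must be square, got {len(row_ids)} rows x {len(col_ids)} columns"
        )
    for i, (r, c) in enumerate(zip(row_ids, col_ids)):
        if r != c:
            raise ValueError(
                f"{path}: header/row id mismatch at position {i}: row {r!r} vs column {c!r}"
            )
    asym = float(np.max(np.abs(values - values.T))) if len(row_ids) else 0.0
    if asym > 1e-6:
        warnings.warn(
            f"{path}: similarity matrix asymmetric (max |K - K^T| = {asym:.3g}); symmetrized",
            stacklevel=2,
        )
    values = (values + values.T) / 2.0
    return KernelMatrix(row_ids, values, side, provenance or str(path))


def write_kernel(kernel: KernelMatrix, path: str | Path, header_comment: str | None = None) -> None:
    _write_labeled(kernel.to_frame(), path, header_comment)


def _write_labeled(frame: pd.DataFrame, path: str | Path, header_comment: str | None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, index_label="")


def read_interactions(
    path: str | Path, drug_ids: Sequence[str], protein_ids: Sequence[str]
) -> InteractionNetwork:
    """Read a two-column edge list into a 0/1 adjacency over given universes.

    An edge naming an id outside its universe is a hard error; duplicate
    edges warn and count once; an empty file yields an all-zero matrix.
    """
    drug_ids = [str(x).strip() for x in drug_ids]
    protein_ids = [str(x).strip() for x in protein_ids]
    d_index = {x: i for i, x in enumerate(drug_ids)}
    p_index = {x: i for i, x in enumerate(protein_ids)}
    Y = np.zeros((len(drug_ids), len(protein_ids)))
    dupes = 0
    for ln, row in enumerate(_read_rows(path), start=1):
        if len(row) < 2:
            raise ValueError(f"{path}: edge line {ln} has fewer than two columns")
        d, p = row[0], row[1]
        if d not in d_index:
            raise ValueError(f"{path}: unknown drug id {d!r} on line {ln}")
        if p not in p_index:
            raise ValueError(f"{path}: unknown protein id {p!r} on line {ln}")
        if Y[d_index[d], p_index[p]]:
            dupes += 1
        Y[d_index[d], p_index[p]] = 1.0
    if dupes:
        warnings.warn(f"{path}: {dupes} duplicate edge(s) counted once", stacklevel=2)
    return InteractionNetwork(drug_ids, protein_ids, Y)


def write_interactions(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d, p in net.edges():
            fh.write(f"{d}\t{p}\n")


def write_edges(edges, path: str | Path, header_comment: str | None = None) -> None:
    """Write scored, categorized edges as a Cytoscape-loadable TSV.

    Columns ``drug_id  protein_id  score  category``, sorted by descending
    score with ties broken lexicographically by (drug_id, protein_id).
    """
    records = sorted(edges.records, key=lambda r: (-r.score, r.drug_id, r.protein_id))
    try:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("drug_id\tprotein_id\tscore\tcategory\n")
            for r in records:
                fh.write(f"{r.drug_id}\t{r.protein_id}\t{_FLOAT_FMT % r.score}\t{r.category}\n")
    except OSError as e:
        raise OSError(f"cannot write edge file {path}: {e}") from e


def read_edges(path: str | Path) -> pd.DataFrame:
    """Read back a written edge TSV (round-trip counterpart of write_edges)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"drug_id": str, "protein_id": str})
    expected = ["drug_id", "protein_id", "score", "category"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df


def restrict_to_intersection(views: Iterable) -> tuple[list, dict[int, list[str]]]:
    """Restrict same-side views to their common objects, in first-view order.

    Integration requires identical id sets per side; when views cover
    different subsets this helper aligns them to the intersection and
    reports what each view dropped.  Returns ``(aligned_views, dropped)``
    where ``dropped[i]`` lists ids removed from view ``i``.
    """
    views = list(views)
    if not views:
        return [], {}
    common = set(views[0].object_ids)
    for v in views[1:]:
        common &= set(v.object_ids)
    if not common:
        raise ValueError("views share no common object ids")
    order = [x for x in views[0].object_ids if x in common]
    dropped = {i: [x for x in v.object_ids if x not in common] for i, v in enumerate(views)}
    return [v.reorder(order) for v in views], dropped
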