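"""Reading and writing expression tables, labels and annotations.

Two text dialects are supported for expression matrices: plain TSV
(header row of sample IDs, first column probe IDs) and the GEO
series-matrix export, where metadata lines are prefixed with ``!`` and
the numeric table is bounded by ``!series_matrix_table_begin`` /
``!series_matrix_table_end`` markers.

Duplicate-sample handling lives here as well: technical replicates that
are value-wise identical are detected by exact equality and collapsed to
one representative column before any decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
CASE = "case"
VALID_CLASSES = frozenset({CONTROL, CASE})


class ExpressionFormatError(ValueError):
    """Malformed expression table (ragged rows, duplicate probes, bad cells)."""


@dataclass
class ExpressionMatrix:
    """A probe-by-sample intensity matrix with per-sample class labels.

    Parameters
    ----------
    values
        m x l array of expression intensities (probes as rows).
    probe_ids
        Length-m unique probe identifiers.
    sample_ids
        Length-l unique sample identifiers.
    labels
        Per-sample class, each ``"control"`` or ``"case"``. May be None
        for an unlabelled matrix; operations that need class structure
        require labels.
    """

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ExpressionFormatError("expression values must be 2-D")
        m, l = self.values.shape
        if m != len(self.probe_ids):
            raise ExpressionFormatError(
                f"{len(self.probe_ids)} probe ids for {m} rows")
        if l != len(self.sample_ids):
            raise ExpressionFormatError(
                f"{len(self.sample_ids)} sample ids for {l} columns")
        if len(set(self.probe_ids)) != m:
            raise ExpressionFormatError("probe ids are not unique")
        if len(set(self.sample_ids)) != l:
            raise ExpressionFormatError("sample ids are not unique")
        if not np.isfinite(self.values).all():
            raise ExpressionFormatError("matrix contains non-finite values")
        if self.labels is not None:
            self.labels = [str(c) for c in self.labels]
            if len(self.labels) != l:
                raise ExpressionFormatError(
                    f"{len(self.labels)} labels for {l} samples")
            bad = set(self.labels) - VALID_CLASSES
            if bad:
                raise ExpressionFormatError(f"unknown class labels: {sorted(bad)}")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_controls(self) -> int:
        self._require_labels()
        return sum(c == CONTROL for c in self.labels)

    @property
    def n_cases(self) -> int:
        self._require_labels()
        return sum(c == CASE for c in self.labels)

    def _require_labels(self) -> None:
        if self.labels is None:
            raise ValueError("this operation requires sample class labels")
        if self.n_samples and (CONTROL not in self.labels or CASE not in self.labels):
            raise ValueError("both classes must be non-empty")

    def with_labels(self, mapping: dict[str, str]) -> "ExpressionMatrix":
        """Attach class labels from a ``sample_id -> class`` mapping."""
        missing = [s for s in self.sample_ids if s not in mapping]
        if missing:
            raise ValueError(f"samples without a label: {missing}")
        labels = [mapping[s] for s in self.sample_ids]
        return ExpressionMatrix(self.values, self.probe_ids, self.sample_ids, labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids,
                            columns=self.sample_ids)


@dataclass
class AnnotationMap:
    """Probe-to-gene-symbol mapping; composite symbols kept verbatim."""

    mapping: dict[str, str] = field(default_factory=dict)

    def symbol(self, probe_id: str) -> str | None:
        return self.mapping.get(probe_id)

    def __len__(self) -> int:
        return len(self.mapping)


def _parse_table_lines(lines: list[str], source: str) -> ExpressionMatrix:
    rows = [ln.rstrip("\n").split("\t") for ln in lines if ln.strip()]
    if len(rows) < 2:
        raise ExpressionFormatError(f"{source}: no data rows")
    header = rows[0]
    sample_ids = [c.strip().strip('"') for c in header[1:]]
    width = len(header)
    probe_ids: list[str] = []
    data = np.empty((len(rows) - 1, len(sample_ids)), dtype=float)
    for i, row in enumerate(rows[1:]):
        if len(row) != width:
            raise ExpressionFormatError(
                f"{source}: ragged row {i + 2} ({len(row)} fields, expected {width})")
        probe = row[0].strip().strip('"')
        probe_ids.append(probe)
        for j, cell in enumerate(row[1:]):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise ExpressionFormatError(
                    f"{source}: non-numeric cell {cell!r} at probe "
                    f"{probe!r}, sample {sample_ids[j]!r}") from None
    if len(set(probe_ids)) != len(probe_ids):
        seen: set[str] = set()
        dup = next(p for p in probe_ids if p in seen or seen.add(p))
        raise ExpressionFormatError(f"{source}: duplicate probe id {dup!r}")
    return ExpressionMatrix(data, probe_ids, sample_ids)


def read_expression_table(path: str | Path,
                          dialect: str = "plain-tsv") -> ExpressionMatrix:
    """Read an expression matrix from a text file.

    ``dialect`` is ``"plain-tsv"`` or ``"series-matrix"``. Row and column
    order of the file are preserved; the result carries no labels.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if dialect == "series-matrix":
        try:
            start = next(i for i, ln in enumerate(lines)
                         if ln.startswith("!series_matrix_table_begin"))
            end = next(i for i, ln in enumerate(lines)
                       if ln.startswith("!series_matrix_table_end"))
        except StopIteration:
            raise ExpressionFormatError(
                f"{path.name}: series-matrix table markers not found") from None
        table = lines[start + 1:end]
    elif dialect == "plain-tsv":
        table = [ln for ln in lines if not ln.startswith("!")]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _parse_table_lines(table, path.name)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id <TAB> class`` table."""
    out: dict[str, str] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines()):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ExpressionFormatError(f"labels line {i + 1}: expected 2 fields")
        sid, cls = parts[0].strip(), parts[1].strip().lower()
        if cls not in VALID_CLASSES:
            raise ExpressionFormatError(
                f"labels line {i + 1}: class must be control/case, got {cls!r}")
        if sid in out:
            raise ExpressionFormatError(f"duplicate sample id {sid!r} in labels")
        out[sid] = cls
    return out


def read_annotation(path: str | Path) -> AnnotationMap:
    """Read a two-column ``probe_id <TAB> gene_symbol`` table."""
    mapping: dict[str, str] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines()):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ExpressionFormatError(
                f"annotation line {i + 1}: expected 2 fields")
        probe = parts[0].strip()
        if probe in mapping:
            raise ExpressionFormatError(f"duplicate probe id {probe!r} in annotation")
        mapping[probe] = parts[1].strip()
    return AnnotationMap(mapping)


def find_duplicate_samples(x: ExpressionMatrix) -> list[list[str]]:
    """Partition sample ids into groups of value-wise identical columns.

    Equality is exact (bitwise on the float values); near-replicates are
    not merged. Singleton groups are returned for unique samples, in
    column order.
    """
    groups: dict[bytes, list[str]] = {}
    for j, sid in enumerate(x.sample_ids):
        key = x.values[:, j].tobytes()
        groups.setdefault(key, []).append(sid)
    return list(groups.values())


def collapse_duplicates(x: ExpressionMatrix) -> ExpressionMatrix:
    """Keep one representative (first in column order) per duplicate group.

    Labels are preserved; a duplicate group whose members carry both
    class labels is contradictory and raises ``ValueError``. Removed
    sample ids are logged.
    """
    groups = find_duplicate_samples(x)
    keep: list[int] = []
    removed: list[str] = []
    idx = {sid: j for j, sid in enumerate(x.sample_ids)}
    for grp in groups:
        if x.labels is not None:
            classes = {x.labels[idx[s]] for s in grp}
            if len(classes) > 1:
                raise ValueError(
                    f"identical samples {grp} carry contradictory labels {sorted(classes)}")
        keep.append(idx[grp[0]])
        removed.extend(grp[1:])
    keep.sort()
    if removed:
        logger.info("collapsed %d duplicate sample(s): %s", len(removed), removed)
    return ExpressionMatrix(
        x.values[:, keep],
        x.probe_ids,
        [x.sample_ids[j] for j in keep],
        [x.labels[j] for j in keep] if x.labels is not None else None,
    )


def write_expression_table(x: ExpressionMatrix, path: str | Path) -> None:
    """Write a plain-TSV expression table (round-trips bit-exactly)."""
    x.to_frame().to_csv(path, sep="\t", index_label="ID_REF",
                        float_format="%.17g")


def sort_score_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Deterministic output order: descending |score|, ties by probe_id."""
    df = scores.copy()
    df["_abs"] = df["score"].abs()
    df = df.sort_values(["_abs", "probe_id"], ascending=[False, True],
                        kind="mergesort").drop(columns="_abs")
    return df.reset_index(drop=True)


def write_tables(results: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named DataFrame as ``<name>.tsv`` under ``out_dir``.

    Tables with a ``score`` column are ordered by descending |score|
    with probe_id as tie-break; empty tables produce header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        if "score" in df.columns and "probe_id" in df.columns:
            df = sort_score_table(df)
        dest = out_dir / f"{name}.tsv"
        df.to_csv(dest, sep="\t", index=False, float_format="%.17g")
        written.append(dest)
    return written
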