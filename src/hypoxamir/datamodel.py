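"""Core data containers and delimited-text I/O.

The analysis operates on three kinds of tabular input:

* expression matrices (miRNA array intensities or metabolite levels in
  fmol/cell), features in rows and samples in columns, with a per-sample
  metadata table carrying cell line, oxygen tension and replicate;
* miRNA→gene target tables with mirSVR scores (more negative = stronger
  predicted down-regulation);
* pathway collections in the standard GMT dialect.

Identifiers are opaque, case-sensitive strings: no miRBase-version lifting or
gene-symbol translation is attempted here — mapping between annotation
releases must happen upstream. Missing values are not permitted in expression
grids; absence is an input error rather than a trigger for imputation.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "TargetTable",
    "PathwayDB",
    "oxygen_code_from_pct",
    "read_expression_table",
    "write_expression_table",
    "read_metadata_table",
    "read_gmt",
    "read_target_table",
    "write_results_table",
]

#: Oxygen tensions (percent O2) used in the cell-line panel, normoxia first.
OXYGEN_TENSIONS = (20.9, 1.0, 0.2)


def _delimiter_for(path: str | Path) -> str:
    """Delimiter from extension: .tsv/.txt → tab, .csv → comma. No sniffing."""
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    return "\t"


@dataclasses.dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations.

    ``oxygen_code`` is the ordinal recoding of decreasing oxygen tension
    (0 = normoxia 20.9%, then 1, 2, ... for successively lower tensions); it is
    the numerical covariate used by the per-feature regression.
    """

    sample_id: str
    cell_line: str
    oxygen_pct: float
    oxygen_code: int
    replicate: int
    group: str | None = None

    def __post_init__(self) -> None:
        if self.oxygen_pct <= 0:
            raise ValueError(f"oxygen_pct must be positive, got {self.oxygen_pct}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate}")


def oxygen_code_from_pct(oxygen_pcts: Sequence[float]) -> list[int]:
    """Ordinal codes for oxygen tensions: 0 for the highest tension, 1 for the
    next lower, and so on. Invariant to the order samples appear in."""
    levels = sorted(set(float(p) for p in oxygen_pcts), reverse=True)
    code = {p: i for i, p in enumerate(levels)}
    return [code[float(p)] for p in oxygen_pcts]


class ExpressionMatrix:
    """Feature × sample grid of expression values.

    Values are arbitrary linear-scale intensities (or fmol/cell for
    metabolites) unless ``is_log`` is set, in which case they are log2.
    Identifiers must be unique and the grid finite; linear-scale values must be
    non-negative.
    """

    def __init__(
        self,
        feature_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
        *,
        is_log: bool = False,
    ) -> None:
        feature_ids = list(feature_ids)
        sample_ids = list(sample_ids)
        values = np.asarray(values, dtype=float)
        for name, ids in (("feature", feature_ids), ("sample", sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} identifier: {i!r}")
                seen.add(i)
        if values.shape != (len(feature_ids), len(sample_ids)):
            raise ValueError(
                f"value grid shape {values.shape} does not match "
                f"{len(feature_ids)} features x {len(sample_ids)} samples"
            )
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at feature {feature_ids[r]!r}, sample {sample_ids[c]!r}"
            )
        if not is_log and values.size and values.min() < 0:
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative linear-scale value at feature {feature_ids[r]!r}, "
                f"sample {sample_ids[c]!r}"
            )
        self.feature_ids = feature_ids
        self.sample_ids = sample_ids
        self.values = values
        self.is_log = bool(is_log)
        self._findex = {f: i for i, f in enumerate(feature_ids)}
        self._sindex = {s: i for i, s in enumerate(sample_ids)}

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, feature_id: str) -> int:
        return self._findex[feature_id]

    def sample_index(self, sample_id: str) -> int:
        return self._sindex[sample_id]

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self._findex[feature_id]]

    def with_values(self, values: np.ndarray, *, is_log: bool | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.feature_ids,
            self.sample_ids,
            values,
            is_log=self.is_log if is_log is None else is_log,
        )

    def subset_features(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep = list(keep)
        rows = [self._findex[f] for f in keep]
        return ExpressionMatrix(keep, self.sample_ids, self.values[rows], is_log=self.is_log)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and self.is_log == other.is_log
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        scale = "log2" if self.is_log else "linear"
        return f"ExpressionMatrix({self.n_features} features x {self.n_samples} samples, {scale})"


class TargetTable:
    """miRNA → gene predicted-target records with mirSVR scores.

    Duplicate (miRNA, gene) pairs collapse to the most negative (most
    confident) score, since downstream filtering keeps scores *below* a
    threshold.
    """

    def __init__(self, records: Iterable[tuple[str, str, float]]) -> None:
        best: dict[tuple[str, str], float] = {}
        order: list[tuple[str, str]] = []
        for mirna, gene, score in records:
            score = float(score)
            if not np.isfinite(score):
                raise ValueError(f"non-finite mirSVR score for ({mirna!r}, {gene!r})")
            key = (str(mirna), str(gene))
            if key in best:
                best[key] = min(best[key], score)
            else:
                best[key] = score
                order.append(key)
        self._records = [(m, g, best[(m, g)]) for m, g in order]
        self._by_mirna: dict[str, set[str]] = {}
        for m, g, _ in self._records:
            self._by_mirna.setdefault(m, set()).add(g)

    @property
    def records(self) -> list[tuple[str, str, float]]:
        return list(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def mirnas(self) -> set[str]:
        return set(self._by_mirna)

    def genes(self) -> set[str]:
        return {g for _, g, _ in self._records}

    def targets_of(self, mirna: str) -> set[str]:
        return set(self._by_mirna.get(mirna, set()))

    def filtered(self, threshold: float) -> "TargetTable":
        """Records with score strictly below ``threshold``."""
        return TargetTable((m, g, s) for m, g, s in self._records if s < threshold)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetTable):
            return NotImplemented
        return sorted(self._records) == sorted(other._records)


class PathwayDB:
    """Named gene or metabolite sets (unique names, non-empty deduplicated members)."""

    def __init__(
        self,
        pathways: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self._sets: dict[str, set[str]] = {}
        for name, members in pathways.items():
            members = set(members)
            if not members:
                raise ValueError(f"pathway {name!r} has no members")
            if name in self._sets:
                raise ValueError(f"duplicate pathway name: {name!r}")
            self._sets[name] = members
        self.descriptions = dict(descriptions or {})

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def members(self, name: str) -> set[str]:
        return set(self._sets[name])

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def items(self):
        return self._sets.items()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_expression_table(
    path: str | Path, metadata_path: str | Path, *, is_log: bool = False
) -> tuple[ExpressionMatrix, list[SampleMetadata]]:
    """Read a feature × sample expression table plus its sample metadata.

    ``is_log`` declares the scale of the stored values (files do not carry
    the flag themselves); linear-scale tables must be non-negative.

    The expression file is delimited text with feature IDs in the first column
    and sample IDs in the header; the metadata file is keyed by sample ID with
    ``cell_line``, ``oxygen_pct``, ``replicate`` and optional ``group``
    columns. Every expression sample must have exactly one metadata record.
    ``oxygen_code`` is derived from ``oxygen_pct`` by rank of decreasing
    oxygen across the metadata file.
    """
    sep = _delimiter_for(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    feature_ids = [str(f) for f in df.index]
    sample_ids = [str(s) for s in df.columns]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {raw!r} at feature {feature_ids[i]!r} "
                    f"(row {i + 2}), sample {sample_ids[j]!r} (column {j + 2})"
                ) from None
    metadata = read_metadata_table(metadata_path)
    by_id = {m.sample_id: m for m in metadata}
    missing = [s for s in sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    matrix = ExpressionMatrix(feature_ids, sample_ids, values, is_log=is_log)
    return matrix, [by_id[s] for s in sample_ids]


def read_metadata_table(path: str | Path) -> list[SampleMetadata]:
    sep = _delimiter_for(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample_id", "cell_line", "oxygen_pct", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    ids = [str(s) for s in df["sample_id"]]
    dup = {s for s in ids if ids.count(s) > 1}
    if dup:
        raise ValueError(f"duplicate sample identifier in metadata: {sorted(dup)}")
    pcts = [float(p) for p in df["oxygen_pct"]]
    codes = oxygen_code_from_pct(pcts)
    records = []
    for i, sid in enumerate(ids):
        group = None
        if "group" in df.columns:
            raw = df["group"].iloc[i]
            group = None if pd.isna(raw) else str(raw)
        records.append(
            SampleMetadata(
                sample_id=sid,
                cell_line=str(df["cell_line"].iloc[i]),
                oxygen_pct=pcts[i],
                oxygen_code=codes[i],
                replicate=int(df["replicate"].iloc[i]),
                group=group,
            )
        )
    return records


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    sep = _delimiter_for(path)
    matrix.to_frame().to_csv(path, sep=sep, index_label="feature_id", float_format="%.10g")


def write_metadata_table(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    sep = _delimiter_for(path)
    pd.DataFrame([dataclasses.asdict(m) for m in metadata]).to_csv(path, sep=sep, index=False)


def read_gmt(path: str | Path) -> PathwayDB:
    """Read a GMT pathway file: one pathway per line, tab-separated
    ``name<TAB>description<TAB>member...``; members deduplicated preserving
    first occurrence."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "expected name, description and at least one member"
                )
            name, description, *members = fields
            if name in sets:
                raise ValueError(f"{path}: duplicate pathway name {name!r} at line {lineno}")
            dedup: list[str] = []
            for m in members:
                if m and m not in dedup:
                    dedup.append(m)
            if not dedup:
                raise ValueError(f"{path}: pathway {name!r} at line {lineno} has no members")
            sets[name] = dedup
            descriptions[name] = description
    return PathwayDB(sets, descriptions)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in db.items():
            desc = db.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_target_table(path: str | Path) -> TargetTable:
    """Read a 3-column (mirna, gene, mirsvr) delimited table."""
    sep = _delimiter_for(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"mirna", "gene", "mirsvr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"target table missing columns: {sorted(missing)}")
    records = []
    for i in range(len(df)):
        raw = df["mirsvr"].iloc[i]
        try:
            score = float(raw)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric mirSVR score {raw!r} at data row {i + 1}") from None
        records.append((str(df["mirna"].iloc[i]), str(df["gene"].iloc[i]), score))
    return TargetTable(records)


def write_target_table(table: TargetTable, path: str | Path) -> None:
    sep = _delimiter_for(path)
    pd.DataFrame(table.records, columns=["mirna", "gene", "mirsvr"]).to_csv(
        path, sep=sep, index=False, float_format="%.6g"
    )


def write_results_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an analysis-results table as delimited text, floats with six
    significant digits, column order as given."""
    df.to_csv(path, sep=_delimiter_for(path), index=False, float_format="%.6g")
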