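"""Input/output for the tab-delimited matrix dialect and result tables.

Matrices are stored features-by-samples: the first row is a header of
sample IDs (an optional leading label cell such as ``id`` is tolerated),
every following row is a feature ID followed by numeric fields.  ``NA``,
``NaN`` and the empty string denote missing values.  This is the dialect
used by the common matrix-eQTL family of tools.

Annotations are BED-like: ``chrom  start  end  feature_id`` with 0-based
half-open coordinates.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple, Union

import numpy as np

from gemscan.errors import ParseError, ValidationError

MATRIX_KINDS = ("methylation", "genotype", "environment", "covariate")

#: tokens parsed as a missing value (case-sensitive match after strip)
MISSING_TOKENS = frozenset({"NA", "NaN", "nan", ""})


@dataclass
class FeatureMatrix:
    """A named numeric feature-by-sample matrix with explicit missingness.

    Missing entries are stored as ``NaN`` in :attr:`values`.

    Parameters
    ----------
    feature_ids
        Row names, unique.
    sample_ids
        Column names, unique.
    values
        Float array of shape ``(len(feature_ids), len(sample_ids))``.
    kind
        One of ``methylation``, ``genotype``, ``environment``, ``covariate``.
        Controls range validation: methylation values must lie in [0, 1]
        (unless ``strict=False`` at read time, for M-values), genotype in
        {0, 1, 2} (or [0, 2] in dosage mode).
    """

    feature_ids: List[str]
    sample_ids: List[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.kind not in MATRIX_KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        for axis, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise ValidationError(f"duplicate {axis} ID {dup!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where a value is missing."""
        return np.isnan(self.values)

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        """Return a copy restricted to ``sample_ids`` in the given order."""
        index = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            cols = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise ValidationError(f"sample {exc.args[0]!r} not present") from exc
        return FeatureMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, cols].copy(),
            kind=self.kind,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass(frozen=True)
class FeatureAnnotation:
    """Genomic location of one feature, 0-based half-open (BED convention)."""

    feature_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError(f"{self.feature_id}: empty chromosome")
        if self.start < 0:
            raise ValidationError(f"{self.feature_id}: negative start {self.start}")
        if self.start > self.end:
            raise ValidationError(
                f"{self.feature_id}: start {self.start} > end {self.end}"
            )


@dataclass
class AssociationRecord:
    """One tested hypothesis from a scan.

    ``env_id`` is set only by the interaction scan; ``pair_class`` only by
    the methQTL scan when annotations are available.
    """

    outcome_id: str
    predictor_id: str
    beta: float
    t_stat: float
    p_value: float
    df: int
    r_squared: float
    fdr: float = math.nan
    env_id: Optional[str] = None
    pair_class: Optional[str] = None
    saturated: bool = False


def _parse_value(token: str, path: str, line_no: int) -> float:
    token = token.strip()
    if token in MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"{path}:{line_no}: non-numeric field {token!r}"
        ) from None


def _validate_range(m: FeatureMatrix, strict: bool, dosage: bool) -> None:
    vals = m.values
    with np.errstate(invalid="ignore"):
        if m.kind == "methylation" and strict:
            bad = (vals < 0.0) | (vals > 1.0)
        elif m.kind == "genotype":
            if dosage:
                bad = (vals < 0.0) | (vals > 2.0)
            else:
                bad = ~np.isin(vals, (0.0, 1.0, 2.0))
        else:
            return
    bad &= ~np.isnan(vals)
    if bad.any():
        rows, cols = np.nonzero(bad)
        cells = ", ".join(
            f"({m.feature_ids[i]}, {m.sample_ids[j]})={vals[i, j]:g}"
            for i, j in list(zip(rows, cols))[:10]
        )
        raise ValidationError(
            f"{int(bad.sum())} out-of-range value(s) for kind={m.kind}: {cells}"
        )


def read_matrix(
    path: Union[str, "os.PathLike[str]"],
    kind: str,
    *,
    strict: bool = True,
    dosage: bool = False,
) -> FeatureMatrix:
    """Read a tab-delimited feature-by-sample matrix.

    Parameters
    ----------
    path
        Input file.  First row: sample IDs (optionally preceded by a label
        cell).  Each data row: feature ID then one numeric field per sample.
    kind
        Matrix role; drives range validation (see :class:`FeatureMatrix`).
    strict
        For methylation, enforce values in [0, 1].  Set False for M-values.
    dosage
        For genotype, accept fractional dosages in [0, 2] instead of hard
        calls in {0, 1, 2}.

    Raises
    ------
    ParseError
        Ragged row (names the 1-based line number) or non-numeric field.
    ValidationError
        Duplicate IDs or out-of-range values for the declared kind.
    """
    path = str(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    data_lines = [(i + 2, ln) for i, ln in enumerate(lines[1:]) if ln.strip() != ""]
    if not data_lines:
        raise ParseError(f"{path}: no data rows")
    # the header has either n_samples fields or n_samples + 1 (optional
    # leading label cell); the first data row disambiguates
    first_no, first_line = data_lines[0]
    first_width = len(first_line.split("\t"))
    if first_width == len(header) + 1:
        sample_ids = [h.strip() for h in header]
    elif first_width == len(header) and len(header) >= 2:
        sample_ids = [h.strip() for h in header[1:]]  # drop leading label cell
    else:
        raise ParseError(
            f"{path}:{first_no}: row has {first_width} fields, expected "
            f"{len(header)} or {len(header) + 1} given the {len(header)}-field header"
        )
    width = first_width
    n_samples = width - 1
    feature_ids: List[str] = []
    rows = np.empty((len(data_lines), n_samples), dtype=np.float64)
    for r, (line_no, line) in enumerate(data_lines):
        fields = line.split("\t")
        if len(fields) != width:
            raise ParseError(
                f"{path}:{line_no}: row has {len(fields)} fields, expected {width}"
            )
        feature_ids.append(fields[0].strip())
        rows[r] = [_parse_value(tok, path, line_no) for tok in fields[1:]]
    m = FeatureMatrix(feature_ids, sample_ids, rows, kind)
    _validate_range(m, strict=strict, dosage=dosage)
    return m


def _format_value(v: float) -> str:
    if math.isnan(v):
        return "NA"
    return repr(float(v))  # shortest string that round-trips bit-exactly


def write_matrix(m: FeatureMatrix, path: Union[str, "os.PathLike[str]"]) -> None:
    """Write a matrix in the dialect read by :func:`read_matrix`.

    Floats are written with shortest round-tripping repr, so
    ``read_matrix(write_matrix(m)) == m`` bit-exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(m.sample_ids) + "\n")
        for fid, row in zip(m.feature_ids, m.values):
            fh.write(fid + "\t" + "\t".join(_format_value(v) for v in row) + "\n")


def align_samples(
    matrices: Sequence[FeatureMatrix],
) -> Tuple[List[FeatureMatrix], Dict[int, List[str]]]:
    """Restrict all matrices to their shared samples, in a common order.

    The shared order is the intersection of all sample sets, in the
    relative order of the first matrix.  Returns the aligned matrices and
    a report mapping input index -> sample IDs dropped from that input.

    Raises
    ------
    ValidationError
        Fewer than two matrices, or no shared samples.
    """
    if len(matrices) < 2:
        raise ValidationError("align_samples needs at least two matrices")
    shared = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        shared &= set(m.sample_ids)
    if not shared:
        raise ValidationError("no shared samples")
    order = [s for s in matrices[0].sample_ids if s in shared]
    dropped = {
        i: [s for s in m.sample_ids if s not in shared]
        for i, m in enumerate(matrices)
    }
    return [m.subset_samples(order) for m in matrices], dropped


def read_annotation(
    path: Union[str, "os.PathLike[str]"],
) -> Dict[str, FeatureAnnotation]:
    """Read a BED4 annotation file into ``{feature_id: FeatureAnnotation}``.

    Columns: chrom, start, end, feature_id (whitespace- or tab-separated);
    extra columns are ignored.  Coordinates are 0-based half-open.
    """
    path = str(path)
    out: Dict[str, FeatureAnnotation] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(
                    f"{path}:{line_no}: expected >=4 columns, got {len(fields)}"
                )
            chrom, start_s, end_s, fid = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{line_no}: non-integer coordinates"
                ) from None
            if fid in out:
                raise ValidationError(
                    f"{path}:{line_no}: duplicate feature ID {fid!r}"
                )
            try:
                out[fid] = FeatureAnnotation(fid, chrom, start, end)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{line_no}: {exc}") from None
    return out


def write_annotation(
    annotations: Iterable[FeatureAnnotation],
    path: Union[str, "os.PathLike[str]"],
) -> None:
    """Write annotations as BED4."""
    with open(path, "w", encoding="utf-8") as fh:
        for a in annotations:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.feature_id}\n")


def write_results(
    records: Iterable[AssociationRecord],
    path: Union[str, "os.PathLike[str]", TextIO],
    *,
    with_env: Optional[bool] = None,
    with_pair_class: Optional[bool] = None,
) -> int:
    """Stream association records to a TSV file; returns rows written.

    Records must arrive sorted by ascending p-value (ties in any order);
    a violation raises :class:`ValidationError`.  Column layout:
    ``outcome_id  predictor_id  [env_id]  beta  t_stat  p_value  fdr
    [pair_class]``.  Numeric fields are printed with 12 significant
    digits.  ``with_env`` / ``with_pair_class`` control the optional
    columns; by default they are inferred from the first record.

    The write is streaming: memory use is independent of record count.
    """
    it = iter(records)
    first: Optional[AssociationRecord] = next(it, None)
    if with_env is None:
        with_env = first is not None and first.env_id is not None
    if with_pair_class is None:
        with_pair_class = first is not None and first.pair_class is not None

    cols = ["outcome_id", "predictor_id"]
    if with_env:
        cols.append("env_id")
    cols += ["beta", "t_stat", "p_value", "fdr"]
    if with_pair_class:
        cols.append("pair_class")

    def fmt(rec: AssociationRecord) -> str:
        parts = [rec.outcome_id, rec.predictor_id]
        if with_env:
            parts.append(rec.env_id if rec.env_id is not None else "NA")
        parts += [f"{rec.beta:.12g}", f"{rec.t_stat:.12g}",
                  f"{rec.p_value:.12g}", f"{rec.fdr:.12g}"]
        if with_pair_class:
            parts.append(rec.pair_class if rec.pair_class is not None else "NA")
        return "\t".join(parts)

    own_handle = not hasattr(path, "write")
    fh: TextIO = open(path, "w", encoding="utf-8") if own_handle else path  # type: ignore[arg-type]
    try:
        fh.write("\t".join(cols) + "\n")
        count = 0
        last_p = -math.inf
        rec = first
        while rec is not None:
            if rec.p_value < last_p:
                raise ValidationError(
                    f"records not sorted by p-value at row {count + 1}: "
                    f"{rec.p_value} after {last_p}"
                )
            last_p = rec.p_value
            fh.write(fmt(rec) + "\n")
            count += 1
            rec = next(it, None)
    finally:
        if own_handle:
            fh.close()
    return count
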