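"""Data model and text I/O for observable ensembles, targets, weights and
secondary-structure assignments.

File dialects
-------------
* Observable matrix: one header row ``frame <tag> <tag> ...`` then one row
  per frame (``frame_id v1 v2 ...``).  Tab or runs of spaces on read,
  single tab on write, dot-decimal floats with up to 17 significant digits.
* Target set: columns ``tag value sigma``; ``#``-prefixed comment lines
  allowed.
* Secondary-structure matrix: one line per frame, ``frame_id CODES`` where
  ``CODES`` is a constant-length string over ``{H, E, C}``.
* Weights: header ``frame weight`` then one row per frame.

Residue indexing is 1-based in labels and files.  Observable tags are the
join key between calculated and target data; tags of the form
``res<k>_<ATOM>`` are parsed into (residue, atom-kind) metadata, anything
else gets ``atom_kind=OTHER`` and no residue index.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import FormatError, ValidationError

__all__ = [
    "AtomKind",
    "ObservableLabel",
    "ObservableMatrix",
    "TargetSet",
    "WeightVector",
    "SSMatrix",
    "read_observable_matrix",
    "write_observable_matrix",
    "read_target_set",
    "write_target_set",
    "read_ss_matrix",
    "write_ss_matrix",
    "read_weights",
    "write_weights",
    "align_by_tags",
    "weighted_observable_means",
    "uniform_weights",
]

SS_ALPHABET = frozenset("HEC")

_FLOAT_FMT = "%.17g"


class AtomKind(str, enum.Enum):
    """Backbone atom category carried by an observable label."""

    CA = "CA"
    CB = "CB"
    C = "C"
    OTHER = "OTHER"


_TAG_RE = re.compile(r"^res(\d+)_(\w+)$")


@dataclass(frozen=True)
class ObservableLabel:
    """Identity of one observable column.

    ``tag`` is the unique join key; ``residue_index`` (1-based) and
    ``atom_kind`` are metadata parsed from tags shaped ``res<k>_<ATOM>``.
    Labels with unparseable tags carry ``residue_index=None`` and kind
    ``OTHER``; operations that need residue metadata reject them.
    """

    tag: str
    residue_index: int | None = None
    atom_kind: AtomKind = AtomKind.OTHER

    def __post_init__(self) -> None:
        if self.residue_index is not None and self.residue_index < 1:
            raise ValidationError(
                f"residue index must be >= 1, got {self.residue_index} in tag {self.tag!r}"
            )

    @classmethod
    def from_tag(cls, tag: str) -> "ObservableLabel":
        m = _TAG_RE.match(tag)
        if m is None:
            return cls(tag=tag)
        idx = int(m.group(1))
        atom = m.group(2).upper()
        kind = AtomKind(atom) if atom in ("CA", "CB", "C") else AtomKind.OTHER
        return cls(tag=tag, residue_index=idx, atom_kind=kind)


def _check_unique_tags(labels: Sequence[ObservableLabel]) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab.tag in seen:
            raise ValidationError(f"duplicate observable tag {lab.tag!r}")
        seen.add(lab.tag)


@dataclass
class ObservableMatrix:
    """Calculated observables, one row per frame, one column per observable."""

    values: np.ndarray  # (N, m) float
    labels: list[ObservableLabel]
    frame_ids: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("observable values must be a 2-D matrix")
        n, m = self.values.shape
        if m < 1:
            raise ValidationError("at least one observable column required")
        if n < 1:
            raise ValidationError("at least one frame required")
        if len(self.labels) != m:
            raise ValidationError(f"{len(self.labels)} labels for {m} columns")
        if len(self.frame_ids) != n:
            raise ValidationError(f"{len(self.frame_ids)} frame ids for {n} rows")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("observable matrix contains non-finite values")
        _check_unique_tags(self.labels)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_observables(self) -> int:
        return self.values.shape[1]

    @property
    def tags(self) -> list[str]:
        return [lab.tag for lab in self.labels]

    def column(self, tag: str) -> np.ndarray:
        try:
            j = self.tags.index(tag)
        except ValueError:
            raise ValidationError(f"no observable with tag {tag!r}") from None
        return self.values[:, j]

    def take_frames(self, idx: np.ndarray | Sequence[int]) -> "ObservableMatrix":
        idx = np.asarray(idx, dtype=int)
        return ObservableMatrix(
            values=self.values[idx],
            labels=list(self.labels),
            frame_ids=[self.frame_ids[i] for i in idx],
        )


@dataclass
class TargetSet:
    """Target (pseudo-experimental) values and their uncertainties."""

    labels: list[ObservableLabel]
    values: np.ndarray  # (m,)
    sigmas: np.ndarray  # (m,) strictly positive

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        m = len(self.labels)
        if self.values.shape != (m,) or self.sigmas.shape != (m,):
            raise ValidationError("labels, values and sigmas must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("target values contain non-finite entries")
        if not np.all(self.sigmas > 0):
            bad = [self.labels[i].tag for i in np.flatnonzero(~(self.sigmas > 0))]
            raise ValidationError(f"sigma must be strictly positive; offending tags: {bad}")
        _check_unique_tags(self.labels)

    @property
    def tags(self) -> list[str]:
        return [lab.tag for lab in self.labels]

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class WeightVector:
    """Normalized, nonnegative frame weights."""

    weights: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValidationError("weights must be a 1-D vector")
        if np.any(self.weights < 0):
            raise ValidationError("weights must be nonnegative")
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"weights must sum to 1 within 1e-12 (got {total!r})")

    def __len__(self) -> int:
        return len(self.weights)


def uniform_weights(n: int, description: str = "uniform") -> WeightVector:
    if n < 1:
        raise ValidationError("need at least one frame")
    return WeightVector(np.full(n, 1.0 / n), description=description)


@dataclass
class SSMatrix:
    """Per-frame, per-residue simplified secondary-structure codes (H/E/C)."""

    codes: np.ndarray  # (N, R) of single characters
    frame_ids: list[int]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype="U1")
        if self.codes.ndim != 2:
            raise ValidationError("secondary-structure codes must be a 2-D matrix")
        if self.codes.shape[0] != len(self.frame_ids):
            raise ValidationError("frame_ids length must match number of rows")
        if self.codes.shape[0] < 1 or self.codes.shape[1] < 1:
            raise ValidationError("secondary-structure matrix must be non-empty")
        bad = set(np.unique(self.codes)) - SS_ALPHABET
        if bad:
            raise ValidationError(f"invalid secondary-structure codes: {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    @property
    def n_residues(self) -> int:
        return self.codes.shape[1]

    def take_frames(self, idx: np.ndarray | Sequence[int]) -> "SSMatrix":
        idx = np.asarray(idx, dtype=int)
        return SSMatrix(codes=self.codes[idx], frame_ids=[self.frame_ids[i] for i in idx])


# ---------------------------------------------------------------------------
# I/O


def _split_line(line: str) -> list[str]:
    return line.split()


def _parse_float(token: str, path: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-numeric value {token!r}") from None


def _parse_int(token: str, path: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer frame id {token!r}") from None


def read_observable_matrix(path: str) -> ObservableMatrix:
    """Read a calculated-observable TSV (header ``frame tag1 tag2 ...``)."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = _split_line(lines[0])
    if len(header) < 2 or header[0] != "frame":
        raise FormatError(f"{path}:1: header must start with 'frame' followed by tags")
    tags = header[1:]
    labels = [ObservableLabel.from_tag(t) for t in tags]
    _check_unique_tags(labels)
    m = len(tags)
    frame_ids: list[int] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        toks = _split_line(line)
        if len(toks) != m + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {m + 1} columns, found {len(toks)}"
            )
        frame_ids.append(_parse_int(toks[0], path, lineno))
        rows.append([_parse_float(t, path, lineno) for t in toks[1:]])
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return ObservableMatrix(values=np.array(rows, dtype=float), labels=labels, frame_ids=frame_ids)


def write_observable_matrix(matrix: ObservableMatrix, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("frame\t" + "\t".join(matrix.tags) + "\n")
        for fid, row in zip(matrix.frame_ids, matrix.values):
            fh.write(str(fid) + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


def read_target_set(path: str) -> TargetSet:
    """Read a target TSV with columns ``tag value sigma``."""
    labels: list[ObservableLabel] = []
    values: list[float] = []
    sigmas: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            toks = _split_line(stripped)
            if len(toks) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'tag value sigma'")
            labels.append(ObservableLabel.from_tag(toks[0]))
            values.append(_parse_float(toks[1], path, lineno))
            sigmas.append(_parse_float(toks[2], path, lineno))
    if not labels:
        raise ValidationError(f"{path}: no target entries")
    return TargetSet(labels=labels, values=np.array(values), sigmas=np.array(sigmas))


def write_target_set(targets: TargetSet, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# tag\tvalue\tsigma\n")
        for lab, v, s in zip(targets.labels, targets.values, targets.sigmas):
            fh.write(f"{lab.tag}\t{_FLOAT_FMT % v}\t{_FLOAT_FMT % s}\n")


def read_ss_matrix(path: str) -> SSMatrix:
    """Read per-frame secondary-structure strings (``frame_id CODES``)."""
    frame_ids: list[int] = []
    rows: list[list[str]] = []
    width: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            toks = _split_line(stripped)
            if len(toks) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'frame_id CODES'")
            codes = toks[1]
            bad = set(codes) - SS_ALPHABET
            if bad:
                raise FormatError(
                    f"{path}:{lineno}: invalid secondary-structure character(s) "
                    f"{''.join(sorted(bad))!r}"
                )
            if width is None:
                width = len(codes)
            elif len(codes) != width:
                raise FormatError(
                    f"{path}:{lineno}: string length {len(codes)} differs from {width}"
                )
            frame_ids.append(_parse_int(toks[0], path, lineno))
            rows.append(list(codes))
    if not rows:
        raise ValidationError(f"{path}: no secondary-structure rows (need N >= 1)")
    return SSMatrix(codes=np.array(rows, dtype="U1"), frame_ids=frame_ids)


def write_ss_matrix(ss: SSMatrix, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for fid, row in zip(ss.frame_ids, ss.codes):
            fh.write(f"{fid}\t{''.join(row)}\n")


def read_weights(path: str) -> WeightVector:
    """Read a weights TSV (header ``frame weight``)."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines or _split_line(lines[0]) != ["frame", "weight"]:
        raise FormatError(f"{path}:1: expected header 'frame weight'")
    w = []
    for lineno, line in enumerate(lines[1:], start=2):
        toks = _split_line(line)
        if len(toks) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'frame weight'")
        w.append(_parse_float(toks[1], path, lineno))
    return WeightVector(np.array(w), description=f"read from {path}")


def write_weights(w: WeightVector, frame_ids: Sequence[int], path: str) -> None:
    if len(frame_ids) != len(w):
        raise ValidationError("frame_ids length must match weights")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("frame\tweight\n")
        for fid, wi in zip(frame_ids, w.weights):
            fh.write(f"{fid}\t{_FLOAT_FMT % wi}\n")


# ---------------------------------------------------------------------------
# Alignment and averaging


def align_by_tags(matrix: ObservableMatrix, targets: TargetSet) -> ObservableMatrix:
    """Restrict and reorder matrix columns to the target tags.

    Raises a validation error listing any target tag absent from the matrix.
    """
    pos = {t: j for j, t in enumerate(matrix.tags)}
    missing = [t for t in targets.tags if t not in pos]
    if missing:
        raise ValidationError(f"target tags missing from matrix: {missing}")
    order = [pos[t] for t in targets.tags]
    return replace(
        matrix,
        values=matrix.values[:, order],
        labels=[matrix.labels[j] for j in order],
        frame_ids=list(matrix.frame_ids),
    )


def weighted_observable_means(matrix: ObservableMatrix, w: WeightVector) -> np.ndarray:
    """Per-column weighted mean of the observables."""
    if len(w) != matrix.n_frames:
        raise ValidationError(
            f"weight length {len(w)} does not match {matrix.n_frames} frames"
        )
    return w.weights @ matrix.values
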