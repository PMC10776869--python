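"""Reading and writing landmark data in the TPS dialect of tpsDig.

The TPS format is the de-facto plain-text interchange format for 2-D
landmark configurations.  Each record starts with an ``LM=k`` header,
followed by *k* whitespace-separated ``x y`` coordinate lines, optionally
followed by ``IMAGE=``, ``ID=`` and ``SCALE=`` lines.  Records are
delimited by the next ``LM=`` header.

Curve/semilandmark records (``CURVES=``/``POINTS=``) are out of scope.
"""

from __future__ import annotations

import csv
import io
import os
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LandmarkConfiguration",
    "LandmarkDataset",
    "TPSParseError",
    "read_tps",
    "write_tps",
    "read_labels",
]


class TPSParseError(ValueError):
    """Raised on a malformed TPS record; the message names the record index."""

    def __init__(self, record_index: int, message: str):
        self.record_index = record_index
        super().__init__(f"record {record_index}: {message}")


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmarks plus identifiers.

    Landmark order is semantic — landmark *i* is homologous across
    specimens — and is never permuted by any operation in this package.

    Parameters
    ----------
    specimen_id : str
        Unique specimen identifier.
    landmarks : (k, 2) ndarray
        Landmark coordinates in digitizer units, or physical units when a
        ``SCALE=`` factor has been applied.
    taxon : str, optional
        Group label (e.g. ``"PAL"``).
    scale : float, optional
        The ``SCALE=`` factor already applied to ``landmarks``; ``None``
        means no scale record was present (factor 1).
    source_image : str, optional
        The ``IMAGE=`` value of the record, if any.
    """

    specimen_id: str
    landmarks: np.ndarray
    taxon: str | None = None
    scale: float | None = None
    source_image: str | None = None

    def __post_init__(self):
        lm = np.asarray(self.landmarks, dtype=float)
        if lm.ndim != 2 or lm.shape[1] != 2:
            raise ValueError("landmarks must be a (k, 2) array")
        if lm.shape[0] < 3:
            raise ValueError("at least 3 landmarks are required")
        if not np.all(np.isfinite(lm)):
            raise ValueError("landmark coordinates must be finite")
        if self.scale is not None and not self.scale > 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "landmarks", lm)

    @property
    def k(self) -> int:
        return self.landmarks.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, LandmarkConfiguration):
            return NotImplemented
        return (
            self.specimen_id == other.specimen_id
            and self.taxon == other.taxon
            and self.scale == other.scale
            and self.source_image == other.source_image
            and self.landmarks.shape == other.landmarks.shape
            and np.array_equal(self.landmarks, other.landmarks)
        )


@dataclass
class LandmarkDataset:
    """An ordered collection of landmark configurations with shared k.

    ``group_names`` preserves first-appearance order of taxon labels; all
    group-level outputs downstream follow this order.
    """

    configurations: list[LandmarkConfiguration] = field(default_factory=list)

    def __post_init__(self):
        ks = {c.k for c in self.configurations}
        if len(ks) > 1:
            raise ValueError(f"inconsistent landmark counts across configurations: {sorted(ks)}")
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dup}")

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    def __getitem__(self, i):
        return self.configurations[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, LandmarkDataset):
            return NotImplemented
        return self.configurations == other.configurations

    @property
    def k(self) -> int:
        if not self.configurations:
            raise ValueError("empty dataset has no landmark count")
        return self.configurations[0].k

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.configurations:
            if c.taxon is not None:
                seen.setdefault(c.taxon, None)
        return list(seen)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {g: 0 for g in self.group_names}
        for c in self.configurations:
            if c.taxon is not None:
                out[c.taxon] += 1
        return out

    def coords(self) -> np.ndarray:
        """Stack coordinates into an (n, k, 2) array."""
        return np.stack([c.landmarks for c in self.configurations])

    def labels(self) -> np.ndarray:
        """Taxon label per specimen as an object array (None where absent)."""
        return np.array([c.taxon for c in self.configurations], dtype=object)

    def subset(self, taxa: Sequence[str]) -> "LandmarkDataset":
        """Restrict to the given taxa, preserving specimen order."""
        keep = set(taxa)
        missing = keep - set(self.group_names)
        if missing:
            raise ValueError(f"unknown taxa in subset: {sorted(missing)}")
        return LandmarkDataset([c for c in self.configurations if c.taxon in keep])

    def with_labels(self, labels: Mapping[str, str]) -> "LandmarkDataset":
        out = []
        for i, c in enumerate(self.configurations):
            if c.specimen_id not in labels:
                raise TPSParseError(i, f"specimen {c.specimen_id!r} missing from label table")
            out.append(replace(c, taxon=labels[c.specimen_id]))
        return LandmarkDataset(out)

    def flip_y(self) -> "LandmarkDataset":
        """Negate the y axis of every configuration (image-row convention)."""
        return LandmarkDataset(
            [replace(c, landmarks=c.landmarks * np.array([1.0, -1.0])) for c in self.configurations]
        )

    def to_frame(self) -> "pd.DataFrame":
        """One row per specimen with columns specimen_id, taxon, x1,y1,…,xk,yk."""
        import pandas as pd

        k = self.k
        cols = [f"{a}{i + 1}" for i in range(k) for a in ("x", "y")]
        data = self.coords().reshape(len(self), 2 * k)
        frame = pd.DataFrame(data, columns=cols)
        frame.insert(0, "taxon", [c.taxon for c in self.configurations])
        frame.insert(0, "specimen_id", [c.specimen_id for c in self.configurations])
        return frame


_LM_RE = re.compile(r"^LM\s*=\s*(\S+)\s*$")
_KV_RE = re.compile(r"^(IMAGE|ID|SCALE)\s*=\s*(.*?)\s*$", re.IGNORECASE)


def _parse_record(index: int, header: str, lines: list[str]) -> LandmarkConfiguration:
    m = _LM_RE.match(header)
    if not m:
        raise TPSParseError(index, f"malformed LM header {header!r}")
    try:
        k = int(m.group(1))
    except ValueError:
        raise TPSParseError(index, f"non-integer landmark count {m.group(1)!r}") from None
    if k < 3:
        raise TPSParseError(index, f"landmark count {k} < 3")

    coord_lines = lines[:k]
    if len(coord_lines) < k:
        raise TPSParseError(index, f"expected {k} coordinate lines, found {len(coord_lines)}")
    pts = np.empty((k, 2))
    for j, line in enumerate(coord_lines):
        parts = line.split()
        if len(parts) != 2:
            raise TPSParseError(index, f"coordinate line {j + 1} is not 'x y': {line!r}")
        try:
            pts[j] = [float(parts[0]), float(parts[1])]
        except ValueError:
            raise TPSParseError(index, f"non-numeric coordinate on line {j + 1}: {line!r}") from None

    image = spec_id = None
    scale = None
    for line in lines[k:]:
        kv = _KV_RE.match(line)
        if kv is None:
            if _LM_RE.match(line):
                raise TPSParseError(index, "unexpected LM= header inside record")
            raise TPSParseError(index, f"unrecognized line {line!r}")
        key, value = kv.group(1).upper(), kv.group(2)
        if key == "IMAGE":
            image = value
        elif key == "ID":
            spec_id = value
        elif key == "SCALE":
            try:
                scale = float(value)
            except ValueError:
                raise TPSParseError(index, f"non-numeric SCALE {value!r}") from None
            if not scale > 0:
                raise TPSParseError(index, f"non-positive SCALE {scale}")

    if scale is not None:
        pts = pts * scale
    if spec_id is None:
        spec_id = Path(image).stem if image else str(index)
    return LandmarkConfiguration(
        specimen_id=spec_id, landmarks=pts, scale=scale, source_image=image
    )


def read_tps(
    path: str | os.PathLike | io.TextIOBase,
    labels: Mapping[str, str] | None = None,
) -> LandmarkDataset:
    """Read a TPS file into a :class:`LandmarkDataset`.

    Coordinates are multiplied by the record's ``SCALE=`` factor when
    present.  Specimen ids resolve as ``ID=`` value, else the ``IMAGE=``
    basename without extension, else the zero-based record index.  When
    ``labels`` is given, every specimen must appear in it and receives its
    taxon.

    Parsing is insensitive to trailing whitespace, blank lines between
    records and CRLF line endings.
    """
    if isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        text = Path(path).read_text()

    lines = [ln.strip() for ln in text.splitlines()]
    # record boundaries: every LM= header starts a new record
    headers = [i for i, ln in enumerate(lines) if _LM_RE.match(ln)]
    stray = next((ln for ln in lines[: headers[0] if headers else len(lines)] if ln), None)
    if stray is not None:
        raise TPSParseError(0, f"content before first LM= header: {stray!r}")
    if not headers:
        raise TPSParseError(0, "no LM= records found")

    configs = []
    bounds = headers + [len(lines)]
    for rec, (start, stop) in enumerate(zip(bounds[:-1], bounds[1:])):
        body = [ln for ln in lines[start + 1 : stop] if ln]
        configs.append(_parse_record(rec, lines[start], body))

    ks = {c.k for c in configs}
    if len(ks) > 1:
        bad = next(i for i, c in enumerate(configs) if c.k != configs[0].k)
        raise TPSParseError(bad, f"landmark count {configs[bad].k} differs from first record ({configs[0].k})")

    dataset = LandmarkDataset(configs)
    if labels is not None:
        dataset = dataset.with_labels(labels)
    return dataset


def write_tps(dataset: LandmarkDataset, path: str | os.PathLike | io.TextIOBase) -> None:
    """Write a dataset as TPS records such that ``read_tps`` round-trips.

    Coordinates are emitted at full precision (``repr`` shortest form).
    When a configuration carries a scale factor, raw (unscaled)
    coordinates and a ``SCALE=`` line are written so re-reading
    reproduces the stored, scaled coordinates.
    """
    if len(dataset) == 0:
        raise ValueError("cannot write an empty dataset")
    buf = io.StringIO()
    for c in dataset:
        pts = c.landmarks if c.scale is None else c.landmarks / c.scale
        buf.write(f"LM={c.k}\n")
        for x, y in pts:
            buf.write(f"{float(x)!r} {float(y)!r}\n")
        if c.source_image is not None:
            buf.write(f"IMAGE={c.source_image}\n")
        buf.write(f"ID={c.specimen_id}\n")
        if c.scale is not None:
            buf.write(f"SCALE={float(c.scale)!r}\n")
    if isinstance(path, io.TextIOBase):
        path.write(buf.getvalue())
    else:
        Path(path).write_text(buf.getvalue())


_HEADER_WORDS = {"specimen", "specimen_id", "id", "sample", "taxon", "group", "label", "species"}


def read_labels(path: str | os.PathLike | io.TextIOBase) -> dict[str, str]:
    """Read a two-column specimen→taxon table (CSV or TSV, optional header)."""
    if isinstance(path, io.TextIOBase):
        text = path.read()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty label table")
    delim = "\t" if "\t" in lines[0] else ","
    rows = list(csv.reader(io.StringIO("\n".join(lines)), delimiter=delim))
    bad = next((r for r in rows if len(r) < 2), None)
    if bad is not None:
        raise ValueError(f"label table row has fewer than 2 columns: {bad!r}")
    first = [cell.strip().lower() for cell in rows[0][:2]]
    if any(cell in _HEADER_WORDS for cell in first):
        rows = rows[1:]
    return {r[0].strip(): r[1].strip() for r in rows}
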