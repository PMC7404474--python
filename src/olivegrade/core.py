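"""Core domain types and plain-text I/O.

A flash-GC instrument for olive-oil volatiles elutes each headspace sample
through two parallel capillary columns (non-polar and polar stationary
phases), each ending in a flame-ionization detector sampled every 0.01 s
over a 100 s run.  A :class:`Chromatogram` holds the two intensity traces on
their shared time axis together with the sample's identity and its sensory
quality grade (EVOO / VOO / LOO), which this package consumes as ground
truth and never derives itself.

File formats are deliberately plain text: chromatograms are CSV tables with
``# key: value`` metadata comment lines, manifests are four-column CSVs, and
fitted models serialize to a self-describing JSON archive with a
``format_version`` field so a model trained in one laboratory can be applied
in another.
"""

from __future__ import annotations

import dataclasses
import enum
import io
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Category",
    "Chromatogram",
    "CompoundSpec",
    "ManifestEntry",
    "SampleManifest",
    "OliveGradeError",
    "ChromatogramParseError",
    "ModelFormatError",
    "read_chromatogram",
    "write_chromatogram",
    "read_manifest",
    "write_manifest",
    "serialize_model",
    "deserialize_model",
]

MODEL_FORMAT_VERSION = 1

#: FID sampling interval (seconds) and nominal run length used throughout.
DT = 0.01
RUN_SECONDS = 100.0


class OliveGradeError(Exception):
    """Base class for all errors raised by this package."""


class ChromatogramParseError(OliveGradeError):
    """Malformed chromatogram or manifest file; message names the line."""


class ModelFormatError(OliveGradeError):
    """Unreadable or version-incompatible model archive."""


class Category(str, enum.Enum):
    """Commercial quality grade assigned by the sensory panel."""

    EVOO = "EVOO"
    VOO = "VOO"
    LOO = "LOO"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def parse(cls, value: str) -> "Category":
        try:
            return cls(value.strip().upper())
        except ValueError:
            raise OliveGradeError(f"unknown category {value!r}") from None


@dataclasses.dataclass(frozen=True)
class CompoundSpec:
    """A volatile marker compound as the instrument sees it.

    Parameters
    ----------
    name:
        Compound name (free text, unique within a library).
    rt_nonpolar, rt_polar:
        Apex retention time in seconds on each column; must lie inside the
        100 s run.
    width:
        Gaussian peak sigma in seconds.
    response_factor:
        Detector response in intensity units per mg·kg⁻¹ of analyte.
    """

    name: str
    rt_nonpolar: float
    rt_polar: float
    width: float
    response_factor: float

    def __post_init__(self) -> None:
        for label, rt in (("nonpolar", self.rt_nonpolar), ("polar", self.rt_polar)):
            if not 0.0 < rt < RUN_SECONDS:
                raise OliveGradeError(
                    f"{self.name}: {label} retention time {rt} outside (0, {RUN_SECONDS})"
                )
        if self.width <= 0:
            raise OliveGradeError(f"{self.name}: width must be positive")
        if self.response_factor <= 0:
            raise OliveGradeError(f"{self.name}: response factor must be positive")

    def rt(self, column: str) -> float:
        if column == "nonpolar":
            return self.rt_nonpolar
        if column == "polar":
            return self.rt_polar
        raise OliveGradeError(f"unknown column {column!r}")


def _check_uniform_axis(time_axis: np.ndarray) -> float:
    if time_axis.ndim != 1 or time_axis.size < 2:
        raise OliveGradeError("time axis must be a 1-D array of length >= 2")
    steps = np.diff(time_axis)
    if np.any(steps <= 0):
        raise OliveGradeError("non-uniform time axis: time must be strictly increasing")
    dt = steps[0]
    if np.any(np.abs(steps - dt) > 1e-9 * max(dt, 1.0)):
        raise OliveGradeError("non-uniform time axis: step varies beyond tolerance")
    return float(dt)


@dataclasses.dataclass
class Chromatogram:
    """One sample's pair of FID traces on a shared uniform time grid."""

    sample_id: str
    category: Category
    time_axis: np.ndarray
    trace_nonpolar: np.ndarray
    trace_polar: np.ndarray
    metadata: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.trace_nonpolar = np.asarray(self.trace_nonpolar, dtype=float)
        self.trace_polar = np.asarray(self.trace_polar, dtype=float)
        _check_uniform_axis(self.time_axis)
        n = self.time_axis.size
        if self.trace_nonpolar.shape != (n,) or self.trace_polar.shape != (n,):
            raise OliveGradeError(
                "trace lengths do not match the time axis "
                f"({self.trace_nonpolar.size}, {self.trace_polar.size} vs {n})"
            )
        if not (np.all(np.isfinite(self.trace_nonpolar)) and np.all(np.isfinite(self.trace_polar))):
            raise OliveGradeError("intensities must be finite")

    @property
    def dt(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0])

    @property
    def n_points(self) -> int:
        return int(self.time_axis.size)

    def trace(self, column: str) -> np.ndarray:
        if column == "nonpolar":
            return self.trace_nonpolar
        if column == "polar":
            return self.trace_polar
        raise OliveGradeError(f"unknown column {column!r}")

    def equals(self, other: "Chromatogram") -> bool:
        return (
            self.sample_id == other.sample_id
            and self.category == other.category
            and np.array_equal(self.time_axis, other.time_axis)
            and np.array_equal(self.trace_nonpolar, other.trace_nonpolar)
            and np.array_equal(self.trace_polar, other.trace_polar)
            and self.metadata == other.metadata
        )


@dataclasses.dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    category: Category
    path: str
    set_tag: str = "none"  # calibration | external | none

    def __post_init__(self) -> None:
        if self.set_tag not in ("calibration", "external", "none"):
            raise OliveGradeError(f"bad set_tag {self.set_tag!r}")


@dataclasses.dataclass
class SampleManifest:
    """Bookkeeping for a dataset: ordered sample ids, labels and file paths."""

    entries: list[ManifestEntry]
    dataset_id: str = ""

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise OliveGradeError("duplicate sample_id in manifest")

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def categories(self) -> dict[str, Category]:
        return {e.sample_id: e.category for e in self.entries}

    def order(self) -> dict[str, int]:
        """Manifest position of each sample, used by venetian-blinds folds."""
        return {e.sample_id: i for i, e in enumerate(self.entries)}


# ---------------------------------------------------------------------------
# Chromatogram CSV dialect
# ---------------------------------------------------------------------------

_HEADER = "time,intensity_nonpolar,intensity_polar"


def read_chromatogram(path: str | Path) -> Chromatogram:
    """Read a chromatogram CSV (``# key: value`` comments + 3-column table)."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    metadata: dict[str, str] = {}
    row0 = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            row0 = i
            break
        body = line.lstrip("#").strip()
        if ":" not in body:
            raise ChromatogramParseError(f"{path}:{i + 1}: malformed metadata comment {line!r}")
        key, value = body.split(":", 1)
        metadata[key.strip()] = value.strip()
    else:
        raise ChromatogramParseError(f"{path}: no data table found")

    if lines[row0].strip() != _HEADER:
        raise ChromatogramParseError(
            f"{path}:{row0 + 1}: malformed header {lines[row0]!r}; expected {_HEADER!r}"
        )
    table = pd.read_csv(
        io.StringIO("\n".join(lines[row0:])),
        dtype=str,
        keep_default_na=False,
    )
    numeric = {}
    for col in table.columns:
        try:
            numeric[col] = table[col].to_numpy(dtype=float)  # exact strtod parsing
        except ValueError:
            for r, cell in enumerate(table[col]):
                try:
                    float(cell)
                except ValueError:
                    raise ChromatogramParseError(
                        f"{path}:{row0 + 2 + r}: non-numeric cell {cell!r} in column {col}"
                    ) from None
            raise
    try:
        _check_uniform_axis(numeric["time"])
    except OliveGradeError as exc:
        raise ChromatogramParseError(f"{path}: {exc}") from None

    sample_id = metadata.pop("sample_id", path.stem)
    category = Category.parse(metadata.pop("category", "UNKNOWN"))
    return Chromatogram(
        sample_id=sample_id,
        category=category,
        time_axis=numeric["time"],
        trace_nonpolar=numeric["intensity_nonpolar"],
        trace_polar=numeric["intensity_polar"],
        metadata=metadata,
    )


def write_chromatogram(c: Chromatogram, path: str | Path) -> Path:
    """Write ``c`` so that :func:`read_chromatogram` round-trips bit-identically.

    Floats are written with ``repr`` (shortest exact representation), so the
    round trip preserves the binary values.
    """
    path = Path(path)
    out = [f"# sample_id: {c.sample_id}", f"# category: {c.category.value}"]
    for key, value in c.metadata.items():
        if key in ("sample_id", "category"):
            raise OliveGradeError(f"metadata key {key!r} is reserved")
        out.append(f"# {key}: {value}")
    out.append(_HEADER)
    out.extend(
        f"{t!r},{a!r},{b!r}"
        for t, a, b in zip(
            c.time_axis.tolist(), c.trace_nonpolar.tolist(), c.trace_polar.tolist()
        )
    )
    path.write_text("\n".join(out) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Manifest CSV
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> SampleManifest:
    path = Path(path)
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["sample_id", "category", "path", "set_tag"]
    if list(table.columns) != expected:
        raise ChromatogramParseError(f"{path}:1: manifest header must be {','.join(expected)}")
    entries = [
        ManifestEntry(
            sample_id=row.sample_id,
            category=Category.parse(row.category),
            path=row.path,
            set_tag=row.set_tag or "none",
        )
        for row in table.itertuples(index=False)
    ]
    return SampleManifest(entries=entries, dataset_id=path.stem)


def write_manifest(manifest: SampleManifest, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in manifest.entries],
            "category": [e.category.value for e in manifest.entries],
            "path": [e.path for e in manifest.entries],
            "set_tag": [e.set_tag for e in manifest.entries],
        }
    )
    frame.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Model serialization (JSON archive with format_version)
# ---------------------------------------------------------------------------


def serialize_model(model, path: str | Path) -> Path:
    """Serialize a fitted PLSDAModel or CascadeModel to a JSON archive.

    All numeric arrays are emitted as JSON number lists; Python's shortest
    round-trip float representation makes the round trip exact at binary
    precision.
    """
    from . import cascade, plsda  # local import to avoid a cycle

    if isinstance(model, plsda.PLSDAModel):
        kind = "plsda"
    elif isinstance(model, cascade.CascadeModel):
        kind = "cascade"
    else:
        raise ModelFormatError(f"cannot serialize object of type {type(model).__name__}")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": kind,
        "model": model.to_dict(),
    }
    path = Path(path)
    path.write_text(json.dumps(payload, sort_keys=True), encoding="utf-8")
    return path


def deserialize_model(path: str | Path):
    """Inverse of :func:`serialize_model`; checks the format version."""
    from . import cascade, plsda

    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"{path}: unreadable or truncated model archive: {exc}") from None
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: model format version {version!r} is not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    kind = payload.get("kind")
    if kind == "plsda":
        return plsda.PLSDAModel.from_dict(payload["model"])
    if kind == "cascade":
        return cascade.CascadeModel.from_dict(payload["model"])
    raise ModelFormatError(f"{path}: unknown model kind {kind!r}")
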