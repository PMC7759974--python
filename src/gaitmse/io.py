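"""Reading and writing gait-force records and cohort manifests.

A record file is plain delimited text, one row per sample, with either two
columns (LF, RF) or three (time, LF, RF); comma, tab and whitespace
delimiters are auto-detected and lines starting with ``#`` are ignored. A
time column is validated as uniformly spaced at ``1/fs`` and then dropped.
Force values are arbitrary force-proportional units (force-sensitive
resistor output); no unit conversion is attempted.

A cohort manifest is a CSV/TSV with columns ``path,subject_id,class_label``;
record paths are resolved relative to the manifest's directory.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical class labels of the four-group movement-disorder cohort. The
#: label set is extensible: synthetic cohorts may use arbitrary labels.
KNOWN_LABELS = ("HC", "PD", "HD", "ALS")


@dataclass
class GaitRecord:
    """One subject's raw left/right vertical gait-force series.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    class_label : str
        Group label (e.g. ``"HC"``, ``"PD"``, ``"HD"``, ``"ALS"``).
    fs : float
        Sampling frequency in Hz (the reference cohort uses 300 Hz).
    lf, rf : ndarray
        Left- and right-foot force samples, equal length, finite.
    """

    subject_id: str
    class_label: str
    fs: float
    lf: np.ndarray
    rf: np.ndarray

    def __post_init__(self) -> None:
        self.lf = np.asarray(self.lf, dtype=float)
        self.rf = np.asarray(self.rf, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.lf.ndim != 1 or self.rf.ndim != 1:
            raise ValueError("lf and rf must be one-dimensional")
        if len(self.lf) != len(self.rf):
            raise ValueError(
                f"lf and rf must have equal length, got {len(self.lf)} and {len(self.rf)}"
            )
        if len(self.lf) == 0:
            raise ValueError("record must contain at least one sample")
        if not (np.isfinite(self.lf).all() and np.isfinite(self.rf).all()):
            raise ValueError("record contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return len(self.lf)

    @property
    def duration_s(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs


@dataclass
class CohortManifest:
    """Mapping of record files to subjects and class labels.

    ``entries`` is a list of ``(path, subject_id, class_label)`` tuples;
    paths may be relative to ``base_dir``.
    """

    entries: list[tuple[str, str, str]]
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        self.base_dir = Path(self.base_dir)
        ids = [subject for _, subject, _ in self.entries]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ValueError(f"duplicate subject_id in manifest: {sorted(dupes)}")

    def class_counts(self) -> dict[str, int]:
        """Number of subjects per class, in first-seen order."""
        counts: dict[str, int] = {}
        for _, _, label in self.entries:
            counts[label] = counts.get(label, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.entries)


def _split_line(line: str) -> list[str]:
    if "," in line:
        return [tok for tok in line.replace(",", " ").split()]
    return line.split()


def read_gait_record(
    path: str | Path,
    fs: float = 300.0,
    label: str = "HC",
    subject_id: str | None = None,
) -> GaitRecord:
    """Read one delimited-text gait record.

    Accepts two numeric columns (LF, RF) or three (time, LF, RF). A time
    column must be uniformly spaced at ``1/fs`` within 1% and is discarded.

    Raises
    ------
    ValueError
        On an unparseable line (the error names the 1-based line number),
        inconsistent column counts, or a non-uniform time column.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    rows: list[list[float]] = []
    ncols: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = _split_line(line)
            try:
                values = [float(t) for t in toks]
            except ValueError as exc:
                raise ValueError(f"{path}: unparseable line {lineno}: {line!r}") from exc
            if ncols is None:
                ncols = len(values)
                if ncols not in (2, 3):
                    raise ValueError(
                        f"{path}: line {lineno}: expected 2 (LF,RF) or 3 (time,LF,RF) "
                        f"columns, got {ncols}"
                    )
            elif len(values) != ncols:
                raise ValueError(
                    f"{path}: line {lineno}: expected {ncols} columns, got {len(values)}"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    if ncols == 3:
        t = data[:, 0]
        if len(t) > 1:
            dt = np.diff(t)
            expected = 1.0 / fs
            if np.any(np.abs(dt - expected) > 0.01 * expected):
                raise ValueError(
                    f"{path}: time column is not uniformly spaced at 1/fs = {expected:g} s"
                )
        data = data[:, 1:]
    return GaitRecord(subject_id=subject_id, class_label=label, fs=fs, lf=data[:, 0], rf=data[:, 1])


def write_gait_record(record: GaitRecord, path: str | Path) -> None:
    """Write a record as two-column delimited text, re-readable by
    :func:`read_gait_record`. Metadata goes into ``#`` header comments."""
    path = Path(path)
    header = (
        f"subject_id: {record.subject_id}\n"
        f"class_label: {record.class_label}\n"
        f"fs_hz: {record.fs:g}\n"
        "columns: LF RF"
    )
    np.savetxt(
        path,
        np.column_stack([record.lf, record.rf]),
        fmt="%.10g",
        header=header,
    )


def load_manifest(path: str | Path) -> CohortManifest:
    """Load a ``path,subject_id,class_label`` manifest (CSV or TSV)."""
    path = Path(path)
    entries: list[tuple[str, str, str]] = []
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if sample.count("\t") > sample.count(",") else ","
        reader = csv.reader(fh, delimiter=delim)
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if [c.strip().lower() for c in row[:3]] == ["path", "subject_id", "class_label"]:
                continue
            if len(row) < 3:
                raise ValueError(f"{path}: manifest row needs 3 columns, got {row!r}")
            entries.append((row[0].strip(), row[1].strip(), row[2].strip()))
    return CohortManifest(entries=entries, base_dir=path.parent)


def save_manifest(manifest: CohortManifest, path: str | Path) -> None:
    """Write a manifest as CSV with a header row."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "subject_id", "class_label"])
        for entry in manifest.entries:
            writer.writerow(entry)


def load_cohort(manifest: CohortManifest, fs: float = 300.0) -> list[GaitRecord]:
    """Load every record named in a manifest, attaching labels.

    Returns one :class:`GaitRecord` per entry; per-class subject counts are
    logged. A missing record file raises ``FileNotFoundError`` naming the
    resolved path. An empty manifest yields an empty list with a warning.
    """
    if len(manifest) == 0:
        logger.warning("empty cohort manifest: no records loaded")
        return []
    records = []
    for rel_path, subject_id, label in manifest.entries:
        full = Path(rel_path)
        if not full.is_absolute():
            full = manifest.base_dir / full
        if not full.exists():
            raise FileNotFoundError(f"manifest entry not found: {full}")
        records.append(read_gait_record(full, fs=fs, label=label, subject_id=subject_id))
    counts = manifest.class_counts()
    logger.info("loaded %d records; subjects per class: %s", len(records), counts)
    return records
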