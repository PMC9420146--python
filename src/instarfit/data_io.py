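"""Reading, validation, and binning of head-capsule-width (HCW) tables.

Measurements arrive as a delimited text table with one row per larva and a
numeric column of head-capsule widths in micrometres (μm). This module
validates that column into an :class:`HCWDataset` and bins it into an
:class:`HCWHistogram` for frequency-distribution display and histogram-mode
mixture fitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Minimum bin width in μm used by the automatic (Freedman–Diaconis) rule.
MIN_BIN_WIDTH = 5.0


class HCWValidationError(ValueError):
    """Raised when a measurement table contains invalid rows in strict mode."""


@dataclass(frozen=True)
class HCWDataset:
    """A validated vector of per-larva head-capsule widths in μm.

    Parameters
    ----------
    values
        Head-capsule widths, one per larva. Every value must be finite
        and strictly positive.
    ids
        Optional per-larva labels, same length as ``values``.
    source
        Optional provenance string (typically the input file path).
    """

    values: np.ndarray
    ids: tuple[str, ...] | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise HCWValidationError("dataset must be a non-empty 1-D vector")
        if not np.all(np.isfinite(values)):
            raise HCWValidationError("dataset contains non-finite values")
        if np.any(values <= 0):
            raise HCWValidationError("head-capsule widths must be > 0 μm")
        object.__setattr__(self, "values", values)
        if self.ids is not None:
            ids = tuple(str(i) for i in self.ids)
            if len(ids) != values.size:
                raise HCWValidationError(
                    f"ids length {len(ids)} != values length {values.size}"
                )
            object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class HCWHistogram:
    """Binned HCW frequency distribution.

    Bins are half-open ``[edge_i, edge_{i+1})`` except the last, which is
    closed on the right, so every in-range value lands in exactly one bin.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("need at least two bin edges")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if counts.size != edges.size - 1:
            raise ValueError("counts length must be len(edges) - 1")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_tsv(self, path: str | Path) -> None:
        """Write the histogram as two-column TSV (bin_start, count)."""
        pd.DataFrame(
            {"bin_start": self.bin_edges[:-1], "count": self.counts}
        ).to_csv(path, sep="\t", index=False)


def read_hcw_table(
    path: str | Path,
    column: str | int = "hcw_um",
    delimiter: str = ",",
    unit: str = "um",
    strict: bool = True,
) -> HCWDataset:
    """Read a delimited measurement table into a validated :class:`HCWDataset`.

    Parameters
    ----------
    path
        Path to a UTF-8 delimited text file with one header row.
    column
        Column name, or zero-based integer position, holding the widths.
    delimiter
        Single-character field delimiter.
    unit
        ``"um"`` (default) or ``"mm"``; millimetre inputs are converted to
        μm by ×1000. No unit inference is attempted from headers.
    strict
        When True (default), any non-numeric or non-positive row is fatal
        and the error names the offending data rows (1-based). When False,
        such rows are dropped with a logged warning.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    KeyError
        If the column is absent.
    HCWValidationError
        On invalid rows in strict mode, or if no valid rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such measurement table: {path}")
    if len(delimiter) != 1:
        raise ValueError("delimiter must be a single character")
    if unit not in ("um", "mm"):
        raise ValueError(f"unit must be 'um' or 'mm', got {unit!r}")

    table = pd.read_csv(path, sep=delimiter, encoding="utf-8",
                        float_precision="round_trip")
    if isinstance(column, int):
        if not 0 <= column < table.shape[1]:
            raise KeyError(f"column index {column} out of range")
        series = table.iloc[:, column]
    else:
        if column not in table.columns:
            raise KeyError(
                f"column {column!r} not found; available: {list(table.columns)}"
            )
        series = table[column]

    numeric = pd.to_numeric(series, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy()) | (numeric.to_numpy() <= 0)
    if bad.any():
        bad_rows = [int(i) + 1 for i in np.flatnonzero(bad)]  # 1-based data rows
        msg = f"invalid (non-numeric or non-positive) values at data rows {bad_rows}"
        if strict:
            raise HCWValidationError(msg)
        logger.warning("%s — dropped", msg)
    values = numeric.to_numpy(dtype=float)[~bad]
    if values.size == 0:
        raise HCWValidationError("no valid rows in measurement table")
    if unit == "mm":
        values = values * 1000.0

    ids = None
    if "id" in table.columns and (isinstance(column, int) or column != "id"):
        ids = tuple(str(v) for v in table["id"].to_numpy()[~bad])
    return HCWDataset(values=values, ids=ids, source=str(path))


def write_hcw_table(
    data: HCWDataset, path: str | Path, delimiter: str = ",", column: str = "hcw_um"
) -> None:
    """Serialize a dataset back to the delimited-table input format."""
    frame: dict[str, Sequence] = {}
    if data.ids is not None:
        frame["id"] = list(data.ids)
    frame[column] = data.values
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(frame).to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def freedman_diaconis_width(values: np.ndarray) -> float:
    """Freedman–Diaconis bin width, floored at :data:`MIN_BIN_WIDTH` μm."""
    q75, q25 = np.percentile(values, [75, 25])
    width = 2.0 * (q75 - q25) / values.size ** (1.0 / 3.0)
    return max(float(width), MIN_BIN_WIDTH)


def make_histogram(
    data: HCWDataset,
    bin_width: float | str = "auto",
    origin: float | None = None,
) -> HCWHistogram:
    """Bin a dataset into a frequency histogram.

    ``bin_width="auto"`` applies the Freedman–Diaconis rule with a 5 μm
    floor. The bin origin defaults to the minimum observed value rounded
    down to a multiple of the bin width, which makes the binning
    deterministic and independent of row order.
    """
    values = data.values
    if bin_width == "auto":
        width = freedman_diaconis_width(values)
    else:
        width = float(bin_width)
        if width <= 0:
            raise ValueError("bin width must be > 0 μm")
    lo = float(values.min())
    hi = float(values.max())
    if origin is None:
        origin = math.floor(lo / width) * width
    elif origin > lo:
        raise ValueError("histogram origin must not exceed the minimum value")
    n_bins = max(1, math.ceil((hi - origin) / width))
    if origin + n_bins * width < hi:  # guard against float round-down
        n_bins += 1
    edges = origin + width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return HCWHistogram(bin_edges=edges, counts=counts)
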