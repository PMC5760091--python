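"""Reading, transforming and writing cytometry event data.

The universal in-memory container is :class:`EventMatrix`: an events x markers
matrix of (possibly arcsinh-transformed) intensities together with the marker
names.  Input formats are FCS 3.0/3.1 (read-only) and delimited text with a
mandatory header row; all tabular output is UTF-8 CSV/TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EventMatrix",
    "read_events",
    "arcsinh_transform",
    "viability_filter",
    "write_assignments",
    "read_assignments",
]


@dataclass
class EventMatrix:
    """Events x markers intensity matrix for one cytometry sample.

    Parameters
    ----------
    values
        ``(n_events, n_markers)`` float array.  No missing values allowed.
    marker_names
        Column names, unique, one per marker.
    sample_id
        Identifier of the sample the events came from.
    transformed
        Whether the variance-stabilizing arcsinh transform has been applied.
    """

    values: np.ndarray
    marker_names: list[str]
    sample_id: str = ""
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D events x markers array")
        self.marker_names = [str(m) for m in self.marker_names]
        if len(self.marker_names) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.marker_names)} marker names for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("duplicate marker names")
        if self.values.shape[1] < 2:
            raise ValueError("an EventMatrix needs at least 2 markers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN or infinities")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def column(self, marker: str) -> np.ndarray:
        """Return the 1-D intensity vector for ``marker``."""
        try:
            idx = self.marker_names.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not present") from None
        return self.values[:, idx]


def read_events(path, format: str | None = None, sample_id: str | None = None) -> EventMatrix:
    """Read an FCS or delimited-text file into an untransformed EventMatrix.

    ``format`` is ``"fcs"`` or ``"delimited"``; when omitted it is inferred
    from the file suffix (``.fcs`` vs anything else).  Column order of the
    source file is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "delimited"
    if format == "fcs":
        values, names = _read_fcs(path)
    elif format == "delimited":
        values, names = _read_delimited(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return EventMatrix(
        values=values,
        marker_names=names,
        sample_id=sample_id if sample_id is not None else path.stem,
        transformed=False,
    )


def _read_delimited(path: Path) -> tuple[np.ndarray, list[str]]:
    # comma default, tab accepted; header row mandatory
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # includes EmptyDataError
        raise ValueError(f"cannot parse delimited file {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path} holds no events")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def _read_fcs(path: Path) -> tuple[np.ndarray, list[str]]:
    """Minimal FCS 3.0/3.1 reader (numeric data segment, single dataset)."""
    raw = path.read_bytes()
    if len(raw) < 58:
        raise ValueError(f"{path} is not an FCS file (truncated header)")
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS"):
        raise ValueError(f"{path} is not an FCS file (magic {version!r})")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise ValueError(f"{path}: unreadable FCS header offsets") from exc
    delim = raw[text_start:text_start + 1].decode("latin-1")
    fields = raw[text_start + 1:text_end + 1].decode("latin-1").split(delim)
    kw = {fields[i].strip().upper(): fields[i + 1]
          for i in range(0, len(fields) - 1, 2)}

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype_code = kw["$DATATYPE"].upper()
    byteorder = kw.get("$BYTEORD", "1,2,3,4")
    little = byteorder.startswith("1")
    data_start = int(kw.get("$BEGINDATA", 0)) or int(raw[26:34])
    data_end = int(kw.get("$ENDDATA", 0)) or int(raw[34:42])

    # prefer $PnS (stain/marker name), fall back to $PnN (short name)
    names = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}S", "").strip() or kw.get(f"$P{i}N", "").strip()
        names.append(name or f"P{i}")
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate marker names in FCS text segment")

    order = "<" if little else ">"
    if dtype_code == "F":
        np_dtype = np.dtype(f"{order}f4")
    elif dtype_code == "D":
        np_dtype = np.dtype(f"{order}f8")
    elif dtype_code == "I":
        bits = {int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (8, 16, 32):
            raise ValueError(f"{path}: unsupported mixed/odd integer widths")
        width = int(kw["$P1B"]) // 8
        np_dtype = np.dtype(f"{order}u{width}")
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {dtype_code!r}")

    n_vals = n_par * n_tot
    buf = raw[data_start:data_start + n_vals * np_dtype.itemsize]
    if len(buf) < n_vals * np_dtype.itemsize:
        raise ValueError(f"{path}: data segment shorter than $TOT*$PAR values")
    values = np.frombuffer(buf, dtype=np_dtype, count=n_vals)
    return values.reshape(n_tot, n_par).astype(float), names


def arcsinh_transform(m: EventMatrix, cofactor: float = 5.0) -> EventMatrix:
    """Apply the variance-stabilizing transform ``asinh(x / cofactor)``.

    Cofactor 5 is the mass-cytometry convention.  Refuses to run twice.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if m.transformed:
        raise ValueError("EventMatrix is already arcsinh-transformed")
    return replace(m, values=np.arcsinh(m.values / cofactor), transformed=True)


def viability_filter(
    m: EventMatrix,
    dna_channel: str,
    viability_channel: str,
    keep_fraction: float = 0.95,
    dna_keep: str = "high",
    viability_keep: str = "low",
) -> EventMatrix:
    """Sequential DNA-content and viability-stain gate.

    First retains the ``keep_fraction`` of events with the highest DNA signal
    (intact cells), then, within the survivors, the ``keep_fraction`` with the
    lowest viability-stain signal (cisplatin only enters dead cells).  Overall
    retention is therefore about ``keep_fraction ** 2``.  The direction of
    each gate is configurable via ``dna_keep`` / ``viability_keep``
    (``"high"`` or ``"low"``).  Quantile ties break by original row order, so
    exactly ``ceil(f * n)`` events survive each stage.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    idx = _top_fraction(m.column(dna_channel), keep_fraction, dna_keep)
    survivors = m.values[idx]
    v = survivors[:, m.marker_names.index(viability_channel)]
    idx2 = _top_fraction(v, keep_fraction, viability_keep)
    return replace(m, values=survivors[idx2])


def _top_fraction(x: np.ndarray, f: float, keep: str) -> np.ndarray:
    if keep not in ("high", "low"):
        raise ValueError("keep direction must be 'high' or 'low'")
    n = len(x)
    k = int(np.ceil(f * n))
    key = -x if keep == "high" else x
    # stable sort so ties at the boundary resolve by original row order
    order = np.argsort(key, kind="stable")[:k]
    return np.sort(order)  # restore original event order


def write_assignments(
    path,
    labels: np.ndarray,
    sample_id: str,
    clades=None,
    sep: str = ",",
) -> None:
    """Write per-event (event_index, sample_id, subpopulation, clade) table.

    ``clades`` maps each event to a clade id; events without a surviving clade
    (discarded) are written as ``"NA"``.  Rows are emitted in event order.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if clades is None:
        clade_col = ["NA"] * n
    else:
        clade_col = ["NA" if c is None or (isinstance(c, float) and np.isnan(c))
                     else c for c in clades]
        if len(clade_col) != n:
            raise ValueError("clades length does not match labels")
    df = pd.DataFrame(
        {
            "event_index": np.arange(n),
            "sample_id": sample_id,
            "subpopulation": labels,
            "clade": clade_col,
        }
    )
    df.to_csv(path, sep=sep, index=False)


def read_assignments(path, sep: str = ",") -> pd.DataFrame:
    """Round-trip reader for :func:`write_assignments` output."""
    df = pd.read_csv(path, sep=sep, keep_default_na=False)
    df["subpopulation"] = df["subpopulation"].astype(int)
    return df
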