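"""Reading and writing cytometry event tables, count series and reports.

The canonical in-memory container is :class:`EventTable`: a pandas
DataFrame of per-event measurements under six canonical column names

    CTV_A  CellTrace Violet area (division-tracking dye), linear a.u.
    AG_A   Apotracker Green area (apoptosis marker), linear a.u.
    PI_A   propidium iodide area (membrane-rupture marker), linear a.u.
    FSC_A, FSC_H, SSC_A  forward/side scatter, linear a.u.

plus optional ``generation`` / ``state`` label columns when the events
are of synthetic origin.  Values are passed through untransformed: no
compensation (an optional spillover hook accepts a matrix; the default
is identity) and no scaling.  Negative values from instrument baseline
subtraction are retained at read time and handled downstream.

On-disk formats are CSV (lossless round trip) and a minimal FCS 3.1
subset (list mode, 32-bit float, ``$PnN`` set to the canonical names).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChannelMappingError

REQUIRED_CHANNELS = ("CTV_A", "AG_A", "PI_A", "FSC_A", "FSC_H", "SSC_A")
LABEL_COLUMNS = ("generation", "state")


@dataclass
class EventTable:
    """Per-event cytometry measurements with canonical column names.

    Parameters
    ----------
    data
        DataFrame with at least the six required channels; optional
        ``generation`` and ``state`` columns carry synthetic truth labels.
    channel_map
        Mapping from canonical name to the original instrument channel
        name the value came from (identity for synthetic tables).
    source
        Path or description of where the events came from.
    meta
        Free-form metadata (e.g. singlet-gate retained fraction).
    """

    data: pd.DataFrame
    channel_map: dict[str, str] = field(default_factory=dict)
    source: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"EventTable missing required channels: {missing}")
        if len(self.data) < 1:
            raise ValueError("EventTable must contain at least one event")
        if not self.channel_map:
            self.channel_map = {c: c for c in REQUIRED_CHANNELS}

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def has_labels(self) -> bool:
        return all(c in self.data.columns for c in LABEL_COLUMNS)

    def subset(self, mask) -> "EventTable":
        """Return a new table restricted to ``mask`` (metadata preserved)."""
        return EventTable(
            self.data.loc[mask].reset_index(drop=True),
            channel_map=dict(self.channel_map),
            source=self.source,
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# channel auto-mapping
# ---------------------------------------------------------------------------

# Keyword dialects seen in exported FCS/CSV channel names: stain names,
# detector filter specs, or the canonical names themselves.
_CHANNEL_PATTERNS: dict[str, tuple[str, ...]] = {
    "CTV_A": ("ctv", "celltrace", "450/40", "bv421", "pacific blue", "violet"),
    "AG_A": ("apotracker", "530/30", "fitc", "annexin"),
    "PI_A": ("propidium", "585/15", "pi-a", "pi_a"),
    "FSC_A": ("fsc-a", "fsc_a", "fsc a"),
    "FSC_H": ("fsc-h", "fsc_h", "fsc h"),
    "SSC_A": ("ssc-a", "ssc_a", "ssc a"),
}


def _norm(name: str) -> str:
    return str(name).strip().lower().replace("-", "_").replace(" ", "_")


def resolve_channel_map(available: list[str], channel_map="auto") -> dict[str, str]:
    """Resolve canonical channel names against the names found in a file.

    ``channel_map`` may be an explicit ``{canonical: original}`` dict or
    ``"auto"``, in which case exact canonical matches are taken first and
    remaining channels are matched by stain/filter keyword.  Deterministic
    given the file's channel names.
    """
    if isinstance(channel_map, dict):
        missing = [c for c in REQUIRED_CHANNELS if c not in channel_map]
        if missing:
            raise ChannelMappingError(
                f"channel_map missing required channels {missing}; "
                f"available: {available}",
                available,
            )
        for canon, orig in channel_map.items():
            if orig not in available:
                raise ChannelMappingError(
                    f"mapped channel {orig!r} for {canon} not present; "
                    f"available: {available}",
                    available,
                )
        return dict(channel_map)

    if channel_map != "auto":
        raise ValueError("channel_map must be a dict or 'auto'")

    normed = {_norm(a): a for a in available}
    result: dict[str, str] = {}
    used: set[str] = set()
    # pass 1: exact canonical-name matches
    for canon in REQUIRED_CHANNELS:
        hit = normed.get(_norm(canon))
        if hit is not None and hit not in used:
            result[canon] = hit
            used.add(hit)
    # pass 2: keyword matches in file order
    for canon in REQUIRED_CHANNELS:
        if canon in result:
            continue
        for orig in available:
            if orig in used:
                continue
            name = str(orig).lower()
            if any(pat in name for pat in _CHANNEL_PATTERNS[canon]):
                result[canon] = orig
                used.add(orig)
                break
        else:
            raise ChannelMappingError(
                f"could not map required channel {canon}; "
                f"available channels: {available}",
                available,
            )
    return result


# ---------------------------------------------------------------------------
# minimal FCS 3.1 subset
# ---------------------------------------------------------------------------

_HEADER_LEN = 58


def _build_text(pairs: dict[str, str], delim: str = "/") -> bytes:
    parts = [delim]
    for k, v in pairs.items():
        parts.append(f"{k}{delim}{v}{delim}")
    return "".join(parts).encode("ascii")


def write_fcs(path, data: pd.DataFrame, channel_names: list[str]) -> None:
    """Write a minimal FCS 3.1 file: list mode, float32, little endian."""
    arr = np.ascontiguousarray(data[channel_names].to_numpy(dtype=np.float32))
    n_events, n_par = arr.shape
    payload = arr.tobytes()

    pairs = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BEGINDATA": "0",
        "$ENDDATA": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(channel_names, start=1):
        pairs[f"$P{i}N"] = name
        pairs[f"$P{i}B"] = "32"
        pairs[f"$P{i}E"] = "0,0"
        pairs[f"$P{i}R"] = str(int(max(1.0, np.ceil(float(arr[:, i - 1].max())))))

    # offsets depend on TEXT length; iterate until self-consistent
    text_start = _HEADER_LEN
    for _ in range(4):
        text = _build_text(pairs)
        data_start = text_start + len(text)
        data_end = data_start + len(payload) - 1
        if pairs["$BEGINDATA"] == str(data_start) and pairs["$ENDDATA"] == str(data_end):
            break
        pairs["$BEGINDATA"] = str(data_start)
        pairs["$ENDDATA"] = str(data_end)
    text = _build_text(pairs)
    data_start = text_start + len(text)
    data_end = data_start + len(payload) - 1
    text_end = text_start + len(text) - 1

    header = b"FCS3.1"
    header += b" " * 4
    for off in (text_start, text_end, data_start, data_end, 0, 0):
        header += f"{off:>8d}".encode("ascii")
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)


def read_fcs(path) -> tuple[pd.DataFrame, list[str]]:
    """Read an FCS 3.0/3.1 file (list mode, float or double data).

    Returns the raw data frame (columns named by ``$PnN``) and the
    channel-name list in file order.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_LEN or not raw[:3] == b"FCS":
        raise ValueError(f"{path} is not an FCS file")

    def _off(a: int, b: int) -> int:
        s = raw[a:b].decode("ascii", errors="replace").strip()
        return int(s) if s else 0

    text_start, text_end = _off(10, 18), _off(18, 26)
    data_start, data_end = _off(26, 34), _off(34, 42)

    text = raw[text_start : text_end + 1].decode("latin-1")
    delim = text[0]
    tokens = text.strip(delim).split(delim)
    kw = {tokens[i].upper().strip(): tokens[i + 1] for i in range(0, len(tokens) - 1, 2)}

    if data_start == 0:
        data_start = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    order = "<" if byteord.startswith("1") else ">"
    if datatype == "F":
        dtype = np.dtype(order + "f4")
    elif datatype == "D":
        dtype = np.dtype(order + "f8")
    else:
        raise ValueError(f"unsupported FCS $DATATYPE {datatype!r} (need F or D)")

    payload = raw[data_start : data_end + 1]
    arr = np.frombuffer(payload, dtype=dtype, count=n_par * n_tot)
    arr = arr.reshape(n_tot, n_par).astype(float)

    names = []
    for i in range(1, n_par + 1):
        names.append(kw.get(f"$P{i}N") or kw.get(f"$P{i}S") or f"P{i}")
    return pd.DataFrame(arr, columns=names), names


# ---------------------------------------------------------------------------
# public event I/O
# ---------------------------------------------------------------------------

def read_events(path, channel_map="auto", spillover: np.ndarray | None = None) -> EventTable:
    """Read events from an FCS 3.0/3.1 file or a CSV event table.

    Values are used uncompensated by default; ``spillover`` accepts an
    optional 6x6 matrix (canonical channel order) that is inverted and
    applied, for files that need compensation.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    with open(path, "rb") as fh:
        magic = fh.read(3)
    if magic == b"FCS":
        raw, names = read_fcs(path)
    else:
        raw = pd.read_csv(path, float_precision="round_trip")
        if len(raw) == 0:
            raise ValueError(f"{path} contains no events")
        names = list(raw.columns)

    label_cols = [c for c in names if _norm(c) in LABEL_COLUMNS]
    mapping = resolve_channel_map([c for c in names if c not in label_cols], channel_map)
    data = pd.DataFrame({canon: raw[orig].to_numpy() for canon, orig in mapping.items()})
    if spillover is not None:
        spill = np.asarray(spillover, dtype=float)
        comp = data[list(REQUIRED_CHANNELS)].to_numpy() @ np.linalg.inv(spill)
        data.loc[:, list(REQUIRED_CHANNELS)] = comp
    for c in label_cols:
        data[_norm(c)] = raw[c].to_numpy()
    return EventTable(data, channel_map=mapping, source=str(path))


def write_events(table: EventTable, path, format: str = "csv") -> None:
    """Write an EventTable as CSV (lossless) or minimal FCS 3.1 (float32).

    FCS holds numeric channels only; synthetic label columns are dropped
    with a warning.
    """
    path = Path(path)
    if format == "csv":
        table.data.to_csv(path, index=False)
    elif format == "fcs":
        dropped = [c for c in table.data.columns if c not in REQUIRED_CHANNELS]
        if dropped:
            warnings.warn(
                f"dropping non-channel columns {dropped} when writing FCS",
                stacklevel=2,
            )
        write_fcs(path, table.data, list(REQUIRED_CHANNELS))
    else:
        raise ValueError(f"unknown format {format!r} (use 'csv' or 'fcs')")


# ---------------------------------------------------------------------------
# count series
# ---------------------------------------------------------------------------

def read_counts(path, condition: str | None = None) -> pd.DataFrame:
    """Read a cell-count series CSV with columns day, replicate, count.

    An optional ``split_factor`` column (multiplicative correction for
    culture splitting) is preserved.  Counts must be positive numbers and
    days non-negative.
    """
    df = pd.read_csv(path)
    cols = {_norm(c): c for c in df.columns}
    missing = [c for c in ("day", "replicate", "count") if c not in cols]
    if missing:
        raise ValueError(f"count series {path} missing columns {missing}")
    out = pd.DataFrame(
        {
            "day": pd.to_numeric(df[cols["day"]], errors="coerce"),
            "replicate": df[cols["replicate"]],
            "count": pd.to_numeric(df[cols["count"]], errors="coerce"),
        }
    )
    if "split_factor" in cols:
        out["split_factor"] = pd.to_numeric(df[cols["split_factor"]], errors="coerce")
    if out["day"].isna().any() or out["count"].isna().any():
        raise ValueError(f"count series {path} contains non-numeric day/count values")
    if (out["day"] < 0).any():
        raise ValueError("count series contains negative days")
    if (out["count"] <= 0).any():
        raise ValueError("count series contains non-positive counts")
    if len(out) == 0:
        raise ValueError("count series is empty")
    out.attrs["condition"] = condition
    return out


def write_counts(series: pd.DataFrame, path) -> None:
    series.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result reports
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(results: dict, path) -> None:
    """Write an analysis report as JSON plus a flat TSV next to it.

    ``results`` is a plain dict (rates, prognosis points, ...); the JSON
    round-trips exactly, the TSV flattens scalars and per-point rows for
    spreadsheet use.
    """
    path = Path(path)
    payload = _jsonable(results)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    def _flat(prefix, obj, rows):
        if isinstance(obj, dict):
            for k, v in obj.items():
                _flat(f"{prefix}.{k}" if prefix else str(k), v, rows)
        elif isinstance(obj, list):
            rows.append((prefix, "\t".join(str(v) for v in obj)))
        else:
            rows.append((prefix, str(obj)))

    rows: list[tuple[str, str]] = []
    _flat("", payload, rows)
    with open(path.with_suffix(".tsv"), "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in rows:
            fh.write(f"{k}\t{v}\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
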