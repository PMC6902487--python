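"""Reading and writing cytometry event data and result artifacts.

Supports FCS 3.0/3.1 list-mode files (integer, float and double data, both
byte orders) and delimited text tables with a header row. Result artifacts
are plain text: a tab-separated counts table, a per-event label CSV and the
mixture-model JSON from :mod:`cytogate.core`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EventTable

__all__ = [
    "CountsReport",
    "read_events",
    "read_fcs",
    "write_fcs",
    "write_counts",
    "read_counts",
    "write_labels",
    "read_labels",
]

#: event_assignment sentinel codes (cluster indices are >= 0)
BACKGROUND = -1
OUTLIER = -2

_LABEL_NAMES = {BACKGROUND: "background", OUTLIER: "outlier"}


@dataclass
class CountsReport:
    """Per-cluster cell counts plus off-gate and outlier totals.

    ``per_cluster`` maps foreground cluster id -> event count; abundances
    are percentages of ``total``. Conservation holds exactly:
    sum(per_cluster) + offgate + outlier == total.
    """

    per_cluster: dict[int, int]
    offgate_count: int
    outlier_count: int
    total: int
    abundances: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.abundances:
            self.abundances = {
                k: (100.0 * v / self.total if self.total else 0.0)
                for k, v in self.per_cluster.items()
            }
        got = sum(self.per_cluster.values()) + self.offgate_count + self.outlier_count
        if got != self.total:
            raise ValueError(
                f"count conservation violated: {got} != total {self.total}"
            )


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 list mode
# ---------------------------------------------------------------------------

_DTYPES = {
    ("I", 16): "u2",
    ("I", 32): "u4",
    ("F", 32): "f4",
    ("D", 64): "f8",
}


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    # a doubled delimiter escapes a literal delimiter inside a value
    parts = raw.decode("latin-1").strip(delim).split(delim)
    keywords: dict[str, str] = {}
    for key, value in zip(parts[::2], parts[1::2]):
        keywords[key.strip().upper()] = value.strip()
    return keywords


def read_fcs(path) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Parse one FCS 3.0/3.1 data set: (events matrix, channel names, keywords).

    Channel names are the short $PnN names; the long $PnS names are kept in
    the returned keyword dictionary. Log-amplified channels ($PnE with a
    non-zero first field) are decoded back to the linear scale.
    """
    with open(path, "rb") as fh:
        header = fh.read(58)
        if len(header) < 58 or not header[:3] == b"FCS":
            raise ValueError(f"{path}: not an FCS file (bad magic in HEADER segment)")
        version = header[:6].decode("ascii")
        if version not in ("FCS3.0", "FCS3.1"):
            raise ValueError(f"{path}: unsupported FCS version {version!r}")
        try:
            text_begin = int(header[10:18])
            text_end = int(header[18:26])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed HEADER segment offsets") from exc
        fh.seek(text_begin)
        keywords = _parse_text_segment(fh.read(text_end - text_begin + 1))

        try:
            n_par = int(keywords["$PAR"])
            n_tot = int(keywords["$TOT"])
            datatype = keywords["$DATATYPE"].upper()
            byteord = keywords["$BYTEORD"]
            mode = keywords["$MODE"].upper()
        except KeyError as exc:
            raise ValueError(f"{path}: TEXT segment missing keyword {exc}") from exc
        if mode != "L":
            raise ValueError(f"{path}: only list mode ($MODE/L) is supported")

        data_begin = int(keywords.get("$BEGINDATA", header[26:34]) or header[26:34])
        data_end = int(keywords.get("$ENDDATA", header[34:42]) or header[34:42])

        bits = [int(keywords[f"$P{i}B"]) for i in range(1, n_par + 1)]
        if len(set(bits)) != 1:
            raise ValueError(f"{path}: mixed per-parameter bit widths unsupported")
        key = (datatype, bits[0])
        if key not in _DTYPES:
            raise ValueError(
                f"{path}: unsupported $DATATYPE/$PnB combination {key}"
            )
        endian = "<" if byteord.startswith("1") else ">"
        dtype = np.dtype(endian + _DTYPES[key])

        fh.seek(data_begin)
        raw = fh.read(data_end - data_begin + 1)

    count = n_tot * n_par
    data = np.frombuffer(raw[: count * dtype.itemsize], dtype=dtype)
    values = data.reshape(n_tot, n_par).astype(np.float64)

    names = []
    for i in range(1, n_par + 1):
        names.append(keywords.get(f"$P{i}N", f"P{i}"))
        # decode log amplification to the linear scale when declared
        pne = keywords.get(f"$P{i}E", "0,0").split(",")
        decades, offset = float(pne[0]), float(pne[1])
        if decades > 0:
            offset = offset if offset > 0 else 1.0
            pnr = float(keywords.get(f"$P{i}R", 65536))
            values[:, i - 1] = offset * 10.0 ** (decades * values[:, i - 1] / pnr)
    return values, names, keywords


def write_fcs(path, values: np.ndarray, channel_names, datatype: str = "D") -> None:
    """Write a minimal FCS 3.1 list-mode file (linear scale, little endian).

    ``datatype`` is "D" (float64, exact round trip — the default), "F"
    (float32) or "I" (uint32). Values are stored untransformed; $PnE is
    written as 0,0 (linear).
    """
    values = np.asarray(values, dtype=np.float64)
    n_tot, n_par = values.shape
    if datatype == "I":
        arr = np.round(values).astype("<u4")
        bits = 32
    elif datatype == "F":
        arr = values.astype("<f4")
        bits = 32
    elif datatype == "D":
        arr = values.astype("<f8")
        bits = 64
    else:
        raise ValueError(f"unsupported datatype {datatype!r}")

    data_bytes = arr.tobytes()
    kv = {
        "$MODE": "L",
        "$DATATYPE": datatype,
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(channel_names, start=1):
        kv[f"$P{i}N"] = str(name)
        kv[f"$P{i}B"] = str(bits)
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = "65536"

    # the TEXT segment contains the data offsets, whose digit count feeds
    # back into the segment length; iterate until the offsets are stable
    header_len = 58
    kv["$BEGINDATA"] = "0"
    kv["$ENDDATA"] = "0"
    for _ in range(5):
        text = "/" + "/".join(f"{k}/{v}" for k, v in kv.items()) + "/"
        text_begin = header_len
        text_end = text_begin + len(text) - 1
        data_begin = text_end + 1
        data_end = data_begin + len(data_bytes) - 1
        if kv["$BEGINDATA"] == str(data_begin) and kv["$ENDDATA"] == str(data_end):
            break
        kv["$BEGINDATA"] = str(data_begin)
        kv["$ENDDATA"] = str(data_end)
    else:
        raise RuntimeError("FCS offset computation did not stabilize")

    header = (
        f"FCS3.1    "
        f"{text_begin:>8d}{text_end:>8d}{data_begin:>8d}{data_end:>8d}"
        f"{0:>8d}{0:>8d}"
    ).encode("ascii")
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("latin-1"))
        fh.write(data_bytes)


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------


def read_events(path, channels: tuple[str, str]) -> EventTable:
    """Read the two named channels from an FCS or delimited-text event file.

    Channel matching is case-insensitive and, for FCS, covers both the
    short $PnN and long $PnS names. Values are returned on the instrument's
    linear scale, in original event order.
    """
    path = os.fspath(path)
    with open(path, "rb") as fh:
        magic = fh.read(3)
    if magic == b"FCS":
        values, names, keywords = read_fcs(path)
        aliases: dict[str, int] = {}
        for i, name in enumerate(names):
            aliases[name.lower()] = i
            long_name = keywords.get(f"$P{i + 1}S")
            if long_name:
                aliases.setdefault(long_name.lower(), i)
        cols = []
        for ch in channels:
            if ch.lower() not in aliases:
                raise KeyError(
                    f"channel {ch!r} not in {path}; available channels: "
                    f"{sorted(set(names))}"
                )
            cols.append(aliases[ch.lower()])
        return EventTable(values[:, cols], (channels[0], channels[1]), source=path)

    # delimited text with a header row; sniff the separator from the header
    try:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ";" if ";" in header else ","
        # round_trip parsing keeps write->read bit-exact for doubles
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"{path}: failed to parse as delimited text: {exc}") from exc
    lower = {c.lower(): c for c in df.columns}
    cols = []
    for ch in channels:
        if ch.lower() not in lower:
            raise KeyError(
                f"channel {ch!r} not in {path}; available channels: "
                f"{sorted(df.columns.astype(str))}"
            )
        cols.append(lower[ch.lower()])
    return EventTable(
        df[cols].to_numpy(dtype=np.float64), (channels[0], channels[1]), source=path
    )


def write_events_csv(path, events: EventTable) -> None:
    pd.DataFrame(events.values, columns=list(events.channel_names)).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Counts and labels
# ---------------------------------------------------------------------------


def write_counts(report: CountsReport, path) -> None:
    """Write the counts report as a tab-separated UTF-8 text table."""
    lines = ["cluster\tcount\tabundance_pct"]
    for cid in sorted(report.per_cluster):
        lines.append(
            f"{cid}\t{report.per_cluster[cid]}\t{report.abundances[cid]:.6f}"
        )
    lines.append(f"offgate\t{report.offgate_count}\t")
    lines.append(f"outlier\t{report.outlier_count}\t")
    lines.append(f"total\t{report.total}\t")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_counts(path) -> CountsReport:
    per_cluster: dict[int, int] = {}
    specials = {}
    with open(path, "r", encoding="utf-8") as fh:
        next(fh)  # header
        for line in fh:
            name, count, _ = line.rstrip("\n").split("\t")
            if name in ("offgate", "outlier", "total"):
                specials[name] = int(count)
            else:
                per_cluster[int(name)] = int(count)
    return CountsReport(
        per_cluster=per_cluster,
        offgate_count=specials["offgate"],
        outlier_count=specials["outlier"],
        total=specials["total"],
    )


def write_labels(path, assignment: np.ndarray) -> None:
    """Per-event label CSV: event index, cluster id or background/outlier."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("event,label\n")
        for i, a in enumerate(np.asarray(assignment, dtype=int)):
            fh.write(f"{i},{_LABEL_NAMES.get(int(a), str(int(a)))}\n")


def read_labels(path) -> np.ndarray:
    rev = {v: k for k, v in _LABEL_NAMES.items()}
    df = pd.read_csv(path)
    return np.array(
        [rev.get(str(v), None) if str(v) in rev else int(v) for v in df["label"]],
        dtype=int,
    )
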