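"""Event-table data model, panel specification, transforms and the FSC ratio.

Cytometry events are held as a dense events x channels matrix together with
per-channel roles (marker / scatter / derived) and per-event metadata.  The
forward-scatter ratio FSC-A / FSC-H — the core multiplet-indicative feature,
since pulse area grows faster than peak height when several cells pass the
laser as one event — is derived here and rescaled into the span of the
transformed marker intensities so it is commensurate with them in PCA.

A minimal FCS 3.0/3.1 list-mode reader/writer (float data types only) is
included alongside CSV support for channel-value exports.
"""

from __future__ import annotations

import configparser
import struct
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "PanelSpec",
    "load_events",
    "transform_intensities",
    "compute_fsc_ratio",
    "read_fcs",
    "write_fcs",
    "infer_channel_roles",
]

SCATTER_ROLE_BY_SUFFIX = {"-A": "scatter_area", "-H": "scatter_height", "-W": "scatter_width"}

FSC_A = "FSC-A"
FSC_H = "FSC-H"
RATIO_RAW = "fsc_ratio_raw"
RATIO_SCALED = "fsc_ratio_scaled"


class PanelError(ValueError):
    """Configuration problem in a panel specification."""


@dataclass
class PanelSpec:
    """Panel description: channel->marker map, cell-type definitions,
    mutual-exclusivity groups and per-channel transforms.

    ``celltype_markers`` maps a cell-type name to the full marker combination
    that defines it (e.g. ``{"CD4 T": {"CD3", "CD4"}}``); ``marker_to_celltype``
    is the inverse view required by the data model (a marker may define several
    nested types).  ``exclusivity_groups`` are sets of lineage markers that no
    single cell co-expresses; simultaneous enrichment of markers from one group
    inside an interacting cluster is the evidence for a heterotypic pair.
    """

    channel_to_marker: dict[str, str]
    celltype_markers: dict[str, set[str]]
    exclusivity_groups: list[set[str]] = field(default_factory=list)
    transforms: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        markers = set(self.channel_to_marker.values())
        for group in self.exclusivity_groups:
            missing = set(group) - markers
            if missing:
                raise PanelError(f"exclusivity group references unknown markers: {sorted(missing)}")
        for ct, mset in self.celltype_markers.items():
            missing = set(mset) - markers
            if missing:
                raise PanelError(f"cell type {ct!r} references unknown markers: {sorted(missing)}")
            for group in self.exclusivity_groups:
                overlap = set(mset) & set(group)
                if len(overlap) > 1:
                    raise PanelError(
                        f"cell type {ct!r} requires {sorted(overlap)} which are mutually exclusive"
                    )

    @property
    def marker_to_celltype(self) -> dict[str, list[str]]:
        inv: dict[str, list[str]] = {}
        for ct, mset in self.celltype_markers.items():
            for m in mset:
                inv.setdefault(m, []).append(ct)
        return inv

    @property
    def marker_channels(self) -> list[str]:
        return list(self.channel_to_marker)

    @classmethod
    def from_file(cls, path) -> "PanelSpec":
        """Read a plain-text key-value panel configuration.

        Sections: ``[channels]`` channel = marker; ``[celltypes]``
        name = comma-separated markers; ``[exclusivity]`` group = markers;
        ``[transforms]`` marker = arcsinh:<cofactor> | logicle[:T,W,M,A] | none.
        """
        cp = configparser.ConfigParser()
        cp.optionxform = str  # channel names are case sensitive
        read = cp.read(path)
        if not read:
            raise OSError(f"cannot read panel file: {path}")
        channels = dict(cp["channels"]) if "channels" in cp else {}
        celltypes = {
            name: {m.strip() for m in val.split(",") if m.strip()}
            for name, val in (cp["celltypes"].items() if "celltypes" in cp else [])
        }
        groups = [
            {m.strip() for m in val.split(",") if m.strip()}
            for _, val in (cp["exclusivity"].items() if "exclusivity" in cp else [])
        ]
        transforms = {}
        if "transforms" in cp:
            for marker, val in cp["transforms"].items():
                parts = val.split(":")
                kind = parts[0].strip()
                if kind == "arcsinh":
                    transforms[marker] = ("arcsinh", float(parts[1]))
                elif kind == "logicle":
                    params = [float(x) for x in parts[1].split(",")] if len(parts) > 1 else []
                    transforms[marker] = ("logicle", *params)
                elif kind == "none":
                    transforms[marker] = ("none",)
                else:
                    raise PanelError(f"unknown transform {val!r} for marker {marker!r}")
        return cls(channels, celltypes, groups, transforms)


@dataclass
class EventTable:
    """Dense events x channels matrix with channel roles and event metadata.

    ``meta`` carries per-event categorical metadata (sample_id, condition,
    timepoint, truth_label when available) aligned row-wise with ``values``.
    """

    values: np.ndarray
    channel_names: list[str]
    channel_roles: dict[str, str]
    meta: pd.DataFrame = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channel_names):
            raise ValueError("values must be 2-D with one column per channel name")
        if np.isnan(self.values).any():
            raise ValueError("EventTable must not contain NaN after loading")
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.RangeIndex(self.values.shape[0]))
        else:
            self.meta = self.meta.reset_index(drop=True)
            if len(self.meta) != self.values.shape[0]:
                raise ValueError("meta must have one row per event")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_names.index(name)]

    def channels_by_role(self, *roles: str) -> list[str]:
        return [c for c in self.channel_names if self.channel_roles.get(c) in roles]

    def matrix(self, channels: list[str]) -> np.ndarray:
        idx = [self.channel_names.index(c) for c in channels]
        return self.values[:, idx]

    def with_channel(self, name: str, values: np.ndarray, role: str = "derived") -> "EventTable":
        if name in self.channel_names:
            raise ValueError(f"channel {name!r} already present")
        vals = np.column_stack([self.values, np.asarray(values, dtype=float)])
        roles = dict(self.channel_roles)
        roles[name] = role
        return EventTable(vals, self.channel_names + [name], roles, self.meta.copy(), self.n_dropped)

    def subset(self, index) -> "EventTable":
        index = np.asarray(index)
        return EventTable(
            self.values[index],
            list(self.channel_names),
            dict(self.channel_roles),
            self.meta.iloc[index].reset_index(drop=True),
            self.n_dropped,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channel_names)
        for col in self.meta.columns:
            df[col] = self.meta[col].to_numpy()
        return df


def infer_channel_roles(channel_names, panel: PanelSpec | None = None) -> dict[str, str]:
    """Assign roles by name: FSC/SSC suffixes -> scatter, panel channels -> marker."""
    marker_channels = set(panel.channel_to_marker) if panel is not None else set()
    roles = {}
    for name in channel_names:
        if name in marker_channels:
            roles[name] = "marker"
        elif name.startswith(("FSC", "SSC")) and name[-2:] in SCATTER_ROLE_BY_SUFFIX:
            roles[name] = SCATTER_ROLE_BY_SUFFIX[name[-2:]]
        elif name in (RATIO_RAW, RATIO_SCALED):
            roles[name] = "derived"
        else:
            roles[name] = "housekeeping"
    return roles


METADATA_COLUMNS = ("sample_id", "condition", "timepoint", "truth_label")


def load_events(path, panel: PanelSpec, format: str = "csv") -> EventTable:
    """Load a cytometry event table from a CSV channel-value export or FCS file.

    Transforms are *not* applied here.  Rows with non-numeric or missing
    channel values are dropped and counted in ``EventTable.n_dropped``.
    Raises ``PanelError`` if the FSC-A/FSC-H scatter channels are absent.
    """
    if format == "csv":
        try:
            df = pd.read_csv(path)
        except OSError as exc:
            raise OSError(f"cannot read event file: {path}") from exc
        meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
        meta = df[meta_cols].copy() if meta_cols else None
        data = df.drop(columns=meta_cols)
        values = data.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        keep = ~np.isnan(values).any(axis=1)
        n_dropped = int((~keep).sum())
        channel_names = list(data.columns)
        values = values[keep]
        if meta is not None:
            meta = meta.loc[keep].reset_index(drop=True)
    elif format == "fcs":
        values, channel_names = read_fcs(path)
        keep = ~np.isnan(values).any(axis=1)
        n_dropped = int((~keep).sum())
        values = values[keep]
        meta = None
    else:
        raise ValueError(f"unknown format {format!r}")

    for required in (FSC_A, FSC_H):
        if required not in channel_names:
            raise PanelError(f"required scatter channel {required!r} missing from {path}")
    roles = infer_channel_roles(channel_names, panel)
    return EventTable(values, channel_names, roles, meta, n_dropped)


def _arcsinh(x: np.ndarray, cofactor: float) -> np.ndarray:
    if cofactor <= 0:
        raise ValueError(f"arcsinh cofactor must be positive, got {cofactor}")
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


def _logicle(x: np.ndarray, T: float = 262144.0, W: float = 0.5, M: float = 4.5, A: float = 0.0) -> np.ndarray:
    """Logicle transform (biexponential with a linearized region around zero).

    The forward map is obtained by numerically inverting the closed-form
    biexponential B(y) with a vectorized bisection; output is on the display
    scale [0, M] (decades), monotone in the input.
    """
    if T <= 0 or M <= 0 or W < 0 or W >= M / 2:
        raise ValueError("invalid logicle parameters")
    b = (M + A) * np.log(10.0)
    # w parameter and d from the defining transcendental relation
    w = W / (M + A)
    x2 = A / (M + A)
    x1 = x2 + w
    x0 = x2 + 2 * w
    # solve d: w = (b - d) / (b * d) * ... use standard relation 2*(ln d - ln b) + w*(b + d) = 0
    from scipy.optimize import brentq

    if w == 0:
        d = b
    else:
        d = brentq(lambda dd: 2 * (np.log(dd) - np.log(b)) + w * (b + dd), 1e-12, b)
    c_a = np.exp(x0 * (b + d))
    mf_a = np.exp(b * x1) - c_a / np.exp(d * x1)
    a_coef = T / (np.exp(b) - mf_a - c_a / np.exp(d))

    def biex(y):
        return a_coef * (np.exp(b * y) - mf_a - c_a / np.exp(d * y))

    x = np.asarray(x, dtype=float)
    lo_b, hi_b = -1.0, 2.0
    for _ in range(200):  # expand the bracket until it covers the data
        if biex(lo_b) < x.min():
            break
        lo_b -= 1.0
    for _ in range(200):
        if biex(hi_b) > x.max():
            break
        hi_b += 1.0
    lo = np.full(x.shape, lo_b)
    hi = np.full(x.shape, hi_b)
    for _ in range(100):  # bisection; monotone biexponential, so order-safe
        mid = 0.5 * (lo + hi)
        below = biex(mid) < x
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi) * M


def transform_intensities(events: EventTable, panel: PanelSpec) -> EventTable:
    """Apply per-marker variance-stabilizing transforms to marker channels.

    Scatter channels are never transformed.  Each marker channel must have a
    transform spec (``("arcsinh", cofactor)``, ``("logicle", ...)`` or
    ``("none",)``); transforms are strictly monotone in the raw input.
    """
    values = events.values.copy()
    for channel, marker in panel.channel_to_marker.items():
        if channel not in events.channel_names:
            continue
        spec = panel.transforms.get(marker, panel.transforms.get(channel))
        if spec is None:
            raise PanelError(f"no transform defined for marker {marker!r}")
        j = events.channel_names.index(channel)
        kind = spec[0]
        if kind == "arcsinh":
            values[:, j] = _arcsinh(values[:, j], spec[1])
        elif kind == "logicle":
            values[:, j] = _logicle(values[:, j], *spec[1:])
        elif kind == "none":
            pass
        else:
            raise PanelError(f"unknown transform kind {kind!r}")
    return EventTable(values, list(events.channel_names), dict(events.channel_roles),
                      events.meta.copy(), events.n_dropped)


def compute_fsc_ratio(events: EventTable, scaling: str = "minmax_to_marker_range") -> EventTable:
    """Derive the FSC ratio (FSC-A / FSC-H) and a scaled copy of it.

    Events with FSC-H <= 0 (electronic artifacts for which the ratio is
    undefined) are excluded; the exclusion count is added to ``n_dropped``.
    Scaling maps the ratio into the span of the transformed marker values so
    it carries comparable weight as a clustering feature:

    - ``minmax_to_marker_range``: linear map of the ratio's robust range
      (0.1/99.9 percentiles) onto the pooled marker channels' robust range;
    - ``quantile``: monotone interpolation of the ratio's ECDF onto pooled
      marker quantiles;
    - ``none``: scaled copy equals the raw ratio.

    Both maps are strictly increasing, so the event ordering by raw ratio is
    preserved exactly.
    """
    for required in (FSC_A, FSC_H):
        if required not in events.channel_names:
            raise PanelError(f"channel {required!r} required for FSC ratio")
    fsc_a = events.channel(FSC_A)
    fsc_h = events.channel(FSC_H)
    keep = fsc_h > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        events = events.subset(np.flatnonzero(keep))
        fsc_a, fsc_h = fsc_a[keep], fsc_h[keep]
    ratio = fsc_a / fsc_h

    marker_channels = events.channels_by_role("marker")
    if scaling == "none" or not marker_channels:
        scaled = ratio.copy()
    else:
        pooled = events.matrix(marker_channels).ravel()
        m_lo, m_hi = np.percentile(pooled, [0.1, 99.9])
        if scaling == "minmax_to_marker_range":
            r_lo, r_hi = np.percentile(ratio, [0.1, 99.9])
            if r_hi <= r_lo:
                raise ValueError("degenerate FSC-ratio distribution, cannot scale")
            scaled = m_lo + (ratio - r_lo) * (m_hi - m_lo) / (r_hi - r_lo)
        elif scaling == "quantile":
            order = np.argsort(ratio, kind="stable")
            ranks = np.empty_like(order, dtype=float)
            # average ranks normalized to (0, 1); strictly monotone via
            # stable-rank interpolation then tie-free by adding rank epsilon
            ranks[order] = np.arange(ratio.size, dtype=float)
            q = (ranks + 0.5) / ratio.size
            scaled = np.quantile(pooled, np.clip(q, 0.0, 1.0))
        else:
            raise ValueError(f"unknown scaling {scaling!r}")

    out = events.with_channel(RATIO_RAW, ratio).with_channel(RATIO_SCALED, scaled)
    out.n_dropped += n_excluded
    return out


# --------------------------------------------------------------------------
# Minimal FCS 3.0/3.1 list-mode support (float data)

def write_fcs(path, values: np.ndarray, channel_names: list[str]) -> None:
    """Write a minimal FCS 3.1 file (list mode, 32-bit float, little endian)."""
    values = np.asarray(values, dtype="<f4")
    n_events, n_par = values.shape
    text_keys = {
        "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_events), "$NEXTDATA": "0",
    }
    for i, name in enumerate(channel_names, start=1):
        text_keys[f"$P{i}N"] = name
        text_keys[f"$P{i}B"] = "32"
        text_keys[f"$P{i}E"] = "0,0"
        text_keys[f"$P{i}R"] = str(int(max(1.0, np.ceil(values[:, i - 1].max(initial=1.0)))))

    delim = "/"
    data_size = values.nbytes

    def render_text(begin_data, end_data):
        keys = dict(text_keys)
        keys["$BEGINDATA"] = str(begin_data)
        keys["$ENDDATA"] = str(end_data)
        body = delim + delim.join(f"{k}{delim}{v}" for k, v in keys.items()) + delim
        return body.encode("ascii")

    header_len = 58
    text_start = header_len
    # iterate since BEGINDATA/ENDDATA digits feed back into the text length
    begin_data = 0
    for _ in range(5):
        text = render_text(begin_data, begin_data + data_size - 1 if data_size else 0)
        new_begin = text_start + len(text)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    end_data = begin_data + data_size - 1 if data_size else 0
    text = render_text(begin_data, end_data)
    text_end = text_start + len(text) - 1

    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{begin_data if begin_data <= 99999999 else 0:>8d}".encode()
        + f"{end_data if end_data <= 99999999 else 0:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(values.tobytes())


def read_fcs(path):
    """Read a list-mode FCS 3.0/3.1 file with float ($DATATYPE F/D) data.

    Returns ``(values, channel_names)``.  Integer data types, multiple data
    segments and analysis segments are out of scope.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise OSError(f"not an FCS 3.0/3.1 file: {path}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start:text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    parts = text[1:].split(delim)
    kv = {parts[i].strip(): parts[i + 1] for i in range(0, len(parts) - 1, 2)}

    n_par = int(kv["$PAR"])
    n_tot = int(kv["$TOT"])
    begin_data = int(kv.get("$BEGINDATA", raw[26:34] or 0))
    if begin_data == 0:
        begin_data = int(raw[26:34])
    datatype = kv.get("$DATATYPE", "F")
    if datatype not in ("F", "D"):
        raise OSError(f"unsupported FCS $DATATYPE {datatype!r} (only float data supported)")
    byteord = kv.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if datatype == "F" else 8
    dtype = np.dtype(f"{endian}f{itemsize}")
    n_values = n_par * n_tot
    data = np.frombuffer(raw, dtype=dtype, count=n_values, offset=begin_data)
    values = data.reshape(n_tot, n_par).astype(float)
    channel_names = [kv.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return values, channel_names
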