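"""Reading and writing of every external format the pipeline touches.

Covers ABIF (AB1) Sanger trace files, FASTA references, delimited
four-channel peak-area tables, Bioanalyzer band-quantity tables,
calibration series and the tab-separated results produced by the
significance caller.  ABIF files are parsed through Biopython's
``SeqIO`` "abi" reader; a minimal ABIF *writer* is provided so the
synthetic generator can emit files any trace viewer (or this package)
can re-read.
"""

from __future__ import annotations

import csv
import io
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Chromatogram",
    "BandTable",
    "FormatError",
    "ContentError",
    "SchemaError",
    "read_ab1",
    "write_ab1",
    "read_reference",
    "read_peak_table",
    "write_peak_table",
    "read_band_tables",
    "read_calibration_csv",
    "write_results",
    "read_results",
    "read_workbook_peak_table",
]

BASES = ("A", "C", "G", "T")

#: IUPAC nucleotide ambiguity codes mapped to the base sets they denote.
IUPAC_SETS: Mapping[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


class FormatError(ValueError):
    """The file is not in the expected container format."""


class ContentError(ValueError):
    """The container parsed but a required record is missing or invalid."""


class SchemaError(ValueError):
    """A delimited table lacks a required column."""


@dataclass
class Chromatogram:
    """A four-channel Sanger trace with basecalls and called-peak positions.

    ``traces`` is a dict keyed by base letter; every array has identical
    length.  ``peak_locations`` holds, per basecall, the 0-based index of
    the called peak centre in the trace arrays, strictly increasing.
    """

    sample_id: str
    traces: dict
    basecalls: str
    peak_locations: np.ndarray
    quality: np.ndarray | None = None
    channel_order: str = "ACGT"

    def __post_init__(self):
        self.peak_locations = np.asarray(self.peak_locations, dtype=int)
        lengths = {len(self.traces[b]) for b in BASES}
        if len(lengths) != 1:
            raise ContentError("trace channels have unequal lengths")
        n = lengths.pop()
        if len(self.basecalls) != len(self.peak_locations):
            raise ContentError(
                f"{len(self.basecalls)} basecalls but "
                f"{len(self.peak_locations)} peak locations"
            )
        if len(self.peak_locations):
            if np.any(np.diff(self.peak_locations) <= 0):
                raise ContentError("peak locations are not strictly increasing")
            if self.peak_locations[0] < 0 or self.peak_locations[-1] >= n:
                raise ContentError("peak locations fall outside the trace")
        for b in BASES:
            self.traces[b] = np.asarray(self.traces[b], dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.traces["A"])

    def __len__(self) -> int:
        return len(self.basecalls)


@dataclass
class BandTable:
    """Per-lane electrophoresis band quantities (e.g. a Bioanalyzer export).

    ``bands`` is a list of ``(length_nt, quantity)`` pairs; ``unit`` is
    ``"molarity"`` or ``"mass"``.  Mass quantities are converted to a
    molar scale (mass / length) wherever molar amounts are required,
    since shorter cleavage fragments carry less mass per molecule.
    """

    lane_id: str
    treatment: str  # "digested" | "undigested"
    bands: list = field(default_factory=list)
    unit: str = "molarity"

    def __post_init__(self):
        if self.treatment not in ("digested", "undigested"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.unit not in ("molarity", "mass"):
            raise ValueError(f"unknown unit {self.unit!r}")
        for length, qty in self.bands:
            if length <= 0:
                raise ValueError(f"non-positive band length {length}")
            if qty < 0:
                raise ValueError(f"negative band quantity {qty}")

    def molar_bands(self) -> list:
        """Bands on a molar scale regardless of the stored unit."""
        if self.unit == "molarity":
            return list(self.bands)
        return [(length, qty / length) for length, qty in self.bands]


# --------------------------------------------------------------------------
# ABIF (AB1)

_HEADFMT = ">H4sI2H3I"   # after the 4-byte "ABIF" marker
_DIRFMT = ">4sI2H4I"     # 28-byte directory entry

# channel-order record -> analyzed data records, in file storage order
_ANALYZED_DATA_TAGS = ("DATA9", "DATA10", "DATA11", "DATA12")


def read_ab1(path) -> Chromatogram:
    """Read an AB1 file into a :class:`Chromatogram`.

    Uses the *analyzed* trace records (DATA9-12), mapping them to bases
    via the file's filter-wheel order record (FWO_1), and the basecaller's
    sequence (PBAS2/1) and peak locations (PLOC2/1).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic != b"ABIF":
        raise FormatError(f"{path}: not an ABIF file (bad magic {magic!r})")
    record = SeqIO.read(str(path), "abi")
    raw = record.annotations["abif_raw"]

    def pick(*keys):
        for k in keys:
            if k in raw:
                return raw[k]
        raise ContentError(f"{path}: missing required ABIF record {keys[0]}")

    order_rec = pick("FWO_1")
    order = order_rec.decode() if isinstance(order_rec, bytes) else str(order_rec)
    if sorted(order) != sorted(BASES):
        raise ContentError(f"{path}: channel order record {order!r} is not a permutation of ACGT")

    traces = {}
    for base, tag in zip(order, _ANALYZED_DATA_TAGS):
        traces[base] = np.asarray(pick(tag), dtype=float)

    basecalls = pick("PBAS2", "PBAS1")
    if isinstance(basecalls, bytes):
        basecalls = basecalls.decode()
    peaks = np.asarray(pick("PLOC2", "PLOC1"), dtype=int)

    quality = None
    if record.letter_annotations.get("phred_quality"):
        quality = np.asarray(record.letter_annotations["phred_quality"], dtype=int)

    return Chromatogram(
        sample_id=str(record.id) if record.id else path.stem,
        traces=traces,
        basecalls=basecalls,
        peak_locations=peaks,
        quality=quality,
        channel_order=order,
    )


def _pack_dir_entry(name: bytes, number: int, elem_type: int, elem_size: int,
                    elem_num: int, data: bytes, data_offset: int):
    """One 28-byte ABIF directory entry; data <= 4 bytes is stored inline."""
    size = len(data)
    if size <= 4:
        offset_field = int.from_bytes(data.ljust(4, b"\0"), "big")
        return struct.pack(_DIRFMT, name, number, elem_type, elem_size,
                           elem_num, size, offset_field, 0), None
    return struct.pack(_DIRFMT, name, number, elem_type, elem_size,
                       elem_num, size, data_offset, 0), data


def write_ab1(chrom: Chromatogram, path) -> None:
    """Write a minimal but standard-conforming AB1 file.

    Emits analyzed trace records (DATA9-12, 16-bit), the channel order
    (FWO_1), basecalls (PBAS1/2), peak locations (PLOC1/2), qualities
    (PCON1/2, when present) and the sample id (SMPL1).  Round-trips
    through :func:`read_ab1`.
    """
    entries = []
    order = chrom.channel_order
    for tag_idx, base in enumerate(order):
        arr = np.clip(np.round(chrom.traces[base]), 0, 32767).astype(">i2")
        entries.append((b"DATA", 9 + tag_idx, 4, 2, len(arr), arr.tobytes()))
    entries.append((b"FWO_", 1, 2, 1, 4, order.encode()))
    seq = chrom.basecalls.encode()
    peaks = np.asarray(chrom.peak_locations, dtype=">i2").tobytes()
    for number in (1, 2):
        entries.append((b"PBAS", number, 2, 1, len(seq), seq))
        entries.append((b"PLOC", number, 4, 2, len(chrom.peak_locations), peaks))
        if chrom.quality is not None:
            qual = bytes(int(q) & 0xFF for q in chrom.quality)
            entries.append((b"PCON", number, 2, 1, len(qual), qual))
    sid = chrom.sample_id.encode()[:255]
    entries.append((b"SMPL", 1, 18, 1, len(sid) + 1, bytes([len(sid)]) + sid))

    header_size = 4 + struct.calcsize(_HEADFMT) + 2 * 47  # pad like real files
    blobs = []
    offset = header_size
    dir_entries = []
    for name, number, etype, esize, enum, data in entries:
        packed, blob = _pack_dir_entry(name, number, etype, esize, enum, data, offset)
        dir_entries.append(packed)
        if blob is not None:
            blobs.append(blob)
            offset += len(blob)
    dir_offset = offset
    header = b"ABIF" + struct.pack(
        _HEADFMT, 101, b"tdir", 1, 1023, 28, len(dir_entries),
        28 * len(dir_entries), dir_offset,
    )
    with open(path, "wb") as fh:
        fh.write(header.ljust(header_size, b"\0"))
        for blob in blobs:
            fh.write(blob)
        for packed in dir_entries:
            fh.write(packed)


# --------------------------------------------------------------------------
# FASTA reference

def read_reference(path, record_id: str | None = None):
    """Return ``(id, sequence)`` for a FASTA reference amplicon.

    The first record is used unless ``record_id`` selects another one.
    The sequence is uppercased; letters must be IUPAC DNA codes.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    if record_id is None:
        rec = records[0]
    else:
        hits = [r for r in records if r.id == record_id]
        if not hits:
            raise ContentError(f"{path}: no record with id {record_id!r}")
        if len(hits) > 1:
            raise ContentError(f"{path}: duplicate record id {record_id!r}")
        rec = hits[0]
    seq = str(rec.seq).upper()
    bad = set(seq) - set(IUPAC_SETS)
    if bad:
        raise ContentError(f"{path}: non-IUPAC letters {sorted(bad)} in reference")
    return rec.id, seq


# --------------------------------------------------------------------------
# Peak-area tables

_PEAK_COLUMNS = ["position", "base", "area_A", "area_C", "area_G", "area_T"]


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_peak_table(path) -> pd.DataFrame:
    """Read a delimited per-base four-channel peak-area table.

    Required columns: position (1-based, strictly increasing), base,
    area_A, area_C, area_G, area_T.  Delimiter is auto-detected among
    comma, tab and semicolon.
    """
    text = Path(path).read_text()
    delim = _sniff_delimiter(text[:4096])
    df = pd.read_csv(io.StringIO(text), sep=delim)
    missing = [c for c in _PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    df = df[_PEAK_COLUMNS + [c for c in df.columns if c not in _PEAK_COLUMNS]]
    for col in ("area_A", "area_C", "area_G", "area_T"):
        neg = df.index[df[col] < 0]
        if len(neg):
            raise ValueError(f"{path}: negative {col} at row {neg[0] + 2}")
    pos = df["position"].to_numpy()
    if np.any(np.diff(pos) <= 0):
        raise ValueError(f"{path}: positions are not strictly increasing")
    df["base"] = df["base"].astype(str).str.upper()
    return df


def write_peak_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a peak-area table with 6-significant-digit numeric fields."""
    out = df.copy()
    for col in ("area_A", "area_C", "area_G", "area_T"):
        out[col] = out[col].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep=sep, index=False)


# --------------------------------------------------------------------------
# Band-quantity tables (CAPS)

def read_band_tables(path) -> list:
    """Read a band CSV (lane_id, treatment, length_nt, quantity[, unit])
    into one :class:`BandTable` per lane."""
    df = pd.read_csv(path)
    required = ["lane_id", "treatment", "length_nt", "quantity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if "unit" not in df.columns:
        df["unit"] = "molarity"
    lanes = []
    for (lane_id, treatment), grp in df.groupby(["lane_id", "treatment"], sort=False):
        units = set(grp["unit"])
        if len(units) > 1:
            raise ValueError(f"{path}: mixed units within lane {lane_id!r}")
        lanes.append(BandTable(
            lane_id=str(lane_id),
            treatment=str(treatment),
            bands=[(float(r.length_nt), float(r.quantity)) for r in grp.itertuples()],
            unit=units.pop(),
        ))
    return lanes


def read_calibration_csv(path) -> pd.DataFrame:
    """Read a calibration series CSV (expected_fraction, measured_fraction)."""
    df = pd.read_csv(path)
    missing = [c for c in ("expected_fraction", "measured_fraction") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col in ("expected_fraction", "measured_fraction"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise ValueError(f"{path}: {col} outside [0, 1]")
    return df


# --------------------------------------------------------------------------
# Results TSV

_RESULT_FIXED = [
    "position", "ref_base", "control_mean", "corrected_mean", "corrected_sd",
    "criterion1", "criterion2", "significant", "n_sample", "n_control",
]


def write_results(results: Iterable, path) -> None:
    """Write significance results as a TSV, one row per candidate site.

    Per-replicate raw editing values appear as ``raw_rep1..raw_repN``
    columns before the fixed statistics block; column order is stable.
    """
    results = list(results)
    n_rep = max((len(r.raw_values) for r in results), default=0)
    rep_cols = [f"raw_rep{i + 1}" for i in range(n_rep)]
    header = ["position", "ref_base"] + rep_cols + _RESULT_FIXED[2:]
    rows = []
    for r in results:
        raw = [f"{v:.6g}" if np.isfinite(v) else "NA" for v in r.raw_values]
        raw += ["NA"] * (n_rep - len(raw))
        rows.append(
            [str(r.position), r.ref_base] + raw + [
                f"{r.control_mean:.6g}", f"{r.corrected_mean:.6g}",
                f"{r.corrected_sd:.6g}",
                str(bool(r.criterion1)).lower(), str(bool(r.criterion2)).lower(),
                str(bool(r.significant)).lower(),
                str(r.n_sample), str(r.n_control),
            ]
        )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def read_results(path) -> pd.DataFrame:
    """Re-read a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("criterion1", "criterion2", "significant"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"true": True, "false": False})
    return df


# --------------------------------------------------------------------------
# Supplementary-workbook import

def read_workbook_peak_table(path, sheet, column_map: Mapping[str, str] | None = None,
                             header_row: int = 0) -> pd.DataFrame:
    """Import a per-position worksheet from an editing-analysis workbook.

    ``column_map`` maps this package's peak-table column names (or, for
    precomputed-ratio worksheets, ``position``/``base`` plus one
    ``editing_rep<i>`` name per replicate column) to the worksheet's own
    column headers.  Worksheets carrying raw areas yield a standard peak
    table; ratio worksheets yield a position/base/editing frame that can
    skip peak integration entirely.
    """
    raw = pd.read_excel(path, sheet_name=sheet, header=header_row, engine="openpyxl")
    if column_map is None:
        column_map = {c: c for c in _PEAK_COLUMNS if c in raw.columns}
    missing = [src for src in column_map.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"{path}[{sheet}]: missing worksheet column(s) {missing}")
    df = pd.DataFrame({ours: raw[theirs] for ours, theirs in column_map.items()})
    if "position" not in df.columns:
        raise SchemaError(f"{path}[{sheet}]: column_map must map 'position'")
    df = df.dropna(subset=["position"]).reset_index(drop=True)
    df["position"] = df["position"].astype(int)
    if "base" in df.columns:
        df["base"] = df["base"].astype(str).str.upper()
    area_cols = [c for c in df.columns if c.startswith("area_")]
    if area_cols:
        needed = {"area_A", "area_C", "area_G", "area_T"}
        if not needed.issubset(df.columns):
            raise SchemaError(
                f"{path}[{sheet}]: raw-area import needs all four area columns")
    return df
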