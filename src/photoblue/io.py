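"""File formats: spectra/curves/traces/decays as CSV, image stacks as TIFF.

All tabular interchange uses plain CSV with fixed column names; image stacks
are multi-page TIFF, frame-major with the channel pair (blue band, red band)
interleaved, 16-bit unsigned, with pixel size and saturation value recorded
in the image description as JSON.  ``validate_files`` checks any supported
file against its format invariants with line-level diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fcs.correlate import CorrelationCurve
from .spectral import EmissionSpectrum, SpectralBinning
from .synth.decays import DecayHistogram
from .synth.images import TwoChannelImage, TwoChannelImageStack
from .synth.trace import IntensityTrace

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_manifest_csv",
    "write_manifest_csv",
    "read_curve_csv",
    "write_curve_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_decay_csv",
    "write_decay_csv",
    "read_stack_tiff",
    "write_stack_tiff",
    "validate_files",
    "ValidationReport",
]


# ---------------------------------------------------------------- spectra

def write_spectrum_csv(s: EmissionSpectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": s.binning.bin_centers, "counts": s.counts}).to_csv(
        path, index=False
    )


def read_spectrum_csv(path, excitation_nm: float | None = None) -> EmissionSpectrum:
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "counts"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    centers = df["wavelength_nm"].to_numpy(dtype=float)
    width = float(np.median(np.diff(centers)))
    binning = SpectralBinning(centers, width)
    return EmissionSpectrum(binning, df["counts"].to_numpy(dtype=float), excitation_nm)


def write_manifest_csv(entries, path) -> None:
    """Manifest mapping frame index -> spectrum/decay file."""
    pd.DataFrame(entries, columns=["frame", "file"]).to_csv(path, index=False)


def read_manifest_csv(path) -> list[tuple[int, str]]:
    df = pd.read_csv(path)
    for col in ("frame", "file"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [(int(r.frame), str(r.file)) for r in df.itertuples()]


# ---------------------------------------------------------------- FCS

def write_curve_csv(curve: CorrelationCurve, path) -> None:
    data = {"lag_s": curve.lags, "G": curve.G}
    if curve.stderr is not None:
        data["stderr"] = curve.stderr
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        fh.write(f"# mean_rate_hz={curve.mean_rate!r}\n")
        df.to_csv(fh, index=False)


def _read_csv_with_meta(path) -> tuple[dict, pd.DataFrame]:
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = float(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return meta, df


def read_curve_csv(path) -> CorrelationCurve:
    meta, df = _read_csv_with_meta(path)
    for col in ("lag_s", "G"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    stderr = df["stderr"].to_numpy(dtype=float) if "stderr" in df.columns else None
    return CorrelationCurve(
        lags=df["lag_s"].to_numpy(dtype=float),
        G=df["G"].to_numpy(dtype=float),
        mean_rate=meta.get("mean_rate_hz", float("nan")),
        stderr=stderr,
    )


def write_trace_csv(trace: IntensityTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_time_s={trace.bin_time!r}\n")
        pd.DataFrame({"counts": trace.counts}).to_csv(fh, index=False)


def read_trace_csv(path) -> IntensityTrace:
    meta, df = _read_csv_with_meta(path)
    if "bin_time_s" not in meta:
        raise ValueError(f"{path}: missing '# bin_time_s=' metadata line")
    if "counts" not in df.columns:
        raise ValueError(f"{path}: missing column 'counts'")
    return IntensityTrace(df["counts"].to_numpy(dtype=np.int64), meta["bin_time_s"])


# ---------------------------------------------------------------- decays

def write_decay_csv(d: DecayHistogram, path) -> None:
    pd.DataFrame({"bin_start_ns": d.bin_edges[:-1], "counts": d.counts}).to_csv(
        path, index=False
    )


def read_decay_csv(path) -> DecayHistogram:
    df = pd.read_csv(path)
    for col in ("bin_start_ns", "counts"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    starts = df["bin_start_ns"].to_numpy(dtype=float)
    if starts.size < 2:
        raise ValueError(f"{path}: need >= 2 bins")
    width = starts[1] - starts[0]
    edges = np.append(starts, starts[-1] + width)
    return DecayHistogram(edges, df["counts"].to_numpy(dtype=np.int64))


# ---------------------------------------------------------------- TIFF stacks

def write_stack_tiff(stack: TwoChannelImageStack, path) -> None:
    """Frame-major, channel-interleaved (b, r) 16-bit multi-page TIFF."""
    pages = []
    for f in stack.frames:
        pages.append(np.clip(np.round(f.i_b), 0, 65535).astype(np.uint16))
        pages.append(np.clip(np.round(f.i_r), 0, 65535).astype(np.uint16))
    meta = {
        "saturation_value": stack.saturation_value,
        "pixel_size_nm": stack.pixel_size,
        "channels": ["b_580_630", "r_650_700"],
    }
    tifffile.imwrite(path, np.stack(pages), description=json.dumps(meta))


def read_stack_tiff(path) -> TwoChannelImageStack:
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    if pages.ndim != 3 or pages.shape[0] % 2 != 0:
        raise ValueError(f"{path}: expected an even number of 2D pages")
    sat = float(meta.get("saturation_value", 65535.0))
    px = float(meta.get("pixel_size_nm", 40.0))
    frames = tuple(
        TwoChannelImage(pages[2 * i], pages[2 * i + 1], saturation_value=sat, pixel_size=px)
        for i in range(pages.shape[0] // 2)
    )
    return TwoChannelImageStack(frames)


# ---------------------------------------------------------------- validation

@dataclass
class ValidationReport:
    """Per-file validation outcome with line-level diagnostics."""

    entries: list = field(default_factory=list)  # (path, ok, [messages])

    @property
    def ok(self) -> bool:
        return all(ok for _, ok, _ in self.entries)

    def add(self, path, ok: bool, messages) -> None:
        self.entries.append((str(path), ok, list(messages)))

    def summary(self) -> str:
        lines = []
        for path, ok, messages in self.entries:
            lines.append(f"{'PASS' if ok else 'FAIL'} {path}")
            lines.extend(f"  {m}" for m in messages)
        return "\n".join(lines)


def _validate_curve(path, messages) -> bool:
    meta, df = _read_csv_with_meta(path)
    ok = True
    for col in ("lag_s", "G"):
        if col not in df.columns:
            messages.append(f"missing column {col!r}")
            return False
    lags = df["lag_s"].to_numpy(dtype=float)
    header_lines = 1 + len(meta)  # column header + metadata lines
    for i in range(lags.size):
        if lags[i] <= 0:
            messages.append(f"line {header_lines + i + 1}: non-positive lag {lags[i]}")
            ok = False
        if i and lags[i] <= lags[i - 1]:
            messages.append(
                f"line {header_lines + i + 1}: non-monotone lag {lags[i]} <= {lags[i - 1]}"
            )
            ok = False
    if not np.all(np.isfinite(df["G"].to_numpy(dtype=float))):
        messages.append("non-finite G values")
        ok = False
    return ok


def _validate_spectrum(path, messages) -> bool:
    try:
        read_spectrum_csv(path)
    except (ValueError, KeyError) as exc:
        messages.append(str(exc))
        return False
    return True


def _validate_decay(path, messages) -> bool:
    try:
        read_decay_csv(path)
    except ValueError as exc:
        messages.append(str(exc))
        return False
    return True


def _validate_trace(path, messages) -> bool:
    try:
        read_trace_csv(path)
    except ValueError as exc:
        messages.append(str(exc))
        return False
    return True


def _validate_tiff(path, messages) -> bool:
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = [p.shape for p in tif.pages]
    except Exception as exc:  # malformed container
        messages.append(f"unreadable TIFF: {exc}")
        return False
    if len(shapes) % 2 != 0:
        messages.append(f"odd number of pages ({len(shapes)}); expected (b, r) pairs")
        return False
    ok = True
    for i in range(0, len(shapes), 2):
        if shapes[i] != shapes[i + 1]:
            messages.append(
                f"pages {i}/{i + 1}: mismatched channel shapes {shapes[i]} vs {shapes[i + 1]}"
            )
            ok = False
    return ok


def _sniff_csv_kind(path) -> str:
    _, df = _read_csv_with_meta(path)
    cols = set(df.columns)
    if {"lag_s", "G"} <= cols:
        return "curve"
    if {"wavelength_nm", "counts"} <= cols:
        return "spectrum"
    if {"bin_start_ns", "counts"} <= cols:
        return "decay"
    if cols == {"counts"}:
        return "trace"
    if {"frame", "file"} <= cols:
        return "manifest"
    return "unknown"


def validate_files(paths) -> ValidationReport:
    """Schema and invariant check of every supported file format."""
    report = ValidationReport()
    for path in paths:
        p = Path(path)
        messages: list[str] = []
        if not p.exists():
            report.add(p, False, ["file does not exist"])
            continue
        try:
            if p.suffix.lower() in (".tif", ".tiff"):
                ok = _validate_tiff(p, messages)
            elif p.suffix.lower() == ".csv":
                kind = _sniff_csv_kind(p)
                if kind == "curve":
                    ok = _validate_curve(p, messages)
                elif kind == "spectrum":
                    ok = _validate_spectrum(p, messages)
                elif kind == "decay":
                    ok = _validate_decay(p, messages)
                elif kind == "trace":
                    ok = _validate_trace(p, messages)
                elif kind == "manifest":
                    ok = True
                else:
                    messages.append("unrecognised CSV columns")
                    ok = False
            else:
                messages.append(f"unsupported file type {p.suffix!r}")
                ok = False
        except Exception as exc:
            messages.append(f"error while validating: {exc}")
            ok = False
        report.add(p, ok, messages)
    return report
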