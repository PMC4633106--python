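"""Readers and writers for the pipeline's on-disk artifacts.

Tabular artifacts (event traces, spot fits, histograms, summaries) are
CSV; images (movies, kymographs) are 32-bit float TIFF and/or plain
numeric text matrices, with an optional linearly-scaled 8-bit PNG export
for figures.  Every writer has a matching reader and round-trips values
exactly (TIFF is float32, so images round-trip at float32 precision).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .simulate import EventTrace, FrameStack
from .spots import AmplitudeHistogram, SpotFit

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_framestack_csv", "read_framestack_csv",
    "write_image_tiff", "read_image_tiff",
    "write_image_txt", "read_image_txt",
    "write_image_png",
    "write_fits_csv", "read_fits_csv",
    "write_histogram_csv", "read_histogram_csv",
    "read_kymograph_image",
]

_EVENTS = ["BIND", "ADP_RELEASE", "DETACH"]


def write_trace_csv(trace: EventTrace, path: str) -> None:
    df = pd.DataFrame({
        "time_s": trace.times,
        "side": trace.side,
        "site": trace.sites,
        "event": [_EVENTS[e] for e in trace.events],
    })
    with open(path, "w") as fh:
        fh.write(f"# n_sites={trace.n_sites} duration_s={trace.duration!r} side={trace.side}\n")
        df.to_csv(fh, index=False)


def read_trace_csv(path: str) -> EventTrace:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, float_precision="round_trip")
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
    return EventTrace(
        times=df["time_s"].to_numpy(float),
        sites=df["site"].to_numpy(np.int32),
        events=np.asarray([_EVENTS.index(e) for e in df["event"]], dtype=np.int8),
        n_sites=int(meta["n_sites"]),
        duration=float(meta["duration_s"]),
        side=meta["side"],
    )


def write_framestack_csv(stack: FrameStack, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_hz={stack.frame_rate_hz!r} rows=frames cols=sites\n")
        np.savetxt(fh, stack.weights, delimiter=",", fmt="%.17g")


def read_framestack_csv(path: str) -> FrameStack:
    with open(path) as fh:
        header = fh.readline().strip()
        weights = np.loadtxt(fh, delimiter=",", ndmin=2)
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
    return FrameStack(weights=weights, frame_rate_hz=float(meta["frame_rate_hz"]))


def write_image_tiff(image: np.ndarray, path: str) -> None:
    """32-bit float TIFF (movies: frames x pixels; kymographs: pixels x frames)."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image_tiff(path: str) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_image_txt(image: np.ndarray, path: str) -> None:
    np.savetxt(path, np.asarray(image, dtype=float), delimiter=",", fmt="%.17g")


def read_image_txt(path: str) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_image_png(image: np.ndarray, path: str,
                    vmin: float | None = None, vmax: float | None = None) -> None:
    """8-bit grayscale PNG with linear scaling from [vmin, vmax] to [0, 255]."""
    img = np.asarray(image, dtype=float)
    lo = img.min() if vmin is None else vmin
    hi = img.max() if vmax is None else vmax
    span = hi - lo if hi > lo else 1.0
    scaled = np.clip((img - lo) / span, 0.0, 1.0)
    Image.fromarray((scaled * 255).astype(np.uint8), mode="L").save(path)


def write_fits_csv(fits: list[SpotFit], path: str) -> None:
    rows = []
    for k, fit in enumerate(fits):
        if fit.n_spots == 0:
            rows.append((k, np.nan, np.nan, fit.sigma_px, fit.rms))
        for c, a in zip(fit.centers, fit.amplitudes):
            rows.append((k, c, a, fit.sigma_px, fit.rms))
    pd.DataFrame(rows, columns=["frame", "center_px", "amplitude", "sigma_px", "rms"]) \
        .to_csv(path, index=False)


def read_fits_csv(path: str) -> list[SpotFit]:
    df = pd.read_csv(path, float_precision="round_trip")
    fits = []
    for _frame, grp in df.groupby("frame", sort=True):
        real = grp.dropna(subset=["amplitude"])
        fits.append(SpotFit(
            centers=real["center_px"].to_numpy(float),
            amplitudes=real["amplitude"].to_numpy(float),
            sigma_px=float(grp["sigma_px"].iloc[0]),
            rms=float(grp["rms"].iloc[0]),
        ))
    return fits


def write_histogram_csv(hist: AmplitudeHistogram, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_hz={hist.frame_rate_hz!r} normalized={hist.normalized}\n")
        pd.DataFrame({
            "bin_left": hist.edges[:-1] if hist.edges.size else [],
            "bin_right": hist.edges[1:] if hist.edges.size else [],
            "count": hist.counts,
        }).to_csv(fh, index=False)


def read_histogram_csv(path: str) -> AmplitudeHistogram:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, float_precision="round_trip")
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
    f = None if meta["frame_rate_hz"] == "None" else float(meta["frame_rate_hz"])
    if len(df):
        edges = np.concatenate([df["bin_left"].to_numpy(float),
                                [float(df["bin_right"].iloc[-1])]])
        counts = df["count"].to_numpy(float)
    else:
        edges, counts = np.empty(0), np.empty(0)
    return AmplitudeHistogram(edges=edges, counts=counts, frame_rate_hz=f,
                              normalized=meta["normalized"] == "True")


def read_kymograph_image(path: str) -> np.ndarray:
    """Read a user-supplied kymograph (TIFF, PNG, CSV/TXT matrix) as floats."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        return read_image_tiff(path)
    if ext == ".png":
        return np.asarray(Image.open(path).convert("F"), dtype=float)
    return read_image_txt(path)
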