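"""Stack and curve I/O: multi-page 32-bit TIFF with a JSON sidecar."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = ["write_stack", "read_stack", "write_curve_csv", "read_curve_csv"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: np.ndarray, path, metadata: dict | None = None) -> Path:
    """Write a (z, y, x) stack as multi-page 32-bit float TIFF.

    Metadata (optical config, seeds, ...) goes to ``<path>.json``.
    """
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("stack must be 2D or 3D")
    tifffile.imwrite(path, stack.astype(np.float32), photometric="minisblack")
    if metadata is not None:
        _sidecar(path).write_text(json.dumps(metadata, indent=2, default=float))
    return path


def read_stack(path):
    """Read a multi-page TIFF as a (z, y, x) float stack plus sidecar metadata.

    A single-page file loads as a 1-plane stack.  A missing sidecar yields
    ``None`` metadata with a logged warning; inconsistent page shapes raise
    a format error.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {page.shape for page in tif.pages}
            if len(shapes) > 1:
                raise ValueError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
            stack = tif.asarray()
    except (TypeError, tifffile.TiffFileError) as exc:
        raise ValueError(f"malformed TIFF stack {path}: {exc}") from exc
    stack = np.asarray(stack)
    if stack.dtype == object or stack.ndim not in (2, 3):
        raise ValueError(f"inconsistent page shapes in {path}")
    if stack.ndim == 2:
        stack = stack[None]
    stack = stack.astype(np.float64)
    sidecar = _sidecar(path)
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
    else:
        logger.warning("no JSON sidecar found for %s; metadata is null", path)
        metadata = None
    return stack, metadata


def write_curve_csv(x, y, path, header: str = "x,y") -> Path:
    """Two-column numeric CSV (e.g. pulse energy versus signal)."""
    path = Path(path)
    np.savetxt(path, np.column_stack([x, y]), delimiter=",", header=header, comments="")
    return path


def read_curve_csv(path):
    """Read a two-column numeric CSV, skipping a single header row if present."""
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter=",")
    except ValueError:
        data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path} is not a two-column numeric CSV")
    return data[:, 0], data[:, 1]
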