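"""Image and result I/O, run configuration, and the summary record.

Float TIFF is the canonical interchange format for images, depth maps
and kernels; PNG (8/16-bit) is supported for viewing, with the integer
scale recorded so values stay ordinally faithful.  Run summaries are
JSON documents validated against the schema shipped with the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from .core import ImageGrid, TransilluminationImage
from .errors import InvalidParameterError

log = logging.getLogger(__name__)

__all__ = [
    "read_image",
    "write_image",
    "RunConfig",
    "write_summary",
    "validate_summary",
    "SUMMARY_SCHEMA_PATH",
]

SUMMARY_SCHEMA_PATH = Path(__file__).with_name("summary_schema.json")


def read_image(path, pitch: float = 0.1) -> TransilluminationImage:
    """Read a TIFF or PNG image as a floating-point intensity map.

    Integer images are rescaled to [0, 1] by their dtype's full range
    (monotone, max preserved ordinally); float images are taken as-is.
    The bit depth and scale applied are logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        data = np.asarray(tifffile.imread(path))
    elif suffix == ".png":
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path))
    else:
        raise InvalidParameterError(f"unsupported image format: {suffix}")
    if data.ndim == 3:
        data = data.mean(axis=-1)
    scale = 1.0
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
    log.info("read %s: dtype=%s shape=%s scale=%g", path, data.dtype,
             data.shape, scale)
    values = data.astype(float) / scale
    grid = ImageGrid(values.shape[0], values.shape[1], pitch)
    return TransilluminationImage(values=values, grid=grid, provenance="raw")


def write_image(path, image: TransilluminationImage) -> None:
    """Write a float32 TIFF (lossless) or an 8-bit PNG (viewing only)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.values.astype(np.float32))
    elif suffix == ".png":
        import imageio.v3 as iio

        v = image.values
        lo, hi = float(v.min()), float(v.max())
        scaled = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
        iio.imwrite(path, (scaled * 255).astype(np.uint8))
        log.warning("PNG output is scale-lossy (range [%g, %g] mapped to "
                    "0-255); use TIFF for quantitative work", lo, hi)
    else:
        raise InvalidParameterError(f"unsupported image format: {suffix}")


@dataclasses.dataclass
class RunConfig:
    """Flat run configuration covering every pipeline stage."""

    mu_s_prime: float = 1.0
    mu_a: float = 0.01
    pitch: float = 0.1
    parse: str = "r"
    absorptance: float = 1.0
    snr_db: float = float("inf")
    seed: int | None = None
    # deconvolution
    method: str = "wiener"
    nsr: float = 1e-3
    iterations: int = 30
    # lookup table
    lut_depth_min: float = 1.0
    lut_depth_max: float = 10.0
    lut_diameter_min: float = 1.0
    lut_diameter_max: float = 10.0
    lut_step: float = 0.1
    half_length: float = 30.0
    # fusion
    window_r: int = 9
    alpha: float = 1.0
    s_th: float = 15.0
    depth_grid: str = "0.1,1:30:1"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def load_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def parse_depth_grid(spec: str) -> np.ndarray:
    """Parse a depth-grid spec like ``"0.1,1:30:1"`` (comma-separated
    values and start:stop:step ranges, stop inclusive)."""
    out: list[float] = []
    for part in spec.split(","):
        if ":" in part:
            bits = [float(b) for b in part.split(":")]
            start, stop = bits[0], bits[1]
            step = bits[2] if len(bits) > 2 else 1.0
            n = int(round((stop - start) / step)) + 1
            out.extend(start + step * np.arange(n))
        else:
            out.append(float(part))
    return np.asarray(sorted(set(out)))


# ---------------------------------------------------------------------------
# Run summary (JSON + shipped schema)
# ---------------------------------------------------------------------------

_SUMMARY_REQUIRED = {
    "config_hash": str,
    "seed": (int, type(None)),
    "versions": dict,
    "outputs": dict,
}


def write_summary(path, config: RunConfig, outputs: dict,
                  extra: dict | None = None) -> dict:
    """Write the reproducibility summary for a run: config hash, seed,
    library versions and the output file map."""
    import numpy
    import scipy

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "versions": {"numpy": numpy.__version__,
                     "scipy": scipy.__version__},
        "outputs": {str(k): str(v) for k, v in outputs.items()},
    }
    if extra:
        summary.update(extra)
    validate_summary(summary)
    Path(path).write_text(json.dumps(summary, indent=1, sort_keys=True,
                                     default=str))
    return summary


def validate_summary(summary: dict) -> None:
    """Check a summary document against the shipped schema (required
    keys and their types)."""
    schema = json.loads(SUMMARY_SCHEMA_PATH.read_text())
    for key, spec in schema["required"].items():
        if key not in summary:
            raise InvalidParameterError(f"summary missing key {key!r}")
        kinds = {"str": str, "int": (int, type(None)), "dict": dict}
        if not isinstance(summary[key], kinds[spec]):
            raise InvalidParameterError(
                f"summary key {key!r} has type {type(summary[key]).__name__},"
                f" expected {spec}")
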