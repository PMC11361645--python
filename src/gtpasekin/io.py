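"""File I/O: trace/time-course CSV with JSON sidecars, TIFF images, run config.

Formats
-------
* Trace CSV: header exactly ``time_s,signal_au``; one trace per file.
  Metadata (mode, concentrations, variant, seed) lives in a sidecar JSON
  named ``<stem>.meta.json`` next to the CSV.
* Hydrolysis CSV: header exactly ``time_s,gtp_fraction``.
* Images: single-plane grayscale TIFF, 16-bit by default (intensities
  scaled to the full range on write).

Readers reject malformed input (bad header, non-numeric rows reported
with their line numbers, non-monotone time) rather than coercing it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import InvalidInputError, TraceFormatError
from .synthetic import (
    DEFAULT_LADDER_UM,
    DEFAULT_REPORTER_UM,
    FluorescenceTrace,
    HydrolysisTimeCourse,
    SyntheticImagePair,
)

logger = logging.getLogger("gtpasekin")

TRACE_HEADER = ["time_s", "signal_au"]
HYDROLYSIS_HEADER = ["time_s", "gtp_fraction"]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_trace_csv(trace: FluorescenceTrace, path) -> Path:
    """Write a trace CSV plus its metadata sidecar; returns the CSV path."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.time_s, "signal_au": trace.signal_au}).to_csv(
        path, index=False, float_format="%.17g"
    )
    meta = {
        "mode": trace.mode,
        "protein_conc_uM": trace.protein_conc_uM,
        "reporter_conc_uM": trace.reporter_conc_uM,
        "variant_label": trace.variant_label,
        "seed": trace.seed,
        "true_rate": trace.true_rate,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _read_two_column_csv(path: Path, header: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != header:
        raise TraceFormatError(
            f"{path}: expected header {','.join(header)!r}, got {','.join(df.columns)!r}"
        )
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1)
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        raise TraceFormatError(f"{path}: malformed rows at lines {lines}")
    # reparse via numpy: exact (correctly rounded) float round-trip
    return pd.DataFrame({c: df[c].to_numpy(dtype=float) for c in df.columns})


def read_trace_csv(path) -> FluorescenceTrace:
    """Read a trace CSV; metadata comes from the sidecar if present."""
    path = Path(path)
    num = _read_two_column_csv(path, TRACE_HEADER)
    t = num["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise TraceFormatError(f"{path}: time_s must be strictly increasing")
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        logger.warning("no metadata sidecar for %s; mode and concentrations unknown", path)
    return FluorescenceTrace(
        time_s=t,
        signal_au=num["signal_au"].to_numpy(),
        mode=meta.get("mode"),
        protein_conc_uM=meta.get("protein_conc_uM"),
        reporter_conc_uM=meta.get("reporter_conc_uM"),
        variant_label=meta.get("variant_label", ""),
        seed=meta.get("seed"),
        true_rate=meta.get("true_rate"),
    )


def write_hydrolysis_csv(tc: HydrolysisTimeCourse, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": tc.time_s, "gtp_fraction": tc.gtp_fraction}).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def read_hydrolysis_csv(path) -> HydrolysisTimeCourse:
    path = Path(path)
    num = _read_two_column_csv(path, HYDROLYSIS_HEADER)
    t = num["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise TraceFormatError(f"{path}: time_s must be strictly increasing")
    return HydrolysisTimeCourse(time_s=t, gtp_fraction=num["gtp_fraction"].to_numpy())


def write_image(img: np.ndarray, path, dtype: str = "uint16") -> Path:
    """Write a single-plane grayscale TIFF (16-bit scaled, or float32)."""
    path = Path(path)
    img = np.asarray(img, dtype=float)
    if dtype == "uint16":
        peak = img.max()
        scaled = (img / peak * 65535.0) if peak > 0 else img
        tifffile.imwrite(path, np.round(scaled).astype(np.uint16))
    elif dtype == "float32":
        tifffile.imwrite(path, img.astype(np.float32))
    else:
        raise InvalidInputError(f"unsupported TIFF dtype {dtype!r}")
    return path


def read_image(path) -> np.ndarray:
    img = tifffile.imread(Path(path))
    if img.ndim != 2:
        raise TraceFormatError(f"{path}: expected a single-plane grayscale image")
    return np.asarray(img, dtype=float)


def write_image_pair(pair: SyntheticImagePair, outdir, dtype: str = "uint16") -> dict:
    """Write both channels plus a ground-truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "channel_a": str(write_image(pair.channel_a, outdir / "channel_a.tif", dtype)),
        "channel_b": str(write_image(pair.channel_b, outdir / "channel_b.tif", dtype)),
        "truth": str(outdir / "truth.json"),
    }
    truth = {
        "truth_centroids_a": pair.truth_centroids_a.tolist(),
        "truth_centroids_b": pair.truth_centroids_b.tolist(),
        "true_coloc_fraction": pair.true_coloc_fraction,
        "n_shared": pair.n_shared,
        "psf_sigma": pair.psf_sigma,
        "seed": pair.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return paths


# --- run configuration -----------------------------------------------------

#: Documented schema for RunConfig files (YAML or JSON): field -> (type, constraint).
RUN_CONFIG_SCHEMA = {
    "seeds": ("list[int]", "nonempty, each >= 0"),
    "ladder_uM": ("list[float]", ">= 3 distinct positive concentrations"),
    "reporter_uM": ("float", "> 0"),
    "noise_sd_frac": ("float", ">= 0, fraction of trace amplitude"),
    "hydrolysis_noise_sd": ("float", ">= 0, absolute sd on GTP fraction"),
    "gtp_pool_uM": ("float", ">= 0"),
    "gdp_pool_uM": ("float", ">= 0"),
    "r1_threshold": ("float", "> 0, exchange/hydrolysis classification cut"),
    "f_gtp_threshold": ("float", "in (0, 1)"),
    "coloc_max_dist_px": ("float", ">= 0"),
    "segmentation_rel_threshold": ("float", "sd units above the mean"),
    "segmentation_min_area_px": ("int", ">= 1"),
    "outdir": ("str", "output directory"),
}


@dataclasses.dataclass
class RunConfig:
    """Validated configuration for scripted/CLI runs."""

    seeds: list[int] = dataclasses.field(default_factory=lambda: [0])
    ladder_uM: list[float] = dataclasses.field(default_factory=lambda: list(DEFAULT_LADDER_UM))
    reporter_uM: float = DEFAULT_REPORTER_UM
    noise_sd_frac: float = 0.01
    hydrolysis_noise_sd: float = 0.02
    gtp_pool_uM: float = 500.0
    gdp_pool_uM: float = 50.0
    r1_threshold: float = 5.0
    f_gtp_threshold: float = 0.5
    coloc_max_dist_px: float = 3.0
    segmentation_rel_threshold: float = 2.0
    segmentation_min_area_px: int = 4
    outdir: str = "gtpasekin_out"

    def __post_init__(self) -> None:
        if not self.seeds or any(int(s) < 0 for s in self.seeds):
            raise InvalidInputError("seeds must be a nonempty list of nonnegative integers")
        ladder = [float(c) for c in self.ladder_uM]
        if len(ladder) < 3 or len(set(ladder)) != len(ladder) or any(c <= 0 for c in ladder):
            raise InvalidInputError("ladder_uM needs >= 3 distinct positive concentrations")
        for name in ("reporter_uM",):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        for name in ("noise_sd_frac", "hydrolysis_noise_sd", "gtp_pool_uM",
                     "gdp_pool_uM", "coloc_max_dist_px"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be nonnegative")
        if not 0 < self.f_gtp_threshold < 1:
            raise InvalidInputError("f_gtp_threshold must lie in (0, 1)")
        if self.segmentation_min_area_px < 1:
            raise InvalidInputError("segmentation_min_area_px must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        raw = path.read_text()
        data = yaml.safe_load(raw) if path.suffix in (".yml", ".yaml") else json.loads(raw)
        if not isinstance(data, dict):
            raise TraceFormatError(f"{path}: config must be a mapping")
        unknown = set(data) - set(RUN_CONFIG_SCHEMA)
        if unknown:
            raise TraceFormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
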