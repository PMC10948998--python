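"""Trace-table and configuration I/O.

Trace tables are plain CSV with the schema written by the generator
(``nucleus_id, frame, t_seconds, ap_um, dv_um, el_pct, fluor_ms2,
fluor_pp7, true_state``; the last two columns are optional on the real-data
path). Image stacks travel as multi-page TIFF with a JSON sidecar naming
the channel order; run configuration is YAML and round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "REQUIRED_COLUMNS",
    "read_traces",
    "write_traces",
    "write_stack",
    "read_stack",
    "RunConfig",
]

REQUIRED_COLUMNS = ["nucleus_id", "frame", "t_seconds", "ap_um", "dv_um",
                    "el_pct", "fluor_ms2"]
OPTIONAL_COLUMNS = ["fluor_pp7", "true_state"]


def read_traces(path: str | Path) -> pd.DataFrame:
    """Read and validate a trace table.

    Raises on missing required columns (naming the first one missing) and on
    non-monotone frame sequences within a nucleus.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    frames_sorted = df.groupby("nucleus_id")["frame"].apply(
        lambda f: bool(np.all(np.diff(f.to_numpy()) > 0)))
    if not frames_sorted.all():
        bad = frames_sorted[~frames_sorted].index[0]
        raise ValueError(f"non-monotone frames for nucleus {bad}")
    return df


def write_traces(df: pd.DataFrame, path: str | Path) -> None:
    """Write a trace table; float columns use shortest round-trip repr."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_stack(stack: np.ndarray, meta: dict, path: str | Path) -> None:
    """Write (n_frames, n_channels, H, W) as multi-page TIFF + JSON sidecar.

    Pages are ordered frame-major: page = frame * n_channels + channel.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nf, nc, h, w = stack.shape
    tifffile.imwrite(path, stack.reshape(nf * nc, h, w).astype(np.float32))
    sidecar = dict(meta)
    sidecar.update({"n_frames": int(nf), "n_channels": int(nc),
                    "page_order": "frame_major"})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    nf, nc = meta["n_frames"], meta["n_channels"]
    return pages.reshape(nf, nc, *pages.shape[-2:]), meta


@dataclass
class RunConfig:
    """Full configuration of a simulate→quantify→compare run.

    Every default carries its provenance in the methods note; the config
    round-trips through YAML without loss.
    """

    seed: int = 0
    n_wt: int = 10
    n_het: int = 10
    preset: str = "default"
    # geometry
    ap_length_um: float = 500.0
    dv_window_um: float = 282.0
    n_ap_nuclei: int = 100
    n_dv_nuclei: int = 17
    frame_interval_s: float = 61.0
    nc14_duration_s: float = 3000.0
    # quantification
    threshold: str | float = "auto"
    n_time_points: int = 100
    n_ap_bins: int = 50
    n_dv_sections: int = 5
    gap_min_el: float = 2.0
    min_cluster: int = 3
    onset_frac: float = 0.10
    late_window: tuple[float, float] = (0.80, 0.90)
    mid_window: tuple[float, float] = (0.40, 0.70)
    aligned_min_n: int = 10
    aligned_window_points: tuple[int, int] = (61, 70)
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["late_window"] = list(d["late_window"])
        d["mid_window"] = list(d["mid_window"])
        d["aligned_window_points"] = list(d["aligned_window_points"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("late_window", "mid_window", "aligned_window_points"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def geometry(self):
        from .simgen import EmbryoGeometry

        return EmbryoGeometry(
            ap_length_um=self.ap_length_um,
            dv_window_um=self.dv_window_um,
            n_ap_nuclei=self.n_ap_nuclei,
            n_dv_nuclei=self.n_dv_nuclei,
            frame_interval_s=self.frame_interval_s,
            nc14_duration_s=self.nc14_duration_s,
        )
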