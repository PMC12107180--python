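"""Thin readers/writers for the package's on-disk formats.

Droplet records travel as CSV with a fixed schema, images and stacks as
TIFF (32-bit float), and every synthetic dataset may carry a JSON
ground-truth sidecar so that recovery analyses stay reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import RECORD_COLUMNS, GroundTruth

__all__ = [
    "write_records",
    "read_records",
    "write_stack",
    "read_stack",
    "write_ground_truth",
    "read_ground_truth",
]


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    """Write a droplet-record table with the canonical column order."""
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    df[RECORD_COLUMNS].to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    return df


def write_stack(arr: np.ndarray, path: str | Path) -> None:
    """Write an image or z-stack as 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {"params": truth.params, "seed": truth.seed}
    Path(path).write_text(json.dumps(payload, indent=2, default=float))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(params=payload["params"], seed=int(payload["seed"]))
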