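"""CSV manifest I/O.

One row per image with columns ``image_id, path, split, labeled, disease,
asymmetry, network, bluewhite``.  Feature cells are empty exactly when the
row is unlabeled (disease-only), mirroring an archive whose large pool
carries only disease tags; a row with some-but-not-all feature cells filled
is ambiguous and rejected.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import MANIFEST_COLUMNS

__all__ = ["read_manifest", "load_images", "ManifestError"]

_FEATURES = ["asymmetry", "network", "bluewhite"]
_MANDATORY = ["image_id", "path", "split", "disease"]


class ManifestError(ValueError):
    """The manifest violated the documented schema."""


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a manifest CSV.

    Returns a DataFrame with a boolean ``labeled`` column derived from the
    feature cells (all filled => labeled, all empty => unlabeled); a mixed
    row is rejected as ambiguous.
    """
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing mandatory columns: {missing}")
    for c in _FEATURES:
        if c not in df.columns:
            df[c] = np.nan
    feat = df[_FEATURES]
    n_filled = feat.notna().sum(axis=1)
    mixed = (n_filled > 0) & (n_filled < len(_FEATURES))
    if mixed.any():
        bad = df.loc[mixed, "image_id"].tolist()[:5]
        raise ManifestError(
            f"rows with partially filled feature cells are ambiguous: {bad}")
    df["labeled"] = n_filled == len(_FEATURES)
    if df["disease"].isna().any():
        raise ManifestError("every row must carry a disease label")
    bad_split = set(df["split"].unique()) - {"train", "val", "holdout"}
    if bad_split:
        raise ManifestError(f"unknown split values: {sorted(bad_split)}")
    return df[MANIFEST_COLUMNS]


def load_images(manifest: pd.DataFrame, root) -> np.ndarray:
    """Load the manifest's PNGs as a (N, 3, H, W) float32 array in [0, 1]."""
    from PIL import Image

    root = Path(root)
    arrays = []
    for p in manifest["path"]:
        with Image.open(root / p) as im:
            arrays.append(np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0)
    return np.stack(arrays).transpose(0, 3, 1, 2)
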