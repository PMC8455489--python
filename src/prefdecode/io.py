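"""On-disk interchange: TSV tables and NIfTI volumes of the BIDS-like tree."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .behavior import ItemRating, TrialResponse

__all__ = [
    "read_ratings_tsv", "read_events_tsv", "read_motion_tsv",
    "load_bold", "save_volume", "load_volume",
]


def read_ratings_tsv(path: str | Path) -> dict[str, ItemRating]:
    df = pd.read_csv(path, sep="\t", dtype={"item_id": str})
    out: dict[str, ItemRating] = {}
    for i, row in df.iterrows():
        try:
            r = ItemRating(str(row["item_id"]), int(row["short_term"]),
                           int(row["long_term"]))
        except ValueError as e:
            raise ValueError(f"{path}, row {i + 2}: {e}") from e
        out[r.item_id] = r
    return out


def read_events_tsv(path: str | Path) -> list[TrialResponse]:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"],
                     keep_default_na=False, dtype={"item_id": str})
    trials = []
    for i, row in df.iterrows():
        dec = None if pd.isna(row["decision"]) or int(row.get("missed", 0)) \
            else int(row["decision"])
        trials.append(TrialResponse(i, str(row["item_id"]),
                                    float(row["onset"]), dec))
    return trials


def read_motion_tsv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(float)


def load_bold(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load 4-D BOLD as (n_scans, nx, ny, nz) plus the affine."""
    img = nib.load(str(path))
    return np.moveaxis(np.asarray(img.dataobj, float), -1, 0), img.affine


def save_volume(vol: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol, np.float32), affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, float), img.affine
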