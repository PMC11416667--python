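"""Reading and writing the pipeline's on-disk formats.

Masks travel as multi-page 16-bit TIFF stacks (or directories of numbered
PNGs); tabular outputs are plain CSV; run metadata and configuration echoes
are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


def write_masks(frames, path) -> Path:
    """Write rendered frames as one multi-page uint16 TIFF."""
    path = Path(path)
    stack = np.stack([f.mask for f in frames]).astype(np.uint16)
    tifffile.imwrite(path, stack)
    return path


def read_masks(path) -> list[np.ndarray]:
    """Read labeled masks from a multi-page TIFF or a directory of numbered
    PNG/TIFF frames (sorted by filename)."""
    path = Path(path)
    if path.is_dir():
        from imageio.v3 import imread

        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no mask images in {path}")
        return [np.asarray(imread(f)).astype(np.int64) for f in files]
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return [frame.astype(np.int64) for frame in arr]


def write_truth(truth, path) -> Path:
    """Ground-truth lineage as CSV (frame, label, track, parent, chain)."""
    rows = []
    for frame, recs in enumerate(truth.per_frame):
        for label0, (track, parent, chain) in enumerate(recs):
            rows.append((frame, label0 + 1, track,
                         -1 if parent is None else parent, chain))
    df = pd.DataFrame(rows, columns=["frame", "label", "track", "parent", "chain"])
    df.to_csv(path, index=False)
    return Path(path)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_forest(forest, frames, path_cells, path_divisions) -> None:
    """Tracking output: cells.csv (frame, label, track, parent, chain, x, y,
    l, w, angle) and divisions.csv (frame, mother, daughter1, daughter2)."""
    by_frame_label = {(r.frame, r.label): r
                      for records in frames for r in records}
    rows = []
    for (frame, label), tid in sorted(forest.assignments.items()):
        tr = forest.tracks[tid]
        r = by_frame_label.get((frame, label))
        rows.append((frame, label, tid,
                     -1 if tr.parent is None else tr.parent,
                     0 if tr.chain is None else tr.chain,
                     r.centroid[0] if r else np.nan,
                     r.centroid[1] if r else np.nan,
                     r.length if r else np.nan,
                     r.width if r else np.nan,
                     r.orientation if r else np.nan))
    pd.DataFrame(rows, columns=["frame", "label", "track", "parent", "chain",
                                "x", "y", "l", "w", "angle"]
                 ).to_csv(path_cells, index=False)
    pd.DataFrame([(f, m, d1, d2) for f, m, (d1, d2) in forest.divisions],
                 columns=["frame", "mother", "daughter1", "daughter2"]
                 ).to_csv(path_divisions, index=False)


def write_yaml(obj, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_echo(config) -> dict:
    """Plain-dict echo of a dataclass config for the YAML manifest."""
    from dataclasses import asdict, is_dataclass

    if is_dataclass(config):
        d = asdict(config)
    elif isinstance(config, dict):
        d = dict(config)
    else:
        d = vars(config)
    return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in d.items()}
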