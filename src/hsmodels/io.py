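"""Plain-text round-tripping of datasets and distributions.

Datasets travel as a pair of files: a tidy CSV of counts (one row per
observed cell per step, so a k-step context cell spans k rows sharing a
``cell_id``) and a JSON side-car holding the variable registry (bin edges
per variable) and provenance metadata.  Only text formats are used.
"""

from __future__ import annotations

import json
from itertools import product as iter_product
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from .errors import SchemaMismatchError
from .inference import ContextDataset, ContextRecord
from .measurement import BinScheme, ContextDistribution

__all__ = [
    "dataset_to_frame",
    "frame_to_dataset",
    "write_dataset",
    "read_dataset",
    "write_distribution",
]

CSV_COLUMNS = [
    "context_id",
    "cell_id",
    "step_order",
    "variable",
    "bin_index",
    "bin_lo",
    "bin_hi",
    "count",
]


def dataset_to_frame(dataset: ContextDataset) -> pd.DataFrame:
    rows = []
    for rec in dataset.records:
        shapes = [b.n_bins for b in rec.bin_schemes]
        for cell, idx in enumerate(iter_product(*(range(k) for k in shapes))):
            c = float(rec.counts[idx])
            for order, (label, j) in enumerate(zip(rec.labels, idx)):
                b = rec.bin_schemes[order]
                rows.append(
                    (rec.context_id, cell, order, label, j, b.edges[j], b.edges[j + 1], c)
                )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_dataset(
    frame: pd.DataFrame, registry: Dict[str, BinScheme], metadata: Optional[Dict] = None
) -> ContextDataset:
    records = []
    for cid, g in frame.groupby("context_id", sort=True):
        steps = g[["step_order", "variable"]].drop_duplicates().sort_values("step_order")
        labels = tuple(steps["variable"])
        schemes = []
        for lbl in labels:
            if lbl not in registry:
                raise SchemaMismatchError(f"variable {lbl!r} missing from registry")
            schemes.append(registry[lbl])
        shape = tuple(b.n_bins for b in schemes)
        counts = np.zeros(shape)
        pivot = g.pivot_table(
            index="cell_id", columns="step_order", values=["bin_index", "count"]
        )
        for cell_id, row in pivot.iterrows():
            idx = tuple(int(row[("bin_index", k)]) for k in range(len(labels)))
            counts[idx] = float(row[("count", 0)])
        records.append(ContextRecord(str(cid), labels, tuple(schemes), counts))
    return ContextDataset(tuple(records), registry, metadata or {})


def write_dataset(dataset: ContextDataset, basepath: Union[str, Path]) -> Dict[str, str]:
    """Write ``<base>.csv`` plus ``<base>.meta.json``; returns the paths."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    csv_path = base.with_suffix(".csv")
    meta_path = base.with_suffix(".meta.json")
    dataset_to_frame(dataset).to_csv(csv_path, index=False)
    meta = {
        "registry": {k: list(v.edges) for k, v in dataset.registry.items()},
        "metadata": dataset.metadata,
    }
    meta_path.write_text(json.dumps(meta, indent=2, default=float))
    return {"csv": str(csv_path), "meta": str(meta_path)}


def read_dataset(basepath: Union[str, Path]) -> ContextDataset:
    base = Path(basepath)
    frame = pd.read_csv(base.with_suffix(".csv"))
    meta = json.loads(base.with_suffix(".meta.json").read_text())
    registry = {k: BinScheme(tuple(v)) for k, v in meta["registry"].items()}
    return frame_to_dataset(frame, registry, meta.get("metadata", {}))


def write_distribution(
    dist: ContextDistribution, path: Union[str, Path], context_id: str = "ctx"
) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dist.to_dataframe(context_id).to_csv(path, index=False)
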