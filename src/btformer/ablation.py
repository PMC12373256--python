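"""Ablation harness: sweep one design axis end-to-end at phantom scale.

The five axes mirror the design questions the architecture answers:
direction count D, positional-encoding type, aggregation type, deep
supervision on/off, and loss selector.  Each variant trains the same tiny
network on the same seeded phantom set and reports held-out Dice and
Jaccard in a mean±sd table (one row per variant, averaged over seeds).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .metrics import format_metrics_table
from .model import BlastocystSegmenter
from .network import NetworkConfig
from .training import TrainConfig

__all__ = ["ABLATION_AXES", "ablation_variants", "run_ablation"]

ABLATION_AXES = {
    "D": [1, 2, 3, 4, 5],
    "pe": ["none", "lrpe", "lsrpe"],
    "agg": ["add", "wadd", "cat", "agg", "soft"],
    "sup": [False, True],
    "loss": ["ce", "sja", "wsja"],
}


def ablation_variants(axis: str, base_net: NetworkConfig, base_train: TrainConfig):
    """Yield (label, network config, train config) for every variant of an axis."""
    if axis not in ABLATION_AXES:
        raise ValueError(f"unknown ablation axis {axis!r}; choose from {sorted(ABLATION_AXES)}")
    for value in ABLATION_AXES[axis]:
        net = dataclasses.replace(base_net)
        tr = dataclasses.replace(base_train)
        if axis == "D":
            net.D = value
            label = f"D={value}"
        elif axis == "pe":
            net.pe = value
            label = {"none": "No PE", "lrpe": "LRPE", "lsrpe": "LSRPE"}[value]
        elif axis == "agg":
            net.agg = value
            label = {"add": "Add", "wadd": "Wadd", "cat": "Cat", "agg": "Agg",
                     "soft": "Soft Agg"}[value]
        elif axis == "sup":
            net.deep_supervision = value
            label = "w/ supervision" if value else "w/o supervision"
        else:
            tr.loss = value
            label = value.upper()
        yield label, net, tr


def run_ablation(axis: str, base_net: NetworkConfig, base_train: TrainConfig,
                 n_train: int = 24, n_val: int = 8, size: int = 32,
                 seeds=(0,), difficulty: str = "medium",
                 out_dir: str | Path | None = None, progress: bool = False) -> dict:
    """Train every variant of one axis and tabulate held-out Dice/Jaccard.

    Returns ``{"axis", "rows", "table"}`` where ``table`` is the TSV text in
    the two-column mean±sd reporting format; optionally writes both TSV and
    JSON to ``out_dir``.
    """
    rows = []
    for label, net, tr in ablation_variants(axis, base_net, base_train):
        dices, jaccards = [], []
        for seed in seeds:
            net_s = dataclasses.replace(net, seed=int(seed))
            tr_s = dataclasses.replace(tr, seed=int(seed))
            seg = BlastocystSegmenter.from_phantoms(
                n_train=n_train, n_val=n_val, size=size, seed=int(seed),
                difficulty=difficulty, network=net_s, training=tr_s)
            fit = seg.fit(progress=progress).use_best()
            m = fit.evaluate(seg.val_pairs)
            dices.append(m["dice"])
            jaccards.append(m["jaccard"])
        row = {"method": label,
               "dice": float(np.mean(dices)), "jaccard": float(np.mean(jaccards))}
        if len(seeds) > 1:
            row["dice_sd"] = float(np.std(dices, ddof=1))
            row["jaccard_sd"] = float(np.std(jaccards, ddof=1))
        rows.append(row)
    table = format_metrics_table(rows)
    result = {"axis": axis, "rows": rows, "table": table}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"ablation_{axis}.tsv").write_text(table + "\n")
        (out / f"ablation_{axis}.json").write_text(json.dumps(rows, indent=1))
    return result
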