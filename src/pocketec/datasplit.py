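"""Leakage-aware train/validation/test partitioning.

The *fold split* removes fold bias: items are first grouped by sequence
cluster (e.g. 30% identity clusters from an external tool), clusters holding
several enzyme classes are separated per class, and then, per class: with
three or more clusters, whole clusters are distributed over train/val/test;
with two clusters, one goes to test and the other is divided over train and
validation; with a single cluster, items are divided 80/10/10 directly.  The
*temporal split* orders items by deposition date (oldest → train).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from itertools import combinations
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .eclabel import ECLabel

logger = logging.getLogger(__name__)

__all__ = [
    "Clustering",
    "SplitAssignment",
    "fold_split",
    "temporal_split",
    "clustering_jaccard",
    "verify_split",
    "read_cluster_tsv",
    "write_split_csv",
    "read_split_csv",
]

PARTITIONS = ("train", "val", "test")


@dataclasses.dataclass(frozen=True)
class Clustering:
    """item_id → cluster_id, total over the item universe."""

    assignment: Mapping[str, str]

    def items(self) -> set:
        return set(self.assignment)

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for item, cl in self.assignment.items():
            out.setdefault(cl, []).append(item)
        return out


@dataclasses.dataclass(frozen=True)
class SplitAssignment:
    """item_id → partition with provenance."""

    assignment: Mapping[str, str]
    provenance: str = "fold"          # "temporal" | "fold" | "random"

    def __post_init__(self):
        bad = {p for p in self.assignment.values() if p not in PARTITIONS}
        if bad:
            raise ValueError(f"unknown partitions {bad}")

    def partition(self, name: str) -> list[str]:
        return sorted(i for i, p in self.assignment.items() if p == name)

    def ratios(self) -> dict[str, float]:
        n = len(self.assignment)
        return {p: len(self.partition(p)) / n for p in PARTITIONS}


def _divide_ratio(items: list, ratios: tuple, rng: np.random.Generator) -> dict:
    """Split one item list by ratios, at least approximately (80/10/10)."""
    items = list(items)
    rng.shuffle(items)
    n = len(items)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    out = {}
    for i, item in enumerate(items):
        if i < n_train:
            out[item] = "train"
        elif i < n_train + n_val:
            out[item] = "val"
        else:
            out[item] = "test"
    # guarantee a non-empty test partition when there are >= 3 items
    if n >= 3 and not any(p == "test" for p in out.values()):
        out[items[-1]] = "test"
    return out


def fold_split(
    clustering: Clustering,
    labels: Mapping[str, ECLabel],
    ratios: tuple = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Cluster-respecting split with per-enzyme-class rules.

    Clusters containing several classes are separated by class first.  Per
    class: ≥3 clusters → whole clusters spread over train/val/test (largest
    clusters to train); 2 clusters → the smaller cluster to test, the other
    divided over train and validation; 1 cluster → items divided by ratio.
    """
    missing = set(labels) - clustering.items()
    if missing:
        raise ValueError(f"items without cluster: {sorted(missing)[:5]}...")
    rng = np.random.default_rng(seed)
    # (EC, cluster) -> members; this is the per-class cluster separation
    by_ec: dict[str, dict[str, list[str]]] = {}
    for item, ec in labels.items():
        by_ec.setdefault(str(ec), {}).setdefault(clustering.assignment[item], []).append(item)

    assignment: dict[str, str] = {}
    for ec in sorted(by_ec):
        clusters = by_ec[ec]
        cluster_ids = sorted(clusters, key=lambda c: (-len(clusters[c]), c))
        sizes = {c: len(clusters[c]) for c in cluster_ids}
        total = sum(sizes.values())
        if total == 1:
            only = clusters[cluster_ids[0]][0]
            warnings.warn(f"enzyme class {ec} has a single item; assigned to train")
            assignment[only] = "train"
            continue
        if len(cluster_ids) >= 3:
            # whole clusters, filled towards the target ratios, val/test first
            target = {"train": ratios[0] * total, "val": ratios[1] * total, "test": ratios[2] * total}
            filled = {p: 0 for p in PARTITIONS}
            # smallest clusters first into val/test so train keeps the mass
            for cl in sorted(cluster_ids, key=lambda c: (sizes[c], c)):
                deficit = {p: target[p] - filled[p] for p in PARTITIONS}
                if filled["test"] == 0:
                    part = "test"
                elif filled["val"] == 0:
                    part = "val"
                else:
                    part = max(("val", "test", "train"),
                               key=lambda p: deficit[p] / max(target[p], 1e-9))
                    if deficit[part] <= 0:
                        part = "train"
                for item in clusters[cl]:
                    assignment[item] = part
                filled[part] += sizes[cl]
        elif len(cluster_ids) == 2:
            small = min(cluster_ids, key=lambda c: (sizes[c], c))
            large = next(c for c in cluster_ids if c != small)
            for item in clusters[small]:
                assignment[item] = "test"
            tv = _divide_ratio(clusters[large], (ratios[0] / (ratios[0] + ratios[1]),
                                                 ratios[1] / (ratios[0] + ratios[1]), 0.0), rng)
            for item, part in tv.items():
                assignment[item] = "train" if part == "train" else "val"
        else:
            assignment.update(_divide_ratio(clusters[cluster_ids[0]], ratios, rng))
    return SplitAssignment(assignment=assignment, provenance="fold")


def temporal_split(
    dates: Mapping[str, Optional[str]],
    ratios: tuple = (0.8, 0.1, 0.1),
) -> SplitAssignment:
    """Deposition-date split: oldest 80% → train, next 10% → val, newest → test.

    Undated items are excluded with a warning (computed structures without a
    homolog date cannot be placed on the time axis).  Ties break by item id.
    """
    dated = {i: d for i, d in dates.items() if d}
    undated = set(dates) - set(dated)
    if undated:
        warnings.warn(f"excluding {len(undated)} undated item(s) from the temporal split")
    order = sorted(dated, key=lambda i: (dated[i], i))
    n = len(order)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    assignment = {}
    for idx, item in enumerate(order):
        if idx < n_train:
            assignment[item] = "train"
        elif idx < n_train + n_val:
            assignment[item] = "val"
        else:
            assignment[item] = "test"
    return SplitAssignment(assignment=assignment, provenance="temporal")


def clustering_jaccard(a: Clustering, b: Clustering) -> float:
    """Jaccard similarity over co-clustered item pairs.

    |pairs co-clustered in both| / |pairs co-clustered in either|, over all
    unordered item pairs of the shared universe.
    """
    if a.items() != b.items():
        raise ValueError("universe mismatch: clusterings cover different items")

    def pair_set(c: Clustering) -> set:
        pairs = set()
        for members in c.clusters().values():
            for x, y in combinations(sorted(members), 2):
                pairs.add((x, y))
        return pairs

    pa, pb = pair_set(a), pair_set(b)
    union = pa | pb
    if not union:
        return 1.0  # two all-singleton clusterings agree vacuously
    return len(pa & pb) / len(union)


def verify_split(split: SplitAssignment, clustering: Clustering,
                 labels: Optional[Mapping[str, ECLabel]] = None) -> list[dict]:
    """List clusters that span partitions for a multi-cluster enzyme class.

    Single-cluster classes are exempt (the one-cluster rule divides within a
    cluster by design).  An empty report means the split is leakage-free.
    """
    violations: list[dict] = []
    if labels is None:
        labels = {i: ECLabel.parse("0") for i in split.assignment}
    by_ec: dict[str, dict[str, list[str]]] = {}
    for item, ec in labels.items():
        if item not in split.assignment:
            continue
        by_ec.setdefault(str(ec), {}).setdefault(clustering.assignment[item], []).append(item)
    for ec, clusters in by_ec.items():
        if len(clusters) < 2:
            continue
        for cl, members in clusters.items():
            parts = {split.assignment[m] for m in members}
            if len(parts) > 1:
                violations.append({"ec": ec, "cluster": cl, "partitions": sorted(parts)})
    return violations


# ---------------------------------------------------------------------------
# File interfaces


def read_cluster_tsv(path) -> Clustering:
    """TSV (representative_id, member_id) — the common clustering-tool dialect."""
    df = pd.read_csv(path, sep="\t", header=None, names=["representative", "member"], dtype=str)
    return Clustering(assignment={row.member: row.representative for row in df.itertuples()})


def write_split_csv(split: SplitAssignment, path) -> None:
    pd.DataFrame(
        sorted(split.assignment.items()), columns=["item_id", "partition"]
    ).to_csv(path, index=False)


def read_split_csv(path, provenance: str = "fold") -> SplitAssignment:
    df = pd.read_csv(path, dtype=str)
    return SplitAssignment(
        assignment=dict(zip(df.item_id, df.partition)), provenance=provenance
    )
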