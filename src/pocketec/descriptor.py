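"""The localized 3D descriptor: selecting the structure region around a site.

A binding site is a point in space with a provenance (experimental annotation,
pocket prediction, homolog transfer, or a random control).  The descriptor
keeps either the *n* closest residues/atoms (count cut), everything within a
radius *r* (circular cut, inclusive boundary), or the whole structure.
Residue-resolution distances are measured at the Cα atom; residues without a
Cα are skipped with a warning.  Selections happen in memory at graph-build
time — input files are never edited.

Custom cut routines can be registered via :func:`register_cut`.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .structure_io import Structure

__all__ = [
    "BindingSite",
    "Selection",
    "EmptyDescriptorError",
    "select_all",
    "select_by_radius",
    "select_by_count",
    "random_center",
    "register_cut",
    "get_cut",
    "read_site_table",
    "write_site_table",
]

SITE_SOURCES = ("experimental", "predicted", "transferred", "random")


class EmptyDescriptorError(ValueError):
    """A cut produced an empty selection (center too far from the structure)."""


@dataclasses.dataclass(frozen=True)
class BindingSite:
    """A 3D site center with provenance and rank."""

    center: np.ndarray  # (3,), Å
    source: str = "experimental"
    rank: int = 1
    score: Optional[float] = None

    def __post_init__(self):
        center = np.asarray(self.center, dtype=np.float64)
        if center.shape != (3,) or not np.all(np.isfinite(center)):
            raise ValueError(f"site center must be a finite 3-vector, got {self.center!r}")
        object.__setattr__(self, "center", center)
        if self.source not in SITE_SOURCES:
            raise ValueError(f"unknown site source {self.source!r}")
        if self.rank < 1:
            raise ValueError(f"site rank must be >= 1, got {self.rank}")


@dataclasses.dataclass(frozen=True)
class Selection:
    """Kept residues (keys) or atoms (indices) of a structure."""

    structure: Structure
    resolution: str                      # "residue" | "atom"
    residue_keys: tuple = ()             # residue resolution
    atom_indices: tuple = ()             # atom resolution
    cut_mode: str = "none"               # "none" | "radius" | "count"
    parameter: Optional[float] = None

    def __post_init__(self):
        if self.resolution not in ("residue", "atom"):
            raise ValueError(f"resolution must be residue|atom, got {self.resolution!r}")

    def __len__(self) -> int:
        return len(self.residue_keys) if self.resolution == "residue" else len(self.atom_indices)


# distances are quantized to 1e-9 Å before ordering/thresholding so that
# geometrically exact ties (e.g. symmetric positions) break by index rather
# than by floating-point noise — keeps cuts invariant under rigid motions
_DIST_DECIMALS = 9


def _residue_distances(s: Structure, center: np.ndarray):
    keys, pos = s.ca_positions()
    all_keys = s.residue_keys()
    if len(keys) < len(all_keys):
        missing = len(all_keys) - len(keys)
        warnings.warn(f"{s.source_id or 'structure'}: skipping {missing} residue(s) without a Cα")
    if not keys:
        raise EmptyDescriptorError("structure has no Cα atoms")
    d = np.round(np.linalg.norm(pos - center[None, :], axis=1), _DIST_DECIMALS)
    return keys, d


def _atom_distances(s: Structure, center: np.ndarray):
    heavy = [i for i, a in enumerate(s.atoms) if not a.is_hydrogen]
    pos = np.array([s.atoms[i].coord for i in heavy], dtype=np.float64)
    d = np.round(np.linalg.norm(pos - center[None, :], axis=1), _DIST_DECIMALS)
    return heavy, d


def select_all(s: Structure, resolution: str = "residue") -> Selection:
    """No cutting: keep the full structure."""
    if resolution == "residue":
        keys, _ = s.ca_positions()
        return Selection(s, "residue", residue_keys=tuple(keys), cut_mode="none")
    heavy = tuple(i for i, a in enumerate(s.atoms) if not a.is_hydrogen)
    return Selection(s, "atom", atom_indices=heavy, cut_mode="none")


def select_by_radius(s: Structure, site: BindingSite, r: float, resolution: str = "residue") -> Selection:
    """Circular cut: keep every residue (Cα) or heavy atom within ``r`` Å (inclusive)."""
    if r < 0:
        raise ValueError(f"radius must be >= 0, got {r}")
    if resolution == "residue":
        keys, d = _residue_distances(s, site.center)
        kept = tuple(k for k, dist in zip(keys, d) if dist <= r)
        if not kept:
            raise EmptyDescriptorError(f"no residue within {r} Å of the site center")
        return Selection(s, "residue", residue_keys=kept, cut_mode="radius", parameter=float(r))
    idx, d = _atom_distances(s, site.center)
    kept = tuple(i for i, dist in zip(idx, d) if dist <= r)
    if not kept:
        raise EmptyDescriptorError(f"no atom within {r} Å of the site center")
    return Selection(s, "atom", atom_indices=kept, cut_mode="radius", parameter=float(r))


def select_by_count(s: Structure, site: BindingSite, n: int, resolution: str = "residue") -> Selection:
    """Count cut: keep the ``min(n, size)`` nearest units, expanding outward.

    Ties are broken deterministically by position in the structure (chain,
    residue number, atom index order).
    """
    if n < 1:
        raise ValueError(f"count must be >= 1, got {n}")
    if resolution == "residue":
        keys, d = _residue_distances(s, site.center)
        order = np.lexsort((np.arange(len(keys)), d))  # distance, then file order
        kept = tuple(keys[i] for i in sorted(order[: min(n, len(keys))]))
        return Selection(s, "residue", residue_keys=kept, cut_mode="count", parameter=float(n))
    idx, d = _atom_distances(s, site.center)
    order = np.lexsort((np.arange(len(idx)), d))
    kept = tuple(idx[i] for i in sorted(order[: min(n, len(idx))]))
    return Selection(s, "atom", atom_indices=kept, cut_mode="count", parameter=float(n))


def random_center(s: Structure, seed: int) -> BindingSite:
    """A control site: center drawn uniformly from the structure's Cα positions."""
    keys, pos = s.ca_positions()
    if not keys:
        raise EmptyDescriptorError("structure has no Cα atoms")
    rng = np.random.default_rng(seed)
    i = int(rng.integers(len(keys)))
    return BindingSite(center=pos[i], source="random", rank=1)


# -- plug-in registry for custom cut routines --------------------------------

_CUTS: dict[str, Callable] = {
    "none": select_all,
    "radius": select_by_radius,
    "count": select_by_count,
}


def register_cut(name: str, fn: Callable) -> None:
    _CUTS[name] = fn


def get_cut(name: str) -> Callable:
    try:
        return _CUTS[name]
    except KeyError:
        raise KeyError(f"unknown cut routine {name!r}; registered: {sorted(_CUTS)}") from None


# -- site table I/O -----------------------------------------------------------

SITE_COLUMNS = ["structure_id", "rank", "center_x", "center_y", "center_z", "source", "score"]


def read_site_table(path) -> dict[str, list[BindingSite]]:
    """CSV site table -> structure_id -> sites sorted by rank."""
    df = pd.read_csv(path)
    missing = set(SITE_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns {sorted(missing)}")
    out: dict[str, list[BindingSite]] = {}
    for _, row in df.iterrows():
        site = BindingSite(
            center=np.array([row.center_x, row.center_y, row.center_z], dtype=np.float64),
            source=str(row.source),
            rank=int(row["rank"]),
            score=float(row.score) if "score" in df.columns and pd.notna(row.get("score")) else None,
        )
        out.setdefault(str(row.structure_id), []).append(site)
    for sid in out:
        out[sid].sort(key=lambda s: s.rank)
    return out


def write_site_table(sites: dict[str, list[BindingSite]], path) -> None:
    rows = []
    for sid, site_list in sites.items():
        for site in site_list:
            rows.append(
                {
                    "structure_id": sid,
                    "rank": site.rank,
                    "center_x": site.center[0],
                    "center_y": site.center[1],
                    "center_z": site.center[2],
                    "source": site.source,
                    "score": site.score,
                }
            )
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, index=False)
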