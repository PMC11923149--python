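"""Binding-site acquisition: pocket-prediction tables and homolog transfer.

When no experimental site annotation exists, sites come either from a
pocket-prediction CSV (rank + center coordinates, P2Rank-style) or by
transferring ligand positions from structurally superposed homologs: hits
with alignment score > 0.5 contribute their (non-additive-ligand) ligand
centroids, mapped into the target frame; centroids closer than an overlap
radius merge into one candidate location, and locations are ranked by how
many ligands support them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptor import BindingSite
from .structure_io import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "Ligand",
    "HomologHit",
    "NoTransferableSiteError",
    "DEFAULT_EXCLUDED_LIGANDS",
    "parse_pocket_table",
    "transfer_sites",
    "superpose",
    "read_homolog_hits",
]

#: Common crystallization additives excluded from transfer (editable default).
DEFAULT_EXCLUDED_LIGANDS = frozenset({
    "GOL",  # glycerol
    "EDO",  # ethylene glycol
    "SO4",  # sulfate
    "PO4",  # phosphate ion
    "PEG", "PG4", "PGE", "1PE",  # PEG fragments
    "ACT",  # acetate
    "DMS",  # dimethyl sulfoxide
    "MPD",  # 2-methyl-2,4-pentanediol
    "TRS",  # tris buffer
    "FMT",  # formate
    "NO3",  # nitrate
    "CIT",  # citrate
    "BME",  # beta-mercaptoethanol
    "IMD",  # imidazole buffer
})


class NoTransferableSiteError(ValueError):
    """No ligand survives the score/name filters."""


@dataclasses.dataclass(frozen=True)
class Ligand:
    """A bound ligand of a homolog: residue name + heavy-atom centroid."""

    name: str
    centroid: np.ndarray  # (3,), homolog frame

    def __post_init__(self):
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=np.float64))


@dataclasses.dataclass(frozen=True)
class HomologHit:
    """A superposed homolog: rigid transform onto the target + its ligands."""

    homolog_id: str
    rotation: np.ndarray       # (3, 3), proper orthogonal
    translation: np.ndarray    # (3,)
    score: float               # alignment score in [0, 1]
    ligands: tuple[Ligand, ...] = ()

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-6) \
                or not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError(f"rotation of {self.homolog_id!r} is not proper orthogonal")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"alignment score must be in [0, 1], got {self.score}")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def map_point(self, p: np.ndarray) -> np.ndarray:
        return self.rotation @ np.asarray(p, dtype=np.float64) + self.translation


def parse_pocket_table(text_or_path, from_text: bool = False) -> list[BindingSite]:
    """Parse a pocket-prediction CSV into ranked predicted sites.

    Requires a rank column and center coordinates; tolerates the common
    dialect variations (whitespace padding, quoting, ``center_x`` vs ``x``).
    """
    import io

    src = io.StringIO(text_or_path) if from_text else text_or_path
    df = pd.read_csv(src, skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    cols = set(df.columns)
    coord_names = None
    for triple in (("center_x", "center_y", "center_z"), ("x", "y", "z")):
        if set(triple) <= cols:
            coord_names = triple
            break
    if coord_names is None or "rank" not in cols:
        raise ValueError(
            "dialect error: pocket table needs a 'rank' column and center_x/y/z (or x/y/z)"
        )
    sites = []
    for row in df.itertuples():
        center = np.array([getattr(row, c) for c in coord_names], dtype=np.float64)
        score = getattr(row, "score", None)
        sites.append(
            BindingSite(center=center, source="predicted", rank=int(getattr(row, "rank")),
                        score=None if score is None or pd.isna(score) else float(score))
        )
    sites.sort(key=lambda s: s.rank)
    return sites


def transfer_sites(
    target: Structure,
    hits: Sequence[HomologHit],
    score_min: float = 0.5,
    excluded_ligands: frozenset = DEFAULT_EXCLUDED_LIGANDS,
    overlap_radius: float = 4.0,
) -> list[BindingSite]:
    """Transfer ligand locations from superposed homologs onto the target.

    Hits with score ≤ ``score_min`` are dropped (strict >), excluded ligand
    names are filtered, surviving centroids are mapped into the target frame,
    merged when within ``overlap_radius`` of an existing location (single-link
    accumulation, center = member mean), and ranked by descending member
    count with ties broken by the best contributing alignment score.
    """
    mapped: list[tuple[np.ndarray, float]] = []  # (target-frame centroid, hit score)
    for hit in hits:
        if hit.score <= score_min:
            continue
        for lig in hit.ligands:
            if lig.name.upper() in excluded_ligands:
                continue
            mapped.append((hit.map_point(lig.centroid), hit.score))
    if not mapped:
        raise NoTransferableSiteError(
            "no transferable site: no ligand passed the score and name filters"
        )
    # deterministic merge order: sort by score desc then coordinates
    mapped.sort(key=lambda m: (-m[1], m[0][0], m[0][1], m[0][2]))
    groups: list[dict] = []
    for point, score in mapped:
        placed = False
        for grp in groups:
            if np.linalg.norm(grp["center"] - point) <= overlap_radius:
                grp["members"].append(point)
                grp["center"] = np.mean(grp["members"], axis=0)
                grp["best_score"] = max(grp["best_score"], score)
                placed = True
                break
        if not placed:
            groups.append({"members": [point], "center": point.copy(), "best_score": score})
    groups.sort(key=lambda g: (-len(g["members"]), -g["best_score"]))
    return [
        BindingSite(center=g["center"], source="transferred", rank=i + 1,
                    score=g["best_score"])
        for i, g in enumerate(groups)
    ]


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition (rotation, translation) mobile → reference.

    Utility for building fixtures from user-given atom correspondences; real
    pipelines take transforms from an external structure-alignment tool.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = rc - R @ mc
    return R, t


def read_homolog_hits(path) -> list[HomologHit]:
    """Load homolog hits from JSON: transform (3×3 + 3), score, ligand records."""
    with open(path) as fh:
        records = json.load(fh)
    hits = []
    for rec in records:
        hits.append(
            HomologHit(
                homolog_id=rec["homolog_id"],
                rotation=np.array(rec["rotation"], dtype=np.float64),
                translation=np.array(rec["translation"], dtype=np.float64),
                score=float(rec["score"]),
                ligands=tuple(
                    Ligand(name=l["name"], centroid=np.array(l["centroid"]))
                    for l in rec.get("ligands", [])
                ),
            )
        )
    return hits
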