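"""Quantification of immune-cell localization and islet viability.

After perfusing labeled PBMCs through the device vasculature, each cell
is classified by where it ended up: still inside a vessel lumen
(adherent), inside an islet outline (invasive), extravascular within
100 µm of an islet (islet-adjacent), or extravascular and away from
every islet (background).  Because extravasation can also happen far
from islets, each islet's region of interest is additionally translated
to islet-free territory and re-counted to estimate the background
extravasation rate for that ROI size.

Islet viability is quantified per islet as dead-stained nuclei as a
percentage of all (Hoechst-stained) nuclei, with dead points matched to
nuclei within a small radius (each nucleus counted at most once).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import LUMEN, WALL, IsletSet, LabeledGrid
from .synth import GenerationError, PointScene, _rng

DEFAULT_ADJACENCY_RADIUS_UM = 100.0
DEFAULT_NUCLEUS_MATCH_RADIUS_UM = 5.0

PBMC_LABELS = ("adherent", "invasive", "adjacent", "background")


class SceneError(ValueError):
    """Raised when a scene and geometry are inconsistent."""


@dataclass
class PBMCClassification:
    """Per-point PBMC labels plus per-islet and background counts.

    Labels partition the points; ``invasive`` and ``adjacent`` are
    subsets of the extravasated population.  ``per_islet`` maps islet
    index -> dict(invasive=…, adjacent=…) counting points whose nearest
    islet is that islet.
    """

    labels: np.ndarray  # str per point
    adjacency_radius: float
    per_islet: dict[int, dict[str, int]]
    counts: dict[str, int]

    def count(self, label: str) -> int:
        return self.counts.get(label, 0)


def classify_points(
    x: np.ndarray,
    y: np.ndarray,
    grid: LabeledGrid,
    islets: IsletSet,
    radius: float = DEFAULT_ADJACENCY_RADIUS_UM,
) -> tuple[np.ndarray, np.ndarray]:
    """Vector core of the PBMC rule; returns (labels, nearest islet index).

    A point in a LUMEN raster cell is adherent; otherwise inside an
    islet disc it is invasive; otherwise within ``radius`` (inclusive)
    of the nearest islet boundary it is adjacent; else background.
    Distances are Euclidean point-to-disc-boundary.
    """
    n = len(x)
    labels = np.empty(n, dtype=object)
    nearest = np.full(n, -1, dtype=int)
    nx, ny = grid.shape
    ix = np.floor((x - grid.origin[0]) / grid.spacing).astype(int)
    iy = np.floor((y - grid.origin[1]) / grid.spacing).astype(int)
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    if not inside.all():
        bad = np.argwhere(~inside).ravel()
        raise SceneError(f"point {bad[0]} at ({x[bad[0]]}, {y[bad[0]]}) outside the domain")
    cell_label = grid.labels[ix, iy]
    if np.any(cell_label == WALL):
        bad = int(np.argwhere(cell_label == WALL).ravel()[0])
        raise SceneError(f"point {bad} lies in a wall cell")
    lum = cell_label == LUMEN
    labels[lum] = "adherent"
    if len(islets) == 0:
        labels[~lum] = "background"
        return labels.astype(str), nearest
    # signed distance to nearest islet boundary (negative inside)
    rest = ~lum
    if rest.any():
        # nearest-center pruning is unsafe here: the nearest boundary may
        # belong to a larger, farther islet — compare against all islets
        dx = x[rest, None] - islets.centers[None, :, 0]
        dy = y[rest, None] - islets.centers[None, :, 1]
        signed = np.hypot(dx, dy) - islets.radii[None, :]
        k = np.argmin(signed, axis=1)
        dmin = signed[np.arange(signed.shape[0]), k]
        nearest[rest] = k
        sub = np.where(dmin <= 0, "invasive", np.where(dmin <= radius, "adjacent", "background"))
        labels[rest] = sub
    return labels.astype(str), nearest


def classify_pbmcs(
    scene: PointScene,
    grid: LabeledGrid,
    islets: IsletSet,
    radius: float = DEFAULT_ADJACENCY_RADIUS_UM,
) -> PBMCClassification:
    """Classify every PBMC point in the scene (see :func:`classify_points`)."""
    pb = scene.select("PBMC")
    labels, nearest = classify_points(pb.x, pb.y, grid, islets, radius)
    per_islet: dict[int, dict[str, int]] = {
        k: {"invasive": 0, "adjacent": 0} for k in range(len(islets))
    }
    for lab, ni in zip(labels, nearest):
        if lab in ("invasive", "adjacent") and ni >= 0:
            per_islet[int(ni)][lab] += 1
    counts = {lab: int((labels == lab).sum()) for lab in PBMC_LABELS}
    return PBMCClassification(
        labels=labels, adjacency_radius=radius, per_islet=per_islet, counts=counts
    )


# --------------------------------------------------------------------------
# Translated control ROIs
# --------------------------------------------------------------------------


@dataclass
class BackgroundROIResult:
    placements: np.ndarray  # (n_islets, 3): x, y, radius of each control ROI
    counts: np.ndarray  # extravasated PBMC per control ROI
    excluded_halo: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": self.placements[:, 0],
                "y_um": self.placements[:, 1],
                "radius_um": self.placements[:, 2],
                "count": self.counts,
            }
        )


def background_roi_counts(
    scene: PointScene,
    islets: IsletSet,
    grid: LabeledGrid,
    seed: int = 0,
    exclude_halo: bool = False,
    adjacency_radius: float = DEFAULT_ADJACENCY_RADIUS_UM,
    max_retries: int = 10_000,
) -> BackgroundROIResult:
    """Translate each islet ROI to islet-free territory and count
    extravasated PBMCs inside — the background-extravasation control.

    Placement is randomized (seeded, exported for audit) rather than
    manual; a placement may overlap no islet disc and no previously
    placed control ROI, and must stay inside the chamber raster.  With
    ``exclude_halo`` the placement also avoids the adjacency halo around
    every islet.
    """
    rng = _rng(seed, 40)
    pb = scene.select("PBMC")
    labels, _ = classify_points(pb.x, pb.y, grid, islets, adjacency_radius)
    extrav = labels != "adherent"
    ex_x, ex_y = pb.x[extrav], pb.y[extrav]

    nx, ny = grid.shape
    x_lo, y_lo = grid.origin
    x_hi = x_lo + nx * grid.spacing
    y_hi = y_lo + ny * grid.spacing
    placements = np.empty((len(islets), 3))
    counts = np.empty(len(islets), dtype=int)
    margin = adjacency_radius if exclude_halo else 0.0
    for k in range(len(islets)):
        r = islets.radii[k]
        placed = False
        for _ in range(max_retries):
            cx = rng.uniform(x_lo + r, x_hi - r)
            cy = rng.uniform(y_lo + r, y_hi - r)
            d_islets = np.hypot(islets.centers[:, 0] - cx, islets.centers[:, 1] - cy)
            if np.any(d_islets < islets.radii + r + margin):
                continue
            if k and np.any(
                np.hypot(placements[:k, 0] - cx, placements[:k, 1] - cy)
                < placements[:k, 2] + r
            ):
                continue
            # ROI must sit on tissue, not wall
            try:
                if grid.label_at(cx, cy) == WALL:
                    continue
            except Exception:
                continue
            placements[k] = (cx, cy, r)
            counts[k] = int(np.sum(np.hypot(ex_x - cx, ex_y - cy) <= r))
            placed = True
            break
        if not placed:
            raise GenerationError(f"could not place control ROI for islet {k}")
    return BackgroundROIResult(placements=placements, counts=counts, excluded_halo=exclude_halo)


# --------------------------------------------------------------------------
# Dead / live quantification
# --------------------------------------------------------------------------


@dataclass
class DeadCellResult:
    """Per-islet viability counts: Dead+ nuclei as % of Hoechst+ nuclei."""

    hoechst_count: np.ndarray
    dead_count: np.ndarray
    dead_percent: np.ndarray
    unmatched_dead: int  # DEAD points not matched to any nucleus

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "islet_id": np.arange(len(self.hoechst_count)),
                "hoechst_count": self.hoechst_count,
                "dead_count": self.dead_count,
                "dead_percent": self.dead_percent,
            }
        )


def dead_fraction(
    scene: PointScene,
    islets: IsletSet,
    match_radius: float = DEFAULT_NUCLEUS_MATCH_RADIUS_UM,
) -> DeadCellResult:
    """Per islet, Hoechst+ nuclei inside the disc and the percentage of
    them matched by a Dead+ point within ``match_radius`` (greedy nearest
    matching, one dead mark per nucleus)."""
    if not match_radius > 0:
        raise ValueError("match_radius must be > 0")
    ho = scene.select("HOECHST")
    de = scene.select("DEAD")
    n_islets = len(islets)
    hoechst = np.zeros(n_islets, dtype=int)
    dead = np.zeros(n_islets, dtype=int)

    if len(ho):
        dx = ho.x[:, None] - islets.centers[None, :, 0]
        dy = ho.y[:, None] - islets.centers[None, :, 1]
        inside = np.hypot(dx, dy) <= islets.radii[None, :]
        islet_of_nucleus = np.where(inside.any(axis=1), inside.argmax(axis=1), -1)
    else:
        islet_of_nucleus = np.empty(0, dtype=int)
    for k in range(n_islets):
        hoechst[k] = int((islet_of_nucleus == k).sum())

    unmatched = 0
    if len(de) and len(ho):
        tree = cKDTree(np.column_stack([ho.x, ho.y]))
        taken = np.zeros(len(ho), dtype=bool)
        # greedy nearest: process dead points by their distance to the
        # closest nucleus so near-coincident pairs match first
        d0, _ = tree.query(np.column_stack([de.x, de.y]))
        for j in np.argsort(d0):
            candidates = tree.query_ball_point((de.x[j], de.y[j]), match_radius)
            candidates = [c for c in candidates if not taken[c]]
            if not candidates:
                unmatched += 1
                continue
            dists = np.hypot(ho.x[candidates] - de.x[j], ho.y[candidates] - de.y[j])
            c = candidates[int(np.argmin(dists))]
            taken[c] = True
            if islet_of_nucleus[c] >= 0:
                dead[islet_of_nucleus[c]] += 1
    elif len(de):
        unmatched = len(de)

    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(hoechst > 0, 100.0 * dead / np.maximum(hoechst, 1), 0.0)
    return DeadCellResult(
        hoechst_count=hoechst, dead_count=dead, dead_percent=pct, unmatched_dead=unmatched
    )
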