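"""Accessible-volume dye modelling and structure screening.

FRET-derived distances refer to the dye positions, not to the labeled
atoms: a dye on a flexible linker explores a cloud of sterically allowed
positions.  The accessible volume (AV) is computed on a Cartesian grid
around the attachment atom: a grid point is allowed when (i) it does not
clash with any obstacle atom (point-to-atom distance exceeds the atom's
radius plus the dye radius) and (ii) the dye can reach it through allowed
space within the linker length, measured as a geodesic distance.
Geodesics combine exact line-of-sight Euclidean distances (when the
straight path is clash-free) with Dijkstra shortest paths on the grid
graph for shadowed regions.  The accessible *contact* volume (ACV)
variant up-weights positions within a contact shell of the obstacle
surface, mimicking dyes that transiently stack against the macromolecule.

Predicted mean inter-dye distances <R_DA> (averaged over position pairs,
matching FRET averaging) feed a chi-square screen of candidate structures
against measured distance sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .kinetics import DomainError

__all__ = [
    "LabelSite",
    "AccessibleVolume",
    "DistanceSet",
    "compute_accessible_volume",
    "av_mean_distance",
    "screen_structures",
    "load_obstacles",
]

#: element -> van der Waals radius (Angstrom); hydrogens are ignored
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "FE": 1.40, "ZN": 1.39, "MG": 1.73, "MN": 1.39,
}
DEFAULT_VDW = 1.7


@dataclass(frozen=True)
class LabelSite:
    """Dye attachment geometry: linker modelled as a flexible tube."""

    attachment: tuple[float, float, float]
    linker_length: float = 20.0
    linker_width: float = 4.5
    dye_radius: float = 3.5

    def __post_init__(self) -> None:
        if min(self.linker_length, self.linker_width, self.dye_radius) < 0:
            raise DomainError("geometry parameters must be non-negative")


@dataclass
class AccessibleVolume:
    """Allowed dye positions with normalized weights."""

    points: np.ndarray  # (n, 3) Angstrom
    weights: np.ndarray  # sum to 1
    grid_spacing: float
    contact_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.weights = np.asarray(self.weights, float)
        if len(self.points) != len(self.weights):
            raise DomainError("points and weights must match")
        s = self.weights.sum()
        if s <= 0:
            raise DomainError("empty accessible volume")
        self.weights = self.weights / s

    @property
    def volume(self) -> float:
        """Occupied volume (number of grid cells x cell volume)."""
        return len(self.points) * self.grid_spacing**3

    @property
    def mean_position(self) -> np.ndarray:
        return self.weights @ self.points


def load_obstacles(path, ignore_hydrogens: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Atom coordinates and vdW radii from a PDB/mmCIF file (via gemmi)."""
    import gemmi

    st = gemmi.read_structure(str(path))
    coords, radii = [], []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    el = atom.element.name.upper()
                    if ignore_hydrogens and el == "H":
                        continue
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    radii.append(VDW_RADII.get(el, DEFAULT_VDW))
        break  # first model only
    return np.array(coords), np.array(radii)


def _line_of_sight(origin, pts, tree, radii_max, obstacles, radii, dye_radius, step):
    """Boolean mask: straight segment origin->point is clash-free."""
    n = len(pts)
    ok = np.ones(n, bool)
    if tree is None:
        return ok
    vec = pts - origin
    dist = np.linalg.norm(vec, axis=1)
    n_samp = np.maximum((dist / step).astype(int), 1)
    max_samp = int(n_samp.max())
    for k in range(1, max_samp + 1):
        active = np.nonzero(ok & (k <= n_samp))[0]
        if len(active) == 0:
            continue
        frac = k / n_samp[active]
        sample = origin + vec[active] * frac[:, None]
        near = tree.query(sample, k=1)[0]
        maybe = near < radii_max + dye_radius
        # refine with per-atom radii for close calls
        check = active[maybe]
        if len(check):
            sample_c = origin + vec[check] * (k / n_samp[check])[:, None]
            idxs = tree.query_ball_point(sample_c, r=radii_max + dye_radius)
            clash = np.zeros(len(check), bool)
            for ii, (pt, neigh) in enumerate(zip(sample_c, idxs)):
                if neigh:
                    d = np.linalg.norm(obstacles[neigh] - pt, axis=1)
                    clash[ii] = bool(np.any(d < radii[neigh] + dye_radius))
            ok[check[clash]] = False
    return ok


def compute_accessible_volume(
    obstacles: np.ndarray,
    obstacle_radii: np.ndarray,
    site: LabelSite,
    grid_spacing: float = 1.0,
    contact_shell: float = 3.0,
    contact_weight: float = 1.0,
) -> AccessibleVolume:
    """Grid accessible volume around an attachment point.

    ``contact_weight`` > 1 turns the AV into an ACV: points within
    ``contact_shell`` of any obstacle surface get their weight multiplied
    by that factor.  Raises when the attachment is fully buried.
    """
    origin = np.asarray(site.attachment, float)
    L = site.linker_length
    if L == 0:
        return AccessibleVolume(origin[None, :], np.array([1.0]), grid_spacing)
    obstacles = np.atleast_2d(np.asarray(obstacles, float)) if len(obstacles) else np.empty((0, 3))
    obstacle_radii = np.asarray(obstacle_radii, float)
    half = int(np.ceil(L / grid_spacing))
    axes = np.arange(-half, half + 1) * grid_spacing
    gx, gy, gz = np.meshgrid(axes, axes, axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + origin
    r_euclid = np.linalg.norm(pts - origin, axis=1)
    inside = r_euclid <= L + 1e-9
    pts = pts[inside]
    r_euclid = r_euclid[inside]

    if len(obstacles):
        tree = cKDTree(obstacles)
        rmax = float(obstacle_radii.max())
        near_d, near_i = tree.query(pts, k=1)
        clash = near_d < obstacle_radii[near_i] + site.dye_radius
        # refine: nearest atom may not be the clashing one
        uncertain = (~clash) & (near_d < rmax + site.dye_radius)
        if uncertain.any():
            cand = np.nonzero(uncertain)[0]
            lists = tree.query_ball_point(pts[cand], r=rmax + site.dye_radius)
            for ii, neigh in zip(cand, lists):
                if neigh:
                    d = np.linalg.norm(obstacles[neigh] - pts[ii], axis=1)
                    if np.any(d < obstacle_radii[neigh] + site.dye_radius):
                        clash[ii] = True
        free = ~clash
    else:
        tree = None
        rmax = 0.0
        free = np.ones(len(pts), bool)

    pts = pts[free]
    r_euclid = r_euclid[free]
    if len(pts) == 0:
        raise DomainError("label site is fully buried")

    # geodesic reachability: line-of-sight points take their Euclidean
    # distance; shadowed points fall back to grid Dijkstra
    los = _line_of_sight(origin, pts, tree, rmax, obstacles, obstacle_radii,
                         site.dye_radius, grid_spacing)
    geo = np.where(los, r_euclid, np.inf)
    if not los.all():
        geo = _grid_geodesic(pts, geo, los, origin, grid_spacing)
    reach = geo <= L + 1e-9
    pts = pts[reach]
    if len(pts) == 0:
        raise DomainError("label site is fully buried (no reachable volume)")

    w = np.ones(len(pts))
    contact_fraction = 0.0
    if len(obstacles) and contact_weight != 1.0:
        near_d, near_i = tree.query(pts, k=1)
        surf_d = near_d - obstacle_radii[near_i]
        contact = surf_d <= contact_shell + site.dye_radius
        w[contact] *= contact_weight
        contact_fraction = float(w[contact].sum() / w.sum())
    elif len(obstacles):
        near_d, near_i = tree.query(pts, k=1)
        contact = (near_d - obstacle_radii[near_i]) <= contact_shell + site.dye_radius
        contact_fraction = float(contact.mean())
    return AccessibleVolume(pts, w / w.sum(), grid_spacing, contact_fraction)


def _grid_geodesic(pts, geo_init, los, origin, h):
    """Dijkstra on the allowed-grid graph, seeded by line-of-sight nodes."""
    key = np.round((pts - origin) / h).astype(int)
    index = {tuple(k): i for i, k in enumerate(key)}
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) != (0, 0, 0):
                    offsets.append((dx, dy, dz))
    rows, cols, vals = [], [], []
    for off in offsets:
        shifted = key + np.array(off)
        w = h * np.linalg.norm(off)
        for i, k in enumerate(map(tuple, shifted)):
            j = index.get(k)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(w)
    n = len(pts)
    graph = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocoo()
    seeds = np.nonzero(los)[0]
    # multi-source Dijkstra with per-seed head starts (each seed already
    # carries its exact line-of-sight distance): augment the graph with a
    # virtual source node connected to every seed at that distance
    rows2 = np.concatenate([graph.row, np.full(len(seeds), n)])
    cols2 = np.concatenate([graph.col, seeds])
    vals2 = np.concatenate([graph.data, geo_init[seeds]])
    aug = coo_matrix((vals2, (rows2, cols2)), shape=(n + 1, n + 1)).tocsr()
    dist = dijkstra(aug, directed=False, indices=n)
    out = np.minimum(geo_init, dist[:n])
    return out


def av_mean_distance(
    av1: AccessibleVolume,
    av2: AccessibleVolume,
    n_samples: int = 200_000,
    seed: int = 0,
    exact_threshold: int = 4_000_000,
) -> tuple[float, float]:
    """Weighted mean inter-dye distance <R_DA> between two volumes.

    Uses the exact double loop when ``len(av1) * len(av2)`` is below the
    threshold, otherwise seeded weighted sampling of point pairs.  The
    mean over *pairs* (not the distance between mean positions) is the
    FRET-relevant average.  Symmetric in its arguments.
    """
    n1, n2 = len(av1.points), len(av2.points)
    if n1 * n2 <= exact_threshold:
        # chunked exact computation
        mean = 0.0
        m2 = 0.0
        for i0 in range(0, n1, 512):
            p = av1.points[i0 : i0 + 512]
            w = av1.weights[i0 : i0 + 512]
            d = np.linalg.norm(p[:, None, :] - av2.points[None, :, :], axis=2)
            mean += float(w @ d @ av2.weights)
            m2 += float(w @ (d**2) @ av2.weights)
        var = max(m2 - mean**2, 0.0)
        return mean, float(np.sqrt(var / (n1 * n2)))
    rng = np.random.default_rng(seed)
    i = rng.choice(n1, n_samples, p=av1.weights)
    j = rng.choice(n2, n_samples, p=av2.weights)
    d = np.linalg.norm(av1.points[i] - av2.points[j], axis=1)
    return float(d.mean()), float(d.std(ddof=1) / np.sqrt(n_samples))


@dataclass
class DistanceSet:
    """Measured mean inter-dye distances with uncertainties per species."""

    entries: pd.DataFrame  # columns: pair_id, species, r_da, dr_da

    def __post_init__(self) -> None:
        req = {"pair_id", "species", "r_da", "dr_da"}
        if not req <= set(self.entries.columns):
            raise DomainError(f"DistanceSet needs columns {sorted(req)}")
        if (self.entries["r_da"] <= 0).any() or (self.entries["dr_da"] <= 0).any():
            raise DomainError("distances and uncertainties must be positive")


def screen_structures(
    candidates: dict[str, dict[str, float]],
    measured: DistanceSet,
) -> pd.DataFrame:
    """Rank candidate structures against measured distances by chi-square.

    ``candidates`` maps structure name -> {pair_id: model <R_DA>}; model
    distances typically come from :func:`av_mean_distance` on AVs built
    from the candidate coordinates.  chi^2 = sum ((R_model - R_meas) /
    dR)^2 per (structure, species); missing pairs are excluded from that
    cell and reported.  Rows with chi^2/n <= 1 are flagged as acceptable.
    """
    rows = []
    for sname, model_d in candidates.items():
        for species, grp in measured.entries.groupby("species"):
            chi2, n_used, missing = 0.0, 0, []
            for _, e in grp.iterrows():
                rm = model_d.get(e["pair_id"])
                if rm is None:
                    missing.append(e["pair_id"])
                    continue
                chi2 += ((rm - e["r_da"]) / e["dr_da"]) ** 2
                n_used += 1
            rows.append(
                {
                    "structure": sname,
                    "species": species,
                    "chi2": chi2,
                    "n_pairs": n_used,
                    "chi2_per_pair": chi2 / n_used if n_used else np.nan,
                    "acceptable": bool(n_used and chi2 / n_used <= 1.0),
                    "missing_pairs": ";".join(missing),
                }
            )
    df = pd.DataFrame(rows)
    df["rank"] = df.groupby("species")["chi2_per_pair"].rank(method="min").astype(int)
    return df.sort_values(["species", "rank"], kind="stable").reset_index(drop=True)
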