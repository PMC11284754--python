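"""Bead-shell nanoparticle surfaces: spheres, spiked stars, ligand layouts.

Surfaces are generated deterministically from a Fibonacci lattice so that
beads, tip axes and patch centers are all near-uniformly distributed.
Coordinates are in sigma and centered at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree, ConvexHull

__all__ = [
    "NanoparticleSpec",
    "SurfaceBeads",
    "fibonacci_sphere",
    "generate_sphere_surface",
    "generate_nanostar_surface",
    "generate_particle",
    "place_tip_ligands",
    "place_patch_ligands",
    "patch_separation",
    "solidity",
    "projection_mask",
    "write_xyz",
    "read_xyz",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

KIND_SURFACE = "np_surface"
KIND_LIGAND = "ligand"


@dataclass
class NanoparticleSpec:
    """Geometric recipe for a star or patched sphere plus ligand placement.

    A star's maximum radial extent is ``core_radius + tip_length``; a
    sphere's is ``sphere_radius``.  Total ligand count is
    ``tip_count * ligands_per_site`` (star) or
    ``n_patches * ligands_per_site`` (sphere).
    """

    shape: str = "star"              # {"star", "sphere"}
    core_radius: float = 7.0
    tip_count: int = 35
    tip_length: float = 5.0
    basal_tip_radius: float = 3.0
    tip_radius: float = 1.5
    sphere_radius: float = 12.0
    bead_spacing: float = 1.0
    ligand_depth: float = 3.0
    n_patches: int = 35
    ligands_per_site: int = 8

    def __post_init__(self):
        if self.shape not in ("star", "sphere"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.bead_spacing <= 0:
            raise ValueError("bead_spacing must be positive")
        if self.shape == "star":
            if self.core_radius <= 0 or self.tip_length < 0:
                raise ValueError("core_radius/tip_length must be positive")
            if not (self.tip_radius <= self.basal_tip_radius <= self.core_radius):
                raise ValueError(
                    "require tip_radius <= basal_tip_radius <= core_radius"
                )
            if self.tip_count < 0:
                raise ValueError("tip_count must be >= 0")
        else:
            if self.sphere_radius <= 0:
                raise ValueError("sphere_radius must be positive")
            if self.bead_spacing >= self.sphere_radius + 1e-12:
                if self.bead_spacing > self.sphere_radius:
                    raise ValueError("bead_spacing must not exceed radius")
            if self.n_patches < 0:
                raise ValueError("n_patches must be >= 0")

    @property
    def max_radius(self) -> float:
        if self.shape == "star":
            return self.core_radius + self.tip_length
        return self.sphere_radius

    @property
    def total_ligands(self) -> int:
        sites = self.tip_count if self.shape == "star" else self.n_patches
        return sites * self.ligands_per_site


@dataclass
class SurfaceBeads:
    """A bead shell: coordinates, per-bead kind, and ligand-site labels.

    ``site_id`` is the tip or patch index a bead belongs to, -1 for core /
    unassigned beads.
    """

    coordinates: np.ndarray                     # (n, 3) float
    kind: np.ndarray                            # (n,) of str
    site_id: np.ndarray                         # (n,) int
    site_centers: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3))
    )                                           # tip apexes / patch centers

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.kind = np.asarray(self.kind, dtype=object)
        self.site_id = np.asarray(self.site_id, dtype=int)
        self.site_centers = np.asarray(self.site_centers, dtype=float)

    def __len__(self) -> int:
        return len(self.coordinates)

    @property
    def n_ligands(self) -> int:
        return int(np.sum(self.kind == KIND_LIGAND))

    @property
    def ligand_coordinates(self) -> np.ndarray:
        return self.coordinates[self.kind == KIND_LIGAND]

    def nn_spacing(self) -> np.ndarray:
        """Nearest-neighbor distance per bead."""
        tree = cKDTree(self.coordinates)
        d, _ = tree.query(self.coordinates, k=2)
        return d[:, 1]


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Deterministic near-uniform lattice of ``n`` points on a sphere."""
    if n < 1:
        raise ValueError("need n >= 1 points")
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * _GOLDEN_ANGLE
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return radius * pts


def generate_sphere_surface(radius: float, bead_spacing: float = 1.0) -> SurfaceBeads:
    """Evenly spaced bead shell on a sphere of ``radius``."""
    if radius <= 0 or bead_spacing <= 0:
        raise ValueError("radius and bead_spacing must be positive")
    if bead_spacing > radius:
        raise ValueError("bead_spacing must not exceed radius")
    n = max(4, int(round(4.0 * np.pi * radius**2 / bead_spacing**2)))
    coords = fibonacci_sphere(n, radius)
    return SurfaceBeads(
        coordinates=coords,
        kind=np.full(n, KIND_SURFACE, dtype=object),
        site_id=np.full(n, -1, dtype=int),
    )


def _tip_beads(axis: np.ndarray, spec: NanoparticleSpec) -> np.ndarray:
    """Beads covering one tip: a frustum swept between radial shells.

    Rings of beads lie on spheres of radius ell in
    [core_radius, core_radius + tip_length]; the lateral ring radius
    narrows linearly from basal_tip_radius to tip_radius, so the maximum
    radial extent is exactly core_radius + tip_length.  The end cap is a
    filled disk (rings + apex bead) on the outermost shell.
    """
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame around the axis
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    s = spec.bead_spacing
    r_lo, length = spec.core_radius, spec.tip_length
    beads = []

    def ring(ell: float, rho: float, phase: float) -> None:
        rho = min(rho, ell)
        ax = np.sqrt(max(0.0, ell * ell - rho * rho))
        m = max(3, int(np.ceil(2.0 * np.pi * rho / s))) if rho > 1e-9 else 1
        if rho <= 1e-9:
            beads.append(ell * axis)
            return
        ang = phase + 2.0 * np.pi * np.arange(m) / m
        beads.extend(
            ax * axis + rho * (np.cos(a) * e1 + np.sin(a) * e2) for a in ang
        )

    n_levels = max(2, int(np.ceil(length / (0.95 * s))) + 1)
    for j, ell in enumerate(np.linspace(r_lo, r_lo + length, n_levels)):
        frac = (ell - r_lo) / length if length > 0 else 1.0
        rho = spec.basal_tip_radius + frac * (spec.tip_radius - spec.basal_tip_radius)
        ring(ell, rho, phase=j * 0.5)
    # cap: fill the end disk inward to the apex with evenly divided rings
    ell_top = r_lo + length
    n_cap = max(1, int(round(spec.tip_radius / s)))
    for j in range(1, n_cap):
        ring(ell_top, spec.tip_radius * (n_cap - j) / n_cap, phase=0.25 + j * 0.5)
    beads.append(ell_top * axis)
    return np.asarray(beads)


def generate_nanostar_surface(spec: NanoparticleSpec) -> SurfaceBeads:
    """Bead shell of a spiked star: core sphere plus frustum tips.

    Tip axes follow the same even-spacing lattice as surface beads.  Core
    beads buried under a tip base are removed, and beads closer than
    0.7 * bead_spacing to an already placed bead are dropped so the shell
    stays homogeneous where tip bases meet.
    """
    if spec.shape != "star":
        raise ValueError("spec.shape must be 'star'")
    core = generate_sphere_surface(spec.core_radius, spec.bead_spacing)
    if spec.tip_count == 0:
        return core

    axes = fibonacci_sphere(spec.tip_count, 1.0)
    sin_base = min(1.0, spec.basal_tip_radius / spec.core_radius)
    theta_base = np.arcsin(sin_base)
    if spec.tip_count > 1:
        # tips whose axis falls inside another tip's basal cone are
        # degenerate: the frusta coincide rather than merely touching
        dots = np.clip(axes @ axes.T, -1.0, 1.0)
        np.fill_diagonal(dots, -1.0)
        min_angle = np.arccos(dots.max())
        if min_angle < theta_base:
            raise ValueError(
                f"{spec.tip_count} tips of basal radius "
                f"{spec.basal_tip_radius:g} overlap beyond tolerance on a "
                f"{spec.core_radius:g}-sigma core"
            )

    # drop core beads under any tip base
    unit = core.coordinates / spec.core_radius
    cos_base = np.cos(theta_base)
    buried = (unit @ axes.T).max(axis=1) > cos_base
    coords = [core.coordinates[~buried]]
    sites = [np.full(int((~buried).sum()), -1, dtype=int)]

    tree_pts = coords[0]
    for t, axis in enumerate(axes):
        tb = _tip_beads(axis, spec)
        if len(tree_pts):
            d, _ = cKDTree(tree_pts).query(tb)
            tb = tb[d > 0.7 * spec.bead_spacing]
        coords.append(tb)
        sites.append(np.full(len(tb), t, dtype=int))
        tree_pts = np.vstack([tree_pts, tb]) if len(tb) else tree_pts

    all_coords = np.vstack(coords)
    all_sites = np.concatenate(sites)
    apexes = (spec.core_radius + spec.tip_length) * axes
    return SurfaceBeads(
        coordinates=all_coords,
        kind=np.full(len(all_coords), KIND_SURFACE, dtype=object),
        site_id=all_sites,
        site_centers=apexes,
    )


def generate_particle(spec: NanoparticleSpec, seed: int | None = 0) -> SurfaceBeads:
    """Build the full ligand-decorated surface for either shape."""
    if spec.shape == "star":
        star = generate_nanostar_surface(spec)
        if spec.tip_count and spec.ligands_per_site:
            star = place_tip_ligands(
                star, spec.ligand_depth, spec.ligands_per_site, seed=seed,
                max_radius=spec.max_radius,
            )
        return star
    sphere = generate_sphere_surface(spec.sphere_radius, spec.bead_spacing)
    if spec.n_patches and spec.ligands_per_site:
        sphere = place_patch_ligands(
            sphere, spec.n_patches, spec.ligands_per_site, seed=seed
        )
    return sphere


def place_tip_ligands(
    star: SurfaceBeads,
    ligand_depth: float,
    ligands_per_site: int,
    seed: int | None = 0,
    max_radius: float | None = None,
) -> SurfaceBeads:
    """Relabel ``ligands_per_site`` beads per tip, within the outer shell.

    Eligible beads lie at radial distance >= max_radius - ligand_depth.
    Selection within the eligible shell of each tip is uniform under the
    given seed (outermost beads are always eligible first).
    """
    if ligand_depth <= 0:
        raise ValueError("ligand_depth must be positive")
    if ligands_per_site < 1:
        raise ValueError("ligands_per_site must be >= 1")
    tips = np.unique(star.site_id[star.site_id >= 0])
    if len(tips) == 0:
        raise ValueError("surface has no tips to decorate")
    radial = np.linalg.norm(star.coordinates, axis=1)
    if max_radius is None:
        max_radius = float(radial.max())
    rmin = max_radius - ligand_depth

    rng = np.random.default_rng(seed)
    kind = star.kind.copy()
    for t in tips:
        idx = np.flatnonzero((star.site_id == t) & (radial >= rmin - 1e-9))
        if len(idx) < ligands_per_site:
            raise ValueError(
                f"tip {t}: only {len(idx)} beads in the outermost "
                f"{ligand_depth:g} sigma, need {ligands_per_site}"
            )
        chosen = rng.choice(idx, size=ligands_per_site, replace=False)
        kind[chosen] = KIND_LIGAND
    return SurfaceBeads(
        coordinates=star.coordinates,
        kind=kind,
        site_id=star.site_id,
        site_centers=star.site_centers,
    )


def place_patch_ligands(
    sphere: SurfaceBeads,
    n_patches: int,
    ligands_per_site: int,
    seed: int | None = 0,
) -> SurfaceBeads:
    """Relabel beads into ``n_patches`` disjoint patches of ligands.

    Patch centers are an even lattice on the sphere; patches claim their
    nearest unassigned surface beads in patch-index order, which resolves
    equidistant ties deterministically in favor of the lowest index.
    """
    if n_patches < 1 or ligands_per_site < 1:
        raise ValueError("n_patches and ligands_per_site must be >= 1")
    n_needed = n_patches * ligands_per_site
    if n_needed > len(sphere):
        raise ValueError(
            f"{n_needed} ligands requested but surface has {len(sphere)} beads"
        )
    radius = float(np.linalg.norm(sphere.coordinates, axis=1).mean())
    centers = fibonacci_sphere(n_patches, radius)

    kind = sphere.kind.copy()
    site = np.full(len(sphere), -1, dtype=int)
    assigned = np.zeros(len(sphere), dtype=bool)
    d2 = ((sphere.coordinates[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    for p in range(n_patches):
        order = np.argsort(d2[:, p], kind="stable")
        order = order[~assigned[order]][:ligands_per_site]
        assigned[order] = True
        kind[order] = KIND_LIGAND
        site[order] = p
    return SurfaceBeads(
        coordinates=sphere.coordinates,
        kind=kind,
        site_id=site,
        site_centers=centers,
    )


def patch_separation(layout: SurfaceBeads, variant: str = "chord") -> float:
    """Mean nearest-neighbor distance between ligand-site centers.

    ``variant="chord"`` uses straight-line center-to-center distance;
    ``variant="surface_gap"`` subtracts twice the mean in-patch radius,
    approximating the free gap between patch edges.
    """
    centers = layout.site_centers
    if centers is None or len(centers) < 2:
        # fall back to per-site ligand centroids
        sites = np.unique(layout.site_id[(layout.kind == KIND_LIGAND)])
        if len(sites) < 2:
            raise ValueError("need at least 2 ligand sites")
        centers = np.array([
            layout.coordinates[(layout.site_id == s) & (layout.kind == KIND_LIGAND)].mean(axis=0)
            for s in sites
        ])
    tree = cKDTree(centers)
    d, _ = tree.query(centers, k=2)
    chord = float(d[:, 1].mean())
    if variant == "chord":
        return chord
    if variant == "surface_gap":
        mask = layout.kind == KIND_LIGAND
        radii = []
        for s in np.unique(layout.site_id[mask]):
            pts = layout.coordinates[mask & (layout.site_id == s)]
            radii.append(np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean())
        return chord - 2.0 * float(np.mean(radii))
    raise ValueError(f"unknown variant {variant!r}")


def projection_mask(
    beads: SurfaceBeads,
    axis: int = 2,
    pixels_per_sigma: int = 10,
    bead_radius: float = 0.5,
) -> np.ndarray:
    """Binary raster of the particle silhouette along ``axis``."""
    dims = [d for d in range(3) if d != axis]
    xy = beads.coordinates[:, dims]
    lo = xy.min(axis=0) - 2 * bead_radius
    hi = xy.max(axis=0) + 2 * bead_radius
    nx, ny = (np.ceil((hi - lo) * pixels_per_sigma).astype(int) + 1)
    gx = lo[0] + (np.arange(nx) + 0.5) / pixels_per_sigma
    gy = lo[1] + (np.arange(ny) + 0.5) / pixels_per_sigma
    px = np.stack(np.meshgrid(gx, gy, indexing="ij"), axis=-1).reshape(-1, 2)
    d, _ = cKDTree(xy).query(px, distance_upper_bound=bead_radius)
    return (np.isfinite(d)).reshape(nx, ny)


def solidity(mask: np.ndarray) -> float:
    """Projection area divided by convex-hull area of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("mask has no foreground pixels")
    pts = np.argwhere(mask).astype(float)
    if area < 3 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        return 1.0
    hull = ConvexHull(pts)
    from skimage.draw import polygon

    rr, cc = polygon(pts[hull.vertices, 0], pts[hull.vertices, 1], mask.shape)
    hull_area = len(rr)
    return min(1.0, area / hull_area)


# ---------------------------------------------------------------------------
# XYZ round-trip (element column encodes bead kind; site ids in the comment)
# ---------------------------------------------------------------------------

_XYZ_ELEM = {KIND_SURFACE: "C", KIND_LIGAND: "N"}
_ELEM_XYZ = {v: k for k, v in _XYZ_ELEM.items()}


def write_xyz(beads: SurfaceBeads, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(beads)}\n")
        fh.write("site_id=" + ",".join(map(str, beads.site_id)) + "\n")
        for (x, y, z), k in zip(beads.coordinates, beads.kind):
            fh.write(f"{_XYZ_ELEM[k]} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path) -> SurfaceBeads:
    with open(path) as fh:
        n = int(fh.readline())
        comment = fh.readline().strip()
        coords, kinds = [], []
        for _ in range(n):
            el, x, y, z = fh.readline().split()
            coords.append([float(x), float(y), float(z)])
            kinds.append(_ELEM_XYZ[el])
    site = np.full(n, -1, dtype=int)
    if comment.startswith("site_id="):
        site = np.array([int(s) for s in comment[len("site_id="):].split(",")])
    return SurfaceBeads(
        coordinates=np.asarray(coords),
        kind=np.asarray(kinds, dtype=object),
        site_id=site,
    )
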