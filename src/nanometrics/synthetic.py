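"""Seeded ground-truth generators for every analysis stage.

Each generator emulates one class of measured object — localization clouds
around curved filament bundles, branched filament networks, AFM force
curves, myotube/nuclei label masks — and returns the generated artifact
together with a :class:`SceneGroundTruth` record of the true parameters, so
parameter-recovery tests never need external data.

What is emulated, and what is not: localizations carry per-event Gaussian
precision noise and a uniform background, at the event densities and frame
counts typical of 20,000-50,000-frame dSTORM acquisitions; photophysics
(blinking kinetics, bleaching), PSF shape and camera noise are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from nanometrics.afm import ForceCurve, hertz_force
from nanometrics.loc_io import DEFAULT_PIXEL_SIZE_NM, LocalizationTable, RenderedImage

__all__ = [
    "BundleSpec",
    "NetworkSpec",
    "SceneGroundTruth",
    "FWHM_FACTOR",
    "simulate_bundle_localizations",
    "random_network_spec",
    "simulate_network_image",
    "inject_drift",
    "linear_drift",
    "simulate_force_curve",
    "generate_myotube_masks",
]

#: FWHM of a Gaussian of unit standard deviation: 2*sqrt(2*ln 2).
FWHM_FACTOR = float(2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SceneGroundTruth:
    """Generator-side record of the true scene parameters.

    Only the fields relevant to the generated scene are populated.
    """

    # bundle scenes
    sigma_true_nm: float | None = None
    fwhm_true_nm: float | None = None
    centerline_coeffs: tuple[float, ...] | None = None
    x_domain_nm: tuple[float, float] | None = None
    n_signal: int | None = None
    n_background: int | None = None
    # network scenes
    branch_count: int | None = None
    branch_lengths_nm: list[float] | None = None
    # drift scenes
    drift_nm: np.ndarray | None = None
    # force curves
    E_pa: float | None = None
    contact_point_nm: float | None = None
    # myotube fixtures
    differentiation_index: float | None = None
    fusion_index: float | None = None
    nuclei_per_myotube: list[int] | None = None
    nuclei_category_hist: dict[str, int] | None = None
    #: nucleus label -> containing desmin label (myotube or mononucleated
    #: cell), or None for nuclei on background
    nucleus_to_desmin: dict[int, int | None] | None = None
    n_nuclei: int | None = None


# --------------------------------------------------------------------------
# bundle localizations
# --------------------------------------------------------------------------

@dataclass
class BundleSpec:
    """Parameters of a synthetic cortical-actin bundle localization cloud.

    The bundle centerline is the polynomial ``y(x) = sum c_k x^k`` (nm,
    coefficients low order first) over ``x_domain_nm``.  Events are placed
    uniformly in arc length, offset perpendicular to the centerline by
    N(0, sigma_true), and then displaced isotropically by that event's own
    localization precision, drawn from a positive-truncated normal.
    Background events are uniform over the bounding box.  The true width is
    ``FWHM_true = 2*sqrt(2 ln 2) * sigma_true_nm``.
    """

    centerline_coeffs: tuple[float, ...] = (0.0,)
    x_domain_nm: tuple[float, float] = (0.0, 2000.0)
    sigma_true_nm: float = 30.0
    density_per_um: float = 3000.0
    precision_mean_nm: float = 15.0
    precision_sd_nm: float = 5.0
    background_per_um2: float = 50.0
    n_frames: int = 30000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_true_nm < 0:
            raise ValueError("sigma_true_nm must be >= 0")
        if self.density_per_um <= 0:
            raise ValueError("density_per_um must be > 0")
        if self.x_domain_nm[1] <= self.x_domain_nm[0]:
            raise ValueError("x domain must have positive length")


def _centerline_samples(
    coeffs: Sequence[float], domain: tuple[float, float], n: int = 4000
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense (x, y, cumulative arc length) samples of the centerline."""
    x = np.linspace(domain[0], domain[1], n)
    y = np.polynomial.polynomial.polyval(x, np.asarray(coeffs, dtype=float))
    seg = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return x, y, s


def _draw_precisions(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    """Per-event localization precisions, truncated to be positive."""
    if sd == 0:
        return np.full(n, mean, dtype=float)
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_bundle_localizations(
    spec: BundleSpec,
) -> tuple[LocalizationTable, SceneGroundTruth]:
    """Generate a localization table around a curved bundle centerline.

    Deterministic for a given spec (the seed lives in the spec).  Event
    count is Poisson around ``density_per_um * arc length``; frames are
    assigned uniformly over ``n_frames``.
    """
    rng = np.random.default_rng(spec.seed)
    xc, yc, s = _centerline_samples(spec.centerline_coeffs, spec.x_domain_nm)
    arc_len = s[-1]
    n_signal = int(rng.poisson(spec.density_per_um * arc_len / 1000.0))
    if n_signal == 0:
        raise ValueError("spec produces zero signal events; raise density")

    # arc-length-uniform positions along the curve
    u = rng.uniform(0.0, arc_len, n_signal)
    x0 = np.interp(u, s, xc)
    y0 = np.interp(u, s, yc)

    # unit normal from the analytic tangent
    dcoeffs = np.polynomial.polynomial.polyder(
        np.asarray(spec.centerline_coeffs, dtype=float)
    )
    slope = np.polynomial.polynomial.polyval(x0, dcoeffs) if len(dcoeffs) else np.zeros_like(x0)
    norm = np.hypot(1.0, slope)
    nx, ny = -slope / norm, 1.0 / norm

    offsets = rng.normal(0.0, spec.sigma_true_nm, n_signal) if spec.sigma_true_nm > 0 else np.zeros(n_signal)
    x = x0 + offsets * nx
    y = y0 + offsets * ny

    precisions = _draw_precisions(
        rng, n_signal, spec.precision_mean_nm, spec.precision_sd_nm
    )
    x = x + rng.normal(0.0, 1.0, n_signal) * precisions
    y = y + rng.normal(0.0, 1.0, n_signal) * precisions

    # uniform background over the padded bounding box of the structure
    pad = 4.0 * spec.sigma_true_nm + 4.0 * spec.precision_mean_nm + 50.0
    bx = (xc.min() - pad, xc.max() + pad)
    by = (yc.min() - pad, yc.max() + pad)
    area_um2 = (bx[1] - bx[0]) * (by[1] - by[0]) / 1e6
    n_bg = int(rng.poisson(spec.background_per_um2 * area_um2))
    xb = rng.uniform(bx[0], bx[1], n_bg)
    yb = rng.uniform(by[0], by[1], n_bg)
    pb = _draw_precisions(rng, n_bg, spec.precision_mean_nm, spec.precision_sd_nm)

    n_total = n_signal + n_bg
    frames = rng.integers(0, spec.n_frames, n_total)
    table = LocalizationTable(
        frame=frames,
        x_nm=np.concatenate([x, xb]),
        y_nm=np.concatenate([y, yb]),
        precision_nm=np.concatenate([precisions, pb]),
    )
    truth = SceneGroundTruth(
        sigma_true_nm=spec.sigma_true_nm,
        fwhm_true_nm=FWHM_FACTOR * spec.sigma_true_nm,
        centerline_coeffs=tuple(spec.centerline_coeffs),
        x_domain_nm=spec.x_domain_nm,
        n_signal=n_signal,
        n_background=n_bg,
    )
    return table, truth


# --------------------------------------------------------------------------
# branched network images
# --------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """A planar filament network to rasterize as a binary-ready image.

    Nodes are nm coordinates; edges are (i, j, width_nm) ribbons.  The
    ground-truth branch decomposition merges pass-through (degree-2) nodes,
    mirroring the skeleton-side definition of a branch as a maximal segment
    between endpoints/junctions.
    """

    nodes: list[tuple[float, float]]
    edges: list[tuple[int, int, float]]
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    margin_nm: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.nodes)
        for i, j, w in self.edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("edge references missing node")
            if w <= 0:
                raise ValueError("edge width must be > 0")
        pts = np.asarray(self.nodes, dtype=float)
        if len(pts) > 1:
            from scipy.spatial.distance import pdist

            if pdist(pts).min() < self.pixel_size_nm:
                raise ValueError("two nodes closer than one pixel (degenerate)")


def _merge_degree2(spec: NetworkSpec) -> list[list[int]]:
    """Ground-truth branches as node chains after merging degree-2 nodes."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(spec.nodes)))
    for i, j, _ in spec.edges:
        g.add_edge(i, j)
    terminal = {n for n in g.nodes if g.degree[n] != 2}
    chains: list[list[int]] = []
    seen_edges: set[frozenset] = set()
    for t in sorted(terminal):
        for nb in sorted(g.neighbors(t)):
            if frozenset((t, nb)) in seen_edges:
                continue
            chain = [t, nb]
            seen_edges.add(frozenset((t, nb)))
            prev, cur = t, nb
            while cur not in terminal:
                nxt = [q for q in g.neighbors(cur) if q != prev][0]
                seen_edges.add(frozenset((cur, nxt)))
                chain.append(nxt)
                prev, cur = cur, nxt
            chains.append(chain)
    # cycles of pure degree-2 nodes would be missed; the generators here
    # only build trees, so assert rather than handle
    assert len(seen_edges) == g.number_of_edges()
    return chains


def simulate_network_image(
    spec: NetworkSpec,
) -> tuple[RenderedImage, SceneGroundTruth]:
    """Rasterize the network as foreground ribbons of the stated widths.

    A pixel is foreground when its center lies within width/2 of an edge
    segment.  Truth records the branch count after degree-2 merging and the
    per-branch polyline arc lengths in nm.
    """
    pts = np.asarray(spec.nodes, dtype=float)
    p = spec.pixel_size_nm
    x_min = pts[:, 0].min() - spec.margin_nm
    y_min = pts[:, 1].min() - spec.margin_nm
    n_cols = int(np.ceil((pts[:, 0].max() + spec.margin_nm - x_min) / p))
    n_rows = int(np.ceil((pts[:, 1].max() + spec.margin_nm - y_min) / p))
    cx = x_min + (np.arange(n_cols) + 0.5) * p
    cy = y_min + (np.arange(n_rows) + 0.5) * p
    gx, gy = np.meshgrid(cx, cy)

    img = np.zeros((n_rows, n_cols), dtype=float)
    for i, j, w in spec.edges:
        a, b = pts[i], pts[j]
        ab = b - a
        L2 = float(ab @ ab)
        t = np.clip(((gx - a[0]) * ab[0] + (gy - a[1]) * ab[1]) / L2, 0.0, 1.0)
        dx = gx - (a[0] + t * ab[0])
        dy = gy - (a[1] + t * ab[1])
        img[np.hypot(dx, dy) <= w / 2.0] = 1.0

    chains = _merge_degree2(spec)
    lengths = [
        float(
            sum(
                np.hypot(*(pts[c[k + 1]] - pts[c[k]]))
                for k in range(len(c) - 1)
            )
        )
        for c in chains
    ]
    truth = SceneGroundTruth(
        branch_count=len(chains),
        branch_lengths_nm=lengths,
    )
    image = RenderedImage(
        pixels=img, pixel_size_nm=p, origin_nm=(x_min, y_min), mode="counts"
    )
    return image, truth


def random_network_spec(
    n_edges: int = 12,
    seed: int = 0,
    edge_length_nm: tuple[float, float] = (220.0, 420.0),
    edge_width_nm: float = 40.0,
    min_angle_deg: float = 70.0,
    min_clearance_nm: float = 140.0,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    max_tries: int = 4000,
    max_restarts: int = 8,
) -> NetworkSpec:
    """Grow a random planar tree with well-separated, resolvable geometry.

    New edges sprout from existing nodes with junction angles of at least
    ``min_angle_deg`` and a clearance of ``min_clearance_nm`` to all
    non-incident segments, so rasterization at the stated ribbon width can
    neither fuse distinct branches nor displace junctions by more than a
    pixel or two.  A growth dead-end restarts with a derived sub-seed
    (still deterministic in ``seed``); only ``max_restarts`` consecutive
    dead-ends raise.
    """
    for restart in range(max_restarts):
        try:
            return _grow_network(
                n_edges,
                seed + 1_000_003 * restart,
                edge_length_nm,
                edge_width_nm,
                min_angle_deg,
                min_clearance_nm,
                pixel_size_nm,
                max_tries,
                seed,
            )
        except RuntimeError:
            continue
    raise RuntimeError("could not grow a non-degenerate network")


def _grow_network(
    n_edges: int,
    grow_seed: int,
    edge_length_nm: tuple[float, float],
    edge_width_nm: float,
    min_angle_deg: float,
    min_clearance_nm: float,
    pixel_size_nm: float,
    max_tries: int,
    spec_seed: int,
) -> NetworkSpec:
    rng = np.random.default_rng(grow_seed)
    nodes: list[np.ndarray] = [np.zeros(2)]
    edges: list[tuple[int, int, float]] = []
    directions: dict[int, list[float]] = {0: []}

    def seg_dist(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
        """Minimum distance between segments ab and cd (sampled)."""
        t = np.linspace(0, 1, 25)
        pa = a[None, :] + t[:, None] * (b - a)[None, :]
        pc = c[None, :] + t[:, None] * (d - c)[None, :]
        diff = pa[:, None, :] - pc[None, :, :]
        return float(np.sqrt((diff**2).sum(-1)).min())

    def angle_ok(src: int, ang: float) -> bool:
        return all(
            min(abs(ang - a0), 2 * np.pi - abs(ang - a0))
            >= np.deg2rad(min_angle_deg)
            for a0 in directions[src]
        )

    def clearance_ok(src: int, new: np.ndarray) -> bool:
        for (i, j, _w) in edges:
            if src in (i, j):
                continue
            if seg_dist(nodes[src], new, nodes[i], nodes[j]) < min_clearance_nm:
                return False
        for k, nd in enumerate(nodes):
            if k == src:
                continue
            if seg_dist(nd, nd, nodes[src], new) < min_clearance_nm:
                return False
        return True

    def try_sprout(src: int) -> bool:
        ang = float(rng.uniform(0, 2 * np.pi))
        if not angle_ok(src, ang):
            return False
        length = float(rng.uniform(*edge_length_nm))
        new = nodes[src] + length * np.array([np.cos(ang), np.sin(ang)])
        if not clearance_ok(src, new):
            return False
        idx = len(nodes)
        nodes.append(new)
        edges.append((src, idx, edge_width_nm))
        directions[src].append(ang)
        directions[idx] = [float(np.arctan2(*(nodes[src] - new)[::-1]))]
        return True

    # Grow so that no node is left at degree 2 (branches in the truth graph
    # then coincide with single edges): leaves sprout two edges (becoming
    # 3-way junctions; the second sprout is owed until it succeeds) and
    # existing 3-way junctions may take a fourth edge.
    tries = 0
    pending: int | None = None
    while len(edges) < n_edges:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not grow a non-degenerate network")
        if not edges:
            try_sprout(0)
            continue
        if pending is not None:
            if try_sprout(pending):
                pending = None
            continue
        remaining = n_edges - len(edges)
        junctions = [k for k, d in directions.items() if len(d) == 3]
        leaves = [k for k, d in directions.items() if len(d) == 1]
        grow_junction = junctions and (remaining == 1 or rng.random() < 0.3)
        if grow_junction:
            try_sprout(int(rng.choice(junctions)))
        elif remaining >= 2 and leaves:
            src = int(rng.choice(leaves))
            if try_sprout(src):
                pending = src
        elif leaves:
            # last edge with no junction available (tiny trees only):
            # a single sprout at a leaf; the truth graph merges the
            # resulting pass-through node into one bent branch
            try_sprout(int(rng.choice(leaves)))
    return NetworkSpec(
        nodes=[tuple(nd) for nd in nodes],
        edges=edges,
        pixel_size_nm=pixel_size_nm,
        seed=spec_seed,
    )


# --------------------------------------------------------------------------
# drift
# --------------------------------------------------------------------------

def linear_drift(
    n_frames: int, total_dx_nm: float, total_dy_nm: float = 0.0
) -> np.ndarray:
    """Per-frame (dx, dy) drift growing linearly from 0 to the stated total."""
    t = np.linspace(0.0, 1.0, n_frames)
    return np.column_stack([t * total_dx_nm, t * total_dy_nm])


def inject_drift(
    table: LocalizationTable, drift_nm: np.ndarray
) -> tuple[LocalizationTable, SceneGroundTruth]:
    """Shift every event by its frame's (dx, dy) drift.

    ``drift_nm`` has shape (n_frames, 2) and must cover every frame index
    present in the table.
    """
    drift_nm = np.asarray(drift_nm, dtype=float)
    if drift_nm.ndim != 2 or drift_nm.shape[1] != 2:
        raise ValueError("drift must have shape (n_frames, 2)")
    if table.frame.max(initial=0) >= len(drift_nm):
        raise ValueError("drift trajectory does not cover all frames")
    shifted = LocalizationTable(
        frame=table.frame.copy(),
        x_nm=table.x_nm + drift_nm[table.frame, 0],
        y_nm=table.y_nm + drift_nm[table.frame, 1],
        precision_nm=table.precision_nm.copy(),
        photons=None if table.photons is None else table.photons.copy(),
    )
    return shifted, SceneGroundTruth(drift_nm=drift_nm)


# --------------------------------------------------------------------------
# force curves
# --------------------------------------------------------------------------

def simulate_force_curve(
    E_true_pa: float,
    geometry: str = "cone",
    alpha_deg: float = 35.0,
    nu: float = 0.5,
    noise_sd_nN: float = 0.0,
    max_force_nN: float = 0.5,
    contact_point_nm: float = 0.0,
    pre_contact_nm: float = 200.0,
    n_samples: int = 400,
    seed: int = 0,
) -> tuple[ForceCurve, SceneGroundTruth]:
    """Hertz forward model plus additive Gaussian force noise.

    The position axis runs from ``contact_point_nm - pre_contact_nm``
    (flat baseline) to the depth where the noiseless force reaches
    ``max_force_nN``.
    """
    if E_true_pa <= 0:
        raise ValueError("E_true_pa must be > 0")
    rng = np.random.default_rng(seed)
    f1 = float(hertz_force(1.0, E_true_pa, geometry, alpha_deg, nu))
    delta_max = float(np.sqrt(max_force_nN / f1))
    z = np.linspace(contact_point_nm - pre_contact_nm,
                    contact_point_nm + delta_max, n_samples)
    F = hertz_force(z - contact_point_nm, E_true_pa, geometry, alpha_deg, nu)
    if noise_sd_nN > 0:
        F = F + rng.normal(0.0, noise_sd_nN, n_samples)
    curve = ForceCurve(position_nm=z, force_nN=F)
    truth = SceneGroundTruth(E_pa=E_true_pa, contact_point_nm=contact_point_nm)
    return curve, truth


# --------------------------------------------------------------------------
# myotube / nuclei masks
# --------------------------------------------------------------------------

def _category(n: int) -> str:
    if n <= 2:
        return "2"
    if n <= 5:
        return "3-5"
    return ">5"


def generate_myotube_masks(
    n_nuclei: int,
    myotube_assignment: Sequence[int],
    n_desmin_pos_cells: int,
    seed: int = 0,
    pixel_size_um: float = 0.64,
) -> tuple["LabeledMasks", SceneGroundTruth]:
    """Build non-overlapping nuclei + desmin label masks with known indices.

    ``myotube_assignment`` lists nuclei per myotube (each >= 2);
    ``n_desmin_pos_cells`` mononucleated desmin-positive cells get one
    nucleus each; remaining nuclei sit on background.  Ground truth:

    - differentiation index = (myotubes + mononucleated desmin cells) / nuclei
    - fusion index = nuclei inside >= 2-nuclei myotubes / nuclei
    - nuclei-per-myotube histogram over the categories {2, 3-5, >5}.
    """
    from nanometrics.myotube import LabeledMasks

    myotube_assignment = list(myotube_assignment)
    if any(m < 2 for m in myotube_assignment):
        raise ValueError("each myotube must contain at least 2 nuclei")
    n_fused = sum(myotube_assignment)
    if n_fused + n_desmin_pos_cells > n_nuclei:
        raise ValueError("assigned nuclei exceed the total nucleus count")
    if n_nuclei <= 0:
        raise ValueError("need at least one nucleus")

    rng = np.random.default_rng(seed)
    nuc_r = 5          # nucleus radius, px
    spacing = 16       # nucleus center spacing inside a myotube, px
    tube_h = 18        # myotube rectangle height, px
    cell_half = 9      # mononucleated desmin cell half-size, px
    row_gap = 8

    widest = max([m * spacing + spacing for m in myotube_assignment], default=0)
    n_loose = n_nuclei - n_fused - n_desmin_pos_cells
    grid_cols = 10
    width = max(widest, grid_cols * (2 * cell_half + 6)) + 20
    rows_needed = (
        len(myotube_assignment) * (tube_h + row_gap)
        + int(np.ceil(n_desmin_pos_cells / grid_cols)) * (2 * cell_half + 6)
        + int(np.ceil(n_loose / grid_cols)) * (2 * nuc_r + 8)
        + 60
    )
    nuclei = np.zeros((rows_needed, width), dtype=np.int32)
    desmin = np.zeros_like(nuclei)

    yy, xx = np.mgrid[: 2 * nuc_r + 1, : 2 * nuc_r + 1]
    disk = (yy - nuc_r) ** 2 + (xx - nuc_r) ** 2 <= nuc_r**2

    def stamp_nucleus(label: int, r: int, c: int) -> None:
        nuclei[r - nuc_r : r + nuc_r + 1, c - nuc_r : c + nuc_r + 1][disk] = label

    nucleus_label = 0
    desmin_label = 0
    nucleus_to_desmin: dict[int, int | None] = {}
    y = 10
    for count in myotube_assignment:
        desmin_label += 1
        tube_len = count * spacing + spacing
        x0 = 10 + int(rng.integers(0, max(width - tube_len - 20, 1)))
        desmin[y : y + tube_h, x0 : x0 + tube_len] = desmin_label
        cy = y + tube_h // 2
        for k in range(count):
            nucleus_label += 1
            cx = x0 + spacing // 2 + nuc_r + k * spacing
            stamp_nucleus(nucleus_label, cy, cx)
            nucleus_to_desmin[nucleus_label] = desmin_label
        y += tube_h + row_gap
    y += 10
    for k in range(n_desmin_pos_cells):
        desmin_label += 1
        r = y + (k // grid_cols) * (2 * cell_half + 6) + cell_half
        c = 10 + (k % grid_cols) * (2 * cell_half + 6) + cell_half
        desmin[r - cell_half : r + cell_half, c - cell_half : c + cell_half] = (
            desmin_label
        )
        nucleus_label += 1
        stamp_nucleus(nucleus_label, r, c)
        nucleus_to_desmin[nucleus_label] = desmin_label
    y += int(np.ceil(n_desmin_pos_cells / grid_cols)) * (2 * cell_half + 6) + 12
    for k in range(n_loose):
        nucleus_label += 1
        r = y + (k // grid_cols) * (2 * nuc_r + 8) + nuc_r + 1
        c = 10 + (k % grid_cols) * (2 * nuc_r + 8) + nuc_r + 1
        stamp_nucleus(nucleus_label, r, c)
        nucleus_to_desmin[nucleus_label] = None

    n_myotubes = len(myotube_assignment)
    hist = {"2": 0, "3-5": 0, ">5": 0}
    for m in myotube_assignment:
        hist[_category(m)] += 1
    truth = SceneGroundTruth(
        differentiation_index=(n_myotubes + n_desmin_pos_cells) / n_nuclei,
        fusion_index=n_fused / n_nuclei,
        nuclei_per_myotube=myotube_assignment,
        nuclei_category_hist=hist,
        nucleus_to_desmin=nucleus_to_desmin,
        n_nuclei=n_nuclei,
    )
    masks = LabeledMasks(
        nuclei=nuclei, desmin=desmin, pixel_size_um=pixel_size_um
    )
    return masks, truth
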