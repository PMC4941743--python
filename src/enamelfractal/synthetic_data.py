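"""Ground-truth fixtures: fractal curves, random trees, trait simulations.

Everything the pipeline consumes can be generated here with a known
answer attached: planar curves of analytic fractal dimension rasterized
to one-pixel-wide binary traces (for validating the box-counting
estimator), pure-birth trees, and trait data simulated under the exact
covariance model the PGLS assumes (Brownian residuals scaled by a chosen
Pagel's lambda).  The published species summary table of the equid study
(35 species, 98 teeth) ships as a packaged CSV fixture for the desk
reconstructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .comparative_stats import ComparativeDataset, lambda_transform
from .phylo import phylo_covariance
from .trace_io import RasterTrace, SpeciesSummary

#: analytic box-counting dimensions of the generator curves
ANALYTIC_D = {
    "line": 1.0,
    "filled_box": 2.0,
    "koch": math.log(4) / math.log(3),  # ~1.2619
    "quadric_koch": 1.5,  # Minkowski sausage: log 8 / log 4
    "sierpinski": math.log(3) / math.log(2),  # ~1.5850
}

# L-system definitions: (axiom, rules, turn angle in degrees, per-iteration
# linear scale factor of the curve's extent in unit steps)
_LSYSTEMS = {
    "koch": ("F", {"F": "F+F--F+F"}, 60.0, 3),
    "quadric_koch": ("F", {"F": "F+F-F-FF+F+F-F"}, 90.0, 4),
    "sierpinski": ("A", {"A": "B-A-B", "B": "A+B+A"}, 60.0, 2),
}


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic curve raster."""

    kind: str  # line | filled_box | koch | quadric_koch | sierpinski
    iterations: int = 4
    raster_px: int = 512
    angle: float = 0.0  # line orientation, degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ANALYTIC_D:
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.raster_px < 64:
            raise ValueError("raster_px must be >= 64")


@dataclass
class SimulatedCohort:
    """A complete synthetic study: tree, species truth, specimen draws."""

    tree: dendropy.Tree
    species: pd.DataFrame  # taxon, tribe, true_mean_D, true_mean_area
    specimens: pd.DataFrame  # specimen_id, taxon, tribe, tooth_position, area_cm2, D
    params: dict


def _expand_lsystem(axiom: str, rules: dict[str, str], iterations: int) -> str:
    s = axiom
    for _ in range(iterations):
        s = "".join(rules.get(c, c) for c in s)
    return s


def _turtle_path(program: str, turn_deg: float) -> np.ndarray:
    """Trace an L-system string; F/A/B draw a unit step, +/- turn."""
    heading = 0.0
    x = y = 0.0
    pts = [(0.0, 0.0)]
    for c in program:
        if c in "FAB":
            x += math.cos(math.radians(heading))
            y += math.sin(math.radians(heading))
            pts.append((x, y))
        elif c == "+":
            heading += turn_deg
        elif c == "-":
            heading -= turn_deg
    return np.array(pts)


def _bresenham(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    """Integer line rasterization (8-connected, no anti-aliasing)."""
    pts = []
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dc - dr
    r, c = r0, c0
    while True:
        pts.append((r, c))
        if r == r1 and c == c1:
            break
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr
    return pts


def _rasterize_polyline(verts: np.ndarray, raster_px: int) -> np.ndarray:
    """Scale a polyline into a raster_px-wide canvas and draw it 1 px wide."""
    mins = verts.min(axis=0)
    extent = verts.max(axis=0) - mins
    span = float(extent.max())
    if span == 0:
        raise ValueError("degenerate polyline")
    margin = 2
    scale = (raster_px - 1 - 2 * margin) / span
    # a unit step must resolve to at least one pixel
    seg = np.sqrt(((verts[1:] - verts[:-1]) ** 2).sum(axis=1))
    if seg.size and float(seg.min()) * scale < 1.0:
        raise ValueError(
            "raster too small to resolve the requested iteration depth "
            f"(minimum feature {seg.min() * scale:.2f} px < 1 px)"
        )
    xy = (verts - mins) * scale + margin
    h = int(math.ceil((extent[1]) * scale)) + 2 * margin + 1
    img = np.zeros((max(h, 2), raster_px), dtype=np.uint8)
    cols = np.round(xy[:, 0]).astype(int)
    rows = np.round(xy[:, 1]).astype(int)
    for i in range(len(xy) - 1):
        for r, c in _bresenham(rows[i], cols[i], rows[i + 1], cols[i + 1]):
            img[r, c] = 1
    return img


def generate_curve(spec: GeneratorSpec) -> tuple[RasterTrace, float]:
    """Build a binary raster of a curve with known fractal dimension.

    Returns the trace and its analytic D: 1 for a line, 2 for a filled
    region, log4/log3 for the Koch curve, 3/2 for the quadric Koch
    (Minkowski sausage), log3/log2 for the Sierpinski arrowhead.
    Construction is deterministic (seed-free) and bit-stable.
    """
    n = spec.raster_px
    if spec.kind == "line":
        ang = math.radians(spec.angle)
        half = (n - 5) / 2.0
        verts = np.array(
            [
                [-half * math.cos(ang), -half * math.sin(ang)],
                [half * math.cos(ang), half * math.sin(ang)],
            ]
        )
        img = _rasterize_polyline(verts, n)
    elif spec.kind == "filled_box":
        img = np.ones((n, n), dtype=np.uint8)
    else:
        axiom, rules, turn, _ = _LSYSTEMS[spec.kind]
        program = _expand_lsystem(axiom, rules, spec.iterations)
        verts = _turtle_path(program, turn)
        img = _rasterize_polyline(verts, n)
    trace = RasterTrace(img, specimen_id=f"{spec.kind}_i{spec.iterations}_{n}px")
    return trace, ANALYTIC_D[spec.kind]


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Simulate a pure-birth (Yule) tree with ``n_tips`` extant tips.

    Waiting times between splits are exponential with rate
    ``birth_rate * k`` for k extant lineages; the lineage that splits is
    chosen uniformly.  The tree is ultrametric with all tips at the
    final simulation time.  Reproducible under ``seed``.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True

    birth_time = {tree.seed_node: 0.0}
    tips = [tree.seed_node]
    t = 0.0
    while len(tips) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        node = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            child = node.new_child()
            birth_time[child] = t
            tips.append(child)
    t += rng.exponential(1.0 / (birth_rate * n_tips))  # stem to the present

    for i, node in enumerate(tips):
        node.taxon = taxa.new_taxon(f"t{i + 1}")
    # edge length = span from a node's own birth to its split (or the present)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        else:
            end = t if node.is_leaf() else birth_time[node.child_nodes()[0]]
            node.edge.length = float(end - birth_time[node])
    return tree


def simulate_traits(
    tree: dendropy.Tree,
    lam: float = 1.0,
    slope: float = 0.0,
    intercept: float = 1.4,
    sigma2: float = 0.01,
    seed: int = 0,
    x_range: tuple[float, float] = (2.0, 9.0),
) -> ComparativeDataset:
    """Draw species traits under the PGLS generating model.

    x (area, cm^2) is independent uniform per tip on ``x_range`` (the
    span of occlusal areas seen in equids); y = intercept + slope*x + e
    with e ~ MVN(0, sigma2 * V(lambda)) where V is the tree covariance.
    """
    rng = np.random.default_rng(seed)
    V = phylo_covariance(tree)
    Vl = lambda_transform(V, lam).V
    n = len(V.taxa)
    x = rng.uniform(*x_range, size=n)
    L = np.linalg.cholesky(sigma2 * Vl + 1e-12 * np.eye(n))
    eps = L @ rng.standard_normal(n)
    y = intercept + slope * x + eps
    return ComparativeDataset(taxa=list(V.taxa), x=x, y=y)


def simulate_cohort(
    n_species: int = 20,
    specimens_per_species: int = 3,
    lam: float = 0.0,
    slope: float = -0.016,
    intercept: float = 1.45,
    sigma2: float = 0.002,
    noise_sd: float = 0.05,
    birth_rate: float = 0.25,
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate a full study: tree, species means, noisy specimens.

    Species-mean D follows the PGLS model on a simulated tree; each
    species then contributes ``specimens_per_species`` teeth whose D is
    the species mean plus Gaussian within-species noise (default SD
    0.05, the median within-species dispersion of the published equid
    sample).  Tribes are assigned by the root split of the tree.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_species, birth_rate=birth_rate, seed=seed)
    data = simulate_traits(
        tree, lam=lam, slope=slope, intercept=intercept, sigma2=sigma2,
        seed=seed + 1,
    )
    # tribe = which side of the root split the tip descends from
    root_kids = tree.seed_node.child_nodes()
    side_a = {lf.taxon.label for lf in root_kids[0].leaf_iter()}
    tribes = ["Hipparionini" if t in side_a else "Equini" for t in data.taxa]

    species = pd.DataFrame(
        {
            "taxon": data.taxa,
            "tribe": tribes,
            "true_mean_D": data.y,
            "true_mean_area": data.x,
        }
    )
    rows = []
    positions = ("P3", "P4", "M1", "M2")
    k = 0
    for taxon, tribe, mu_d, mu_a in species.itertuples(index=False):
        for _ in range(specimens_per_species):
            k += 1
            rows.append(
                {
                    "specimen_id": f"S{k:04d}",
                    "taxon": taxon,
                    "tribe": tribe,
                    "tooth_position": positions[int(rng.integers(4))],
                    "area_cm2": max(float(mu_a + rng.normal(0, 0.3)), 0.1),
                    "D": float(mu_d + rng.normal(0, noise_sd)),
                }
            )
    specimens = pd.DataFrame(rows)
    params = {
        "lambda": lam,
        "slope": slope,
        "intercept": intercept,
        "sigma2": sigma2,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return SimulatedCohort(tree=tree, species=species, specimens=specimens, params=params)


def table1_fixture() -> list[SpeciesSummary]:
    """The packaged equid species-summary table (35 species, 98 teeth).

    Per-species sample sizes, means and SDs of fractal dimensionality
    and occlusal area as published for the Hipparionini/Equini sample;
    missing entries (singletons' SDs, species without measured areas)
    are ``None``.
    """
    with resources.files("enamelfractal.data").joinpath(
        "species_summaries.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            SpeciesSummary(
                taxon=r.taxon,
                tribe=r.tribe,
                n_D=int(r.n_D),
                mean_D=float(r.mean_D),
                sd_D=None if pd.isna(r.sd_D) else float(r.sd_D),
                n_area=int(r.n_area),
                mean_area=None if pd.isna(r.mean_area) else float(r.mean_area),
                sd_area=None if pd.isna(r.sd_area) else float(r.sd_area),
            )
        )
    return out
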