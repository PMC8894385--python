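"""Synthetic inputs for every pipeline stage.

Vascular smooth muscle cells (VSMCs) switch between an elongated,
spindle-shaped *contractile* state and a rounded, rhomboid *synthetic*
state.  This module fabricates the raw material the rest of the package
consumes, with known ground truth at every level:

* two-channel well images (nucleus stain + whole-cell-body stain) built
  from elliptical cells whose true semi-axes — hence true elongation E
  and cell shape index CSI — are recorded per cell;
* multi-replicate plate designs for a miRNA over-expression screen;
* negative-binomial miRNA count matrices with a planted differentially
  expressed fraction;
* miRNA→target, protein–protein interaction and drug–gene fixture
  tables with planted k-way target sharing and planted hub cliques.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely.affinity
from scipy import ndimage
from scipy.special import ellipe
from shapely.geometry import Point

__all__ = [
    "CellSpec",
    "PhenotypeGeometry",
    "WellPlan",
    "PlateDesign",
    "CountSimConfig",
    "FixturePlan",
    "ellipse_perimeter",
    "true_csi",
    "sample_well_truth",
    "sample_cell_specs",
    "render_well",
    "generate_plate",
    "simulate_counts",
    "generate_fixtures",
]


# ---------------------------------------------------------------------------
# cell geometry


@dataclass(frozen=True)
class CellSpec:
    """One elliptical cell: center (x, y) in px, semi-axes in px,
    orientation in radians (counter-clockwise from the x axis)."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float = 0.0
    body_intensity: float = 160.0
    nucleus_scale: float = 0.45

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError(
                f"require semi_major >= semi_minor > 0, got "
                f"({self.semi_major}, {self.semi_minor})"
            )
        if not (0 < self.nucleus_scale < 1):
            raise ValueError("nucleus_scale must be in (0, 1)")

    @property
    def elongation(self) -> float:
        return self.semi_major / self.semi_minor

    @property
    def csi(self) -> float:
        return true_csi(self.semi_major, self.semi_minor)


def ellipse_perimeter(semi_major: float, semi_minor: float) -> float:
    """Exact ellipse perimeter via the complete elliptic integral."""
    a, b = float(semi_major), float(semi_minor)
    if not (a >= b > 0):
        raise ValueError("require semi_major >= semi_minor > 0")
    return 4.0 * a * float(ellipe(1.0 - (b / a) ** 2))


def true_csi(semi_major: float, semi_minor: float) -> float:
    """Cell shape index 4π·area/perimeter² of an ideal ellipse (1 for a circle)."""
    area = math.pi * semi_major * semi_minor
    perim = ellipse_perimeter(semi_major, semi_minor)
    return min(1.0, 4.0 * math.pi * area / perim**2)


@dataclass(frozen=True)
class PhenotypeGeometry:
    """Sampling distributions for the two morphological classes.

    Contractile cells are long spindles: aspect ratios uniform in
    (6.5, 10), which puts their true CSI in (0.24, 0.36) — safely below
    the 0.4 classification bound.  Synthetic cells are near-round,
    aspect ratios uniform in (1, 2), true CSI in (0.84, 1.0) — safely
    above 0.6.  Both classes therefore sit with margin away from the
    decision boundaries so planted labels are unambiguous.
    """

    contractile_axis_ratio: tuple[float, float] = (6.5, 10.0)
    synthetic_axis_ratio: tuple[float, float] = (1.0, 2.0)
    semi_minor_range: tuple[float, float] = (8.0, 12.0)
    body_intensity_range: tuple[float, float] = (120.0, 220.0)
    nucleus_scale: float = 0.45


def _sample_one(
    rng: np.random.Generator, contractile: bool, geom: PhenotypeGeometry
) -> tuple[float, float]:
    lo, hi = (
        geom.contractile_axis_ratio if contractile else geom.synthetic_axis_ratio
    )
    ratio = rng.uniform(lo, hi)
    b = rng.uniform(*geom.semi_minor_range)
    return ratio * b, b


def sample_well_truth(
    n_cells: int,
    contractile_fraction: float,
    rng: np.random.Generator,
    geometry: PhenotypeGeometry | None = None,
) -> pd.DataFrame:
    """Sample per-cell true geometry and phenotype labels without placing
    cells in an image.  Used for fast, rendering-free screen simulations."""
    if not 0.0 <= contractile_fraction <= 1.0:
        raise ValueError("contractile_fraction must be in [0, 1]")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    geom = geometry or PhenotypeGeometry()
    labels = rng.random(n_cells) < contractile_fraction
    rows = []
    for i, is_con in enumerate(labels):
        a, b = _sample_one(rng, bool(is_con), geom)
        rows.append(
            {
                "cell_id": i,
                "semi_major": a,
                "semi_minor": b,
                "true_E": a / b,
                "true_csi": true_csi(a, b),
                "true_phenotype": "contractile" if is_con else "synthetic",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# placement and rendering


def _ellipse_polygon(spec: CellSpec) -> shapely.geometry.base.BaseGeometry:
    circ = Point(0.0, 0.0).buffer(1.0, quad_segs=16)
    ell = shapely.affinity.scale(circ, spec.semi_major, spec.semi_minor)
    ell = shapely.affinity.rotate(ell, math.degrees(spec.orientation))
    return shapely.affinity.translate(ell, spec.center[0], spec.center[1])


def sample_cell_specs(
    n_cells: int,
    contractile_fraction: float,
    image_size: int,
    rng: np.random.Generator,
    geometry: PhenotypeGeometry | None = None,
    max_attempts: int = 10_000,
    margin: float = 3.0,
) -> tuple[list[CellSpec], pd.DataFrame]:
    """Place ``n_cells`` mutually non-overlapping ellipses inside a square
    image by rejection sampling.

    Raises RuntimeError when a cell cannot be placed within
    ``max_attempts`` attempts (the well is too crowded for the requested
    geometry).
    """
    geom = geometry or PhenotypeGeometry()
    truth = sample_well_truth(n_cells, contractile_fraction, rng, geom)

    specs: list[CellSpec] = []
    placed: list = []
    bounds: list[tuple[float, float, float, float]] = []
    for row in truth.itertuples():
        a, b = row.semi_major, row.semi_minor
        lim = a + margin
        if 2 * lim >= image_size:
            raise ValueError(
                f"image_size={image_size} too small for a cell with "
                f"semi_major={a:.1f}"
            )
        for _ in range(max_attempts):
            cx = rng.uniform(lim, image_size - lim)
            cy = rng.uniform(lim, image_size - lim)
            theta = rng.uniform(0.0, math.pi)
            spec = CellSpec(
                center=(cx, cy),
                semi_major=a,
                semi_minor=b,
                orientation=theta,
                body_intensity=rng.uniform(*geom.body_intensity_range),
                nucleus_scale=geom.nucleus_scale,
            )
            poly = _ellipse_polygon(spec).buffer(margin / 2.0)
            pb = poly.bounds
            ok = True
            for other, ob in zip(placed, bounds):
                if (
                    pb[0] <= ob[2]
                    and ob[0] <= pb[2]
                    and pb[1] <= ob[3]
                    and ob[1] <= pb[3]
                    and poly.intersects(other)
                ):
                    ok = False
                    break
            if ok:
                specs.append(spec)
                placed.append(poly)
                bounds.append(pb)
                break
        else:
            raise RuntimeError(
                f"could not place cell {row.cell_id} after {max_attempts} "
                f"attempts; reduce cell count or enlarge the image"
            )

    truth = truth.copy()
    truth["x"] = [s.center[0] for s in specs]
    truth["y"] = [s.center[1] for s in specs]
    truth["orientation"] = [s.orientation for s in specs]
    return specs, truth


def _truth_from_specs(specs: list[CellSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": np.arange(len(specs)),
            "x": [s.center[0] for s in specs],
            "y": [s.center[1] for s in specs],
            "semi_major": [s.semi_major for s in specs],
            "semi_minor": [s.semi_minor for s in specs],
            "orientation": [s.orientation for s in specs],
            "true_E": [s.elongation for s in specs],
            "true_csi": [s.csi for s in specs],
        }
    )


def render_well(
    specs: list[CellSpec],
    image_size: int,
    noise_sd: float = 4.0,
    seed: int | np.random.Generator = 0,
    blur_sigma: float = 1.0,
    check_overlap: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a two-channel well image from cell specs.

    Channel 0 holds the nuclei (inner ellipses scaled by
    ``nucleus_scale``, emulating a DNA stain), channel 1 the whole cell
    bodies (emulating a lipophilic membrane stain).  Both channels get a
    Gaussian blur of ``blur_sigma`` px and additive Gaussian read noise.

    Returns ``(image, truth)`` where image is float32 of shape
    (2, image_size, image_size) and truth lists each cell's true
    semi-axes, E and CSI.
    """
    from skimage.draw import ellipse as draw_ellipse

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    for s in specs:
        cx, cy = s.center
        if (
            cx - s.semi_major < 0
            or cy - s.semi_major < 0
            or cx + s.semi_major > image_size
            or cy + s.semi_major > image_size
        ):
            raise ValueError(f"cell at {s.center} extends beyond image bounds")
    if check_overlap and len(specs) > 1:
        polys = [_ellipse_polygon(s) for s in specs]
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                if polys[i].intersects(polys[j]):
                    raise ValueError(f"cells {i} and {j} overlap")

    nuc = np.zeros((image_size, image_size), dtype=np.float32)
    body = np.zeros_like(nuc)
    for s in specs:
        cx, cy = s.center
        # skimage.draw uses (row, col) = (y, x); rotation is measured
        # against the column axis with opposite sign, hence -orientation.
        rr, cc = draw_ellipse(
            cy, cx, s.semi_minor, s.semi_major,
            shape=nuc.shape, rotation=-s.orientation,
        )
        body[rr, cc] = s.body_intensity
        rr, cc = draw_ellipse(
            cy, cx,
            s.semi_minor * s.nucleus_scale,
            s.semi_major * s.nucleus_scale,
            shape=nuc.shape, rotation=-s.orientation,
        )
        nuc[rr, cc] = s.body_intensity * 1.2

    if blur_sigma > 0:
        nuc = ndimage.gaussian_filter(nuc, blur_sigma)
        body = ndimage.gaussian_filter(body, blur_sigma)
    if noise_sd > 0:
        nuc = nuc + rng.normal(0.0, noise_sd, nuc.shape).astype(np.float32)
        body = body + rng.normal(0.0, noise_sd, body.shape).astype(np.float32)

    return np.stack([nuc, body]), _truth_from_specs(specs)


# ---------------------------------------------------------------------------
# plate designs


@dataclass(frozen=True)
class WellPlan:
    well_id: str
    condition_label: str
    replicate_id: str
    is_negative_control: bool
    n_cells: int
    contractile_fraction: float


@dataclass(frozen=True)
class PlateDesign:
    wells: tuple[WellPlan, ...]

    def __post_init__(self) -> None:
        reps: dict[str, bool] = {}
        for w in self.wells:
            if not 0.0 <= w.contractile_fraction <= 1.0:
                raise ValueError(
                    f"well {w.well_id}: contractile_fraction outside [0, 1]"
                )
            if w.n_cells <= 0:
                raise ValueError(f"well {w.well_id}: n_cells must be positive")
            reps.setdefault(w.replicate_id, False)
            if w.is_negative_control:
                reps[w.replicate_id] = True
        missing = [r for r, has in reps.items() if not has]
        if missing:
            raise ValueError(
                f"replicates without a negative control well: {missing}"
            )

    @staticmethod
    def screen(
        conditions: list[str],
        replicates: tuple[str, ...] = ("A", "B", "C"),
        n_cells: int = 450,
        control_fraction: float = 0.2,
        condition_fractions: dict[str, float] | None = None,
        default_fraction: float = 0.2,
    ) -> "PlateDesign":
        """Convenience constructor: one negative-control well plus one well
        per condition in each replicate screen."""
        fr = condition_fractions or {}
        wells = []
        for rep in replicates:
            wells.append(
                WellPlan(
                    f"{rep}_NC", "neg_control", rep, True, n_cells,
                    control_fraction,
                )
            )
            for cond in conditions:
                wells.append(
                    WellPlan(
                        f"{rep}_{cond}", cond, rep, False, n_cells,
                        fr.get(cond, default_fraction),
                    )
                )
        return PlateDesign(tuple(wells))


def generate_plate(
    design: PlateDesign,
    geometry: PhenotypeGeometry | None = None,
    seed: int = 0,
    render: bool = False,
    image_size: int = 2000,
    noise_sd: float = 4.0,
) -> dict[str, dict]:
    """Generate every well of a plate design.

    Returns ``{well_id: {"truth": DataFrame, "image": array | None,
    "plan": WellPlan}}``.  With ``render=False`` only ground-truth cell
    geometry (and per-cell true phenotype label) is produced, which is
    orders of magnitude faster and sufficient for classifier- and
    screen-level simulations.
    """
    geom = geometry or PhenotypeGeometry()
    out: dict[str, dict] = {}
    children = np.random.SeedSequence(seed).spawn(len(design.wells))
    for plan, ss in zip(design.wells, children):
        rng = np.random.default_rng(ss)
        if render:
            specs, truth = sample_cell_specs(
                plan.n_cells, plan.contractile_fraction, image_size, rng, geom
            )
            image, _ = render_well(
                specs, image_size, noise_sd=noise_sd, seed=rng,
                check_overlap=False,
            )
        else:
            truth = sample_well_truth(
                plan.n_cells, plan.contractile_fraction, rng, geom
            )
            image = None
        out[plan.well_id] = {"plan": plan, "truth": truth, "image": image}
    return out


# ---------------------------------------------------------------------------
# count simulation


@dataclass(frozen=True)
class CountSimConfig:
    """Negative-binomial miRNA count simulation: two serum conditions,
    ``n_per_group`` replicates each, a ``de_fraction`` of miRNAs shifted
    in the low-serum group by ±``effect_log2fc`` on the log2 scale."""

    n_mirnas: int = 2000
    n_per_group: int = 4
    nb_dispersion: float = 0.1
    de_fraction: float = 0.0
    effect_log2fc: float = 1.5
    mean_log_range: tuple[float, float] = (1.0, 10.0)
    libsize_range: tuple[float, float] = (0.5e6, 2e6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be positive")
        for lo, hi in (self.mean_log_range, self.libsize_range):
            if not lo < hi:
                raise ValueError("ranges must be non-degenerate (lo < hi)")
        if self.n_mirnas < 1 or self.n_per_group < 2:
            raise ValueError("need n_mirnas >= 1 and n_per_group >= 2")
        if self.de_fraction > 0 and self.de_fraction * self.n_mirnas < 1:
            raise ValueError("de_fraction too small to plant any effect")


def simulate_counts(
    config: CountSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a miRNA × sample count matrix.

    Returns ``(counts, samples, truth)``:

    * counts — integer DataFrame, rows ``mir_0001…``, columns
      ``low_1…low_n, normal_1…normal_n``;
    * samples — sample sheet with ``group`` ∈ {low_serum, normal_serum}
      and realized ``lib_size`` (column totals);
    * truth — per-miRNA planted log2 fold change (0 for nulls), low
      versus normal serum.
    """
    rng = np.random.default_rng(config.seed)
    G, n = config.n_mirnas, config.n_per_group
    mirnas = [f"mir_{i + 1:04d}" for i in range(G)]
    low = [f"low_{j + 1}" for j in range(n)]
    normal = [f"normal_{j + 1}" for j in range(n)]

    base_cpm = 2.0 ** rng.uniform(*config.mean_log_range, size=G)
    lfc = np.zeros(G)
    n_de = int(round(config.de_fraction * G))
    if n_de > 0:
        idx = rng.choice(G, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        lfc[idx] = signs * config.effect_log2fc

    lo, hi = config.libsize_range
    libs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=2 * n))

    disp = config.nb_dispersion
    nb_n = 1.0 / disp
    cols = []
    for j, lib in enumerate(libs):
        cpm = base_cpm * (2.0**lfc if j < n else 1.0)
        mu = cpm / 1e6 * lib
        p = nb_n / (nb_n + mu)
        cols.append(rng.negative_binomial(nb_n, p))
    counts = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(mirnas, name="mirna"),
        columns=low + normal,
    )
    samples = pd.DataFrame(
        {
            "sample": low + normal,
            "group": ["low_serum"] * n + ["normal_serum"] * n,
            "lib_size": counts.sum(axis=0).to_numpy(),
        }
    ).set_index("sample")
    truth = pd.DataFrame(
        {"mirna": mirnas, "planted_log2fc": lfc}
    ).set_index("mirna")
    return counts, samples, truth


# ---------------------------------------------------------------------------
# target / PPI / drug fixtures


@dataclass(frozen=True)
class FixturePlan:
    """Plan for target, interaction and drug fixture tables.

    ``planted_shared`` maps k → genes that will be targeted by exactly k
    distinct miRNAs.  ``planted_hub_cliques`` lists (mirna, genes)
    pairs: the genes are added to that miRNA's target list and wired
    into a complete clique in the interaction graph, so they dominate
    maximal-clique-centrality hub ranking for that miRNA.
    """

    mirnas: tuple[str, ...]
    gene_universe: tuple[str, ...]
    planted_shared: dict[int, tuple[str, ...]] = field(default_factory=dict)
    planted_hub_cliques: tuple[tuple[str, tuple[str, ...]], ...] = ()
    drug_rows: tuple[tuple[str, str], ...] = ()
    n_filler_per_mirna: int = 5
    # sparse enough that random edges cannot out-score a planted clique
    # in maximal-clique-centrality ranking
    ppi_background_p: float = 0.005

    def __post_init__(self) -> None:
        shared_genes: set[str] = set()
        for k, genes in self.planted_shared.items():
            if not 1 <= k <= len(self.mirnas):
                raise ValueError(f"planted_shared k={k} exceeds miRNA count")
            for g in genes:
                if g in shared_genes:
                    raise ValueError(f"gene {g} planted more than once")
                shared_genes.add(g)
        clique_genes: set[str] = set()
        for mirna, genes in self.planted_hub_cliques:
            if mirna not in self.mirnas:
                raise ValueError(f"clique miRNA {mirna} not in plan")
            # a gene MAY sit in several miRNAs' cliques (a shared hub),
            # but must not collide with the exact-k shared planting
            clique_genes.update(genes)
        collisions = shared_genes & clique_genes
        if collisions:
            raise ValueError(
                f"genes planted both as shared and as clique hubs: "
                f"{sorted(collisions)}"
            )
        unknown = (shared_genes | clique_genes) - set(self.gene_universe)
        if unknown:
            raise ValueError(f"planted genes outside gene_universe: {unknown}")


def generate_fixtures(
    plan: FixturePlan, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit (targets, ppi_edges, drugs) realizing the plan exactly.

    targets: columns (mirna, gene, evidence); the planted k-way sharing
    is exact — a gene in ``planted_shared[k]`` appears in exactly k
    target lists; filler genes are unique to one miRNA.
    ppi_edges: columns (gene_a, gene_b); planted cliques are complete;
    sparse random background edges are added among non-clique genes.
    drugs: columns (drug, gene), realizing ``drug_rows``.
    """
    rng = np.random.default_rng(seed)
    evidence_levels = ("predicted", "weak_validated", "strong_validated")
    rows: list[tuple[str, str, str]] = []
    planted: set[str] = set()

    for k in sorted(plan.planted_shared):
        for gene in plan.planted_shared[k]:
            planted.add(gene)
            chosen = rng.choice(len(plan.mirnas), size=k, replace=False)
            for i in sorted(chosen):
                rows.append(
                    (plan.mirnas[i], gene, evidence_levels[rng.integers(3)])
                )

    clique_nodes: set[str] = set()
    clique_rows: set[tuple[str, str]] = set()
    for mirna, genes in plan.planted_hub_cliques:
        for gene in genes:
            planted.add(gene)
            clique_nodes.add(gene)
            if (mirna, gene) not in clique_rows:
                clique_rows.add((mirna, gene))
                rows.append((mirna, gene, evidence_levels[rng.integers(3)]))

    pool = [g for g in plan.gene_universe if g not in planted]
    rng.shuffle(pool)
    need = plan.n_filler_per_mirna * len(plan.mirnas)
    if len(pool) < need:
        raise ValueError("gene_universe too small for requested filler genes")
    it = iter(pool)
    filler_used: list[str] = []
    for mirna in plan.mirnas:
        for _ in range(plan.n_filler_per_mirna):
            g = next(it)
            filler_used.append(g)
            rows.append((mirna, g, "predicted"))

    targets = pd.DataFrame(rows, columns=["mirna", "gene", "evidence"])

    edges: set[tuple[str, str]] = set()
    for _, genes in plan.planted_hub_cliques:
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                edges.add(tuple(sorted((genes[i], genes[j]))))
    background = sorted(set(targets["gene"]) - clique_nodes)
    for i in range(len(background)):
        for j in range(i + 1, len(background)):
            if rng.random() < plan.ppi_background_p:
                edges.add((background[i], background[j]))
    ppi = pd.DataFrame(sorted(edges), columns=["gene_a", "gene_b"])

    drugs = pd.DataFrame(list(plan.drug_rows), columns=["drug", "gene"])
    return targets, ppi, drugs
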