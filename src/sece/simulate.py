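"""Synthetic spatial-transcriptomics fixtures with known domain structure.

The generator lays spots on a square/hex lattice or uniformly at random,
partitions them into spatially contiguous domains (horizontal layers,
concentric rings or Voronoi patches), assigns each domain an expression
program, and draws counts from an NB or ZINB model:

* every gene has a baseline log-mean drawn from a normal distribution
  (log-normal spread of gene abundances);
* each program up-regulates its own marker block (10% of genes by
  default) by ``effect_size`` on the log scale;
* relative expression per domain is the softmax of the log-means;
  per-spot means are relative expression times a log-uniform library
  size; counts are NB with dispersion ``r`` (mean m, variance
  m + m^2/r), optionally zeroed with probability ``pi`` (ZINB).

The named presets mimic the sparsity regimes of the common platforms at
desk scale — an in-situ "starmap-like" slide (~77% zeros), a hexagonal
"visium-like" array (~77% zeros) and a highly sparse bead-based
"slideseq-like" slide (~98% zeros, zero-inflated) — with gene counts
scaled down so the whole pipeline runs in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import CountMatrix, CoordinateTable, DomainLabeling

GEOMETRIES = ("horizontal-layers", "concentric-rings", "voronoi-patches")
GRIDS = ("square", "hex", "uniform-random")

#: fraction of genes acting as markers for each program
MARKER_FRACTION = 0.1


@dataclass(frozen=True)
class FixtureSpec:
    geometry: str = "horizontal-layers"
    n_spots: int = 1000
    grid: str = "square"
    n_domains: int = 4
    n_genes: int = 500
    n_programs: int | None = None
    effect_size: float = 2.0
    family: str = "nb"
    dispersion: float = 2.0
    zero_inflation: float = 0.0
    library_size_range: tuple[float, float] = (300.0, 900.0)
    gene_logmean_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.grid not in GRIDS:
            raise ValueError(f"unknown grid {self.grid!r}")
        if self.n_domains < 2:
            raise ValueError("n_domains must be >= 2")
        if self.n_domains > self.n_spots:
            raise ValueError("more domains than spots")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library sizes must be positive with low <= high")
        if self.family not in ("nb", "zinb"):
            raise ValueError(f"unknown family {self.family!r}")


def _coordinates(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_spots
    # ring domains are radius bands, so the support must be a disk —
    # on a square support the outermost band degenerates into corner patches
    disk = spec.geometry == "concentric-rings"
    if spec.grid == "uniform-random":
        if disk:
            r = 0.5 * np.sqrt(rng.uniform(0.0, 1.0, size=n))
            theta = rng.uniform(0.0, 2 * np.pi, size=n)
            return 0.5 + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        return rng.uniform(0.0, 1.0, size=(n, 2))
    n_grid = int(np.ceil(n * 4 / np.pi)) + 8 if disk else n
    ncol = int(np.ceil(np.sqrt(n_grid)))
    rows, cols = np.divmod(np.arange(n_grid), ncol)
    x = cols.astype(float)
    y = rows.astype(float)
    if spec.grid == "hex":
        x = x + 0.5 * (rows % 2)       # offset alternate rows
        y = y * (np.sqrt(3.0) / 2.0)
    pts = np.column_stack([x, y])
    if disk:
        center = pts.mean(axis=0)
        keep = np.argsort(np.linalg.norm(pts - center, axis=1), kind="stable")[:n]
        pts = pts[np.sort(keep)]
    span = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]), 1.0)
    return pts / span


def _domain_labels(spec: FixtureSpec, coords: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    k = spec.n_domains
    if spec.geometry == "horizontal-layers":
        score = coords[:, 1]
    elif spec.geometry == "concentric-rings":
        center = coords.mean(axis=0)
        score = np.linalg.norm(coords - center, axis=1)
    else:  # voronoi-patches
        seeds = rng.uniform(coords.min(0), coords.max(0), size=(k, 2))
        d = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2)
        return d.argmin(axis=1).astype(np.int64)
    # equal-occupancy contiguous bands along the score
    edges = np.quantile(score, np.linspace(0, 1, k + 1)[1:-1])
    return np.digitize(score, edges).astype(np.int64)


def generate_fixture(spec: FixtureSpec) -> tuple[CountMatrix, CoordinateTable, DomainLabeling]:
    """Draw one fixture; fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    coords = _coordinates(spec, rng)
    labels = _domain_labels(spec, coords, rng)

    g = spec.n_genes
    n_prog = spec.n_programs or spec.n_domains
    baseline = rng.normal(0.0, spec.gene_logmean_sd, size=g)
    n_markers = max(1, int(round(MARKER_FRACTION * g)))
    logmean = np.tile(baseline, (n_prog, 1))
    for prog in range(n_prog):
        start = (prog * n_markers) % g
        idx = (np.arange(start, start + n_markers)) % g
        logmean[prog, idx] += spec.effect_size
    rel = np.exp(logmean)
    rel /= rel.sum(axis=1, keepdims=True)          # relative expression per program

    program_of_domain = np.arange(spec.n_domains) % n_prog
    lo, hi = spec.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_spots))
    mean = lib[:, None] * rel[program_of_domain[labels]]

    r = spec.dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)
    if spec.family == "zinb" and spec.zero_inflation > 0:
        counts[rng.random(counts.shape) < spec.zero_inflation] = 0

    spots = np.array([f"spot_{i}" for i in range(spec.n_spots)], dtype=object)
    genes = np.array([f"gene_{j}" for j in range(g)], dtype=object)
    return (CountMatrix(counts, spots, genes),
            CoordinateTable(coords, spots),
            DomainLabeling(labels))


#: named presets mimicking platform regimes at desk scale
PRESETS: dict[str, FixtureSpec] = {
    "starmap-like": FixtureSpec(
        geometry="horizontal-layers", grid="square", n_spots=1200, n_genes=1000,
        n_domains=7, effect_size=2.0, family="nb", dispersion=2.0,
        library_size_range=(250.0, 750.0), gene_logmean_sd=1.3, seed=11),
    "visium-like": FixtureSpec(
        geometry="horizontal-layers", grid="hex", n_spots=3800, n_genes=1000,
        n_domains=7, effect_size=2.0, family="nb", dispersion=2.0,
        library_size_range=(250.0, 750.0), gene_logmean_sd=1.3, seed=22),
    "slideseq-like": FixtureSpec(
        geometry="horizontal-layers", grid="uniform-random", n_spots=5000, n_genes=1000,
        n_domains=6, effect_size=2.5, family="zinb", dispersion=0.5,
        zero_inflation=0.45, library_size_range=(30.0, 100.0),
        gene_logmean_sd=1.3, seed=33),
}


def fixture_suite(seed_offset: int = 0) -> dict[str, FixtureSpec]:
    """The shipped presets, optionally re-seeded by a constant offset."""
    if seed_offset == 0:
        return dict(PRESETS)
    return {name: replace(s, seed=s.seed + seed_offset) for name, s in PRESETS.items()}


def generate_preset(name: str, seed: int | None = None
                    ) -> tuple[CountMatrix, CoordinateTable, DomainLabeling]:
    spec = PRESETS[name]
    if seed is not None:
        spec = replace(spec, seed=seed)
    return generate_fixture(spec)
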