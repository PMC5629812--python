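"""Synthetic resistance landscapes and microsatellite genotypes.

The generator exists so the full pipeline — genetics, population graphs,
circuit maps, covariates, regression — can be exercised end to end with
known structure.  Landscapes are three-class cost surfaces (10 permeable /
100 semi-permeable / 1000 resistant by default) built by thresholding
smoothed Gaussian noise at quantiles, which gives seedable, tunably
autocorrelated maps.  Genotypes follow a Dirichlet drift model: each
locus draws ancestral allele frequencies from a flat Dirichlet, and each
site draws its own frequencies from a Dirichlet centered on the ancestral
vector whose concentration shrinks as the site's mean effective
resistance to all other sites grows — so genetic divergence increases
with landscape resistance, the coupling every recovery test leans on.
This is a statistical stand-in, not a coalescent: no mutation model, no
migration history, no linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .circuit import build_circuit, effective_resistance_matrix
from .genetics import MISSING, GenotypeTable
from .raster import Raster

__all__ = [
    "LandscapeSpec",
    "SimSpec",
    "generate_landscape",
    "place_sites",
    "simulate_genotypes",
    "inject_missing",
    "morans_i",
]


@dataclass
class LandscapeSpec:
    """Parameters of a three-class synthetic resistance landscape.

    ``habitat_fraction`` is the share of lowest-cost (habitat) cells;
    the remaining mass is split between the semi-permeable and resistant
    classes by ``semi_fraction`` (default an even split).  ``clustering``
    is the Gaussian smoothing length in cells and sets the spatial
    autocorrelation scale.
    """

    grid_rows: int
    grid_cols: int
    cell_size_m: float = 100.0
    habitat_fraction: float = 0.5
    clustering: float = 3.0
    cost_classes: tuple[float, float, float] = (10.0, 100.0, 1000.0)
    semi_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 3 or self.grid_cols < 3:
            raise ValueError("grid must be at least 3x3")
        if not 0 <= self.habitat_fraction <= 1:
            raise ValueError("habitat_fraction must lie in [0, 1]")
        if not 0 <= self.semi_fraction <= 1:
            raise ValueError("semi_fraction must lie in [0, 1]")
        if self.clustering < 0:
            raise ValueError("clustering must be >= 0")
        c = self.cost_classes
        if len(c) != 3 or not (0 < c[0] < c[1] < c[2]):
            raise ValueError("cost_classes must be a strictly increasing positive triple")


@dataclass
class SimSpec:
    """Parameters of the genotype simulation.

    ``drift_scale`` maps mean effective resistance (ohms) to drift: the
    site Dirichlet concentration is 1 / (drift_scale x mean resistance),
    so 0 means no drift at all.  ``missing_rate`` defaults below the 0.35
    filter threshold so simulated individuals survive the standard filter.
    """

    n_sites: int = 8
    n_loci: int = 12
    alleles_per_locus: int = 8
    n_per_site: int | list[int] = 20
    drift_scale: float = 0.01
    missing_rate: float = 0.0
    min_site_separation_m: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError("n_sites must be >= 3")
        if self.n_loci < 1 or self.alleles_per_locus < 2:
            raise ValueError("need >= 1 locus with >= 2 alleles")
        if self.drift_scale < 0:
            raise ValueError("drift_scale must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for n in self.site_sizes():
            if n < 1:
                raise ValueError("every site needs >= 1 individual")

    def site_sizes(self) -> list[int]:
        if isinstance(self.n_per_site, int):
            return [self.n_per_site] * self.n_sites
        if len(self.n_per_site) != self.n_sites:
            raise ValueError("n_per_site list length must equal n_sites")
        return list(self.n_per_site)


def generate_landscape(spec: LandscapeSpec) -> Raster:
    """Threshold smoothed Gaussian noise into the three cost classes.

    Quantile cuts make class fractions exact up to one cell, so the
    realized habitat fraction tracks ``habitat_fraction`` tightly at any
    clustering level.
    """
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((spec.grid_rows, spec.grid_cols))
    if spec.clustering > 0:
        noise = ndimage.gaussian_filter(noise, sigma=spec.clustering, mode="reflect")
    flat = noise.ravel()
    order = np.argsort(flat, kind="stable")
    n = flat.size
    n_hab = int(round(spec.habitat_fraction * n))
    n_semi = int(round(spec.semi_fraction * (n - n_hab)))
    costs = np.empty(n)
    lo, mid, hi = spec.cost_classes
    costs[order[:n_hab]] = lo
    costs[order[n_hab:n_hab + n_semi]] = mid
    costs[order[n_hab + n_semi:]] = hi
    return Raster(costs.reshape(noise.shape), cell_size=spec.cell_size_m)


def morans_i(raster: Raster) -> float:
    """Moran's I spatial autocorrelation with rook (4-neighbor) weights."""
    z = raster.data - np.nanmean(raster.data)
    z = np.where(np.isnan(z), 0.0, z)
    num = (z[:, :-1] * z[:, 1:]).sum() + (z[:-1, :] * z[1:, :]).sum()
    w = z[:, :-1].size + z[:-1, :].size  # directed pairs counted once
    denom = (z**2).sum()
    n = np.isfinite(raster.data).sum()
    return float((n / w) * (num / denom))


def place_sites(
    raster: Raster,
    spec: SimSpec,
    max_attempts: int = 10_000,
    habitat_only: bool = False,
) -> pd.DataFrame:
    """Drop sample sites on valid cells with a minimum pairwise spacing.

    Uniform rejection sampling over non-NoData cells; gives up with an
    error naming the separation constraint after ``max_attempts`` draws.
    With ``habitat_only`` sites are restricted to lowest-cost cells,
    mirroring surveys that trap animals where the species actually lives.
    Returns a frame (site_id, x, y, row, col).
    """
    rng = np.random.default_rng(spec.seed)
    if habitat_only:
        lo = np.nanmin(raster.data)
        valid = np.argwhere(np.isfinite(raster.data) & (raster.data == lo))
    else:
        valid = np.argwhere(np.isfinite(raster.data))
    if valid.shape[0] < spec.n_sites:
        raise ValueError("fewer valid cells than requested sites")
    placed: list[tuple[int, int]] = []
    coords: list[tuple[float, float]] = []
    attempts = 0
    while len(placed) < spec.n_sites:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {spec.n_sites} sites at "
                f">= {spec.min_site_separation_m} m separation within "
                f"{max_attempts} attempts; relax min_site_separation_m"
            )
        attempts += 1
        r, c = valid[rng.integers(valid.shape[0])]
        if any((r, c) == p for p in placed):
            continue
        x, y = raster.cell_center(int(r), int(c))
        if all(
            np.hypot(x - px, y - py) >= spec.min_site_separation_m
            for px, py in coords
        ):
            placed.append((int(r), int(c)))
            coords.append((x, y))
    width = len(str(spec.n_sites))
    return pd.DataFrame(
        {
            "site_id": [f"S{i + 1:0{width}d}" for i in range(spec.n_sites)],
            "x": [c[0] for c in coords],
            "y": [c[1] for c in coords],
            "row": [p[0] for p in placed],
            "col": [p[1] for p in placed],
        }
    )


def site_effective_resistance(
    raster: Raster, sites: pd.DataFrame, connectivity: str = "four"
) -> np.ndarray:
    """Pairwise landscape effective resistance between site cells."""
    circuit = build_circuit(raster, connectivity=connectivity)
    cells = [(int(r), int(c)) for r, c in zip(sites["row"], sites["col"])]
    return effective_resistance_matrix(circuit, cells)


def simulate_genotypes(
    raster: Raster,
    sites: pd.DataFrame,
    spec: SimSpec,
    resistance: np.ndarray | None = None,
) -> GenotypeTable:
    """Dirichlet-drift genotypes whose divergence tracks landscape resistance.

    Per locus, ancestral frequencies p ~ Dirichlet(1, ..., 1).  Site i
    draws its frequencies from Dirichlet(c_i x p) with concentration
    c_i = 1 / (drift_scale x mean effective resistance from site i to all
    others); diploid genotypes are then sampled by drawing two alleles per
    locus from the site frequencies.  ``resistance`` can inject a
    precomputed pairwise matrix to skip the circuit solve.
    """
    if resistance is None:
        resistance = site_effective_resistance(raster, sites)
    k = spec.n_sites
    if resistance.shape != (k, k):
        raise ValueError("resistance matrix does not match n_sites")
    mean_r = (resistance.sum(axis=1)) / (k - 1)

    rng = np.random.default_rng(spec.seed)
    sizes = spec.site_sizes()
    n_total = sum(sizes)
    calls = np.zeros((n_total, spec.n_loci, 2), dtype=int)
    loci = [f"L{j + 1:02d}" for j in range(spec.n_loci)]
    for j in range(spec.n_loci):
        ancestral = rng.dirichlet(np.ones(spec.alleles_per_locus))
        row0 = 0
        for i in range(k):
            if spec.drift_scale == 0 or mean_r[i] <= 0:
                freqs = ancestral
            else:
                conc = 1.0 / (spec.drift_scale * mean_r[i])
                alpha = np.maximum(conc * ancestral, 1e-6)
                freqs = rng.dirichlet(alpha)
            draws = rng.choice(
                spec.alleles_per_locus, size=(sizes[i], 2), p=freqs
            )
            calls[row0:row0 + sizes[i], j, :] = draws + 1  # allele codes 1-based
            row0 += sizes[i]

    ids: list[str] = []
    site_ids: list[str] = []
    for i, (sid, n) in enumerate(zip(sites["site_id"], sizes)):
        ids.extend(f"{sid}_I{m + 1:03d}" for m in range(n))
        site_ids.extend([sid] * n)
    site_xy = {
        str(r.site_id): (float(r.x), float(r.y)) for r in sites.itertuples()
    }
    return GenotypeTable(ids, site_ids, loci, calls, site_xy)


def inject_missing(table: GenotypeTable, missing_rate: float, seed: int = 0) -> GenotypeTable:
    """Mask a random fraction of allele calls with the missing code.

    Each allele call is independently set to missing with probability
    ``missing_rate``; the input table is untouched.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    if missing_rate == 0:
        return table
    rng = np.random.default_rng(seed)
    calls = table.calls.copy()
    mask = rng.random(calls.shape) < missing_rate
    calls[mask] = MISSING
    return GenotypeTable(
        list(table.individual_ids), list(table.site_ids), list(table.loci),
        calls, dict(table.sites),
    )
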