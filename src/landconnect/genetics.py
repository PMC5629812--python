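"""Codominant genotype tables, filtering, multivariate encoding, and
among-population genetic covariance/distance.

Genotypes are diploid microsatellite calls: two positive-integer allele
codes per individual per locus, with 0 the reserved missing code.  The
CSV dialect is one row per individual — ``individual_id, site_id`` then
two columns ``<locus>_1, <locus>_2`` per locus; site coordinates travel in
a sidecar CSV (``site_id, x, y``, projected meters).  Genepop files are
also accepted, with site blocks taken from ``Pop`` delimiters.

The multivariate encoding follows the population-graph lineage: one column
per observed (locus, allele), holding the within-individual allele
frequency 0 / 0.5 / 1.  Site centroids of that encoding yield the
among-population covariance C, and the squared-distance identity
``D_ij = C_ii + C_jj - 2 C_ij`` gives the pairwise genetic distance fed to
the population graph.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeTable",
    "PopulationMatrixSet",
    "read_genotypes",
    "write_genotypes",
    "filter_individuals",
    "encode_multivariate",
    "population_covariance",
]

log = logging.getLogger(__name__)

#: reserved allele code for a missing call
MISSING = 0


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with site metadata.

    ``calls`` has shape (n_individuals, n_loci, 2); allele codes are
    positive integers, 0 = missing.  ``sites`` maps site_id to projected
    (x, y) coordinates in meters.
    """

    individual_ids: list[str]
    site_ids: list[str]
    loci: list[str]
    calls: np.ndarray
    sites: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=int)
        n, L = len(self.individual_ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n} individuals, {L} loci, 2)"
            )
        if n < 1 or L < 1:
            raise ValueError("need at least one individual and one locus")
        if len(set(self.individual_ids)) != n:
            dupes = pd.Series(self.individual_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate individual_id: {dupes}")
        if np.any(self.calls < 0):
            raise ValueError("allele codes must be nonnegative (0 = missing)")
        if self.sites:
            orphans = sorted(set(self.site_ids) - set(self.sites))
            if orphans:
                raise ValueError(f"site_ids without coordinates: {orphans}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of missing allele calls out of 2 x n_loci."""
        return (self.calls == MISSING).reshape(self.n_individuals, -1).mean(axis=1)

    def n_per_site(self) -> pd.Series:
        return pd.Series(self.site_ids).value_counts().sort_index()

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, object] = {
            "individual_id": self.individual_ids,
            "site_id": self.site_ids,
        }
        for j, locus in enumerate(self.loci):
            cols[f"{locus}_1"] = self.calls[:, j, 0]
            cols[f"{locus}_2"] = self.calls[:, j, 1]
        return pd.DataFrame(cols)


def write_genotypes(table: GenotypeTable, path: str | Path, sites_path: str | Path | None = None) -> None:
    table.to_frame().to_csv(path, index=False)
    if sites_path is not None:
        pd.DataFrame(
            [(s, x, y) for s, (x, y) in sorted(table.sites.items())],
            columns=["site_id", "x", "y"],
        ).to_csv(sites_path, index=False)


def _read_sites_sidecar(path: str | Path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path)
    need = {"site_id", "x", "y"}
    if not need.issubset(df.columns):
        raise ValueError(f"sites file {path} must have columns {sorted(need)}")
    return {str(r.site_id): (float(r.x), float(r.y)) for r in df.itertuples()}


def _read_csv(path: Path) -> tuple[list[str], list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, dtype={"individual_id": str, "site_id": str})
    if list(df.columns[:2]) != ["individual_id", "site_id"]:
        raise ValueError(
            f"{path}: first two columns must be individual_id, site_id "
            f"(got {list(df.columns[:2])})"
        )
    locus_cols = list(df.columns[2:])
    loci: list[str] = []
    for c in locus_cols:
        if not (c.endswith("_1") or c.endswith("_2")):
            raise ValueError(f"{path}: unknown locus column '{c}' (expect <locus>_1/_2)")
        base = c[:-2]
        if base not in loci:
            loci.append(base)
    for locus in loci:
        for suffix in ("_1", "_2"):
            if f"{locus}{suffix}" not in df.columns:
                raise ValueError(f"{path}: locus {locus} is missing column {locus}{suffix}")
    if df[locus_cols].isna().any().any():
        bad = int(df[locus_cols].isna().any(axis=1).idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: ragged/empty allele cell near line {bad}")
    n = len(df)
    calls = np.zeros((n, len(loci), 2), dtype=int)
    for j, locus in enumerate(loci):
        calls[:, j, 0] = df[f"{locus}_1"].astype(int)
        calls[:, j, 1] = df[f"{locus}_2"].astype(int)
    return list(df["individual_id"]), list(df["site_id"]), loci, calls


def _read_genepop(path: Path) -> tuple[list[str], list[str], list[str], np.ndarray]:
    lines = [ln.rstrip("\n") for ln in open(path)]
    if len(lines) < 3:
        raise ValueError(f"{path}: not a Genepop file (too short)")
    body = lines[1:]  # first line is a free-text title
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        chunk = [t.strip() for t in body[i].split(",") if t.strip()]
        loci.extend(chunk)
        i += 1
    if i == len(body):
        raise ValueError(f"{path}: no 'Pop' delimiter found")
    ids: list[str] = []
    site_ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_idx = 0
    for ln in body[i:]:
        stripped = ln.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in stripped:
            raise ValueError(f"{path}: genotype line lacks ',' separator: {stripped!r}")
        ind, geno = stripped.split(",", 1)
        toks = geno.split()
        if len(toks) != len(loci):
            raise ValueError(
                f"{path}: individual {ind.strip()!r} has {len(toks)} loci, "
                f"expected {len(loci)}"
            )
        pair_row = []
        for tok in toks:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ValueError(f"{path}: bad genotype token {tok!r} for {ind.strip()!r}")
            half = len(tok) // 2
            pair_row.append((int(tok[:half]), int(tok[half:])))
        ids.append(ind.strip())
        site_ids.append(f"Pop{pop_idx}")
        rows.append(pair_row)
    calls = np.array(rows, dtype=int)
    return ids, site_ids, loci, calls


def read_genotypes(
    path: str | Path,
    format: str = "csv",
    sites_path: str | Path | None = None,
) -> GenotypeTable:
    """Load genotypes from CSV (native dialect) or Genepop.

    Genepop carries no coordinates, so a sidecar sites CSV is attached
    when given; validation (duplicate ids, ragged rows) raises with the
    offending line or id named.
    """
    path = Path(path)
    if format == "csv":
        ids, site_ids, loci, calls = _read_csv(path)
    elif format == "genepop":
        ids, site_ids, loci, calls = _read_genepop(path)
    else:
        raise ValueError(f"unknown genotype format {format!r} (csv|genepop)")
    sites = _read_sites_sidecar(sites_path) if sites_path else {}
    table = GenotypeTable(ids, site_ids, loci, calls, sites)
    log.info(
        "read %d individuals x %d loci from %s (%d sites)",
        table.n_individuals, table.n_loci, path, len(set(site_ids)),
    )
    return table


def filter_individuals(table: GenotypeTable, max_missing: float = 0.35) -> GenotypeTable:
    """Drop individuals with *more than* ``max_missing`` missing allele calls.

    The fraction denominator is 2 x n_loci (allele calls, not loci) and
    the inequality is strict: an individual at exactly the threshold is
    retained.  Sites left empty are dropped with a warning.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must lie in [0, 1]")
    frac = table.missing_fraction()
    keep = frac <= max_missing
    removed = pd.Series(table.site_ids)[~keep].value_counts()
    for site, k in removed.items():
        log.info("filter_individuals: removed %d individual(s) at site %s", k, site)
    kept_sites = {s for s, k in zip(table.site_ids, keep) if k}
    lost_sites = sorted(set(table.site_ids) - kept_sites)
    if lost_sites:
        warnings.warn(
            f"sites dropped entirely by the missing-data filter: {lost_sites}"
        )
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("missing-data filter removed every individual")
    return replace(
        table,
        individual_ids=[table.individual_ids[i] for i in idx],
        site_ids=[table.site_ids[i] for i in idx],
        calls=table.calls[idx],
        sites={s: xy for s, xy in table.sites.items() if s in kept_sites} or table.sites,
    )


def encode_multivariate(table: GenotypeTable) -> pd.DataFrame:
    """Individual x (locus, allele) within-individual allele-frequency matrix.

    Each observed (locus, allele) pair gets a column holding the allele's
    count in the individual's genotype divided by 2, so a homozygote is 1,
    a heterozygote splits 0.5/0.5, and each locus's columns sum to 1 for a
    scored locus.  Missing loci are imputed with the individual's site
    mean for those columns (falling back to the overall mean when a whole
    site lacks the locus), which leaves site centroids unbiased.
    """
    columns: list[tuple[str, int]] = []
    for j, locus in enumerate(table.loci):
        alleles = np.unique(table.calls[:, j, :])
        alleles = alleles[alleles != MISSING]
        columns.extend((locus, int(a)) for a in alleles)
    if len(columns) <= 1:
        raise ValueError("monomorphic dataset: multivariate covariance undefined")

    n = table.n_individuals
    mat = np.zeros((n, len(columns)))
    missing_rows: dict[str, np.ndarray] = {}
    for j, locus in enumerate(table.loci):
        cols = [k for k, (lc, _) in enumerate(columns) if lc == locus]
        allele_of = {columns[k][1]: k for k in cols}
        pair = table.calls[:, j, :]
        scored = np.all(pair != MISSING, axis=1)
        for i in np.flatnonzero(scored):
            for a in pair[i]:
                mat[i, allele_of[int(a)]] += 0.5
        missing_rows[locus] = np.flatnonzero(~scored)

    site_arr = np.asarray(table.site_ids)
    for j, locus in enumerate(table.loci):
        miss = missing_rows[locus]
        if miss.size == 0:
            continue
        cols = [k for k, (lc, _) in enumerate(columns) if lc == locus]
        pair = table.calls[:, j, :]
        scored = np.all(pair != MISSING, axis=1)
        overall = mat[np.ix_(np.flatnonzero(scored), cols)].mean(axis=0) if scored.any() \
            else np.full(len(cols), 1.0 / len(cols))
        for i in miss:
            same = scored & (site_arr == site_arr[i])
            fill = mat[np.ix_(np.flatnonzero(same), cols)].mean(axis=0) if same.any() else overall
            mat[i, cols] = fill

    index = pd.Index(table.individual_ids, name="individual_id")
    return pd.DataFrame(
        mat, index=index,
        columns=pd.MultiIndex.from_tuples(columns, names=["locus", "allele"]),
    )


@dataclass
class PopulationMatrixSet:
    """Among-population covariance C and squared genetic distance D."""

    site_order: list[str]
    C: np.ndarray
    D: np.ndarray
    n_per_site: pd.Series

    def __post_init__(self) -> None:
        k = len(self.site_order)
        assert self.C.shape == (k, k) and self.D.shape == (k, k)
        if not np.allclose(self.C, self.C.T, atol=1e-10):
            raise ValueError("covariance matrix not symmetric")
        check = self.C.diagonal()[:, None] + self.C.diagonal()[None, :] - 2 * self.C
        if not np.allclose(self.D, check, atol=1e-10):
            raise ValueError("D violates D_ij = C_ii + C_jj - 2 C_ij")


def population_covariance(
    encoded: pd.DataFrame,
    site_ids: list[str] | np.ndarray,
) -> PopulationMatrixSet:
    """Site-centroid covariance and pairwise genetic distance.

    Site centroids of the encoded rows are grand-centered (unweighted over
    sites) and C = Xc Xc' / (n_columns - 1); D follows the squared-distance
    identity.  Requires >= 3 sites of >= 2 individuals each.
    """
    site_ids = np.asarray(site_ids)
    if len(site_ids) != encoded.shape[0]:
        raise ValueError("site_ids length must match encoded rows")
    order = sorted(pd.unique(site_ids))
    if len(order) < 3:
        raise ValueError(f"need >= 3 sites for a population graph, got {len(order)}")
    counts = pd.Series(site_ids).value_counts()
    thin = sorted(counts[counts < 2].index)
    if thin:
        raise ValueError(f"sites with < 2 individuals: {thin}")
    X = encoded.to_numpy(dtype=float)
    centroids = np.vstack([X[site_ids == s].mean(axis=0) for s in order])
    centered = centroids - centroids.mean(axis=0, keepdims=True)
    C = centered @ centered.T / (X.shape[1] - 1)
    C = 0.5 * (C + C.T)
    d = C.diagonal()
    D = d[:, None] + d[None, :] - 2 * C
    np.fill_diagonal(D, 0.0)
    D = np.maximum(0.5 * (D + D.T), 0.0)
    return PopulationMatrixSet(
        site_order=list(order),
        C=C,
        D=D,
        n_per_site=counts.loc[order],
    )
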