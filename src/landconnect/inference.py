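"""PCA of the landscape covariates and OLS models of node connectivity.

The 12 buffered covariates are strongly inter-correlated, so they are
reduced by PCA on their correlation matrix and the leading components
(first 4, or enough for 85% cumulative variance) enter an ordinary
least-squares model of the standardized node connectivity response
against x, y, sample size and the retained PC scores — fit for the full
node set and separately for northern and southern species groups.
A recovery experiment re-runs the whole synthetic pipeline across
landscapes of varying habitat amount and tabulates the sign and
confidence interval of the cost- and current-loaded PC effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .covariates import covariate_columns

__all__ = [
    "PcaResult",
    "RegressionResult",
    "run_pca",
    "fit_ols",
    "recovery_experiment",
]

log = logging.getLogger(__name__)

#: |loading| above which a covariate is flagged as a major PC contributor
LOADING_FLAG = 0.25


@dataclass
class PcaResult:
    """Correlation-matrix PCA of the node covariates."""

    columns: list[str]
    loadings: np.ndarray            # columns x n_pc, orthonormal columns
    variance_explained: np.ndarray  # proportions, sum to 1
    scores: np.ndarray              # nodes x n_pc (z-scored data x loadings)
    k: int                          # retained components

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.variance_explained)

    def loading_table(self) -> pd.DataFrame:
        """Loadings with major contributors (|loading| > 0.25) flagged."""
        df = pd.DataFrame(
            self.loadings[:, : self.k],
            index=self.columns,
            columns=[f"PC{i + 1}" for i in range(self.k)],
        )
        for c in df.columns:
            df[f"{c}_major"] = df[c].abs() > LOADING_FLAG
        return df


def _zscore(X: np.ndarray, ddof: int = 1) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def run_pca(
    records: pd.DataFrame,
    columns: list[str] | None = None,
    k_rule: tuple[str, float] = ("fixed", 4),
) -> PcaResult:
    """Eigendecomposition of the covariate correlation matrix.

    ``k_rule`` is ``("fixed", k)`` or ``("cumulative", q)`` retaining the
    smallest k whose cumulative variance proportion reaches q.  Each
    loading column is sign-fixed so its largest-magnitude element is
    positive.  Rank deficiency (fewer nodes than covariates) is legal but
    logged.
    """
    if columns is None:
        radii = records.attrs.get("radii_m")
        if radii is None:
            raise ValueError("no covariate columns given and no radii recorded")
        columns = covariate_columns(radii)
    X = records[columns].to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 nodes")
    if n <= p:
        log.warning("PCA on %d nodes < %d covariates: correlation matrix rank-deficient", n, p)
    Z = _zscore(X)
    R = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        i_max = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i_max, j] < 0:
            eigvec[:, j] *= -1
    prop = eigval / eigval.sum()
    mode, val = k_rule
    if mode == "fixed":
        k = int(val)
    elif mode == "cumulative":
        k = int(np.searchsorted(np.cumsum(prop), val) + 1)
    else:
        raise ValueError("k_rule must be ('fixed', k) or ('cumulative', q)")
    k = min(k, p)
    if k < 1:
        raise ValueError("must retain at least one component")
    return PcaResult(
        columns=list(columns),
        loadings=eigvec,
        variance_explained=prop,
        scores=Z @ eigvec,
        k=k,
    )


@dataclass
class RegressionResult:
    """A fitted connectivity model in Table-style layout."""

    subset: str
    coef: pd.DataFrame        # slope, se, ci_low, ci_high, excludes_zero
    r_squared: float
    adj_r_squared: float
    f_stat: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n_nodes: int


#: the species grouping of the northern/southern models
DEFAULT_SPECIES_GROUPS: dict[str, list[str]] = {
    "north": ["lynx", "marten"],
    "south": ["fisher", "flying_squirrel"],
}


def fit_ols(
    records: pd.DataFrame,
    pca: PcaResult,
    subset: str = "full",
    species_groups: dict[str, list[str]] | None = None,
) -> RegressionResult:
    """OLS of standardized connectivity on x, y, n and the retained PCs.

    The response is the within-species z-scored average inverse edge
    weight; predictors are z-scored within the modeled subset so slopes
    are standardized effects.  Confidence intervals use the t(df)
    quantile; a slope whose 95% CI excludes zero is flagged.
    """
    groups = species_groups or DEFAULT_SPECIES_GROUPS
    if subset == "full":
        mask = np.ones(len(records), dtype=bool)
    elif subset in groups:
        mask = records["species"].isin(groups[subset]).to_numpy()
    else:
        raise ValueError(f"unknown subset {subset!r}; expected full|{'|'.join(groups)}")
    sub = records.loc[mask].reset_index(drop=True)
    scores = pca.scores[mask][:, : pca.k]
    y = sub["connectivity_z"].to_numpy(dtype=float)
    ok = np.isfinite(y)
    if not ok.all():
        log.warning("dropping %d node(s) with undefined connectivity", int((~ok).sum()))
        sub, scores, y = sub.loc[ok].reset_index(drop=True), scores[ok], y[ok]

    names = ["X", "Y", "Sample Size"] + [f"PC{i + 1}" for i in range(pca.k)]
    raw = np.column_stack([sub["x"], sub["y"], sub["n"], scores])
    n, p = raw.shape
    if n <= p + 1:
        raise ValueError(f"subset {subset!r} has {n} nodes for {p + 1} parameters")
    Xz = _zscore(raw)
    design = sm.add_constant(Xz)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(Xz, rowvar=False)
        pairs = [
            (names[i], names[j])
            for i in range(p) for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design in subset {subset!r}; collinear: {pairs}")
    fit = sm.OLS(y, design).fit()
    tcrit = stats.t.ppf(0.975, fit.df_resid)
    coef = pd.DataFrame(
        {
            "slope": fit.params,
            "se": fit.bse,
            "ci_low": fit.params - tcrit * fit.bse,
            "ci_high": fit.params + tcrit * fit.bse,
        },
        index=["Intercept"] + names,
    )
    coef["excludes_zero"] = (coef["ci_low"] > 0) | (coef["ci_high"] < 0)
    return RegressionResult(
        subset=subset,
        coef=coef,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n_nodes=n,
    )


def _pc_for(pca: PcaResult, keyword: str) -> int:
    """Retained PC with the largest mean |loading| on columns containing
    ``keyword`` ('cost' or 'current')."""
    rows = [i for i, c in enumerate(pca.columns) if keyword in c]
    strength = np.abs(pca.loadings[rows, : pca.k]).mean(axis=0)
    return int(np.argmax(strength))


def recovery_experiment(
    n_replicates: int = 20,
    habitat_fractions: tuple[float, ...] = (0.2, 0.35, 0.65, 0.8),
    drift_scale: float = 0.5,
    seed: int = 0,
    grid: int = 56,
    n_sites: int = 20,
    n_per_site: int = 20,
    n_loci: int = 12,
    n_pairs: int = 24,
    buffer_cells: int = 6,
    radius_m: float = 1200.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Simulate landscapes, run the full pipeline, and record the signed
    PC effects on node connectivity in low- vs high-habitat strata.

    Each replicate draws a landscape at one of the ``habitat_fractions``,
    simulates genotypes under ``drift_scale``, builds the population
    graph, maps omnidirectional current, extracts buffered covariates at
    a single scaled radius, and fits the PCA+OLS model.  The summary has
    one row per replicate with the slope and CI of the cost- and
    current-loaded PCs; failed replicates are recorded, not fatal.
    """
    from .pipeline import run_synthetic_study  # deferred: avoids an import cycle

    rows = []
    rng = np.random.default_rng(seed)
    for rep in range(n_replicates):
        hf = habitat_fractions[rep % len(habitat_fractions)]
        rep_seed = int(rng.integers(2**31 - 1))
        try:
            out = run_synthetic_study(
                habitat_fraction=hf,
                drift_scale=drift_scale,
                seed=rep_seed,
                grid=grid,
                n_sites=n_sites,
                n_per_site=n_per_site,
                n_loci=n_loci,
                n_pairs=n_pairs,
                buffer_cells=buffer_cells,
                radii_m=(radius_m,),
                alpha=alpha,
            )
            pca, reg = out["pca"], out["regression"]
            i_cur = _pc_for(pca, "current")
            i_cost = _pc_for(pca, "cost")
            # orient each PC so it points along increasing mean current / cost
            cur_rows = [i for i, c in enumerate(pca.columns)
                        if "current" in c and c.startswith("mean")]
            cost_rows = [i for i, c in enumerate(pca.columns)
                         if "cost" in c and c.startswith("mean")]
            cur_sign = np.sign(pca.loadings[cur_rows, i_cur].mean()) or 1.0
            cost_sign = np.sign(pca.loadings[cost_rows, i_cost].mean()) or 1.0
            c_cur = reg.coef.loc[f"PC{i_cur + 1}"]
            c_cost = reg.coef.loc[f"PC{i_cost + 1}"]
            excl = reg.coef.loc[reg.coef.index != "Intercept", "excludes_zero"]
            # sample size has a real effect even without drift (sampling
            # noise inflates distances at small-n sites), so the type-I
            # summary tracks the landscape/coordinate predictors separately
            land_idx = [i for i in excl.index if i != "Sample Size"]
            rows.append(
                {
                    "replicate": rep,
                    "habitat_fraction": hf,
                    "stratum": "low" if hf < 0.5 else "high",
                    "seed": rep_seed,
                    "ok": True,
                    "current_pc": i_cur + 1,
                    "current_slope": float(c_cur["slope"] * cur_sign),
                    "current_excludes_zero": bool(c_cur["excludes_zero"]),
                    "cost_pc": i_cost + 1,
                    "cost_slope": float(c_cost["slope"] * cost_sign),
                    "cost_excludes_zero": bool(c_cost["excludes_zero"]),
                    "n_ci_excluding_zero": int(excl.sum()),
                    "n_predictors": int(len(excl)),
                    "n_ci_excluding_zero_landscape": int(excl[land_idx].sum()),
                    "n_landscape_predictors": int(len(land_idx)),
                    "adj_r_squared": reg.adj_r_squared,
                    "error": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 — replicate failures are data
            log.warning("replicate %d failed: %s", rep, exc)
            rows.append(
                {
                    "replicate": rep, "habitat_fraction": hf,
                    "stratum": "low" if hf < 0.5 else "high",
                    "seed": rep_seed, "ok": False, "error": str(exc),
                }
            )
    return pd.DataFrame(rows)
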