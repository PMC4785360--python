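"""Per-gene confounder-adjusted association of expression with drug sensitivity.

For each gene *j* the model is an ordinary least-squares fit

    Y_ij = beta_j + gamma_j * Sensitivity_i + lambda_j * Age_i + mu_j * Sex_i
           + theta_j * Batch_i + kappa_j * Cancer_i + phi_j * Tissue_i
           + sum_k delta_jk * GenotypePC_ik + eps_ij

with sex, batch, cancer and tissue dummy-encoded against a reference level
(lexicographically first).  A gene is called drug-response associated (DRA)
when the two-sided t-test of gamma_j = 0 survives Benjamini–Hochberg
adjustment at the chosen FDR level (default 0.1), and is classed positive or
negative by the sign of gamma_j.

The scan is vectorised: the design matrix is shared by all genes, so a
single linear solve fits every gene at once.  That keeps 1,000-permutation
null studies and 100-replicate subsampling power curves cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io
from .exceptions import ConfigError, InputError, ValidationError

__all__ = [
    "adjust_bh",
    "fit_gene_model",
    "DRAScan",
    "DRAScanResults",
    "run_dra_scan",
    "permutation_null",
    "PermutationSummary",
    "subsample_power",
]

#: flags attached to genes the scan could not test normally
FLAG_OK = ""
FLAG_ZERO_VARIANCE = "zero_variance"
FLAG_DEGENERATE = "degenerate"
FLAG_RANK_DEFICIENT = "rank_deficient"

_RESID_TOL = 1e-12


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1.

    NaN entries are passed through and do not count toward the number of
    tests.  Raises :class:`ValidationError` for p outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[mask] = restored
    return out


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _complete_rows(samples: pd.DataFrame, drug: str) -> pd.DataFrame:
    """Samples usable for this drug: sensitivity and every covariate present."""
    cols = [io.sensitivity_column(drug), *io.NUMERIC_COLUMNS, *io.FACTOR_COLUMNS]
    missing = [c for c in cols if c not in samples.columns]
    if missing:
        raise InputError(f"sample table lacks columns {missing} needed for drug {drug!r}")
    sub = samples[cols]
    keep = sub.notna().all(axis=1)
    for c in io.FACTOR_COLUMNS:
        keep &= sub[c].astype(str).str.len() > 0
    return samples.loc[keep]


def build_design(samples: pd.DataFrame, sensitivity: pd.Series) -> pd.DataFrame:
    """Design matrix: intercept, sensitivity, numeric covariates, factor dummies.

    Constant numeric covariates are dropped (they alias the intercept);
    single-level factors contribute no dummy columns.
    """
    parts = {
        "intercept": pd.Series(1.0, index=samples.index),
        "sensitivity": sensitivity.astype(float),
    }
    for c in io.NUMERIC_COLUMNS:
        if c in samples.columns:
            col = samples[c].astype(float)
            if col.nunique() > 1:
                parts[c] = col
    X = pd.DataFrame(parts)
    factors = [c for c in io.FACTOR_COLUMNS if c in samples.columns]
    if factors:
        dummies = pd.get_dummies(samples[factors].astype(str), drop_first=True,
                                 dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return X


# ---------------------------------------------------------------------------
# OLS core
# ---------------------------------------------------------------------------

def _ols_scan(Y: np.ndarray, X: np.ndarray):
    """Fit OLS for every row of Y (genes × samples) against shared design X.

    Returns (gamma_hat, p_value, flags): the sensitivity coefficient (design
    column 1), its two-sided t-test p-value, and a per-gene flag.
    """
    n, p = X.shape
    n_genes = Y.shape[0]
    gamma = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    flags = np.array([FLAG_OK] * n_genes, dtype=object)

    if n <= p + 1 or np.linalg.matrix_rank(X) < p:
        flags[:] = FLAG_RANK_DEFICIENT
        return gamma, pval, flags

    zero_var = Y.max(axis=1) == Y.min(axis=1)
    flags[zero_var] = FLAG_ZERO_VARIANCE

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ Y.T)            # p × genes
    resid = Y.T - X @ beta                  # n × genes
    rss = np.einsum("ij,ij->j", resid, resid)
    dof = n - p
    gamma[:] = beta[1]
    scale = np.maximum(np.einsum("ij,ij->i", Y, Y), 1.0)
    degenerate = (rss <= _RESID_TOL * scale) & ~zero_var
    sigma2 = rss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        t = gamma / se
    pval[:] = 2.0 * stats.t.sf(np.abs(t), dof)
    pval[degenerate] = 0.0
    flags[degenerate] = FLAG_DEGENERATE
    gamma[zero_var] = np.nan
    pval[zero_var] = np.nan
    return gamma, pval, flags


class GeneFit(NamedTuple):
    gamma_hat: float
    p_value: float
    flag: str


def fit_gene_model(y, sensitivity, covariates: pd.DataFrame | None = None) -> GeneFit:
    """OLS fit of one gene's expression on sensitivity plus covariates.

    ``covariates`` is a sample-table slice (any subset of the standard
    numeric/factor columns); samples with a missing value in any field are
    excluded.  Degenerate cases are flagged rather than raised: a perfect
    fit reports p = 0 with the ``degenerate`` flag, an unidentifiable design
    reports NaN with ``rank_deficient``.
    """
    y = pd.Series(np.asarray(y, dtype=float))
    sens = pd.Series(np.asarray(sensitivity, dtype=float))
    if len(y) != len(sens):
        raise InputError("expression and sensitivity lengths differ")
    frame = pd.DataFrame({"_y": y.to_numpy(), "_sens": sens.to_numpy()})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        frame = pd.concat([frame, cov], axis=1)
    frame = frame.dropna()
    samples = frame.drop(columns=["_y", "_sens"])
    X = build_design(samples, frame["_sens"])
    gamma, pval, flags = _ols_scan(frame["_y"].to_numpy()[None, :], X.to_numpy())
    return GeneFit(float(gamma[0]), float(pval[0]), str(flags[0]))


# ---------------------------------------------------------------------------
# scan model / results
# ---------------------------------------------------------------------------

class DRAScan:
    """Per-gene DRA scan for one drug, statsmodels-style.

    Parameters
    ----------
    expr : DataFrame
        Genes × samples expression matrix.
    samples : DataFrame
        Sample table (see :mod:`dranet.io`) indexed by sample id, holding
        the covariates and a ``sens_<drug>`` column.
    drug : str
        Drug name; selects the sensitivity column.
    alpha : float
        BH-FDR significance level for the DRA call (default 0.1).
    """

    def __init__(self, expr: pd.DataFrame, samples: pd.DataFrame, drug: str,
                 alpha: float = 0.1):
        io.validate_expression_matrix(expr)
        usable = _complete_rows(samples, drug)
        common = [s for s in expr.columns if s in usable.index]
        if not common:
            raise InputError(
                f"no samples shared between expression matrix and usable "
                f"annotation rows for drug {drug!r}"
            )
        self.drug = drug
        self.alpha = float(alpha)
        self.samples = usable.loc[common]
        self.expr = expr[common]
        self.sensitivity = self.samples[io.sensitivity_column(drug)].astype(float)
        self.design = build_design(self.samples, self.sensitivity)

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    def fit(self) -> "DRAScanResults":
        gamma, pval, flags = _ols_scan(self.expr.to_numpy(dtype=float),
                                       self.design.to_numpy(dtype=float))
        fdr = adjust_bh(pval)
        sign = np.where(
            (fdr <= self.alpha) & (gamma > 0), "positive",
            np.where((fdr <= self.alpha) & (gamma < 0), "negative", "nonsignificant"),
        )
        sign[np.isnan(fdr)] = "nonsignificant"
        table = pd.DataFrame(
            {
                "gene": self.expr.index,
                "gamma_hat": gamma,
                "p_value": pval,
                "fdr": fdr,
                "sign_class": sign,
                "flag": flags,
            }
        ).set_index("gene", drop=False)
        table.index.name = None
        return DRAScanResults(self, table)


@dataclass
class DRAScanResults:
    """Per-gene estimates, FDR and sign classes from a :class:`DRAScan`."""

    model: DRAScan
    table: pd.DataFrame

    @property
    def drug(self) -> str:
        return self.model.drug

    @property
    def alpha(self) -> float:
        return self.model.alpha

    @property
    def significant_genes(self) -> pd.Index:
        return self.table.index[self.table["sign_class"] != "nonsignificant"]

    @property
    def n_significant(self) -> int:
        return int((self.table["sign_class"] != "nonsignificant").sum())

    @property
    def n_positive(self) -> int:
        return int((self.table["sign_class"] == "positive").sum())

    @property
    def n_negative(self) -> int:
        return int((self.table["sign_class"] == "negative").sum())

    def ranking(self) -> list[str]:
        """Genes ordered by ascending p-value (ties broken by gene id)."""
        t = self.table.dropna(subset=["p_value"])
        return t.sort_values(["p_value", "gene"]).index.tolist()

    def summary(self) -> str:
        flagged = int((self.table["flag"] != FLAG_OK).sum())
        lines = [
            "DRA scan results",
            "================",
            f"drug:               {self.drug}",
            f"samples used:       {self.model.n_samples}",
            f"genes tested:       {int(self.table['p_value'].notna().sum())}",
            f"FDR level:          {self.alpha}",
            f"DRA genes:          {self.n_significant} "
            f"({self.n_positive} positive / {self.n_negative} negative)",
            f"flagged genes:      {flagged}",
        ]
        return "\n".join(lines)

    def to_table(self) -> pd.DataFrame:
        return self.table.reset_index(drop=True)


def run_dra_scan(expr, samples, drug, alpha: float = 0.1) -> DRAScanResults:
    """Fit the per-gene scan; convenience wrapper over :class:`DRAScan`."""
    return DRAScan(expr, samples, drug, alpha=alpha).fit()


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

@dataclass
class PermutationSummary:
    """Background DRA-gene counts under sensitivity permutation."""

    n_perm: int
    frequency: int          # permutations whose count ties/beats the observed
    average_count: float    # mean significant-gene count across permutations
    observed_count: int
    tie_rule: str = "geq"

    def summary(self) -> str:
        return (
            f"observed DRA genes: {self.observed_count}\n"
            f"permutations:       {self.n_perm}\n"
            f"frequency (count {'>=' if self.tie_rule == 'geq' else '>'} observed): "
            f"{self.frequency}\n"
            f"average permuted count: {self.average_count:.2f}"
        )


def _count_significant(Y: np.ndarray, X: np.ndarray, alpha: float) -> int:
    _, pval, _ = _ols_scan(Y, X)
    fdr = adjust_bh(pval)
    return int(np.nansum(fdr <= alpha))


def permutation_null(expr, samples, drug, n_perm: int = 1000, alpha: float = 0.1,
                     seed: int | None = None, tie_rule: str = "geq") -> PermutationSummary:
    """Permute sensitivity across samples and re-run the scan ``n_perm`` times.

    Covariates stay attached to their samples; only the sensitivity labels
    move.  ``frequency`` counts permutations whose significant-gene count
    ties or beats the observed count (``tie_rule="geq"``, conservative;
    ``"gt"`` counts strict exceedances only).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if tie_rule not in ("geq", "gt"):
        raise ConfigError(f"unknown tie_rule {tie_rule!r}")
    model = DRAScan(expr, samples, drug, alpha=alpha)
    Y = model.expr.to_numpy(dtype=float)
    sens = model.sensitivity.to_numpy()
    observed = _count_significant(Y, model.design.to_numpy(dtype=float), alpha)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        perm = rng.permutation(sens)
        Xp = build_design(model.samples, pd.Series(perm, index=model.samples.index))
        counts[i] = _count_significant(Y, Xp.to_numpy(dtype=float), alpha)
    if tie_rule == "geq":
        freq = int((counts >= observed).sum())
    else:
        freq = int((counts > observed).sum())
    return PermutationSummary(n_perm=n_perm, frequency=freq,
                              average_count=float(counts.mean()),
                              observed_count=observed, tie_rule=tie_rule)


# ---------------------------------------------------------------------------
# subsampling power
# ---------------------------------------------------------------------------

def subsample_power(expr, samples, drug, sizes: Sequence[int], reps: int = 100,
                    alpha: float = 0.1, seed: int | None = None) -> pd.DataFrame:
    """Mean DRA-gene count over random subsamples at each sample size.

    For each size, ``reps`` subsamples are drawn without replacement and the
    full scan re-run; the mean significant count estimates detection power
    at that panel size.
    """
    model = DRAScan(expr, samples, drug, alpha=alpha)
    n = model.n_samples
    sizes = list(sizes)
    for s in sizes:
        if s > n:
            raise ConfigError(f"subsample size {s} exceeds available samples {n}")
        if s < 3:
            raise ConfigError(f"subsample size {s} too small")
    rng = np.random.default_rng(seed)
    Y = model.expr.to_numpy(dtype=float)
    rows = []
    for size in sizes:
        counts = np.empty(reps, dtype=int)
        for r in range(reps):
            idx = np.sort(rng.choice(n, size=size, replace=False))
            sub = model.samples.iloc[idx]
            X = build_design(sub, model.sensitivity.iloc[idx])
            counts[r] = _count_significant(Y[:, idx], X.to_numpy(dtype=float), alpha)
        rows.append({"size": size, "mean_significant": float(counts.mean()),
                     "reps": reps})
    return pd.DataFrame(rows)
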