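"""Least-squares means of hybrids across environments.

The adjustment model is the two-way fixed-effects layout

    Y_hl = mu + lambda_l + H_h + E_hl,   E_hl ~ N(0, sigma2_E)

with environment and hybrid both fixed. The ls-mean of hybrid h is the fitted
value mu + H_h averaged over environments with equal weights, which for a
balanced design reduces to the simple mean of the hybrid's plots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .datatypes import LsMeans


def _check_connected(plot_table: pd.DataFrame, hybrids: pd.Index, envs: pd.Index) -> None:
    """The hybrid/environment incidence graph must have a single component."""
    hi = hybrids.get_indexer(plot_table["hybrid"])
    ei = envs.get_indexer(plot_table["environment"])
    n_h, n_e = len(hybrids), len(envs)
    adj = coo_matrix((np.ones(len(hi)), (hi, n_h + ei)), shape=(n_h + n_e, n_h + n_e))
    n_comp, labels = connected_components(adj + adj.T, directed=False)
    if n_comp > 1:
        groups = [
            sorted(hybrids[np.flatnonzero(labels[:n_h] == c)].tolist())[:5]
            for c in range(n_comp)
        ]
        raise ValueError(f"design disconnected across environments; components start with {groups}")


def fit_lsmeans(
    plot_table: pd.DataFrame,
    exclude_environments: tuple[str, ...] = (),
) -> LsMeans:
    """OLS fit of value ~ environment + hybrid and ls-means per hybrid.

    ``plot_table`` needs columns hybrid, environment, value. Environment
    effects enter the ls-means with equal weights. Hybrids absent from every
    environment simply do not appear. ``exclude_environments`` drops listed
    environments before fitting (an explicit per-trait choice, e.g. an
    environment uncorrelated with the others — no automatic rule is
    applied). Returns the residual variance estimate as ``sigma2_E``.
    """
    t = plot_table.dropna(subset=["value"]).reset_index(drop=True)
    if exclude_environments:
        t = t[~t["environment"].isin(exclude_environments)].reset_index(drop=True)
    if len(t) == 0:
        raise ValueError("no phenotype records")
    hybrids = pd.Index(pd.unique(t["hybrid"]))
    envs = pd.Index(pd.unique(t["environment"]))
    for e, grp in t.groupby("environment"):
        if grp["hybrid"].nunique() < 2 and len(envs) > 1:
            raise ValueError(f"environment {e!r} contains fewer than 2 distinct hybrids")
    _check_connected(t, hybrids, envs)

    if len(envs) == 1:
        # a single environment: ls-means are the replicate averages
        means = t.groupby("hybrid")["value"].mean()
        resid = t["value"].to_numpy() - means.loc[t["hybrid"]].to_numpy()
        dof = len(t) - len(hybrids)
        table = pd.DataFrame(
            {
                "hybrid": hybrids,
                "lsmean": means.loc[hybrids].to_numpy(),
                "n_env": 1,
            }
        )
        return LsMeans(table, float(resid @ resid / dof) if dof > 0 else float("nan"))

    n = len(t)
    hi = hybrids.get_indexer(t["hybrid"])
    ei = envs.get_indexer(t["environment"])
    n_h, n_e = len(hybrids), len(envs)
    # treatment coding: intercept, env 2..E, hybrid 2..H
    X = np.zeros((n, 1 + (n_e - 1) + (n_h - 1)))
    X[:, 0] = 1.0
    mask_e = ei > 0
    X[np.flatnonzero(mask_e), ei[mask_e]] = 1.0
    mask_h = hi > 0
    X[np.flatnonzero(mask_h), n_e - 1 + hi[mask_h]] = 1.0
    y = t["value"].to_numpy(dtype=float)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("singular ls-means fit (confounded hybrid/environment labels)")
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2_E = float(resid @ resid / dof) if dof > 0 else float("nan")

    env_eff = np.r_[0.0, beta[1:n_e]]
    hyb_eff = np.r_[0.0, beta[n_e : n_e + n_h - 1]]
    lsmean = beta[0] + hyb_eff + env_eff.mean()
    n_env = t.groupby("hybrid")["environment"].nunique()
    table = pd.DataFrame(
        {
            "hybrid": hybrids,
            "lsmean": lsmean,
            "n_env": n_env.loc[hybrids].to_numpy(),
        }
    )
    return LsMeans(table, sigma2_E)
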