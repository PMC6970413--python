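"""Cohort-level statistics: rank and linear correlations and 2^-ddCT
relative gene-expression quantification.

Conventions: two-sided p-values throughout; Spearman uses midrank ties and an
exact permutation p-value for n <= 9 (t-approximation above); no multiple-
testing correction by default (optional Benjamini-Hochberg column in
:func:`correlation_report`).
"""

from __future__ import annotations

import itertools
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "spearman_test",
    "pearson_test",
    "ddct_fold_change",
    "correlation_report",
]

EXACT_N_MAX = 9


def _validate_pair(x, y, min_n: int = 3) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance in an input")
    return x, y


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of midrank vectors (tie-aware Spearman rho)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation with an exact small-sample p-value.

    Midranks handle ties.  For n <= 9 the two-sided p is computed by full
    enumeration of the n! equally likely rank pairings under independence:
    ``p = P(|rho_perm| >= |rho_obs|)``.  For larger n the usual
    t-approximation with n-2 degrees of freedom is used.
    """
    x, y = _validate_pair(x, y)
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_rho(rx, ry)
    if n <= EXACT_N_MAX:
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        ryc = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc @ rxc) * np.sum(ryc**2, axis=1))
        rhos = (ryc @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif abs(rho) >= 1.0 - 1e-13:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def pearson_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson correlation with the two-sided t-transform p (n-2 df)."""
    x, y = _validate_pair(x, y)
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def ddct_fold_change(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "18s",
    control_group: str = "control",
) -> pd.DataFrame:
    """Livak 2^-ddCT relative quantification.

    ``ct`` is a tidy table with columns ``sample_id, group, gene, ct``.
    Per sample: ``dCT = ct(target) - ct(reference)``; ``ddCT`` centres dCT on
    the arithmetic mean over the control group; ``fold = 2**(-ddCT)``.  The
    control-group mean ddCT is therefore 0 by construction.
    """
    required = {"sample_id", "group", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"CT table must have columns {sorted(required)}")
    wide = ct.pivot_table(index=["sample_id", "group"], columns="gene", values="ct", aggfunc="mean")
    if target_gene not in wide.columns:
        raise ValueError(f"no CT values for target gene {target_gene!r}")
    if reference_gene not in wide.columns:
        raise ValueError(f"no CT values for reference gene {reference_gene!r}")
    missing_ref = wide.index[wide[reference_gene].isna()].get_level_values("sample_id").tolist()
    if missing_ref:
        raise ValueError(f"missing reference CT ({reference_gene}) for sample(s): {missing_ref}")
    missing_tgt = wide.index[wide[target_gene].isna()].get_level_values("sample_id").tolist()
    if missing_tgt:
        raise ValueError(f"missing target CT ({target_gene}) for sample(s): {missing_tgt}")
    out = wide.reset_index()[["sample_id", "group"]].copy()
    out["dct"] = (wide[target_gene] - wide[reference_gene]).to_numpy()
    ctrl = out.loc[out["group"] == control_group, "dct"]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} is empty")
    out["ddct"] = out["dct"] - ctrl.mean()
    out["fold"] = 2.0 ** (-out["ddct"])
    return out


_METHODS = {"spearman": spearman_test, "pearson": pearson_test}


def correlation_report(
    cohort: pd.DataFrame,
    pairs: Sequence[Tuple[str, str, str]],
    symptomatic_only: bool = False,
    region: str | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Tidy correlation table: one row per (x, y, method) pair.

    ``symptomatic_only`` keeps animals with score > 0; ``region`` filters the
    per-region rows of the cohort table first.  ``bh_adjust`` appends a
    Benjamini-Hochberg adjusted-p column (raw p-values are always reported).
    """
    df = cohort
    if region is not None:
        if "region" not in df.columns:
            raise ValueError("cohort table has no 'region' column")
        df = df[df["region"] == region]
    if symptomatic_only:
        if "score" not in df.columns:
            raise ValueError("cohort table has no 'score' column")
        df = df[df["score"] > 0]
    if df.empty:
        raise ValueError("no rows left in the cohort after filtering")
    rows = []
    for xvar, yvar, method in pairs:
        if method not in _METHODS:
            raise ValueError(f"unknown method {method!r}; use one of {sorted(_METHODS)}")
        for v in (xvar, yvar):
            if v not in df.columns:
                raise ValueError(f"unknown variable {v!r}")
        sub = df[[xvar, yvar]].dropna()
        if xvar == yvar:
            coef, p = 1.0, 0.0
        else:
            coef, p = _METHODS[method](sub[xvar].to_numpy(), sub[yvar].to_numpy())
        rows.append(
            {
                "x": xvar,
                "y": yvar,
                "method": method,
                "n": len(sub),
                "coefficient": coef,
                "p": p,
                "symptomatic_only": symptomatic_only,
                "region": region if region is not None else "all",
            }
        )
    out = pd.DataFrame(rows)
    if bh_adjust:
        out["p_bh"] = sps.false_discovery_control(out["p"].to_numpy(), method="bh")
    return out
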