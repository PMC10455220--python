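"""Mutation-synergy association: ANOVA effect sizes and Storey q-values.

Each binary genomic alteration is tested against per-cell-line combination
synergy scores by one-way fixed-effects ANOVA (with a binary factor this is
exactly the pooled two-sample t-test: F = t^2 and the p-values coincide),
reported with Cohen's d on the pooled standard deviation, and corrected by
the Storey-Tibshirani q-value with a smoother-based pi0 estimate.  The
screening thresholds follow the pharmacogenomic-scan convention: p < 0.001
and q < 0.25, with at least ``min_group`` cell lines on each side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import MutationMatrix

__all__ = [
    "AssociationResult",
    "anova_association",
    "storey_qvalues",
    "run_association_scan",
    "split_high_low",
    "plot_volcano",
]


@dataclass
class AssociationResult:
    gene: str
    n_mut: int
    n_wt: int
    delta_mean: float
    cohens_d: float
    f_stat: float
    pvalue: float
    qvalue: float
    significant: bool


def anova_association(synergy, mutated, covariate=None) -> tuple[float, float, float, float]:
    """Association of a binary alteration with synergy scores.

    Returns ``(f_stat, pvalue, cohens_d, delta_mean)``.  Without a covariate
    this is one-way ANOVA on ``synergy ~ mutated``; with a categorical
    covariate a two-factor fixed-effects model is fitted and the mutation
    main-effect F is reported.  Cohen's d uses the pooled standard
    deviation; delta_mean is mean(mutant) - mean(wild-type).
    """
    y = np.asarray(synergy, dtype=float)
    g = np.asarray(mutated)
    if y.shape != g.shape:
        raise ValueError("synergy and mutation vectors must have equal length")
    mut = y[g == 1]
    wt = y[g == 0]
    if len(mut) == 0 or len(wt) == 0:
        raise ValueError("both groups must be non-empty")
    delta = float(mut.mean() - wt.mean())
    n1, n2 = len(mut), len(wt)
    df = n1 + n2 - 2
    pooled_var = (
        ((n1 - 1) * mut.var(ddof=1) + (n2 - 1) * wt.var(ddof=1)) / df if df > 0 else 0.0
    )
    if pooled_var == 0:
        d = 0.0 if delta == 0 else np.sign(delta) * np.inf
        if delta == 0:
            return 0.0, 1.0, 0.0, 0.0
        return np.inf, 0.0, float(d), delta
    d = delta / np.sqrt(pooled_var)
    if covariate is None:
        t = delta / np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
        f = t * t
        p = 2.0 * stats.t.sf(abs(t), df)
        return float(f), float(p), float(d), delta
    dfm = pd.DataFrame({"y": y, "mut": g.astype(int), "cov": np.asarray(covariate)})
    model = sm.OLS.from_formula("y ~ C(mut) + C(cov)", data=dfm).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f = float(table.loc["C(mut)", "F"])
    p = float(table.loc["C(mut)", "PR(>F)"])
    return f, p, float(d), delta


def storey_qvalues(pvalues, pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Storey-Tibshirani q-values with smoother-based pi0 estimation.

    pi0 is estimated on the lambda grid 0.05, 0.10, ..., 0.95 as the
    fraction of p-values above each lambda (scaled by 1/(1 - lambda)),
    smoothed by a cubic least-squares fit and evaluated at the largest
    lambda, then clamped to (0, 1].  q(p_(i)) = min_{j >= i}
    pi0 * n * p_(j) / j, monotone in p and capped at 1.  Passing ``pi0=1``
    reproduces Benjamini-Hochberg exactly.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if pi0 is None:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
        if n < 100:
            # smoother estimate is unstable for small scans; use the
            # conservative pi0 = 1 (pure BH) instead
            pi0 = 1.0
        else:
            coef = np.polyfit(lam, pi0_lam, deg=3)
            pi0 = float(np.polyval(coef, lam[-1]))
        pi0 = min(1.0, max(pi0, 1.0 / n))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * n * ranked / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out, float(pi0)


def run_association_scan(
    mutations: MutationMatrix,
    synergy: pd.Series | dict,
    min_group: int = 3,
    p_max: float = 0.001,
    fdr_max: float = 0.25,
    covariate: pd.Series | None = None,
) -> list[AssociationResult]:
    """Scan every alteration with adequate group sizes; q over the tested set.

    Cell lines are aligned by intersecting the mutation matrix with the
    synergy vector (mismatches are logged as a warning).  Genes with fewer
    than ``min_group`` mutant or wild-type lines are skipped.  Results are
    sorted by p-value; the ``significant`` flag requires p < p_max AND
    q < fdr_max.
    """
    syn = pd.Series(synergy, dtype=float)
    common = [cl for cl in mutations.cell_lines if cl in syn.index]
    dropped = set(mutations.cell_lines) ^ set(syn.index)
    if dropped:
        warnings.warn(f"{len(dropped)} cell lines not shared between inputs were dropped")
    if not common:
        warnings.warn("no shared cell lines; empty scan")
        return []
    mat = mutations.data.loc[common]
    y = syn.loc[common].to_numpy()
    cov = covariate.loc[common].to_numpy() if covariate is not None else None
    tested = []
    for gene in mat.columns:
        g = mat[gene].to_numpy()
        n_mut = int(g.sum())
        n_wt = len(g) - n_mut
        if n_mut < min_group or n_wt < min_group:
            continue
        f, p, d, delta = anova_association(y, g, covariate=cov)
        tested.append((gene, n_mut, n_wt, delta, d, f, p))
    if not tested:
        warnings.warn("no testable gene after the minimum-group filter")
        return []
    qvals, _pi0 = storey_qvalues([t[6] for t in tested])
    out = [
        AssociationResult(
            gene=gene, n_mut=n_mut, n_wt=n_wt, delta_mean=delta, cohens_d=d,
            f_stat=f, pvalue=p, qvalue=float(q),
            significant=bool(p < p_max and q < fdr_max),
        )
        for (gene, n_mut, n_wt, delta, d, f, p), q in zip(tested, qvals)
    ]
    out.sort(key=lambda r: (r.pvalue, r.gene))
    return out


def split_high_low(synergy: pd.Series | dict) -> pd.Series:
    """Median split: top half 'higher' synergy, bottom half 'lower'.

    Cell lines are ranked by score descending; the top ceil(n/2) are labeled
    ``higher``, the rest ``lower``.  Ties at the boundary are broken by
    cell-line name ascending so the split is deterministic.
    """
    syn = pd.Series(synergy, dtype=float)
    if len(syn) < 2:
        raise ValueError("need at least two cell lines to split")
    order = sorted(syn.index, key=lambda cl: (-syn[cl], cl))
    n_high = int(np.ceil(len(order) / 2))
    labels = {cl: ("higher" if i < n_high else "lower") for i, cl in enumerate(order)}
    return pd.Series({cl: labels[cl] for cl in syn.index}, name="synergy_group")


def plot_volcano(results: list[AssociationResult], path, p_max: float = 0.001) -> None:
    """Effect size vs. -log10 p for a scan, significant genes labeled (SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    d = np.array([r.cohens_d for r in results])
    logp = -np.log10(np.maximum([r.pvalue for r in results], 1e-300))
    sig = np.array([r.significant for r in results])
    ax.scatter(d[~sig], logp[~sig], s=12, c="grey", alpha=0.6)
    ax.scatter(d[sig], logp[sig], s=18, c="crimson")
    for r in results:
        if r.significant:
            ax.annotate(r.gene, (r.cohens_d, -np.log10(max(r.pvalue, 1e-300))), fontsize=7)
    ax.axhline(-np.log10(p_max), ls="--", lw=0.8, c="black")
    ax.set_xlabel("Cohen's d (mutant - wild-type)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
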