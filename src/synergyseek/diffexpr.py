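"""Differential expression from integer counts.

The stage that turns a :class:`~synergyseek.io.CountsMatrix` into directional
up/down gene sets per (cell line, treatment vs. DMSO reference):

* TMM (trimmed mean of M-values) library-composition normalization;
* an exact negative-binomial test at a fixed dispersion, conditional on the
  pooled two-group total (the conditional distribution of one group's pooled
  count given the total is Beta-Binomial; at dispersion 0 it degenerates to
  the conditional binomial);
* Benjamini-Hochberg FDR adjustment;
* the call rule |log2FC| > 1 and FDR < 0.05 (strict inequalities).

Replicates within a (cell line, treatment) condition are scaled to a common
effective library size, rounded, and pooled before testing; the NB shape of a
pooled group of n samples is n/dispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .io import CountsMatrix

__all__ = [
    "DEResult",
    "DEGeneSet",
    "tmm_factors",
    "nb_exact_test",
    "bh_adjust",
    "call_de",
    "essential_overlap",
    "de_analysis",
]


@dataclass
class DEResult:
    gene: str
    log2fc: float
    pvalue: float
    fdr: float


@dataclass
class DEGeneSet:
    """Directional DE call sets for one (cell line, treatment) contrast."""

    cell_line: str
    treatment: str
    up: frozenset[str]
    down: frozenset[str]
    table: list[DEResult] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up and down")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene": [r.gene for r in self.table],
                "log2fc": [r.log2fc for r in self.table],
                "pvalue": [r.pvalue for r in self.table],
                "fdr": [r.fdr for r in self.table],
            }
        )
        call = np.where(
            df["gene"].isin(self.up), "up", np.where(df["gene"].isin(self.down), "down", "ns")
        )
        df["call"] = call
        return df


# ---------------------------------------------------------------------------
# TMM normalization


def _quantile_ref(counts: np.ndarray) -> int:
    # reference sample: 75th-percentile count fraction closest to the mean of those
    lib = counts.sum(axis=0)
    q75 = np.array([np.quantile(counts[:, j], 0.75) for j in range(counts.shape[1])])
    f = q75 / lib
    return int(np.argmin(np.abs(f - f.mean())))


def tmm_factors(counts: CountsMatrix | np.ndarray | pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean rescaled to 1.

    M-values (log2 relative-proportion ratios to the reference sample) are
    trimmed 30% from each tail, A-values (average log2 abundance) 5% from
    each tail, and the factor is 2**(precision-weighted mean M) over the
    intersection of genes kept by both trims.  Genes zero in either sample
    are dropped.  A sample sharing no nonzero gene with the reference gets
    factor 1 with a warning.
    """
    if isinstance(counts, CountsMatrix):
        mat = counts.counts.to_numpy(dtype=float)
        names = counts.sample_ids
    elif isinstance(counts, pd.DataFrame):
        mat = counts.to_numpy(dtype=float)
        names = list(counts.columns)
    else:
        mat = np.asarray(counts, dtype=float)
        names = list(range(mat.shape[1]))
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero total count")
    ref = _quantile_ref(mat)
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref:
            factors[j] = _tmm_pair(mat[:, j], mat[:, j], lib[j], lib[j])
            continue
        factors[j] = _tmm_pair(mat[:, j], mat[:, ref], lib[j], lib[ref])
    # rescale so the geometric mean of factors is 1
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=names, name="tmm_factor")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float) -> float:
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        warnings.warn("sample shares no nonzero gene with the reference; factor set to 1")
        return 1.0
    o, r = obs[keep], ref[keep]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # asymptotic delta-method variance of M, used as precision weight
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    n = len(m)
    if n == 0:
        return 1.0
    lo_m = int(np.floor(n * 0.3)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * 0.05)) + 1
    hi_a = n + 1 - lo_a
    rank_m = m.argsort().argsort() + 1  # 1-based ranks
    rank_a = a.argsort().argsort() + 1
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


# ---------------------------------------------------------------------------
# exact NB test


def _cond_logpmf(k: np.ndarray, t: int, r1: float, r2: float) -> np.ndarray:
    """log P(A = k | A + B = t) for A ~ NB(r1, p), B ~ NB(r2, p), equal means.

    The conditional law is Beta-Binomial(t, r1, r2):
    P(k|t) = C(t,k) B(k+r1, t-k+r2) / B(r1, r2).
    """
    k = np.asarray(k)
    return (
        gammaln(t + 1)
        - gammaln(k + 1)
        - gammaln(t - k + 1)
        + gammaln(k + r1)
        + gammaln(t - k + r2)
        - gammaln(t + r1 + r2)
        + gammaln(r1 + r2)
        - gammaln(r1)
        - gammaln(r2)
    )


def _binom_logpmf(k: np.ndarray, t: int, p1: float) -> np.ndarray:
    k = np.asarray(k)
    return (
        gammaln(t + 1)
        - gammaln(k + 1)
        - gammaln(t - k + 1)
        + k * np.log(p1)
        + (t - k) * np.log1p(-p1)
    )


def nb_exact_test(
    counts_treat,
    counts_ref,
    dispersion: float,
    n_treat: int = 1,
    n_ref: int = 1,
    method: str = "min_likelihood",
):
    """Two-sided exact test p-value per gene for pooled two-group counts.

    Parameters
    ----------
    counts_treat, counts_ref
        Pooled integer counts per gene (library sizes must have been
        equalized before pooling).  Scalars are accepted.
    dispersion
        NB dispersion (squared BCV) shared by all genes; 0 gives the
        conditional Binomial(t, n_treat/(n_treat+n_ref)) test.
    n_treat, n_ref
        Number of pooled samples per group; the pooled NB shape is
        n/dispersion.
    method
        ``min_likelihood`` (default): p = sum of conditional probabilities of
        all outcomes no more likely than the observed one.
        ``doubletail``: p = 2 * min(lower tail, upper tail), capped at 1
        (ties at the observed outcome counted in both tails).

    Returns p in (0, 1] per gene.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if method not in ("min_likelihood", "doubletail"):
        raise ValueError(f"unknown method {method!r}")
    a_arr = np.atleast_1d(np.asarray(counts_treat, dtype=np.int64))
    b_arr = np.atleast_1d(np.asarray(counts_ref, dtype=np.int64))
    if a_arr.shape != b_arr.shape:
        raise ValueError("count vectors must have equal length")
    out = np.ones(len(a_arr))
    for i, (a, b) in enumerate(zip(a_arr, b_arr)):
        out[i] = _exact_p(int(a), int(b), dispersion, n_treat, n_ref, method)
    if np.isscalar(counts_treat) or np.asarray(counts_treat).ndim == 0:
        return float(out[0])
    return out


def _exact_p(a: int, b: int, disp: float, n1: int, n2: int, method: str) -> float:
    t = a + b
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    if disp == 0:
        logpmf = _binom_logpmf(k, t, n1 / (n1 + n2))
    else:
        logpmf = _cond_logpmf(k, t, n1 / disp, n2 / disp)
    if method == "min_likelihood":
        # numerical tolerance keeps exact ties (symmetric outcomes) in the sum
        sel = logpmf <= logpmf[a] + 1e-9
        logp = logsumexp(logpmf[sel])
    else:
        lower = logsumexp(logpmf[: a + 1])
        upper = logsumexp(logpmf[a:])
        logp = np.log(2) + min(lower, upper)
    return float(min(1.0, np.exp(logp)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# calling and reporting


def call_de(
    table: list[DEResult],
    cell_line: str = "",
    treatment: str = "",
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> DEGeneSet:
    """Apply the significance rule: |log2FC| > lfc_min AND FDR < fdr_max.

    Both inequalities are strict, so a gene at exactly log2FC 1.0 is not
    called regardless of its FDR.
    """
    up = frozenset(r.gene for r in table if r.log2fc > lfc_min and r.fdr < fdr_max)
    down = frozenset(r.gene for r in table if r.log2fc < -lfc_min and r.fdr < fdr_max)
    return DEGeneSet(cell_line=cell_line, treatment=treatment, up=up, down=down, table=table)


def essential_overlap(down, essential) -> tuple[int, list[str]]:
    """Overlap of a down-regulated set with an essential-gene list."""
    members = sorted(set(down) & set(essential))
    return len(members), members


def de_analysis(
    cm: CountsMatrix,
    reference: str = "DMSO",
    dispersion: float = 0.16,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
    method: str = "min_likelihood",
) -> dict[tuple[str, str], DEGeneSet]:
    """Run TMM -> pooled exact NB test -> BH -> call per (cell line, treatment).

    For every cell line, each non-reference treatment is contrasted against
    that line's reference (DMSO) samples.  Counts are scaled to the common
    (geometric-mean) effective library size using TMM factors, rounded, and
    pooled within condition.  Log2FC is computed on CPM with a 0.5 pseudo-
    count.
    """
    factors = tmm_factors(cm)
    lib = cm.counts.sum(axis=0).astype(float)
    eff_lib = lib * factors
    common = float(np.exp(np.mean(np.log(eff_lib))))
    scaled = cm.counts.to_numpy(dtype=float) * (common / eff_lib.to_numpy())[None, :]
    scaled = np.round(scaled).astype(np.int64)
    scaled = pd.DataFrame(scaled, index=cm.counts.index, columns=cm.counts.columns)

    results: dict[tuple[str, str], DEGeneSet] = {}
    for cl in cm.cell_lines:
        ref_samples = cm.samples_for(cl, reference)
        if not ref_samples:
            warnings.warn(f"cell line {cl!r} has no {reference!r} samples; skipped")
            continue
        ref_pool = scaled[ref_samples].sum(axis=1).to_numpy()
        n_ref = len(ref_samples)
        for tr in cm.treatments:
            if tr == reference:
                continue
            tr_samples = cm.samples_for(cl, tr)
            if not tr_samples:
                continue
            tr_pool = scaled[tr_samples].sum(axis=1).to_numpy()
            n_tr = len(tr_samples)
            pvals = nb_exact_test(tr_pool, ref_pool, dispersion, n_tr, n_ref, method)
            fdr = bh_adjust(pvals)
            # CPM with 0.5 pseudo-count on the equalized libraries
            cpm_tr = tr_pool / (n_tr * common) * 1e6
            cpm_ref = ref_pool / (n_ref * common) * 1e6
            lfc = np.log2(cpm_tr + 0.5) - np.log2(cpm_ref + 0.5)
            table = [
                DEResult(gene=g, log2fc=float(l), pvalue=float(p), fdr=float(q))
                for g, l, p, q in zip(cm.gene_ids, lfc, pvals, fdr)
            ]
            results[(cl, tr)] = call_de(table, cl, tr, lfc_min=lfc_min, fdr_max=fdr_max)
    return results
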