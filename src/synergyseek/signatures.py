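"""Response/resistance signature construction, DE-overlap tallies and ORA.

The resistance profile holds the expression changes seen in the resistant
line under the drug alone and absent (same direction) from every sensitive
line under both the drug and the combination; the response profile holds the
changes common to all sensitive lines under drug and combination and absent
from the resistant line.  Matching is direction-specific: a gene induced in
the resistant line and repressed in a sensitive one is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import reduce

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import DEGeneSet, bh_adjust
from .io import GeneSetCollection

__all__ = [
    "ExpressionSignature",
    "EnrichmentRow",
    "build_resist_profile",
    "build_response_profile",
    "overlap_report",
    "ora_enrichment",
]


@dataclass
class ExpressionSignature:
    """A directional up/down gene-set pair queried against the library."""

    label: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        self.up = frozenset(self.up)
        self.down = frozenset(self.down)
        if self.up & self.down:
            raise ValueError("up and down sets overlap")
        if not self.up and not self.down:
            raise ValueError("signature is empty")


@dataclass
class EnrichmentRow:
    set_name: str
    overlap: int
    query_size: int
    set_size: int
    universe_size: int
    pvalue: float
    adj_pvalue: float
    significant: bool
    members: tuple[str, ...] = ()


def _require(de: dict, keys) -> None:
    for key in keys:
        if key not in de:
            raise KeyError(f"missing DE set for (cell line, treatment) = {key}")


def build_resist_profile(
    de: dict[tuple[str, str], DEGeneSet],
    resistant: str,
    sensitive: list[str],
    drug: str,
    combo: str,
    label: str = "DNRResist",
    strict: bool = False,
) -> ExpressionSignature:
    """Changes unique to the resistant line's single-drug response.

    up = up(resistant, drug) minus the union of up-sets of every sensitive
    line under drug and combination; down analogously.  With ``strict`` the
    resistant line's own combination set is subtracted as well.
    """
    required = [(resistant, drug)] + [(s, t) for s in sensitive for t in (drug, combo)]
    if strict:
        required.append((resistant, combo))
    _require(de, required)
    up = set(de[(resistant, drug)].up)
    down = set(de[(resistant, drug)].down)
    for s in sensitive:
        for t in (drug, combo):
            up -= de[(s, t)].up
            down -= de[(s, t)].down
    if strict:
        up -= de[(resistant, combo)].up
        down -= de[(resistant, combo)].down
    return ExpressionSignature(label=label, up=frozenset(up), down=frozenset(down))


def build_response_profile(
    de: dict[tuple[str, str], DEGeneSet],
    resistant: str,
    sensitive: list[str],
    drug: str,
    combo: str,
    label: str = "DNRResponse",
    relaxed: bool = False,
) -> ExpressionSignature:
    """Changes shared by all sensitive lines and absent from the resistant one.

    up = intersection of the up-sets over every sensitive line and both
    {drug, combo} conditions, minus up(resistant, drug) | up(resistant,
    combo); down analogously.  With ``relaxed`` the intersection runs over
    the drug condition only.
    """
    conditions = (drug,) if relaxed else (drug, combo)
    required = [(s, t) for s in sensitive for t in conditions] + [
        (resistant, drug),
        (resistant, combo),
    ]
    _require(de, required)
    up_sets = [de[(s, t)].up for s in sensitive for t in conditions]
    down_sets = [de[(s, t)].down for s in sensitive for t in conditions]
    up = reduce(frozenset.intersection, up_sets)
    down = reduce(frozenset.intersection, down_sets)
    up = up - de[(resistant, drug)].up - de[(resistant, combo)].up
    down = down - de[(resistant, drug)].down - de[(resistant, combo)].down
    return ExpressionSignature(label=label, up=frozenset(up), down=frozenset(down))


def overlap_report(de: dict[tuple[str, str], DEGeneSet], mode: str = "by_treatment") -> pd.DataFrame:
    """Pairwise shared-gene tallies between DE sets, direction-stratified.

    ``by_treatment``: within each cell line, compare treatment pairs; the
    percentage denominator is the union of that cell line's changes across
    all treatments (per direction).  ``by_cell_line``: within each treatment,
    compare cell-line pairs; the denominator is the union across cell lines.
    Denominators are recorded in the report.
    """
    if mode not in ("by_treatment", "by_cell_line"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    if mode == "by_treatment":
        groups = sorted({cl for cl, _ in de})
        for cl in groups:
            items = sorted(t for c, t in de if c == cl)
            for direction in ("up", "down"):
                union = set()
                for t in items:
                    union |= getattr(de[(cl, t)], direction)
                denom = len(union)
                for i, t1 in enumerate(items):
                    for t2 in items[i + 1 :]:
                        shared = len(
                            getattr(de[(cl, t1)], direction) & getattr(de[(cl, t2)], direction)
                        )
                        rows.append(
                            (cl, t1, t2, direction, shared, denom,
                             100.0 * shared / denom if denom else 0.0)
                        )
    else:
        groups = sorted({t for _, t in de})
        for tr in groups:
            items = sorted(c for c, t in de if t == tr)
            for direction in ("up", "down"):
                union = set()
                for c in items:
                    union |= getattr(de[(c, tr)], direction)
                denom = len(union)
                for i, c1 in enumerate(items):
                    for c2 in items[i + 1 :]:
                        shared = len(
                            getattr(de[(c1, tr)], direction) & getattr(de[(c2, tr)], direction)
                        )
                        rows.append(
                            (tr, c1, c2, direction, shared, denom,
                             100.0 * shared / denom if denom else 0.0)
                        )
    return pd.DataFrame(
        rows, columns=["group", "item_a", "item_b", "direction", "shared", "denominator", "pct"]
    )


def ora_enrichment(
    query,
    collection: GeneSetCollection,
    universe,
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of a query set in each pathway.

    One-sided upper-tail p per set (drawing n = |query| genes from a universe
    of N containing K pathway members, P[overlap >= k]); BH adjustment across
    the collection; rows with adjusted p < alpha are flagged.  Query members
    outside the universe are dropped with a warning; pathway sets are
    intersected with the universe.  Rows are sorted by p-value then name.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query)
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe were dropped")
        query &= universe
    n = len(query)
    N = len(universe)
    names, pvals, rows = [], [], []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        K = len(members)
        hit = query & members
        k = len(hit)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        names.append(name)
        pvals.append(min(1.0, max(p, 0.0)))
        rows.append((name, k, n, K, N, tuple(sorted(hit))))
    adj = bh_adjust(pvals) if pvals else []
    out = [
        EnrichmentRow(
            set_name=name, overlap=k, query_size=n, set_size=K, universe_size=N,
            pvalue=p, adj_pvalue=float(q), significant=bool(q < alpha), members=hit,
        )
        for (name, k, n, K, N, hit), p, q in zip(rows, pvals, adj)
    ]
    out.sort(key=lambda r: (r.pvalue, r.set_name))
    return out
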