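"""Connectivity scoring of query signatures against a perturbagen library.

Implements the Connectivity Map scoring convention: a weighted
Kolmogorov-Smirnov enrichment score (ES) per gene set, combined over the
up/down pair into a weighted total connectivity score (WTCS), then
normalized within (cell line, perturbagen type) groups into NCS by dividing
by the mean |WTCS| of same-sign members.  Positive scores mark mimics of
the query, negative scores mark reversers.

``predict_partners`` applies the candidate logic: keep perturbagens that
reverse the resistance profile and mimic the response profile, drop
ambiguous knockdown/overexpression pairs and perturbagens concordant with
both profiles, require compounds to be concordant with a knockdown of their
annotated target, aggregate to target class, and rank by cell-line support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import RankedReferenceSignature
from .signatures import ExpressionSignature

__all__ = [
    "ConnectivityResult",
    "CandidateRanking",
    "enrichment_score",
    "wtcs",
    "normalize_scores",
    "score_library",
    "predict_partners",
]


@dataclass
class ConnectivityResult:
    perturbagen_id: str
    pert_type: str
    target_gene: str
    cell_line: str
    es_up: float
    es_down: float
    wtcs: float
    ncs: float | None = None


@dataclass
class CandidateRanking:
    """One ranked candidate class (mechanism/target) of combination partners."""

    class_name: str
    members: tuple[str, ...]
    n_support_cell_lines: int
    mean_ncs_resist: float
    mean_ncs_response: float
    filters_passed: dict[str, bool] = field(
        default_factory=lambda: {
            "unambiguous_kd_oe": True,
            "single_profile": True,
            "target_concordant": True,
        }
    )


def enrichment_score(query, ranked: RankedReferenceSignature, weight: float = 0.0) -> float:
    """GSEA-style running-sum enrichment of a gene set in a ranked profile.

    Hits increment the running sum by |score|**weight normalized to sum 1
    (weight 0 gives equal steps 1/|hits|); misses decrement by 1/(N - |hits|).
    The ES is the signed maximum deviation from zero, in [-1, 1].  Query
    genes absent from the ranked list are ignored; an empty intersection
    returns 0 with a warning.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    query = frozenset(query)
    n = len(ranked.genes)
    is_hit = np.fromiter((g in query for g in ranked.genes), dtype=bool, count=n)
    n_hit = int(is_hit.sum())
    if n_hit == 0:
        warnings.warn(
            f"query shares no gene with signature {ranked.perturbagen_id!r}; ES = 0"
        )
        return 0.0
    if n_hit == n:
        return 1.0
    if weight == 0:
        hit_w = np.full(n_hit, 1.0 / n_hit)
    else:
        w = np.abs(ranked.scores[is_hit]) ** weight
        total = w.sum()
        hit_w = w / total if total > 0 else np.full(n_hit, 1.0 / n_hit)
    steps = np.full(n, -1.0 / (n - n_hit))
    steps[is_hit] = hit_w
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def wtcs(up, down, ranked: RankedReferenceSignature, weight: float = 0.0) -> tuple[float, float, float]:
    """Weighted total connectivity score of an up/down query pair.

    Returns ``(es_up, es_down, wtcs)``.  wtcs = (es_up - es_down)/2 when the
    two component scores disagree in sign, else 0.  If one set is empty the
    other's ES carries the score alone (the down-set ES negated, since
    enrichment of the down set at the top of a profile means the profile
    opposes the query).
    """
    up, down = frozenset(up), frozenset(down)
    if up & down:
        raise ValueError("up and down query sets overlap")
    if not up and not down:
        raise ValueError("both query sets empty")
    if not up:
        b = enrichment_score(down, ranked, weight)
        return 0.0, b, -b
    if not down:
        a = enrichment_score(up, ranked, weight)
        return a, 0.0, a
    a = enrichment_score(up, ranked, weight)
    b = enrichment_score(down, ranked, weight)
    score = (a - b) / 2.0 if a * b <= 0 else 0.0
    return a, b, score


def normalize_scores(results: list[ConnectivityResult]) -> list[ConnectivityResult]:
    """Fill ``ncs`` in place: wtcs / mean |wtcs| of same-sign group members.

    Groups are (cell_line, pert_type).  A zero wtcs normalizes to 0; if a
    group somehow has no same-sign member the raw wtcs is kept with a
    warning.
    """
    groups: dict[tuple[str, str], list[ConnectivityResult]] = {}
    for r in results:
        groups.setdefault((r.cell_line, r.pert_type), []).append(r)
    for members in groups.values():
        pos = [abs(r.wtcs) for r in members if r.wtcs > 0]
        neg = [abs(r.wtcs) for r in members if r.wtcs < 0]
        mu_pos = float(np.mean(pos)) if pos else 0.0
        mu_neg = float(np.mean(neg)) if neg else 0.0
        for r in members:
            if r.wtcs == 0:
                r.ncs = 0.0
            elif r.wtcs > 0:
                r.ncs = r.wtcs / mu_pos if mu_pos > 0 else _warn_raw(r)
            else:
                r.ncs = r.wtcs / mu_neg if mu_neg > 0 else _warn_raw(r)
    return results


def _warn_raw(r: ConnectivityResult) -> float:
    warnings.warn(
        f"no same-sign member to normalize {r.perturbagen_id!r}; keeping raw wtcs"
    )
    return r.wtcs


def score_library(
    query: ExpressionSignature,
    library: list[RankedReferenceSignature],
    weight: float = 0.0,
) -> list[ConnectivityResult]:
    """Score one query signature against every library signature, NCS-normalized."""
    results = []
    for sig in library:
        a, b, w = wtcs(query.up, query.down, sig, weight)
        results.append(
            ConnectivityResult(
                perturbagen_id=sig.perturbagen_id,
                pert_type=sig.pert_type,
                target_gene=sig.target_gene,
                cell_line=sig.cell_line,
                es_up=a,
                es_down=b,
                wtcs=w,
            )
        )
    return normalize_scores(results)


def predict_partners(
    resist: ExpressionSignature,
    response: ExpressionSignature,
    library: list[RankedReferenceSignature],
    ncs_min: float = 1.0,
    weight: float = 0.0,
) -> list[CandidateRanking]:
    """Rank combination-partner classes from the two query profiles.

    A (perturbagen, cell line) record supports candidacy when the resistance
    profile is reversed (ncs <= -ncs_min) and the response profile mimicked
    (ncs >= +ncs_min).  Exclusions: (a) targets whose knockdown and
    overexpression signatures score concordantly (same sign, both beyond
    ncs_min) against the same query; (b) perturbagens concordant with both
    profiles in the same direction in any cell line; (c) compounds with no
    annotated-target knockdown signature sign-concordant with them.  The
    surviving perturbagens are aggregated by target class (unannotated
    compounds form singleton classes) and ranked by the number of supporting
    cell lines, then |mean ncs vs. resistance profile|, then class name.
    """
    if not library:
        raise ValueError("empty signature library")
    res_scores = score_library(resist, library, weight)
    resp_scores = score_library(response, library, weight)
    key = lambda r: (r.perturbagen_id, r.cell_line)
    resp_by_key = {key(r): r for r in resp_scores}

    # per-record table: (pid, cell line) -> (ncs_resist, ncs_response)
    records = []
    info: dict[str, ConnectivityResult] = {}
    for r in res_scores:
        mate = resp_by_key.get(key(r))
        records.append((r, mate))
        info[r.perturbagen_id] = r

    # (a) ambiguous KD/OE pairs: same target, same-sign effect beyond threshold
    ambiguous_targets: set[str] = set()
    genetic: dict[tuple[str, str], dict[str, list[float]]] = {}
    for scores, tag in ((res_scores, "resist"), (resp_scores, "response")):
        for r in scores:
            if r.pert_type in ("knockdown", "overexpression"):
                slot = genetic.setdefault((r.target_gene, tag), {})
                slot.setdefault(r.pert_type, []).append(r.ncs)
    for (target, _tag), slot in genetic.items():
        if "knockdown" in slot and "overexpression" in slot:
            for kd in slot["knockdown"]:
                for oe in slot["overexpression"]:
                    if abs(kd) >= ncs_min and abs(oe) >= ncs_min and kd * oe > 0:
                        ambiguous_targets.add(target)
    # (b) concordant with both profiles in the same direction
    both_profile_pids: set[str] = set()
    for r, mate in records:
        if mate is None:
            continue
        if (
            abs(r.ncs) >= ncs_min
            and abs(mate.ncs) >= ncs_min
            and r.ncs * mate.ncs > 0
        ):
            both_profile_pids.add(r.perturbagen_id)

    # mean ncs per perturbagen (across cell lines) for the concordance check
    mean_res: dict[str, float] = {}
    for pid in {r.perturbagen_id for r in res_scores}:
        vals = [r.ncs for r in res_scores if r.perturbagen_id == pid]
        mean_res[pid] = float(np.mean(vals))

    def target_concordant(pid: str) -> bool:
        r = info[pid]
        if r.pert_type != "compound":
            return True
        if not r.target_gene:
            return False
        kd = [
            s
            for s in res_scores
            if s.pert_type == "knockdown" and s.target_gene == r.target_gene
        ]
        return any(abs(s.ncs) >= ncs_min and s.ncs * mean_res[pid] > 0 for s in kd)

    # support records: pass both thresholds
    support: dict[str, list[tuple[str, float, float]]] = {}
    for r, mate in records:
        if mate is None:
            continue
        if r.ncs <= -ncs_min and mate.ncs >= ncs_min:
            support.setdefault(r.perturbagen_id, []).append((r.cell_line, r.ncs, mate.ncs))

    classes: dict[str, dict] = {}
    for pid, recs in sorted(support.items()):
        r = info[pid]
        if r.pert_type in ("knockdown", "overexpression") and r.target_gene in ambiguous_targets:
            continue
        if pid in both_profile_pids:
            continue
        if not target_concordant(pid):
            continue
        cname = r.target_gene if r.target_gene else pid
        c = classes.setdefault(
            cname, {"members": set(), "cell_lines": set(), "res": [], "resp": []}
        )
        c["members"].add(pid)
        for cl, nr, np_ in recs:
            c["cell_lines"].add(cl)
            c["res"].append(nr)
            c["resp"].append(np_)

    out = [
        CandidateRanking(
            class_name=name,
            members=tuple(sorted(c["members"])),
            n_support_cell_lines=len(c["cell_lines"]),
            mean_ncs_resist=float(np.mean(c["res"])),
            mean_ncs_response=float(np.mean(c["resp"])),
        )
        for name, c in classes.items()
    ]
    out.sort(key=lambda c: (-c.n_support_cell_lines, -abs(c.mean_ncs_resist), c.class_name))
    return out
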