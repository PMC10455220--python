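"""End-to-end orchestration from a single config.

``run_pipeline`` executes, in order: differential expression, overlap
tallies, essential-gene overlap, pathway over-representation, profile
construction, connectivity-based partner ranking, Bliss scoring of any dose
matrices, and the mutation-association scan — skipping (with a logged
reason) any stage whose optional inputs are absent, so the transcriptomics
half and the synergy half run independently.  A manifest records the config
hash, seed and per-stage row counts, making every output re-derivable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .assoc import run_association_scan, split_high_low
from .connectivity import predict_partners
from .diffexpr import de_analysis, essential_overlap
from .signatures import build_resist_profile, build_response_profile, ora_enrichment, overlap_report
from .synergy import bliss_matrix_score

log = logging.getLogger("synergyseek")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    counts: str | None = None
    meta: str | None = None
    library: str | None = None
    essential: str | None = None
    gene_sets: str | None = None
    dose_matrices: list[str] = field(default_factory=list)
    mutations: str | None = None
    mutation_synergy: str | None = None  # TSV cell_line -> score for the scan
    resistant: str = "R1"
    sensitive: list[str] = field(default_factory=lambda: ["S1", "S2"])
    reference: str = "DMSO"
    drug: str = "DNR"
    combo: str = "COMBO"
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    dispersion: float = 0.16
    ncs_min: float = 1.0
    min_group: int = 3
    p_max: float = 0.001
    fdr_max_assoc: float = 0.25
    seed: int = 0
    out_dir: str = "run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        # out_dir is a location, not content: identical configs targeting
        # different directories hash identically
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write_de(de, out: Path) -> int:
    out.mkdir(parents=True, exist_ok=True)
    n = 0
    for (cl, tr), result in sorted(de.items()):
        result.to_frame().to_csv(out / f"de_{cl}_{tr}.tsv", sep="\t", index=False)
        n += 1
    return n


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage the config provides inputs for; return the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.digest(), "seed": config.seed, "stages": {}}

    de = None
    if config.counts and config.meta:
        cm = sio.read_counts_table(config.counts, config.meta)
        de = de_analysis(
            cm,
            reference=config.reference,
            dispersion=config.dispersion,
            lfc_min=config.lfc_min,
            fdr_max=config.fdr_max,
        )
        manifest["stages"]["de"] = {"n_contrasts": _write_de(de, out / "de")}
        for mode in ("by_treatment", "by_cell_line"):
            rep = overlap_report(de, mode=mode)
            rep.to_csv(out / f"overlap_{mode}.tsv", sep="\t", index=False)
        manifest["stages"]["overlap"] = {"modes": 2}
    else:
        log.info("counts/meta not provided; transcriptomics stages skipped")
        manifest["stages"]["de"] = "skipped: no counts/meta"

    if de and config.essential:
        essential = sio.read_gene_list(config.essential)
        rows = []
        for (cl, tr), d in sorted(de.items()):
            n, members = essential_overlap(d.down, essential)
            rows.append((cl, tr, n, ";".join(members)))
        pd.DataFrame(rows, columns=["cell_line", "treatment", "n_essential_down", "members"]).to_csv(
            out / "essential_overlap.tsv", sep="\t", index=False
        )
        manifest["stages"]["essential"] = {"n_rows": len(rows)}
    elif de:
        log.info("essential list not provided; stage skipped")
        manifest["stages"]["essential"] = "skipped: no essential list"

    if de and config.gene_sets:
        collection = sio.read_gene_sets(config.gene_sets)
        universe = frozenset(de[next(iter(de))].table[i].gene for i in range(len(de[next(iter(de))].table)))
        rows = []
        for (cl, tr), d in sorted(de.items()):
            for direction in ("up", "down"):
                query = getattr(d, direction)
                if not query:
                    continue
                for r in ora_enrichment(query, collection, universe):
                    rows.append(
                        (cl, tr, direction, r.set_name, r.overlap, r.query_size, r.set_size,
                         r.universe_size, r.pvalue, r.adj_pvalue, r.significant)
                    )
        pd.DataFrame(
            rows,
            columns=["cell_line", "treatment", "direction", "set", "k", "n", "K", "N",
                     "pvalue", "adj_pvalue", "significant"],
        ).to_csv(out / "ora.tsv", sep="\t", index=False)
        manifest["stages"]["ora"] = {"n_rows": len(rows)}
    elif de:
        manifest["stages"]["ora"] = "skipped: no gene sets"

    profiles = None
    if de:
        resist = build_resist_profile(
            de, config.resistant, config.sensitive, config.drug, config.combo
        )
        response = build_response_profile(
            de, config.resistant, config.sensitive, config.drug, config.combo
        )
        profiles = (resist, response)
        with open(out / "profiles.json", "w") as fh:
            json.dump(
                {
                    "config_hash": config.digest(),
                    resist.label: {"up": sorted(resist.up), "down": sorted(resist.down)},
                    response.label: {"up": sorted(response.up), "down": sorted(response.down)},
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        manifest["stages"]["profiles"] = {
            "resist": [len(resist.up), len(resist.down)],
            "response": [len(response.up), len(response.down)],
        }

    if profiles and config.library:
        library = sio.read_signature_library(config.library)
        candidates = predict_partners(profiles[0], profiles[1], library, ncs_min=config.ncs_min)
        rows = [
            (c.class_name, c.n_support_cell_lines, c.mean_ncs_resist, c.mean_ncs_response,
             ";".join(c.members))
            for c in candidates
        ]
        pd.DataFrame(
            rows,
            columns=["class", "n_support_cell_lines", "mean_ncs_resist", "mean_ncs_response",
                     "members"],
        ).to_csv(out / "candidates.tsv", sep="\t", index=False)
        manifest["stages"]["connectivity"] = {"n_classes": len(candidates)}
    elif profiles:
        log.info("library not provided; connectivity stage skipped")
        manifest["stages"]["connectivity"] = "skipped: no library"

    if config.dose_matrices:
        rows = []
        for path in config.dose_matrices:
            m = sio.read_dose_matrix(path, drug_a="drug_a", drug_b="drug_b")
            r = bliss_matrix_score(m)
            rows.append((Path(path).name, r.bliss_score, r.label))
        pd.DataFrame(rows, columns=["matrix", "bliss_score", "label"]).to_csv(
            out / "synergy.tsv", sep="\t", index=False
        )
        manifest["stages"]["synergy"] = {"n_matrices": len(rows)}
    else:
        log.info("no dose matrices provided; synergy stage skipped")
        manifest["stages"]["synergy"] = "skipped: no dose matrices"

    if config.mutations and config.mutation_synergy:
        mm = sio.read_mutation_matrix(config.mutations)
        syn = pd.read_csv(config.mutation_synergy, sep="\t", index_col=0).iloc[:, 0]
        results = run_association_scan(
            mm, syn, min_group=config.min_group, p_max=config.p_max, fdr_max=config.fdr_max_assoc
        )
        pd.DataFrame(
            [
                (r.gene, r.n_mut, r.n_wt, r.delta_mean, r.cohens_d, r.f_stat, r.pvalue,
                 r.qvalue, r.significant)
                for r in results
            ],
            columns=["gene", "n_mut", "n_wt", "delta_mean", "cohens_d", "f_stat", "pvalue",
                     "qvalue", "significant"],
        ).to_csv(out / "associations.tsv", sep="\t", index=False)
        split = split_high_low(syn)
        split.to_csv(out / "synergy_split.tsv", sep="\t", header=["group"], index_label="cell_line")
        manifest["stages"]["assoc"] = {"n_tested": len(results)}
    else:
        log.info("mutations/synergy not provided; association stage skipped")
        manifest["stages"]["assoc"] = "skipped: no mutation data"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
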