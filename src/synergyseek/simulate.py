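"""Synthetic data with the statistical structure the pipeline assumes.

Every generator is a pure function of its :class:`SimConfig` (including the
seed), and returns ground truth alongside the data so each downstream stage
can be tested for parameter recovery without any download:

* ``simulate_counts`` — NB-distributed RNA-seq gene counts for a panel of
  AML-like cell lines under vehicle, two single drugs and their combination,
  with treatment-induced DE dominated by inductions (79% up by default), a
  resistance program planted only in the resistant line's single-drug
  condition, and a response program shared by the sensitive lines' drug and
  combination conditions;
* ``simulate_signature_library`` — a perturbagen reference library with
  planted reversers/mimics of those programs, exchangeable-score decoys, and
  knockdown/overexpression pairs of which a configurable subset is
  "ambiguous" (both concordant with the query);
* ``simulate_dose_matrix`` — Hill-curve monotherapies combined under Bliss
  independence with a planted excess;
* ``simulate_mutation_synergy`` — binary mutation matrices with planted
  synergy-shifting genes.

Independent random streams are derived from the single config seed with
``np.random.default_rng([seed, stream])`` so stages are individually
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CountsMatrix,
    DoseResponseMatrix,
    GeneSetCollection,
    MutationMatrix,
    RankedReferenceSignature,
)

__all__ = [
    "SimConfig",
    "LibraryConfig",
    "DoseConfig",
    "AssocConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_signature_library",
    "simulate_dose_matrix",
    "simulate_mutation_synergy",
    "simulate_gene_sets",
    "simulate_essential_genes",
]

TREATMENTS = ("DMSO", "AraC", "DNR", "COMBO")


@dataclass
class LibraryConfig:
    n_perturbagens: int = 60
    n_reversers: int = 2
    kd_oe_pairs: int = 3
    n_ambiguous_pairs: int = 1
    n_genetic_decoys: int = 20  # decoy KD + OE perturbagens (each, own target)
    cell_lines: tuple[str, ...] = ("LIB_A", "LIB_B", "LIB_C")
    signal_strength: float = 4.0  # score offset separating planted program genes


@dataclass
class DoseConfig:
    conc_a: tuple[float, ...] = (0.0, 6.25, 12.5, 25.0, 50.0, 100.0)
    conc_b: tuple[float, ...] = (0.0, 6.25, 12.5, 25.0)
    ec50_a: float = 66.0
    ec50_b: float = 37.5
    hill: float = 1.0
    planted_delta: float = 15.0
    noise_sd: float = 3.0


@dataclass
class AssocConfig:
    n_cell_lines: int = 30
    n_genes: int = 50
    n_assoc_genes: int = 1
    effect_d: float = 3.0
    assoc_freq: float = 0.3
    freq_range: tuple[float, float] = (0.1, 0.4)


@dataclass
class SimConfig:
    n_genes: int = 2000
    n_cell_lines: int = 3  # first is resistant, rest sensitive
    n_replicates: int = 3
    fraction_up: float = 0.79
    de_lfc_mean: float = 2.0
    program_lfc_boost: float = 1.0  # programs are coherent strong modules
    nb_dispersion: float = 0.16
    library_size_mean: float = 3e5
    n_de_per_condition: int = 300
    program_sizes: dict = field(
        default_factory=lambda: {
            "resist_up": 60,
            "resist_down": 30,
            "response_up": 40,
            "response_down": 10,
        }
    )
    library: LibraryConfig = field(default_factory=LibraryConfig)
    dose: DoseConfig = field(default_factory=DoseConfig)
    assoc: AssocConfig = field(default_factory=AssocConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cell_lines < 2 or self.n_replicates <= 0:
            raise ValueError("sizes must be positive (and >= 2 cell lines)")
        if not 0.0 <= self.fraction_up <= 1.0:
            raise ValueError("fraction_up must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if sum(self.program_sizes.values()) + self.n_de_per_condition > self.n_genes:
            raise ValueError("program sizes plus per-condition DE exceed n_genes")
        if self.library.n_reversers > self.library.n_perturbagens:
            raise ValueError("n_reversers exceeds n_perturbagens")

    @property
    def cell_line_names(self) -> list[str]:
        return ["R1"] + [f"S{i}" for i in range(1, self.n_cell_lines)]

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]


@dataclass
class SimTruth:
    """Ground truth planted by the generators."""

    planted_de: dict = field(default_factory=dict)  # (cell_line, treatment) -> {up, down}
    resist_program: dict = field(default_factory=lambda: {"up": frozenset(), "down": frozenset()})
    response_program: dict = field(default_factory=lambda: {"up": frozenset(), "down": frozenset()})
    planted_partners: tuple[str, ...] = ()
    planted_partner_class: str = ""
    ambiguous_targets: tuple[str, ...] = ()
    planted_delta: float = 0.0
    assoc_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        resist = self.resist_program["up"] | self.resist_program["down"]
        response = self.response_program["up"] | self.response_program["down"]
        if resist & response:
            raise ValueError("resistance and response programs overlap")


# ---------------------------------------------------------------------------
# counts


def simulate_counts(config: SimConfig) -> tuple[CountsMatrix, SimTruth]:
    """NB counts for cell lines x treatments x replicates, with planted DE.

    Counts ~ NB(mean = relative abundance x library size x 2^lfc,
    dispersion).  Planted DE genes carry |lfc| >= ``de_lfc_mean``; all other
    genes have lfc 0.  The resistance program is planted only in the
    resistant line's single-drug (DNR) condition; the response program in
    every sensitive line's DNR and COMBO conditions.  The expected up:down
    ratio among generically planted DE genes is ``fraction_up``.
    """
    rng = np.random.default_rng([config.seed, 0])
    genes = np.array(config.gene_names)
    lines = config.cell_line_names
    ps = config.program_sizes

    # baseline relative abundances (lognormal composition)
    w = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    rel = w / w.sum()

    # reserve disjoint program genes, generic DE drawn from the remainder
    perm = rng.permutation(config.n_genes)
    i = 0
    resist_up = frozenset(genes[perm[i : i + ps["resist_up"]]]); i += ps["resist_up"]
    resist_down = frozenset(genes[perm[i : i + ps["resist_down"]]]); i += ps["resist_down"]
    response_up = frozenset(genes[perm[i : i + ps["response_up"]]]); i += ps["response_up"]
    response_down = frozenset(genes[perm[i : i + ps["response_down"]]]); i += ps["response_down"]
    generic_pool = perm[i:]

    gene_index = {g: j for j, g in enumerate(genes)}
    truth = SimTruth(
        resist_program={"up": resist_up, "down": resist_down},
        response_program={"up": response_up, "down": response_down},
    )

    def lfc_mag(size, boost=0.0):
        return config.de_lfc_mean + boost + rng.exponential(scale=0.5, size=size)

    # lfc array per (line, treatment): genes
    lfc: dict[tuple[str, str], np.ndarray] = {}
    for cl in lines:
        for tr in TREATMENTS:
            lfc[(cl, tr)] = np.zeros(config.n_genes)
    for cl in lines:
        for tr in ("AraC", "DNR", "COMBO"):
            chosen = rng.choice(generic_pool, size=config.n_de_per_condition, replace=False)
            up_mask = rng.random(config.n_de_per_condition) < config.fraction_up
            mags = lfc_mag(config.n_de_per_condition)
            vec = lfc[(cl, tr)]
            vec[chosen[up_mask]] += mags[up_mask]
            vec[chosen[~up_mask]] -= mags[~up_mask]
            up_set = frozenset(genes[chosen[up_mask]])
            down_set = frozenset(genes[chosen[~up_mask]])
            truth.planted_de[(cl, tr)] = {"up": set(up_set), "down": set(down_set)}

    def plant(cl, tr, members, sign):
        idx = [gene_index[g] for g in sorted(members)]
        lfc[(cl, tr)][idx] = sign * lfc_mag(len(idx), boost=config.program_lfc_boost)
        key = "up" if sign > 0 else "down"
        truth.planted_de[(cl, tr)][key] |= set(members)

    plant("R1", "DNR", resist_up, +1)
    plant("R1", "DNR", resist_down, -1)
    for cl in lines[1:]:
        for tr in ("DNR", "COMBO"):
            plant(cl, tr, response_up, +1)
            plant(cl, tr, response_down, -1)

    for key in truth.planted_de:
        truth.planted_de[key] = {
            "up": frozenset(truth.planted_de[key]["up"]),
            "down": frozenset(truth.planted_de[key]["down"]),
        }

    cols, data, meta_rows = [], [], []
    for cl in lines:
        for tr in TREATMENTS:
            mu_gene = rel * config.library_size_mean * np.exp2(lfc[(cl, tr)])
            for rep in range(1, config.n_replicates + 1):
                if config.nb_dispersion == 0:
                    counts = rng.poisson(mu_gene)
                else:
                    n_shape = 1.0 / config.nb_dispersion
                    p = n_shape / (n_shape + mu_gene)
                    counts = rng.negative_binomial(n_shape, p)
                sid = f"{cl}_{tr}_r{rep}"
                cols.append(sid)
                data.append(counts)
                meta_rows.append((sid, cl, tr, rep))
    counts_df = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "cell_line", "treatment", "replicate"]
    ).set_index("sample")
    return CountsMatrix(counts=counts_df, meta=meta), truth


# ---------------------------------------------------------------------------
# signature library


def simulate_signature_library(
    config: SimConfig, truth: SimTruth
) -> tuple[list[RankedReferenceSignature], SimTruth]:
    """Perturbagen library with planted reversers, decoys and KD/OE pairs.

    Planted reverser compounds (all annotated with the same synthetic target,
    which also gets a concordant knockdown signature) score the resistance
    program's up-genes at the bottom and the response program's up-genes at
    the top of their profiles, so they reverse one query and mimic the
    other.  Decoy compounds carry exchangeable N(0, 1) scores and no target
    annotation.  ``kd_oe_pairs`` knockdown/overexpression pairs are added;
    the first ``n_ambiguous_pairs`` of them are both planted concordant with
    the query (the ambiguity the partner filter must remove).
    """
    lib = config.library
    rng = np.random.default_rng([config.seed, 1])
    genes = config.gene_names
    n = config.n_genes

    r_up = sorted(truth.resist_program["up"])
    r_down = sorted(truth.resist_program["down"])
    p_up = sorted(truth.response_program["up"])
    p_down = sorted(truth.response_program["down"])
    gene_index = {g: j for j, g in enumerate(genes)}

    def reverser_scores() -> np.ndarray:
        """Scores opposing the resistance program and mimicking response."""
        s = rng.normal(size=n)
        off = lib.signal_strength
        for gset, sign in ((r_up, -1), (r_down, +1), (p_up, +1), (p_down, -1)):
            idx = [gene_index[g] for g in gset]
            s[idx] = sign * (off + np.abs(rng.normal(size=len(idx))))
        return s

    sigs: list[RankedReferenceSignature] = []
    target_class = "TGTR"
    partner_ids = []
    for k in range(lib.n_reversers):
        pid = f"CPD_REV{k + 1}"
        partner_ids.append(pid)
        for cl in lib.cell_lines:
            sigs.append(
                RankedReferenceSignature(
                    perturbagen_id=pid, pert_type="compound", target_gene=target_class,
                    cell_line=cl, genes=list(genes), scores=reverser_scores(),
                )
            )
    # concordant knockdown of the planted target (supports the compound filter)
    if lib.n_reversers > 0:
        for cl in lib.cell_lines:
            sigs.append(
                RankedReferenceSignature(
                    perturbagen_id="KD_TGTR", pert_type="knockdown", target_gene=target_class,
                    cell_line=cl, genes=list(genes), scores=reverser_scores(),
                )
            )

    ambiguous = []
    for k in range(lib.kd_oe_pairs):
        target = f"PAIR{k + 1}"
        planted = k < lib.n_ambiguous_pairs
        if planted:
            ambiguous.append(target)
        for ptype, pid in (("knockdown", f"KD_{target}"), ("overexpression", f"OE_{target}")):
            for cl in lib.cell_lines:
                scores = reverser_scores() if planted else rng.normal(size=n)
                sigs.append(
                    RankedReferenceSignature(
                        perturbagen_id=pid, pert_type=ptype, target_gene=target,
                        cell_line=cl, genes=list(genes), scores=scores,
                    )
                )

    n_decoys = lib.n_perturbagens - lib.n_reversers
    for k in range(n_decoys):
        pid = f"CPD_DEC{k + 1:03d}"
        for cl in lib.cell_lines:
            sigs.append(
                RankedReferenceSignature(
                    perturbagen_id=pid, pert_type="compound", target_gene="",
                    cell_line=cl, genes=list(genes), scores=rng.normal(size=n),
                )
            )
    # genetic decoys: random KD and OE signatures, each with its own target,
    # so NCS group normalization is driven by the bulk library as in CMap
    for k in range(lib.n_genetic_decoys):
        for ptype, prefix in (("knockdown", "KD_DEC"), ("overexpression", "OE_DEC")):
            pid = f"{prefix}{k + 1:03d}"
            for cl in lib.cell_lines:
                sigs.append(
                    RankedReferenceSignature(
                        perturbagen_id=pid, pert_type=ptype, target_gene=f"DEC{k + 1:03d}",
                        cell_line=cl, genes=list(genes), scores=rng.normal(size=n),
                    )
                )

    truth.planted_partners = tuple(partner_ids)
    truth.planted_partner_class = target_class
    truth.ambiguous_targets = tuple(ambiguous)
    return sigs, truth


# ---------------------------------------------------------------------------
# dose matrices


def _hill(conc: np.ndarray, ec50: float, h: float) -> np.ndarray:
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        y = 1.0 / (1.0 + (ec50 / np.where(conc > 0, conc, np.nan)) ** h)
    return np.where(conc > 0, y, 0.0)


def simulate_dose_matrix(
    config: SimConfig, drug_a: str = "DNR", drug_b: str = "PARTNER"
) -> tuple[DoseResponseMatrix, SimTruth]:
    """Dose grid with Hill monotherapies and a planted Bliss excess.

    Combination viability = Bliss-expected viability - planted_delta +
    N(0, noise_sd), clamped to [0, 120].  Monotherapy rows are noise-free so
    the planted excess is exactly identifiable at noise 0.
    """
    d = config.dose
    rng = np.random.default_rng([config.seed, 2])
    conc_a = np.asarray(d.conc_a, dtype=float)
    conc_b = np.asarray(d.conc_b, dtype=float)
    y_a = _hill(conc_a, d.ec50_a, d.hill)
    y_b = _hill(conc_b, d.ec50_b, d.hill)
    expected = y_a[:, None] + y_b[None, :] - y_a[:, None] * y_b[None, :]
    via = (1.0 - expected) * 100.0
    noise = rng.normal(scale=d.noise_sd, size=via.shape) if d.noise_sd > 0 else np.zeros_like(via)
    combo = via[1:, 1:] - d.planted_delta + noise[1:, 1:]
    via[1:, 1:] = np.clip(combo, 0.0, 120.0)
    truth = SimTruth(planted_delta=d.planted_delta)
    return (
        DoseResponseMatrix(drug_a=drug_a, drug_b=drug_b, conc_a=conc_a, conc_b=conc_b, viability=via),
        truth,
    )


# ---------------------------------------------------------------------------
# mutations vs. synergy


def simulate_mutation_synergy(
    config: SimConfig, min_group: int = 3
) -> tuple[MutationMatrix, pd.Series, SimTruth]:
    """Binary mutation matrix plus synergy scores with planted shifts.

    Synergy ~ N(0, 1), shifted by ``effect_d`` for carriers of the planted
    association genes; all other genes are mutated independently of synergy.
    Warns when a planted gene's mutant count falls below the scan's minimum
    group size (its truth is then unrecoverable).
    """
    a = config.assoc
    rng = np.random.default_rng([config.seed, 3])
    lines = [f"CL{i:03d}" for i in range(1, a.n_cell_lines + 1)]
    genes = [f"M{i:03d}" for i in range(1, a.n_genes + 1)]
    freqs = rng.uniform(*a.freq_range, size=a.n_genes)
    planted = genes[: a.n_assoc_genes]
    freqs[: a.n_assoc_genes] = a.assoc_freq
    mat = (rng.random((a.n_cell_lines, a.n_genes)) < freqs[None, :]).astype(np.int8)
    synergy = rng.normal(size=a.n_cell_lines)
    for j in range(a.n_assoc_genes):
        synergy = synergy + a.effect_d * mat[:, j]
    for j, gene in enumerate(planted):
        n_mut = int(mat[:, j].sum())
        if n_mut < min_group or (a.n_cell_lines - n_mut) < min_group:
            warnings.warn(f"planted gene {gene!r} has only {n_mut} mutant lines; truth unrecoverable")
    truth = SimTruth(assoc_genes=tuple(planted))
    mm = MutationMatrix(data=pd.DataFrame(mat, index=lines, columns=genes))
    return mm, pd.Series(synergy, index=lines, name="bliss_score"), truth


# ---------------------------------------------------------------------------
# small helpers for the end-to-end demo


def simulate_gene_sets(config: SimConfig, truth: SimTruth, n_random: int = 10) -> GeneSetCollection:
    """Pathway collection: the two planted programs plus random decoy sets."""
    rng = np.random.default_rng([config.seed, 4])
    genes = np.array(config.gene_names)
    sets = {
        "RESIST_PROGRAM": truth.resist_program["up"] | truth.resist_program["down"],
        "RESPONSE_PROGRAM": truth.response_program["up"] | truth.response_program["down"],
    }
    for k in range(n_random):
        size = int(rng.integers(20, 80))
        sets[f"RANDOM_{k + 1:02d}"] = frozenset(rng.choice(genes, size=size, replace=False))
    return GeneSetCollection(sets={k: frozenset(v) for k, v in sets.items()})


def simulate_essential_genes(config: SimConfig, fraction: float = 0.1) -> frozenset[str]:
    """A random subset of the gene universe standing in for an essential list."""
    rng = np.random.default_rng([config.seed, 5])
    k = max(1, int(fraction * config.n_genes))
    return frozenset(rng.choice(np.array(config.gene_names), size=k, replace=False))
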