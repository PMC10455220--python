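"""On-disk formats and in-memory domain containers.

Every artifact the pipeline touches — gene count tables, GMT gene sets, the
perturbagen reference-signature library, dose-response viability matrices and
binary mutation matrices — is read into (and written from) one of the
dataclasses below.  Readers validate aggressively and never coerce silently:
a malformed cell raises :class:`FormatError` naming its location, and every
reader/writer pair round-trips valid files bit-exactly.

Gene identifiers are HGNC-style symbols compared case-sensitively throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "CountsMatrix",
    "GeneSetCollection",
    "RankedReferenceSignature",
    "DoseResponseMatrix",
    "MutationMatrix",
    "read_counts_table",
    "write_counts_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_signature_library",
    "write_signature_library",
    "read_dose_matrix",
    "write_dose_matrix",
    "read_mutation_matrix",
    "write_mutation_matrix",
    "read_gene_list",
]

PERT_TYPES = ("compound", "knockdown", "overexpression")


class FormatError(ValueError):
    """A file violated its format contract; the message locates the offence."""


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class CountsMatrix:
    """Integer gene x sample count table with per-sample metadata.

    ``counts`` is a genes x samples DataFrame of non-negative integers;
    ``meta`` is indexed by sample id with columns ``cell_line``, ``treatment``
    and ``replicate``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene symbol {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.floor(vals)):
                bad = np.argwhere(~np.isfinite(vals) | (vals != np.floor(vals)))[0]
                raise FormatError(
                    f"non-integer count at gene {self.counts.index[bad[0]]!r}, "
                    f"sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative count at gene {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        missing = [s for s in self.counts.columns if s not in self.meta.index]
        if missing:
            raise FormatError(f"sample {missing[0]!r} missing from metadata")
        for col in ("cell_line", "treatment", "replicate"):
            if col not in self.meta.columns:
                raise FormatError(f"metadata missing column {col!r}")
        self.meta = self.meta.loc[self.counts.columns]
        # normalize axis labels so write/read round-trips compare equal
        self.counts.index.name = None
        self.counts.columns.name = None
        self.meta.index.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, cell_line: str, treatment: str) -> list[str]:
        m = self.meta
        sel = (m["cell_line"] == cell_line) & (m["treatment"] == treatment)
        return list(m.index[sel])

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.meta["cell_line"].unique())

    @property
    def treatments(self) -> list[str]:
        return sorted(self.meta["treatment"].unique())


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class RankedReferenceSignature:
    """One perturbagen expression profile: genes ranked by DE score.

    Ranks are descending in ``scores``; ties are broken by ascending gene
    symbol so output is deterministic.  ``pert_type`` is one of ``compound``,
    ``knockdown`` or ``overexpression``; knockdown/overexpression entries must
    name their ``target_gene`` (compounds may leave it empty).
    """

    perturbagen_id: str
    pert_type: str
    target_gene: str
    cell_line: str
    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.pert_type not in PERT_TYPES:
            raise FormatError(
                f"unknown pert_type {self.pert_type!r} for {self.perturbagen_id!r}"
            )
        if self.pert_type in ("knockdown", "overexpression") and not self.target_gene:
            raise FormatError(
                f"{self.pert_type} perturbagen {self.perturbagen_id!r} must name a target_gene"
            )
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise FormatError("genes and scores length mismatch")
        order = sorted(range(len(self.genes)), key=lambda i: (-self.scores[i], self.genes[i]))
        self.genes = [self.genes[i] for i in order]
        self.scores = self.scores[order]

    def rank_of(self) -> dict[str, int]:
        """1-based rank per gene (1 = highest score)."""
        return {g: i + 1 for i, g in enumerate(self.genes)}


@dataclass
class DoseResponseMatrix:
    """Percent viability over a complete concentration grid.

    Row/column 0 are the single agents; cell (0, 0) is the untreated anchor
    and is normalized to 100 at read time.
    """

    drug_a: str
    drug_b: str
    conc_a: np.ndarray
    conc_b: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.conc_a = np.asarray(self.conc_a, dtype=float)
        self.conc_b = np.asarray(self.conc_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        for name, c in (("conc_a", self.conc_a), ("conc_b", self.conc_b)):
            if c[0] != 0:
                raise FormatError(f"{name} must start at 0 (untreated anchor)")
            if np.any(np.diff(c) <= 0):
                raise FormatError(f"{name} concentrations must be strictly ascending")
            if np.any(c < 0):
                raise FormatError(f"{name} contains a negative concentration")
        if self.viability.shape != (len(self.conc_a), len(self.conc_b)):
            raise FormatError(
                f"viability grid {self.viability.shape} does not match "
                f"({len(self.conc_a)}, {len(self.conc_b)}) concentrations"
            )
        if not np.all(np.isfinite(self.viability)):
            bad = np.argwhere(~np.isfinite(self.viability))[0]
            raise FormatError(f"non-finite viability at grid cell {tuple(bad)}")


@dataclass
class MutationMatrix:
    """Binary cell line x gene alteration indicator (1 = altered)."""

    data: pd.DataFrame  # index: cell lines, columns: genes, values 0/1

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate cell line {dup!r}")
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = np.argwhere(~np.isin(vals, (0, 1)))[0]
            raise FormatError(
                f"non-binary entry at cell line {self.data.index[bad[0]]!r}, "
                f"gene {self.data.columns[bad[1]]!r}"
            )
        self.data = self.data.astype(np.int8)
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def cell_lines(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# readers / writers


def read_counts_table(path, meta_path) -> CountsMatrix:
    """Read a gene x sample count TSV plus its sample-metadata TSV.

    The counts file has a header row of sample ids and gene symbols in the
    first column.  The metadata file maps sample id -> cell_line, treatment,
    replicate.  Any duplicate gene, non-integer/negative count or sample
    absent from the metadata is rejected with a located error.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    counts = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str))
    arr = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        for i, val in enumerate(raw[col]):
            try:
                f = float(val)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric count {val!r} at gene {raw.index[i]!r}, sample {col!r}"
                ) from None
            if not float(f).is_integer():
                raise FormatError(
                    f"non-integer count {val!r} at gene {raw.index[i]!r}, sample {col!r}"
                )
            if f < 0:
                raise FormatError(
                    f"negative count {val!r} at gene {raw.index[i]!r}, sample {col!r}"
                )
            arr[i, j] = int(f)
    counts = pd.DataFrame(arr, index=raw.index.astype(str), columns=raw.columns.astype(str))
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={0: str})
    meta.index = meta.index.astype(str)
    if "replicate" in meta.columns:
        meta["replicate"] = meta["replicate"].astype(int)
        if (meta["replicate"] < 1).any():
            bad = meta.index[meta["replicate"] < 1][0]
            raise FormatError(f"non-positive replicate for sample {bad!r}")
    return CountsMatrix(counts=counts, meta=meta)


def write_counts_table(cm: CountsMatrix, path, meta_path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene")
    cm.meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB member...`` per line."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: GMT line has fewer than 3 fields")
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"line {lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"line {lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
            desc[name] = description
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


_LIBRARY_COLS = ["perturbagen_id", "pert_type", "target_gene", "cell_line", "gene", "score"]


def read_signature_library(path) -> list[RankedReferenceSignature]:
    """Read the long-format perturbagen reference library TSV.

    Columns: perturbagen_id, pert_type, target_gene, cell_line, gene, score.
    One :class:`RankedReferenceSignature` is returned per
    (perturbagen_id, cell_line), genes sorted by descending score with ties
    broken by ascending symbol.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _LIBRARY_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"library missing column {missing[0]!r}")
    df["score"] = df["score"].astype(float)
    dup = df.duplicated(subset=["perturbagen_id", "cell_line", "gene"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise FormatError(
            f"duplicate row for ({row['perturbagen_id']!r}, {row['cell_line']!r}, "
            f"{row['gene']!r})"
        )
    sigs = []
    for (pid, cl), grp in df.groupby(["perturbagen_id", "cell_line"], sort=True):
        ptypes = grp["pert_type"].unique()
        if len(ptypes) > 1:
            raise FormatError(f"perturbagen {pid!r} has conflicting pert_type values")
        targets = grp["target_gene"].unique()
        sigs.append(
            RankedReferenceSignature(
                perturbagen_id=pid,
                pert_type=ptypes[0],
                target_gene=targets[0],
                cell_line=cl,
                genes=list(grp["gene"]),
                scores=grp["score"].to_numpy(),
            )
        )
    return sigs


def write_signature_library(sigs: list[RankedReferenceSignature], path) -> None:
    rows = []
    for s in sorted(sigs, key=lambda s: (s.perturbagen_id, s.cell_line)):
        for g, sc in zip(s.genes, s.scores):
            rows.append((s.perturbagen_id, s.pert_type, s.target_gene, s.cell_line, g, sc))
    pd.DataFrame(rows, columns=_LIBRARY_COLS).to_csv(path, sep="\t", index=False)


def read_dose_matrix(path, drug_a: str = "drug_a", drug_b: str = "drug_b") -> DoseResponseMatrix:
    """Read a dose-response CSV: first row/col concentrations, body % viability.

    The grid is renormalized so the untreated (0, 0) cell equals 100; every
    other cell is scaled by the same 100/raw(0,0) factor.
    """
    raw = pd.read_csv(path, index_col=0)
    conc_a = raw.index.to_numpy(dtype=float)
    conc_b = raw.columns.to_numpy(dtype=float)
    if len(conc_a) == 0 or conc_a[0] != 0 or conc_b[0] != 0:
        raise FormatError("dose matrix missing the (0, 0) untreated anchor")
    via = raw.to_numpy(dtype=float)
    anchor = via[0, 0]
    if not np.isfinite(anchor) or anchor <= 0:
        raise FormatError("untreated anchor viability must be positive and finite")
    via = via * (100.0 / anchor)
    return DoseResponseMatrix(drug_a=drug_a, drug_b=drug_b, conc_a=conc_a, conc_b=conc_b, viability=via)


def write_dose_matrix(m: DoseResponseMatrix, path) -> None:
    df = pd.DataFrame(m.viability, index=m.conc_a, columns=m.conc_b)
    df.to_csv(path, index_label="conc")


def read_mutation_matrix(path) -> MutationMatrix:
    """Read a binary cell line x gene mutation CSV (1 = altered)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return MutationMatrix(data=df)


def write_mutation_matrix(m: MutationMatrix, path) -> None:
    m.data.to_csv(path, index_label="cell_line")


def read_gene_list(path) -> frozenset[str]:
    """Read a plain-text gene list, one symbol per line (e.g. essential genes)."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())
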