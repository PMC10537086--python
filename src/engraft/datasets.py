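"""Core domain containers and file I/O shared by every analysis stage.

The universal substrate is an ASV count table (samples x amplicon sequence
variants) plus a taxonomy table, per-sample metadata, and optionally a rooted
phylogenetic tree over the ASVs.  Everything downstream (diversity,
permutation inference, engraftment, similarity shifts) consumes the
:class:`CohortDataset` assembled here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("engraft")

#: taxonomic ranks carried by the taxonomy table, coarsest to finest
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: controlled vocabulary for the sample role field
ROLES = ("recipient_pre", "recipient_post", "donor", "healthy")
RECIPIENT_ROLES = ("recipient_pre", "recipient_post")

CLINICAL_SIGNS = (
    "diarrhea",
    "constipation",
    "vomiting_diarrhea",
    "vomiting_constipation",
)

#: metadata columns understood by the pipeline
METADATA_COLUMNS = (
    "sample_id",
    "cat_id",
    "role",
    "donor_id",
    "age_years",
    "sex",
    "clinical_signs",
    "responder",
    "antibiotics",
    "kibble",
    "fecal_score",
)

#: default per-sample read-depth floor used for QC filtering
DEFAULT_QC_FLOOR = 8600


class CohortValidationError(ValueError):
    """Raised when a cohort component violates a structural invariant."""


def unclassified_label(deepest_resolved: str) -> str:
    """Sentinel genus label for an ASV unresolved below ``deepest_resolved``."""
    return f"unclassified {deepest_resolved}"


# ---------------------------------------------------------------------------
# ASV table
# ---------------------------------------------------------------------------


class AsvTable:
    """Samples x ASVs abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and ASV ids as columns.
        Cells are non-negative read counts (or relative abundances when
        ``is_proportions`` is set; count-only operations such as
        singleton/doubleton removal then refuse to run).
    is_proportions:
        Whether cells are proportions rather than integer read counts.
    """

    def __init__(self, data: pd.DataFrame, *, is_proportions: bool = False):
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise CohortValidationError(f"duplicated sample ids: {dupes}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise CohortValidationError(f"duplicated ASV ids: {dupes}")
        values = data.to_numpy()
        if values.size and (values < 0).any():
            raise CohortValidationError("abundances must be non-negative")
        if not is_proportions:
            if values.size and not np.allclose(values, np.round(values)):
                raise CohortValidationError(
                    "non-integer cells in count mode; pass is_proportions=True "
                    "for a relative-abundance table"
                )
            data = data.astype(np.int64)
        else:
            data = data.astype(float)
        self.data = data.rename_axis(index="sample_id", columns=None)
        self.is_proportions = bool(is_proportions)

    # -- basic accessors ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def asv_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "AsvTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return AsvTable(self.data.loc[list(sample_ids)], is_proportions=self.is_proportions)

    def drop_samples(self, sample_ids: Iterable[str]) -> "AsvTable":
        keep = self.data.drop(index=list(sample_ids))
        return AsvTable(keep, is_proportions=self.is_proportions)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return (
            isinstance(other, AsvTable)
            and self.is_proportions == other.is_proportions
            and self.data.equals(other.data)
        )

    def __repr__(self) -> str:  # pragma: no cover
        kind = "proportions" if self.is_proportions else "counts"
        return f"AsvTable({self.shape[0]} samples x {self.shape[1]} ASVs, {kind})"


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a metric label."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise CohortValidationError(
                f"distance matrix shape {v.shape} does not match {n} sample ids"
            )
        if not np.allclose(v, v.T, atol=1e-12):
            raise CohortValidationError("distance matrix is not symmetric")
        v = (v + v.T) / 2.0
        if (np.diag(v) != 0).any():
            raise CohortValidationError("distance matrix diagonal must be zero")
        if v.size and v.min() < 0:
            raise CohortValidationError("distances must be non-negative")
        self.values = v

    def submatrix(self, sample_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)], self.metric)

    def between(self, a: str, b: str) -> float:
        return float(self.values[self.sample_ids.index(a), self.sample_ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleRecord:
    """Per-sample host metadata (one fecal sample from one cat)."""

    sample_id: str
    cat_id: str
    role: str
    donor_id: str | None = None
    age_years: float | None = None
    sex: str | None = None
    clinical_signs: str | None = None
    responder: str | None = None
    antibiotics: str | None = None
    kibble: str | None = None
    fecal_score: int | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise CohortValidationError(
                f"sample {self.sample_id}: role {self.role!r} not in {ROLES}"
            )
        if self.role in RECIPIENT_ROLES and not self.donor_id:
            raise CohortValidationError(
                f"recipient sample {self.sample_id} lacks a donor assignment"
            )
        if self.age_years is not None and self.age_years < 0:
            raise CohortValidationError(f"sample {self.sample_id}: negative age")
        if self.fecal_score is not None and not (1 <= self.fecal_score <= 7):
            raise CohortValidationError(
                f"sample {self.sample_id}: fecal score {self.fecal_score} outside [1, 7]"
            )


def metadata_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Assemble SampleRecords into the canonical metadata DataFrame."""
    df = pd.DataFrame([vars(r) for r in records], columns=list(METADATA_COLUMNS))
    return df.set_index("sample_id", drop=False)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate the metadata frame; returns it indexed by sample_id.

    Checks controlled vocabularies, recipient pre/post pairing and donor
    resolvability.  Missing optional fields are permitted; each analysis
    stage re-checks the columns it actually needs.
    """
    required = {"sample_id", "cat_id", "role"}
    missing = required - set(meta.columns)
    if missing:
        raise CohortValidationError(f"metadata missing required columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise CohortValidationError(f"duplicated sample ids in metadata: {dupes}")
    bad_roles = set(meta["role"]) - set(ROLES)
    if bad_roles:
        raise CohortValidationError(f"unknown roles: {sorted(bad_roles)}")

    recip = meta[meta["role"].isin(RECIPIENT_ROLES)]
    for cat_id, grp in recip.groupby("cat_id"):
        roles = sorted(grp["role"])
        if roles != ["recipient_post", "recipient_pre"]:
            raise CohortValidationError(
                f"recipient cat {cat_id!r} must have exactly one pre and one post "
                f"sample, found roles {roles}"
            )
    donor_ids = set(meta.loc[meta["role"] == "donor", "donor_id"].dropna())
    for _, row in recip.iterrows():
        if pd.isna(row.get("donor_id")) or not row.get("donor_id"):
            raise CohortValidationError(
                f"recipient sample {row['sample_id']} lacks a donor assignment"
            )
        if donor_ids and row["donor_id"] not in donor_ids:
            raise CohortValidationError(
                f"recipient {row['cat_id']} assigned to unknown donor {row['donor_id']!r}"
            )
    if "fecal_score" in meta.columns:
        scores = pd.to_numeric(meta["fecal_score"], errors="coerce").dropna()
        if ((scores < 1) | (scores > 7)).any():
            raise CohortValidationError("fecal scores must lie in [1, 7]")
    return meta.set_index("sample_id", drop=False) if meta.index.name != "sample_id" else meta


# ---------------------------------------------------------------------------
# Cohort dataset
# ---------------------------------------------------------------------------


@dataclass
class CohortDataset:
    """A complete, validated analysis input: table + taxonomy + metadata (+ tree)."""

    table: AsvTable
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame
    tree: TreeNode | None = None

    def __post_init__(self):
        self.metadata = validate_metadata(self.metadata)
        table_samples = set(self.table.sample_ids)
        meta_samples = set(self.metadata["sample_id"])
        if table_samples != meta_samples:
            only_table = sorted(table_samples - meta_samples)
            only_meta = sorted(meta_samples - table_samples)
            raise CohortValidationError(
                "metadata and table cover different samples; "
                f"table-only={only_table} metadata-only={only_meta}"
            )
        missing_tax = [a for a in self.table.asv_ids if a not in self.taxonomy.index]
        if missing_tax:
            raise CohortValidationError(
                f"{len(missing_tax)} ASVs lack taxonomy rows, e.g. {missing_tax[:5]}"
            )
        if self.tree is not None:
            leaf_names = {t.name for t in self.tree.tips()}
            missing = [a for a in self.table.asv_ids if a not in leaf_names]
            if missing:
                raise CohortValidationError(
                    f"{len(missing)} ASVs missing from tree leaves, e.g. {missing[:5]}"
                )

    # -- convenience sample selectors ---------------------------------------
    def samples_with_role(self, role: str) -> list[str]:
        return self.metadata.loc[self.metadata["role"] == role, "sample_id"].tolist()

    def recipient_cats(self) -> list[str]:
        mask = self.metadata["role"].isin(RECIPIENT_ROLES)
        return sorted(self.metadata.loc[mask, "cat_id"].unique())

    def sample_of(self, cat_id: str, role: str) -> str:
        mask = (self.metadata["cat_id"] == cat_id) & (self.metadata["role"] == role)
        hits = self.metadata.loc[mask, "sample_id"].tolist()
        if len(hits) != 1:
            raise KeyError(f"expected one {role} sample for cat {cat_id}, found {hits}")
        return hits[0]

    def donor_ids(self) -> list[str]:
        return sorted(self.metadata.loc[self.metadata["role"] == "donor", "donor_id"].dropna().unique())

    def donor_samples(self, donor_id: str) -> list[str]:
        mask = (self.metadata["role"] == "donor") & (self.metadata["donor_id"] == donor_id)
        hits = self.metadata.loc[mask, "sample_id"].tolist()
        if not hits:
            raise KeyError(f"unknown donor id {donor_id!r}")
        return hits

    def recipient_meta(self) -> pd.DataFrame:
        """One row per recipient cat with host covariates (taken from the pre sample)."""
        pre = self.metadata[self.metadata["role"] == "recipient_pre"]
        return pre.set_index("cat_id", drop=False)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _read_table_file(path: str | Path, *, orientation: str, known_samples: set[str] | None,
                     proportions: bool) -> AsvTable:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "asvs":
        df = df.T
    elif orientation == "auto" and known_samples is not None:
        row_hits = len(set(df.index) & known_samples)
        col_hits = len(set(df.columns) & known_samples)
        if col_hits > row_hits:
            df = df.T
        elif row_hits == col_hits == 0:
            raise CohortValidationError(
                "cannot orient abundance table: neither axis overlaps metadata sample ids"
            )
    return AsvTable(df, is_proportions=proportions)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if "asv_id" not in tax.columns:
        raise CohortValidationError("taxonomy file must have an 'asv_id' column")
    missing = [r for r in RANKS if r not in tax.columns]
    if missing:
        raise CohortValidationError(f"taxonomy file missing rank columns: {missing}")
    if tax["asv_id"].duplicated().any():
        raise CohortValidationError("duplicated ASV ids in taxonomy file")
    return tax.set_index("asv_id")


def apply_qc_floor(table: AsvTable, meta: pd.DataFrame, qc_floor: int) -> tuple[AsvTable, pd.DataFrame]:
    """Drop samples below the read-depth floor, warning (never silent)."""
    if table.is_proportions or qc_floor <= 0:
        return table, meta
    totals = table.sample_totals()
    low = totals[totals < qc_floor].index.tolist()
    if low:
        logger.warning(
            "QC: dropping %d sample(s) below the %d-read floor: %s",
            len(low), qc_floor, ", ".join(f"{s} ({totals[s]} reads)" for s in low),
        )
        table = table.drop_samples(low)
        meta = meta[~meta["sample_id"].isin(low)]
    return table, meta


def read_cohort(
    table_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
    tree_path: str | Path | None = None,
    *,
    qc_floor: int = DEFAULT_QC_FLOOR,
    orientation: str = "auto",
    proportions: bool = False,
) -> CohortDataset:
    """Read and validate a cohort from TSV/CSV files (+ optional newick tree).

    Samples below ``qc_floor`` total reads are dropped with a logged warning.
    ``orientation`` is ``samples`` (rows are samples), ``asvs`` (rows are
    ASVs) or ``auto`` (resolved by id overlap with the metadata).  Set
    ``proportions=True`` for a relative-abundance table; count-only steps
    (e.g. singleton/doubleton removal) will then refuse to run.
    """
    meta = pd.read_csv(metadata_path, sep=None, engine="python", dtype={"sample_id": str, "cat_id": str, "donor_id": str})
    meta = validate_metadata(meta)
    table = _read_table_file(
        table_path, orientation=orientation,
        known_samples=set(meta["sample_id"]), proportions=proportions,
    )
    table, meta = apply_qc_floor(table, meta, qc_floor)
    taxonomy = read_taxonomy(taxonomy_path)
    tree = TreeNode.read(str(tree_path)) if tree_path is not None else None
    return CohortDataset(table=table, taxonomy=taxonomy, metadata=meta, tree=tree)


def write_cohort(cohort: CohortDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort back to the documented TSV layouts; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": outdir / "asv_table.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.tsv",
    }
    cohort.table.data.rename_axis("sample_id").to_csv(paths["table"], sep="\t")
    cohort.taxonomy.rename_axis("asv_id").to_csv(paths["taxonomy"], sep="\t")
    cohort.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    if cohort.tree is not None:
        paths["tree"] = outdir / "tree.nwk"
        cohort.tree.write(str(paths["tree"]))
    return paths


def write_results(result, path: str | Path, format: str = "tsv") -> Path:
    """Write a stage result (DataFrame or object with ``to_frame``) to disk.

    Re-reading the TSV with :func:`pandas.read_csv` reproduces the tabular
    content.  ``format`` is ``tsv`` or ``json`` (records orientation).
    """
    frame = result.to_frame() if hasattr(result, "to_frame") else result
    if not isinstance(frame, pd.DataFrame):
        frame = pd.DataFrame(frame)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=2, default=str))
    else:
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'json'")
    return path
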