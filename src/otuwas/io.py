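"""Core tables and text-format readers/writers.

The canonical in-memory orientation is samples-as-rows everywhere; readers
normalize to it regardless of how the file is laid out. Identifiers are
opaque strings and never parsed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SEX_NORMALIZATION = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
}


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dups))}")


@dataclass
class OtuCountTable:
    """Integer tag counts, one row per sample, one column per OTU."""

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.sample_ids),
            len(self.otu_ids),
        ):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_samples(self, sample_ids: list[str]) -> "OtuCountTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return OtuCountTable(list(sample_ids), list(self.otu_ids), self.counts[rows])

    def select_otus(self, otu_ids: list[str]) -> "OtuCountTable":
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        cols = [idx[o] for o in otu_ids]
        return OtuCountTable(list(self.sample_ids), list(otu_ids), self.counts[:, cols])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuCountTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class RelAbundanceTable:
    """Per-sample OTU fractions; rows sum to 1 unless OTUs were filtered out."""

    sample_ids: list[str]
    otu_ids: list[str]
    abundances: np.ndarray
    # After prevalence/abundance filtering rows no longer sum to 1 by design;
    # the flag records whether the row-sum invariant is enforceable.
    normalized: bool = True

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError("abundance matrix shape inconsistent with id lists")
        if (self.abundances < 0).any() or (self.abundances > 1).any():
            raise ValueError("abundances must lie in [0, 1]")
        if self.normalized and len(self.otu_ids):
            sums = self.abundances.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = [self.sample_ids[i] for i in np.flatnonzero(np.abs(sums - 1) > 1e-9)]
                raise ValueError(f"rows do not sum to 1: {bad[:5]}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundances, index=self.sample_ids, columns=self.otu_ids)

    def select_samples(self, sample_ids: list[str]) -> "RelAbundanceTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return RelAbundanceTable(
            list(sample_ids), list(self.otu_ids), self.abundances[rows], self.normalized
        )

    def select_otus(self, otu_ids: list[str]) -> "RelAbundanceTable":
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        cols = [idx[o] for o in otu_ids]
        return RelAbundanceTable(
            list(self.sample_ids), list(otu_ids), self.abundances[:, cols], normalized=False
        )


@dataclass
class PhenotypeFrame:
    """Per-sample sex, cage and weaning weight (raw and covariate-adjusted).

    ``phenotype_adj`` is absent (None) until :func:`otuwas.preprocess.adjust_phenotype`
    has been applied.
    """

    data: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "sex", "cage", "phenotype_raw")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"missing column {col!r}")
        _check_unique(list(self.data["sample_id"]), "sample")
        raw = self.data["phenotype_raw"].to_numpy(dtype=float)
        if not np.isfinite(raw).all():
            bad = list(self.data.loc[~np.isfinite(raw), "sample_id"])
            raise ValueError(f"non-finite phenotype for samples: {bad}")
        bad_sex = set(self.data["sex"]) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"unnormalized sex values: {sorted(bad_sex)}")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def adjusted(self) -> bool:
        return "phenotype_adj" in self.data.columns

    def phenotype_adj(self, sample_ids: list[str] | None = None) -> np.ndarray:
        if not self.adjusted:
            raise ValueError("phenotype has not been adjusted yet")
        s = self.data.set_index("sample_id")["phenotype_adj"]
        if sample_ids is not None:
            missing = [x for x in sample_ids if x not in s.index]
            if missing:
                raise ValueError(f"samples missing from phenotype frame: {missing[:5]}")
            s = s.loc[sample_ids]
        return s.to_numpy(dtype=float)

    def select_samples(self, sample_ids: list[str]) -> "PhenotypeFrame":
        sub = self.data.set_index("sample_id").loc[sample_ids].reset_index()
        return PhenotypeFrame(sub)


def read_otu_table(path, orientation: str = "samples_as_rows") -> OtuCountTable:
    """Read a tab-delimited count table (header row + leading id column).

    ``orientation`` names what the file's ROWS are; the returned table is
    always samples-as-rows.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if orientation == "otus_as_rows":
        df = df.T
    sample_ids = [str(s) for s in df.index]
    otu_ids = [str(o) for o in df.columns]
    values = df.to_numpy()
    counts = np.empty(values.shape, dtype=np.int64)
    for j in range(values.shape[1]):
        col = pd.to_numeric(values[:, j], errors="coerce")
        bad = ~np.isfinite(col) | (col != np.floor(col)) | (col < 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-integer or negative count {values[i, j]!r} at "
                f"sample {sample_ids[i]!r}, OTU {otu_ids[j]!r}"
            )
        counts[:, j] = col.astype(np.int64)
    return OtuCountTable(sample_ids, otu_ids, counts)


def write_otu_table(table: OtuCountTable, path) -> None:
    df = table.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_relabundance_table(path) -> pd.DataFrame:
    """Generic samples-as-rows feature table (KO / pathway profiles)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_metadata(path) -> PhenotypeFrame:
    """Read the sample sheet (sample id, sex, cage, weaning weight in grams)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    colmap = {c.lower().strip(): c for c in df.columns}
    out = {}
    for want in ("sample_id", "sex", "cage", "weight"):
        if want not in colmap:
            raise ValueError(f"metadata is missing required column {want!r}")
        out[want] = df[colmap[want]]
    sex = out["sex"].str.strip().str.lower().map(_SEX_NORMALIZATION)
    if sex.isna().any():
        bad = sorted(set(out["sex"][sex.isna()]))
        raise ValueError(f"unrecognized sex values: {bad}")
    weight = pd.to_numeric(out["weight"], errors="coerce")
    if weight.isna().any():
        bad = list(out["sample_id"][weight.isna()])
        raise ValueError(f"missing or non-numeric weight for samples: {bad}")
    frame = pd.DataFrame(
        {
            "sample_id": out["sample_id"].astype(str),
            "sex": sex,
            "cage": out["cage"].astype(str),
            "phenotype_raw": weight.astype(float),
        }
    )
    return PhenotypeFrame(frame)


def write_metadata(pheno: PhenotypeFrame, path) -> None:
    df = pheno.data.rename(columns={"phenotype_raw": "weight"})
    df.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> dict[str, str]:
    """Two-column TSV: otu_id <tab> semicolon-delimited lineage."""
    df = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "lineage"], dtype=str)
    return dict(zip(df["otu_id"], df["lineage"]))


def read_biom_json(path) -> OtuCountTable:
    """Read a BIOM 1.0 JSON table (dense or sparse payload).

    BIOM stores observations (OTUs) as rows and samples as columns; the
    result is re-oriented to samples-as-rows.
    """
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    n_otus, n_samples = doc["shape"]
    mat = np.zeros((n_otus, n_samples), dtype=np.int64)
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    return OtuCountTable(sample_ids, otu_ids, mat.T)


def align_samples(
    table: OtuCountTable, pheno: PhenotypeFrame
) -> tuple[OtuCountTable, PhenotypeFrame]:
    """Restrict both inputs to their common samples (OTU-table order).

    Samples present on only one side are dropped with a logged warning; the
    analysis cohort is always the intersection.
    """
    meta_ids = set(pheno.sample_ids)
    common = [s for s in table.sample_ids if s in meta_ids]
    dropped = sorted(set(table.sample_ids) ^ meta_ids)
    if dropped:
        logger.warning("dropping %d unmatched samples: %s", len(dropped), dropped[:10])
    if not common:
        raise ValueError("no samples shared between OTU table and metadata")
    return table.select_samples(common), pheno.select_samples(common)
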