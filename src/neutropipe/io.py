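"""Readers, writers and the shared data model.

All tabular exchange formats are plain text: counts and metabolite matrices
as TSV (first column = feature ID, header row = sample IDs), sample metadata
and biomarker/stimulation tables as CSV, gene sets as Broad-style GMT.
Identifier matching everywhere is exact, case-sensitive string equality.
Missing values are encoded as empty cells and propagate as NaN, never as
zero — zero is a meaningful count or intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("control", "cap_admission", "cap_recovery")
STIM_CONDITIONS = ("vehicle", "lps", "kpneu")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    if dups:
        raise FormatError(f"duplicate {what} IDs: {', '.join(sorted(dups))}")


@dataclass
class CountMatrix:
    """Raw gene-by-sample count matrix.

    Parameters
    ----------
    gene_ids : sequence of unique gene identifiers (rows)
    sample_ids : sequence of unique sample identifiers (columns)
    counts : non-negative integer array, shape (n_genes, n_samples)
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise FormatError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return CountMatrix(list(gene_ids), list(self.sample_ids), self.counts[idx, :])


@dataclass
class SampleTable:
    """Per-sample metadata: subject, comparison group and severity flag."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        required = {"sample_id", "group"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"sample table missing columns: {sorted(missing)}")
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(list(df["sample_id"]), "sample")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise FormatError(
                f"unknown group values {sorted(bad)}; allowed: {GROUPS}"
            )
        if "subject_id" not in df.columns:
            df["subject_id"] = df["sample_id"]
        if "severe" not in df.columns:
            df["severe"] = False
        df["severe"] = df["severe"].astype(bool)
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def group_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in sample table")
        return str(row["group"].iloc[0])

    def samples_in_group(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return list(self.frame.loc[self.frame["group"] == group, "sample_id"])

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        """Reject inputs whose sample IDs are absent from the metadata."""
        known = set(self.frame["sample_id"])
        unknown = [s for s in sample_ids if s not in known]
        if unknown:
            raise FormatError(
                f"samples absent from sample table: {', '.join(sorted(unknown)[:10])}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets mapping set name -> (description, ordered gene list)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_desc, genes) in self.sets.items():
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return list(self.sets[name][1])

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def intersect(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Restrict every set to a measured gene universe; drop emptied sets."""
        uni = set(universe)
        out: dict[str, tuple[str, list[str]]] = {}
        for name, (desc, genes) in self.sets.items():
            kept = [g for g in genes if g in uni]
            if kept:
                out[name] = (desc, kept)
            else:
                logger.warning("gene set %s has no measured genes; dropped", name)
        return GeneSetCollection(out)


# ---------------------------------------------------------------------------
# counts TSV


def read_counts(path: str | Path) -> CountMatrix:
    """Read a genes-x-samples TSV count matrix.

    First column holds gene IDs, the header row sample IDs, the body
    non-negative integers. Lines starting with ``#`` are comments.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(c) for c in df.columns]
    try:
        body = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path.name}: non-numeric count cell ({exc})") from exc
    if np.isnan(body).any():
        i, j = np.argwhere(np.isnan(body))[0]
        raise FormatError(
            f"{path.name}: missing count at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    try:
        return CountMatrix(gene_ids, sample_ids, body)
    except FormatError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc


def _version_comment(comment: str | None) -> str | None:
    from . import __version__

    if comment is None:
        return None
    return f"# neutropipe {__version__} | {comment}"


def write_counts(cm: CountMatrix, path: str | Path, comment: str | None = None) -> None:
    """Write a CountMatrix as canonical TSV (tab-separated, UTF-8, no quoting)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        hdr = _version_comment(comment)
        if hdr:
            fh.write(hdr + "\n")
        fh.write("gene_id\t" + "\t".join(cm.sample_ids) + "\n")
        for g, row in zip(cm.gene_ids, cm.counts):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """Canonical TSV writer for result tables ('.' decimal, empty cell = NA)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        hdr = _version_comment(comment)
        if hdr:
            fh.write(hdr + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="", lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read Broad-format GMT: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a set are dropped (first occurrence kept) with a
    logged warning. An empty file yields an empty collection.
    """
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    logger.warning(
                        "%s:%d: duplicate gene %s in set %s dropped", path.name, lineno, g, name
                    )
                    continue
                seen.add(g)
                genes.append(g)
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, (desc, genes) in gsc.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# metadata / phenotype CSVs


def read_samples(path: str | Path) -> SampleTable:
    """Read sample metadata CSV with columns sample_id, group[, subject_id, severe]."""
    df = pd.read_csv(path, comment="#")
    return SampleTable(df)


def read_metabolites(path: str | Path) -> pd.DataFrame:
    """Read a metabolite-by-sample TSV intensity matrix (floats, NaN = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(list(df.index), "metabolite")
    _check_unique(list(df.columns), "sample")
    return df.astype(float)


def write_metabolites(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        hdr = _version_comment(comment)
        if hdr:
            fh.write(hdr + "\n")
        out = df.copy()
        out.index.name = "metabolite"
        out.to_csv(fh, sep="\t", na_rep="", lineterminator="\n")


BIOMARKER_FLAGS = ("in_range", "below_lloq", "above_uloq")


def read_biomarkers(path: str | Path) -> pd.DataFrame:
    """Read a long-format biomarker CSV: sample_id, analyte, value, lloq, uloq."""
    df = pd.read_csv(path, comment="#")
    required = {"sample_id", "analyte", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"biomarker table missing columns: {sorted(missing)}")
    for col in ("lloq", "uloq"):
        if col not in df.columns:
            df[col] = np.nan
    df["sample_id"] = df["sample_id"].astype(str)
    df["analyte"] = df["analyte"].astype(str)
    return df


def clean_biomarkers(table: pd.DataFrame) -> pd.DataFrame:
    """Apply limit-of-quantification imputation to a biomarker table.

    Values below the lower limit of quantification (LLOQ) are imputed as half
    the LLOQ; values above the upper limit (ULOQ) are set to the ULOQ;
    in-range values are untouched. A ``flag`` column records which rule fired.
    The operation is idempotent.
    """
    df = table.copy()
    value = df["value"].astype(float)
    lloq = df["lloq"].astype(float) if "lloq" in df else pd.Series(np.nan, index=df.index)
    uloq = df["uloq"].astype(float) if "uloq" in df else pd.Series(np.nan, index=df.index)
    if (lloq.notna() & uloq.notna() & (lloq >= uloq)).any():
        raise FormatError("biomarker table has lloq >= uloq")
    # a value flagged out of range but with no recorded limit cannot be imputed
    if "flag" in df.columns:
        if ((df["flag"] == "below_lloq") & lloq.isna()).any():
            raise FormatError("below_lloq flag present but lloq missing")
        if ((df["flag"] == "above_uloq") & uloq.isna()).any():
            raise FormatError("above_uloq flag present but uloq missing")
    below = value.notna() & lloq.notna() & (value < lloq)
    above = value.notna() & uloq.notna() & (value > uloq)
    cleaned = value.copy()
    cleaned[below] = lloq[below] / 2.0  # idempotent: lloq/2 < lloq maps to itself
    cleaned[above] = uloq[above]
    # existing flags survive re-cleaning (a capped value sits at the limit)
    if "flag" in df.columns:
        flag = df["flag"].where(df["flag"].isin(BIOMARKER_FLAGS), "in_range").copy()
    else:
        flag = pd.Series("in_range", index=df.index)
    flag[below] = "below_lloq"
    flag[above] = "above_uloq"
    df["value"] = cleaned
    df["flag"] = flag.to_numpy()
    return df


def read_stimulation(path: str | Path) -> pd.DataFrame:
    """Read ex vivo stimulation CSV: sample_id, condition, mpo.

    Conditions are vehicle / lps / kpneu; each (sample, condition) pair may
    appear at most once.
    """
    df = pd.read_csv(path, comment="#")
    required = {"sample_id", "condition", "mpo"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"stimulation table missing columns: {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    bad = set(df["condition"]) - set(STIM_CONDITIONS)
    if bad:
        raise FormatError(f"unknown stimulation conditions {sorted(bad)}")
    if df.duplicated(subset=["sample_id", "condition"]).any():
        dup = df[df.duplicated(subset=["sample_id", "condition"])].iloc[0]
        raise FormatError(
            f"duplicate stimulation row for sample {dup['sample_id']!r}, "
            f"condition {dup['condition']!r}"
        )
    if (df["mpo"].dropna() < 0).any():
        raise FormatError("negative MPO value in stimulation table")
    return df
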