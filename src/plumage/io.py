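"""Shared data types and readers/writers for every on-disk format the pipeline touches.

Conventions
-----------
* Intensity matrices are tab-separated, proteins in rows and samples in
  columns, first column the protein identifier — the orientation of typical
  search-engine LFQ exports. Missingness (not-detected) is encoded as NaN in
  memory and as an empty field on disk; readers accept a configurable token
  list because export dialects vary.
* Pathway collections use the Broad GMT dialect (pathway, description,
  members, tab-separated).
* Metadata, secretion, organ and Ct tables are plain tab-separated tables
  with a header row. All readers accept gzip-compressed files transparently.

Intensities are treated as already cross-run normalised upstream; no
renormalisation happens at the I/O layer, and missingness is preserved
exactly (no silent imputation).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_MISSING_TOKENS: tuple[str, ...] = ("", "NA", "NaN", "Filtered")

VALID_GROUPS = frozenset({"low", "high"})
VALID_SECRETION = frozenset({"secreted", "intracellular", "unknown"})
VALID_TISSUES = frozenset({"plasma", "brain", "liver", "proventriculus"})


class FormatError(ValueError):
    """Raised when an input file violates the expected format or an invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class IntensityMatrix:
    """LFQ protein abundances, proteins x samples, with explicit missingness.

    ``values`` is a float DataFrame indexed by protein id with sample ids as
    columns; NaN marks not-detected. Every non-missing value is > 0.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein id(s): {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample id(s): {dup}")
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            bad = self.values.index[np.nanmin(np.where(np.isnan(vals), np.inf, vals), axis=1) <= 0]
            raise FormatError(f"nonpositive abundance for protein(s): {bad.tolist()[:5]}")
        self.values = self.values.astype(float)
        self.values.index.name = "protein_id"

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where a value is not detected."""
        return self.values.isna()

    def detected_in(self, sample_ids: Sequence[str]) -> set[str]:
        """Protein ids detected (non-missing) in at least one of the given samples."""
        sub = self.values[list(sample_ids)]
        return set(sub.index[sub.notna().any(axis=1)])

    def subset(self, protein_ids: Iterable[str] | None = None,
               sample_ids: Iterable[str] | None = None) -> "IntensityMatrix":
        v = self.values
        if protein_ids is not None:
            v = v.loc[[p for p in protein_ids if p in v.index]]
        if sample_ids is not None:
            v = v[[s for s in sample_ids]]
        return IntensityMatrix(v.copy())


@dataclass
class AnnotationSet:
    """Protein annotations: pathway membership, secretion status, organ of origin.

    ``pathways`` maps pathway id -> set of member protein ids; ``sources``
    maps pathway id -> annotation source tag (GO, KEGG, WikiPathways);
    ``descriptions`` carries the free-text GMT description field.
    ``secretion`` maps protein id -> {secreted, intracellular, unknown};
    ``organs`` maps protein id -> set of organ labels.
    """

    pathways: dict[str, set[str]] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    secretion: dict[str, str] = field(default_factory=dict)
    organs: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, members in self.pathways.items():
            if not members:
                raise FormatError(f"pathway {pid!r} has no members")
        for prot, status in self.secretion.items():
            if status not in VALID_SECRETION:
                raise FormatError(
                    f"secretion status {status!r} for {prot!r} not in {sorted(VALID_SECRETION)}"
                )

    def merged_with(self, other: "AnnotationSet") -> "AnnotationSet":
        return AnnotationSet(
            pathways={**self.pathways, **other.pathways},
            sources={**self.sources, **other.sources},
            descriptions={**self.descriptions, **other.descriptions},
            secretion={**self.secretion, **other.secretion},
            organs={**self.organs, **other.organs},
        )

    def secretion_of(self, protein_id: str) -> str:
        return self.secretion.get(protein_id, "unknown")


@dataclass
class CtTable:
    """qPCR cycle-threshold measurements in long format.

    One row per (sample, gene, replicate): columns ``sample_id``, ``gene``,
    ``replicate``, ``ct``, ``group``, ``housekeeping`` (bool). Ct values are
    finite positive cycles.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "gene", "replicate", "ct", "group", "housekeeping")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"Ct table missing column(s): {missing}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
            raise FormatError("Ct values must be finite and positive")
        bad_groups = set(self.data["group"].str.lower()) - VALID_GROUPS
        if bad_groups:
            raise FormatError(f"unknown group label(s): {sorted(bad_groups)}")
        self.data = self.data.assign(group=self.data["group"].str.lower())

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def housekeeping_genes(self) -> list[str]:
        return sorted(self.data.loc[self.data["housekeeping"].astype(bool), "gene"].unique())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_intensity_matrix(
    path: str | Path,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
) -> IntensityMatrix:
    """Read a tab-separated proteins-x-samples LFQ matrix.

    First column is the protein id; every listed token (and only those)
    becomes MISSING. Any other cell must parse as a positive real.
    Raises :class:`FormatError` on duplicate protein ids or nonpositive
    abundances, naming the offending id.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
        na_values=(),
    )
    tokens = set(missing_tokens)
    # strip whitespace so " NA " counts as the NA token
    out = df.apply(lambda col: col.str.strip())
    masked = out.isin(tokens) | (out == "")
    try:
        numeric = out.mask(masked).astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric abundance cell in {path}: {exc}") from exc
    numeric.index = numeric.index.astype(str).str.strip()
    numeric.index.name = "protein_id"
    numeric.columns = [str(c).strip() for c in numeric.columns]
    return IntensityMatrix(numeric)


def write_intensity_matrix(matrix: IntensityMatrix, path: str | Path,
                           missing_token: str = "") -> None:
    """Write a matrix back to disk; missing cells become ``missing_token``."""
    out = matrix.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep=missing_token, lineterminator="\n")


def read_gmt(path: str | Path, source: str | None = None) -> AnnotationSet:
    """Read a Broad-dialect GMT file into pathway membership sets.

    Each line: pathway_id <TAB> description <TAB> member [<TAB> member ...].
    Duplicate members within a line are deduplicated; a line with fewer than
    three fields is rejected with its line number. ``source`` tags every
    pathway (e.g. GO / KEGG / WikiPathways); when None, the tag is inferred
    from a ``source:`` prefix in the description if present, else "unknown".
    """
    pathways: dict[str, set[str]] = {}
    sources: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            pid, desc, *members = fields
            members = [m.strip() for m in members if m.strip()]
            if not members:
                raise FormatError(f"{path}:{lineno}: pathway {pid!r} has no members")
            if pid in pathways:
                raise FormatError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            pathways[pid] = set(dict.fromkeys(members))
            descriptions[pid] = desc
            if source is not None:
                sources[pid] = source
            elif ":" in desc and desc.split(":", 1)[0] in {"GO", "KEGG", "WikiPathways"}:
                sources[pid] = desc.split(":", 1)[0]
            else:
                sources[pid] = "unknown"
    return AnnotationSet(pathways=pathways, sources=sources, descriptions=descriptions)


def write_gmt(annotations: AnnotationSet, path: str | Path) -> None:
    """Write pathway membership as GMT; members sorted for byte stability."""
    with _open_text(path, "wt") as fh:
        for pid in annotations.pathways:
            desc = annotations.descriptions.get(pid, annotations.sources.get(pid, ""))
            members = sorted(annotations.pathways[pid])
            fh.write("\t".join([pid, desc, *members]) + "\n")


_METADATA_NUMERIC = {
    "plastic_count": "Int64",
    "plastic_mass": float,
    "weight": float,
    "wing_length": float,
    "culmen_length": float,
    "head_bill_length": float,
}


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-bird sample metadata table.

    Requires ``sample_id`` and ``group`` columns; group is case-folded to
    {low, high}. Known numeric columns are typed; unknown columns are kept
    as opaque extras. Negative plastic burdens are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=("", "NA"))
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"metadata missing required column {col!r}")
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample_id(s): {dup}")
    df["group"] = df["group"].str.strip().str.lower()
    bad = set(df["group"]) - VALID_GROUPS
    if bad:
        raise FormatError(f"group labels must be low/high, got {sorted(bad)}")
    for col, dtype in _METADATA_NUMERIC.items():
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(dtype)
    for col in ("plastic_count", "plastic_mass"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise FormatError(f"negative {col} in metadata")
    if "tissue" in df.columns:
        df["tissue"] = df["tissue"].str.strip().str.lower()
        bad_t = set(df["tissue"].dropna()) - VALID_TISSUES
        if bad_t:
            raise FormatError(f"unknown tissue label(s): {sorted(bad_t)}")
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_secretion_table(path: str | Path) -> AnnotationSet:
    """Read a two-column protein_id / secretion-status table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "secretion"):
        if col not in df.columns:
            raise FormatError(f"secretion table missing column {col!r}")
    mapping = dict(zip(df["protein_id"].str.strip(), df["secretion"].str.strip().str.lower()))
    return AnnotationSet(secretion=mapping)


def write_secretion_table(annotations: AnnotationSet, path: str | Path) -> None:
    rows = sorted(annotations.secretion.items())
    pd.DataFrame(rows, columns=["protein_id", "secretion"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def read_organ_table(path: str | Path) -> AnnotationSet:
    """Read a protein_id / organ table; multiple rows per protein allowed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "organ"):
        if col not in df.columns:
            raise FormatError(f"organ table missing column {col!r}")
    organs: dict[str, set[str]] = {}
    for prot, organ in zip(df["protein_id"].str.strip(), df["organ"].str.strip()):
        organs.setdefault(prot, set()).add(organ)
    return AnnotationSet(organs=organs)


def write_organ_table(annotations: AnnotationSet, path: str | Path) -> None:
    rows = [(p, o) for p in sorted(annotations.organs) for o in sorted(annotations.organs[p])]
    pd.DataFrame(rows, columns=["protein_id", "organ"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def read_ct_table(path: str | Path) -> CtTable:
    """Read a long-format qPCR Ct table (typically triplicate wells)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str, "group": str})
    if "housekeeping" in df.columns:
        df["housekeeping"] = df["housekeeping"].astype(str).str.strip().str.lower().isin(
            {"true", "1", "yes"})
    return CtTable(df)


def write_ct_table(ct: CtTable, path: str | Path) -> None:
    ct.data.to_csv(path, sep="\t", index=False, lineterminator="\n")


def group_samples(metadata: pd.DataFrame) -> dict[str, list[str]]:
    """Map group label -> ordered sample id list."""
    return {
        g: metadata.loc[metadata["group"] == g, "sample_id"].tolist()
        for g in ("low", "high")
    }
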