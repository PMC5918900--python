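"""Data model and I/O for OTU count tables with clonal-network metadata.

The universal currency between analysis stages is :class:`OtuDataset`: a
non-negative integer count matrix (samples x OTUs), a per-OTU taxonomy table
(kingdom/phylum, lower ranks optional), and per-sample metadata describing the
position of each sample in the clonal network (ecotype, role, position along
the stolon, stolon number, amplicon marker).

Files are plain tab-separated text.  Counts may be laid out samples-as-rows
(first header token ``sample_id``) or OTUs-as-rows (first header token
``otu_id``); the transposed layout is auto-detected and normalised.  A
permissive one-file reader for spreadsheet-style exports (taxonomy columns
followed by per-sample count columns) is provided in :func:`read_merged_table`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROLES = ("mother_root", "daughter_root", "internode", "control_substrate")
POSITIONS = ("M", "D1", "D2", "NA")
MARKERS = ("bacteria_16S", "archaea_16S", "fungi_18S")

#: metadata columns, in canonical order
META_COLUMNS = ("ecotype", "role", "position", "stolon", "marker")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample.

    ``ecotype`` is an integer label (1..E) or None for control substrate;
    ``position`` is the generation index along a stolon (M, D1, D2, or NA);
    ``stolon`` is 1, 2 or None.
    """

    sample_id: str
    ecotype: int | None
    role: str
    position: str
    stolon: int | None
    marker: str

    def violations(self) -> list[tuple[str, str]]:
        """Return (code, message) pairs for every invariant this row breaks."""
        out: list[tuple[str, str]] = []
        if self.role not in ROLES:
            out.append(("bad_role", f"{self.sample_id}: unknown role {self.role!r}"))
        if self.position not in POSITIONS:
            out.append(("bad_position", f"{self.sample_id}: unknown position {self.position!r}"))
        if self.marker not in MARKERS:
            out.append(("bad_marker", f"{self.sample_id}: unknown marker {self.marker!r}"))
        if self.role == "mother_root" and not (self.position == "M" and self.stolon is None):
            out.append(("mother_position", f"{self.sample_id}: mother_root must have position M and no stolon"))
        if self.role == "daughter_root" and not (self.position in ("D1", "D2") and self.stolon in (1, 2)):
            out.append(("daughter_position", f"{self.sample_id}: daughter_root must have position D1/D2 and stolon 1/2"))
        if self.role == "control_substrate" and self.ecotype is not None:
            out.append(("control_ecotype", f"{self.sample_id}: control_substrate must have no ecotype"))
        return out


@dataclass
class ValidationReport:
    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class OtuDataset:
    """Counts + taxonomy + sample metadata, with a provenance trail.

    ``counts``: integer DataFrame indexed by sample_id with otu_id columns.
    ``taxonomy``: DataFrame indexed by otu_id with at least kingdom and phylum.
    ``samples``: DataFrame indexed by sample_id with columns
    ecotype/role/position/stolon/marker (ecotype and stolon nullable ints).
    ``provenance``: ordered list of transformation records (dicts).
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    samples: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        # normalise ordering for determinism
        self.counts = self.counts.sort_index(axis=0).sort_index(axis=1)
        self.samples = self.samples.loc[self.counts.index]
        self.taxonomy = self.taxonomy.loc[self.counts.columns]

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_meta(self, sample_id: str) -> SampleMeta:
        row = self.samples.loc[sample_id]
        return SampleMeta(
            sample_id=sample_id,
            ecotype=None if pd.isna(row["ecotype"]) else int(row["ecotype"]),
            role=str(row["role"]),
            position=str(row["position"]),
            stolon=None if pd.isna(row["stolon"]) else int(row["stolon"]),
            marker=str(row["marker"]),
        )

    def iter_meta(self) -> Iterable[SampleMeta]:
        for sid in self.counts.index:
            yield self.sample_meta(sid)

    def with_provenance(self, record: dict) -> "OtuDataset":
        return OtuDataset(self.counts, self.taxonomy, self.samples,
                          self.provenance + [record])


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _normalise_meta(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    for col in ("ecotype", "stolon"):
        meta[col] = pd.to_numeric(meta[col].replace({"NA": None, "": None}), errors="coerce").astype("Int64")
    meta["position"] = meta["position"].fillna("NA").replace({"": "NA"})
    return meta[list(META_COLUMNS)]


def read_otu_dataset(counts_path: str | Path, taxonomy_path: str | Path,
                     metadata_path: str | Path) -> OtuDataset:
    """Read the TSV triplet (counts, taxonomy, metadata) into an OtuDataset.

    Raises ``FileNotFoundError`` for missing files and ``ValueError`` for
    inconsistent sample ids or non-integer counts.
    """
    for p in (counts_path, taxonomy_path, metadata_path):
        if not Path(p).exists():
            raise FileNotFoundError(str(p))

    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.index.name == "otu_id" or str(counts.index.name).lower().startswith("otu"):
        counts = counts.T  # transposed layout: OTUs as rows
    counts.index.name = "sample_id"
    counts.columns.name = "otu_id"

    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        frac, _ = np.modf(arr.astype(float))
        if np.any(frac != 0):
            bad = counts.columns[np.any(frac != 0, axis=0)].tolist()
            raise ValueError(f"non-integer counts in OTU columns {bad[:5]}")
        counts = counts.astype(np.int64)

    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str)
    taxonomy.index.name = "otu_id"
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    meta.index.name = "sample_id"
    meta = _normalise_meta(meta)

    missing_meta = sorted(set(counts.index) - set(meta.index))
    if missing_meta:
        raise ValueError(f"samples in counts absent from metadata: {missing_meta}")
    missing_tax = sorted(set(counts.columns) - set(taxonomy.index))
    if missing_tax:
        raise ValueError(f"OTUs in counts absent from taxonomy: {missing_tax}")

    ds = OtuDataset(counts, taxonomy.loc[list(counts.columns)],
                    meta.loc[list(counts.index)],
                    provenance=[{"step": "read", "counts": str(counts_path)}])
    report = validate_dataset(ds)
    if not report.ok:
        raise ValueError("invalid dataset: " + "; ".join(m for _, m in report.errors[:10]))
    return ds


def write_otu_dataset(ds: OtuDataset, out_dir: str | Path, prefix: str = "dataset") -> dict[str, Path]:
    """Write the TSV triplet; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / f"{prefix}_counts.tsv",
        "taxonomy": out / f"{prefix}_taxonomy.tsv",
        "metadata": out / f"{prefix}_metadata.tsv",
    }
    ds.counts.to_csv(paths["counts"], sep="\t")
    ds.taxonomy.to_csv(paths["taxonomy"], sep="\t")
    meta = ds.samples.copy()
    meta.to_csv(paths["metadata"], sep="\t")
    return paths


_TAX_TOKENS = {"otu", "otu_id", "observation", "kingdom", "domain", "phylum",
               "class", "order", "family", "genus", "species", "taxonomy",
               "blast_taxonomy", "affiliation"}

DEFAULT_SAMPLE_PATTERN = re.compile(
    r"^E(?P<ecotype>\d+)[-_](?P<pos>M|D[12])(?:[._-](?P<stolon>[12]))?$", re.I)


def parse_sample_name(name: str, marker: str,
                      pattern: re.Pattern = DEFAULT_SAMPLE_PATTERN) -> SampleMeta | None:
    """Infer SampleMeta from names like ``E3-M`` or ``E3-D1.2`` (ecotype 3,
    first daughter on stolon 2). Returns None when the name does not match."""
    m = pattern.match(name)
    if not m:
        return None
    pos = m.group("pos").upper()
    if pos == "M":
        return SampleMeta(name, int(m.group("ecotype")), "mother_root", "M", None, marker)
    stolon = int(m.group("stolon")) if m.group("stolon") else 1
    return SampleMeta(name, int(m.group("ecotype")), "daughter_root", pos, stolon, marker)


def read_merged_table(path: str | Path, marker: str,
                      metadata: pd.DataFrame | None = None,
                      sample_pattern: re.Pattern = DEFAULT_SAMPLE_PATTERN) -> OtuDataset:
    """Permissive one-file reader for spreadsheet-style OTU exports.

    Rows are OTUs; leading columns whose (lowercased) header is a recognised
    taxonomy token become the taxonomy block, every remaining column is a
    sample. Sample metadata is taken from ``metadata`` when given, otherwise
    inferred from sample names via ``sample_pattern``.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        table = pd.read_excel(path)
    else:
        table = pd.read_csv(path, sep=None, engine="python")
    table = table.rename(columns=lambda c: str(c).strip())
    first = table.columns[0]
    table = table.set_index(first)
    table.index.name = "otu_id"
    tax_cols = [c for c in table.columns if c.lower() in _TAX_TOKENS]
    sample_cols = [c for c in table.columns if c not in tax_cols]
    taxonomy = table[tax_cols].astype(str)
    if "kingdom" not in taxonomy.columns:
        taxonomy["kingdom"] = "unknown"
    if "phylum" not in taxonomy.columns:
        taxonomy["phylum"] = "unknown"
    counts = table[sample_cols].fillna(0).astype(np.int64).T
    counts.index.name = "sample_id"
    counts.columns.name = "otu_id"
    if metadata is None:
        rows = []
        for sid in counts.index:
            sm = parse_sample_name(str(sid), marker, sample_pattern)
            if sm is None:
                raise ValueError(f"cannot infer metadata for sample {sid!r}; pass metadata=")
            rows.append({"sample_id": sm.sample_id, "ecotype": sm.ecotype, "role": sm.role,
                         "position": sm.position, "stolon": sm.stolon, "marker": sm.marker})
        metadata = pd.DataFrame(rows).set_index("sample_id")
    metadata = _normalise_meta(metadata)
    return OtuDataset(counts, taxonomy, metadata.loc[list(counts.index)],
                      provenance=[{"step": "read_merged", "path": str(path)}])


# ---------------------------------------------------------------------------
# validation & subsetting
# ---------------------------------------------------------------------------

def validate_dataset(ds: OtuDataset) -> ValidationReport:
    """Check every dataset invariant; violations are reported, never raised."""
    rep = ValidationReport()
    counts = ds.counts
    if set(counts.index) != set(ds.samples.index):
        rep.errors.append(("sample_mismatch", "counts and metadata sample ids differ"))
    missing_tax = sorted(set(counts.columns) - set(ds.taxonomy.index))
    if missing_tax:
        rep.errors.append(("missing_taxonomy", f"OTUs without taxonomy: {missing_tax[:5]}"))
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        rep.errors.append(("count_dtype", "counts are not integers"))
    elif (arr < 0).any():
        bad = counts.columns[(arr < 0).any(axis=0)].tolist()
        rep.errors.append(("negative_count", f"negative counts in OTUs {bad[:5]}"))
    zero_cols = counts.columns[(arr == 0).all(axis=0)].tolist() if arr.size else []
    if zero_cols:
        rep.warnings.append(("all_zero_otu", f"all-zero OTU columns: {zero_cols[:5]}"))
    for sid in counts.index:
        try:
            sm = ds.sample_meta(sid)
        except Exception as exc:  # malformed metadata row
            rep.errors.append(("bad_metadata", f"{sid}: {exc}"))
            continue
        rep.errors.extend(sm.violations())
    rep.summary = {
        "n_samples": int(ds.n_samples),
        "n_otus": int(ds.n_otus),
        "per_role": {str(k): int(v) for k, v in ds.samples["role"].value_counts().items()},
        "per_marker": {str(k): int(v) for k, v in ds.samples["marker"].value_counts().items()},
        "per_ecotype": {str(k): int(v) for k, v in ds.samples["ecotype"].value_counts().items()},
    }
    return rep


def subset_dataset(ds: OtuDataset,
                   predicate: Callable[[SampleMeta], bool] | Mapping[str, object] | None = None,
                   *, drop_empty_otus: bool = True,
                   allow_empty: bool = False,
                   description: str | None = None) -> OtuDataset:
    """Restrict the dataset to samples matching ``predicate``.

    ``predicate`` may be a callable on SampleMeta, or a mapping of metadata
    column to an allowed value / collection of values (e.g.
    ``{"role": "mother_root"}``). OTU columns that become all-zero are dropped
    unless ``drop_empty_otus`` is False.
    """
    if callable(predicate):
        keep = [sid for sid in ds.counts.index if predicate(ds.sample_meta(sid))]
        desc = description or getattr(predicate, "__name__", "predicate")
    elif predicate:
        mask = pd.Series(True, index=ds.samples.index)
        for col, val in predicate.items():
            allowed = val if isinstance(val, (set, list, tuple)) else [val]
            mask &= ds.samples[col].isin(list(allowed))
        keep = list(ds.samples.index[mask])
        desc = description or str(dict(predicate))
    else:
        keep, desc = list(ds.counts.index), description or "all"
    if not keep and not allow_empty:
        raise ValueError(f"subset {desc!r} selects no samples")
    counts = ds.counts.loc[keep]
    if drop_empty_otus and counts.shape[0]:
        counts = counts.loc[:, counts.sum(axis=0) > 0]
    elif drop_empty_otus:
        counts = counts.iloc[:, :0]
    return OtuDataset(counts, ds.taxonomy.loc[counts.columns], ds.samples.loc[keep],
                      ds.provenance + [{"step": "subset", "predicate": desc,
                                        "n_samples": len(keep), "n_otus": counts.shape[1]}])
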