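"""Data model and I/O for OTU count tables, taxonomy maps, and qPCR records.

Tables are oriented OTU-rows x sample-columns throughout; files with
samples as rows must be transposed explicitly by the caller (``transpose=True``
on :func:`read_count_table`) — orientation is never auto-detected.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DNA = "DNA"
RNA = "RNA"
LIBRARIES = (DNA, RNA)

#: catch-all taxonomic group; group frequencies always sum to 1 because every
#: OTU not listed in a taxonomy file lands here explicitly.
OTHER_GROUP = "other"


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


@dataclass
class CountTable:
    """OTU-by-sample abundance matrix with per-sample station/library labels.

    Parameters
    ----------
    data :
        DataFrame with unique OTU ids as index and unique sample ids as
        columns.  Entries are non-negative; integral when ``require_integer``
        (raw read counts), real-valued otherwise (rarefied means).
    sample_meta :
        DataFrame indexed by sample id with columns ``station`` and
        ``library`` (one of ``"DNA"``/``"RNA"``).
    """

    data: pd.DataFrame
    sample_meta: pd.DataFrame
    require_integer: bool = True

    def __post_init__(self) -> None:
        # normalized axis labels so write/read round trips are lossless
        self.data.index.name = "otu_id"
        self.data.columns.name = None
        self.sample_meta.index.name = "sample_id"
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate otu_ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample_ids: {dups}")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ValidationError("counts contain non-finite values")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at otu_id={self.data.index[r]!r}, "
                f"sample_id={self.data.columns[c]!r}"
            )
        if self.require_integer and not np.allclose(values, np.round(values)):
            r, c = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ValidationError(
                f"non-integer count at otu_id={self.data.index[r]!r}, "
                f"sample_id={self.data.columns[c]!r}"
            )
        missing = [s for s in self.data.columns if s not in self.sample_meta.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        bad_lib = [
            s
            for s in self.data.columns
            if self.sample_meta.loc[s, "library"] not in LIBRARIES
        ]
        if bad_lib:
            raise ValidationError(
                f"samples with library not in {LIBRARIES}: {bad_lib}"
            )
        if (values.sum(axis=0) <= 0).any():
            empty = self.data.columns[values.sum(axis=0) <= 0].tolist()
            raise ValidationError(f"samples with zero total counts: {empty}")

    # ------------------------------------------------------------------ #
    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def column_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def proportions(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        return self.data / self.data.sum(axis=0)

    def library(self, which: str) -> "CountTable":
        """Sub-table restricted to DNA or RNA libraries."""
        if which not in LIBRARIES:
            raise ValidationError(f"library must be one of {LIBRARIES}")
        keep = [s for s in self.data.columns if self.sample_meta.loc[s, "library"] == which]
        return CountTable(
            self.data[keep].copy(),
            self.sample_meta.loc[keep].copy(),
            require_integer=self.require_integer,
        )

    def stations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.data.columns:
            seen.setdefault(str(self.sample_meta.loc[s, "station"]), None)
        return list(seen)

    def station_of(self, sample_id: str) -> str:
        return str(self.sample_meta.loc[sample_id, "station"])


@dataclass
class TaxonomyMap:
    """Total mapping otu_id -> taxonomic group over a table's OTU universe."""

    mapping: dict[str, str]
    n_defaulted: int = 0  # OTUs absent from the source file, assigned OTHER_GROUP

    def __getitem__(self, otu_id: str) -> str:
        return self.mapping[otu_id]

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g, None)
        return list(seen)

    def as_series(self, otu_ids) -> pd.Series:
        return pd.Series([self.mapping[o] for o in otu_ids], index=list(otu_ids))


@dataclass
class QpcrRecord:
    sample_id: str
    station: str
    template: str  # "DNA" or "cDNA"
    ct_replicates: list[float] = field(default_factory=list)


@dataclass
class QpcrTable:
    """Raw qPCR cycle-threshold records; replicates kept unaveraged.

    Averaging over technical replicates happens on the Ct scale inside the
    expression-ratio computation so that provenance stays auditable.
    """

    records: list[QpcrRecord]

    TEMPLATES = ("DNA", "cDNA")

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.template not in self.TEMPLATES:
                raise ValidationError(
                    f"template {rec.template!r} for sample {rec.sample_id!r} "
                    f"not in {self.TEMPLATES}"
                )
            cts = np.asarray(rec.ct_replicates, dtype=float)
            if cts.size < 1:
                raise ValidationError(f"sample {rec.sample_id!r}: no Ct replicates")
            if not np.isfinite(cts).all() or (cts <= 0).any():
                raise ValidationError(
                    f"sample {rec.sample_id!r} ({rec.template}): Ct values must "
                    f"be finite and > 0, got {rec.ct_replicates}"
                )

    def mean_ct(self, station: str, template: str) -> float:
        cts = [
            ct
            for rec in self.records
            if rec.station == station and rec.template == template
            for ct in rec.ct_replicates
        ]
        if not cts:
            raise KeyError(f"no {template} Ct records for station {station!r}")
        return float(np.mean(cts))

    def stations(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.station, None)
        return list(seen)

    def has(self, station: str, template: str) -> bool:
        return any(
            rec.station == station and rec.template == template for rec in self.records
        )


# ===================================================================== #
# readers / writers
# ===================================================================== #

def read_count_table(
    path: str | Path,
    meta_path: str | Path,
    *,
    transpose: bool = False,
    require_integer: bool = True,
) -> CountTable:
    """Read a tab-delimited OTU table plus sample metadata.

    The table file has otu ids in the first column and sample ids in the
    header; the metadata file has columns ``sample_id``, ``station``,
    ``library``.  Row and column order are preserved from the file.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        raw = raw.T
    try:
        data = raw.astype(float)
    except ValueError as exc:
        # locate the offending cell for the error message
        for otu in raw.index:
            for sample in raw.columns:
                try:
                    float(raw.loc[otu, sample])
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric count at otu_id={otu!r}, sample_id={sample!r}: "
                        f"{raw.loc[otu, sample]!r}"
                    ) from exc
        raise
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    expected = {"sample_id", "station", "library"}
    if not expected.issubset(meta.columns):
        raise ValidationError(
            f"metadata must have columns {sorted(expected)}, got {list(meta.columns)}"
        )
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    meta = meta.set_index("sample_id")
    if require_integer:
        data = _as_int_checked(data)
    return CountTable(data, meta, require_integer=require_integer)


def _as_int_checked(data: pd.DataFrame) -> pd.DataFrame:
    values = data.to_numpy()
    if np.isfinite(values).all() and np.allclose(values, np.round(values)):
        return data.round().astype(np.int64)
    return data  # CountTable.validate will name the offending cell


def write_count_table(
    table: CountTable, path: str | Path, meta_path: str | Path | None = None
) -> None:
    table.data.to_csv(path, sep="\t", index_label="otu_id")
    if meta_path is not None:
        table.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path, table: CountTable) -> TaxonomyMap:
    """Read a two-column otu_id<TAB>group file into a total map.

    OTUs of ``table`` absent from the file are assigned :data:`OTHER_GROUP`
    explicitly; the number of such defaults is recorded and logged.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "group"], dtype=str)
    if df.empty:
        raise ValidationError(f"taxonomy file {path} is empty")
    conflicts = df.groupby("otu_id")["group"].nunique()
    bad = conflicts[conflicts > 1].index.tolist()
    if bad:
        raise ValidationError(f"conflicting group assignments for otu_ids: {bad}")
    file_map = dict(zip(df["otu_id"], df["group"]))
    mapping: dict[str, str] = {}
    n_defaulted = 0
    for otu in table.otu_ids:
        if otu in file_map:
            mapping[otu] = file_map[otu]
        else:
            mapping[otu] = OTHER_GROUP
            n_defaulted += 1
    if n_defaulted:
        logger.warning(
            "%d of %d OTUs absent from taxonomy file; assigned %r",
            n_defaulted,
            len(table.otu_ids),
            OTHER_GROUP,
        )
    return TaxonomyMap(mapping, n_defaulted=n_defaulted)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for otu, group in tax.mapping.items():
            fh.write(f"{otu}\t{group}\n")


def read_qpcr(path: str | Path) -> QpcrTable:
    """Read a qPCR CSV: sample_id,station,template,ct1[,ct2,...].

    Replicates are retained raw.  A station missing one template is accepted
    here; the gap is flagged when the expression ratio is requested.
    """
    records: list[QpcrRecord] = []
    df = pd.read_csv(path, dtype=str)
    fixed = ["sample_id", "station", "template"]
    if not set(fixed).issubset(df.columns):
        raise ValidationError(f"qPCR CSV must have columns {fixed}")
    ct_cols = [c for c in df.columns if c not in fixed]
    for _, row in df.iterrows():
        cts = []
        for c in ct_cols:
            v = row[c]
            if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
                continue
            try:
                ct = float(v)
            except ValueError as exc:
                raise ValidationError(
                    f"non-numeric Ct {v!r} for sample {row['sample_id']!r}"
                ) from exc
            if not np.isfinite(ct):
                raise ValidationError(
                    f"non-finite Ct {v!r} for sample {row['sample_id']!r}"
                )
            cts.append(ct)
        records.append(
            QpcrRecord(
                sample_id=str(row["sample_id"]),
                station=str(row["station"]),
                template=str(row["template"]),
                ct_replicates=cts,
            )
        )
    return QpcrTable(records)


def write_qpcr(qpcr: QpcrTable, path: str | Path) -> None:
    k = max(len(r.ct_replicates) for r in qpcr.records)
    cols = ["sample_id", "station", "template"] + [f"ct{i+1}" for i in range(k)]
    rows = []
    for r in qpcr.records:
        cts = list(r.ct_replicates) + [""] * (k - len(r.ct_replicates))
        rows.append([r.sample_id, r.station, r.template, *cts])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
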