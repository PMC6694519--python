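"""OTU ranking, group frequencies, DNA:RNA proportionality and nifH
expression ratios.

The expression model has two layers.  The bulk mRNA/DNA ratio per station
comes from qPCR:

    R_bulk = E ** dCt,        dCt = mean Ct(DNA) - mean Ct(cDNA),

with E the per-cycle amplification efficiency (1 < E <= 2, estimable from a
standard-curve slope as E = 10**(-1/slope)).  More transcript means a lower
cDNA Ct, hence dCt > 0 and R_bulk > 1.  The group-level ratio partitions the
bulk signal by the amplicon-library frequencies of each taxonomic group:

    R_group = R_bulk * f_RNA / f_DNA,

undefined when the group is absent from the DNA library (f_DNA = 0).
Summing f_DNA * R_group over groups recovers R_bulk whenever every group is
defined, since the RNA frequencies sum to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CountTable, QpcrTable, TaxonomyMap, ValidationError

PROPORTIONAL = "proportional"
RNA_ENRICHED = "RNA-enriched"
DNA_ENRICHED = "DNA-enriched"
UNDEFINED = "undefined"


# --------------------------------------------------------------------- #
# ranking and frequencies
# --------------------------------------------------------------------- #

def rank_abundant_otus(
    dna: CountTable, rna: CountTable, n: int = 20
) -> pd.DataFrame:
    """Top-n OTUs by reads aggregated across all samples of both libraries.

    The OTU universe is the union of both tables (missing = 0).  Ties break
    lexicographically by otu_id.  Returns columns ``aggregated_reads``,
    ``rank`` and ``cumulative_fraction`` indexed by otu_id.
    """
    agg = (
        dna.data.sum(axis=1)
        .add(rna.data.sum(axis=1), fill_value=0.0)
        .astype(float)
    )
    total = agg.sum()
    order = sorted(agg.index, key=lambda o: (-agg[o], o))
    if n > len(order):
        n = len(order)
    ranked = agg.loc[order]
    out = pd.DataFrame(
        {
            "aggregated_reads": ranked,
            "rank": np.arange(1, len(order) + 1),
            "cumulative_fraction": ranked.cumsum() / total,
        }
    )
    out.index.name = "otu_id"
    return out.head(n)


@dataclass
class GroupFrequencyTable:
    """Per-(group, station) relative abundances in the DNA and RNA library.

    ``per_station`` has a (group, station) MultiIndex with columns ``f_dna``
    and ``f_rna``; ``averages`` holds the across-station mean frequency per
    group and library.  Within each sample the group frequencies (including
    the explicit catch-all group) sum to one.
    """

    per_station: pd.DataFrame
    averages: pd.DataFrame

    def frequency(self, group: str, station: str, library: str) -> float:
        col = "f_dna" if library == "DNA" else "f_rna"
        return float(self.per_station.loc[(group, station), col])

    def average(self, group: str, library: str) -> float:
        col = "f_dna" if library == "DNA" else "f_rna"
        return float(self.averages.loc[group, col])


def group_frequencies(table: CountTable, tax: TaxonomyMap) -> GroupFrequencyTable:
    """Sum per-sample proportions within taxonomic groups, per station."""
    props = table.proportions()
    groups = tax.as_series(table.otu_ids)
    by_group = props.groupby(groups).sum()  # group x sample
    rows = []
    for sample in table.sample_ids:
        station = table.station_of(sample)
        lib = table.sample_meta.loc[sample, "library"]
        for group in by_group.index:
            rows.append(
                {
                    "group": group,
                    "station": station,
                    "library": lib,
                    "f": float(by_group.loc[group, sample]),
                }
            )
    long = pd.DataFrame(rows)
    wide = (
        long.pivot_table(
            index=["group", "station"], columns="library", values="f", aggfunc="mean"
        )
        .rename(columns={"DNA": "f_dna", "RNA": "f_rna"})
        .fillna(0.0)
    )
    for col in ("f_dna", "f_rna"):
        if col not in wide.columns:
            wide[col] = 0.0
    averages = wide.groupby(level="group")[["f_dna", "f_rna"]].mean()
    return GroupFrequencyTable(per_station=wide[["f_dna", "f_rna"]], averages=averages)


def classify_proportionality(
    f_dna: float, f_rna: float, threshold: float = 2.0
) -> str:
    """Classify a taxon's DNA-vs-RNA frequency relationship.

    Within ``threshold``-fold of the 1:1 line -> proportional; otherwise
    enriched on the larger side.  A zero frequency on one side classifies to
    the non-zero side; both zero -> undefined.
    """
    if threshold <= 1:
        raise ValidationError("fold threshold must be > 1")
    if not (0 <= f_dna <= 1) or not (0 <= f_rna <= 1):
        raise ValidationError("frequencies must lie in [0, 1]")
    if f_dna == 0 and f_rna == 0:
        return UNDEFINED
    if f_dna == 0:
        return RNA_ENRICHED
    if f_rna == 0:
        return DNA_ENRICHED
    log_ratio = math.log2(f_rna / f_dna)
    if abs(log_ratio) <= math.log2(threshold):
        return PROPORTIONAL
    return RNA_ENRICHED if log_ratio > 0 else DNA_ENRICHED


def proportionality_table(
    dna: CountTable, rna: CountTable, threshold: float = 2.0
) -> pd.DataFrame:
    """Across-sample average frequencies and proportionality class per OTU."""
    f_dna = dna.proportions().mean(axis=1)
    f_rna = rna.proportions().mean(axis=1)
    otus = f_dna.index.union(f_rna.index, sort=False)
    f_dna = f_dna.reindex(otus, fill_value=0.0)
    f_rna = f_rna.reindex(otus, fill_value=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = np.log2(f_rna / f_dna)
    classes = [
        classify_proportionality(f_dna[o], f_rna[o], threshold) for o in otus
    ]
    return pd.DataFrame(
        {
            "f_dna": f_dna,
            "f_rna": f_rna,
            "log2_rna_dna": log2_ratio,
            "class": classes,
        },
        index=otus,
    )


# --------------------------------------------------------------------- #
# qPCR expression ratios
# --------------------------------------------------------------------- #

def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency from a standard-curve slope
    (cycles per log10 copies): E = 10**(-1/slope)."""
    if slope >= 0:
        raise ValidationError("standard-curve slope must be negative")
    return float(10.0 ** (-1.0 / slope))


def bulk_expression_ratio(qpcr: QpcrTable, efficiency: float, station: str) -> float:
    """Bulk mRNA/DNA ratio for one station: E ** (meanCt(DNA) - meanCt(cDNA)).

    Technical replicates are averaged on the Ct scale.  Raises ``KeyError``
    if either template is missing for the station.
    """
    if efficiency <= 1:
        raise ValidationError("amplification efficiency must exceed 1")
    delta_ct = qpcr.mean_ct(station, "DNA") - qpcr.mean_ct(station, "cDNA")
    return float(efficiency**delta_ct)


def group_expression_ratio(
    r_bulk: float, f_rna: float, f_dna: float
) -> float:
    """Group-level mRNA/DNA ratio: R_bulk * f_RNA / f_DNA.

    Returns NaN (undefined) when the group is absent from the DNA library.
    """
    if r_bulk <= 0:
        raise ValidationError("bulk ratio must be positive")
    if f_rna < 0 or f_dna < 0:
        raise ValidationError("frequencies must be non-negative")
    if f_dna == 0:
        return float("nan")
    return float(r_bulk * f_rna / f_dna)


def expression_ratio_table(
    qpcr: QpcrTable,
    freqs: GroupFrequencyTable,
    efficiency: float = 2.0,
    average_frequencies: bool = False,
) -> pd.DataFrame:
    """Per-(station, group) expression ratios from qPCR plus frequencies.

    Columns: ``efficiency``, ``delta_ct``, ``r_bulk``, ``f_dna``, ``f_rna``,
    ``r_group`` (NaN where the group is absent from the DNA library) and
    ``undefined`` (that flag).  ``average_frequencies=True`` uses the
    across-station mean frequency of each group instead of the station's
    own frequencies.  Stations missing a qPCR template are skipped with a
    ``skipped_stations`` entry in ``DataFrame.attrs``.
    """
    stations = sorted(
        {st for (_, st) in freqs.per_station.index}
    )
    groups = sorted({g for (g, _) in freqs.per_station.index})
    rows = []
    skipped = []
    for station in stations:
        if not (qpcr.has(station, "DNA") and qpcr.has(station, "cDNA")):
            skipped.append(station)
            continue
        delta_ct = qpcr.mean_ct(station, "DNA") - qpcr.mean_ct(station, "cDNA")
        r_bulk = bulk_expression_ratio(qpcr, efficiency, station)
        for group in groups:
            if average_frequencies:
                f_dna = freqs.average(group, "DNA")
                f_rna = freqs.average(group, "RNA")
            else:
                f_dna = freqs.frequency(group, station, "DNA")
                f_rna = freqs.frequency(group, station, "RNA")
            r_group = group_expression_ratio(r_bulk, f_rna, f_dna)
            rows.append(
                {
                    "station": station,
                    "group": group,
                    "efficiency": efficiency,
                    "delta_ct": delta_ct,
                    "r_bulk": r_bulk,
                    "f_dna": f_dna,
                    "f_rna": f_rna,
                    "r_group": r_group,
                    "undefined": bool(f_dna == 0),
                }
            )
    columns = [
        "station", "group", "efficiency", "delta_ct", "r_bulk",
        "f_dna", "f_rna", "r_group", "undefined",
    ]
    out = pd.DataFrame(rows, columns=columns).set_index(["station", "group"])
    out.attrs["skipped_stations"] = skipped
    return out


def expression_summary(expr: pd.DataFrame) -> dict:
    """Bulk range/mean and per-group mean/range of defined ratios."""
    bulk = expr.reset_index().drop_duplicates("station").set_index("station")["r_bulk"]
    per_group = {}
    for group, sub in expr.groupby(level="group"):
        defined = sub.loc[~sub["undefined"], "r_group"].dropna()
        per_group[str(group)] = {
            "mean": float(defined.mean()) if len(defined) else None,
            "min": float(defined.min()) if len(defined) else None,
            "max": float(defined.max()) if len(defined) else None,
            "n_defined": int(len(defined)),
            "n_undefined": int(sub["undefined"].sum()),
        }
    return {
        "r_bulk_mean": float(bulk.mean()),
        "r_bulk_min": float(bulk.min()),
        "r_bulk_max": float(bulk.max()),
        "groups": per_group,
    }
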