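"""Synthetic paired DNA/RNA amplicon libraries and qPCR records with known
ground truth.

The community model: each taxon ``i`` has a relative DNA abundance ``d_i``
(proportions summing to 1) and an activity multiplier ``r_i >= 0`` — its
per-gene-copy mRNA/DNA ratio.  Per station the DNA composition is a
lognormal perturbation of ``d`` (renormalized) and each group's activity is
jittered lognormally, so that active-community composition varies more
between stations than total-community composition.  RNA proportions are
``d_i r_i`` renormalized; read counts are multinomial draws at a fixed
library size (sequencing samples reads with replacement; pipeline
rarefaction then subsamples them without replacement — distinct roles).

The station's true bulk mRNA/DNA ratio is ``R_bulk = sum_i d_i r_i`` (with
``sum d_i = 1``), and the frequency-partition identity
``R_bulk * f_RNA,i / f_DNA,i = r_i`` holds exactly at the proportion level,
which is what makes every pipeline stage testable against ground truth.

qPCR: with amplification efficiency ``E`` and an arbitrary fixed anchor
cycle, ``Ct(DNA) = anchor - log_E(S)`` and
``Ct(cDNA) = anchor - log_E(S * R_bulk)`` for a station-specific total
signal ``S``; technical triplicates get independent Gaussian Ct noise.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CountTable, QpcrRecord, QpcrTable, TaxonomyMap, ValidationError


@dataclass
class CommunitySpec:
    """Ground-truth community and measurement model.

    ``taxa`` is a DataFrame with columns ``taxon_id``, ``group``, ``d``
    (relative DNA abundance, sums to 1) and ``r`` (activity multiplier).
    ``station_effect_sd`` is the log-scale SD of per-(station, taxon)
    perturbations of ``d``; ``activity_dispersion_sd`` the log-scale SD of
    per-(station, group) jitter on ``r`` — the knob behind the higher
    between-station dispersion of active communities.  ``ct_noise_sd`` is
    the technical-replicate Ct SD in cycles.
    """

    taxa: pd.DataFrame
    n_stations: int = 9
    library_size: int = 4746
    station_effect_sd: float = 0.25
    activity_dispersion_sd: float = 1.0
    ct_noise_sd: float = 0.15
    n_ct_replicates: int = 3
    efficiency: float = 2.0
    ct_anchor: float = 15.0
    seed: int | None = None

    def __post_init__(self) -> None:
        required = {"taxon_id", "group", "d", "r"}
        if not required.issubset(self.taxa.columns):
            raise ValidationError(f"taxa must have columns {sorted(required)}")
        if self.taxa["taxon_id"].duplicated().any():
            raise ValidationError("duplicate taxon_id in spec")
        d = self.taxa["d"].to_numpy(dtype=float)
        r = self.taxa["r"].to_numpy(dtype=float)
        if (d < 0).any() or not np.isclose(d.sum(), 1.0, atol=1e-9):
            raise ValidationError("d must be non-negative and sum to 1")
        if (r < 0).any():
            raise ValidationError("activity multipliers must be >= 0")
        if (r == 0).all():
            raise ValidationError("all activities zero: RNA library undefined")
        if self.library_size < 1:
            raise ValidationError("library_size must be >= 1")
        if self.efficiency <= 1:
            raise ValidationError("efficiency must exceed 1")

    @property
    def station_names(self) -> list[str]:
        letters = string.ascii_uppercase
        return [
            letters[i] if i < 26 else f"S{i:03d}" for i in range(self.n_stations)
        ]


@dataclass
class SyntheticDataset:
    dna_table: CountTable
    rna_table: CountTable
    qpcr: QpcrTable
    taxonomy: TaxonomyMap
    truth: pd.DataFrame  # (station, taxon_id) -> d, r, f_rna_true
    bulk_truth: pd.Series  # station -> R_bulk_true
    spec: CommunitySpec = field(repr=False, default=None)

    def merged_table(self) -> CountTable:
        """Both libraries as one CountTable (DNA columns then RNA)."""
        data = self.dna_table.data.join(self.rna_table.data)
        meta = pd.concat([self.dna_table.sample_meta, self.rna_table.sample_meta])
        return CountTable(data, meta)

    def group_truth(self) -> pd.DataFrame:
        """Station x group ground truth: DNA fraction and effective ratio
        r_g = sum(d_i r_i) / sum(d_i) over the group's taxa."""
        rows = []
        for (station, group), sub in self.truth.groupby(["station", "group"]):
            d_sum = sub["d"].sum()
            rows.append(
                {
                    "station": station,
                    "group": group,
                    "f_dna_true": d_sum,
                    "r_true": (sub["d"] * sub["r"]).sum() / d_sum if d_sum > 0 else 0.0,
                }
            )
        return pd.DataFrame(rows).set_index(["station", "group"])


def ground_truth_ratios(
    spec: CommunitySpec, d: np.ndarray | None = None, r: np.ndarray | None = None
) -> dict:
    """Bulk and per-taxon true ratios for one community realization.

    ``R_bulk = sum(d_i r_i) / sum(d_i)``; per-taxon true ratio is ``r_i``;
    RNA proportions are ``d_i r_i`` renormalized.
    """
    if d is None:
        d = spec.taxa["d"].to_numpy(dtype=float)
    if r is None:
        r = spec.taxa["r"].to_numpy(dtype=float)
    d = d / d.sum()
    activity = d * r
    r_bulk = activity.sum() / d.sum()
    f_rna = activity / activity.sum()
    return {"r_bulk": float(r_bulk), "f_dna": d, "f_rna": f_rna, "r": r}


def _station_realizations(spec: CommunitySpec, rng: np.random.Generator):
    """Per-station perturbed (d, r) arrays."""
    base_d = spec.taxa["d"].to_numpy(dtype=float)
    base_r = spec.taxa["r"].to_numpy(dtype=float)
    groups = spec.taxa["group"].to_numpy()
    uniq_groups = pd.unique(groups)
    for _ in range(spec.n_stations):
        d = base_d * np.exp(
            rng.normal(0.0, spec.station_effect_sd, size=base_d.size)
        )
        d = d / d.sum()
        group_jitter = {
            g: np.exp(rng.normal(0.0, spec.activity_dispersion_sd))
            for g in uniq_groups
        }
        r = base_r * np.array([group_jitter[g] for g in groups])
        yield d, r


def simulate_dataset(spec: CommunitySpec, seed: int | None = None) -> SyntheticDataset:
    """Generate paired count tables, qPCR records, taxonomy and truth."""
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    taxon_ids = spec.taxa["taxon_id"].tolist()
    stations = spec.station_names

    dna_cols, rna_cols = {}, {}
    truth_rows = []
    bulk_truth = {}
    signal_rng_values = rng.lognormal(mean=0.0, sigma=0.5, size=len(stations))
    qpcr_records = []

    for s_idx, ((d, r), station) in enumerate(
        zip(_station_realizations(spec, rng), stations)
    ):
        truth = ground_truth_ratios(spec, d, r)
        rna_props = truth["f_rna"]
        dna_cols[f"{station}_DNA"] = rng.multinomial(spec.library_size, d)
        rna_cols[f"{station}_RNA"] = rng.multinomial(spec.library_size, rna_props)
        bulk_truth[station] = truth["r_bulk"]
        for i, taxon in enumerate(taxon_ids):
            truth_rows.append(
                {
                    "station": station,
                    "taxon_id": taxon,
                    "group": spec.taxa["group"].iloc[i],
                    "d": d[i],
                    "r": r[i],
                    "f_rna_true": rna_props[i],
                }
            )
        # qPCR: Ct from total signal and the true bulk ratio
        signal = signal_rng_values[s_idx]
        log_e = np.log(spec.efficiency)
        ct_dna = spec.ct_anchor - np.log(signal) / log_e
        ct_cdna = spec.ct_anchor - np.log(signal * truth["r_bulk"]) / log_e
        for template, ct in (("DNA", ct_dna), ("cDNA", ct_cdna)):
            reps = ct + rng.normal(0.0, spec.ct_noise_sd, size=spec.n_ct_replicates)
            qpcr_records.append(
                QpcrRecord(
                    sample_id=f"{station}_{template}",
                    station=station,
                    template=template,
                    ct_replicates=[float(v) for v in reps],
                )
            )

    def _make_table(cols: dict, library: str) -> CountTable:
        data = pd.DataFrame(cols, index=taxon_ids)
        meta = pd.DataFrame(
            {
                "station": [c.rsplit("_", 1)[0] for c in data.columns],
                "library": library,
            },
            index=data.columns,
        )
        return CountTable(data, meta)

    taxonomy = TaxonomyMap(
        dict(zip(taxon_ids, spec.taxa["group"].astype(str)))
    )
    truth_df = pd.DataFrame(truth_rows).set_index(["station", "taxon_id"])
    return SyntheticDataset(
        dna_table=_make_table(dna_cols, "DNA"),
        rna_table=_make_table(rna_cols, "RNA"),
        qpcr=QpcrTable(qpcr_records),
        taxonomy=taxonomy,
        truth=truth_df,
        bulk_truth=pd.Series(bulk_truth, name="r_bulk_true"),
        spec=spec,
    )


def simulate_paired_libraries(spec: CommunitySpec, seed: int | None = None):
    """Count tables only (convenience split of :func:`simulate_dataset`)."""
    ds = simulate_dataset(spec, seed=seed)
    return ds.dna_table, ds.rna_table


def simulate_qpcr(spec: CommunitySpec, seed: int | None = None) -> QpcrTable:
    """qPCR records only (convenience split of :func:`simulate_dataset`)."""
    return simulate_dataset(spec, seed=seed).qpcr


def exact_proportion_tables(spec: CommunitySpec):
    """Noise-free single-station 'tables' of exact proportions plus truth.

    Used for algebraic-recovery checks: no station effects, no sampling,
    no Ct noise — the frequency-partition identity then holds to machine
    precision through the whole pipeline.
    """
    truth = ground_truth_ratios(spec)
    idx = spec.taxa["taxon_id"].tolist()
    dna = pd.DataFrame({"X_DNA": truth["f_dna"]}, index=idx)
    rna = pd.DataFrame({"X_RNA": truth["f_rna"]}, index=idx)
    meta = lambda col, lib: pd.DataFrame(
        {"station": ["X"], "library": [lib]}, index=[col]
    )
    dna_t = CountTable(dna, meta("X_DNA", "DNA"), require_integer=False)
    rna_t = CountTable(rna, meta("X_RNA", "RNA"), require_integer=False)
    log_e = np.log(spec.efficiency)
    ct_dna = spec.ct_anchor
    ct_cdna = spec.ct_anchor - np.log(truth["r_bulk"]) / log_e
    qpcr = QpcrTable(
        [
            QpcrRecord("X_DNA", "X", "DNA", [float(ct_dna)]),
            QpcrRecord("X_cDNA", "X", "cDNA", [float(ct_cdna)]),
        ]
    )
    return dna_t, rna_t, qpcr, truth


# --------------------------------------------------------------------- #
# default scenario
# --------------------------------------------------------------------- #

#: (group, DNA fraction, mean activity multiplier, number of OTUs)
#: Magnitudes mirror an oligotrophic-ocean plankton-associated diazotroph
#: assemblage: one hyperdominant filamentous cyanobacterium of modest
#: activity, rare but highly active heterocystous and unicellular
#: cyanobacteria and proteobacteria, and present-but-silent cluster III /
#: Betaproteobacteria lineages.
DEFAULT_GROUPS = (
    ("Trichodesmium", 0.978, 0.15, 200),
    ("cluster III", 0.011, 0.0, 100),
    ("Betaproteobacteria", 0.0033, 0.02, 60),
    ("Gammaproteobacteria", 0.003, 2.0, 120),
    ("Deltaproteobacteria", 0.002, 2.5, 80),
    ("heterocystous cyanobacteria", 0.002, 3.5, 40),
    ("unicellular cyanobacteria", 0.0001, 7.8, 30),
    ("other", 0.0006, 1.0, 101),
)


def paper_like_spec(
    n_stations: int = 9,
    library_size: int = 4746,
    station_effect_sd: float = 0.25,
    activity_dispersion_sd: float = 1.0,
    ct_noise_sd: float = 0.15,
    efficiency: float = 2.0,
    seed: int | None = None,
    within_group_r_sd: float = 0.3,
    abundance_decay: float = 1.5,
) -> CommunitySpec:
    """Default 731-OTU community emulating the study system.

    Within each group, OTU abundances follow a power law (rank^-decay) and
    OTU activities jitter lognormally (SD ``within_group_r_sd``) around the
    group mean; groups with zero mean activity stay exactly silent.  The
    implied bulk ratio sum(d*r) is about 0.166.
    """
    rng = np.random.default_rng(0 if seed is None else seed)
    rows = []
    for group, d_total, r_mean, n_otus in DEFAULT_GROUPS:
        ranks = np.arange(1, n_otus + 1, dtype=float)
        weights = ranks**-abundance_decay
        weights /= weights.sum()
        if r_mean > 0:
            r_vals = r_mean * np.exp(
                rng.normal(0.0, within_group_r_sd, size=n_otus)
            )
        else:
            r_vals = np.zeros(n_otus)
        tag = group.replace(" ", "_")
        for i in range(n_otus):
            rows.append(
                {
                    "taxon_id": f"OTU_{tag}_{i+1:03d}",
                    "group": group,
                    "d": d_total * weights[i],
                    "r": float(r_vals[i]),
                }
            )
    taxa = pd.DataFrame(rows)
    taxa["d"] = taxa["d"] / taxa["d"].sum()
    return CommunitySpec(
        taxa=taxa,
        n_stations=n_stations,
        library_size=library_size,
        station_effect_sd=station_effect_sd,
        activity_dispersion_sd=activity_dispersion_sd,
        ct_noise_sd=ct_noise_sd,
        efficiency=efficiency,
        seed=seed,
    )
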