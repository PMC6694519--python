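"""Pipeline orchestration: normalize -> alpha -> beta -> activity.

Every stage writes derived files into the output directory and never
mutates an upstream artifact; a run manifest (parameters, per-stage seeds,
input checksums, package versions) suffices to reproduce a run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import (
    expression_ratio_table,
    expression_summary,
    group_frequencies,
    proportionality_table,
    rank_abundant_otus,
)
from .alpha import alpha_contrast_table, alpha_diversity_table
from .beta import beta_dispersion, bray_curtis, nmds
from .normalization import rarefy_repeated
from .tables import (
    CountTable,
    ValidationError,
    read_count_table,
    read_qpcr,
    read_taxonomy,
    write_count_table,
)

logger = logging.getLogger(__name__)

DEFAULTS = {
    "depth": "auto",
    "iterations": 100,
    "seed": 0,
    "top_n": 20,
    "efficiency": 2.0,
    "slope": None,
    "fold_threshold": 2.0,
    "n_permutations": 999,
    "nmds_restarts": 20,
    "average_frequencies": False,
}


def _stage_seeds(master: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run all stages on declared inputs; returns the result bundle.

    ``config`` keys: ``counts``, ``metadata``, ``taxonomy`` (paths;
    required), ``qpcr`` (path; optional — expression stage is skipped with
    a notice when absent), plus any of the parameter keys in
    :data:`DEFAULTS`.
    """
    params = {**DEFAULTS, **{k: v for k, v in config.items() if k in DEFAULTS}}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    table = read_count_table(config["counts"], config["metadata"])
    tax = read_taxonomy(config["taxonomy"], table)
    qpcr = None
    if config.get("qpcr"):
        qpcr = read_qpcr(config["qpcr"])
        qpcr_stations = set(qpcr.stations())
        table_stations = set(table.stations())
        if not table_stations & qpcr_stations:
            raise ValidationError(
                "no station shared between the count table and the qPCR file"
            )

    seeds = _stage_seeds(int(params["seed"]))
    depth = (
        int(table.column_sums().min())
        if params["depth"] in (None, "auto")
        else int(params["depth"])
    )

    # --- normalization -------------------------------------------------
    normalized = rarefy_repeated(
        table, depth=depth, iterations=int(params["iterations"]), seed=seeds[0]
    )
    write_count_table(normalized, outdir / "normalized_table.tsv")

    # --- alpha ----------------------------------------------------------
    alpha_df = alpha_diversity_table(
        table, depth=depth, iterations=int(params["iterations"]), seed=seeds[0]
    )
    alpha_df.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    contrast = alpha_contrast_table(alpha_df)
    contrast.to_csv(outdir / "alpha_contrast.tsv", sep="\t")

    # --- beta -----------------------------------------------------------
    props = normalized.proportions()
    dist = bray_curtis(props.to_numpy(), sample_ids=normalized.sample_ids)
    pd.DataFrame(
        dist.data, index=dist.ids, columns=dist.ids
    ).to_csv(outdir / "bray_curtis.tsv", sep="\t")
    ord_res = nmds(dist, k=2, restarts=int(params["nmds_restarts"]), seed=seeds[1])
    coords = pd.DataFrame(
        ord_res.coordinates, index=dist.ids, columns=["NMDS1", "NMDS2"]
    )
    with open(outdir / "nmds_coordinates.tsv", "w", encoding="utf-8") as fh:
        fh.write(f"# stress={ord_res.stress:.6g} converged={ord_res.converged}\n")
        coords.to_csv(fh, sep="\t")
    libraries = {
        s: str(normalized.sample_meta.loc[s, "library"]) for s in normalized.sample_ids
    }
    disp = beta_dispersion(
        dist, libraries, n_permutations=int(params["n_permutations"]), seed=seeds[2]
    )
    pd.DataFrame(
        {
            "sample_id": disp.sample_ids,
            "group": disp.groups,
            "distance_to_centroid": disp.distances,
        }
    ).to_csv(outdir / "beta_dispersion.tsv", sep="\t", index=False)
    disp_summary = {
        "F": disp.F,
        "p_parametric": disp.p_parametric,
        "p_perm": disp.p_perm,
        "n_permutations": disp.n_permutations,
        "group_mean_distance": disp.group_means,
        "nmds_stress": ord_res.stress,
    }
    (outdir / "beta_summary.json").write_text(json.dumps(disp_summary, indent=2))

    # --- activity --------------------------------------------------------
    dna = normalized.library("DNA")
    rna = normalized.library("RNA")
    ranking = rank_abundant_otus(dna, rna, n=int(params["top_n"]))
    ranking.to_csv(outdir / "otu_ranking.tsv", sep="\t")
    freqs = group_frequencies(normalized, tax)
    freqs.per_station.to_csv(outdir / "group_frequencies.tsv", sep="\t")
    freqs.averages.to_csv(outdir / "group_frequency_averages.tsv", sep="\t")
    prop = proportionality_table(dna, rna, threshold=float(params["fold_threshold"]))
    prop.to_csv(outdir / "proportionality.tsv", sep="\t", index_label="otu_id")

    expr = None
    summary = None
    if qpcr is not None:
        if params["slope"] is not None:
            from .activity import efficiency_from_slope

            efficiency = efficiency_from_slope(float(params["slope"]))
        else:
            efficiency = float(params["efficiency"])
        expr = expression_ratio_table(
            qpcr,
            freqs,
            efficiency=efficiency,
            average_frequencies=bool(params["average_frequencies"]),
        )
        expr.to_csv(outdir / "expression_ratios.tsv", sep="\t")
        summary = expression_summary(expr)
        (outdir / "expression_summary.json").write_text(json.dumps(summary, indent=2))
    else:
        logger.warning("no qPCR file declared: expression-ratio stage skipped")
        (outdir / "expression_SKIPPED.txt").write_text(
            "Expression-ratio stage skipped: no qPCR input was declared.\n"
        )

    # --- manifest ---------------------------------------------------------
    manifest = {
        "actampl_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "parameters": {**params, "depth_used": depth},
        "stage_seeds": seeds,
        "inputs": {
            key: {"path": str(config[key]), "sha256": _sha256(config[key])}
            for key in ("counts", "metadata", "taxonomy", "qpcr")
            if config.get(key)
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    bundle = {
        "outdir": outdir,
        "normalized": normalized,
        "alpha": alpha_df,
        "alpha_contrast": contrast,
        "distance": dist,
        "ordination": ord_res,
        "dispersion": disp,
        "ranking": ranking,
        "group_frequencies": freqs,
        "proportionality": prop,
        "expression": expr,
        "expression_summary": summary,
        "manifest": manifest,
    }
    (outdir / "report.txt").write_text(generate_report(bundle))
    return bundle


def generate_report(bundle: dict) -> str:
    """Plain-text summary mirroring the pipeline's headline tables."""
    lines: list[str] = []
    add = lines.append
    add("actampl pipeline report")
    add("=" * 60)

    add("")
    add("Alpha-diversity contrast (total DNA vs active RNA libraries)")
    add("-" * 60)
    c = bundle["alpha_contrast"]
    for idx, row in c.iterrows():
        add(
            f"  {idx:>6}: mean DNA={row['mean_dna']:.4f} RNA={row['mean_rna']:.4f}"
            f"  Welch t={row['t_welch']:.3f} (p={row['p_welch']:.3g})"
            f"  ANOVA F={row['F']:.3f} (p={row['p_anova']:.3g})"
            f"  higher in {row['higher_in']}"
        )

    add("")
    add("Beta-dispersion (between-community variation)")
    add("-" * 60)
    disp = bundle["dispersion"]
    for grp, mean in disp.group_means.items():
        add(f"  mean distance to centroid [{grp}]: {mean:.4f}")
    add(
        f"  ANOVA F={disp.F:.3f}  p_parametric={disp.p_parametric:.3g}"
        f"  p_perm={disp.p_perm:.3g} ({disp.n_permutations} permutations)"
    )
    add(f"  NMDS stress (k=2): {bundle['ordination'].stress:.4g}")

    add("")
    add("Group frequencies (across-station averages)")
    add("-" * 60)
    avgs = bundle["group_frequencies"].averages
    for grp, row in avgs.iterrows():
        if row["f_dna"] == 0 and row["f_rna"] == 0:
            continue  # empty catch-all group: omit
        add(f"  {grp:<30} f_DNA={row['f_dna']:.4f}  f_RNA={row['f_rna']:.4f}")

    add("")
    rk = bundle["ranking"]
    add(f"Top {len(rk)} OTUs by aggregated normalized reads")
    add("-" * 60)
    for otu, row in rk.iterrows():
        add(
            f"  #{int(row['rank']):>3} {otu:<28} reads={row['aggregated_reads']:.1f}"
            f"  cumulative={row['cumulative_fraction']:.4f}"
        )

    add("")
    add("DNA:RNA proportionality classes")
    add("-" * 60)
    counts = bundle["proportionality"]["class"].value_counts()
    for cls, cnt in counts.items():
        add(f"  {cls:<16} {cnt} OTUs")

    add("")
    if bundle.get("expression") is not None:
        s = bundle["expression_summary"]
        add("nifH expression ratios (qPCR-anchored)")
        add("-" * 60)
        add(
            f"  bulk R: mean={s['r_bulk_mean']:.4f}"
            f"  range=[{s['r_bulk_min']:.4f}, {s['r_bulk_max']:.4f}]"
        )
        for grp, g in s["groups"].items():
            if g["mean"] is None:
                add(
                    f"  {grp:<30} R_group=n.d. (no sequence found in the DNA"
                    " libraries)"
                )
            else:
                extra = ""
                if g["n_undefined"]:
                    extra = (
                        f"  [{g['n_undefined']} station(s) n.d.: no sequence"
                        " found in the DNA libraries]"
                    )
                add(
                    f"  {grp:<30} R_group mean={g['mean']:.4f}"
                    f"  range=[{g['min']:.4f}, {g['max']:.4f}]"
                    f"  n={g['n_defined']}{extra}"
                )
    else:
        add("nifH expression ratios: skipped (no qPCR input declared)")
    add("")
    return "\n".join(lines)
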