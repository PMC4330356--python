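"""End-to-end pipeline orchestration and summary reporting.

``run_pipeline`` chains simulate -> tile -> test -> classify -> annotate ->
rank -> report on a fully synthetic experiment, emitting the tables behind
the usual figure panels (state fractions, retention classes, feature/repeat
compositions, trajectory pattern counts, candidate loss bins) as TSVs plus a
JSON summary whose printed percentages all satisfy one fixed rounding rule
(half away from zero).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import differential as diff
from . import dynamics as dyn
from . import genome as gen
from . import io as mio
from . import tiling
from . import trajectory as traj


def pct_value(numerator: int, denominator: int, decimals: int = 0) -> float:
    """100 * numerator / denominator, rounded half away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    q = Decimal(1).scaleb(-decimals)
    val = Decimal(100 * numerator) / Decimal(denominator)
    return float(val.quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, decimals: int = 0) -> str:
    """Percentage string in the reporting convention, e.g. ``"68%"``."""
    v = pct_value(numerator, denominator, decimals)
    return f"{v:.{decimals}f}%"


def diff_counts(total_changed: int, reduced: int) -> int:
    """Tiles with increased methylation among all changed tiles."""
    if reduced > total_changed:
        raise ValueError("reduced count exceeds total changed count")
    return total_changed - reduced


def ratio_entry(n: int, total: int, decimals: int = 0) -> dict[str, Any]:
    """A (count, total, percentage) report triple; the percentage is always
    reproducible from the two counts via :func:`pct`."""
    return {"n": int(n), "total": int(total), "pct": pct(n, total, decimals)}


def _verify_ratios(obj: Any) -> None:
    if isinstance(obj, dict):
        if set(obj) >= {"n", "total", "pct"}:
            decimals = len(obj["pct"].rstrip("%").split(".")[1]) if "." in obj["pct"] else 0
            assert obj["pct"] == pct(obj["n"], obj["total"], decimals), (
                f"inconsistent ratio triple {obj}"
            )
        for v in obj.values():
            _verify_ratios(v)
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            _verify_ratios(v)


@dataclass
class RunConfig:
    """All tunables of the pipeline, with defaults equal to the study's
    stated analysis settings (100 bp tiles, 1 CpG minimum, 20x coverage,
    q = 0.01 BH, +/- 20-point effect gate, 500 bp merge gap, patterns
    thresholds 0.20/0.75/0.20)."""

    chromosomes: tuple[tuple[str, int], ...] = gen.DEFAULT_CHROMOSOMES
    class_counts: dict[gen.LocusClass, int] = field(
        default_factory=lambda: dict(gen.DEFAULT_CLASS_COUNTS)
    )
    cpg_density: int = 10
    hyper_fraction: float = 0.01
    timeline: dyn.Timeline = field(default_factory=dyn.Timeline)
    noise: dyn.NoiseParams = field(default_factory=dyn.NoiseParams)
    replicates: dict[str, int] = field(
        default_factory=lambda: dict(dyn.DEFAULT_REPLICATES)
    )
    tile_width: int = 100
    min_cpg: int = 1
    min_cov: float = 20.0
    cov_rule: str = "tile_mean"
    method: str = "counts"
    alpha: float = 0.05
    q_threshold: float = 0.01
    min_diff: float = 0.20
    low: float = 0.20
    partial_hi: float = 0.75
    recover_tol: float = 0.20
    max_gap: int = 500
    promoter_flank: int = 1000
    tts_flank: int = 1000
    proximity: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        if "chromosomes" in raw:
            kwargs["chromosomes"] = tuple(
                (str(c["name"]), int(c["length"])) for c in raw.pop("chromosomes")
            )
        if "class_counts" in raw:
            kwargs["class_counts"] = {
                gen.LocusClass(k): int(v) for k, v in raw.pop("class_counts").items()
            }
        if "timeline" in raw:
            t = raw.pop("timeline")
            if "timepoints" in t:
                t["timepoints"] = tuple(t["timepoints"])
            kwargs["timeline"] = dyn.Timeline(**t)
        if "noise" in raw:
            kwargs["noise"] = dyn.NoiseParams(**raw.pop("noise"))
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    loci: list[gen.AnnotatedLocus]
    manifest: pd.DataFrame
    matrix: tiling.TileMatrix
    correlations: pd.DataFrame
    diff_d0: pd.DataFrame
    diff_d21: pd.DataFrame
    retention: pd.DataFrame
    trajectories: pd.DataFrame
    annotations: pd.DataFrame
    candidates: pd.DataFrame
    regions: pd.DataFrame
    tss_prof: pd.DataFrame
    true_class: pd.Series
    report: dict[str, Any]


def tiles_true_class(
    tiles: pd.DataFrame, loci: list[gen.AnnotatedLocus]
) -> pd.Series:
    """Ground-truth locus class per tile (by tile midpoint), for synthetic
    genomes where the generating class is known.  Tiles whose midpoint falls
    between loci are labelled 'NONE'."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for l in loci:
        label = "HYPER_PRONE" if l.hyper_prone else l.locus_class.value
        trees.setdefault(l.chrom, IntervalTree()).addi(l.start, l.end, label)
    labels = []
    for row in tiles.itertuples():
        mid = (row.start + row.end) // 2
        hits = trees.get(row.chrom, IntervalTree())[mid]
        labels.append(next(iter(hits)).data if hits else "NONE")
    return pd.Series(labels, index=tiles.index, name="true_class")


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic experiment and analysis.

    Deterministic under ``config.seed``; if ``outdir`` is given, all stage
    outputs are written there as TSV/BED/JSON.
    """
    spec = gen.GenomeSpec(chromosomes=config.chromosomes, rng_seed=config.seed)
    loci, sites = gen.build_genome(
        spec,
        class_counts=config.class_counts,
        cpg_density=config.cpg_density,
        hyper_fraction=config.hyper_fraction,
    )
    calls, manifest = dyn.simulate_experiment(
        loci,
        sites,
        timeline=config.timeline,
        noise=config.noise,
        n_replicates=config.replicates,
        seed=config.seed + 1,
    )
    matrix = tiling.make_tiles(
        calls,
        manifest,
        tile_width=config.tile_width,
        min_cpg=config.min_cpg,
        min_cov=config.min_cov,
        cov_rule=config.cov_rule,
    )
    n_candidate_tiles = len(
        {(s.chrom, s.pos // config.tile_width) for s in sites}
    )
    corr, corr_order = tiling.sample_correlations(matrix)

    kwargs = dict(
        method=config.method,
        alpha=config.alpha,
        q_threshold=config.q_threshold,
        min_diff=config.min_diff,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        diff_d0 = diff.differential_table(matrix, "control", "d0", **kwargs)
        diff_d21 = diff.differential_table(matrix, "control", "d21", **kwargs)
        retention = diff.retention_calls(matrix, min_loss=config.min_diff)
    states = {
        tp: diff.state_fractions(matrix, tp) for tp in ("control", "d0", "d21")
    }
    trajectories = traj.classify_table(
        matrix.group_means(),
        low=config.low,
        partial_hi=config.partial_hi,
        recover_tol=config.recover_tol,
    )

    chrom_lengths = spec.chrom_lengths
    feats = gen.gene_feature_intervals(
        loci, chrom_lengths, config.promoter_flank, config.tts_flank
    )
    cgis = pd.DataFrame(
        [(l.chrom, l.start, l.end, l.gene_id or str(l.locus_id)) for l in loci if l.cgi_flag],
        columns=["chrom", "start", "end", "name"],
    )
    reps = pd.DataFrame(
        [
            (l.chrom, l.start, l.end, l.repeat_class)
            for l in loci
            if l.repeat_class is not None
        ],
        columns=["chrom", "start", "end", "repeat_class"],
    )
    annotations = ann.assign_features(matrix.tiles, feats)
    annotations["cgi"] = ann.cgi_overlap(matrix.tiles, cgis)
    annotations = annotations.join(
        ann.repeat_context(matrix.tiles, reps, proximity=config.proximity)
    )

    hypo_d21 = diff_d21[diff_d21["status"] == "hypo"]
    cand_tiles = pd.DataFrame(
        {
            "gene_id": annotations.loc[hypo_d21.index, "gene_id"],
            "m_control": hypo_d21["mean_a"],
            "m_d21": hypo_d21["mean_b"],
        }
    )
    imprinted = {l.gene_id for l in loci if l.locus_class is gen.LocusClass.IMPRINTED_GDMD}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        candidates = traj.rank_candidates(cand_tiles, imprinted=imprinted)

    hypo_d0 = diff_d0[diff_d0["status"] == "hypo"]
    regions = traj.merge_tiles(
        matrix.tiles.loc[hypo_d0.index], max_gap=config.max_gap
    )

    genes = gen.genes_frame(loci)
    tss_prof = tiling.tss_profile(matrix, genes)

    true_class = tiles_true_class(matrix.tiles, loci)

    # ---- summary report -------------------------------------------------
    n_tiles = len(matrix)
    n_hypo_d21 = int((diff_d21["status"] == "hypo").sum())
    n_hyper_d21 = int((diff_d21["status"] == "hyper").sum())
    n_changed_d21 = n_hypo_d21 + n_hyper_d21
    lost = retention[retention["lost"]]
    ret20 = lost[lost["retained_gt20"]]
    ret40 = lost[lost["retained_gt40"]]
    genic_feats = [f for f in gen.FEATURES if f != "intergenic"]
    ret20_ann = annotations.loc[ret20.index]
    hypo_ann = annotations.loc[hypo_d21.index]
    pattern_counts = trajectories["pattern"].value_counts().to_dict()

    report: dict[str, Any] = {
        "config": {"seed": config.seed, "method": config.method},
        "filters": {
            "cpg_sites_simulated": len(sites),
            "candidate_tiles": n_candidate_tiles,
            "tiles_retained": n_tiles,
        },
        "samples": {"order_by_correlation": corr_order},
        "state_fractions": states,
        "differential": {
            "d0": {
                "tested": n_tiles,
                "hypo": int((diff_d0["status"] == "hypo").sum()),
                "hyper": int((diff_d0["status"] == "hyper").sum()),
                "stable": int((diff_d0["status"] == "stable").sum()),
            },
            "d21": {
                "tested": n_tiles,
                "hypo": n_hypo_d21,
                "hyper": n_hyper_d21,
                "stable": int((diff_d21["status"] == "stable").sum()),
                "changed": n_changed_d21,
                "increased_of_changed": diff_counts(n_changed_d21, n_hypo_d21)
                if n_changed_d21 >= n_hypo_d21
                else 0,
            },
        },
        "retention_d0": {
            "lost_tiles": int(len(lost)),
            "retained_gt20": ratio_entry(len(ret20), max(len(lost), 1)),
            "retained_gt40": ratio_entry(len(ret40), max(len(lost), 1)),
            "retained_abs_40_74": int(lost["retained_abs_40_74"].sum()),
            "retained_gt20_genic": ratio_entry(
                int(ret20_ann["feature"].isin(genic_feats).sum()), max(len(ret20), 1)
            ),
            "retained_gt20_re_overlap": ratio_entry(
                int(ret20_ann["repeat_overlap"].notna().sum()), max(len(ret20), 1)
            ),
        },
        "hypo_d21_context": {
            "genic": ratio_entry(
                int(hypo_ann["feature"].isin(genic_feats).sum()), max(n_hypo_d21, 1), 1
            ),
            "re_overlap": ratio_entry(
                int(hypo_ann["repeat_overlap"].notna().sum()), max(n_hypo_d21, 1)
            ),
            "cgi": int(hypo_ann["cgi"].sum()),
        },
        "patterns": {p: int(pattern_counts.get(p, 0)) for p in traj.PATTERNS},
        "regions": {"merged_hypo_d0": int(len(regions)), "max_gap": config.max_gap},
        "candidates": {
            "genes_ranked": int(len(candidates)),
            "top_bin": candidates["bin"].iloc[0] if len(candidates) else None,
            "top_bin_genes": candidates.loc[
                candidates["bin"] == f"[{traj.DEFAULT_BIN_EDGES[0]:g},100]", "gene_id"
            ].tolist(),
        },
    }
    _verify_ratios(report)

    result = PipelineResult(
        loci=loci,
        manifest=manifest,
        matrix=matrix,
        correlations=corr,
        diff_d0=diff_d0,
        diff_d21=diff_d21,
        retention=retention,
        trajectories=trajectories,
        annotations=annotations,
        candidates=candidates,
        regions=regions,
        tss_prof=tss_prof,
        true_class=true_class,
        report=report,
    )
    if outdir is not None:
        _write_outputs(result, matrix, Path(outdir))
    return result


def _heatmap_frame(result: PipelineResult) -> pd.DataFrame:
    """Figure-style tile matrix: clustered by repeat presence, then genic
    feature, then sorted by d0 methylation within each cluster."""
    gm = result.matrix.group_means()
    df = gm.join(result.annotations[["feature", "repeat_overlap"]])
    df["has_repeat"] = df["repeat_overlap"].notna()
    return df.sort_values(
        ["has_repeat", "feature", "d0"], ascending=[False, True, False]
    )


def _write_outputs(result: PipelineResult, matrix, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_manifest(result.manifest, outdir / "manifest.tsv")
    mio.write_tile_matrix(matrix, outdir / "tiles.tsv")
    result.correlations.to_csv(outdir / "sample_correlations.tsv", sep="\t")
    result.diff_d0.to_csv(outdir / "differential_control_vs_d0.tsv", sep="\t")
    result.diff_d21.to_csv(outdir / "differential_control_vs_d21.tsv", sep="\t")
    result.retention.to_csv(outdir / "retention_d0.tsv", sep="\t")
    result.trajectories.to_csv(outdir / "trajectories.tsv", sep="\t")
    result.annotations.to_csv(outdir / "annotated_tiles.tsv", sep="\t")
    result.candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    regions = result.regions.copy()
    if not regions.empty:
        regions["name"] = ["region_%d" % i for i in range(len(regions))]
        mio.write_bed(regions, outdir / "regions_hypo_d0.bed", dialect="bed4")
    result.tss_prof.to_csv(outdir / "tss_profile.tsv", sep="\t")
    _heatmap_frame(result).to_csv(outdir / "heatmap_tiles.tsv", sep="\t")
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
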