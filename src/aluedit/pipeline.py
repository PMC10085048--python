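"""End-to-end orchestration: simulate -> pileup -> indices -> ISG -> statistics
-> clustering -> ROC, with a run manifest and digest-based stage caching.

Every stage writes plain TSV tables into the run directory; ``manifest.json``
records the configuration snapshot, seed, tool version and per-stage input /
output digests.  On re-runs a stage whose input digests match the previous
manifest and whose outputs are intact is skipped and marked as a cache hit.
By default the manifest carries a fixed placeholder timestamp so that two
runs with the same configuration and seed are byte-identical; wall-clock
stamps can be enabled explicitly.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotations import CohortDesign, read_table, write_table
from .expression import ISGSignature, isg_score, marker_expression, scores_to_frame
from .indices import (
    centralization,
    compute_aei,
    compute_cei,
    select_utr3_alus,
    site_levels,
)
from .pileup import ReadFilterPolicy, pileup
from .profiles import build_profile, cluster_tissues, contribution_profile, filter_profile
from .simulate import MARKER_GENES, SimulationConfig, simulate_cohort
from .stats import (
    compare_two_groups,
    correlate,
    covariate_regression,
    interaction_model,
    meaningful_sites,
    roc_auc,
)

__all__ = ["run_pipeline", "report", "bundle_digest"]

STAGES = ("simulate", "indices", "isg", "stats", "cluster", "roc")


@dataclass
class _Manifest:
    run_id: str
    seed: int
    version: str
    config: dict
    timestamp: str
    stages: dict

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _digests(paths) -> dict:
    return {Path(p).name: _digest(Path(p)) for p in sorted(map(str, paths))}


def bundle_digest(out_dir: str | Path) -> dict:
    """Name -> sha256 of every result table in a run directory."""
    out_dir = Path(out_dir)
    return _digests(p for p in sorted(out_dir.rglob("*")) if p.is_file())


def run_pipeline(
    config: SimulationConfig | None = None,
    out_dir: str | Path = "aluedit_run",
    seed: int | None = None,
    policy: ReadFilterPolicy | None = None,
    use_cache: bool = True,
    wall_clock: bool = False,
) -> dict:
    """Run the full synthetic-cohort pipeline into ``out_dir``.

    Returns a result-bundle dict mapping table names to paths.  A stage
    failure raises with the stage named; downstream outputs are not written.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**_config_dict(config), "seed": seed})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    policy = policy or ReadFilterPolicy()

    cfg_dict = _config_dict(config)
    run_id = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    manifest_path = out_dir / "manifest.json"
    previous = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else None
    )
    if previous is not None and previous.get("run_id") != run_id:
        previous = None  # different configuration: no cache reuse
    manifest = _Manifest(
        run_id=run_id,
        seed=config.seed,
        version=__version__,
        config=json.loads(json.dumps(cfg_dict, default=str)),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S") if wall_clock else "fixed",
        stages={},
    )
    bundle: dict[str, Path] = {"manifest": manifest_path}

    def stage_done(name, inputs, outputs, cached=False):
        manifest.stages[name] = {
            "status": "ok",
            "cached": cached,
            "inputs": _digests(inputs),
            "outputs": _digests(outputs),
        }

    def cache_hit(name, inputs, outputs) -> bool:
        if not use_cache or previous is None:
            return False
        prev = previous.get("stages", {}).get(name)
        if not prev or prev.get("status") != "ok":
            return False
        try:
            if prev.get("inputs") != _digests(inputs):
                return False
            for p in outputs:
                if not Path(p).exists():
                    return False
            return prev.get("outputs") == _digests(outputs)
        except OSError:
            return False

    current_stage = "simulate"
    try:
        # -- stage: simulate ------------------------------------------------
        data_dir = out_dir / "data"
        sim_outputs = [
            data_dir / n
            for n in ("reference.fa", "alu.bed", "utr3.bed", "sites.tsv",
                      "expression.tsv", "cohort.tsv", "truth_samples.tsv",
                      "truth_site_levels.tsv")
        ]
        reads_dir = data_dir / "reads"
        if cache_hit("simulate", [], sim_outputs):
            # reconstruct the in-memory bundle without re-emitting reads
            cohort = simulate_cohort(config, out_dir=data_dir, reads=False)
            cohort.sam_paths = {
                s: reads_dir / f"{s}.sam" for s in cohort.design.samples
            }
            stage_done("simulate", [], sim_outputs, cached=True)
        else:
            cohort = simulate_cohort(config, out_dir=data_dir, reads=True)
            stage_done("simulate", [], sim_outputs)

        design = cohort.design
        groups = design.groups
        pair = (groups[0], groups[1])

        # -- stage: pileup + editing indices -------------------------------
        current_stage = "indices"
        idx_path = out_dir / "indices.tsv"
        sites_path = out_dir / "site_levels.tsv"
        sim_inputs = list(cohort.sam_paths.values()) + [cohort.paths["sites"]]
        if cache_hit("indices", sim_inputs, [idx_path, sites_path]):
            stage_done("indices", sim_inputs, [idx_path, sites_path], cached=True)
        else:
            utr3_subset = select_utr3_alus(cohort.reference.alus, cohort.reference.utr3s)
            index_rows, site_frames = [], []
            targets = list(cohort.reference.alus) + list(cohort.reference.sites)
            for sample, sam in cohort.sam_paths.items():
                pile = pileup(sam, targets, policy, cohort.paths["reference"])
                index_rows.append(
                    compute_aei(pile, cohort.reference.alus, sample, "all-Alu").to_row()
                )
                index_rows.append(
                    compute_aei(pile, utr3_subset, sample, "utr3-Alu").to_row()
                )
                table = site_levels(pile, cohort.reference.sites, sample=sample)
                site_frames.append(table)
                index_rows.append(compute_cei(table, sample).to_row())
            write_table(pd.DataFrame(index_rows), idx_path)
            write_table(pd.concat(site_frames, ignore_index=True), sites_path)
            stage_done("indices", sim_inputs, [idx_path, sites_path])
        bundle["indices"] = idx_path
        bundle["site_levels"] = sites_path

        # -- stage: ISG / markers -------------------------------------------
        current_stage = "isg"
        isg_path = out_dir / "isg_scores.tsv"
        markers_path = out_dir / "markers.tsv"
        if cache_hit("isg", [cohort.paths["expression"]], [isg_path, markers_path]):
            stage_done("isg", [cohort.paths["expression"]], [isg_path, markers_path], True)
        else:
            scores = isg_score(
                cohort.expression, ISGSignature.default(), design.samples_in(pair[0])
            )
            write_table(scores_to_frame(scores), isg_path)
            markers = marker_expression(
                cohort.expression, list(MARKER_GENES) + ["ADAR", "ADARB1"]
            )
            out = markers.T.reset_index(names="sample")
            write_table(out, markers_path)
            stage_done("isg", [cohort.paths["expression"]], [isg_path, markers_path])
        bundle["isg_scores"] = isg_path
        bundle["markers"] = markers_path

        # -- stage: cohort statistics ---------------------------------------
        current_stage = "stats"
        stat_inputs = [idx_path, sites_path, isg_path, markers_path,
                       cohort.paths["cohort"]]
        comp_path = out_dir / "comparisons.tsv"
        meaningful_path = out_dir / "meaningful_sites.tsv"
        corr_path = out_dir / "correlations.tsv"
        inter_path = out_dir / "interaction_model.tsv"
        covar_path = out_dir / "covariate_model.tsv"
        stat_outputs = [comp_path, meaningful_path, corr_path, inter_path, covar_path]
        if cache_hit("stats", stat_inputs, stat_outputs):
            stage_done("stats", stat_inputs, stat_outputs, cached=True)
        else:
            _stats_stage(
                idx_path, sites_path, isg_path, markers_path, design, pair,
                comp_path, meaningful_path, corr_path, inter_path, covar_path,
            )
            stage_done("stats", stat_inputs, stat_outputs)
        bundle.update(
            comparisons=comp_path, meaningful_sites=meaningful_path,
            correlations=corr_path, interaction_model=inter_path,
            covariate_model=covar_path,
        )

        # -- stage: profile clustering --------------------------------------
        current_stage = "cluster"
        profile_path = out_dir / "profile_matrix.tsv"
        tree_path = out_dir / "tissue_tree.nwk"
        embed_path = out_dir / "embedding.tsv"
        contrib_path = out_dir / "contribution.tsv"
        central_path = out_dir / "centralization.tsv"
        cluster_outputs = [profile_path, tree_path, embed_path, contrib_path, central_path]
        if cache_hit("cluster", [sites_path], cluster_outputs):
            stage_done("cluster", [sites_path], cluster_outputs, cached=True)
        else:
            _cluster_stage(
                sites_path, cohort.tissue_of, len(config.tissues),
                profile_path, tree_path, embed_path, contrib_path, central_path,
            )
            stage_done("cluster", [sites_path], cluster_outputs)
        bundle.update(
            profile_matrix=profile_path, tissue_tree=tree_path,
            embedding=embed_path, contribution=contrib_path,
            centralization=central_path,
        )

        # -- stage: ROC marker comparison -----------------------------------
        current_stage = "roc"
        roc_path = out_dir / "roc.tsv"
        roc_inputs = [idx_path, sites_path, markers_path, cohort.paths["cohort"]]
        if cache_hit("roc", roc_inputs, [roc_path]):
            stage_done("roc", roc_inputs, [roc_path], cached=True)
        else:
            _roc_stage(idx_path, sites_path, markers_path, design, pair, roc_path)
            stage_done("roc", roc_inputs, [roc_path])
        bundle["roc"] = roc_path
    except Exception as exc:
        manifest.stages[current_stage] = {"status": "failed", "error": str(exc)}
        for name in STAGES:
            manifest.stages.setdefault(name, {"status": "not-run"})
        manifest.save(manifest_path)
        raise RuntimeError(f"pipeline failed in stage {current_stage!r}: {exc}") from exc

    manifest.save(manifest_path)
    return {k: Path(v) for k, v in bundle.items()}


def _config_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def _stats_stage(
    idx_path, sites_path, isg_path, markers_path, design, pair,
    comp_path, meaningful_path, corr_path, inter_path, covar_path,
):
    indices = read_table(idx_path)
    site_table = read_table(sites_path)
    isg = read_table(isg_path).set_index("sample")["isg_score"]
    markers = read_table(markers_path).set_index("sample")

    comparisons = []
    series_by_variable = {}
    for region_set in ("all-Alu", "utr3-Alu", "coding-sites"):
        sub = indices[indices["region_set"] == region_set]
        series = sub.set_index("sample")["index_pct"]
        label = {"all-Alu": "AEI", "utr3-Alu": "AEI-utr3", "coding-sites": "CEI"}[region_set]
        series_by_variable[label] = series
    series_by_variable["ISG"] = isg
    for gene in ("ADAR", "ADARB1"):
        series_by_variable[gene] = np.log2(markers[gene].astype(float) + 1.0)
    for label, series in series_by_variable.items():
        try:
            comparisons.append(compare_two_groups(series, design, pair, label).to_row())
        except ValueError as exc:
            # e.g. an undefined index for too many samples: skip the variable
            warnings.warn(f"skipping comparison of {label!r}: {exc}", stacklevel=2)
    write_table(pd.DataFrame(comparisons), comp_path)

    calls, excluded = meaningful_sites(site_table, design, pair)
    call_rows = [
        {"site": c.site, "gene": c.gene, "mean_diff_pct": c.mean_diff_pct,
         "p_value": c.p_value, "adjusted_p": c.adjusted_p, "meaningful": c.meaningful,
         "mean_control": c.comparison.means[0], "mean_patient": c.comparison.means[1],
         "n_control": c.comparison.ns[0], "n_patient": c.comparison.ns[1],
         "test": c.comparison.test_used}
        for c in calls
    ]
    frame = pd.DataFrame(call_rows)
    frame.attrs["excluded"] = excluded
    write_table(frame, meaningful_path)

    aei = series_by_variable["AEI"]
    adar = np.log2(markers["ADAR"].astype(float) + 1.0)
    corr_rows = []
    for a, b, la, lb in (
        (adar, isg, "ADAR1", "ISG"),
        (adar, aei, "ADAR1", "AEI"),
        (aei, isg, "AEI", "ISG"),
    ):
        rho, p = correlate(a, b)
        corr_rows.append({"x": la, "y": lb, "spearman_rho": rho, "p_value": p,
                          "n": int(pd.concat([a, b], axis=1).dropna().shape[0])})
    write_table(pd.DataFrame(corr_rows), corr_path)

    inter = interaction_model(aei, adar, isg)
    write_table(inter, inter_path)

    covar = covariate_regression(aei, design, pair)
    write_table(covar, covar_path)


def _cluster_stage(
    sites_path, tissue_of, n_tissues,
    profile_path, tree_path, embed_path, contrib_path, central_path,
):
    site_table = read_table(sites_path)
    profile = build_profile(site_table, tissue_of)
    # the >= 5-tissue availability cutoff is capped at the number of tissues
    filtered = filter_profile(profile, min_tissues=min(5, n_tissues))
    values = filtered.values.copy()
    values.insert(0, "tissue", values.index)
    write_table(values.reset_index(drop=True), profile_path)
    clustering = cluster_tissues(filtered)
    Path(tree_path).write_text(clustering.newick + "\n")
    emb = clustering.embedding.copy()
    emb.insert(0, "tissue", emb.index)
    write_table(emb.reset_index(drop=True), embed_path)
    contrib = contribution_profile(filtered.edited)
    out = contrib.copy()
    out.insert(0, "tissue", out.index)
    write_table(out.reset_index(drop=True), contrib_path)
    central_rows = [
        {"tissue": t, "top5_fraction": centralization(filtered.edited.loc[t], k=5)}
        for t in filtered.tissues
    ]
    write_table(pd.DataFrame(central_rows), central_path)


def _roc_stage(idx_path, sites_path, markers_path, design, pair, roc_path):
    indices = read_table(idx_path)
    site_table = read_table(sites_path)
    markers = read_table(markers_path).set_index("sample")
    keep = [s for s in design.samples if design.group_of()[s] in pair]
    labels = {s: design.group_of()[s] for s in keep}

    candidates: dict[str, pd.Series] = {}
    for gene in MARKER_GENES:
        candidates[f"{gene} expression"] = markers[gene].astype(float)
    aei = indices[indices["region_set"] == "all-Alu"].set_index("sample")["index_pct"]
    candidates["Alu editing"] = aei
    igf = site_table[(site_table["gene"] == "IGFBP7") & site_table["included"]]
    candidates["IGFBP7 editing"] = igf.set_index("sample")["level_pct"]

    rows = []
    for name, series in candidates.items():
        series = series.reindex(keep).dropna()
        res = roc_auc(series, [labels[s] for s in series.index], positive=pair[1])
        rows.append(
            {"marker": name, "auc": res.auc, "ci_low": res.ci_low,
             "ci_high": res.ci_high, "n_case": res.n_case,
             "n_control": res.n_control}
        )
    write_table(pd.DataFrame(rows), roc_path)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def report(out_dir: str | Path) -> str:
    """Render a deterministic text summary of a completed run directory."""
    out_dir = Path(out_dir)
    lines = ["# Editing-analysis run summary", ""]
    comp = read_table(out_dir / "comparisons.tsv")
    manifest = json.loads((out_dir / "manifest.json").read_text())
    lines.append(f"Run ID: {manifest['run_id']} (seed {manifest['seed']}, "
                 f"aluedit {manifest['version']})")
    lines.append("")
    lines.append("## Group comparisons (mean +/- SEM, n)")
    lines.append("")
    g1, g2 = comp.iloc[0]["groups"].split("|")
    lines.append(f"variable\t{g1}\t{g2}\ttest\tp\tdirection")
    for row in comp.itertuples():
        a = f"{getattr(row, f'mean_{g1}'):.3g} +/- {getattr(row, f'sem_{g1}'):.2g} (n={getattr(row, f'n_{g1}')})"
        b = f"{getattr(row, f'mean_{g2}'):.3g} +/- {getattr(row, f'sem_{g2}'):.2g} (n={getattr(row, f'n_{g2}')})"
        arrow = {"up": "^", "down": "v", "none": "-"}[row.direction]
        lines.append(f"{row.variable}\t{a}\t{b}\t{row.test}\t{row.p_value:.3g}\t{arrow}")
    lines.append("")
    meaningful = read_table(out_dir / "meaningful_sites.tsv")
    called = meaningful[meaningful["meaningful"] == True] if not meaningful.empty else meaningful  # noqa: E712
    lines.append(f"## Meaningful differential editing sites ({len(called)} of {len(meaningful)} tested)")
    lines.append("")
    lines.append("site\tgene\tmean_control\tmean_patient\tdiff\tFDR")
    for row in called.itertuples():
        lines.append(
            f"{row.site}\t{row.gene}\t{row.mean_control:.2f}\t{row.mean_patient:.2f}"
            f"\t{row.mean_diff_pct:+.2f}\t{row.adjusted_p:.3g}"
        )
    lines.append("")
    roc = read_table(out_dir / "roc.tsv")
    lines.append("## Marker ROC comparison")
    lines.append("")
    lines.append("marker\tAUC\t95% CI")
    for row in roc.itertuples():
        lines.append(f"{row.marker}\t{row.auc:.2f}\t[{row.ci_low:.2f}, {row.ci_high:.2f}]")
    lines.append("")
    tree = (out_dir / "tissue_tree.nwk").read_text().strip()
    lines.append("## Tissue clustering (Newick)")
    lines.append("")
    lines.append(tree)
    lines.append("")
    text = "\n".join(lines)
    (out_dir / "report.md").write_text(text)
    return text
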