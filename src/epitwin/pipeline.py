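"""End-to-end orchestration: simulate -> QC -> call -> compare -> integrate.

The pipeline runs the complete analysis on a cohort (synthetic by default):
probe QC, iiDMR calling over a labelled comparison plan, the
biological-vs-technical permutation test, RMS variability, temporal
direction consistency, methylation/chromatin/expression integration and
the enrichment battery, writing per-stage TSVs and one machine-readable
summary. Identical configs give identical summaries. No multiple-testing
correction is applied anywhere: like the analyses it reproduces, every
p-value is reported raw.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import dmr, enrichment, integration, io, qc, temporal, variability
from .simulate import (
    Cohort,
    SimulationConfig,
    generate_age_correlations,
    generate_chip_counts,
    generate_cohort,
    generate_expression,
)
from .types import GenomicInterval, SampleSheet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Comparison:
    """One labelled pairwise comparison between two samples."""

    sample_a: str
    sample_b: str
    individual_a: str
    individual_b: str
    label: str  # intra_pair | inter_pair | technical

    @property
    def comparison_id(self) -> str:
        return f"{self.label}:{self.sample_a}~{self.sample_b}"


def comparison_plan(
    sheet: SampleSheet,
    time_point: Optional[int] = None,
    platform: Optional[str] = None,
    inter_pair_mode: str = "exhaustive",
    include_technical: bool = True,
) -> list[Comparison]:
    """Enumerate labelled pairwise comparisons from the design sheet.

    intra_pair: co-twin comparisons (first replicate of each individual).
    inter_pair: comparisons between individuals from different pairs —
    either every cross-pair individual pairing (``exhaustive``, the
    default) or one representative individual per pair per unordered pair
    of pairs (``representative``, which on a 2-full-pairs + 1-singleton
    design reproduces the classic five pairwise comparisons).
    technical: replicate-vs-replicate comparisons within each individual.
    Ordering is deterministic.
    """
    if inter_pair_mode not in ("exhaustive", "representative"):
        raise ValueError(f"unknown inter_pair_mode {inter_pair_mode!r}")
    pairs = sheet.pairs()

    def first_sample(ind: str) -> Optional[str]:
        ss = sheet.samples_for(ind, time_point=time_point, platform=platform)
        return ss[0] if ss else None

    plan: list[Comparison] = []
    # intra-pair (co-twin) comparisons
    for pid in sorted(pairs):
        members = pairs[pid]
        if len(members) != 2:
            continue
        sa, sb = first_sample(members[0]), first_sample(members[1])
        if sa and sb:
            plan.append(Comparison(sa, sb, members[0], members[1], "intra_pair"))
    # inter-pair comparisons
    pair_ids = sorted(pid for pid in pairs if any(first_sample(i) for i in pairs[pid]))
    for pa, pb in combinations(pair_ids, 2):
        if inter_pair_mode == "representative":
            ia = min(i for i in pairs[pa] if first_sample(i))
            ib = min(i for i in pairs[pb] if first_sample(i))
            plan.append(Comparison(first_sample(ia), first_sample(ib), ia, ib,
                                   "inter_pair"))
        else:
            for ia in pairs[pa]:
                for ib in pairs[pb]:
                    sa, sb = first_sample(ia), first_sample(ib)
                    if sa and sb:
                        plan.append(Comparison(sa, sb, ia, ib, "inter_pair"))
    # technical replicate comparisons
    if include_technical:
        for ind in sheet.individuals():
            ss = sheet.samples_for(ind, time_point=time_point, platform=platform)
            for sa, sb in combinations(ss, 2):
                plan.append(Comparison(sa, sb, ind, ind, "technical"))
    return plan


@dataclass
class PipelineConfig:
    """Parameters for a full run; one global seed drives all stage seeds."""

    seed: int = 0
    outdir: str = "epitwin_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_delta: float = 0.05
    min_probes: int = 2
    max_gap: int = 500
    temporal_threshold: float = 0.05
    bin_width: float = 0.05
    n_boot: int = 1000
    n_perm: int = 1000
    hi_quantile: float = 0.75
    n_age_top: int = 500
    n_age_control: int = 500
    inter_pair_mode: str = "exhaustive"
    stages: tuple[str, ...] = (
        "qc",
        "call_dmrs",
        "variability",
        "temporal",
        "integrate",
        "enrich",
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(simulation=sim, **raw)
        cfg.simulation.seed = cfg.seed
        return cfg

    def stage_seed(self, stage: str) -> int:
        offsets = {"variability": 11, "integrate": 13, "enrich": 17}
        return (self.seed * 31 + offsets.get(stage, 19)) % (2**31)


def run_pipeline(config: PipelineConfig, cohort: Optional[Cohort] = None) -> dict:
    """Run every enabled stage; returns the summary dict (also written to
    ``outdir/summary.json`` with per-stage TSVs alongside)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "INCOMPLETE"
    marker.write_text("run in progress\n")
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}
    try:
        if cohort is None:
            config.simulation.seed = config.seed
            cohort = generate_cohort(config.simulation)
        io.write_probe_manifest(cohort.manifest, outdir / "manifest.tsv")
        io.write_sample_sheet(cohort.sheet, outdir / "samples.tsv")

        stage = "qc"
        kept, report = qc.filter_probes(cohort.manifest)
        if stage in config.stages:
            qc.report_frame(report).to_csv(outdir / "qc_report.tsv", sep="\t",
                                           index=False)
            summary["qc"] = {"n_input": report.n_input, "n_kept": report.n_kept,
                             "removed": report.removed}

        matrix = cohort.matrix(2, "dense")
        plan = comparison_plan(
            cohort.sheet, time_point=2, platform="dense",
            inter_pair_mode=config.inter_pair_mode,
        )
        caller = dict(min_delta=config.min_delta, min_probes=config.min_probes,
                      max_gap=config.max_gap)

        calls_by_comparison: dict[str, list] = {}
        if "call_dmrs" in config.stages:
            stage = "call_dmrs"
            rows = []
            all_calls = []
            for comp in plan:
                if comp.label == "technical":
                    continue
                track = dmr.compute_deltas(matrix, comp.sample_a, comp.sample_b, kept)
                calls = dmr.call_iidmrs(track, comparison_id=comp.comparison_id,
                                        **caller)
                calls_by_comparison[comp.comparison_id] = calls
                counts = dmr.count_dmr_probes(calls, cohort.manifest)
                rows.append({"comparison": comp.comparison_id, "label": comp.label,
                             "n_dmrs": counts["n_calls"],
                             "n_probes": counts["n_probes"]})
                all_calls.extend(calls)
            pd.DataFrame(rows).to_csv(outdir / "dmr_counts.tsv", sep="\t", index=False)
            io.write_dmr_bed(all_calls, outdir / "dmrs.bed")
            summary["call_dmrs"] = {"per_comparison": rows,
                                    "n_total_calls": len(all_calls)}

        if "variability" in config.stages:
            stage = "variability"
            result = variability.technical_vs_biological_test(
                matrix, cohort.sheet, kept, caller_params=caller,
                n_perm=config.n_perm, seed=config.stage_seed("variability"),
            )
            profile = variability.rms_profile(
                matrix, cohort.sheet, seed=config.stage_seed("variability")
            )
            profile.to_csv(outdir / "rms_profile.tsv", sep="\t", index=False)
            summary["variability"] = {
                "bio_vs_tech_ratio": result.statistic,
                "p_value": result.p_value,
                **result.extras,
                "mean_rms_intra": float(profile["rms_intra"].mean()),
                "mean_rms_inter": float(profile["rms_inter"].mean()),
            }

        if "temporal" in config.stages:
            stage = "temporal"
            sparse_manifest = cohort.sparse_manifest()
            common = temporal.match_platforms(cohort.manifest, sparse_manifest)
            kept_common = [r for r in kept if r.probe_id in set(common)]
            sparse = cohort.matrix(1, "sparse")
            rows = []
            for comp in plan:
                if comp.label != "intra_pair":
                    continue
                t2 = dmr.compute_deltas(matrix, comp.sample_a, comp.sample_b,
                                        kept_common)
                sa = cohort.sheet.samples_for(comp.individual_a, 1, "sparse")[0]
                sb = cohort.sheet.samples_for(comp.individual_b, 1, "sparse")[0]
                t1 = dmr.compute_deltas(sparse, sa, sb, kept_common)
                res = temporal.direction_consistency_test(
                    t2, t1, threshold=config.temporal_threshold
                )
                rows.append({"comparison": comp.comparison_id,
                             "chi2": res.statistic, "p_value": res.p_value,
                             **res.extras})
            pd.DataFrame(rows).to_csv(outdir / "temporal.tsv", sep="\t", index=False)
            summary["temporal"] = rows

        assignment = integration.assign_probes_to_tss(
            kept,
            [
                GenomicInterval(r.chromosome, int(r.tss_pos), int(r.tss_pos) + 1,
                                name=r.tss_id)
                for r in cohort.truth.promoters.itertuples()
            ],
        )
        expr = generate_expression(cohort.truth, cohort.config)

        if "integrate" in config.stages:
            stage = "integrate"
            inds = cohort.truth.individuals
            rep_samples = {
                i: cohort.sheet.samples_for(i, 2, "dense")[0] for i in inds
            }
            h2az = {
                i: generate_chip_counts(cohort.truth, matrix, "H2A.Z",
                                        cohort.config, sample_id=rep_samples[i])
                for i in inds
            }
            # promoter-level correlations for the first individual
            ind0 = inds[0]
            beta0 = matrix.beta(rep_samples[ind0])
            prom_beta, prom_chip, prom_expr = [], [], []
            chip0 = h2az[ind0].as_series()
            probe_frame = pd.DataFrame(
                {"probe_id": [r.probe_id for r in kept],
                 "tss": [assignment.get(r.probe_id) for r in kept]}
            ).dropna()
            for tss, grp in probe_frame.groupby("tss"):
                pids = list(grp["probe_id"])
                prom_beta.append(float(beta0.loc[pids].mean()))
                prom_chip.append(float(chip0.loc[pids].mean()))
                prom_expr.append(float(expr.fpkm(ind0).get(tss, np.nan)))
            ok = ~np.isnan(prom_expr)
            sp_mc = integration.spearman(np.array(prom_beta)[ok],
                                         np.array(prom_chip)[ok])
            sp_ce = integration.spearman(np.array(prom_chip)[ok],
                                         np.log1p(np.array(prom_expr)[ok]))
            sp_me = integration.spearman(np.array(prom_beta)[ok],
                                         np.log1p(np.array(prom_expr)[ok]))
            # binned H2A.Z-difference series for the first co-twin comparison
            intra = [c for c in plan if c.label == "intra_pair"][0]
            track = dmr.compute_deltas(matrix, intra.sample_a, intra.sample_b, kept)
            diff = (h2az[intra.individual_a].as_series()
                    - h2az[intra.individual_b].as_series())
            resp = diff.reindex(track.probe_ids).to_numpy()
            sel = ~np.isnan(track.deltas) & (np.abs(track.deltas) > config.min_delta)
            series = integration.binned_mean_ci(
                track.deltas[sel], resp[sel], bin_width=config.bin_width,
                n_boot=config.n_boot, seed=config.stage_seed("integrate"),
            )
            series.to_frame().to_csv(outdir / "h2az_binned.tsv", sep="\t",
                                     index=False)
            ratio = integration.expression_ratio_series(
                track, expr.fpkm(intra.individual_a), expr.fpkm(intra.individual_b),
                assignment, bin_width=config.bin_width, n_boot=config.n_boot,
                seed=config.stage_seed("integrate"),
            )
            ratio.to_frame().to_csv(outdir / "expression_ratio_binned.tsv",
                                    sep="\t", index=False)
            summary["integrate"] = {
                "spearman_meth_h2az": sp_mc.statistic,
                "spearman_h2az_expr": sp_ce.statistic,
                "spearman_meth_expr": sp_me.statistic,
                "n_promoters": int(ok.sum()),
            }

        if "enrich" in config.stages:
            stage = "enrich"
            dmr_probes = set()
            for comp_id, calls in calls_by_comparison.items():
                if comp_id.startswith("intra_pair"):
                    dmr_probes |= dmr.dmr_probe_ids(calls)
            universe = [r.probe_id for r in kept]
            dmr_probes &= set(universe)
            feat_map = {r.probe_id: r.feature_class for r in kept}
            feat = enrichment.category_enrichment(dmr_probes, feat_map, universe)
            enrichment.enrichment_frame(feat).to_csv(
                outdir / "feature_enrichment.tsv", sep="\t", index=False)
            k4 = generate_chip_counts(cohort.truth, matrix, "H3K4me3", cohort.config)
            k27 = generate_chip_counts(cohort.truth, matrix, "H3K27me3", cohort.config)
            states = enrichment.classify_chromatin_states(
                k4, k27, hi_quantile=config.hi_quantile)
            state_of_tss = dict(zip(states["tss_id"], states["state"]))
            prom_universe = [p for p in universe if p in assignment]
            state_map = {p: state_of_tss[assignment[p]] for p in prom_universe
                         if assignment[p] in state_of_tss}
            state_enr = enrichment.category_enrichment(
                dmr_probes & set(prom_universe), state_map, prom_universe)
            enrichment.enrichment_frame(state_enr).to_csv(
                outdir / "chromatin_state_enrichment.tsv", sep="\t", index=False)
            hk = set(cohort.truth.promoters.loc[
                cohort.truth.promoters["housekeeping"], "tss_id"])
            dmr_tss = {assignment[p] for p in dmr_probes if p in assignment}
            all_tss = {assignment[p] for p in prom_universe}
            hk_res = enrichment.housekeeping_depletion_test(
                dmr_tss, hk & all_tss, all_tss)
            shift = integration.expression_shift_test(
                dmr_tss, all_tss, expr.mean_fpkm())
            scores, _ = generate_age_correlations(cohort.truth, cohort.manifest,
                                                  cohort.config)
            admr_comps = [(c.sample_a, c.sample_b) for c in plan
                          if c.label in ("intra_pair", "inter_pair")]
            admr = enrichment.admr_variability_comparison(
                scores, matrix, cohort.sheet, kept, admr_comps,
                n_top=config.n_age_top, n_control=config.n_age_control,
                n_boot=config.n_boot, seed=config.stage_seed("enrich"),
            )
            summary["enrich"] = {
                "feature": [vars(r) | {} for r in feat],
                "chromatin_state": [
                    {"category": r.category, "fraction": r.fraction,
                     "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "background": r.background_fraction}
                    for r in state_enr
                ],
                "housekeeping_p": hk_res.p_value,
                "housekeeping_direction": hk_res.extras["direction"],
                "expression_shift_p": shift.p_value,
                "frac_low_expression_dmr": shift.extras["frac_low_expression_dmr"],
                "frac_low_expression_other": shift.extras["frac_low_expression_other"],
                "admr_mean_abs_delta": admr["admr"].statistic,
                "admr_ci": [admr["admr"].ci_low, admr["admr"].ci_high],
                "control_mean_abs_delta": admr["control"].statistic,
                "control_ci": [admr["control"].ci_low, admr["control"].ci_high],
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_default) + "\n"
    )
    marker.unlink(missing_ok=True)
    return summary
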