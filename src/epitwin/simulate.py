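"""Synthetic twin-cohort generator with a machine-readable truth table.

Emulates the statistical structure of an array-based MZ-twin methylation
study: a dense 450K-like probe grid laid out in CGI-like clusters (with a
sparse, promoter-biased 27K-like subset), bimodal baseline beta values,
co-twins sharing a pair-level profile, and three planting mechanisms on top
of technical noise:

* **individual epialleles** — coherent beta shifts of ``epiallele_delta``
  over 2-5 consecutive probes in one individual, preferentially at
  low-expression / H3K4me3-low promoters, persisting to the second time
  point with probability ``temporal_stability``;
* **pair-shared (genetic-like) shifts** — runs shared by both co-twins of a
  pair, creating inter-pair but not intra-pair differences;
* **variable probes** — per-individual Gaussian deviations of sd
  ``biological_sd`` at a designated probe subset, giving every pair a
  twin-difference SD of sqrt(2)*biological_sd at those probes.

Companion generators produce ChIP fragment-count tracks whose rank
correlation with methylation matches ``meth_chip_coupling`` (H2A.Z) or the
per-promoter truth chromatin state (H3K4me3/H3K27me3), FPKM tables with a
<1 / >=1 low/high expression split, and probe-level ageing-correlation
scores with a designated top set.

All randomness derives from one integer seed; each component uses its own
deterministic sub-stream, so identical configs give byte-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm, rankdata

from .types import (
    CountTrack,
    ExpressionTable,
    MethylationMatrix,
    ProbeRecord,
    SampleSheet,
)

_STATES_HIGH = (  # chromatin-state probabilities at high-expression promoters
    ("K4hi/K27hi", 0.10),
    ("K4hi/K27lo", 0.85),
    ("K4lo/K27hi", 0.02),
    ("K4lo/K27lo", 0.03),
)
_STATES_LOW = (  # ... and at low-expression promoters (mostly K4lo)
    ("K4hi/K27hi", 0.03),
    ("K4hi/K27lo", 0.04),
    ("K4lo/K27hi", 0.465),
    ("K4lo/K27lo", 0.465),
)

# sub-stream labels -> offsets mixed into the seed sequence
_STREAMS = {
    "layout": 1,
    "baseline": 2,
    "genetic": 3,
    "epialleles": 4,
    "variable": 5,
    "noise": 6,
    "chip": 7,
    "expression": 8,
    "age": 9,
}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[component]]))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Rates are fractions in [0, 1]; deltas and sds are on the beta scale.
    """

    seed: int = 0
    n_probes: int = 20_000
    n_pairs: int = 5
    n_tech_replicates: int = 2
    cgi_cluster_size: int = 8
    cgi_spacing_bp: int = 10_000
    baseline_beta_modes: tuple[float, float] = (0.15, 0.85)
    tech_noise_sd: float = 0.015
    epiallele_rate: float = 0.05
    epiallele_delta: float = 0.15
    temporal_stability: float = 0.9
    genetic_delta: float = 0.10
    meth_chip_coupling: float = -0.6
    lowexpr_targeting: float = 0.9

    # planting extras
    genetic_rate: float = 0.05
    variable_probe_rate: float = 0.02
    biological_sd: float = 0.05
    epiallele_run_range: tuple[int, int] = (2, 5)

    # genome layout
    n_autosomes: int = 5
    sex_cluster_rate: float = 0.02
    multi_mapped_rate: float = 0.01
    snp_rate: float = 0.02
    promoter_fraction: float = 0.5
    probe_spacing_range: tuple[int, int] = (60, 180)
    baseline_jitter: float = 0.3

    # expression / chromatin coupling
    high_expr_fraction: float = 0.25
    expr_low_mean: float = 0.1
    expr_high_mean: float = 10.0
    expr_log_sd: float = 1.0
    expr_ind_sd: float = 0.15
    expr_epiallele_effect: float = 8.0
    housekeeping_high_rate: float = 0.6
    housekeeping_low_rate: float = 0.02

    # ChIP count model
    nb_dispersion: float = 0.2
    chip_mu0: float = 50.0
    chip_slope: float = 1.5
    chip_mu_hi: float = 120.0
    chip_mu_lo: float = 8.0

    # ageing scores
    n_age_top: int = 500
    age_overlap: float = 1.0

    def validate(self) -> None:
        rates = {
            "epiallele_rate": self.epiallele_rate,
            "temporal_stability": self.temporal_stability,
            "lowexpr_targeting": self.lowexpr_targeting,
            "genetic_rate": self.genetic_rate,
            "variable_probe_rate": self.variable_probe_rate,
            "sex_cluster_rate": self.sex_cluster_rate,
            "multi_mapped_rate": self.multi_mapped_rate,
            "snp_rate": self.snp_rate,
            "promoter_fraction": self.promoter_fraction,
            "high_expr_fraction": self.high_expr_fraction,
            "age_overlap": self.age_overlap,
        }
        for name, value in rates.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.tech_noise_sd <= 0:
            raise ValueError("tech_noise_sd must be > 0")
        if self.epiallele_delta <= 0:
            raise ValueError("epiallele_delta must be > 0")
        if self.meth_chip_coupling > 0:
            raise ValueError("meth_chip_coupling must be <= 0")
        if self.n_probes < 2 * self.cgi_cluster_size:
            raise ValueError("n_probes too small for even two probe clusters")
        if self.n_pairs < 1:
            raise ValueError("need at least one twin pair")
        lo, hi = self.epiallele_run_range
        if not (2 <= lo <= hi):
            raise ValueError("epiallele_run_range must satisfy 2 <= lo <= hi")


@dataclass
class TruthTable:
    """Ground truth for recovery tests.

    ``epialleles`` has one row per planted (probe, individual); ``genetic``
    one row per planted (probe, pair); ``variable_probes`` lists probes with
    per-individual biological deviations; ``promoters`` carries per-promoter
    expression tier, chromatin state, methylation mode and housekeeping flag.
    """

    promoters: pd.DataFrame
    epialleles: pd.DataFrame
    genetic: pd.DataFrame
    variable_probes: pd.DataFrame
    individuals: list[str]
    pairs: dict[str, list[str]]
    probe_clusters: pd.Series = None  # probe_id -> CGI cluster index

    def epiallele_probes(self, persisting_only: bool = False) -> set[str]:
        df = self.epialleles
        if persisting_only and len(df):
            df = df[df["persists_t2"]]
        return set(df["probe_id"]) if len(df) else set()

    def planted_variability_probes(self) -> set[str]:
        """Probes with any planted inter-individual variability."""
        out = self.epiallele_probes()
        if len(self.variable_probes):
            out |= set(self.variable_probes["probe_id"])
        if len(self.genetic):
            out |= set(self.genetic["probe_id"])
        return out


@dataclass
class Cohort:
    config: SimulationConfig
    manifest: list[ProbeRecord]
    sheet: SampleSheet
    matrices: dict[tuple[int, str], MethylationMatrix]
    truth: TruthTable
    sparse_probe_ids: list[str]

    def sparse_manifest(self) -> list[ProbeRecord]:
        sparse = set(self.sparse_probe_ids)
        return [r for r in self.manifest if r.probe_id in sparse]

    def matrix(self, time_point: int, platform: str) -> MethylationMatrix:
        return self.matrices[(time_point, platform)]


def _layout(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Probe grid: CGI-like clusters blocked into chromosomes."""
    size = config.cgi_cluster_size
    n_clusters = config.n_probes // size
    sizes = [size] * n_clusters
    rem = config.n_probes - n_clusters * size
    if rem >= 2:
        sizes.append(rem)
        n_clusters += 1
    n_sex = int(round(config.sex_cluster_rate * n_clusters))
    n_auto = n_clusters - n_sex
    chrom_of = []
    per_chrom = max(1, int(np.ceil(n_auto / config.n_autosomes)))
    for i in range(n_auto):
        chrom_of.append(f"chr{min(config.n_autosomes, i // per_chrom + 1)}")
    chrom_of += ["chrX"] * n_sex

    u = rng.random(n_clusters)
    multi = u < config.multi_mapped_rate
    snp = (~multi) & (u < config.multi_mapped_rate + config.snp_rate)
    feat_u = rng.random(n_clusters)
    other_feats = np.array(["regulatory", "exon", "intron", "other"])
    feat_pick = rng.integers(0, 4, n_clusters)
    features = np.where(
        feat_u < config.promoter_fraction, "promoter", other_feats[feat_pick]
    )

    rows = []
    pos_cursor: dict[str, int] = {}
    lo_sp, hi_sp = config.probe_spacing_range
    tss_counter = 0
    for ci in range(n_clusters):
        chrom = chrom_of[ci]
        start = pos_cursor.get(chrom, 10_000)
        spacings = rng.integers(lo_sp, hi_sp + 1, sizes[ci])
        positions = start + np.cumsum(spacings)
        is_promoter = features[ci] == "promoter"
        tss_id = None
        tss_pos = None
        if is_promoter:
            tss_id = f"TSS{tss_counter:05d}"
            tss_pos = int(positions[len(positions) // 2])
            tss_counter += 1
        for k, pos in enumerate(positions):
            cgi = "open_sea"
            if is_promoter:
                cgi = "shore" if k in (0, sizes[ci] - 1) else "island"
            rows.append(
                {
                    "probe_id": f"cg{ci:05d}_{k:02d}",
                    "chromosome": chrom,
                    "position": int(pos),
                    "cluster": ci,
                    "cluster_index": k,
                    "multi_mapped": bool(multi[ci]),
                    "snp_overlap": bool(snp[ci]),
                    "feature_class": str(features[ci]),
                    "cgi_relation": cgi,
                    "tss_id": tss_id,
                    "tss_pos": tss_pos,
                }
            )
        pos_cursor[chrom] = int(positions[-1]) + config.cgi_spacing_bp
    frame = pd.DataFrame(rows)
    frame.sort_values(["chromosome", "position"], inplace=True, kind="mergesort")
    frame.reset_index(drop=True, inplace=True)
    return frame


def _sample_state(rng: np.random.Generator, table) -> str:
    labels = [s for s, _ in table]
    probs = np.array([p for _, p in table])
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def _plant_runs(
    rng: np.random.Generator,
    probes: pd.DataFrame,
    clusters: Sequence[int],
    run_range: tuple[int, int],
) -> list[list[int]]:
    """For each chosen cluster, one run of consecutive probe row-indices."""
    by_cluster = probes.groupby("cluster").indices
    runs = []
    for ci in clusters:
        idx = np.sort(by_cluster[ci])
        length = int(rng.integers(run_range[0], run_range[1] + 1))
        length = min(length, len(idx))
        start = int(rng.integers(0, len(idx) - length + 1))
        runs.append(list(idx[start : start + length]))
    return runs


def _measure(
    rng: np.random.Generator, true_beta: np.ndarray, sd: float
) -> np.ndarray:
    """One noisy measurement of a true beta vector.

    Noise is applied on the logit scale with a per-probe sd calibrated so the
    realized beta-scale sd is ~``sd`` at each probe's own value (not just near
    0.5), then squashed back into (0, 1) — no truncation artefacts.
    """
    t = np.clip(true_beta, 0.02, 0.98)
    sd_logit = sd / (t * (1.0 - t))
    return expit(logit(t) + rng.standard_normal(t.shape) * sd_logit)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Build the full in-silico cohort; deterministic given the config."""
    config.validate()
    probes = _layout(config, _rng(config.seed, "layout"))
    n = len(probes)
    kept_mask = (
        ~probes["multi_mapped"]
        & ~probes["snp_overlap"]
        & (probes["chromosome"] != "chrX")
    ).to_numpy()

    # --- promoter annotation: tier, chromatin state, methylation mode, HK
    rng_base = _rng(config.seed, "baseline")
    prom = (
        probes[probes["tss_id"].notna()]
        .groupby("cluster")
        .agg(
            tss_id=("tss_id", "first"),
            chromosome=("chromosome", "first"),
            tss_pos=("tss_pos", "first"),
            flagged=("multi_mapped", "any"),
            snp=("snp_overlap", "any"),
        )
        .reset_index()
    )
    tiers, states, modes, hks = [], [], [], []
    for _ in range(len(prom)):
        high = rng_base.random() < config.high_expr_fraction
        tiers.append("high" if high else "low")
        states.append(_sample_state(rng_base, _STATES_HIGH if high else _STATES_LOW))
        p_meth = 0.05 if high else 0.7
        modes.append("methylated" if rng_base.random() < p_meth else "unmethylated")
        p_hk = config.housekeeping_high_rate if high else config.housekeeping_low_rate
        hks.append(bool(rng_base.random() < p_hk))
    prom["expression_tier"] = tiers
    prom["chromatin_state"] = states
    prom["methylation_mode"] = modes
    prom["housekeeping"] = hks
    prom["eligible"] = (
        ~prom["flagged"] & ~prom["snp"] & (prom["chromosome"] != "chrX")
    )

    # --- baseline beta per probe (bimodal, cluster-coherent mode)
    mode_lo, mode_hi = config.baseline_beta_modes
    mode_of_cluster = dict(zip(prom["cluster"], prom["methylation_mode"]))
    cluster_mode = np.empty(n)
    nonprom_meth = {}
    for i, ci in enumerate(probes["cluster"]):
        mode = mode_of_cluster.get(ci)
        if mode is None:
            if ci not in nonprom_meth:
                nonprom_meth[ci] = rng_base.random() < 0.5
            mode = "methylated" if nonprom_meth[ci] else "unmethylated"
        cluster_mode[i] = mode_hi if mode == "methylated" else mode_lo
    base = expit(
        logit(np.clip(cluster_mode, 0.02, 0.98))
        + rng_base.standard_normal(n) * config.baseline_jitter
    )
    base = np.clip(base, 0.03, 0.97)

    pairs = {f"P{p:02d}": [f"I{p:02d}a", f"I{p:02d}b"] for p in range(config.n_pairs)}
    individuals = [ind for mem in pairs.values() for ind in mem]
    ind_index = {ind: k for k, ind in enumerate(individuals)}
    pair_of_ind = {ind: pid for pid, mem in pairs.items() for ind in mem}

    # --- pair-shared (genetic-like) runs
    rng_gen = _rng(config.seed, "genetic")
    eligible_clusters = sorted(
        set(probes.loc[kept_mask, "cluster"].unique())
    )
    genetic_rows = []
    gen_shift = np.zeros((n, len(pairs)))
    n_gen = int(round(config.genetic_rate * len(eligible_clusters)))
    if n_gen and config.genetic_delta > 0:
        for pi, pid in enumerate(pairs):
            chosen = rng_gen.choice(eligible_clusters, size=n_gen, replace=False)
            for run in _plant_runs(rng_gen, probes, chosen, config.epiallele_run_range):
                for ri in run:
                    direction = 1 if base[ri] < 0.5 else -1
                    gen_shift[ri, pi] = direction * config.genetic_delta
                    genetic_rows.append(
                        {
                            "probe_id": probes["probe_id"].iloc[ri],
                            "cluster": int(probes["cluster"].iloc[ri]),
                            "pair_id": pid,
                            "direction": direction,
                            "delta": config.genetic_delta,
                        }
                    )
    genetic_df = pd.DataFrame(
        genetic_rows, columns=["probe_id", "cluster", "pair_id", "direction", "delta"]
    )

    # --- individual epialleles at promoters, low-expression targeted
    rng_epi = _rng(config.seed, "epialleles")
    elig_prom = prom[prom["eligible"]]
    low_pool = elig_prom[
        (elig_prom["expression_tier"] == "low")
        & elig_prom["chromatin_state"].str.startswith("K4lo")
    ]["cluster"].to_numpy()
    other_pool = elig_prom[~elig_prom["cluster"].isin(low_pool)]["cluster"].to_numpy()
    n_epi = int(round(config.epiallele_rate * len(elig_prom)))
    epi_rows = []
    epi_shift = np.zeros((n, len(individuals)))
    if n_epi:
        for ind in individuals:
            n_low = int(round(config.lowexpr_targeting * n_epi))
            n_other = n_epi - n_low
            if n_low > len(low_pool) or n_other > len(other_pool):
                raise ValueError(
                    "n_probes too small to host the requested epialleles: "
                    f"need {n_low} low-expression and {n_other} other promoters, "
                    f"have {len(low_pool)} and {len(other_pool)}"
                )
            chosen = np.concatenate(
                [
                    rng_epi.choice(low_pool, size=n_low, replace=False),
                    rng_epi.choice(other_pool, size=n_other, replace=False),
                ]
            ).astype(int)
            tss_of_cluster = dict(zip(prom["cluster"], prom["tss_id"]))
            ki = ind_index[ind]
            for ci, run in zip(
                chosen,
                _plant_runs(rng_epi, probes, chosen, config.epiallele_run_range),
            ):
                persists = bool(rng_epi.random() < config.temporal_stability)
                for ri in run:
                    direction = 1 if base[ri] < 0.5 else -1
                    epi_shift[ri, ki] = direction * config.epiallele_delta
                    epi_rows.append(
                        {
                            "probe_id": probes["probe_id"].iloc[ri],
                            "tss_id": tss_of_cluster[int(ci)],
                            "individual_id": ind,
                            "pair_id": pair_of_ind[ind],
                            "direction": direction,
                            "delta": config.epiallele_delta,
                            "persists_t2": persists,
                        }
                    )
    epialleles_df = pd.DataFrame(
        epi_rows,
        columns=[
            "probe_id",
            "tss_id",
            "individual_id",
            "pair_id",
            "direction",
            "delta",
            "persists_t2",
        ],
    )

    # --- variable probes: per-individual biological deviations
    rng_var = _rng(config.seed, "variable")
    planted = set(genetic_df["probe_id"]) | set(epialleles_df["probe_id"])
    free_idx = np.array(
        [
            i
            for i in range(n)
            if kept_mask[i] and probes["probe_id"].iloc[i] not in planted
        ]
    )
    n_var = int(round(config.variable_probe_rate * kept_mask.sum()))
    var_shift = np.zeros((n, len(individuals)))
    var_rows = []
    if n_var and config.biological_sd > 0 and len(free_idx):
        n_var = min(n_var, len(free_idx))
        var_idx = np.sort(rng_var.choice(free_idx, size=n_var, replace=False))
        var_shift[var_idx, :] = rng_var.normal(
            0.0, config.biological_sd, size=(n_var, len(individuals))
        )
        for ri in var_idx:
            var_rows.append(
                {
                    "probe_id": probes["probe_id"].iloc[ri],
                    "pair_difference_sd": np.sqrt(2.0) * config.biological_sd,
                }
            )
    variable_df = pd.DataFrame(
        var_rows, columns=["probe_id", "pair_difference_sd"]
    )

    # --- true beta per individual and time point
    pair_idx_of_ind = np.array(
        [list(pairs).index(pair_of_ind[ind]) for ind in individuals]
    )
    true_common = base[:, None] + gen_shift[:, pair_idx_of_ind] + var_shift
    true_t1 = np.clip(true_common + epi_shift, 0.02, 0.98)
    epi_shift_t2 = epi_shift.copy()
    if len(epialleles_df):
        row_of_probe = {p: i for i, p in enumerate(probes["probe_id"])}
        for r in epialleles_df.itertuples():
            if not r.persists_t2:
                epi_shift_t2[row_of_probe[r.probe_id], ind_index[r.individual_id]] = 0.0
    true_t2 = np.clip(true_common + epi_shift_t2, 0.02, 0.98)

    # --- manifest records
    manifest = []
    for r in probes.itertuples():
        tss_id = r.tss_id if isinstance(r.tss_id, str) else None
        manifest.append(
            ProbeRecord(
                probe_id=r.probe_id,
                chromosome=r.chromosome,
                position=int(r.position),
                multi_mapped=bool(r.multi_mapped),
                snp_overlap=bool(r.snp_overlap),
                feature_class=r.feature_class,
                cgi_relation=r.cgi_relation,
                nearest_tss_id=tss_id,
                tss_distance=(int(r.position - r.tss_pos) if tss_id else None),
            )
        )

    # --- sparse (27K-like) platform: first <=2 probes of each promoter cluster
    sparse_ids = list(
        probes[probes["tss_id"].notna() & (probes["cluster_index"] < 2)]["probe_id"]
    )

    # --- measurements
    rng_noise = _rng(config.seed, "noise")
    probe_ids = list(probes["probe_id"])
    sheet_rows = []
    dense_cols = {}
    for ki, ind in enumerate(individuals):
        for rep in range(1, config.n_tech_replicates + 1):
            sid = f"{ind}_t2_dense_r{rep}"
            dense_cols[sid] = _measure(rng_noise, true_t2[:, ki], config.tech_noise_sd)
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "individual_id": ind,
                    "pair_id": pair_of_ind[ind],
                    "replicate_id": f"r{rep}",
                    "time_point": 2,
                    "platform": "dense",
                }
            )
    dense_t2 = MethylationMatrix(pd.DataFrame(dense_cols, index=probe_ids))

    sparse_pos = probes["probe_id"].isin(set(sparse_ids)).to_numpy()
    sparse_cols = {}
    for ki, ind in enumerate(individuals):
        sid = f"{ind}_t1_sparse_r1"
        full = _measure(rng_noise, true_t1[:, ki], config.tech_noise_sd)
        sparse_cols[sid] = full[sparse_pos]
        sheet_rows.append(
            {
                "sample_id": sid,
                "individual_id": ind,
                "pair_id": pair_of_ind[ind],
                "replicate_id": "r1",
                "time_point": 1,
                "platform": "sparse",
            }
        )
    sparse_index = [p for p, keep in zip(probe_ids, sparse_pos) if keep]
    sparse_t1 = MethylationMatrix(pd.DataFrame(sparse_cols, index=sparse_index))

    truth = TruthTable(
        promoters=prom[
            [
                "cluster",
                "tss_id",
                "chromosome",
                "tss_pos",
                "expression_tier",
                "chromatin_state",
                "methylation_mode",
                "housekeeping",
                "eligible",
            ]
        ].reset_index(drop=True),
        epialleles=epialleles_df,
        genetic=genetic_df,
        variable_probes=variable_df,
        individuals=individuals,
        pairs=pairs,
        probe_clusters=pd.Series(
            probes["cluster"].to_numpy(), index=probes["probe_id"].to_numpy()
        ),
    )
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    return Cohort(
        config=config,
        manifest=manifest,
        sheet=sheet,
        matrices={(2, "dense"): dense_t2, (1, "sparse"): sparse_t1},
        truth=truth,
        sparse_probe_ids=sparse_ids,
    )


def _nb_draws(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Overdispersed counts: gamma-Poisson with var = mu + dispersion*mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    k = 1.0 / dispersion
    lam = rng.gamma(k, np.asarray(mu) / k)
    return rng.poisson(lam)


def generate_chip_counts(
    truth: TruthTable,
    matrix: MethylationMatrix,
    mark: str,
    config: SimulationConfig,
    sample_id: Optional[str] = None,
) -> CountTrack:
    """Synthesize a fragment-count track for one ChIP mark.

    H2A.Z: per-probe counts whose Spearman correlation with that sample's
    beta values approximates ``meth_chip_coupling`` (a Gaussian-copula latent
    drives a log-linear negative-binomial mean; the latent correlation is
    inflated slightly to offset count-noise attenuation).

    H3K4me3/H3K27me3: per-promoter counts driven by the truth chromatin
    state (hi -> ``chip_mu_hi``, lo -> ``chip_mu_lo``), a synthetic stand-in
    for an ES-cell reference ChIP experiment.
    """
    # deterministic sub-stream per (mark, sample) so tracks differ
    tag = f"{mark}|{sample_id or ''}"
    tag_key = zlib.crc32(tag.encode()) % (2**31)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _STREAMS["chip"], tag_key])
    )
    if mark == "H2A.Z":
        sid = sample_id or matrix.sample_ids[0]
        beta = matrix.beta(sid).to_numpy(dtype=float)
        ok = ~np.isnan(beta)
        z = np.zeros_like(beta)
        ranks = rankdata(beta[ok])
        z[ok] = norm.ppf((ranks - 0.5) / ok.sum())
        rho = config.meth_chip_coupling
        # bivariate-normal Spearman: rho_s = (6/pi) asin(r/2); inflate for
        # the attenuation from NB count noise around the log-linear mean
        r_latent = 2.0 * np.sin(np.pi * rho / 6.0)
        atten = 0.96 * config.chip_slope / np.sqrt(
            config.chip_slope**2 + config.nb_dispersion + 1.0 / config.chip_mu0
        )
        r_latent = float(np.clip(r_latent / atten, -0.99, 0.99))
        # latent noise shared within a CGI cluster so promoter averaging does
        # not sharpen the correlation beyond the configured coupling
        if truth.probe_clusters is not None:
            clusters = truth.probe_clusters.reindex(matrix.probe_ids).to_numpy()
            uniq, inv = np.unique(clusters, return_inverse=True)
            eps = rng.standard_normal(len(uniq))[inv]
        else:
            eps = rng.standard_normal(len(z))
        g = r_latent * z + np.sqrt(1.0 - r_latent**2) * eps
        mu = config.chip_mu0 * np.exp(config.chip_slope * (g - g.mean()))
        counts = _nb_draws(rng, mu, config.nb_dispersion)
        region_ids = np.array(matrix.probe_ids, dtype=object)
        out_sample = sid
    elif mark in ("H3K4me3", "H3K27me3"):
        prom = truth.promoters
        key = "K4hi" if mark == "H3K4me3" else "K27hi"
        is_hi = (
            prom["chromatin_state"].str.contains(key).to_numpy()
            if key == "K27hi"
            else prom["chromatin_state"].str.startswith("K4hi").to_numpy()
        )
        mu = np.where(is_hi, config.chip_mu_hi, config.chip_mu_lo)
        counts = _nb_draws(rng, mu.astype(float), config.nb_dispersion)
        region_ids = prom["tss_id"].to_numpy(dtype=object)
        out_sample = sample_id or "ESC_ref"
    else:
        raise ValueError(f"unknown ChIP mark {mark!r}")
    total = int(counts.sum())
    norm_scores = counts * (1e7 / total) if total > 0 else counts.astype(float)
    return CountTrack(
        region_ids=region_ids,
        raw_counts=counts.astype(np.int64),
        mark=mark,
        sample_id=out_sample,
        norm_scores=norm_scores,
        library_total=total,
    )


def generate_expression(truth: TruthTable, config: SimulationConfig) -> ExpressionTable:
    """FPKM per promoter per individual.

    Low-tier promoters get FPKM < 1 and high-tier >= 1 (log-normal within
    tier around the configured tier means); individuals carrying a
    persisting methylation-gain epiallele at a promoter have that gene's
    FPKM depressed by exp(-effect * delta), within the tier's range.
    """
    rng = _rng(config.seed, "expression")
    prom = truth.promoters
    sd = config.expr_log_sd
    means = np.where(
        prom["expression_tier"] == "high", config.expr_high_mean, config.expr_low_mean
    )
    mu_log = np.log(means) - sd**2 / 2.0
    base = np.exp(rng.normal(mu_log, sd))
    low = (prom["expression_tier"] == "low").to_numpy()
    base = np.where(low, np.clip(base, 1e-4, 0.999), np.clip(base, 1.0, None))

    depress = {}
    if len(truth.epialleles):
        persisting = truth.epialleles[truth.epialleles["persists_t2"]]
        for r in persisting.itertuples():
            key = (r.tss_id, r.individual_id)
            depress[key] = np.exp(-config.expr_epiallele_effect * r.direction * r.delta)

    cols = {}
    tss_ids = prom["tss_id"].to_numpy()
    for ind in truth.individuals:
        mult = np.exp(rng.normal(0.0, config.expr_ind_sd, len(prom)))
        fpkm = base * mult
        for j, tss in enumerate(tss_ids):
            factor = depress.get((tss, ind))
            if factor is not None:
                fpkm[j] *= factor
        fpkm = np.where(low, np.clip(fpkm, 1e-4, 0.999), np.clip(fpkm, 1.0, None))
        cols[ind] = fpkm
    return ExpressionTable(pd.DataFrame(cols, index=tss_ids))


def generate_age_correlations(
    truth: TruthTable,
    manifest: Sequence[ProbeRecord],
    config: SimulationConfig,
) -> tuple[pd.Series, list[str]]:
    """Per-probe methylation-ageing correlation scores.

    Returns (scores, designated): a designated top set of ``n_age_top``
    probes receives high scores (drawn U(0.6, 0.95)); the rest are near 0.
    A fraction ``age_overlap`` of the designated set is drawn from the
    planted-variability probes, the remainder from unplanted probes.
    """
    rng = _rng(config.seed, "age")
    all_ids = [r.probe_id for r in manifest]
    pool = sorted(truth.planted_variability_probes() & set(all_ids))
    rest = sorted(set(all_ids) - set(pool))
    n_top = config.n_age_top
    if n_top > len(all_ids):
        raise ValueError("n_age_top exceeds the number of probes")
    n_from_pool = min(int(round(config.age_overlap * n_top)), len(pool))
    designated = list(rng.choice(pool, size=n_from_pool, replace=False)) + list(
        rng.choice(rest, size=n_top - n_from_pool, replace=False)
    )
    scores = pd.Series(
        rng.normal(0.0, 0.05, len(all_ids)), index=all_ids, name="age_correlation"
    )
    scores.loc[designated] = rng.uniform(0.6, 0.95, len(designated))
    return scores, sorted(designated)


def truth_to_frames(truth: TruthTable) -> dict[str, pd.DataFrame]:
    """Truth table as flat frames for TSV export."""
    return {
        "promoters": truth.promoters,
        "epialleles": truth.epialleles,
        "genetic": truth.genetic,
        "variable_probes": truth.variable_probes,
    }
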