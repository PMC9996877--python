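"""Synthetic inputs with the statistical structure the analysis assumes.

The cohort generator emulates a tumor/normal expression study on two
circadian gene classes: on the log2 scale, core-clock genes shift up and
clock-control genes shift down in tumors, a latent per-sample score
(control minus core mean expression, standardized) drives exponential
proportional-hazards survival with independent uniform censoring.  Further
generators emulate gene-knockout cohorts, 24-h time courses under circadian
deregulation, SNV/CNV tables with tunable CNV-expression coupling,
compound ranking libraries with planted mimic/revert signals, and
Dirichlet immune-cell fraction matrices optionally linked to a score.

Randomness: one master seed spawns one fixed substream per draw site
(``numpy.random.SeedSequence.spawn``), so adding a stream never perturbs
the others, and identical params + seed give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import (
    ClinicalTable,
    CNVMatrix,
    ExpressionMatrix,
    FractionMatrix,
    MutationTable,
    SignatureLibrary,
    VARIANT_CLASSES,
)

__all__ = [
    "CohortParams",
    "KnockoutParams",
    "TimecourseParams",
    "CohortData",
    "simulate_cohort",
    "simulate_knockout",
    "simulate_timecourse",
    "simulate_genomics",
    "simulate_compound_library",
    "simulate_fractions",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CohortParams:
    """Parameters of one synthetic tumor/normal cohort.

    Expression is simulated on the log2(x+1) scale with gene baselines
    mu_g ~ N(7, 1).  Defaults give the canonical study condition: 13
    clock-control genes shifted -1 log2 unit and 35 core-clock genes +1
    log2 unit in tumors, and a log-hazard of 0.8 per unit of the latent
    standardized score.
    """

    n_genes_background: int = 1000
    control_set_size: int = 13
    core_set_size: int = 35
    n_tumor: int = 200
    n_normal: int = 50
    effect_core_log2: float = 1.0
    effect_control_log2: float = -1.0
    noise_sd_log2: float = 0.5
    hazard_beta: float = 0.8
    baseline_hazard: float = 1.0 / 500.0  # per day; median OS ~ 1 year
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.control_set_size < 1 or self.core_set_size < 1:
            raise SimulationError("gene set sizes must be >= 1")
        if self.n_tumor < 2 or self.n_normal < 2:
            raise SimulationError("need n_tumor >= 2 and n_normal >= 2")
        if not 0 <= self.censor_rate < 1:
            raise SimulationError("censor_rate must be in [0, 1)")
        if self.noise_sd_log2 <= 0 or self.baseline_hazard <= 0:
            raise SimulationError("noise_sd_log2 and baseline_hazard must be > 0")


@dataclass(frozen=True)
class KnockoutParams:
    """Knockout cohort: target genes retain ``knockdown_factor`` of their
    linear expression in KO samples (0 = complete knockout)."""

    target_genes: tuple[str, ...]
    n_ko: int = 10
    n_ctrl: int = 10
    knockdown_factor: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.knockdown_factor <= 1:
            raise SimulationError("knockdown_factor must be in [0, 1]")
        if self.n_ko < 2 or self.n_ctrl < 2:
            raise SimulationError("need >= 2 samples per arm")


@dataclass(frozen=True)
class TimecourseParams:
    """Time course: circadian genes oscillate as A*sin(2*pi*t/period + phi_g)
    with group amplitude A (normal vs circadian-deregulated), shared per-gene
    phases, non-rhythmic background."""

    timepoints_h: tuple[float, ...] = (0, 4, 8, 12, 16, 20)
    period_h: float = 24.0
    amplitude_normal: float = 1.0
    amplitude_cdt: float = 0.25
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.amplitude_cdt > self.amplitude_normal:
            raise SimulationError("amplitude_cdt must be <= amplitude_normal")
        if self.period_h <= 0:
            raise SimulationError("period must be positive")


@dataclass
class CohortData:
    expr: ExpressionMatrix  # log2 units, genes x samples
    clinical: ClinicalTable  # tumor samples only
    control_genes: tuple[str, ...]
    core_genes: tuple[str, ...]
    tissue: dict[str, str]  # sample -> tumor/normal
    true_score: pd.Series  # latent standardized score per sample


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _gene_names(params: CohortParams):
    ctrl = tuple(f"CTRL{i:03d}" for i in range(1, params.control_set_size + 1))
    core = tuple(f"CORE{i:03d}" for i in range(1, params.core_set_size + 1))
    bg = tuple(f"BG{i:05d}" for i in range(1, params.n_genes_background + 1))
    return ctrl, core, bg


def _baselines(params: CohortParams, rng) -> np.ndarray:
    n = (
        params.control_set_size
        + params.core_set_size
        + params.n_genes_background
    )
    return rng.normal(7.0, 1.0, size=n)


def _censoring_horizon(rates: np.ndarray, censor_rate: float) -> float:
    """Uniform(0, tau) censoring horizon giving the requested expected
    censoring fraction for exponential event times with the given rates."""

    def frac_censored(tau):
        lt = rates * tau
        return float(np.mean((1.0 - np.exp(-lt)) / lt)) - censor_rate

    # frac_censored decreases from ~1 (tau -> 0) to 0 (tau -> inf)
    lo, hi = 1e-9, 1e12
    return brentq(frac_censored, lo, hi, xtol=1e-9, rtol=1e-12)


def simulate_cohort(params: CohortParams) -> CohortData:
    """Generate expression, survival and the latent score for one cohort."""
    rng_mu, rng_expr, rng_surv, rng_cens = _streams(params.seed, 4)
    ctrl, core, bg = _gene_names(params)
    genes = list(ctrl) + list(core) + list(bg)
    mu = _baselines(params, rng_mu)
    n = params.n_tumor + params.n_normal
    samples = [f"T{i:04d}" for i in range(1, params.n_tumor + 1)] + [
        f"N{i:04d}" for i in range(1, params.n_normal + 1)
    ]
    tissue = {
        s: ("tumor" if s.startswith("T") else "normal") for s in samples
    }
    vals = mu[:, None] + rng_expr.normal(0.0, params.noise_sd_log2, size=(len(genes), n))
    is_tumor = np.array([tissue[s] == "tumor" for s in samples])
    n_ctrl, n_core = len(ctrl), len(core)
    vals[:n_ctrl, is_tumor] += params.effect_control_log2
    vals[n_ctrl : n_ctrl + n_core, is_tumor] += params.effect_core_log2
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=genes, columns=samples), unit="log2"
    )
    raw_score = vals[:n_ctrl].mean(axis=0) - vals[n_ctrl : n_ctrl + n_core].mean(axis=0)
    tum_scores = raw_score[is_tumor]
    sd = tum_scores.std(ddof=0)
    if sd == 0:
        sd = 1.0
    true_score = (raw_score - tum_scores.mean()) / sd
    score_s = pd.Series(true_score, index=samples, name="true_score")
    # survival for tumor samples: exponential PH on the latent score
    z = true_score[is_tumor]
    rates = params.baseline_hazard * np.exp(params.hazard_beta * z)
    t_event = rng_surv.exponential(1.0 / rates)
    if params.censor_rate > 0:
        tau = _censoring_horizon(rates, params.censor_rate)
        c = rng_cens.uniform(0.0, tau, size=len(rates))
        obs = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        obs, event = t_event, np.ones(len(rates), dtype=int)
    obs = np.maximum(obs, 1e-6)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": np.asarray(samples)[is_tumor],
                "os_time_days": obs,
                "os_event": event,
            }
        )
    )
    return CohortData(expr, clinical, ctrl, core, tissue, score_s)


def simulate_knockout(
    params: KnockoutParams, base: CohortParams
) -> tuple[ExpressionMatrix, pd.Series]:
    """Knockout vs control expression (no tumor shifts; normal-like samples).

    Target genes are multiplied by ``knockdown_factor`` on the linear
    (2^x - 1) scale in KO samples; everything else matches the control arm.
    Returns the matrix and a sample -> {"ko", "ctrl"} label Series.
    """
    rng_mu, rng_expr = _streams(params.seed, 2)
    ctrl, core, bg = _gene_names(base)
    genes = list(ctrl) + list(core) + list(bg)
    missing = set(params.target_genes) - set(genes)
    if missing:
        raise SimulationError(f"target genes not in cohort universe: {sorted(missing)}")
    mu = _baselines(base, rng_mu)
    n = params.n_ko + params.n_ctrl
    samples = [f"KO{i:03d}" for i in range(1, params.n_ko + 1)] + [
        f"CT{i:03d}" for i in range(1, params.n_ctrl + 1)
    ]
    vals = mu[:, None] + rng_expr.normal(0.0, base.noise_sd_log2, size=(len(genes), n))
    is_ko = np.array([s.startswith("KO") for s in samples])
    target_idx = [genes.index(g) for g in params.target_genes]
    for gi in target_idx:
        linear = np.exp2(vals[gi, is_ko]) - 1.0
        vals[gi, is_ko] = np.log2(params.knockdown_factor * linear + 1.0)
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=genes, columns=samples), unit="log2"
    )
    labels = pd.Series(
        np.where(is_ko, "ko", "ctrl"), index=samples, name="group"
    )
    return expr, labels


def simulate_timecourse(
    params: TimecourseParams, base: CohortParams
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Two-group (normal vs CDT) circadian time course.

    Returns the matrix and an annotation DataFrame (sample_id, group,
    timepoint_h).  Per-gene phases are drawn once and shared between groups,
    so the only group difference is the oscillation amplitude.
    """
    rng_mu, rng_phase, rng_expr = _streams(params.seed, 3)
    ctrl, core, bg = _gene_names(base)
    genes = list(ctrl) + list(core) + list(bg)
    mu = _baselines(base, rng_mu)
    n_crg = len(ctrl) + len(core)
    # clock transcription is phase-organized by class: core-clock genes
    # oscillate roughly together and control-loop output genes in antiphase;
    # per-gene jitter keeps genes from being exact copies
    phases = np.concatenate(
        [
            rng_phase.normal(0.0, 0.4, size=len(ctrl)),
            rng_phase.normal(np.pi, 0.4, size=len(core)),
        ]
    )
    rows = []
    cols = []
    ann = []
    for group, amp in (("normal", params.amplitude_normal), ("cdt", params.amplitude_cdt)):
        for t in params.timepoints_h:
            for rep in range(1, params.n_replicates + 1):
                sample = f"{group}_t{t:g}_r{rep}"
                v = mu + rng_expr.normal(0.0, base.noise_sd_log2, size=len(genes))
                osc = amp * np.sin(2 * np.pi * t / params.period_h + phases)
                v[:n_crg] += osc
                rows.append(v)
                cols.append(sample)
                ann.append((sample, group, float(t)))
    vals = np.column_stack(rows)
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=genes, columns=cols), unit="log2"
    )
    annotation = pd.DataFrame(ann, columns=["sample_id", "group", "timepoint_h"])
    return expr, annotation


def simulate_genomics(
    n_genes: int = 48,
    n_samples: int = 200,
    per_gene_mut_rate: float = 0.01,
    cnv_event_rate: float = 0.1,
    coupling: float = 1.0,
    seed: int = 0,
) -> tuple[MutationTable, CNVMatrix, ExpressionMatrix]:
    """Mutations, focal copy-number scores and coupled expression.

    Mutations are Bernoulli per gene x sample with a random variant class
    (missense-heavy mix).  Focal scores are near-zero noise, except a
    ``cnv_event_rate`` fraction of entries drawn beyond |0.3| with random
    sign.  Expression is baseline log2 noise shifted by
    ``coupling * categorized CNV``.
    """
    rng_mut, rng_class, rng_cnv, rng_expr, rng_mu = _streams(seed, 5)
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    samples = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    # mutations
    hits = rng_mut.random((n_genes, n_samples)) < per_gene_mut_rate
    class_p = np.array([0.55, 0.08, 0.0, 0.08, 0.1, 0.09, 0.05, 0.05])
    rows = []
    for gi, si in zip(*np.nonzero(hits)):
        cls = rng_class.choice(VARIANT_CLASSES, p=class_p / class_p.sum())
        rows.append((samples[si], genes[gi], str(cls), "synthetic"))
    mut = MutationTable(
        pd.DataFrame(rows, columns=["sample_id", "gene_id", "variant_class", "cohort"])
        if rows
        else pd.DataFrame(columns=["sample_id", "gene_id", "variant_class", "cohort"]),
        cohort_sizes={"synthetic": n_samples},
    )
    # focal CNV scores
    focal = rng_cnv.uniform(-0.25, 0.25, size=(n_genes, n_samples))
    events = rng_cnv.random((n_genes, n_samples)) < cnv_event_rate
    signs = rng_cnv.choice([-1.0, 1.0], size=(n_genes, n_samples))
    magnitudes = rng_cnv.uniform(0.35, 1.2, size=(n_genes, n_samples))
    focal[events] = (signs * magnitudes)[events]
    cnv = CNVMatrix(pd.DataFrame(focal, index=genes, columns=samples))
    # expression coupled to the categorized CNV
    category = np.zeros_like(focal)
    category[focal > 0.3] = 1.0
    category[focal < -0.3] = -1.0
    mu = rng_mu.normal(7.0, 1.0, size=n_genes)
    vals = (
        mu[:, None]
        + rng_expr.normal(0.0, 0.5, size=(n_genes, n_samples))
        + coupling * category
    )
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=genes, columns=samples), unit="log2"
    )
    return mut, cnv, expr


def simulate_compound_library(
    n_compounds: int,
    universe: list[str],
    planted: list[tuple[str, str]] = (),
    up_genes: list[str] = (),
    down_genes: list[str] = (),
    seed: int = 0,
) -> SignatureLibrary:
    """Compound ranking library with optional planted signals.

    ``planted`` lists (compound_id, "mimic"|"revert") entries relative to the
    query (``up_genes``, ``down_genes``): a mimic ranks the query's up-genes
    at the very top and down-genes at the very bottom, a revert the
    opposite; all other compounds are uniform random permutations.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    universe = list(universe)
    uset = set(universe)
    for g in list(up_genes) + list(down_genes):
        if g not in uset:
            raise SimulationError(f"query gene {g!r} not in universe")
    planted = list(planted)
    planted_ids = {c for c, _ in planted}
    rankings: dict[str, list[str]] = {}
    middle_pool = [g for g in universe if g not in set(up_genes) | set(down_genes)]
    for cid, mode in planted:
        mid = list(middle_pool)
        rng.shuffle(mid)
        if mode == "mimic":
            rankings[cid] = list(up_genes) + mid + list(down_genes)
        elif mode == "revert":
            rankings[cid] = list(down_genes) + mid + list(up_genes)
        else:
            raise SimulationError(f"unknown planted mode {mode!r}")
    i = 0
    while len(rankings) < n_compounds:
        cid = f"CP{i:05d}"
        i += 1
        if cid in planted_ids:
            continue
        perm = list(universe)
        rng.shuffle(perm)
        rankings[cid] = perm
    return SignatureLibrary(rankings)


def simulate_fractions(
    n_samples: int,
    n_celltypes: int = 22,
    crs_link=None,
    score=None,
    base_concentration: float = 5.0,
    seed: int = 0,
) -> tuple[FractionMatrix, pd.Series]:
    """Dirichlet cell-type fraction columns linked to a per-sample score.

    Concentration for cell type c in sample s is
    ``base_concentration * exp(crs_link[c] * score[s])``; a zero link vector
    gives exchangeable Dirichlet columns.  Returns the matrix and the score
    used (drawn N(0,1) when not supplied).
    """
    rng_score, rng_frac = _streams(seed, 2)
    celltypes = [f"cell_type_{i:02d}" for i in range(1, n_celltypes + 1)]
    samples = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    if score is None:
        score = pd.Series(rng_score.normal(size=n_samples), index=samples)
    else:
        score = pd.Series(np.asarray(score, dtype=float), index=samples)
    link = np.zeros(n_celltypes) if crs_link is None else np.asarray(crs_link, float)
    if len(link) != n_celltypes:
        raise SimulationError("crs_link length must equal n_celltypes")
    cols = np.empty((n_celltypes, n_samples))
    for j, s in enumerate(samples):
        conc = base_concentration * np.exp(link * score[s])
        cols[:, j] = rng_frac.dirichlet(conc)
    frac = FractionMatrix(pd.DataFrame(cols, index=celltypes, columns=samples))
    return frac, score.rename("score")
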