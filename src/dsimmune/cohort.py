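"""Seeded synthetic cohorts with the statistical structure the analyses assume.

The real study data (bead-array reactivities, multiplex cytokine panels,
whole-blood transcriptomes, mass-cytometry cluster frequencies, trial time
courses) are access controlled, so every downstream stage in this package
is exercised against synthetic cohorts generated here. The generators
emulate structure, not biology: trisomy-21 (T21) effects enter as log2
shifts on markers, fold-changes on interferon-stimulated genes (ISGs),
positivity-odds multipliers on autoantigens and logit shifts on cell
cluster proportions, on top of age trends, sex terms, and source/batch
offsets. All randomness flows from explicit integer seeds; identical
spec + seed gives bit-identical outputs.

The generative models are deliberately the simplest ones consistent with
each analysis's assumptions: Gaussian noise on the log2 scale for
concentrations and expression, beta draws for proportions, Bernoulli
reactivity spikes for autoantigen positivity. Effect sizes are
configurable stand-ins, not estimates of the study's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .autoantibody import AntigenReactivityMatrix
from .ifn import ExpressionMatrix
from .markers import CYTOKINE_SCORE_COMPONENTS, WELL_COLUMNS, MarkerPanel

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "simulate_participants",
    "simulate_marker_panel",
    "simulate_autoantigen_mfi",
    "simulate_isg_expression",
    "simulate_cluster_frequencies",
    "simulate_trial_timecourse",
    "default_gene_annotation",
    "default_marker_names",
]

VISITS = ("B", "W2", "W8", "W16")


@dataclass(frozen=True)
class CohortSpec:
    """Sizes and demographics of a synthetic case-control cohort.

    Defaults follow the shape of a large DS cohort study: cases outnumber
    controls roughly 2:1, ages span infancy to late adulthood, and samples
    come from a handful of collection sites.
    """

    n_t21: int = 300
    n_d21: int = 150
    age_range: tuple[float, float] = (0.5, 57.0)
    sex_ratio: float = 0.5
    n_sources: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_t21 <= 0 or self.n_d21 <= 0 or self.n_sources <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must satisfy low < high")


@dataclass(frozen=True)
class EffectSpec:
    """Injected effect sizes for the generators (all default to null).

    elevated_analytes: analyte -> log2 shift in T21.
    age_slopes: analyte -> per-year log2 slope.
    batch_sd: SD (log2 units) of per-source-per-feature offsets.
    isg_fold_changes: gene -> linear fold-change in T21.
    enriched_antigens: antigen -> positivity-odds multiplier in T21.
    cluster_logit_shifts: cluster -> logit shift of the mean proportion in T21.
    treatment_effect: multiplicative change of treated-visit values (1 = none).
    """

    elevated_analytes: dict = field(default_factory=dict)
    age_slopes: dict = field(default_factory=dict)
    batch_sd: float = 0.25
    isg_fold_changes: dict = field(default_factory=dict)
    enriched_antigens: dict = field(default_factory=dict)
    cluster_logit_shifts: dict = field(default_factory=dict)
    treatment_effect: float = 1.0

    def __post_init__(self) -> None:
        if any(fc <= 0 for fc in self.isg_fold_changes.values()):
            raise ValueError("fold-changes must be positive")
        if any(m <= 0 for m in self.enriched_antigens.values()):
            raise ValueError("odds multipliers must be positive")
        if self.treatment_effect <= 0:
            raise ValueError("treatment_effect must be positive")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be non-negative")


def simulate_participants(spec: CohortSpec) -> pd.DataFrame:
    """Participant table: karyotype, age, sex, source; seeded and exact."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_t21 + spec.n_d21
    ids = [f"P{i + 1:04d}" for i in range(n)]
    karyotype = ["T21"] * spec.n_t21 + ["D21"] * spec.n_d21
    age = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    sex = np.where(rng.random(n) < spec.sex_ratio, "Female", "Male")
    source = rng.choice([f"Site{i + 1}" for i in range(spec.n_sources)], size=n)
    return pd.DataFrame(
        {"karyotype": karyotype, "age": age, "sex": sex, "source": source},
        index=pd.Index(ids, name="participant_id"),
    )


def default_marker_names(n_analytes: int) -> list[str]:
    """Analyte names; the four cytokine-score components come first."""
    if n_analytes < 1:
        raise ValueError("n_analytes must be >= 1")
    base = list(CYTOKINE_SCORE_COMPONENTS)[:n_analytes]
    extra = [f"MK{i + 1:02d}" for i in range(max(0, n_analytes - len(base)))]
    return base + extra


def simulate_marker_panel(
    participants: pd.DataFrame,
    effects: EffectSpec,
    n_analytes: int = 54,
    seed: int = 0,
    noise_sd: float = 0.5,
    out_of_range_frac: float = 0.02,
    n_duplicates: int = 2,
    plate_size: int = 40,
    baseline_log2_range: tuple[float, float] = (2.0, 10.0),
) -> MarkerPanel:
    """Multiplex marker panel with duplicate wells, plates and range flags.

    log2 concentration = analyte baseline + delta*[T21] + slope*age +
    source offset + Gaussian noise, exponentiated to pg/mL. A fraction
    ``out_of_range_frac`` of wells is flagged below/above the fit-curve
    range and reported with a missing concentration (the preprocessing
    stage imputes them from in-range plate values).
    """
    if len(participants) == 0:
        raise ValueError("participants table is empty")
    names = default_marker_names(n_analytes)
    for d in (effects.elevated_analytes, effects.age_slopes):
        unknown = set(d) - set(names)
        if unknown:
            raise ValueError(f"unknown analytes in effects: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    baselines = rng.uniform(*baseline_log2_range, size=n_analytes)
    sources = sorted(participants["source"].unique())
    src_offsets = {
        (s, a): rng.normal(0.0, effects.batch_sd)
        for s in sources
        for a in names
    }
    is_t21 = (participants["karyotype"] == "T21").values
    ages = participants["age"].values
    plate_of = {
        sid: f"plate{(i // plate_size) + 1}"
        for i, sid in enumerate(participants.index)
    }

    rows = []
    for j, analyte in enumerate(names):
        delta = effects.elevated_analytes.get(analyte, 0.0)
        slope = effects.age_slopes.get(analyte, 0.0)
        mean_log2 = (
            baselines[j]
            + delta * is_t21
            + slope * ages
            + np.array([src_offsets[(s, analyte)] for s in participants["source"]])
        )
        for w in range(n_duplicates):
            vals = mean_log2 + rng.normal(0.0, noise_sd, size=len(participants))
            u = rng.random(len(participants))
            below = u < out_of_range_frac / 2
            above = (u >= out_of_range_frac / 2) & (u < out_of_range_frac)
            conc = np.power(2.0, vals)
            conc[below | above] = np.nan
            status = np.where(
                below, "below_range", np.where(above, "above_range", "in_range")
            )
            for i, sid in enumerate(participants.index):
                rows.append(
                    (
                        sid,
                        analyte,
                        plate_of[sid],
                        f"{sid}_{analyte}_w{w + 1}",
                        conc[i],
                        status[i],
                    )
                )
    wells = pd.DataFrame(rows, columns=WELL_COLUMNS)
    return MarkerPanel(wells=wells)


def simulate_autoantigen_mfi(
    participants: pd.DataFrame,
    effects: EffectSpec,
    n_antigens: int = 380,
    seed: int = 0,
    base_positivity: float = 0.10,
    spike_log2: float = 3.0,
    noise_sd: float = 0.3,
    sample_bg_sd: float = 0.5,
    bead_mean: float = 50.0,
    low_bead_frac: float = 0.0,
) -> AntigenReactivityMatrix:
    """Bead-array MFI matrix with sample backgrounds and reactivity spikes.

    MFI = per-sample multiplicative background x per-antigen lognormal
    baseline x lognormal noise, with a 2**spike_log2 reactivity spike for
    positive reactions. Baseline positivity probability is
    ``base_positivity`` for everyone; for antigens listed in
    ``effects.enriched_antigens`` the positivity odds of T21 samples are
    multiplied by the stated factor.
    """
    if len(participants) == 0:
        raise ValueError("participants table is empty")
    if n_antigens < 2:
        raise ValueError("n_antigens must be >= 2")
    antigens = [f"AG{i + 1:03d}" for i in range(n_antigens)]
    unknown = set(effects.enriched_antigens) - set(antigens)
    if unknown:
        raise ValueError(f"unknown antigens in effects: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n = len(participants)
    is_t21 = (participants["karyotype"] == "T21").values
    sample_bg = rng.normal(0.0, sample_bg_sd, size=n)
    antigen_base = rng.uniform(6.0, 10.0, size=n_antigens)
    base_odds = base_positivity / (1.0 - base_positivity)

    log2_mfi = np.empty((n_antigens, n))
    for i, antigen in enumerate(antigens):
        mult = effects.enriched_antigens.get(antigen, 1.0)
        odds = np.where(is_t21, base_odds * mult, base_odds)
        p = odds / (1.0 + odds)
        spike = rng.random(n) < p
        log2_mfi[i] = (
            antigen_base[i]
            + sample_bg
            + rng.normal(0.0, noise_sd, size=n)
            + spike_log2 * spike
        )
    mfi = pd.DataFrame(
        np.power(2.0, log2_mfi),
        index=pd.Index(antigens, name="antigen"),
        columns=participants.index,
    )
    beads = rng.poisson(bead_mean, size=(n_antigens, n)).astype(float)
    if low_bead_frac > 0:
        low = rng.random((n_antigens, n)) < low_bead_frac
        beads[low] = rng.poisson(5.0, size=int(low.sum()))
    bead_counts = pd.DataFrame(beads, index=mfi.index, columns=mfi.columns)
    meta = pd.Series(
        [f"PROT{(i % max(1, n_antigens // 2)) + 1:03d}" for i in range(n_antigens)],
        index=mfi.index,
        name="protein",
    )
    return AntigenReactivityMatrix(mfi=mfi, bead_counts=bead_counts, antigen_meta=meta)


def default_gene_annotation(
    n_genes: int = 200,
    n_isgs: int = 16,
    n_chr21: int = 10,
) -> pd.DataFrame:
    """Gene annotation with ISG-like names and chromosome labels.

    The first ``n_isgs`` genes are named ISG01.. and placed off chr21; the
    next ``n_chr21`` are chr21 genes (selectable for exclusion downstream);
    the remainder cycle through the autosomes.
    """
    if n_genes < n_isgs + n_chr21:
        raise ValueError("n_genes too small for requested ISG/chr21 counts")
    genes, chroms = [], []
    for i in range(n_isgs):
        genes.append(f"ISG{i + 1:02d}")
        chroms.append(f"chr{(i % 20) + 1}")
    for i in range(n_chr21):
        genes.append(f"C21G{i + 1:02d}")
        chroms.append("chr21")
    for i in range(n_genes - n_isgs - n_chr21):
        genes.append(f"G{i + 1:04d}")
        chroms.append(f"chr{(i % 20) + 1}")
    return pd.DataFrame(
        {"chromosome": chroms}, index=pd.Index(genes, name="gene")
    )


def simulate_isg_expression(
    participants: pd.DataFrame,
    effects: EffectSpec,
    gene_annotation: pd.DataFrame | None = None,
    seed: int = 0,
    noise_sd: float = 0.5,
    age_slope_sd: float = 0.002,
    sex_effect_sd: float = 0.05,
    baseline_log2_range: tuple[float, float] = (1.0, 8.0),
) -> ExpressionMatrix:
    """FPKM-like expression with ISG fold-changes in T21 plus nuisance terms.

    Genes listed in ``effects.isg_fold_changes`` are multiplied by their
    fold-change in T21 samples; every gene gets a small random age slope,
    sex offset and per-source batch offset.
    """
    if len(participants) == 0:
        raise ValueError("participants table is empty")
    if gene_annotation is None:
        gene_annotation = default_gene_annotation()
    if len(gene_annotation) == 0:
        raise ValueError("gene annotation is empty")
    unknown = set(effects.isg_fold_changes) - set(gene_annotation.index)
    if unknown:
        raise ValueError(f"genes in effects missing from annotation: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    genes = list(gene_annotation.index)
    n_genes, n = len(genes), len(participants)
    is_t21 = (participants["karyotype"] == "T21").values
    ages = participants["age"].values
    is_female = (participants["sex"] == "Female").values
    sources = sorted(participants["source"].unique())
    src_idx = participants["source"].map({s: i for i, s in enumerate(sources)}).values

    baselines = rng.uniform(*baseline_log2_range, size=n_genes)
    age_slopes = rng.normal(0.0, age_slope_sd, size=n_genes)
    sex_effects = rng.normal(0.0, sex_effect_sd, size=n_genes)
    batch = rng.normal(0.0, effects.batch_sd, size=(n_genes, len(sources)))

    log2e = (
        baselines[:, None]
        + age_slopes[:, None] * ages[None, :]
        + sex_effects[:, None] * is_female[None, :]
        + batch[:, src_idx]
        + rng.normal(0.0, noise_sd, size=(n_genes, n))
    )
    for g, fc in effects.isg_fold_changes.items():
        i = genes.index(g)
        log2e[i] += np.log2(fc) * is_t21
    values = pd.DataFrame(
        np.power(2.0, log2e),
        index=pd.Index(genes, name="gene"),
        columns=participants.index,
    )
    return ExpressionMatrix(values=values, gene_annotation=gene_annotation)


def true_de_table(
    effects: EffectSpec,
    gene_annotation: pd.DataFrame,
    null_q: float = 0.5,
    shifted_q: float = 1e-4,
) -> pd.DataFrame:
    """Differential-expression result table consistent with the generator.

    Stands in for the upstream (out-of-scope) DE analysis: genes with an
    injected fold-change get that fold-change and a small q-value, the rest
    fold-change 1 and a null q-value. Used to exercise the ISG selection
    rule, which consumes a DE table as an input contract.
    """
    fc = pd.Series(1.0, index=gene_annotation.index)
    q = pd.Series(null_q, index=gene_annotation.index)
    for g, f in effects.isg_fold_changes.items():
        fc.loc[g] = f
        q.loc[g] = shifted_q
    return pd.DataFrame(
        {
            "fold_change": fc,
            "q_value": q,
            "chromosome": gene_annotation["chromosome"],
        }
    )


def simulate_cluster_frequencies(
    participants: pd.DataFrame,
    effects: EffectSpec,
    n_clusters: int = 30,
    seed: int = 0,
    precision: float = 50.0,
    base_logit_range: tuple[float, float] = (-4.0, -1.0),
    age_coef_sd: float = 0.005,
    sex_coef_sd: float = 0.05,
) -> pd.DataFrame:
    """Cluster x sample proportions from beta draws with logit-scale effects.

    Per cluster, the mean proportion is expit(base + shift*[T21] +
    age and sex terms); draws are Beta(mu*phi, (1-mu)*phi). Rows need not
    sum to 1 — clusters are modelled marginally downstream.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    clusters = [f"CL{i + 1:02d}" for i in range(n_clusters)]
    unknown = set(effects.cluster_logit_shifts) - set(clusters)
    if unknown:
        raise ValueError(f"unknown clusters in effects: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n = len(participants)
    is_t21 = (participants["karyotype"] == "T21").values
    age_c = participants["age"].values - participants["age"].values.mean()
    is_female = (participants["sex"] == "Female").values

    rows = {}
    for cluster in clusters:
        base = rng.uniform(*base_logit_range)
        shift = effects.cluster_logit_shifts.get(cluster, 0.0)
        if not np.isfinite(shift):
            raise ValueError(f"non-finite logit shift for {cluster}")
        eta = (
            base
            + shift * is_t21
            + rng.normal(0.0, age_coef_sd) * age_c
            + rng.normal(0.0, sex_coef_sd) * is_female
        )
        mu = expit(eta)
        if np.any(mu <= 0) or np.any(mu >= 1):
            raise ValueError(f"mean proportion outside (0,1) for {cluster}")
        rows[cluster] = rng.beta(mu * precision, (1.0 - mu) * precision)
    freqs = pd.DataFrame(rows, index=participants.index).T
    freqs.index.name = "cluster"
    return freqs


@dataclass
class TrialTable:
    """Trial time-course container: samples, markers, expression, titers.

    ``samples`` is indexed by sample id with participant, visit, an
    ``excluded`` annotation flag and a free-text ``note`` (e.g. an
    immune-trigger excursion such as a recent vaccination or infection).
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    expression: pd.DataFrame
    gene_annotation: pd.DataFrame
    titers: pd.DataFrame

    def values_for(self, series: pd.Series) -> pd.DataFrame:
        """Pivot a per-sample series to participant x visit."""
        df = self.samples[["participant", "visit"]].copy()
        df["value"] = series.reindex(df.index)
        return df.pivot(index="participant", columns="visit", values="value")


def simulate_trial_timecourse(
    n_participants: int = 10,
    effects: EffectSpec | None = None,
    treatment_effect: float | None = None,
    trigger_prob: float = 0.05,
    seed: int = 0,
    visits: tuple = VISITS,
    n_analytes: int = 8,
    n_universe_genes: int = 136,
    n_isgs: int = 16,
    noise_sd: float = 0.2,
    titer_uln: float = 60.0,
) -> TrialTable:
    """Open-label trial time course: visits B, W2, W8, W16.

    Each participant gets baseline marker concentrations, ISG expression
    and an autoantibody titer; at treated visits (all but baseline) values
    are multiplied by ``treatment_effect``. With probability
    ``trigger_prob`` a treated visit suffers an immune-trigger excursion
    that reverses the treatment effect (value multiplied by
    1/treatment_effect instead) and is annotated as such.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    effects = effects or EffectSpec()
    te = effects.treatment_effect if treatment_effect is None else treatment_effect
    if te <= 0:
        raise ValueError("treatment_effect must be positive")
    rng = np.random.default_rng(seed)
    parts = [f"TR{i + 1:02d}" for i in range(n_participants)]
    sample_ids, meta_rows = [], []
    for p in parts:
        for v in visits:
            sid = f"{p}_{v}"
            sample_ids.append(sid)
            trigger = v != "B" and rng.random() < trigger_prob
            meta_rows.append(
                {
                    "participant": p,
                    "visit": v,
                    "excluded": False,
                    "note": "immune_trigger" if trigger else "",
                }
            )
    samples = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    treated = (samples["visit"] != "B").values
    trigger = (samples["note"] == "immune_trigger").values
    log2_mult = np.where(
        treated, np.where(trigger, -np.log2(te), np.log2(te)), 0.0
    )

    analytes = default_marker_names(n_analytes)
    part_idx = samples["participant"].map({p: i for i, p in enumerate(parts)}).values
    marker_base = rng.uniform(3.0, 9.0, size=(n_analytes, n_participants))
    mvals = (
        marker_base[:, part_idx]
        + log2_mult[None, :]
        + rng.normal(0.0, noise_sd, size=(n_analytes, len(samples)))
    )
    markers = pd.DataFrame(
        np.power(2.0, mvals),
        index=pd.Index(analytes, name="analyte"),
        columns=samples.index,
    )

    annotation = default_gene_annotation(
        n_genes=n_universe_genes + n_isgs + 10, n_isgs=n_isgs + n_universe_genes,
        n_chr21=10,
    )
    genes = list(annotation.index)
    expr_base = rng.uniform(2.0, 8.0, size=(len(genes), n_participants))
    evals = (
        expr_base[:, part_idx]
        + log2_mult[None, :]
        + rng.normal(0.0, noise_sd, size=(len(genes), len(samples)))
    )
    expression = pd.DataFrame(
        np.power(2.0, evals),
        index=pd.Index(genes, name="gene"),
        columns=samples.index,
    )

    titer_base = np.exp(rng.normal(np.log(1.5 * titer_uln), 0.4, n_participants))
    titer_rows = []
    for i, p in enumerate(parts):
        for v in visits:
            sid = f"{p}_{v}"
            pos = list(samples.index).index(sid)
            val = titer_base[i] * 2.0 ** (
                log2_mult[pos] + rng.normal(0.0, noise_sd / 2)
            )
            titer_rows.append(
                {"participant": p, "visit": v, "analyte": "anti-TPO", "value": val}
            )
    titers = pd.DataFrame(titer_rows)
    return TrialTable(
        samples=samples,
        markers=markers,
        expression=expression,
        gene_annotation=annotation,
        titers=titers,
    )
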