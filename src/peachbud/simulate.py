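"""Study-shaped synthetic data with known ground truth.

Emulates the design of a GA-treatment time-course on peach buds: two bud
positions (apical, basal) x three sequenced timepoints (T1, T3, T5) x three
RNA-seq replicates; ten quantified hormones at the same timepoints with five
replicates; an ex-post two-level treatment-efficacy factor on the basal buds
(high at T3, low at T1/T5); planted hormone-correlated gene modules; planted
efficacy DEGs; and a downstream qPCR + return-bloom experiment in which an
AP1-like floral marker tracks next-spring bloom at a configured correlation.

Everything is driven by a single integer seed; a fixed seed reproduces every
table bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "HORMONES",
    "HORMONE_TEMPLATES",
    "ModuleSpec",
    "DegSpec",
    "SimulationConfig",
    "HormoneProfile",
    "TruthTable",
    "simulate_hormone_profiles",
    "simulate_counts",
    "simulate_gene_sets",
    "simulate_qpcr_and_bloom",
    "subnetwork_recovery_config",
    "simulate_all",
]

HORMONES = ("ABA", "IAA", "JA", "JA-Ile", "SA", "tZ", "2-iP", "GA3", "GA4", "GA7")

#: Relative per-timepoint concentration means (T1, T3, T5), arbitrary units.
#: Directions follow the measured qualitative trends: gibberellins generally
#: increase (GA3 up from T1 to T3, GA7 peaking at T5, GA4 roughly flat), ABA,
#: JA and SA decrease, IAA peaks at T3, tZ is flat and 2-iP rises at T5.
HORMONE_TEMPLATES: dict[str, tuple[float, float, float]] = {
    "ABA": (30.0, 22.0, 12.0),
    "IAA": (15.0, 25.0, 10.0),
    "JA": (25.0, 16.0, 8.0),
    "JA-Ile": (10.0, 11.0, 9.5),
    "SA": (22.0, 15.0, 9.0),
    "tZ": (10.0, 9.5, 11.0),
    "2-iP": (10.0, 11.0, 22.0),
    "GA3": (10.0, 20.0, 23.0),
    "GA4": (10.0, 10.5, 11.0),
    "GA7": (10.0, 18.0, 35.0),
}

AP1_GENE = "PRUPE_1G290600"  # AP1-like floral-identity marker planted in the matrix
REFERENCE_GENES = ("TEF2", "UBQ10")
BLOCKS = ("UTC", "T1", "T2", "T3", "T4", "T5")

#: Return-bloom block means as fractions of the untreated control: every
#: treated block blooms less than UTC, with a V-shaped minimum at T3.
BLOOM_TEMPLATE: dict[str, float] = {
    "UTC": 1.00,
    "T1": 0.75,
    "T2": 0.60,
    "T3": 0.40,
    "T4": 0.55,
    "T5": 0.70,
}


@dataclass(frozen=True)
class ModuleSpec:
    """A planted hormone-correlated gene module."""

    hormone: str
    n_genes: int
    sign: int  # +1 direct, -1 inverse correlation with the hormone profile

    def __post_init__(self):
        if self.hormone not in HORMONES:
            raise ValueError(f"unknown hormone label {self.hormone!r}")
        if self.n_genes <= 0:
            raise ValueError("module size must be positive")
        if self.sign not in (-1, 1):
            raise ValueError("module sign must be +1 or -1")


@dataclass(frozen=True)
class DegSpec:
    """Planted efficacy DEGs: fraction of genes and |log2FC| values used."""

    fraction: float = 0.05
    log2fc_values: tuple[float, ...] = (2.0,)
    up_fraction: float = 0.5

    def __post_init__(self):
        if not 0 <= self.fraction < 1:
            raise ValueError("deg fraction must be in [0, 1)")
        if any(v < 1 for v in self.log2fc_values):
            raise ValueError("planted |log2FC| must be >= 1")


def _default_modules() -> tuple[ModuleSpec, ...]:
    return (
        ModuleSpec("GA7", 50, +1),
        ModuleSpec("2-iP", 30, -1),
        ModuleSpec("ABA", 20, +1),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the seed fully determines every output."""

    n_genes: int = 2000
    timepoints: tuple[str, ...] = ("T1", "T3", "T5")
    n_rna_reps: int = 3
    n_hormone_reps: int = 5
    positions: tuple[str, ...] = ("apical", "basal")
    dispersion: float = 0.05  # NB shape alpha: var = mu + alpha * mu^2
    module_spec: tuple[ModuleSpec, ...] = field(default_factory=_default_modules)
    deg_spec: DegSpec = field(default_factory=DegSpec)
    seed: int = 0

    # hormone replicate noise (lognormal coefficient of variation)
    hormone_noise_cv: float = 0.15
    # baseline expression: lognormal over genes
    base_mean_median: float = 150.0
    base_mean_log_sd: float = 1.3
    module_min_mean: float = 50.0  # hormone-responsive genes kept clearly expressed
    module_amp_range: tuple[float, float] = (1.5, 2.5)  # peak-to-peak log2 units
    # broad developmental structure (drives PCA / clustering, not the truth table)
    trend_fraction: float = 0.35
    trend_log2_sd: float = 0.5
    position_fraction: float = 0.20
    position_log2_sd: float = 0.4
    depth_log_sd: float = 0.15  # per-sample sequencing-depth variation
    count_noise: bool = True  # False -> counts are rounded expected means
    gene_length_range: tuple[int, int] = (500, 5000)

    # qPCR / return-bloom experiment
    ap1_bloom_r: float = 0.99
    n_trees_per_block: int = 5
    utc_mean_area: float = 1000.0  # arbitrary flower-covered-area units
    tree_area_cv: float = 0.05
    n_qpcr_bio_reps: int = 3
    n_qpcr_tech_reps: int = 2
    ct_tech_sd: float = 0.05  # cycles
    qpcr_bio_log2_sd: float = 0.10
    reference_genes: tuple[str, ...] = REFERENCE_GENES
    qpcr_efficiency: float = 2.0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_rna_reps <= 0 or self.n_hormone_reps <= 0:
            raise ValueError("counts and replicate numbers must be positive")
        if self.dispersion <= 0:
            raise ValueError("NB dispersion must be strictly positive")
        if sum(m.n_genes for m in self.module_spec) > self.n_genes:
            raise ValueError("module genes exceed n_genes")
        if not -1.0 <= self.ap1_bloom_r <= 1.0:
            raise ValueError("configured AP1-bloom correlation must be in [-1, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        # independent, seed-determined stream per generator stage
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


@dataclass
class HormoneProfile:
    """Replicate-level hormone concentrations plus per-timepoint means."""

    replicates: pd.DataFrame  # columns: hormone, timepoint, replicate, concentration
    timepoints: tuple[str, ...]

    def means(self) -> pd.DataFrame:
        """hormone x timepoint mean concentrations, timepoints in order."""
        m = self.replicates.pivot_table(
            index="hormone", columns="timepoint", values="concentration",
            aggfunc="mean",
        )
        return m.loc[list(HORMONES), list(self.timepoints)]

    def to_tsv(self, path) -> None:
        self.replicates.to_csv(path, sep="\t", index=False)


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset: the acceptance surface.

    ``genes`` is indexed by gene ID with columns ``deg_status`` (up/down/null
    for the efficacy contrast, high vs low), ``true_log2fc`` (planted efficacy
    effect; 0 for null genes), ``module_hormone``/``module_sign`` (planted
    hormone module membership) and ``trend``/``position_effect`` flags for the
    broad developmental structure.
    """

    genes: pd.DataFrame
    ap1_gene: str = AP1_GENE
    ap1_bloom_r: float = 0.99
    reference_genes: tuple[str, ...] = REFERENCE_GENES

    def module_genes(self, hormone: str | None = None) -> pd.Index:
        g = self.genes[self.genes["module_hormone"] != ""]
        if hormone is not None:
            g = g[g["module_hormone"] == hormone]
        return g.index

    def deg_genes(self, direction: str | None = None) -> pd.Index:
        g = self.genes[self.genes["deg_status"] != "null"]
        if direction is not None:
            g = g[g["deg_status"] == direction]
        return g.index

    def to_tsv(self, path) -> None:
        out = self.genes.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def simulate_hormone_profiles(config: SimulationConfig) -> HormoneProfile:
    """Draw replicate hormone concentrations around the template trends.

    Replicate noise is lognormal (mass-spec concentrations are positive and
    right-skewed), mean-corrected so that expected values equal the template
    means; ``hormone_noise_cv = 0`` reproduces the templates exactly.
    """
    for h in HORMONE_TEMPLATES:
        if h not in HORMONES:
            raise ValueError(f"unknown hormone label {h!r} in template")
    if len(config.timepoints) != 3:
        raise ValueError("hormone templates are defined for 3 timepoints")
    rng = config.rng(1)
    cv = config.hormone_noise_cv
    sigma = math.sqrt(math.log(1 + cv**2)) if cv > 0 else 0.0
    rows = []
    for h in HORMONES:
        tmpl = HORMONE_TEMPLATES[h]
        for t, mean in zip(config.timepoints, tmpl):
            for r in range(1, config.n_hormone_reps + 1):
                noise = (
                    math.exp(rng.normal(-sigma**2 / 2, sigma)) if sigma > 0 else 1.0
                )
                rows.append((h, t, r, mean * noise))
    df = pd.DataFrame(rows, columns=["hormone", "timepoint", "replicate", "concentration"])
    return HormoneProfile(df, tuple(config.timepoints))


def _scaled_profile(template: tuple[float, ...]) -> np.ndarray:
    """Template means rescaled to zero mean and unit peak-to-peak range."""
    v = np.asarray(template, dtype=float)
    return (v - v.mean()) / (v.max() - v.min())


def simulate_counts(
    config: SimulationConfig, profiles: HormoneProfile
) -> tuple[CountMatrix, pd.DataFrame, TruthTable]:
    """Draw the gene x sample NB count matrix plus metadata and ground truth.

    Per-gene expected means combine: a lognormal baseline; a monotone
    developmental trend on a random subset of genes (drives PC1); an
    apical/basal offset on another subset (drives PC2); sign-respecting
    affine tracking of the assigned hormone's template profile for planted
    module genes; and the planted efficacy log2FC on basal buds (high = T3,
    low = T1/T5).  Counts are negative binomial with shape ``dispersion``
    (var = mu + alpha mu^2) on top of per-sample depth factors.
    """
    rng = config.rng(2)
    G = config.n_genes
    tps = list(config.timepoints)

    gene_ids = np.array([f"PRUPE_G{i + 1:06d}" for i in range(G)], dtype=object)

    # --- assign gene roles on a seeded shuffle, all special sets disjoint
    order = rng.permutation(G)
    cursor = 0
    module_hormone = np.full(G, "", dtype=object)
    module_sign = np.zeros(G, dtype=int)
    for m in config.module_spec:
        idx = order[cursor: cursor + m.n_genes]
        cursor += m.n_genes
        module_hormone[idx] = m.hormone
        module_sign[idx] = m.sign
    n_deg = int(round(config.deg_spec.fraction * G))
    deg_idx = order[cursor: cursor + n_deg]
    cursor += n_deg
    n_up = int(round(config.deg_spec.up_fraction * n_deg))
    lfc = np.zeros(G)
    mags = rng.choice(config.deg_spec.log2fc_values, size=n_deg)
    lfc[deg_idx[:n_up]] = mags[:n_up]
    lfc[deg_idx[n_up:]] = -mags[n_up:]
    deg_status = np.full(G, "null", dtype=object)
    deg_status[lfc > 0] = "up"
    deg_status[lfc < 0] = "down"
    remaining = order[cursor:]
    n_trend = int(round(config.trend_fraction * G))
    trend_idx = remaining[:n_trend]
    n_pos = int(round(config.position_fraction * G))
    pos_idx = remaining[n_trend: n_trend + n_pos]
    trend_flag = np.zeros(G, dtype=bool)
    trend_flag[trend_idx] = True
    pos_flag = np.zeros(G, dtype=bool)
    pos_flag[pos_idx] = True

    # the AP1-like marker is a down-regulated efficacy DEG (lowest where the
    # treatment bites hardest, i.e. basal T3), renamed to its PRUPE-style ID
    down_idx = deg_idx[n_up:]
    ap1_gene = ""
    if len(down_idx) > 0:
        gene_ids[int(down_idx[0])] = AP1_GENE
        ap1_gene = AP1_GENE

    # --- per-gene log2 baseline
    base = rng.lognormal(math.log(config.base_mean_median), config.base_mean_log_sd, G)
    is_module = module_hormone != ""
    base[is_module] = np.maximum(base[is_module], config.module_min_mean)
    log2_base = np.log2(base)

    # --- per-gene per-timepoint offsets (log2)
    t_idx = {t: i for i, t in enumerate(tps)}
    x_dev = np.linspace(0.0, 1.0, len(tps))  # developmental axis
    trend_amp = rng.normal(0.0, config.trend_log2_sd, G) * trend_flag
    pos_amp = rng.normal(0.0, config.position_log2_sd, G) * pos_flag
    amp_lo, amp_hi = config.module_amp_range
    mod_amp = rng.uniform(amp_lo, amp_hi, G) * is_module
    time_offsets = np.zeros((G, len(tps)))
    for h in HORMONES:
        sel = module_hormone == h
        if sel.any():
            prof = _scaled_profile(HORMONE_TEMPLATES[h])
            time_offsets[sel] = (
                module_sign[sel, None] * mod_amp[sel, None] * prof[None, :]
            )
    time_offsets += trend_amp[:, None] * (x_dev - x_dev.mean())[None, :]

    # --- samples
    sample_ids, sample_pos, sample_tp, sample_rep = [], [], [], []
    for pos in config.positions:
        for t in tps:
            for r in range(1, config.n_rna_reps + 1):
                sample_ids.append(f"{pos}_{t}_r{r}")
                sample_pos.append(pos)
                sample_tp.append(t)
                sample_rep.append(str(r))
    S = len(sample_ids)
    efficacy = [
        ("high" if t == "T3" else "low") if p == "basal" else ""
        for p, t in zip(sample_pos, sample_tp)
    ]
    metadata = pd.DataFrame(
        {
            "position": sample_pos,
            "timepoint": sample_tp,
            "replicate": sample_rep,
            "efficacy": efficacy,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    depth = np.exp(rng.normal(0.0, config.depth_log_sd, S)) if config.depth_log_sd > 0 else np.ones(S)

    log2_mu = np.empty((G, S))
    for j in range(S):
        ti = t_idx[sample_tp[j]]
        col = log2_base + time_offsets[:, ti]
        if sample_pos[j] == "apical":
            col = col + pos_amp  # position shift, constant across time
        else:
            # efficacy effect lives on basal buds only: high = T3
            if sample_tp[j] == "T3":
                col = col + lfc
        log2_mu[:, j] = col
    mu = np.power(2.0, log2_mu) * depth[None, :]

    if config.count_noise:
        alpha = config.dispersion
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)
    else:
        counts = np.round(mu).astype(np.int64)

    lengths = pd.Series(
        rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, G),
        index=pd.Index(gene_ids, name="gene_id"),
        dtype=float,
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        lengths,
    )

    truth_df = pd.DataFrame(
        {
            "deg_status": deg_status,
            "true_log2fc": lfc,
            "module_hormone": module_hormone,
            "module_sign": module_sign,
            "trend": trend_flag,
            "position_effect": pos_flag,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth = TruthTable(
        truth_df,
        ap1_gene=ap1_gene,
        ap1_bloom_r=config.ap1_bloom_r,
        reference_genes=config.reference_genes,
    )
    return cm, metadata, truth


def simulate_gene_sets(
    truth: TruthTable,
    config: SimulationConfig,
    n_random_sets: int = 20,
    random_set_size: tuple[int, int] = (10, 40),
) -> dict[str, tuple[str, frozenset]]:
    """Toy gene-set collection: one set per planted module + random null sets.

    Returns a GMT-style mapping ``name -> (description, members)`` usable by
    the pathway module.
    """
    rng = config.rng(4)
    genes = truth.genes.index.to_numpy()
    sets: dict[str, tuple[str, frozenset]] = {}
    for m in config.module_spec:
        name = f"MODULE_{m.hormone}_{'UP' if m.sign > 0 else 'DOWN'}"
        members = truth.genes.index[
            (truth.genes["module_hormone"] == m.hormone)
            & (truth.genes["module_sign"] == m.sign)
        ]
        sets[name] = (f"planted {m.hormone} module (sign {m.sign:+d})", frozenset(members))
    lo, hi = random_set_size
    for i in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"RANDOM_{i + 1:03d}"] = ("random null set", frozenset(members))
    return sets


def simulate_qpcr_and_bloom(
    truth: TruthTable, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the follow-up qPCR and return-bloom experiment.

    Blocks are the untreated control plus one block per application timepoint.
    True per-block bloom follows the V-shaped template (minimum at the most
    sensitive stage, T3; all treated blocks below UTC).  Block-level AP1
    normalized expression is constructed to correlate with the true block
    bloom means at exactly the configured level before measurement noise
    (orthogonal-residual construction), then expressed as Ct values for the
    marker and two stable reference genes over biological x technical
    replicates.  Per-tree flower-covered areas get lognormal tree noise.
    """
    if truth.ap1_gene is None or truth.ap1_gene == "":
        raise ValueError("truth table does not contain an AP1-like marker")
    if len(config.reference_genes) < 2:
        raise ValueError("at least 2 reference genes are required")
    rng = config.rng(3)
    rho = config.ap1_bloom_r

    bloom_means = np.array([BLOOM_TEMPLATE[b] for b in BLOCKS]) * config.utc_mean_area

    # exact-correlation construction of block-level AP1 expression
    b = bloom_means
    zb = (b - b.mean()) / b.std()
    e = rng.normal(size=len(b))
    e = e - e.mean()
    e = e - (e @ zb) / (zb @ zb) * zb
    if np.allclose(e, 0):  # degenerate residual draw; use a fixed contrast
        e = np.arange(len(b)) - (len(b) - 1) / 2.0
        e = e - (e @ zb) / (zb @ zb) * zb
    ze = e / np.sqrt((e**2).mean())
    a = rho * zb + math.sqrt(max(0.0, 1.0 - rho**2)) * ze
    mne_true = 1.0 + 0.35 * a  # linear-scale target MNE per block, kept positive
    mne_true = np.maximum(mne_true, 0.05)

    E = config.qpcr_efficiency
    ref_base_ct = {g: 20.0 + i for i, g in enumerate(config.reference_genes)}
    mean_ref_ct = float(np.mean(list(ref_base_ct.values())))

    rows = []
    for k, block in enumerate(BLOCKS):
        for bio in range(1, config.n_qpcr_bio_reps + 1):
            log2_mne_bio = math.log2(mne_true[k]) + (
                rng.normal(0.0, config.qpcr_bio_log2_sd)
                if config.qpcr_bio_log2_sd > 0
                else 0.0
            )
            sample = f"{block}_b{bio}"
            for tech in range(1, config.n_qpcr_tech_reps + 1):
                tech_noise = (
                    rng.normal(0.0, config.ct_tech_sd, 1 + len(config.reference_genes))
                    if config.ct_tech_sd > 0
                    else np.zeros(1 + len(config.reference_genes))
                )
                # marker Ct so that E^(ref mean - Ct) recovers the planted MNE
                ct_target = mean_ref_ct - log2_mne_bio / math.log2(E) + tech_noise[0]
                rows.append((sample, block, bio, tech, "AP1", ct_target, E))
                for gi, g in enumerate(config.reference_genes):
                    rows.append(
                        (sample, block, bio, tech, g, ref_base_ct[g] + tech_noise[1 + gi], E)
                    )
    qpcr = pd.DataFrame(
        rows,
        columns=["sample_id", "block", "bio_rep", "tech_rep", "gene", "ct", "efficiency"],
    )

    tree_rows = []
    cv = config.tree_area_cv
    sigma = math.sqrt(math.log(1 + cv**2)) if cv > 0 else 0.0
    for k, block in enumerate(BLOCKS):
        for tree in range(1, config.n_trees_per_block + 1):
            noise = math.exp(rng.normal(-sigma**2 / 2, sigma)) if sigma > 0 else 1.0
            tree_rows.append((block, tree, bloom_means[k] * noise))
    bloom = pd.DataFrame(tree_rows, columns=["block", "tree", "flower_area"])
    return qpcr, bloom


def subnetwork_recovery_config(seed: int = 0) -> SimulationConfig:
    """Fixture configuration for exact subnetwork-size recovery.

    Three planted modules of sizes 50/20/10 on hormones whose profiles are
    maximally separated in the 3-timepoint correlation geometry (GA7
    monotone-up, tZ late-dip, IAA T3-peak), with noiseless hormone means, a
    low count dispersion, large module amplitudes and an unstructured
    background so library composition stays stable.  With only two degrees
    of freedom in a 3-point profile, most hormone pairs are nearly collinear
    and their subnetworks are not separable even in principle; this
    configuration keeps the planted assignment geometrically identifiable.
    """
    return SimulationConfig(
        n_genes=1000,
        seed=seed,
        dispersion=0.005,
        module_spec=(
            ModuleSpec("GA7", 50, +1),
            ModuleSpec("tZ", 20, -1),
            ModuleSpec("IAA", 10, +1),
        ),
        deg_spec=DegSpec(fraction=0.0),
        trend_fraction=0.0,
        position_fraction=0.0,
        module_amp_range=(1.5, 2.5),
        hormone_noise_cv=0.0,
    )


def simulate_all(config: SimulationConfig | None = None, **kwargs):
    """One-call convenience: profiles, counts, metadata, truth, qPCR, bloom."""
    if config is None:
        config = SimulationConfig(**kwargs)
    elif kwargs:
        config = replace(config, **kwargs)
    profiles = simulate_hormone_profiles(config)
    counts, metadata, truth = simulate_counts(config, profiles)
    qpcr, bloom = simulate_qpcr_and_bloom(truth, config)
    return {
        "config": config,
        "profiles": profiles,
        "counts": counts,
        "metadata": metadata,
        "truth": truth,
        "qpcr": qpcr,
        "bloom": bloom,
    }
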