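"""Synthetic SNP panels with injectable ground truth.

The generator emulates the statistical structure the analysis consumes:
per-SNP p-value/coefficient pairs from a clinal and a seasonal model,
eQTLs clustered in cis around gene positions, sex-class labels and
allelic effect signs, six cosmopolitan inversions on the four autosomal
arms, and per-sample focal-allele frequencies for twenty paired
spring-fall localities plus two clinal endpoint samples.

Enrichment is injected by mixture assignment: non-eQTL p-values are
uniform on (0, 1], and a fraction phi of eQTL p-values falls below the
q = 5% cutoff, where phi solves the target odds ratio

    theta = [phi / (1 - phi)] / [q / (1 - q)]   =>   phi = theta r / (1 + theta r),  r = q/(1-q).

Directionality is injected through the coefficient signs: for an eQTL
whose gene carries a differential-expression direction, the sign of the
clinal (or seasonal) coefficient matches the predicted direction pi
with probability kappa (the concordance rate), independently per axis;
non-eQTL signs are symmetric.  Both theta and kappa are therefore
directly recoverable targets for the downstream pipeline.

All draws descend from one integer seed through labelled substreams
("genes", "de_sets", "snps", "freqs"), so identical configurations
produce byte-identical tables and each stage is reproducible in
isolation.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._streams import substream
from .errors import ConfigError
from .tables_io import (
    ARMS,
    DE_LABELS,
    FREQ_PREFIX,
    SEX_CLASSES,
    DeGeneSet,
    InversionDef,
)

#: The six cosmopolitan inversions (release-5 reference breakpoints).
DEFAULT_INVERSIONS: tuple[InversionDef, ...] = (
    InversionDef("In(2L)t", "2L", 2_225_744, 13_154_180),
    InversionDef("In(2R)NS", "2R", 11_278_659, 16_163_839),
    InversionDef("In(3L)P", "3L", 3_173_046, 16_301_941),
    InversionDef("In(3R)K", "3R", 7_576_289, 21_966_092),
    InversionDef("In(3R)P", "3R", 12_257_931, 20_569_732),
    InversionDef("In(3R)Mo", "3R", 17_232_639, 24_857_019),
)

#: release-5 autosomal arm lengths, matching the inversion coordinates.
DEFAULT_ARM_LENGTHS: Mapping[str, int] = {
    "2L": 23_011_544,
    "2R": 21_146_708,
    "3L": 24_543_557,
    "3R": 27_905_053,
}

#: DE set sizes: latitudinal genes overlapping the eQTL catalogue, and the
#: five environmental-treatment sets.
DEFAULT_DE_SET_SIZES: Mapping[str, int] = {
    "latitudinal": 39,
    "heat_shock": 57,
    "chill_coma": 16,
    "starvation": 28,
    "high_temp": 19,
    "low_temp": 20,
}

FL_LATITUDE = 25.5  # Florida clinal endpoint, degrees north
ME_LATITUDE = 44.8  # Maine clinal endpoint


def solve_phi(theta: float, q: float = 0.05) -> float:
    """Fraction of eQTL p-values below the q cutoff giving odds ratio theta."""
    if theta <= 0:
        raise ConfigError(f"enrichment odds ratio must be positive, got {theta}")
    if not 0 < q < 1:
        raise ConfigError(f"cutoff quantile must lie in (0, 1), got {q}")
    r = q / (1 - q)
    phi = theta * r / (1 + theta * r)
    if not 0 < phi < 1:
        raise ConfigError(f"theta={theta} yields phi={phi} outside (0, 1)")
    return phi


@dataclasses.dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    The defaults describe a panel of 4 x 50,000 SNPs with 400 genes at
    about five cis-clustered eQTLs each (~2,000 eQTLs), clinal
    enrichment at odds ratio 2 with no seasonal enrichment, and a
    concordance rate of 0.6 - i.e. a clinally enriched, directionally
    concordant genome against a seasonally null background.
    """

    seed: int = 0
    n_snps_per_arm: int = 50_000
    arm_lengths: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ARM_LENGTHS)
    )
    n_genes: int = 400
    eqtls_per_gene: float = 5.0          # mean count, >= 1 per gene
    cis_window: int = 20_000             # bp of clustering around the gene
    frac_eqtl_sexclass: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"female": 0.3, "male": 0.2, "non_sex_biased": 0.5}
    )
    # focal-allele MAF; het = 2 maf (1 - maf).  The lower bound keeps every
    # heterozygosity bin either well populated or empty, so occupied
    # matching strata retain usable candidate pools at desk scale.
    maf_range: tuple[float, float] = (0.1, 0.5)
    inversions: tuple[InversionDef, ...] = DEFAULT_INVERSIONS
    clinal_enrichment: float = 2.0       # theta_c, odds ratio at the 5% cutoff
    seasonal_enrichment: float = 1.0     # theta_s
    enrich_quantile: float = 0.05
    concordance_rate: float = 0.6        # kappa
    beta_scale_clinal: float = 0.01      # half-normal scale, frequency per degree
    beta_scale_seasonal: float = 0.02    # half-normal scale, spring-minus-fall
    n_pairs: int = 20
    noise_sd: float = 0.05               # per-sample frequency noise
    de_set_sizes: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_DE_SET_SIZES)
    )
    de_sign_prob: float = 0.5            # P(de_sign = +1)

    def __post_init__(self) -> None:
        if self.clinal_enrichment <= 0 or self.seasonal_enrichment <= 0:
            raise ConfigError("enrichment odds ratios theta must be > 0")
        if not 0 <= self.concordance_rate <= 1:
            raise ConfigError("concordance_rate kappa must lie in [0, 1]")
        fracs = self.frac_eqtl_sexclass
        if set(fracs) != set(SEX_CLASSES):
            raise ConfigError(f"frac_eqtl_sexclass must cover {SEX_CLASSES}")
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ConfigError("sex-class proportions must sum to 1")
        if set(self.arm_lengths) != set(ARMS):
            raise ConfigError(f"arm_lengths must cover arms {ARMS}")
        if self.eqtls_per_gene < 1:
            raise ConfigError("eqtls_per_gene must be >= 1")
        unknown = set(self.de_set_sizes) - set(DE_LABELS)
        if unknown:
            raise ConfigError(f"unknown DE set label(s): {sorted(unknown)}")
        for label, size in self.de_set_sizes.items():
            if size > self.n_genes:
                raise ConfigError(
                    f"DE set {label!r} size {size} exceeds n_genes {self.n_genes}"
                )
        if sum(self.de_set_sizes.values()) > self.n_genes:
            raise ConfigError("DE set sizes must sum to at most n_genes (sets are disjoint)")
        if not 0 < self.maf_range[0] < self.maf_range[1] <= 0.5:
            raise ConfigError("maf_range must satisfy 0 < low < high <= 0.5")
        # both targets must yield a valid mixture weight
        solve_phi(self.clinal_enrichment, self.enrich_quantile)
        solve_phi(self.seasonal_enrichment, self.enrich_quantile)


@dataclasses.dataclass
class GroundTruth:
    """Injected parameters recorded alongside every simulated dataset."""

    theta_clinal: float
    theta_seasonal: float
    phi_clinal: float
    phi_seasonal: float
    kappa: float
    de_membership: dict      # gene_id -> DE label (disjoint sets)
    de_signs: dict           # gene_id -> +1/-1
    predicted_sign_clinal: dict    # eqtl snp_id -> pi on the clinal axis
    predicted_sign_seasonal: dict
    enriched_strata: list    # strata truly enriched under this configuration

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def simulate_genes(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Gene positions: arms drawn proportional to length, positions uniform."""
    if rng is None:
        rng = substream(config.seed, "genes")
    arms = list(ARMS)
    lengths = np.array([config.arm_lengths[a] for a in arms], dtype=float)
    gene_arms = rng.choice(arms, size=config.n_genes, p=lengths / lengths.sum())
    margin = config.cis_window + 1
    pos = np.array(
        [rng.integers(margin, config.arm_lengths[a] - margin) for a in gene_arms]
    )
    width = len(str(config.n_genes))
    return pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:0{width}d}" for i in range(config.n_genes)],
            "arm": gene_arms,
            "pos": pos,
        }
    )


def simulate_de_sets(
    config: SimConfig,
    genes: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, DeGeneSet], dict, dict]:
    """Sample disjoint DE gene sets and per-gene direction signs.

    Membership is drawn without replacement from the gene catalogue and
    the six sets are mutually disjoint, so each gene has a single
    predicted direction.  Returns (sets, membership, signs).
    """
    if rng is None:
        rng = substream(config.seed, "de_sets")
    order = rng.permutation(genes["gene_id"].to_numpy(dtype=object))
    sets: dict[str, DeGeneSet] = {}
    membership: dict[str, str] = {}
    signs: dict[str, int] = {}
    offset = 0
    for label in sorted(config.de_set_sizes):
        size = config.de_set_sizes[label]
        members = order[offset:offset + size]
        offset += size
        de_signs = np.where(rng.random(size) < config.de_sign_prob, 1, -1)
        entries = dict(zip(members, (int(s) for s in de_signs)))
        sets[label] = DeGeneSet(label=label, entries=entries)
        membership.update({g: label for g in members})
        signs.update(entries)
    return sets, membership, signs


def _mixture_pvalues(rng: np.random.Generator, n: int, phi: float, q: float) -> np.ndarray:
    """Draw n p-values: below the cutoff w.p. phi, uniform in each stratum."""
    below = rng.random(n) < phi
    u = rng.random(n)
    return np.where(below, q * (1 - u), q + (1 - q) * (1 - u))


def simulate_snps(
    config: SimConfig,
    genes: pd.DataFrame | None = None,
    de_sets: tuple[dict, dict, dict] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the SNP panel and eQTL annotations.

    Returns (snp table, eQTL annotation table, ground truth).  The SNP
    table carries an extra ``base_freq`` column (the focal-allele
    baseline frequency) used by :func:`simulate_sample_freqs`.
    """
    if rng is None:
        rng = substream(config.seed, "snps")
    if genes is None:
        genes = simulate_genes(config)
    if de_sets is None:
        de_sets = simulate_de_sets(config, genes)
    _, membership, de_signs = de_sets

    phi_c = solve_phi(config.clinal_enrichment, config.enrich_quantile)
    phi_s = solve_phi(config.seasonal_enrichment, config.enrich_quantile)
    kappa = config.concordance_rate
    q = config.enrich_quantile

    # eQTLs clustered in cis around each gene; mean count = eqtls_per_gene, min 1
    counts = 1 + rng.poisson(config.eqtls_per_gene - 1, size=len(genes))
    gene_arm = np.repeat(genes["arm"].to_numpy(dtype=object), counts)
    gene_pos = np.repeat(genes["pos"].to_numpy(), counts)
    gene_ids = np.repeat(genes["gene_id"].to_numpy(dtype=object), counts)
    offsets = rng.integers(-config.cis_window, config.cis_window + 1, size=counts.sum())
    eqtl_pos = np.clip(gene_pos + offsets, 1, None)

    # per-eQTL labels
    classes = np.array(SEX_CLASSES, dtype=object)
    probs = np.array([config.frac_eqtl_sexclass[c] for c in SEX_CLASSES])
    sex_class = rng.choice(classes, size=counts.sum(), p=probs)
    effect_sign = np.where(rng.random(counts.sum()) < 0.5, 1, -1)

    # predicted direction per axis; genes outside every DE set get an
    # arbitrary symmetric target so kappa has a well-defined meaning
    from .directionality import DIRECTION_HYPOTHESES

    sigma_c = np.array(
        [DIRECTION_HYPOTHESES[membership[g]][0] if g in membership else 0 for g in gene_ids]
    )
    sigma_s = np.array(
        [DIRECTION_HYPOTHESES[membership[g]][1] if g in membership else 0 for g in gene_ids]
    )
    gsign = np.array([de_signs.get(g, 0) for g in gene_ids])
    rand_target = np.where(rng.random(counts.sum()) < 0.5, 1, -1)
    pi_c = np.where(sigma_c != 0, effect_sign * gsign * sigma_c, rand_target)
    pi_s = np.where(sigma_s != 0, effect_sign * gsign * sigma_s, rand_target)

    frames = []
    for arm in ARMS:
        on_arm = gene_arm == arm
        n_e = int(on_arm.sum())
        n_bg = config.n_snps_per_arm - n_e
        if n_bg < 0:
            raise ConfigError(
                f"arm {arm}: more eQTLs ({n_e}) than n_snps_per_arm "
                f"({config.n_snps_per_arm})"
            )
        # background positions: oversample, deduplicate, trim
        draw = rng.integers(1, config.arm_lengths[arm] + 1,
                            size=int(n_bg * 1.02) + 64)
        bg_pos = pd.unique(draw)[:n_bg]
        if bg_pos.size < n_bg:
            raise ConfigError(f"arm {arm}: could not place {n_bg} unique SNPs")
        frames.append(
            pd.DataFrame(
                {
                    "arm": arm,
                    "pos": np.concatenate([eqtl_pos[on_arm], bg_pos]),
                    "is_eqtl": np.concatenate(
                        [np.ones(n_e, bool), np.zeros(n_bg, bool)]
                    ),
                    "_eqtl_row": np.concatenate(
                        [np.flatnonzero(on_arm), np.full(n_bg, -1)]
                    ),
                }
            )
        )
    snps = pd.concat(frames, ignore_index=True)
    # collisions between cis-clustered eQTLs or with background are rare;
    # keep eQTLs in preference, then first occurrence
    snps = snps.sort_values(["arm", "pos", "is_eqtl"], ascending=[True, True, False])
    snps = snps.drop_duplicates(subset=["arm", "pos"], keep="first").reset_index(drop=True)

    n = len(snps)
    is_eqtl = snps["is_eqtl"].to_numpy()
    eqtl_row = snps["_eqtl_row"].to_numpy()

    maf = rng.uniform(*config.maf_range, size=n)
    het = 2 * maf * (1 - maf)
    base_freq = np.where(rng.random(n) < 0.5, maf, 1 - maf)

    clinal_p = 1 - rng.random(n)
    seasonal_p = 1 - rng.random(n)
    e = np.flatnonzero(is_eqtl)
    clinal_p[e] = _mixture_pvalues(rng, e.size, phi_c, q)
    seasonal_p[e] = _mixture_pvalues(rng, e.size, phi_s, q)

    clinal_beta = rng.normal(0, 1, n)
    seasonal_beta = rng.normal(0, 1, n)
    clinal_beta = np.abs(clinal_beta) * config.beta_scale_clinal
    seasonal_beta = np.abs(seasonal_beta) * config.beta_scale_seasonal
    sign_c = np.where(rng.random(n) < 0.5, 1, -1)
    sign_s = np.where(rng.random(n) < 0.5, 1, -1)
    # eQTLs: sign matches the predicted direction with probability kappa
    match_c = rng.random(e.size) < kappa
    match_s = rng.random(e.size) < kappa
    sign_c[e] = np.where(match_c, pi_c[eqtl_row[e]], -pi_c[eqtl_row[e]])
    sign_s[e] = np.where(match_s, pi_s[eqtl_row[e]], -pi_s[eqtl_row[e]])
    clinal_beta *= sign_c
    seasonal_beta *= sign_s

    snps = snps.assign(
        snp_id=snps["arm"].astype(str) + ":" + snps["pos"].astype(str),
        het=het,
        clinal_p=clinal_p,
        clinal_beta=clinal_beta,
        seasonal_p=seasonal_p,
        seasonal_beta=seasonal_beta,
        base_freq=base_freq,
    )

    kept = eqtl_row[is_eqtl]
    eqtls = pd.DataFrame(
        {
            "snp_id": snps.loc[is_eqtl, "snp_id"].to_numpy(),
            "gene_id": gene_ids[kept],
            "sex_class": sex_class[kept],
            "effect_sign": effect_sign[kept],
        }
    ).sort_values(["snp_id", "gene_id"], ignore_index=True)

    eqtl_id_of = dict(zip(kept, snps.loc[is_eqtl, "snp_id"]))
    truth = GroundTruth(
        theta_clinal=config.clinal_enrichment,
        theta_seasonal=config.seasonal_enrichment,
        phi_clinal=phi_c,
        phi_seasonal=phi_s,
        kappa=kappa,
        de_membership=membership,
        de_signs=de_signs,
        predicted_sign_clinal={eqtl_id_of[r]: int(pi_c[r]) for r in kept},
        predicted_sign_seasonal={eqtl_id_of[r]: int(pi_s[r]) for r in kept},
        enriched_strata=(["genome:clinal"] if config.clinal_enrichment != 1 else [])
        + (["genome:seasonal"] if config.seasonal_enrichment != 1 else []),
    )
    cols = ["snp_id", "arm", "pos", "het", "clinal_p", "clinal_beta",
            "seasonal_p", "seasonal_beta", "is_eqtl", "base_freq"]
    return snps[cols], eqtls, truth


def default_sample_design(config: SimConfig) -> pd.DataFrame:
    """Two clinal endpoints (FL, ME) plus n_pairs spring-fall localities."""
    rows = [
        {"sample_id": "FL", "locality": "FL", "role": "clinal",
         "latitude": FL_LATITUDE, "pair_id": None},
        {"sample_id": "ME", "locality": "ME", "role": "clinal",
         "latitude": ME_LATITUDE, "pair_id": None},
    ]
    for i in range(1, config.n_pairs + 1):
        loc = f"loc{i:02d}"
        for role in ("spring", "fall"):
            rows.append(
                {"sample_id": f"{loc}_{role}", "locality": loc, "role": role,
                 "latitude": np.nan, "pair_id": loc}
            )
    return pd.DataFrame(rows)


def simulate_sample_freqs(
    snps: pd.DataFrame,
    design: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill per-sample focal-allele frequencies consistent with the betas.

    Clinal samples: base_freq + clinal_beta x (latitude - mean clinal
    latitude) + noise; spring/fall samples: base_freq +/- seasonal_beta/2
    + noise, with independent noise per sample and truncation to [0, 1].
    """
    if rng is None:
        rng = substream(config.seed, "freqs")
    if "base_freq" not in snps.columns:
        raise ConfigError("simulate_sample_freqs needs the base_freq column")
    out = snps.copy()
    f0 = snps["base_freq"].to_numpy()
    cb = snps["clinal_beta"].to_numpy()
    sb = snps["seasonal_beta"].to_numpy()
    clinal_lats = design.loc[design["role"] == "clinal", "latitude"]
    lat_ref = float(clinal_lats.mean()) if len(clinal_lats) else 0.0
    for row in design.itertuples(index=False):
        if row.role == "clinal":
            mean = f0 + cb * (row.latitude - lat_ref)
        elif row.role == "spring":
            mean = f0 + sb / 2
        else:  # fall
            mean = f0 - sb / 2
        noise = rng.normal(0, config.noise_sd, size=len(snps)) if config.noise_sd > 0 else 0.0
        out[FREQ_PREFIX + row.sample_id] = np.clip(mean + noise, 0.0, 1.0)
    return out


@dataclasses.dataclass
class SimulatedData:
    """A complete simulated input bundle for the pipeline."""

    snps: pd.DataFrame
    eqtls: pd.DataFrame
    de_sets: dict[str, DeGeneSet]
    design: pd.DataFrame
    ground_truth: GroundTruth
    config: SimConfig


def simulate_dataset(config: SimConfig, with_freqs: bool = True) -> SimulatedData:
    """Generate the full input bundle (SNPs, eQTLs, DE sets, design, freqs)."""
    genes = simulate_genes(config)
    de = simulate_de_sets(config, genes)
    snps, eqtls, truth = simulate_snps(config, genes=genes, de_sets=de)
    design = default_sample_design(config)
    if with_freqs:
        snps = simulate_sample_freqs(snps, design, config)
    return SimulatedData(
        snps=snps, eqtls=eqtls, de_sets=de[0], design=design,
        ground_truth=truth, config=config,
    )
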