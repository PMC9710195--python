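"""Odds-ratio enrichment of eQTLs for clinal or seasonal SNPs.

For a quantile threshold t, count eQTLs at/below t (A) and above t (B)
on the ranked p-value quantile scale, and the same for each of the 1000
matched control sets (C_k, D_k).  The odds ratio is OR_k = (A * D_k) /
(B * C_k); results report the mean log2 OR over control sets, a
confidence half-width of 1.96 x SD of the 1000 log2 ORs, and an
empirical p-value comparing the eQTL proportion S = A/(A+B) against the
control proportions S0_k = C_k/(C_k+D_k).

Ranked quantiles are computed once over the analysis universe (by
default the union of eQTLs and all matched candidate controls), with
ties sharing the maximum rank of their tie group, so "top 5%" denotes
the same cutoff for eQTLs and controls.  Zero cells are handled with
the Haldane-Anscombe correction (0.5 added to all four cells) and
flagged, keeping the 1000-set null at full size.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from ._streams import substream
from .errors import ConfigError, DataError
from .matched_controls import ControlSets, inversion_status_vector
from .resampling_stats import bonferroni_threshold, ci_half_width, empirical_p
from .tables_io import ARMS, SEX_CLASSES, InversionDef

DEFAULT_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.25, 0.5)
TOP_QUANTILE = 0.05
BLOCK_WINDOW = 10_000
BLOCK_REPS = 100

MODELS = ("clinal", "seasonal")


def validate_grid(grid: Sequence[float]) -> tuple[float, ...]:
    grid = tuple(float(t) for t in grid)
    if not grid:
        raise ConfigError("quantile grid must be non-empty")
    if any(not 0 < t <= 0.5 for t in grid):
        raise ConfigError(f"quantile thresholds must lie in (0, 0.5]: {grid}")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ConfigError(f"quantile grid must be strictly increasing: {grid}")
    return grid


def rank_quantile(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Ranked p-value quantiles in (0, 1]: rank/n with max-rank tie sharing."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DataError("rank_quantile: empty input")
    if not np.isfinite(p).all() or np.any(p <= 0) or np.any(p > 1):
        raise DataError("rank_quantile: p-values must be finite and in (0, 1]")
    return scipy.stats.rankdata(p, method="max") / p.size


@dataclasses.dataclass(frozen=True)
class ContingencyCounts:
    """Counts at a threshold: A/B eQTLs at-or-below/above, C/D controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("contingency counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise DataError("odds ratio undefined: an empty margin (A+B or C+D is 0)")


class OddsRatio(NamedTuple):
    odds_ratio: float
    log2_odds_ratio: float
    corrected: bool  # Haldane-Anscombe 0.5 applied because of a zero cell


def odds_ratio(counts: ContingencyCounts) -> OddsRatio:
    """OR = AD/BC with the Haldane-Anscombe correction on zero cells."""
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    return OddsRatio(odds_ratio=float(orr), log2_odds_ratio=float(np.log2(orr)), corrected=corrected)


def _log2_or_sets(a: int, b: int, c: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, bool]:
    """Vectorized log2 OR of fixed eQTL counts against per-set control counts."""
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    af = np.where(zero, a + 0.5, a).astype(float)
    bf = np.where(zero, b + 0.5, b).astype(float)
    cf = np.where(zero, c + 0.5, c).astype(float)
    df = np.where(zero, d + 0.5, d).astype(float)
    return np.log2((af * df) / (bf * cf)), bool(np.any(zero))


@dataclasses.dataclass
class EnrichmentResult:
    """One enrichment test: a stratum x sex class x quantile threshold."""

    stratum: str                 # "genome" | "genome_block" | arm | "<inv>:<region>" | "gene:<id>"
    sex_class: str               # one of SEX_CLASSES or "all"
    model: str                   # clinal | seasonal
    quantile_threshold: float
    n_eqtls: int
    a_count: int                 # eQTLs at/below the threshold
    log2_or_mean: float
    ci_half_width: float
    emp_p: float
    adj_significant: bool
    corrected: bool              # any control set needed the zero-cell correction
    testable: bool = True
    null_log2_or: np.ndarray | None = dataclasses.field(default=None, repr=False)


def _quantiles_for_universe(
    snps: pd.DataFrame,
    control_sets: ControlSets,
    model: str,
    universe: str = "union",
) -> np.ndarray:
    """Per-row ranked quantiles over the analysis universe (NaN elsewhere).

    universe="union": eQTLs plus every matched candidate control (default);
    universe="all": every SNP in the table.
    """
    if model not in MODELS:
        raise ConfigError(f"model must be one of {MODELS}, got {model!r}")
    p = snps[f"{model}_p"].to_numpy(dtype=float)
    if universe == "all":
        return rank_quantile(p)
    if universe != "union":
        raise ConfigError(f"universe must be 'union' or 'all', got {universe!r}")
    rows = np.union1d(control_sets.eqtl_idx, control_sets.candidate_idx)
    q = np.full(len(snps), np.nan)
    q[rows] = rank_quantile(p[rows])
    return q


def _sex_class_rows(eqtls: pd.DataFrame, control_sets: ControlSets,
                    sex_class: str) -> np.ndarray:
    """Rows of the control matrix for the distinct eQTL SNPs of a sex class."""
    if sex_class == "all":
        ids = eqtls["snp_id"].drop_duplicates()
    else:
        ids = eqtls.loc[eqtls["sex_class"] == sex_class, "snp_id"].drop_duplicates()
    return control_sets.rows_for(ids.to_numpy(dtype=object), skip_missing=True)


def _enrich_one(
    below: np.ndarray,
    cs_rows: np.ndarray,
    control_sets: ControlSets,
    stratum: str,
    sex_class: str,
    model: str,
    threshold: float,
    adjusted_alpha: float,
) -> EnrichmentResult:
    """Enrichment of one eQTL subset (rows of the control matrix) at one cutoff."""
    n_e = cs_rows.size
    if n_e == 0:
        return EnrichmentResult(
            stratum=stratum, sex_class=sex_class, model=model,
            quantile_threshold=threshold, n_eqtls=0, a_count=0,
            log2_or_mean=np.nan, ci_half_width=np.nan, emp_p=np.nan,
            adj_significant=False, corrected=False, testable=False,
        )
    a = int(below[control_sets.eqtl_idx[cs_rows]].sum())
    b = n_e - a
    c = below[control_sets.control_idx[cs_rows]].sum(axis=0).astype(np.int64)
    d = n_e - c
    log2_ors, corrected = _log2_or_sets(a, b, c, d)
    summary = ci_half_width(log2_ors)
    ep = empirical_p(a / n_e, c / n_e)
    return EnrichmentResult(
        stratum=stratum, sex_class=sex_class, model=model,
        quantile_threshold=threshold, n_eqtls=n_e, a_count=a,
        log2_or_mean=summary.mean, ci_half_width=summary.half_width,
        emp_p=ep.emp_p, adj_significant=bool(ep.emp_p <= adjusted_alpha),
        corrected=corrected, null_log2_or=log2_ors,
    )


def genome_wide_enrichment(
    snps: pd.DataFrame,
    eqtls: pd.DataFrame,
    control_sets: ControlSets,
    model: str,
    grid: Sequence[float] = DEFAULT_GRID,
    sex_classes: Sequence[str] = SEX_CLASSES,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
    universe: str = "union",
) -> list[EnrichmentResult]:
    """Genome-wide enrichment over a quantile grid, per sex class.

    The Bonferroni family defaults to every (sex class x threshold) test
    in this run; pass ``bonferroni_m`` to pin it to a fixed family size.
    """
    grid = validate_grid(grid)
    q = _quantiles_for_universe(snps, control_sets, model, universe)
    m = bonferroni_m if bonferroni_m is not None else len(grid) * len(sex_classes)
    adj = bonferroni_threshold(alpha, m).threshold
    results = []
    for sex_class in sex_classes:
        cs_rows = _sex_class_rows(eqtls, control_sets, sex_class)
        for t in grid:
            below = q <= t  # NaN (outside universe) compares False
            results.append(
                _enrich_one(below, cs_rows, control_sets, "genome",
                            sex_class, model, t, adj)
            )
    return results


def block_downsample(
    eqtl_snps: pd.DataFrame,
    rng: np.random.Generator,
    window: int = BLOCK_WINDOW,
) -> np.ndarray:
    """One replicate of per-window thinning: keep one eQTL per non-
    overlapping ``window``-bp window per arm (windows anchored at
    coordinate 1), chosen uniformly.  Returns the retained snp_ids.
    """
    df = eqtl_snps[["snp_id", "arm", "pos"]].copy()
    df["win"] = (df["pos"].to_numpy() - 1) // window
    order = rng.permutation(len(df))
    kept = df.iloc[order].drop_duplicates(subset=["arm", "win"], keep="first")
    return kept["snp_id"].to_numpy(dtype=object)


def block_downsampled_enrichment(
    snps: pd.DataFrame,
    eqtls: pd.DataFrame,
    control_sets: ControlSets,
    model: str,
    grid: Sequence[float] = DEFAULT_GRID,
    sex_classes: Sequence[str] = SEX_CLASSES,
    window: int = BLOCK_WINDOW,
    n_rep: int = BLOCK_REPS,
    seed: int = 0,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
    universe: str = "union",
) -> list[EnrichmentResult]:
    """Enrichment after linkage thinning, aggregated over replicates.

    Each replicate retains one eQTL per 10-kb window and reruns the
    genome-wide analysis on the retained eQTLs and their control
    columns; the ranking universe (hence the quantile cutoffs) is held
    fixed across replicates.  Reported per (sex class, threshold):
    across-replicate mean of the per-replicate mean log2 OR, with a
    half-width of 1.96 x SD of the per-replicate means and the median
    per-replicate empirical p-value.
    """
    grid = validate_grid(grid)
    rng = substream(seed, "block_downsample")
    q = _quantiles_for_universe(snps, control_sets, model, universe)
    m = bonferroni_m if bonferroni_m is not None else len(grid) * len(sex_classes)
    adj = bonferroni_threshold(alpha, m).threshold
    eqtl_snps = snps.loc[snps["is_eqtl"], ["snp_id", "arm", "pos"]]

    per_rep: dict[tuple[str, float], list[EnrichmentResult]] = {
        (s, t): [] for s in sex_classes for t in grid
    }
    for _ in range(n_rep):
        retained = set(block_downsample(eqtl_snps, rng, window))
        for sex_class in sex_classes:
            cs_rows = _sex_class_rows(eqtls, control_sets, sex_class)
            keep = np.array(
                [sid in retained for sid in control_sets.eqtl_ids[cs_rows]], dtype=bool
            )
            cs_keep = cs_rows[keep]
            for t in grid:
                below = q <= t
                per_rep[(sex_class, t)].append(
                    _enrich_one(below, cs_keep, control_sets, "genome_block",
                                sex_class, model, t, adj)
                )
    out = []
    for (sex_class, t), reps in per_rep.items():
        testable = [r for r in reps if r.testable]
        if not testable:
            out.append(reps[0])
            continue
        means = np.array([r.log2_or_mean for r in testable])
        emps = np.array([r.emp_p for r in testable])
        med_emp = float(np.median(emps))
        out.append(
            EnrichmentResult(
                stratum="genome_block", sex_class=sex_class, model=model,
                quantile_threshold=t,
                n_eqtls=int(np.mean([r.n_eqtls for r in testable])),
                a_count=int(np.mean([r.a_count for r in testable])),
                log2_or_mean=float(means.mean()),
                ci_half_width=float(1.96 * means.std(ddof=1)) if means.size > 1 else 0.0,
                emp_p=med_emp,
                adj_significant=bool(med_emp <= adj),
                corrected=any(r.corrected for r in testable),
            )
        )
    return out


def partitioned_enrichment(
    snps: pd.DataFrame,
    eqtls: pd.DataFrame,
    control_sets: ControlSets,
    inversions: Sequence[InversionDef],
    model: str,
    threshold: float = TOP_QUANTILE,
    sex_classes: Sequence[str] = SEX_CLASSES,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
    universe: str = "union",
) -> list[EnrichmentResult]:
    """Enrichment at the top quantile, per whole arm and per inversion region.

    Strata are each arm as a whole, and for each inversion its
    breakpoint / inside / outside partition of the arm.  Controls are
    matched on the joint inversion-status tuple, so an eQTL's controls
    lie in the same region by construction and the stratum analysis
    simply restricts to the stratum's eQTL rows.  A stratum with zero
    eQTLs is reported as not testable, never an error.
    """
    q = _quantiles_for_universe(snps, control_sets, model, universe)
    below = q <= threshold
    arm_of = pd.Series(snps["arm"].to_numpy(), index=snps["snp_id"]).to_dict()
    eqtl_arm = np.array([arm_of[s] for s in control_sets.eqtl_ids], dtype=object)
    eqtl_pos = snps["pos"].to_numpy()[control_sets.eqtl_idx]

    strata: list[tuple[str, np.ndarray]] = []
    for arm in ARMS:
        strata.append((arm, np.flatnonzero(eqtl_arm == arm)))
    for inv in inversions:
        on_arm = np.flatnonzero(eqtl_arm == inv.arm)
        status = inversion_status_vector(eqtl_pos[on_arm], inv)
        for region in ("breakpoint", "inside", "outside"):
            strata.append((f"{inv.name}:{region}", on_arm[status == region]))

    m = bonferroni_m if bonferroni_m is not None else len(strata) * len(sex_classes)
    adj = bonferroni_threshold(alpha, m).threshold
    results = []
    for name, stratum_rows in strata:
        for sex_class in sex_classes:
            cs_rows = np.intersect1d(
                stratum_rows, _sex_class_rows(eqtls, control_sets, sex_class)
            )
            results.append(
                _enrich_one(below, cs_rows, control_sets, name, sex_class,
                            model, threshold, adj)
            )
    return results


@dataclasses.dataclass
class GeneExcessSummary:
    """Excess of enriched over depleted genes among significant gene tests."""

    n_tested: int            # genes with >= 1 eQTL at/below the cutoff
    n_significant: int       # emp_p <= alpha
    n_enriched: int          # significant with mean log2 OR > 0
    proportion_enriched: float
    binomial_p: float        # two-sided exact test of the proportion vs 0.5


def gene_enrichment(
    snps: pd.DataFrame,
    eqtls: pd.DataFrame,
    control_sets: ControlSets,
    model: str,
    threshold: float = TOP_QUANTILE,
    sex_classes: Sequence[str] = SEX_CLASSES,
    alpha: float = 0.05,
    universe: str = "union",
) -> tuple[list[EnrichmentResult], GeneExcessSummary]:
    """Per-gene enrichment at the top quantile, plus the excess summary.

    Only genes with at least one eQTL at/below the cutoff are tested.
    The excess summary reports, among genes significant at
    emp_p <= ``alpha``, the proportion enriched (mean log2 OR > 0) with
    a two-sided exact binomial test against 0.5.
    """
    q = _quantiles_for_universe(snps, control_sets, model, universe)
    below = q <= threshold
    sub = eqtls[eqtls["sex_class"].isin(sex_classes)]
    results = []
    for gene, grp in sub.groupby("gene_id", sort=True):
        cs_rows = control_sets.rows_for(
            grp["snp_id"].drop_duplicates().to_numpy(dtype=object), skip_missing=True
        )
        if cs_rows.size == 0:
            continue
        res = _enrich_one(below, cs_rows, control_sets, f"gene:{gene}", "all",
                          model, threshold, alpha)
        if res.a_count >= 1:
            results.append(res)
    sig = [r for r in results if r.emp_p <= alpha]
    n_enriched = sum(r.log2_or_mean > 0 for r in sig)
    if sig:
        test = scipy.stats.binomtest(n_enriched, len(sig), 0.5, alternative="two-sided")
        prop, bp = n_enriched / len(sig), test.pvalue
    else:
        prop, bp = np.nan, np.nan
    summary = GeneExcessSummary(
        n_tested=len(results),
        n_significant=len(sig),
        n_enriched=int(n_enriched),
        proportion_enriched=float(prop),
        binomial_p=float(bp),
    )
    return results, summary
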