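"""Directional concordance of eQTL allele-frequency change.

For an eQTL linked to a differentially expressed (DE) gene, the
predicted direction of frequency change is the sign product

    pi = effect_sign x de_sign x sigma(de_label, axis)

where effect_sign is +1 if the focal allele upregulates the gene,
de_sign is +1 if the gene is more highly expressed in the north (or
upregulated by the treatment), and sigma encodes the comparison-axis
hypothesis: genes up in the north / induced by chill-coma, starvation
or constant low temperature have their upregulating alleles expected
more common in the north and in the spring (sigma = +1); heat-shock and
high-temperature genes the converse (sigma = -1).  Spring is the
positive pole of the seasonal axis, mirroring north.

The observed direction omega is the sign of the clinal or seasonal
regression coefficient (cross-population comparisons) or of a pairwise
frequency difference (Maine minus Florida; spring minus fall within a
locality).  The concordance score is the fraction of scored records
with pi x omega = +1 among those with omega != 0; records with
omega = 0 are excluded from the denominator and counted separately.
The null distribution replaces each eQTL's omega with that of its
matched controls (which inherit the eQTL's pi), one score per control
set.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .matched_controls import ControlSets
from .resampling_stats import bonferroni_threshold, empirical_p
from .tables_io import FREQ_PREFIX, DeGeneSet

log = logging.getLogger(__name__)

#: de_label -> (sigma_clinal, sigma_seasonal); +1 maps "upregulated gene"
#: to "up-allele more common northward / in spring".
DIRECTION_HYPOTHESES: Mapping[str, tuple[int, int]] = {
    "latitudinal": (1, 1),
    "chill_coma": (1, 1),
    "starvation": (1, 1),
    "low_temp": (1, 1),
    "heat_shock": (-1, -1),
    "high_temp": (-1, -1),
}

#: default eQTL sex classes per DE set: the latitudinal set was assayed
#: in females only (female-specific + non-sex-biased eQTLs); treatment
#: sets use non-sex-biased eQTLs.
DEFAULT_SEX_CLASSES: Mapping[str, tuple[str, ...]] = {
    "latitudinal": ("female", "non_sex_biased"),
    "chill_coma": ("non_sex_biased",),
    "starvation": ("non_sex_biased",),
    "low_temp": ("non_sex_biased",),
    "heat_shock": ("non_sex_biased",),
    "high_temp": ("non_sex_biased",),
}

AXES = ("clinal", "seasonal")
VERDICTS = ("concordant", "discordant", "neutral")
DOMINANCE_FRACTION = 0.5


def predicted_sign(effect_sign: int, de_sign: int, de_label: str, axis: str) -> int:
    """pi = effect_sign x de_sign x sigma(de_label, axis); axis is clinal|seasonal."""
    if de_label not in DIRECTION_HYPOTHESES:
        raise ConfigError(f"unknown DE label {de_label!r}")
    if axis not in AXES:
        raise ConfigError(f"axis must be one of {AXES}, got {axis!r}")
    if effect_sign not in (1, -1) or de_sign not in (1, -1):
        raise DataError("effect_sign and de_sign must be +1 or -1")
    sigma = DIRECTION_HYPOTHESES[de_label][AXES.index(axis)]
    return effect_sign * de_sign * sigma


@dataclasses.dataclass
class ConcordanceResult:
    """One concordance test: a DE set against one comparison axis."""

    comparison: str              # crosspop_clinal | crosspop_seasonal | fl_me | locality:<pair>
    de_label: str
    sex_classes: tuple[str, ...]
    score: float                 # fraction concordant in [0, 1]
    n_eqtls: int                 # records entering the score (omega != 0)
    n_zero: int                  # records dropped for omega == 0
    emp_p: float
    verdict: str
    adjusted_alpha: float
    testable: bool = True
    null_scores: np.ndarray | None = dataclasses.field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.testable and not 0 <= self.score <= 1:
            raise DataError(f"concordance score out of [0, 1]: {self.score}")


def _verdict(score: float, emp_p: float, adjusted_alpha: float) -> str:
    if emp_p <= adjusted_alpha and score > 0.5:
        return "concordant"
    if emp_p <= adjusted_alpha and score < 0.5:
        return "discordant"
    return "neutral"


def _not_testable(comparison, de_label, sex_classes, adjusted_alpha, n_zero=0):
    return ConcordanceResult(
        comparison=comparison, de_label=de_label, sex_classes=tuple(sex_classes),
        score=np.nan, n_eqtls=0, n_zero=n_zero, emp_p=np.nan, verdict="neutral",
        adjusted_alpha=adjusted_alpha, testable=False,
    )


def direction_records(
    eqtls: pd.DataFrame,
    de_set: DeGeneSet,
    axis: str,
    sex_classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Scored records for one DE set: snp_id, gene_id, predicted sign pi.

    An eQTL linked to several DE genes contributes one record per
    (gene, set) membership.
    """
    if sex_classes is None:
        sex_classes = DEFAULT_SEX_CLASSES[de_set.label]
    sub = eqtls[
        eqtls["gene_id"].isin(de_set.entries)
        & eqtls["sex_class"].isin(list(sex_classes))
    ].copy()
    if sub.empty:
        return sub.assign(pi=pd.Series(dtype=int))
    de_sign = sub["gene_id"].map(de_set.entries).astype(int)
    sigma = DIRECTION_HYPOTHESES[de_set.label][AXES.index(axis)]
    sub["pi"] = sub["effect_sign"].astype(int) * de_sign * sigma
    return sub


def _score(pi: np.ndarray, omega: np.ndarray) -> tuple[float, int, int]:
    """Concordance score, scored count, zero-omega count."""
    nonzero = omega != 0
    n = int(nonzero.sum())
    if n == 0:
        return np.nan, 0, int(pi.size)
    conc = int(((pi * omega) == 1)[nonzero].sum())
    return conc / n, n, int(pi.size) - n


def _null_scores(pi: np.ndarray, omega_all: np.ndarray, cs_rows: np.ndarray,
                 control_sets: ControlSets) -> np.ndarray:
    """Per-set control scores: each control inherits its eQTL's pi."""
    omega_ctrl = omega_all[control_sets.control_idx[cs_rows]]  # (n_records, n_sets)
    nonzero = omega_ctrl != 0
    conc = (pi[:, None] * omega_ctrl) == 1
    denom = nonzero.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, conc.sum(axis=0) / np.maximum(denom, 1), np.nan)


def _concordance(
    records: pd.DataFrame,
    omega_all: np.ndarray,
    control_sets: ControlSets,
    comparison: str,
    de_label: str,
    sex_classes: Sequence[str],
    adjusted_alpha: float,
) -> ConcordanceResult:
    records = records[records["snp_id"].isin(control_sets.eqtl_ids)]
    if records.empty:
        return _not_testable(comparison, de_label, sex_classes, adjusted_alpha)
    cs_rows = control_sets.rows_for(records["snp_id"].to_numpy(dtype=object))
    pi = records["pi"].to_numpy(dtype=np.int64)
    omega = omega_all[control_sets.eqtl_idx[cs_rows]]
    score, n, n_zero = _score(pi, omega)
    if n == 0:
        return _not_testable(comparison, de_label, sex_classes, adjusted_alpha, n_zero)
    null = _null_scores(pi, omega_all, cs_rows, control_sets)
    null = null[np.isfinite(null)]
    ep = empirical_p(score, null)
    return ConcordanceResult(
        comparison=comparison, de_label=de_label, sex_classes=tuple(sex_classes),
        score=score, n_eqtls=n, n_zero=n_zero, emp_p=ep.emp_p,
        verdict=_verdict(score, ep.emp_p, adjusted_alpha),
        adjusted_alpha=adjusted_alpha, null_scores=null,
    )


def _omega_from_betas(snps: pd.DataFrame, model: str) -> np.ndarray:
    return np.sign(snps[f"{model}_beta"].to_numpy(dtype=float)).astype(np.int64)


def concordance_crosspop(
    snps: pd.DataFrame,
    eqtls: pd.DataFrame,
    de_set: DeGeneSet,
    control_sets: ControlSets,
    model: str,
    sex_classes: Sequence[str] | None = None,
    alpha: float = 0.05,
    bonferroni_m: int = 1,
) -> ConcordanceResult:
    """Concordance against the cross-population clinal or seasonal model.

    omega is the sign of the model coefficient: positive means the focal
    allele is more common at higher latitude (clinal) or in spring
    (seasonal).
    """
    if model not in AXES:
        raise ConfigError(f"model must be one of {AXES}, got {model!r}")
    if sex_classes is None:
        sex_classes = DEFAULT_SEX_CLASSES[de_set.label]
    adj = bonferroni_threshold(alpha, bonferroni_m).threshold
    records = direction_records(eqtls, de_set, model, sex_classes)
    omega_all = _omega_from_betas(snps, model)
    return _concordance(records, omega_all, control_sets, f"crosspop_{model}",
                        de_set.label, sex_classes, adj)


def _freq_column(snps: pd.DataFrame, sample_id: str) -> np.ndarray:
    col = FREQ_PREFIX + sample_id
    if col not in snps.columns:
        raise ConfigError(f"SNP table lacks frequency column {col!r}")
    return snps[col].to_numpy(dtype=float)


def _omega_from_freq_diff(snps: pd.DataFrame, high_id: str, low_id: str) -> np.ndarray:
    diff = _freq_column(snps, high_id) - _freq_column(snps, low_id)
    omega = np.sign(diff)
    omega[~np.isfinite(diff)] = 0  # missing frequency: drop from the score
    n_missing = int((~np.isfinite(diff)).sum())
    if n_missing:
        log.info("pairwise comparison %s-%s: %d SNP(s) without frequencies dropped",
                 high_id, low_id, n_missing)
    return omega.astype(np.int64)


def resolve_comparison(comparison: str, design: pd.DataFrame) -> tuple[str, str, str]:
    """Map a comparison name to (axis, positive-pole sample, negative-pole sample).

    fl_me: the two clinal samples, north (max latitude) minus south;
    locality:<pair_id>: that locality's spring minus fall sample.
    """
    if comparison == "fl_me":
        clinal = design[design["role"] == "clinal"]
        if len(clinal) < 2:
            raise ConfigError("fl_me comparison needs two clinal endpoint samples")
        north = clinal.loc[clinal["latitude"].idxmax(), "sample_id"]
        south = clinal.loc[clinal["latitude"].idxmin(), "sample_id"]
        return "clinal", north, south
    if comparison.startswith("locality:"):
        pair = comparison.split(":", 1)[1]
        grp = design[(design["pair_id"] == pair) & design["role"].isin(["spring", "fall"])]
        if len(grp) != 2:
            raise ConfigError(f"locality {pair!r} absent from the sample design")
        spring = grp.loc[grp["role"] == "spring", "sample_id"].iloc[0]
        fall = grp.loc[grp["role"] == "fall", "sample_id"].iloc[0]
        return "seasonal", spring, fall
    raise ConfigError(f"unknown comparison {comparison!r}")


def concordance_pairwise(
    snps: pd.DataFrame,
    eqtls: pd.DataFrame,
    de_set: DeGeneSet,
    control_sets: ControlSets,
    comparison: str,
    design: pd.DataFrame,
    sex_classes: Sequence[str] | None = None,
    alpha: float = 0.05,
    bonferroni_m: int = 1,
) -> ConcordanceResult:
    """Concordance against a pairwise allele-frequency difference.

    omega = sign(freq_north - freq_south) for fl_me, or
    sign(freq_spring - freq_fall) for a locality pair; zero differences
    are excluded from the denominator.
    """
    if sex_classes is None:
        sex_classes = DEFAULT_SEX_CLASSES[de_set.label]
    adj = bonferroni_threshold(alpha, bonferroni_m).threshold
    axis, pos_sample, neg_sample = resolve_comparison(comparison, design)
    records = direction_records(eqtls, de_set, axis, sex_classes)
    omega_all = _omega_from_freq_diff(snps, pos_sample, neg_sample)
    return _concordance(records, omega_all, control_sets, comparison,
                        de_set.label, sex_classes, adj)


@dataclasses.dataclass
class GeneConcordance:
    gene_id: str
    de_label: str
    axis: str
    score: float
    n_eqtls: int
    n_zero: int
    dominant: bool  # this gene holds more than DOMINANCE_FRACTION of the set's records


def gene_concordance(
    snps: pd.DataFrame,
    eqtls: pd.DataFrame,
    de_set: DeGeneSet,
    control_sets: ControlSets,
    model: str,
    sex_classes: Sequence[str] | None = None,
    dominance_fraction: float = DOMINANCE_FRACTION,
) -> pd.DataFrame:
    """Per-gene concordance scores on a cross-population axis.

    Flags genes holding more than ``dominance_fraction`` of the set's
    scored eQTLs, the situation in which a pooled score mostly reflects
    a single locus.  The pooled score is, by construction, the
    eQTL-count-weighted mean of the per-gene scores; this identity is
    asserted on every call.
    """
    records = direction_records(eqtls, de_set, model, sex_classes)
    records = records[records["snp_id"].isin(control_sets.eqtl_ids)]
    omega_all = _omega_from_betas(snps, model)
    rows = []
    total_scored = 0
    for gene, grp in records.groupby("gene_id", sort=True):
        cs_rows = control_sets.rows_for(grp["snp_id"].to_numpy(dtype=object))
        omega = omega_all[control_sets.eqtl_idx[cs_rows]]
        score, n, n_zero = _score(grp["pi"].to_numpy(dtype=np.int64), omega)
        total_scored += n
        rows.append([gene, de_set.label, model, score, n, n_zero])
    df = pd.DataFrame(rows, columns=["gene_id", "de_label", "axis", "score",
                                     "n_eqtls", "n_zero"])
    df["dominant"] = (df["n_eqtls"] > dominance_fraction * total_scored) & (total_scored > 0)
    # exact identity: pooled score == weighted mean of per-gene scores
    scored = df[df["n_eqtls"] > 0]
    if total_scored > 0:
        pooled = float((scored["score"] * scored["n_eqtls"]).sum() / total_scored)
        cs_rows = control_sets.rows_for(records["snp_id"].to_numpy(dtype=object))
        direct, _, _ = _score(records["pi"].to_numpy(dtype=np.int64),
                              omega_all[control_sets.eqtl_idx[cs_rows]])
        assert abs(pooled - direct) < 1e-12, "pooled/per-gene score mismatch"
    return df
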