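"""Matched-control construction.

Every eQTL is compared to non-eQTL SNPs matched on three covariates:
chromosomal arm, expected heterozygosity (binned by 0.05) and inversion
status.  Inversion status is the joint tuple over all inversions on the
SNP's arm, each element one of breakpoint / inside / outside, where
"breakpoint" means within ``margin`` (default 0.5 Mb) of either
inversion endpoint and "inside" excludes the breakpoint zones.

For each eQTL we draw ``n_sets`` (default 1000) matched controls;
column k across eQTLs forms control set k, so every control set has
exactly one control per eQTL and the per-eQTL matching structure is
preserved across sets.  Sampling is without replacement within an
eQTL's list when the candidate pool holds at least ``n_sets`` SNPs,
with replacement (and a warning) otherwise.  The same control SNP may
serve different eQTLs.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._streams import substream
from .errors import ConfigError, DataError
from .tables_io import InversionDef, write_table

log = logging.getLogger(__name__)

HET_BIN_WIDTH = 0.05
N_HET_BINS = 10

STATUS_BREAKPOINT = "breakpoint"
STATUS_INSIDE = "inside"
STATUS_OUTSIDE = "outside"


def inversion_status(pos: int, inv: InversionDef) -> str:
    """Classify a position against one inversion.

    breakpoint: within ``inv.margin`` of either endpoint (inclusive,
    so pos == start or pos == end is breakpoint at distance 0);
    inside: strictly between the endpoints and not breakpoint;
    outside: anywhere else on the arm.
    """
    if pos < 1:
        raise DataError(f"inversion_status: pos must be >= 1, got {pos}")
    if abs(pos - inv.start) <= inv.margin or abs(pos - inv.end) <= inv.margin:
        return STATUS_BREAKPOINT
    if inv.start < pos < inv.end:
        return STATUS_INSIDE
    return STATUS_OUTSIDE


def inversion_status_vector(pos: np.ndarray, inv: InversionDef) -> np.ndarray:
    """Vectorized :func:`inversion_status` over an array of positions."""
    pos = np.asarray(pos)
    near_bp = (np.abs(pos - inv.start) <= inv.margin) | (
        np.abs(pos - inv.end) <= inv.margin
    )
    inside = (pos > inv.start) & (pos < inv.end) & ~near_bp
    out = np.full(pos.shape, STATUS_OUTSIDE, dtype=object)
    out[inside] = STATUS_INSIDE
    out[near_bp] = STATUS_BREAKPOINT
    return out


def het_bin(het) -> np.ndarray | int:
    """0.05-wide heterozygosity bin index in {0..9}; het == 0.5 -> bin 9."""
    arr = np.asarray(het, dtype=float)
    if np.any((arr < 0) | (arr > 0.5)):
        raise DataError("het_bin: heterozygosity must lie in [0, 0.5]")
    bins = np.minimum(np.floor(arr / HET_BIN_WIDTH).astype(int), N_HET_BINS - 1)
    return int(bins) if np.isscalar(het) or arr.ndim == 0 else bins


def match_keys(snps: pd.DataFrame, inversions: Sequence[InversionDef]) -> pd.Series:
    """Per-SNP matching key: arm | het bin | joint inversion-status tuple.

    The status tuple covers, in listed order, every inversion on the
    SNP's arm; arms without inversions contribute an empty tuple.
    Returned as strings so grouping is cheap and keys are printable.
    """
    bins = het_bin(snps["het"].to_numpy())
    key = snps["arm"].astype(str) + "|" + pd.Series(bins, index=snps.index).astype(str)
    for inv in inversions:
        on_arm = snps["arm"] == inv.arm
        status = np.full(len(snps), "", dtype=object)
        status[on_arm.to_numpy()] = inversion_status_vector(
            snps.loc[on_arm, "pos"].to_numpy(), inv
        )
        tail = pd.Series(status, index=snps.index)
        key = key.where(~on_arm, key + "|" + inv.name + ":" + tail)
    key.name = "match_key"
    return key


@dataclasses.dataclass
class ControlSets:
    """Matched controls for a panel: one row per eQTL, one column per set.

    ``control_idx[i, k]`` is the positional row index (into the SNP
    table the sets were built from) of the k-th control of eQTL i.
    ``eqtl_idx`` holds the eQTL rows in the same order as ``eqtl_ids``.
    ``candidate_idx`` lists every non-eQTL row whose match key is
    occupied by at least one eQTL (the candidate pool, which together
    with the eQTLs forms the default ranking universe downstream).
    """

    eqtl_ids: np.ndarray            # (n_eqtls,) str
    eqtl_idx: np.ndarray            # (n_eqtls,) int row positions
    control_idx: np.ndarray         # (n_eqtls, n_sets) int row positions
    candidate_idx: np.ndarray       # sorted row positions of all candidates
    pool_sizes: np.ndarray          # (n_eqtls,) candidate-pool size per eQTL
    n_sets: int
    seed: int | None
    with_replacement: np.ndarray    # (n_eqtls,) bool, pool < n_sets
    snp_ids: np.ndarray             # snp_id of every row of the source table

    def __post_init__(self) -> None:
        self._row_of = {s: i for i, s in enumerate(self.eqtl_ids)}

    @property
    def n_eqtls(self) -> int:
        return len(self.eqtl_ids)

    def rows_for(self, snp_ids: Sequence[str], skip_missing: bool = False) -> np.ndarray:
        """Rows of ``control_idx`` corresponding to the given eQTL snp_ids.

        With ``skip_missing`` eQTLs without control sets (dropped for an
        empty candidate pool) are silently omitted.
        """
        if skip_missing:
            return np.array(
                [self._row_of[s] for s in snp_ids if s in self._row_of],
                dtype=np.int64,
            )
        try:
            return np.array([self._row_of[s] for s in snp_ids], dtype=np.int64)
        except KeyError as exc:
            raise DataError(f"no control sets for eQTL snp_id {exc.args[0]!r}") from None

    def to_long_frame(self) -> pd.DataFrame:
        """Long form (eqtl_id, set_index, control_id) for on-disk storage."""
        n_e, n_s = self.control_idx.shape
        return pd.DataFrame(
            {
                "eqtl_id": np.repeat(self.eqtl_ids, n_s),
                "set_index": np.tile(np.arange(n_s), n_e),
                "control_id": self.snp_ids[self.control_idx.ravel()],
            }
        )

    def write(self, path) -> None:
        write_table(self.to_long_frame(), path)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, snps: pd.DataFrame,
                        seed: int | None = None) -> "ControlSets":
        """Rebuild from the long form against the same SNP table."""
        snp_ids = snps["snp_id"].to_numpy(dtype=object)
        pos_of = {s: i for i, s in enumerate(snp_ids)}
        eqtl_ids = df["eqtl_id"].drop_duplicates().to_numpy(dtype=object)
        n_sets = int(df["set_index"].max()) + 1
        ctrl = np.empty((len(eqtl_ids), n_sets), dtype=np.int64)
        for i, eid in enumerate(eqtl_ids):
            sub = df[df["eqtl_id"] == eid].sort_values("set_index")
            ctrl[i] = [pos_of[c] for c in sub["control_id"]]
        eqtl_idx = np.array([pos_of[e] for e in eqtl_ids], dtype=np.int64)
        pool = np.full(len(eqtl_ids), -1, dtype=np.int64)
        return cls(
            eqtl_ids=eqtl_ids,
            eqtl_idx=eqtl_idx,
            control_idx=ctrl,
            candidate_idx=np.unique(ctrl),
            pool_sizes=pool,
            n_sets=n_sets,
            seed=seed,
            with_replacement=np.zeros(len(eqtl_ids), dtype=bool),
            snp_ids=snp_ids,
        )


def build_control_sets(
    snps: pd.DataFrame,
    inversions: Sequence[InversionDef],
    n_sets: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    on_empty: str = "error",
) -> ControlSets:
    """Draw ``n_sets`` matched controls for every distinct eQTL SNP.

    Deterministic given ``seed`` (match keys are processed in sorted
    order and eQTLs within a key in table order).  An occupied match key
    with no non-eQTL candidate raises ``DataError`` by default;
    ``on_empty="drop"`` instead excludes those eQTLs from the analysis
    with a warning (they are untestable against matched controls).
    """
    if on_empty not in ("error", "drop"):
        raise ConfigError(f"on_empty must be 'error' or 'drop', got {on_empty!r}")
    if n_sets <= 0:
        raise ConfigError(f"build_control_sets: n_sets must be positive, got {n_sets}")
    if rng is None:
        rng = substream(seed if seed is not None else 0, "matched_controls")

    keys = match_keys(snps, inversions).to_numpy(dtype=object)
    is_eqtl = snps["is_eqtl"].to_numpy(dtype=bool)
    snp_ids = snps["snp_id"].to_numpy(dtype=object)

    eqtl_rows = np.flatnonzero(is_eqtl)
    if eqtl_rows.size == 0:
        raise DataError("build_control_sets: the panel contains no eQTLs")

    cand_rows = np.flatnonzero(~is_eqtl)
    cand_by_key: dict[str, np.ndarray] = {
        k: grp.to_numpy()
        for k, grp in pd.Series(cand_rows).groupby(pd.Series(keys[cand_rows]))
    }

    n_e = eqtl_rows.size
    control_idx = np.empty((n_e, n_sets), dtype=np.int64)
    pool_sizes = np.empty(n_e, dtype=np.int64)
    with_repl = np.zeros(n_e, dtype=bool)
    row_of_eqtl = {r: i for i, r in enumerate(eqtl_rows)}
    used_candidates: list[np.ndarray] = []

    small_pools: list[tuple[str, int]] = []
    dropped = np.zeros(n_e, dtype=bool)
    eqtl_keys = pd.Series(eqtl_rows).groupby(pd.Series(keys[eqtl_rows]))
    for key in sorted(eqtl_keys.groups):
        rows = eqtl_keys.get_group(key).to_numpy()
        pool = cand_by_key.get(key)
        if pool is None or pool.size == 0:
            if on_empty == "drop":
                for r in rows:
                    dropped[row_of_eqtl[r]] = True
                log.warning(
                    "match key %s: no candidates; dropping %d eQTL(s)",
                    key, rows.size,
                )
                continue
            raise DataError(
                f"build_control_sets: no non-eQTL candidates for match key {key!r} "
                f"({rows.size} eQTL(s) affected)"
            )
        used_candidates.append(pool)
        out_rows = np.fromiter((row_of_eqtl[r] for r in rows), dtype=np.int64)
        pool_sizes[out_rows] = pool.size
        if pool.size >= n_sets:
            # independent without-replacement draw per eQTL: random keys, take first n_sets
            u = rng.random((rows.size, pool.size))
            order = np.argsort(u, axis=1)[:, :n_sets]
            control_idx[out_rows] = pool[order]
        else:
            with_repl[out_rows] = True
            small_pools.append((key, pool.size))
            log.debug(
                "match key %s: pool %d < n_sets %d, sampling with replacement",
                key, pool.size, n_sets,
            )
            picks = rng.integers(0, pool.size, size=(rows.size, n_sets))
            control_idx[out_rows] = pool[picks]

    if small_pools:
        examples = ", ".join(f"{k} ({m})" for k, m in small_pools[:3])
        warnings.warn(
            f"{len(small_pools)} match key(s) have candidate pools smaller than "
            f"n_sets={n_sets}; controls sampled with replacement there "
            f"(e.g. {examples})",
            stacklevel=2,
        )
        log.warning("%d match key(s) with pool < n_sets=%d", len(small_pools), n_sets)
    if dropped.any():
        warnings.warn(
            f"{int(dropped.sum())} eQTL(s) had no matched candidates and were "
            f"dropped (on_empty='drop')",
            stacklevel=2,
        )
        if dropped.all():
            raise DataError("build_control_sets: every eQTL lacked candidates")
    keep = ~dropped
    if not used_candidates:
        raise DataError("build_control_sets: no candidate pools were found")

    return ControlSets(
        eqtl_ids=snp_ids[eqtl_rows[keep]],
        eqtl_idx=eqtl_rows[keep],
        control_idx=control_idx[keep],
        candidate_idx=np.unique(np.concatenate(used_candidates)),
        pool_sizes=pool_sizes[keep],
        n_sets=n_sets,
        seed=seed,
        with_replacement=with_repl[keep],
        snp_ids=snp_ids,
    )


def permute_eqtl_labels(
    snps: pd.DataFrame,
    eqtls: pd.DataFrame,
    inversions: Sequence[InversionDef],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Self-null construction: shuffle eQTL labels within match-key strata.

    Within each (arm, het bin, inversion status) stratum the is_eqtl
    flags are randomly reassigned, and the eQTL annotations follow
    their flags (old eQTL i of a stratum becomes the i-th newly
    labelled SNP).  Matching covariates are preserved exactly, so any
    association between eQTL status and the model p-values is
    destroyed: downstream enrichment and concordance statistics are
    draws from their null distributions.
    """
    rng = substream(seed, "permute_eqtl_labels")
    keys = match_keys(snps, inversions).to_numpy(dtype=object)
    new_flags = np.zeros(len(snps), dtype=bool)
    mapping: dict[str, str] = {}
    snp_ids = snps["snp_id"].to_numpy(dtype=object)
    is_eqtl = snps["is_eqtl"].to_numpy(dtype=bool)
    for key in sorted(set(keys)):
        stratum = np.flatnonzero(keys == key)
        old = stratum[is_eqtl[stratum]]
        if old.size == 0:
            continue
        new = rng.choice(stratum, size=old.size, replace=False)
        new_flags[new] = True
        mapping.update(zip(snp_ids[old], snp_ids[new]))
    snps2 = snps.copy()
    snps2["is_eqtl"] = new_flags
    eqtls2 = eqtls.copy()
    eqtls2["snp_id"] = eqtls2["snp_id"].map(mapping)
    if eqtls2["snp_id"].isna().any():
        raise DataError("permute_eqtl_labels: annotation references an unknown eQTL")
    return snps2, eqtls2
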