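"""Screen statistics: sgRNA phenotypes, gene aggregation, hit calling.

The reporter phenotype of an sgRNA is its log2 enrichment in the
high-fluorescence bin over the low-fluorescence bin,

    value_i = log2[ (c_high,i + pc) / (T_high + P)  /
                    ((c_low,i  + pc) / (T_low  + P)) ],

with pseudocount ``pc`` (default 1 read) added before depth normalization
(``T`` = mapped reads of the bin, ``P = pc * n_sgRNAs``).  By default the
median raw phenotype of the negative-control sgRNAs is subtracted from every
value, so unequal bin depths do not shift the whole distribution.

A gene's phenotype rho is the mean over its sgRNAs; its p-value is a
two-sided Mann-Whitney U test of the gene's sgRNA phenotypes against the
full negative-control set; and its discriminant score is

    score = | (rho / sigma) * log10(p) |,

where sigma is the standard deviation of all evaluated phenotypes.  Genes
with score > tau (default 7) are screen hits.  Two readings of "all
evaluated phenotypes" are supported for sigma: the per-sgRNA phenotype SD
(``sd_mode='all_sgrnas'``, the default) and two gene-level alternatives
(``'all_genes'``, ``'control_pseudogenes'``); see docs/methods.md for the
calibration argument behind the default.

Negative-control sgRNAs are additionally grouped into disjoint
*pseudogenes* of gene size, scored exactly like genes: an empirical null
that rides through classification as the gray background population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .screen_model import BinCounts, LibraryDesign

logger = logging.getLogger("facscreen")

SD_MODES = ("all_sgrnas", "all_genes", "control_pseudogenes")

#: Prefix of pseudogene labels in gene-stats tables.
PSEUDOGENE_PREFIX = "pseudo_"


class StatsError(ValueError):
    pass


@dataclass
class StatsConfig:
    """Tunables of the hit-calling statistic (defaults follow the screen)."""

    pseudocount: float = 1.0        # reads added per sgRNA per bin
    min_reads: int = 0              # c_high + c_low filter; 0 = no filter
    center_on_controls: bool = True
    sd_mode: str = "all_sgrnas"
    tau: float = 7.0                # hit threshold on the discriminant score
    p_floor: float = 1e-16          # smallest reportable p before log10
    pseudogene_size: int = 5
    exact_limit: int = 200_000      # largest C(n+m, n) for exact Mann-Whitney
    seed: int = 0

    def validate(self) -> None:
        if self.tau <= 0:
            raise StatsError("tau must be > 0")
        if self.pseudocount < 0:
            raise StatsError("pseudocount must be >= 0")
        if self.sd_mode not in SD_MODES:
            raise StatsError(f"sd_mode must be one of {SD_MODES}")
        if not 0 < self.p_floor <= 1:
            raise StatsError("p_floor must be in (0, 1]")
        if self.pseudogene_size < 1:
            raise StatsError("pseudogene_size must be >= 1")


# ---------------------------------------------------------------------------
# sgRNA phenotypes


def sgrna_phenotypes(
    high: BinCounts,
    low: BinCounts,
    design: LibraryDesign,
    cfg: StatsConfig | None = None,
) -> pd.DataFrame:
    """Per-sgRNA reporter phenotypes for one arm.

    Returns a frame with columns ``arm, sgrna_id, value, passed_filter,
    is_control``, one row per library sgRNA (sgRNAs absent from a count
    table count as zero reads there).
    """
    cfg = cfg or StatsConfig()
    cfg.validate()
    if high.arm != low.arm:
        raise StatsError(f"arm mismatch: {high.arm} vs {low.arm}")
    if high.bin != "high" or low.bin != "low":
        raise StatsError("expected bins (high, low), got "
                         f"({high.bin}, {low.bin})")
    ids = design.sgrna_ids
    c_hi = high.counts.reindex(ids, fill_value=0).to_numpy(float)
    c_lo = low.counts.reindex(ids, fill_value=0).to_numpy(float)
    pc = cfg.pseudocount
    P = pc * design.n_sgrnas
    f_hi = (c_hi + pc) / (c_hi.sum() + P)
    f_lo = (c_lo + pc) / (c_lo.sum() + P)
    with np.errstate(divide="raise"):
        value = np.log2(f_hi / f_lo)

    is_control = design.df.is_control.to_numpy()
    if cfg.center_on_controls:
        if not is_control.any():
            raise StatsError("centering requested but library has no "
                             "negative-control sgRNAs")
        value = value - np.median(value[is_control])
    return pd.DataFrame({
        "arm": high.arm,
        "sgrna_id": ids,
        "value": value,
        "passed_filter": (c_hi + c_lo) >= cfg.min_reads,
        "is_control": is_control,
    })


# ---------------------------------------------------------------------------
# Mann-Whitney against the negative-control null


def mann_whitney_p(
    x: Sequence[float],
    y: Sequence[float],
    exact_limit: int = 200_000,
    p_floor: float = 1e-16,
) -> float:
    """Two-sided Mann-Whitney U p-value of sample ``x`` against ``y``.

    Uses the exact null distribution of U when the data are tie-free and
    the number of labelings C(n+m, n) is at most ``exact_limit``; otherwise
    the normal approximation with midranks and tie correction.  The result
    is clamped to ``[p_floor, 1]``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise StatsError("mann_whitney_p requires non-empty samples")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and comb(x.size + y.size, x.size) <= exact_limit:
        method = "exact"
    else:
        method = "asymptotic"
    p = mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    return float(np.clip(p, p_floor, 1.0))


# ---------------------------------------------------------------------------
# Pseudogenes and gene-level statistics


def control_pseudogenes(
    control_ids: Sequence[str], pseudogene_size: int, seed: int
) -> dict[str, list[str]]:
    """Partition control sgRNAs into disjoint gene-sized groups.

    A seeded permutation is split into consecutive chunks; the remainder
    (fewer than ``pseudogene_size`` controls) is dropped.
    """
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(np.asarray(control_ids, dtype=object)))
    n_groups = len(perm) // pseudogene_size
    return {
        f"{PSEUDOGENE_PREFIX}{i:03d}":
            perm[i * pseudogene_size:(i + 1) * pseudogene_size]
        for i in range(n_groups)
    }


def _score(rho: np.ndarray, sigma: float, p: np.ndarray,
           p_floor: float) -> np.ndarray:
    # "score = 0 when rho = 0" takes precedence over the degenerate-sigma
    # error: identical bins give all-zero rho and must score 0, not raise.
    p = np.clip(p, p_floor, 1.0)
    if sigma == 0:
        if np.any(rho != 0):
            raise StatsError("sigma = 0 with nonzero phenotypes: "
                             "degenerate input")
        return np.zeros_like(rho)
    return np.abs(rho / sigma * np.log10(p))


def gene_stats(
    phenotypes: pd.DataFrame,
    design: LibraryDesign,
    cfg: StatsConfig | None = None,
    include_pseudogenes: bool = True,
) -> pd.DataFrame:
    """Aggregate sgRNA phenotypes into per-gene statistics for one arm.

    Returns columns ``arm, gene, rho, p, score, hit, n_used, control``.
    ``control`` marks negative-control pseudogenes.  A gene whose sgRNAs all
    fail the read filter is reported with ``rho = NaN``, ``p = 1``,
    ``hit = False`` and ``n_used = 0``.
    """
    cfg = cfg or StatsConfig()
    cfg.validate()
    arm = phenotypes["arm"].iloc[0]
    ph = phenotypes.set_index("sgrna_id")
    ctrl = ph[ph.is_control & ph.passed_filter]
    if len(ctrl) == 0:
        raise StatsError("no negative-control sgRNA passed the read filter")
    ctrl_values = ctrl["value"].to_numpy()

    groups: dict[str, list[str]] = {g: design.gene_sgrnas(g)
                                    for g in design.genes}
    pseudo = control_pseudogenes(
        design.control_ids, cfg.pseudogene_size, cfg.seed
    ) if include_pseudogenes else {}

    def one_group(members: list[str]) -> tuple[float, float, int]:
        sub = ph.loc[members]
        used = sub[sub.passed_filter]
        if len(used) == 0:
            return np.nan, 1.0, 0
        values = used["value"].to_numpy()
        p = mann_whitney_p(values, ctrl_values,
                           exact_limit=cfg.exact_limit, p_floor=cfg.p_floor)
        return float(values.mean()), p, len(used)

    records = []
    for gene, members in groups.items():
        rho, p, n = one_group(members)
        records.append((arm, gene, rho, p, n, False))
    for name, members in pseudo.items():
        rho, p, n = one_group(members)
        records.append((arm, name, rho, p, n, True))
    out = pd.DataFrame(records,
                       columns=["arm", "gene", "rho", "p", "n_used", "control"])

    filtered_out = out["n_used"] == 0
    if filtered_out.any():
        logger.warning("%d gene(s) had all sgRNAs filtered: %s",
                       filtered_out.sum(),
                       list(out.loc[filtered_out, "gene"]))

    gene_rho = out.loc[~out.control, "rho"].dropna().to_numpy()
    if cfg.sd_mode == "all_sgrnas":
        sigma = float(np.std(ph.loc[ph.passed_filter, "value"], ddof=1))
    elif cfg.sd_mode == "all_genes":
        sigma = float(np.std(gene_rho, ddof=1)) if gene_rho.size > 1 else 0.0
    else:  # control_pseudogenes
        pr = out.loc[out.control, "rho"].dropna().to_numpy()
        if pr.size < 2:
            raise StatsError("sd_mode='control_pseudogenes' needs >= 2 "
                             "pseudogenes")
        sigma = float(np.std(pr, ddof=1))

    rho_arr = out["rho"].fillna(0.0).to_numpy()
    out["score"] = _score(rho_arr, sigma, out["p"].to_numpy(), cfg.p_floor)
    out.loc[filtered_out, "score"] = 0.0
    out["hit"] = out["score"] > cfg.tau
    return out[["arm", "gene", "rho", "p", "score", "hit", "n_used", "control"]]


def analyze_arm(
    high: BinCounts,
    low: BinCounts,
    design: LibraryDesign,
    cfg: StatsConfig | None = None,
    include_pseudogenes: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts -> (sgRNA phenotypes, gene stats) for one arm."""
    cfg = cfg or StatsConfig()
    ph = sgrna_phenotypes(high, low, design, cfg)
    gs = gene_stats(ph, design, cfg, include_pseudogenes=include_pseudogenes)
    return ph, gs
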