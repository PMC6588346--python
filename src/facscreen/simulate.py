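"""Synthetic two-arm, two-bin FACS-sorted CRISPRi reporter screen.

The generator models the screen as four stochastic layers:

1. **Library and knockdown efficacy.**  ``n_genes`` genes with ``k`` sgRNAs
   each plus non-targeting negative controls.  Each targeting sgRNA gets an
   efficacy ``e ~ Beta(efficacy_alpha, efficacy_beta)`` on [0, 1] (defaults
   5, 1: most guides in a compact CRISPRi library are active, with a
   realistic within-gene spread); controls get ``e = 0`` exactly, so they
   define the null by construction.

2. **Per-cell reporter fluorescence.**  Cells per sgRNA are
   ``Poisson(coverage)``.  A cell carrying sgRNA *i* of gene *g* in arm *a*
   fluoresces ``log2F = mu0 + delta_a + e_i * (shift_{g,a} - delta_a) + eps``
   with ``eps ~ Normal(0, sigma_cell)``.  ``delta_a`` is the wild-type
   stress induction of the arm: ``delta_induction`` (default 1.0, the
   two-fold reporter induction) under stress alone, and 0 under stress plus
   the inhibitor, where reporter activation is blocked in wild-type cells.
   ``shift_{g,a}`` is the reporter level a *complete* knockdown of gene *g*
   produces in arm *a*; unspecified genes default to the wild-type regime
   (``shift_tm = delta_induction``, ``shift_tm_ceapin = 0``), so knocking
   them down changes nothing.

3. **FACS gates.**  Within each arm the pooled cells are ranked and the top
   and bottom ``gate_fraction`` (default 0.30) are collected; ties are
   broken by seeded uniform jitter so bins have exactly ``round(f*N)``
   cells.

4. **Sequencing.**  Each bin is sequenced as one multinomial draw of
   ``reads_per_bin`` reads with probabilities proportional to cell tallies
   (amplification bias beyond multinomial sampling is not modelled).
   Optionally, reads are emitted as FASTQ: constant 10-nt 5' flank +
   protospacer + constant 3' flank, 50 nt total, with an optional per-base
   substitution rate.

Ground truth (effacies, per-bin cell tallies, expected categories) is
returned alongside the counts so recovery tests can score the pipeline.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .screen_model import (
    ARMS,
    BINS,
    NEG_CTRL,
    TABLE1_PROTOSPACERS,
    BinCounts,
    LibraryDesign,
    ScreenModelError,
)

logger = logging.getLogger("facscreen")

#: Read layout constants: 10-nt 5' flank, protospacer, 3' filler to 50 nt.
READ_LENGTH = 50
PROTOSPACER_OFFSET = 10
FLANK5 = "TTGTGGAAAG"
FLANK3 = "GTTTAAGAGCTAAGCTGGAAACAGCATAGCAAGTTTAAATAAGGCTAGTC"

#: Expected-category labels carried in an :class:`EffectSpec`.
CATEGORIES = ("null", "ceapin_hit", "ceapin_independent", "reporter_inhibitor")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationParams:
    """Knobs of the synthetic screen; defaults are the screen's study scale."""

    n_genes: int = 200
    k_sgrnas_per_gene: int = 5
    n_control_sgrnas: int = 100
    coverage: float = 500.0          # expected cells per sgRNA
    mu0: float = 10.0                # baseline log2 reporter fluorescence
    sigma_cell: float = 1.0          # per-cell noise SD, log2 units
    delta_induction: float = 1.0     # wild-type stress induction (two-fold)
    gate_fraction: float = 0.30      # fraction of cells per FACS bin
    reads_per_bin: int = 2_000_000
    efficacy_alpha: float = 5.0
    efficacy_beta: float = 1.0
    mutation_rate: float = 0.0       # per-base substitution rate in FASTQ reads
    protospacer_length: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.gate_fraction < 0.5:
            raise SimulationError(
                f"gate_fraction must be in (0, 0.5), got {self.gate_fraction}"
            )
        for name in ("n_genes", "k_sgrnas_per_gene", "n_control_sgrnas",
                     "reads_per_bin"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.coverage <= 0:
            raise SimulationError("coverage must be positive")
        if self.sigma_cell < 0 or self.mutation_rate < 0 or self.mutation_rate >= 1:
            raise SimulationError("invalid noise parameters")
        if self.efficacy_alpha <= 0 or self.efficacy_beta <= 0:
            raise SimulationError("efficacy Beta shapes must be positive")


@dataclass(frozen=True)
class GeneEffect:
    """Reporter level of a complete knockdown of one gene, per arm."""

    shift_tm: float
    shift_tm_ceapin: float
    expected_category: str = "null"

    def __post_init__(self) -> None:
        if self.expected_category not in CATEGORIES:
            raise SimulationError(
                f"unknown category {self.expected_category!r}"
            )


@dataclass
class EffectSpec:
    """Mapping gene -> :class:`GeneEffect`; unlisted genes are wild-type."""

    effects: dict[str, GeneEffect] = field(default_factory=dict)

    def shift(self, gene: str, arm: str, delta_induction: float) -> float:
        eff = self.effects.get(gene)
        if eff is None:
            return delta_induction if arm == "tm" else 0.0
        return eff.shift_tm if arm == "tm" else eff.shift_tm_ceapin

    def genes_of_category(self, category: str) -> list[str]:
        return [g for g, e in self.effects.items()
                if e.expected_category == category]

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls({})


def spiked_effects(
    n_ceapin_hit: int = 3,
    n_ceapin_independent: int = 2,
    n_reporter_inhibitor: int = 2,
    delta_induction: float = 1.0,
    constitutive_shift: float = 1.5,
    gene_prefix: str = "gene",
) -> EffectSpec:
    """Standard spike-in truth for recovery runs.

    Ceapin-hit genes (ABCD3/PEX19-like) restore stress induction in the
    inhibitor arm (shift = delta in both arms); constitutive genes
    (HSPA5-like) activate the reporter in both arms; reporter-inhibitor
    genes (ATF6/MBTPS2-like) abolish induction (shift 0 in both arms).
    Spiked genes take the first library gene labels.
    """
    effects: dict[str, GeneEffect] = {}
    i = 0
    for _ in range(n_ceapin_hit):
        effects[f"{gene_prefix}{i:04d}"] = GeneEffect(
            delta_induction, delta_induction, "ceapin_hit")
        i += 1
    for _ in range(n_ceapin_independent):
        effects[f"{gene_prefix}{i:04d}"] = GeneEffect(
            constitutive_shift, constitutive_shift, "ceapin_independent")
        i += 1
    for _ in range(n_reporter_inhibitor):
        effects[f"{gene_prefix}{i:04d}"] = GeneEffect(
            0.0, 0.0, "reporter_inhibitor")
        i += 1
    return EffectSpec(effects)


@dataclass
class SimTruth:
    """Ground truth of one simulated screen."""

    effects: EffectSpec
    efficacies: pd.Series                      # sgrna_id -> e in [0, 1]
    tallies: dict[tuple[str, str], pd.Series]  # (arm, bin) -> cells per sgRNA
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "effects": {
                g: asdict(e) for g, e in self.effects.effects.items()
            },
            "efficacies": self.efficacies.round(6).to_dict(),
            "tallies": {
                f"{arm}:{bin_}": t.to_dict()
                for (arm, bin_), t in self.tallies.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Library construction


def _random_protospacers(n: int, length: int, rng: np.random.Generator,
                         taken: set[str], max_retries: int = 50) -> list[str]:
    bases = np.array(list("ACGT"))
    out: list[str] = []
    for _ in range(n):
        for attempt in range(max_retries):
            proto = "".join(bases[rng.integers(0, 4, size=length)])
            if proto not in taken:
                taken.add(proto)
                out.append(proto)
                break
        else:
            raise SimulationError(
                f"could not draw a unique {length}-mer in {max_retries} tries"
            )
    return out


def make_default_library(
    params: SimulationParams,
    spike_table1: bool = False,
    rng: np.random.Generator | None = None,
) -> LibraryDesign:
    """Random library: n_genes x k targeting sgRNAs plus negative controls.

    With ``spike_table1=True``, the individually validated protospacers whose
    length matches ``params.protospacer_length`` replace the first random
    protospacers of correspondingly named genes (e.g. ABCD3-1 -> gene
    ``ABCD3``), so sequencing fixtures can exercise real sequences.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    k, L = params.k_sgrnas_per_gene, params.protospacer_length

    taken: set[str] = set()
    spike: dict[str, list[str]] = {}
    if spike_table1:
        skipped = []
        for name, proto in TABLE1_PROTOSPACERS.items():
            if len(proto) != L or name.startswith("NegCtrl"):
                skipped.append(name)
                continue
            gene = name.split("-")[0]
            spike.setdefault(gene, []).append(proto)
            taken.add(proto)
        if skipped:
            logger.info("spike_table1: skipping %s (length != %d or control)",
                        skipped, L)

    rows = []
    spiked_genes = list(spike)
    for g in range(params.n_genes):
        if g < len(spiked_genes):
            gene = spiked_genes[g]
            protos = list(spike[gene])
        else:
            gene = f"gene{g:04d}"
            protos = []
        protos += _random_protospacers(k - len(protos), L, rng, taken)
        for j, proto in enumerate(protos):
            rows.append((f"{gene}_sg{j}", proto, gene, gene))
    for c, proto in enumerate(
        _random_protospacers(params.n_control_sgrnas, L, rng, taken)
    ):
        rows.append((f"negctrl_sg{c}", proto, NEG_CTRL, ""))
    df = pd.DataFrame(rows, columns=["sgrna_id", "protospacer", "target", "tss"])
    return LibraryDesign(df, k=k)


def draw_efficacies(
    design: LibraryDesign, params: SimulationParams, rng: np.random.Generator
) -> pd.Series:
    """Per-sgRNA knockdown efficacy: Beta for targeting guides, 0 for controls."""
    e = rng.beta(params.efficacy_alpha, params.efficacy_beta,
                 size=design.n_sgrnas)
    e[design.df.is_control.to_numpy()] = 0.0
    return pd.Series(e, index=design.sgrna_ids, name="efficacy")


# ---------------------------------------------------------------------------
# Cells, gates, sequencing


def simulate_cell_fluorescence(
    design: LibraryDesign,
    effects: EffectSpec,
    params: SimulationParams,
    arm: str,
    efficacies: pd.Series,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-cell reporter fluorescence for one arm.

    Returns ``(sg_idx, log2F)``: the library row index of each cell's sgRNA
    and its log2 fluorescence.
    """
    if arm not in ARMS:
        raise SimulationError(f"unknown arm {arm!r}")
    params.validate()
    delta = params.delta_induction if arm == "tm" else 0.0
    shifts = np.array([
        effects.shift(t, arm, params.delta_induction) if not ctrl else delta
        for t, ctrl in zip(design.df.target, design.df.is_control)
    ])
    # controls have e=0, so their shift value is irrelevant; delta keeps the
    # formula uniform.
    e = efficacies.reindex(design.sgrna_ids).to_numpy()
    cells_per_sg = rng.poisson(params.coverage, size=design.n_sgrnas)
    sg_idx = np.repeat(np.arange(design.n_sgrnas), cells_per_sg)
    mean = params.mu0 + delta + e[sg_idx] * (shifts[sg_idx] - delta)
    log2F = mean
    if params.sigma_cell > 0:
        log2F = mean + rng.normal(0.0, params.sigma_cell, size=sg_idx.size)
    return sg_idx, log2F


def gate_cells(
    log2F: np.ndarray, gate_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Assign each cell to 'high', 'low' or 'unsorted'.

    Gates are global percentiles of the pooled fluorescence within the arm;
    exactly ``round(f*N)`` cells land in each bin, ties broken by seeded
    uniform jitter.
    """
    n = log2F.size
    if n < 10:
        raise SimulationError(f"need >= 10 cells to gate, got {n}")
    if not 0 < gate_fraction < 0.5:
        raise SimulationError("gate_fraction must be in (0, 0.5)")
    n_bin = int(round(gate_fraction * n))
    order = np.lexsort((rng.random(n), log2F))
    labels = np.full(n, "unsorted", dtype=object)
    labels[order[:n_bin]] = "low"
    labels[order[n - n_bin:]] = "high"
    return labels


def tally_bins(
    design: LibraryDesign, sg_idx: np.ndarray, labels: np.ndarray
) -> dict[str, pd.Series]:
    """Cells per sgRNA in each bin."""
    out = {}
    for bin_ in BINS:
        counts = np.bincount(sg_idx[labels == bin_], minlength=design.n_sgrnas)
        out[bin_] = pd.Series(counts, index=design.sgrna_ids, name="cells")
    return out


def sequence_bin(
    tallies: pd.Series,
    reads_per_bin: int,
    rng: np.random.Generator,
    arm: str,
    bin: str,
) -> BinCounts:
    """Sequence one bin: a single multinomial draw over cell tallies."""
    total = float(tallies.sum())
    if total <= 0:
        raise SimulationError(f"no cells in bin ({arm}, {bin})")
    counts = rng.multinomial(reads_per_bin, tallies.to_numpy() / total)
    return BinCounts(arm, bin, pd.Series(counts, index=tallies.index))


def simulate_screen(
    design: LibraryDesign,
    effects: EffectSpec,
    params: SimulationParams,
) -> tuple[dict[tuple[str, str], BinCounts], SimTruth]:
    """Run the full generative model: four count tables plus ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    efficacies = draw_efficacies(design, params, rng)
    counts: dict[tuple[str, str], BinCounts] = {}
    tallies: dict[tuple[str, str], pd.Series] = {}
    for arm in ARMS:
        sg_idx, log2F = simulate_cell_fluorescence(
            design, effects, params, arm, efficacies, rng)
        labels = gate_cells(log2F, params.gate_fraction, rng)
        per_bin = tally_bins(design, sg_idx, labels)
        for bin_ in BINS:
            tallies[(arm, bin_)] = per_bin[bin_]
            counts[(arm, bin_)] = sequence_bin(
                per_bin[bin_], params.reads_per_bin, rng, arm, bin_)
    return counts, SimTruth(effects, efficacies, tallies, params.seed)


# ---------------------------------------------------------------------------
# FASTQ emission


def reads_from_counts(
    bc: BinCounts,
    design: LibraryDesign,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) triples realizing a count table.

    Reads are ``FLANK5 + protospacer + FLANK3`` truncated to 50 nt, so the
    protospacer occupies ``[10, 10 + L)``.  With ``mutation_rate > 0`` each
    base substitutes independently to one of the three other bases.
    """
    protos = dict(zip(design.df.sgrna_id, design.df.protospacer))
    bases = "ACGT"
    qual = "I" * READ_LENGTH
    r = 0
    for sg, n in bc.counts.items():
        template = (FLANK5 + protos[sg] + FLANK3)[:READ_LENGTH]
        for _ in range(int(n)):
            seq = template
            if mutation_rate > 0:
                hits = np.flatnonzero(rng.random(READ_LENGTH) < mutation_rate)
                if hits.size:
                    chars = list(seq)
                    for pos in hits:
                        alt = bases.replace(chars[pos], "")
                        chars[pos] = alt[rng.integers(0, 3)]
                    seq = "".join(chars)
            yield f"read{r}:{sg}:{bc.arm}:{bc.bin}", seq, qual
            r += 1


def write_fastq(
    reads: Iterable[tuple[str, str, str]], path: str | Path
) -> int:
    """Write reads to FASTQ (gzip when the path ends in .gz); returns count."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def simulate_growth_table(
    design: LibraryDesign,
    flagged_genes: Iterable[str] = (),
    gamma_flagged: float = -0.25,
    gamma_null_sd: float = 0.05,
    seed: int = 0,
) -> pd.Series:
    """Mock growth-screen annotation: flagged genes get a fixed growth defect,
    the rest draw from a tight null around zero."""
    rng = np.random.default_rng(seed)
    genes = design.genes
    flagged = set(flagged_genes)
    unknown = flagged - set(genes)
    if unknown:
        raise SimulationError(f"flagged genes not in library: {sorted(unknown)}")
    gamma = rng.normal(0.0, gamma_null_sd, size=len(genes)) if gamma_null_sd > 0 \
        else np.zeros(len(genes))
    out = pd.Series(gamma, index=pd.Index(genes, name="gene"), name="gamma")
    out[list(flagged)] = gamma_flagged
    return out
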